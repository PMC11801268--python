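# alistrat

Stratification and individual forecasting of prothrombin-time activity (PT%)
dynamics in acute liver injury (ALI).

## The problem

ALI is highly heterogeneous: some patients recover on their own, some respond
to intensive care, and some progress to acute liver failure (ALF) and need a
liver transplant. PT% — the prothrombin time expressed as a percentage of a
normal reference (normal 70–130%; ALF is diagnosed at PT% ≤ 40% or INR ≥ 1.5)
— tracks hepatic synthesis of coagulation factors and is the single most
informative routine biomarker of ALI status. This package implements a
complete analysis of longitudinal PT% measured on days 0, 1, 2, 3 and 7 after
admission, aimed at hepatologists and clinical-modeling researchers who want
to (a) stratify an ALI cohort by its PT% trajectory shape and (b) forecast an
individual patient's PT% course from admission data alone.

## The model and the pipeline

PT% kinetics are described by a linear balance between supply and
consumption/degradation of coagulation factors,

    dP/dt = g − D·P(t),   P(t) = g/D + (P0 − g/D)·e^(−D·t),

with supply rate *g* (PT%/day), loss rate *D* (/day) and admission value
*P0*. Around this kernel the pipeline provides:

1. **Nonlinear mixed-effects fitting** (`alistrat.nlmem`) — patient *k* has
   parameters θ·e^(η_k) with η_k ~ N(0, Ω) on the log scale and Gaussian
   residuals of SD σ; estimated by SAEM (random-walk Metropolis E-step,
   closed-form M-step) with empirical-Bayes MAP estimates per patient.
2. **Trajectory stratification** (`alistrat.trajectory_clustering`) —
   k-means under dynamic time warping with DBA centroids; at k = 6 the
   clusters are relabeled G1…G6 by descending centroid PT% (G1/G2
   self-limited, G3/G4 care-responsive, G5/G6 care-refractory).
3. **Outcome models** (`alistrat.outcome_models`) — random-forest
   classifiers of transplant-free survival (TFS vs non-TFS) and of group
   membership under stratified 5-fold CV with SMOTE rebalancing inside each
   training fold, exact TreeSHAP attribution, and the day-7 logistic PT%
   threshold (the PT% where P(non-TFS) = 0.5).
4. **Individual forecasting** (`alistrat.param_prediction`) — leave-one-out
   multi-output random forests map tiered clinical features (D0 = admission;
   Dt adds blood values through day t; DTIt adds treatment flags) to each
   patient's kinetic parameters; per-tree parameter triples give 95%
   prediction intervals for the whole trajectory.
5. **Synthetic cohorts** (`alistrat.synthetic_cohort`) — a seeded generator
   with six trajectory archetypes, lognormal inter-patient variability,
   severity-linked admission features and treatments, and outcomes drawn
   from a logistic in day-7 PT%, so the full pipeline is testable end to end
   against known ground truth.

## Worked example

```bash
$ alistrat synth --seed 1 --n 150 --out cohort/
wrote 150 patients to cohort

$ alistrat threshold --cohort cohort/
{"threshold_pt": 50.39907913151944, "cv_auc": 0.9925925925925926}

$ alistrat fit-nlmem --cohort cohort/ --seed 1 --out fit/
theta=(g=48.26, D=0.788, P0=39.33) sigma=3.05

$ alistrat cluster --cohort cohort/ --k 6 --seed 1 --out clusters/
k=6 inertia=13908.9
```

The threshold (≈ 50.4 PT%) is the day-7 PT% at which the fitted probability
of death-or-transplant is 0.5 — patients below it at day 7 are likely
non-TFS (this cohort was generated with a crossing of 50, so the estimate is
on target, and the CV AUC ≈ 0.99 says day-7 PT% alone nearly separates the
outcomes). The population fit reports the fixed effects: a median supply
rate of ~48 PT%/day, loss rate ~0.79/day (equilibrium ≈ 61 PT%) and median
admission PT% ≈ 39, with residual noise SD ≈ 3 PT%. `cluster_labels.csv`
assigns each patient to G1…G6; `alistrat run-all` chains every stage and
writes per-stage artifacts plus a manifest with checksums and seeds.

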