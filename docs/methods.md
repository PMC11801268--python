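# Methods

## Kinetic model of PT%

PT% is modeled as a linear production–elimination balance, dP/dt = g − D·P,
reflecting hepatic supply (*g*, PT%/day) and consumption/degradation (*D*,
/day) of the vitamin-K-dependent coagulation factors that the prothrombin
time measures. The closed form P(t) = g/D + (P0 − g/D)·e^(−Dt) is used
everywhere; no numerical integration enters the pipeline (a Runge–Kutta
integrator appears only as an independent test oracle). Trajectories are
monotone between P0 and the equilibrium g/D, which matches the observed
course of ALI over the first week: risers relax upward toward a recovered
plateau, non-recovering patients sit at a low equilibrium. The model has no
assay ceiling; observed PT% is clipped to [0, 200] only in the synthetic
generator, mirroring the plausible assay range.

Time is measured in days postadmission with the observation grid
{0, 1, 2, 3, 7}. Three free parameters against five observations leaves the
per-patient least-squares problem identified but ill-conditioned near
equilibrium (only g/D is then determined); the individual fit therefore uses
a log-parameterization (positivity for free), multi-start, and reports a
`degenerate` flag for flat series.

## Population model and SAEM

Patient k's parameters are θ·e^(η_k), η_k ~ N(0, Ω) with Ω diagonal — three
log-scale variances; a correlation structure is not identifiable with five
points per patient and is deliberately omitted. Residuals are additive
Gaussian with constant SD σ on the PT% scale; PT% spans 0–150 and the
absolute residual spread of fitted trajectories shows no strong
mean–variance relation, so a proportional error model was not adopted. All
three parameters carry random effects; P0 is estimated rather than pinned to
the day-0 observation because that observation is itself noisy.

Estimation is SAEM: 300 exploration iterations (stochastic-approximation
step 1) and 200 smoothing iterations (step 1/j), five Metropolis transitions
per patient per iteration. The transition kernel uses componentwise
random-walk proposals plus a joint g–D proposal along the
equilibrium-preserving ridge (adding the same increment to log g and log D),
because near-equilibrium patients constrain only g/D and the componentwise
kernel alone mixes slowly along that ridge. Proposal scales adapt toward a
30% acceptance rate. M-step updates for log θ, diag Ω and σ² are closed
form in the stochastically approximated sufficient statistics.

Two details matter for robustness on heterogeneous cohorts (which are
mixtures of trajectory shapes, i.e. deliberately misspecified for a single
lognormal population):

* **Initialization** — chains start at each patient's least-squares
  log-parameters (clipped to ±3 around the population start); the starting
  Ω is the LS log-parameter variance clipped to [0.04, 1.0] because ridge
  degeneracy can inflate raw LS variances absurdly.
* **Anti-collapse floor** — during exploration the Ω diagonal is floored at
  0.01; a variance component that hits zero freezes its chains in whatever
  mode they started from, which is the classic SAEM premature-collapse
  failure (observed as σ absorbing all dynamics with D → 0).

Empirical-Bayes individual estimates are MAP in η (L-BFGS-B, bounded at
±12, multi-start from the prior mode and the LS fit). Two provable
properties are tested: the Ω-weighted norm of the EB deviation never exceeds
that of the LS deviation, and the deviation shrinks monotonically as σ
grows. Componentwise shrinkage does *not* hold in general — the g–D ridge
can trade one component against another — and is not asserted.

A naive two-stage estimator (exponentiated mean of per-patient LS
log-parameters) serves as SAEM initializer in the degenerate-variability
tests and as an independent cross-check oracle; it is upward-biased in Ω
under noise and is never the estimator of record.

## Trajectory stratification

Dissimilarity is classic DTW with squared local cost over the step set
{(1,0),(0,1),(1,1)}, computed on raw PT% (absolute level is clinically
meaningful; z-normalization would erase the distinction between a high and a
low plateau). An optional Sakoe–Chiba window is exposed but off by default.
Series are equal-length 5-point vectors; DTW is retained anyway because the
stratification is defined in terms of temporal-pattern alignment, and the
brute-force path-enumeration oracle in the tests guarantees the DP is exact.
Centroids are DBA (align-and-average, cost non-increasing per iteration);
k-means uses k-means++-style seeding in DTW space and restarts (default 10;
uniform random seeding was observed to merge adjacent archetypes on ~1 in 5
cohorts). k is fixed at 6 for the replication path; the elbow curve is
diagnostic output, not an automatic selector. Missing PT% days are filled
from the selected imputation before clustering. With k = 6 clusters are
deterministically renamed G1…G6 by descending centroid time-average PT%
(ties by day-0 value), so G1 is always the mildest stratum regardless of the
arbitrary cluster indices.

## Outcome and group classifiers

Random forests (500 trees by default, √p features per split, probability
votes) under stratified 5-fold CV. Class imbalance (non-TFS is the minority)
is handled by SMOTE — interpolation between minority nearest neighbors —
applied **inside each training fold only**: oversampling before splitting
would place synthetic copies of test patients into training folds and
inflate the AUC. The mean ROC is the vertical average of fold ROCs on a
fixed 101-point FPR grid; the fold SD of the AUC is reported. The final
model for attribution is refit on the full resampled data, and SHAP values
are computed on the original (unresampled) patients.

SHAP uses an exact path-dependent TreeSHAP implementation (polynomial
recursion over root-to-leaf paths with the tree's own training cover as the
background distribution). Local accuracy — base value plus attribution sum
equals the forest probability — holds to machine precision and is asserted
at 1e-6; features a forest never splits on receive exactly zero.

The day-7 threshold is L2-regularized logistic regression (C = 1.0,
unstandardized single predictor) of non-TFS on day-7 PT% over all patients;
the threshold is −intercept/slope, the PT% at fitted probability 0.5.
Complete separation is flagged (regularization keeps the fit finite).
Group-membership models are one-vs-rest forests on admission features for
G3–G6 only; admission PT% alone separates G1/G2 from the rest, so those
targets are uninteresting by construction.

## Tiered trajectory prediction

Feature tiers: D0 = imputed admission features; Dt appends day-stamped blood
columns for 0 < day ≤ t; DTIt appends the four treatment flags for day ≤ t.
Column counts are non-decreasing along D0→D7 and D→DTI by construction.

For each patient a multi-output random forest is trained on all *other*
patients (leave-one-out), each tree predicting a coherent (g, D, P0) triple
from one training leaf — this is what makes per-tree trajectory ensembles
meaningful; three independent single-output forests would scramble the
joint. Targets are the empirical-Bayes parameters on the natural scale (tree
predictions are averages of positive training values, hence positive). The
trajectory mean uses the ensemble-mean parameters; the 95% band is the
pointwise 2.5th/97.5th percentile (linear interpolation, i.e. type-7) over
per-tree closed-form trajectories. RMSE per patient is computed against
observed PT% on the full day grid — days whose blood values entered the
features are not excluded — and the determination coefficient pools
fitted-model and RF-predicted values over all patients and days (the per-day
R² vector is also reported). The by-day-2 improvement fraction is
(RMSE(D0) − RMSE(D2)) / (RMSE(D0) − RMSE(D7)); the formula is isolated in
one function so an alternative reading of "total RMSE difference" can be
swapped in.

Known limitation: the per-tree band reflects forest parameter uncertainty
only, not residual observation noise, so its empirical coverage of noisy
observations sits near the lower end of the nominal range (≈ 84–90% in the
synthetic experiments) and narrows further as features become more
informative.

## Synthetic cohort generator

The generator emulates the structure of a single-center ALI registry:

* **Archetypes** — six groups with medians (g, D, P0): G1 (45, 0.50, 85),
  G2 (68, 0.80, 60), G3 (96, 1.20, 35), G4 (41.25, 0.55, 28),
  G5 (22.5, 0.50, 40), G6 (12, 0.40, 25); equilibria 90/85/80/75/45/30 PT%.
  P0 and g/D follow the qualitative shapes of the observed strata (high- and
  moderate-stable, fast and slow risers, low-stable, non-recovering); D is a
  package choice separating fast from slow risers. Prevalences follow the
  observed group sizes 31/66/42/70/55/55 in a 319-patient cohort.
* **Variability and noise** — lognormal per-parameter SDs of 0.06 within
  each archetype and additive Gaussian observation noise of SD 3 PT%,
  clipped to [0, 200]. The archetypes themselves carry the between-patient
  heterogeneity (admission PT% 25–85, equilibria 30–90); the within-group
  SD is set so that the six strata remain distinguishable trajectories
  rather than a continuum, which is the premise of the stratification
  analysis.
* **Outcome** — non-TFS is drawn from a logistic in the *noiseless* day-7
  PT%, crossing 50 PT%, steepness 0.3/PT%. This makes the day-7 threshold
  recoverable by construction and ties prognosis to the trajectory, not to
  noise.
* **Admission features** — transaminases (AST/ALT/LDH) scale with g,
  antithrombin III with D, cholinesterase with P0, albumin/platelets with
  the equilibrium, and a liver-atrophy flag is enriched at low equilibrium;
  age, sex, etiology, BUN and creatinine are uninformative background.
  These links are what give the admission-tier forests their signal.
* **Treatments** — four intensive-care flags (plasma exchange, steroid
  pulse, anticoagulation, hemodiafiltration) drawn per day with probability
  a logistic in the noiseless PT% that day: severity-triggered and therefore
  redundant with the blood data, making "treatment information does not
  improve the forecasts" a testable property of the synthetic world.
* **Missingness** — injected completely at random per variable (default cap
  20%); day-0/day-7 PT% and the outcome are protected, as in a registry
  where the defining measurements are always recorded.

What the generator does **not** emulate: etiology-specific dynamics,
encephalopathy grades, causal treatment effects, informative missingness,
assay change-points over 14 years of recruitment, or inter-center
differences. Passing tests on this cohort therefore demonstrate correctness
and internal consistency of the estimation/stratification machinery, not
clinical transportability.

## Preprocessing

Variables missing in more than 20% of patients are excluded (exactly 20% is
retained). Categoricals are full-dummy coded (k indicators for k levels —
tree ensembles are indifferent to the collinearity, and full coding keeps
every level attributable in SHAP); encoding precedes imputation, and
indicator cells of a missing categorical are imputed as binaries. Imputation
is chained equations with predictive-mean matching (donor pool 5, 10
sweeps): numeric columns match on a linear predicted mean, indicator columns
on a logistic score, so imputed values always come from the observed
support. One completion is the representative analysis set; m up to 50 is
used for sensitivity (across 50 completions the downstream classifier AUC
SD is < 0.005 in the shipped test). Observed cells are never altered.
Rubin-style pooling of estimates is out of scope.

## Problem sizes and determinism

Default experiment sizes were chosen for single-CPU runs: synthetic cohorts
of n = 150 (pipeline default) and n = 300 for clustering experiments; SAEM
recovery studies use 10 cohorts of n = 200; leave-one-out forests use
120–200 trees in tests and 150–200 in the acceptance script (500 remains
the library default for analysis use). Every stochastic component takes an
explicit seed; the pipeline fans a single global seed out to per-stage seeds
via `numpy.random.SeedSequence`, records them in the run manifest, and
reruns with the same config are byte-identical.
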