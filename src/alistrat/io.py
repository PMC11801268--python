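"""Reading and writing per-patient cohort tables.

A cohort on disk is three text files in one directory:

* ``daily.csv`` — long format ``id, day, variable, value`` holding the PT%
  series (variable ``PT``), day-stamped labs and treatment flags
  (``treat_<name>``);
* ``admission.csv`` — wide per-patient admission features plus ``outcome``;
* ``meta.json`` — variable metadata, generator seed and (synthetic cohorts
  only) the true kinetic parameters and archetype labels.

UTF-8, "." decimal, integer day stamps.  The reader is tolerant: unknown
admission columns are carried along as features.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from alistrat.pt_model import PTParams
from alistrat.synthetic_cohort import Cohort, PatientRecord, TREATMENT_NAMES

__all__ = ["write_cohort", "load_deposited"]


def write_cohort(cohort: Cohort, outdir, seed: int | None = None) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for p in cohort.patients:
        for t, v in zip(p.times, p.pt_obs):
            if np.isfinite(v):
                rows.append((p.id, int(t), "PT", float(v)))
        for day, labs in p.labs_daily.items():
            for name, v in labs.items():
                if v is not None and np.isfinite(v):
                    rows.append((p.id, int(day), name, float(v)))
        for name, per_day in p.treatments.items():
            for day, flag in per_day.items():
                rows.append((p.id, int(day), f"treat_{name}", int(flag)))
    daily = pd.DataFrame(rows, columns=["id", "day", "variable", "value"])
    daily_path = outdir / "daily.csv"
    daily.to_csv(daily_path, index=False)

    adm = pd.DataFrame(
        [{"id": p.id, **p.features_admission, "outcome": p.outcome} for p in cohort.patients]
    )
    adm_path = outdir / "admission.csv"
    adm.to_csv(adm_path, index=False)

    meta = {
        "seed": seed,
        "variable_meta": cohort.variable_meta,
        "truth": {
            p.id: {
                "group": p.true_group,
                "g": p.true_params.g if p.true_params else None,
                "D": p.true_params.D if p.true_params else None,
                "P0": p.true_params.P0 if p.true_params else None,
            }
            for p in cohort.patients
            if p.true_params is not None or p.true_group is not None
        },
    }
    meta_path = outdir / "meta.json"
    meta_path.write_text(json.dumps(meta, indent=1))
    return {"daily": daily_path, "admission": adm_path, "meta": meta_path}


def load_deposited(path) -> Cohort:
    """Load a cohort directory (deposited or generator-written) into memory.

    Validates PT% in [0, 200] (out-of-range rows dropped with a count kept
    in ``variable_meta['_load_report']``) and requires ``id`` and ``outcome``
    columns in the admission table.  Unknown admission columns are carried
    as features.
    """
    path = Path(path)
    daily_path, adm_path = path / "daily.csv", path / "admission.csv"
    for f in (daily_path, adm_path):
        if not f.exists():
            raise FileNotFoundError(f"required cohort file missing: {f}")
    daily = pd.read_csv(daily_path)
    for col in ("id", "day", "variable", "value"):
        if col not in daily.columns:
            raise ValueError(f"daily table is missing required column '{col}'")
    adm = pd.read_csv(adm_path)
    for col in ("id", "outcome"):
        if col not in adm.columns:
            raise ValueError(f"admission table is missing required column '{col}'")

    meta: dict = {}
    if (path / "meta.json").exists():
        meta = json.loads((path / "meta.json").read_text())
    truth = meta.get("truth", {})

    pt = daily[daily["variable"] == "PT"].copy()
    bad = ~pt["value"].between(0.0, 200.0)
    n_bad = int(bad.sum())
    pt = pt[~bad]

    labs = daily[~daily["variable"].str.startswith("treat_") & (daily["variable"] != "PT")]
    treats = daily[daily["variable"].str.startswith("treat_")]

    patients = []
    for _, arow in adm.iterrows():
        pid = str(arow["id"])
        sub = pt[pt["id"] == pid].sort_values("day")
        feats = {
            k: (None if pd.isna(v) else v)
            for k, v in arow.items()
            if k not in ("id", "outcome")
        }
        lsub = labs[labs["id"] == pid]
        labs_daily: dict[int, dict[str, float]] = {}
        for _, r in lsub.iterrows():
            labs_daily.setdefault(int(r["day"]), {})[str(r["variable"])] = float(r["value"])
        tsub = treats[treats["id"] == pid]
        treatments: dict[str, dict[int, int]] = {name: {} for name in TREATMENT_NAMES}
        for _, r in tsub.iterrows():
            name = str(r["variable"]).removeprefix("treat_")
            treatments.setdefault(name, {})[int(r["day"])] = int(r["value"])
        tp = truth.get(pid, {})
        true_params = (
            PTParams(g=tp["g"], D=tp["D"], P0=tp["P0"])
            if tp.get("g") is not None
            else None
        )
        patients.append(
            PatientRecord(
                id=pid,
                times=sub["day"].to_numpy(dtype=float),
                pt_obs=sub["value"].to_numpy(dtype=float),
                features_admission=feats,
                treatments=treatments,
                outcome=str(arow["outcome"]),
                labs_daily=labs_daily,
                true_params=true_params,
                true_group=tp.get("group"),
            )
        )
    variable_meta = meta.get("variable_meta", {})
    variable_meta["_load_report"] = {
        "n_patients": len(patients),
        "n_pt_rows_dropped": n_bad,
    }
    return Cohort(patients=patients, variable_meta=variable_meta)
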