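"""Balanced stratified k-fold splitting of a survival cohort.

Patients are stratified by the half-year bin of their observed survival time
(``floor(2 t)`` with t in years, half-open bins) crossed with the event
indicator, then dealt round-robin into folds after a seeded shuffle within
each stratum.  This keeps per-fold survival-time and event-rate composition
within one patient of proportional allocation — the balanced-partition goal —
and a standardized-mean-difference (SMD) report over arbitrary covariates
verifies comparability of the train/test cohorts for each fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SMD_FLAG_THRESHOLD = 0.1


@dataclass(frozen=True)
class StratumLabel:
    half_year_bin: int
    event: int


@dataclass
class FoldSplit:
    fold_index: int  # 1-based
    train_ids: tuple
    test_ids: tuple


def assign_strata(times_years, events) -> list[StratumLabel]:
    """Half-year survival bin (floor(2 t)) crossed with the event indicator."""
    t = np.asarray(times_years, dtype=np.float64).ravel()
    e = np.asarray(events).ravel().astype(int)
    if (t <= 0).any():
        raise ValueError("survival times must be positive")
    bins = np.floor(2.0 * t).astype(int)
    return [StratumLabel(int(b), int(ev)) for b, ev in zip(bins, e)]


def make_folds(patient_ids, times_years, events, k: int = 5, seed: int = 0) -> list[FoldSplit]:
    """Stratified randomized k-fold partition (test sets disjoint, exhaustive).

    Within each (half-year bin, event) stratum, patients are shuffled with the
    seed and dealt round-robin to folds, so per-stratum fold sizes differ by
    at most one.
    """
    ids = list(patient_ids)
    n = len(ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds cohort size {n}")
    strata = assign_strata(times_years, events)
    rng = np.random.default_rng(seed)
    fold_of = {}
    by_stratum: dict[StratumLabel, list] = {}
    for pid, s in zip(ids, strata):
        by_stratum.setdefault(s, []).append(pid)
    # deterministic stratum order, then per-stratum shuffle + round-robin
    offset = 0
    for s in sorted(by_stratum, key=lambda s: (s.half_year_bin, s.event)):
        members = by_stratum[s]
        rng.shuffle(members)
        for i, pid in enumerate(members):
            fold_of[pid] = (offset + i) % k
        offset += len(members)  # stagger so small strata spread across folds
    folds = []
    for f in range(k):
        test = tuple(pid for pid in ids if fold_of[pid] == f)
        train = tuple(pid for pid in ids if fold_of[pid] != f)
        folds.append(FoldSplit(fold_index=f + 1, train_ids=train, test_ids=test))
    return folds


def balance_report(split: FoldSplit, covariates: pd.DataFrame) -> pd.DataFrame:
    """Standardized mean differences between train and test cohorts.

    ``covariates`` is indexed by patient id; numeric columns are compared as
    means over pooled standard deviations, with complete-case handling per
    covariate.  |SMD| > 0.1 is flagged as imbalance.
    """
    rows = []
    train = covariates.loc[[i for i in split.train_ids if i in covariates.index]]
    test = covariates.loc[[i for i in split.test_ids if i in covariates.index]]
    for col in covariates.columns:
        a = pd.to_numeric(train[col], errors="coerce").dropna()
        b = pd.to_numeric(test[col], errors="coerce").dropna()
        if len(a) < 2 or len(b) < 2:
            rows.append({"covariate": col, "smd": np.nan, "flagged": False,
                         "n_train": len(a), "n_test": len(b)})
            continue
        pooled_sd = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
        smd = 0.0 if pooled_sd == 0 else float((a.mean() - b.mean()) / pooled_sd)
        rows.append(
            {
                "covariate": col,
                "smd": smd,
                "flagged": abs(smd) > SMD_FLAG_THRESHOLD,
                "n_train": len(a),
                "n_test": len(b),
            }
        )
    return pd.DataFrame(rows).set_index("covariate")


def folds_to_frame(folds: list[FoldSplit]) -> pd.DataFrame:
    """Long-format split table (patient_id, fold, role) for CSV export."""
    rows = []
    for f in folds:
        rows += [{"patient_id": p, "fold": f.fold_index, "role": "train"} for p in f.train_ids]
        rows += [{"patient_id": p, "fold": f.fold_index, "role": "test"} for p in f.test_ids]
    return pd.DataFrame(rows)
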