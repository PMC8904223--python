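"""Cleaning, imputation, cohort splitting and the Charlson index.

The cleaning rules follow standard EHR practice for readmission modeling:
lab/vital values outside a plausible physiological range are treated as
recording errors and nulled; remaining missing values are imputed with the
median of the *training* cohort only; the cohort is split either randomly
(80/20 by default) or with a temporal holdout stratum kept aside as the
test set and the remainder split at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .synthetic_cohort import EVENT_COL, ID_COL, TIME_COL

__all__ = [
    "RangeMap",
    "default_ranges",
    "flag_outliers",
    "MedianImputer",
    "impute_median",
    "SplitScheme",
    "split_cohort",
    "charlson_index",
    "CHARLSON_WEIGHTS",
]

#: plausible physiological ranges, inclusive bounds, in each variable's units
RangeMap = Mapping[str, tuple[float, float]]

_PROTECTED = (ID_COL, TIME_COL, EVENT_COL)


def default_ranges() -> dict[str, tuple[float, float]]:
    """Plausible-range table for the packaged vitals and labs.

    Only SpO2 (cannot exceed 100%) and non-negativity are externally fixed
    rules; the remaining bounds are deliberately wide implementation
    defaults documented here, not clinical reference ranges.
    """
    return {
        "spo2": (0.0, 100.0),
        "temperature": (25.0, 45.0),
        "heart_rate": (0.0, 300.0),
        "systolic_bp": (0.0, 300.0),
        "diastolic_bp": (0.0, 250.0),
        "creatinine": (0.0, 4000.0),
        "albumin": (0.0, 70.0),
        "sodium": (80.0, 200.0),
        "hemoglobin": (0.0, 25.0),
        "bicarbonate": (0.0, 60.0),
        "potassium": (0.0, 12.0),
    }


def flag_outliers(
    table: pd.DataFrame, ranges: RangeMap | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Null values outside their plausible physiological range.

    Values strictly below the lower or strictly above the upper inclusive
    bound become missing; everything else is untouched.  Returns the cleaned
    copy and the per-variable count of nulled cells.
    """
    if ranges is None:
        ranges = default_ranges()
    bad = [c for c in ranges if c in _PROTECTED]
    if bad:
        raise ValueError(f"RangeMap must not reference outcome/id columns: {bad}")
    out = table.copy()
    counts = {}
    for col, (lo, hi) in ranges.items():
        if col not in out.columns:
            continue
        if lo >= hi:
            raise ValueError(f"range for {col!r} has lower >= upper")
        x = out[col].astype(float).to_numpy()
        mask = (~np.isnan(x)) & ((x < lo) | (x > hi))
        counts[col] = int(mask.sum())
        if mask.any():
            x[mask] = np.nan
            out[col] = x
    return out, pd.Series(counts, dtype=int)


class MedianImputer(BaseEstimator, TransformerMixin):
    """Impute missing values with training-cohort column medians.

    Parameters
    ----------
    columns : list of str, optional
        Columns to impute.  Default: every float-dtype column except the
        outcome and identifier columns.  Even-count medians are the mean of
        the two central order statistics (numpy convention).
    """

    def __init__(self, columns: Sequence[str] | None = None):
        self.columns = columns

    def fit(self, X: pd.DataFrame, y=None) -> "MedianImputer":
        cols = self.columns
        if cols is None:
            cols = [
                c for c in X.columns
                if c not in _PROTECTED and pd.api.types.is_float_dtype(X[c])
            ]
        medians = {}
        for c in cols:
            if c not in X.columns:
                raise KeyError(f"imputable column {c!r} not in training table")
            vals = X[c].astype(float)
            if vals.notna().sum() == 0:
                raise ValueError(f"column {c!r} has no non-missing training values")
            medians[c] = float(vals.median())
        self.columns_ = list(cols)
        self.medians_ = pd.Series(medians, dtype=float)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        for c in self.columns_:
            if c in out.columns:
                out[c] = out[c].astype(float).fillna(self.medians_[c])
        return out


def impute_median(
    train: pd.DataFrame,
    others: Sequence[pd.DataFrame] = (),
    columns: Sequence[str] | None = None,
) -> tuple[list[pd.DataFrame], pd.Series]:
    """Training-median imputation of train and any further tables.

    Returns ``([train_filled, *others_filled], medians)``; the medians come
    from the training partition only.
    """
    if len(train) == 0:
        raise ValueError("training table is empty")
    imp = MedianImputer(columns=columns).fit(train)
    tables = [imp.transform(train)] + [imp.transform(t) for t in others]
    return tables, imp.medians_


@dataclass(frozen=True)
class SplitScheme:
    """Cohort-splitting recipe.

    mode "random": shuffle and split at ``train_fraction`` (test empty).
    mode "temporal+random": rows whose ``temporal_key`` value is in
    ``holdout_values`` form the test set; the remainder is randomly split
    train/validation at ``train_fraction``.
    """

    mode: str = "random"
    train_fraction: float = 0.8
    temporal_key: str | None = None
    holdout_values: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.mode not in ("random", "temporal+random"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if self.mode == "temporal+random" and self.temporal_key is None:
            raise ValueError("temporal+random split requires temporal_key")


def split_cohort(
    table: pd.DataFrame, scheme: SplitScheme
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Partition episodes into (train, validation, test).

    Pure partition: row content is never mutated, partitions are disjoint
    and exhaustive, and the result is reproducible from ``scheme.seed``.
    """
    if scheme.mode == "temporal+random":
        if scheme.temporal_key not in table.columns:
            raise KeyError(f"temporal_key {scheme.temporal_key!r} not in table")
        hold = table[scheme.temporal_key].isin(scheme.holdout_values)
        test = table.loc[hold]
        rest = table.loc[~hold]
    else:
        test = table.iloc[0:0]
        rest = table
    if len(rest) == 0:
        raise ValueError("no rows left outside the holdout stratum")
    rng = np.random.default_rng(scheme.seed)
    perm = rng.permutation(len(rest))
    n_train = int(round(scheme.train_fraction * len(rest)))
    train = rest.iloc[np.sort(perm[:n_train])]
    validation = rest.iloc[np.sort(perm[n_train:])]
    return train, validation, test


#: classic Charlson weights over comorbidity flag columns
CHARLSON_WEIGHTS: dict[str, int] = {
    "myocardial_infarction": 1,
    "heart_failure": 1,
    "peripheral_vascular": 1,
    "stroke": 1,
    "dementia": 1,
    "chronic_pulmonary": 1,
    "rheumatologic": 1,
    "peptic_ulcer": 1,
    "liver_disease": 1,
    "hemiplegia": 2,
    "renal_disease": 2,
    "aids": 6,
}

_DIABETES_WEIGHTS = {"none": 0, "uncomplicated": 1, "complicated": 2}
_MALIGNANCY_WEIGHTS = {"none": 0, "local": 2, "metastatic": 6}


def charlson_index(episodes: pd.DataFrame) -> np.ndarray:
    """Charlson Comorbidity Index from condition flags (classic weights).

    Flag columns carry the 1/2/6-tier weights in :data:`CHARLSON_WEIGHTS`;
    the graded conditions are the ``diabetes`` column (none/uncomplicated/
    complicated -> 0/1/2) and ``malignancy`` (none/local/metastatic ->
    0/2/6).  A missing column raises.
    """
    total = np.zeros(len(episodes), dtype=int)
    for col, w in CHARLSON_WEIGHTS.items():
        if col not in episodes.columns:
            raise KeyError(f"Charlson flag column {col!r} missing")
        total += w * episodes[col].astype(int).to_numpy()
    for col, weights in (("diabetes", _DIABETES_WEIGHTS), ("malignancy", _MALIGNANCY_WEIGHTS)):
        if col not in episodes.columns:
            raise KeyError(f"Charlson column {col!r} missing")
        total += episodes[col].map(weights).astype(int).to_numpy()
    return total
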