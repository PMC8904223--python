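"""Point-based clinical score tables and their application to episode data.

A point-based survival score maps each predictor to a small set of ordered
categories, attaches a non-negative integer number of points to every
category, and sums the per-variable points into a total that stratifies
time-to-event risk.  This module provides the :class:`ScoreTable` container,
scoring of episode tables, the packaged score tables for SERAP (six-variable
Score for Emergency ReAdmission Prediction), the LACE index and the HOSPITAL
score, and Kaplan-Meier risk profiles per score band.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = [
    "ScoreVariable",
    "ScoreTable",
    "RiskProfile",
    "apply_score",
    "score_range",
    "max_component",
    "risk_profile",
    "builtin_tables",
    "serap_table",
    "lace_table",
    "hospital_table",
]


class ScoringError(ValueError):
    """Raised when an episode cannot be scored under a table."""


@dataclass(frozen=True)
class ScoreVariable:
    """One scored predictor: an ordered set of categories with integer points.

    ``kind`` is ``"interval"`` for continuous/count predictors binned at
    ``boundaries`` (closed-open on the left boundary: bins are
    ``(-inf, b1), [b1, b2), ..., [bk, +inf)``), or ``"categorical"`` for
    predictors matched by exact level value.  ``points`` has one entry per
    bin/level.
    """

    name: str
    kind: str  # "interval" | "categorical"
    points: tuple[int, ...]
    boundaries: tuple[float, ...] = ()
    levels: tuple[Any, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("interval", "categorical"):
            raise ValueError(f"unknown variable kind {self.kind!r}")
        if self.kind == "interval":
            b = np.asarray(self.boundaries, dtype=float)
            if b.size + 1 != len(self.points):
                raise ValueError(
                    f"{self.name}: {b.size} boundaries need {b.size + 1} point values"
                )
            if b.size and not np.all(np.diff(b) > 0):
                raise ValueError(f"{self.name}: boundaries must be strictly increasing")
        else:
            if len(self.levels) != len(self.points):
                raise ValueError(f"{self.name}: levels and points length mismatch")
            if len(set(self.levels)) != len(self.levels):
                raise ValueError(f"{self.name}: duplicate category levels")
        if any((not float(p).is_integer()) or p < 0 for p in self.points):
            raise ValueError(f"{self.name}: points must be non-negative integers")
        if min(self.points) != 0:
            raise ValueError(f"{self.name}: at least one category must carry 0 points")

    @property
    def n_categories(self) -> int:
        return len(self.points)

    def category_labels(self) -> list[str]:
        if self.kind == "categorical":
            return [str(v) for v in self.levels]
        b = list(self.boundaries)
        if not b:
            return ["any"]
        labels = [f"<{b[0]:g}"]
        labels += [f"[{lo:g},{hi:g})" for lo, hi in zip(b[:-1], b[1:])]
        labels.append(f">={b[-1]:g}")
        return labels

    def assign(self, values: np.ndarray | pd.Series) -> np.ndarray:
        """Map raw values to integer points for this variable."""
        values = pd.Series(values)
        if self.kind == "interval":
            x = values.to_numpy(dtype=float)
            if np.isnan(x).any():
                bad = int(np.flatnonzero(np.isnan(x))[0])
                raise ScoringError(
                    f"variable {self.name!r}: missing value at episode index {bad}; "
                    "impute before scoring"
                )
            idx = np.searchsorted(np.asarray(self.boundaries, dtype=float), x, side="right")
            return np.asarray(self.points, dtype=int)[idx]
        lookup = {lvl: pt for lvl, pt in zip(self.levels, self.points)}
        out = np.empty(len(values), dtype=int)
        for i, v in enumerate(values.to_numpy()):
            key = v
            if key not in lookup:
                # tolerate float/int flag mismatch (0.0 vs 0)
                if isinstance(v, float) and not math.isnan(v) and v.is_integer():
                    key = int(v)
                if key not in lookup:
                    raise ScoringError(
                        f"variable {self.name!r}: unmapped category {v!r} at episode index {i}"
                    )
            out[i] = lookup[key]
        return out


@dataclass(frozen=True)
class ScoreTable:
    """An additive integer point-score over categorized predictors."""

    name: str
    variables: tuple[ScoreVariable, ...]
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in score table")

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    def apply(self, episodes: pd.DataFrame) -> np.ndarray:
        missing = [v.name for v in self.variables if v.name not in episodes.columns]
        if missing:
            raise ScoringError(f"table {self.name!r}: episodes lack columns {missing}")
        total = np.zeros(len(episodes), dtype=int)
        for v in self.variables:
            total += v.assign(episodes[v.name])
        return total

    def score_range(self) -> tuple[int, int]:
        lo = sum(min(v.points) for v in self.variables)
        hi = sum(max(v.points) for v in self.variables)
        return int(lo), int(hi)

    def max_component(self) -> tuple[str, int]:
        best_name, best_pts = self.variables[0].name, max(self.variables[0].points)
        for v in self.variables[1:]:
            if max(v.points) > best_pts:
                best_name, best_pts = v.name, max(v.points)
        return best_name, int(best_pts)

    # -- JSON dialect -------------------------------------------------
    def to_dict(self) -> dict:
        out: dict[str, Any] = {"name": self.name, "variables": [], "metadata": dict(self.metadata)}
        for v in self.variables:
            d: dict[str, Any] = {"name": v.name, "kind": v.kind, "points": list(v.points)}
            if v.kind == "interval":
                d["boundaries"] = list(v.boundaries)
            else:
                d["levels"] = list(v.levels)
            d["labels"] = v.category_labels()
            out["variables"].append(d)
        return out

    def to_json(self, path=None, **kwargs) -> str | None:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, default=str, **kwargs)
        if path is None:
            return text
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text + "\n")
        return None

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ScoreTable":
        variables = []
        for v in d["variables"]:
            variables.append(
                ScoreVariable(
                    name=v["name"],
                    kind=v["kind"],
                    points=tuple(int(p) for p in v["points"]),
                    boundaries=tuple(v.get("boundaries", ())),
                    levels=tuple(v.get("levels", ())),
                )
            )
        return cls(name=d["name"], variables=tuple(variables), metadata=d.get("metadata", {}))

    @classmethod
    def from_json(cls, path) -> "ScoreTable":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Thin functional wrappers (spec surface)
# ---------------------------------------------------------------------------

def apply_score(table: ScoreTable, episodes: pd.DataFrame) -> np.ndarray:
    """Additive per-episode point total under ``table``."""
    return table.apply(episodes)


def score_range(table: ScoreTable) -> tuple[int, int]:
    """(minimum, maximum) achievable total of ``table``."""
    return table.score_range()


def max_component(table: ScoreTable) -> tuple[str, int]:
    """Variable contributing the largest maximum points (ties: table order)."""
    return table.max_component()


# ---------------------------------------------------------------------------
# Published score tables
# ---------------------------------------------------------------------------

def serap_table() -> ScoreTable:
    """The published six-variable SERAP point table.

    Units: creatinine in µmol/L, albumin in g/L, age in years; prior-year ED
    admissions is a count.  Interval bins are closed-open on the left
    boundary, so e.g. creatinine scores 0 for 65 <= x < 105.
    """
    return ScoreTable(
        name="SERAP",
        variables=(
            ScoreVariable(
                "ed_admissions_last_year", "interval",
                boundaries=(1, 3, 5, 7, 10), points=(0, 7, 10, 13, 15, 19),
            ),
            ScoreVariable("age", "interval", boundaries=(30, 50, 80), points=(0, 2, 4, 5)),
            ScoreVariable(
                "malignancy", "categorical",
                levels=("none", "local", "metastatic"), points=(0, 2, 7),
            ),
            ScoreVariable("renal_disease", "categorical", levels=(0, 1), points=(0, 2)),
            ScoreVariable("creatinine", "interval", boundaries=(65, 105), points=(1, 0, 2)),
            ScoreVariable(
                "albumin", "interval", boundaries=(24, 31, 35, 40), points=(5, 3, 2, 1, 0),
            ),
        ),
        metadata={"source": "published SERAP score table", "units": {
            "age": "years", "creatinine": "umol/L", "albumin": "g/L"}},
    )


def lace_table() -> ScoreTable:
    """LACE index (van Walraven et al., CMAJ 2010): length of stay, acuity,
    Charlson comorbidity index, ED visits in the prior six months."""
    return ScoreTable(
        name="LACE",
        variables=(
            ScoreVariable(
                "length_of_stay", "interval",
                boundaries=(1, 2, 3, 4, 7, 14), points=(0, 1, 2, 3, 4, 5, 7),
            ),
            ScoreVariable("acute_admission", "categorical", levels=(0, 1), points=(0, 3)),
            ScoreVariable(
                "charlson_index", "interval", boundaries=(1, 2, 3, 4), points=(0, 1, 2, 3, 5),
            ),
            ScoreVariable("ed_visits_6m", "interval", boundaries=(1, 2, 3, 4),
                          points=(0, 1, 2, 3, 4)),
        ),
        metadata={"source": "van Walraven et al. 2010, CMAJ 182(6):551-557",
                  "units": {"length_of_stay": "days"}},
    )


def hospital_table() -> ScoreTable:
    """HOSPITAL score (Donzé et al., JAMA Intern Med 2013): hemoglobin,
    oncology discharge, sodium, procedure, admission type, prior-year
    admissions, length of stay."""
    return ScoreTable(
        name="HOSPITAL",
        variables=(
            ScoreVariable("hemoglobin", "interval", boundaries=(12,), points=(1, 0)),
            ScoreVariable("oncology_discharge", "categorical", levels=(0, 1), points=(0, 2)),
            ScoreVariable("sodium", "interval", boundaries=(135,), points=(1, 0)),
            ScoreVariable("procedure", "categorical", levels=(0, 1), points=(0, 1)),
            ScoreVariable("admission_type_urgent", "categorical", levels=(0, 1), points=(0, 1)),
            ScoreVariable("admissions_last_year", "interval", boundaries=(2, 6), points=(0, 2, 5)),
            ScoreVariable("length_of_stay", "interval", boundaries=(5,), points=(0, 2)),
        ),
        metadata={"source": "Donzé et al. 2013, JAMA Intern Med 173(8):632-638",
                  "units": {"hemoglobin": "g/dL", "sodium": "mmol/L",
                            "length_of_stay": "days"}},
    )


def builtin_tables() -> dict[str, ScoreTable]:
    """Validated packaged tables: SERAP, LACE, HOSPITAL."""
    return {"SERAP": serap_table(), "LACE": lace_table(), "HOSPITAL": hospital_table()}


# ---------------------------------------------------------------------------
# Risk profiles per score band
# ---------------------------------------------------------------------------

@dataclass
class RiskProfile:
    """Per score band: cohort fraction, percentile readmission times, and
    Kaplan-Meier readmission probabilities at fixed horizons.

    Percentile times beyond the administrative horizon carry the sentinel
    ``inf`` internally and serialize as ``">{horizon}"``.
    """

    bands: list[tuple[int, int]]
    n_per_band: list[int]
    fractions: list[float]
    percentiles: tuple[float, ...]
    percentile_times: list[dict[float, float]]  # inf => beyond horizon
    horizons: tuple[float, ...]
    probabilities: list[dict[float, float]]  # readmission probability (1 - S)
    horizon: float = 90.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for band, n, frac, ptimes, probs in zip(
            self.bands, self.n_per_band, self.fractions,
            self.percentile_times, self.probabilities,
        ):
            row: dict[str, Any] = {
                "band": f"{band[0]}-{band[1]}",
                "n": n,
                "fraction": frac,
            }
            for p in self.percentiles:
                t = ptimes[p]
                row[f"p{int(round(p * 100))}_time_days"] = (
                    f">{self.horizon:g}" if np.isinf(t) else t
                )
            for h in self.horizons:
                row[f"readmission_prob_{int(h)}d"] = probs[h]
            rows.append(row)
        return pd.DataFrame(rows)


def risk_profile(
    scores: np.ndarray,
    episodes: pd.DataFrame,
    bands: Sequence[tuple[int, int]],
    horizons: Sequence[float] = (7, 14, 30, 60, 90),
    percentiles: Sequence[float] = (0.10, 0.25, 0.50),
    *,
    time_col: str = "time_days",
    event_col: str = "event",
    horizon: float = 90.0,
) -> RiskProfile:
    """Kaplan-Meier risk profile of ``scores`` stratified into ``bands``.

    Bands are closed integer intervals ``[lo, hi]`` that must partition the
    achievable score range.  Within each band the product-limit estimate of
    the readmission (cumulative incidence) curve yields the probability at
    each horizon and the infimum time at which it reaches each percentile;
    percentile times never reached inside the administrative window are the
    ``inf`` sentinel (rendered ``">90"``).
    """
    scores = np.asarray(scores)
    if len(scores) != len(episodes):
        raise ValueError("scores and episodes are not aligned")
    times = episodes[time_col].to_numpy(dtype=float)
    events = episodes[event_col].to_numpy(dtype=int)
    n_total = len(scores)
    n_per_band, fractions, ptimes_all, probs_all = [], [], [], []
    for lo, hi in bands:
        mask = (scores >= lo) & (scores <= hi)
        n = int(mask.sum())
        n_per_band.append(n)
        fractions.append(n / n_total if n_total else float("nan"))
        if n == 0:
            warnings.warn(f"empty score band [{lo}, {hi}]; estimates undefined")
            ptimes_all.append({p: float("nan") for p in percentiles})
            probs_all.append({h: float("nan") for h in horizons})
            continue
        km = KaplanMeierFitter()
        km.fit(times[mask], events[mask])
        surv = km.survival_function_.iloc[:, 0]
        probs_all.append({h: float(1.0 - km.predict(h)) for h in horizons})
        incidence = 1.0 - surv  # step function, right-continuous
        ptimes = {}
        for p in percentiles:
            reached = incidence[incidence >= p]
            t = float(reached.index[0]) if len(reached) else float("inf")
            ptimes[p] = float("inf") if t > horizon else t
        ptimes_all.append(ptimes)
    return RiskProfile(
        bands=[(int(lo), int(hi)) for lo, hi in bands],
        n_per_band=n_per_band,
        fractions=fractions,
        percentiles=tuple(percentiles),
        percentile_times=ptimes_all,
        horizons=tuple(float(h) for h in horizons),
        probabilities=probs_all,
        horizon=horizon,
    )
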