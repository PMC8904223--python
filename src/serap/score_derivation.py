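"""Derivation of parsimonious integer point scores for survival outcomes.

The derivation pipeline mirrors the AutoScore family of interpretable
score generators for time-to-event data:

1. **rank** candidate variables by permutation importance under a random
   survival forest;
2. **parsimony**: for each model size m, build a tentative score from the
   top-m variables on the training cohort and measure its integrated AUC on
   the validation cohort; pick m where the curve plateaus;
3. **categorize** continuous and count variables at training quantiles;
4. **fine-tune** the cut-offs to clinician-friendly round numbers;
5. **assign points**: fit a Cox proportional-hazards model on the
   dummy-coded categories, divide the coefficients by the smallest positive
   coefficient magnitude, round half away from zero, and shift each
   variable so its minimum category scores 0.

The result is a :class:`~serap.scorers.ScoreTable` whose total is an
additive non-negative integer risk score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sklearn.base import BaseEstimator
from sksurv.ensemble import RandomSurvivalForest
from sksurv.util import Surv

from .scorers import ScoreTable, ScoreVariable
from .survival_eval import harrell_c, iauc
from .synthetic_cohort import EVENT_COL, ID_COL, TIME_COL

__all__ = [
    "DerivationError",
    "RankedVariables",
    "CutoffScheme",
    "VariableCutoffs",
    "ParsimonyCurve",
    "DeriveConfig",
    "DeriveResult",
    "rank_variables",
    "categorize_variables",
    "fine_tune_cutoffs",
    "assign_points",
    "points_from_coefficients",
    "build_parsimony_curve",
    "derive_score",
    "ScoreDeriver",
]

_NON_CANDIDATES = (ID_COL, TIME_COL, EVENT_COL, "admission_year")


class DerivationError(RuntimeError):
    """A derivation stage failed (non-convergence, empty category, ...)."""


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankedVariables:
    """Variables ordered by non-increasing importance."""

    items: tuple[tuple[str, float], ...]

    def __post_init__(self):
        names = [n for n, _ in self.items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in ranking")
        imps = [v for _, v in self.items]
        if any(b > a for a, b in zip(imps, imps[1:])):
            raise ValueError("importances must be non-increasing")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.items]

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.items, columns=["variable", "importance"])


def default_candidates(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _NON_CANDIDATES]


def _encode_features(table: pd.DataFrame, candidates: Sequence[str]) -> np.ndarray:
    """Numeric design matrix: categorical columns become ordinal codes over
    their sorted unique levels (deterministic); numeric columns pass through."""
    cols = []
    for c in candidates:
        s = table[c]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(s.dropna()))
            codes = s.map({lv: i for i, lv in enumerate(levels)}).to_numpy(dtype=float)
        else:
            codes = s.to_numpy(dtype=float)
        if np.isnan(codes).any():
            raise ValueError(f"candidate column {c!r} contains missing values; impute first")
        cols.append(codes)
    return np.column_stack(cols) if cols else np.empty((len(table), 0))


def rank_variables(
    train: pd.DataFrame,
    candidates: Sequence[str] | None = None,
    *,
    n_trees: int = 100,
    max_samples: int | None = 1000,
    min_samples_leaf: int = 20,
    n_repeats: int = 3,
    importance_subsample: int = 2000,
    seed: int = 0,
) -> RankedVariables:
    """Permutation variable importance under a random survival forest.

    The forest grows ``n_trees`` log-rank trees on bootstrap subsamples of
    at most ``max_samples`` episodes.  Importance of a variable is the drop
    in Harrell's C (on a fixed evaluation subsample of the training data)
    when that variable's column is permuted, averaged over ``n_repeats``
    permutations.  Ties are broken by training-column order.
    """
    if candidates is None:
        candidates = default_candidates(train)
    if len(candidates) < 1:
        raise ValueError("no candidate variables")
    events = train[EVENT_COL].to_numpy(dtype=int)
    if events.sum() == 0:
        raise ValueError("no events in training cohort; cannot rank variables")
    X = _encode_features(train, candidates)
    times = train[TIME_COL].to_numpy(dtype=float)
    y = Surv.from_arrays(events.astype(bool), times)
    n = len(train)
    rsf = RandomSurvivalForest(
        n_estimators=n_trees,
        min_samples_leaf=min_samples_leaf,
        max_features="sqrt",
        max_samples=min(max_samples, n) if max_samples else None,
        random_state=seed,
        n_jobs=1,
    )
    rsf.fit(X, y)
    rng = np.random.default_rng(seed)
    m = min(importance_subsample, n)
    eval_idx = rng.choice(n, size=m, replace=False)
    X_eval = X[eval_idx]
    t_eval, e_eval = times[eval_idx], events[eval_idx]
    baseline = harrell_c(rsf.predict(X_eval), t_eval, e_eval)
    importances = np.zeros(len(candidates))
    for j in range(len(candidates)):
        drops = []
        for _ in range(n_repeats):
            Xp = X_eval.copy()
            Xp[:, j] = Xp[rng.permutation(m), j]
            drops.append(baseline - harrell_c(rsf.predict(Xp), t_eval, e_eval))
        importances[j] = float(np.mean(drops))
    order = np.argsort(-importances, kind="stable")
    items = tuple((candidates[j], float(importances[j])) for j in order)
    return RankedVariables(items)


# ---------------------------------------------------------------------------
# Categorization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableCutoffs:
    """Binning of one variable: interior interval boundaries (closed-open on
    the left boundary) or an explicit category level order."""

    kind: str  # "interval" | "categorical"
    boundaries: tuple[float, ...] = ()
    levels: tuple = ()

    def __post_init__(self):
        if self.kind == "interval":
            b = np.asarray(self.boundaries, dtype=float)
            if b.size and not np.all(np.diff(b) > 0):
                raise ValueError("boundaries must be strictly increasing")
        elif self.kind != "categorical":
            raise ValueError(f"unknown cutoff kind {self.kind!r}")

    @property
    def n_categories(self) -> int:
        return len(self.boundaries) + 1 if self.kind == "interval" else len(self.levels)

    def bin_index(self, values: pd.Series) -> np.ndarray:
        if self.kind == "interval":
            x = values.to_numpy(dtype=float)
            return np.searchsorted(np.asarray(self.boundaries, float), x, side="right")
        lookup = {lv: i for i, lv in enumerate(self.levels)}
        try:
            return values.map(lookup).to_numpy(dtype=int)
        except (ValueError, TypeError) as exc:
            raise DerivationError(f"unmapped category level in {values.name!r}") from exc


@dataclass(frozen=True)
class CutoffScheme:
    """Per-variable cut-offs produced by categorization / fine-tuning."""

    variables: Mapping[str, VariableCutoffs]

    def __getitem__(self, name: str) -> VariableCutoffs:
        return self.variables[name]

    def __contains__(self, name: str) -> bool:
        return name in self.variables


def _is_integral(x: np.ndarray) -> bool:
    return bool(np.all(np.equal(np.mod(x, 1), 0)))


def categorize_variables(
    train: pd.DataFrame,
    variables: Sequence[str],
    quantile_vector: Sequence[float] = (0, 0.05, 0.2, 0.8, 0.95, 1),
) -> CutoffScheme:
    """Bin continuous/count variables at training quantiles.

    The quantile vector must start at 0, end at 1 and be strictly
    increasing.  Duplicate empirical boundaries are collapsed; boundaries at
    or below the observed minimum are dropped (they would create an empty
    lowest bin).  Integer-valued variables get integer boundaries (ceil).
    Binary and categorical variables pass through unchanged.
    """
    q = np.asarray(quantile_vector, dtype=float)
    if q[0] != 0 or q[-1] != 1 or not np.all(np.diff(q) > 0):
        raise ValueError("quantile_vector must start at 0, end at 1, strictly increasing")
    out: dict[str, VariableCutoffs] = {}
    for name in variables:
        s = train[name]
        if s.isna().any():
            raise ValueError(f"variable {name!r} has missing values; impute first")
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = tuple(sorted(pd.unique(s)))
            out[name] = VariableCutoffs("categorical", levels=levels)
            continue
        x = s.to_numpy(dtype=float)
        uniq = np.unique(x)
        if uniq.size <= 2:
            if uniq.size == 1:
                warnings.warn(f"variable {name!r} is constant; single category")
            lv = tuple(int(v) if float(v).is_integer() else float(v) for v in uniq)
            out[name] = VariableCutoffs("categorical", levels=lv)
            continue
        cuts = np.quantile(x, q[1:-1])
        if _is_integral(uniq):
            cuts = np.ceil(cuts)
        cuts = np.unique(cuts)
        cuts = cuts[(cuts > uniq[0]) & (cuts <= uniq[-1])]
        if cuts.size == 0:
            warnings.warn(f"variable {name!r}: all quantile boundaries collapsed; single bin")
        out[name] = VariableCutoffs("interval", boundaries=tuple(float(b) for b in cuts))
    return CutoffScheme(out)


def fine_tune_cutoffs(
    scheme: CutoffScheme, overrides: Mapping[str, Sequence[float]]
) -> CutoffScheme:
    """Replace selected interval boundaries with (typically round) values.

    Overrides must reference existing interval variables and stay strictly
    increasing; everything else is preserved.
    """
    new = dict(scheme.variables)
    for name, bounds in overrides.items():
        if name not in new:
            raise KeyError(f"override references unknown variable {name!r}")
        if new[name].kind != "interval":
            raise ValueError(f"cannot override boundaries of categorical variable {name!r}")
        new[name] = VariableCutoffs("interval", boundaries=tuple(float(b) for b in bounds))
    return CutoffScheme(new)


# ---------------------------------------------------------------------------
# Point assignment
# ---------------------------------------------------------------------------

def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def points_from_coefficients(
    coef_by_var: Mapping[str, Sequence[float]],
    divisor: float | None = None,
) -> tuple[dict[str, tuple[int, ...]], float]:
    """Integer points from per-category Cox coefficients.

    Each variable's coefficient vector includes its reference category as 0.
    The scaling divisor defaults to the smallest positive coefficient
    magnitude across all categories; coefficients are divided, rounded half
    away from zero, and shifted so every variable's minimum category is 0.
    """
    all_coefs = np.concatenate([np.asarray(v, float) for v in coef_by_var.values()])
    if divisor is None:
        mags = np.abs(all_coefs[all_coefs != 0])
        divisor = float(mags.min()) if mags.size else 1.0
    if divisor <= 0:
        raise ValueError("divisor must be positive")
    points = {}
    for name, coefs in coef_by_var.items():
        raw = _round_half_away(np.asarray(coefs, float) / divisor).astype(int)
        points[name] = tuple(int(p) for p in raw - raw.min())
    return points, divisor


def assign_points(
    train: pd.DataFrame,
    scheme: CutoffScheme,
    variables: Sequence[str],
    *,
    divisor: float | None = None,
    penalizer: float = 1e-4,
    name: str = "derived",
) -> ScoreTable:
    """Cox-scaled integer points for categorized variables.

    Categories are dummy-coded against each variable's first category; a Cox
    proportional-hazards model supplies per-category log-hazard
    coefficients, which :func:`points_from_coefficients` converts to
    non-negative integer points.
    """
    design = {}
    cat_counts = {}
    for var in variables:
        if var not in scheme:
            raise KeyError(f"variable {var!r} not categorized by scheme")
        cuts = scheme[var]
        idx = cuts.bin_index(train[var])
        k = cuts.n_categories
        counts = np.bincount(idx, minlength=k)
        empty = np.flatnonzero(counts == 0)
        if empty.size:
            raise DerivationError(
                f"variable {var!r}: empty categories after binning at indices {empty.tolist()}"
            )
        cat_counts[var] = counts.tolist()
        for j in range(1, k):
            design[f"{var}__cat{j}"] = (idx == j).astype(float)
    df = pd.DataFrame(design, index=train.index)
    df[TIME_COL] = train[TIME_COL].to_numpy(dtype=float)
    df[EVENT_COL] = train[EVENT_COL].to_numpy(dtype=int)
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=TIME_COL, event_col=EVENT_COL)
    except (ConvergenceError, ValueError) as exc:
        raise DerivationError(
            f"Cox fit for point assignment did not converge: {exc}"
        ) from exc
    coef = cph.params_
    coef_by_var = {}
    for var in variables:
        k = scheme[var].n_categories
        coef_by_var[var] = [0.0] + [float(coef[f"{var}__cat{j}"]) for j in range(1, k)]
    points, used_divisor = points_from_coefficients(coef_by_var, divisor)
    score_vars = []
    for var in variables:
        cuts = scheme[var]
        if cuts.kind == "interval":
            score_vars.append(ScoreVariable(var, "interval",
                                            boundaries=cuts.boundaries,
                                            points=points[var]))
        else:
            score_vars.append(ScoreVariable(var, "categorical",
                                            levels=cuts.levels,
                                            points=points[var]))
    meta = {
        "divisor": used_divisor,
        "coefficients": {k: list(v) for k, v in coef_by_var.items()},
        "category_counts": cat_counts,
        "n_train": int(len(train)),
        "penalizer": penalizer,
    }
    return ScoreTable(name=name, variables=tuple(score_vars), metadata=meta)


# ---------------------------------------------------------------------------
# Parsimony and orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParsimonyCurve:
    """Validation iAUC as a function of model size m."""

    points: tuple[tuple[int, float], ...]

    def __post_init__(self):
        ms = [m for m, _ in self.points]
        if any(b <= a for a, b in zip(ms, ms[1:])):
            raise ValueError("model sizes must be strictly increasing")
        if any(not np.isfinite(v) for _, v in self.points):
            raise ValueError("iAUC values must be finite")

    def __len__(self):
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["n_variables", "iauc_validation"])


def build_parsimony_curve(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    ranked: RankedVariables,
    m_range: Sequence[int] | None = None,
    *,
    quantiles: Sequence[float] = (0, 0.05, 0.2, 0.8, 0.95, 1),
    penalizer: float = 1e-4,
    t_from: float = 1.0,
    t_to: float = 90.0,
) -> ParsimonyCurve:
    """Validation iAUC of the top-m variable score, for each m."""
    if len(validation) == 0:
        raise ValueError("validation cohort is empty")
    if m_range is None:
        m_range = range(1, len(ranked) + 1)
    m_range = sorted(set(int(m) for m in m_range))
    if m_range and (m_range[0] < 1 or m_range[-1] > len(ranked)):
        raise ValueError("m_range outside [1, number of candidates]")
    t = validation[TIME_COL].to_numpy(dtype=float)
    e = validation[EVENT_COL].to_numpy(dtype=int)
    pts = []
    for m in m_range:
        vars_m = ranked.names[:m]
        scheme = categorize_variables(train, vars_m, quantiles)
        table = assign_points(train, scheme, vars_m, penalizer=penalizer,
                              name=f"tentative_m{m}")
        scores = table.apply(validation)
        pts.append((m, iauc(scores, t, e, t_from, t_to)))
    return ParsimonyCurve(tuple(pts))


@dataclass(frozen=True)
class DeriveConfig:
    """Every tunable of the derivation pipeline, reproducible from ``seed``."""

    candidates: tuple[str, ...] | None = None
    n_variables: int | None = None          # None: auto-select from the curve
    max_m: int = 10
    quantiles: tuple[float, ...] = (0, 0.05, 0.2, 0.8, 0.95, 1)
    cutoff_overrides: Mapping[str, Sequence[float]] = field(default_factory=dict)
    n_trees: int = 100
    max_samples: int | None = 1000
    min_samples_leaf: int = 20
    n_repeats: int = 3
    importance_subsample: int = 2000
    penalizer: float = 1e-4
    t_from: float = 1.0
    t_to: float = 90.0
    select_tolerance: float = 0.005
    seed: int = 0

    def replace(self, **kw) -> "DeriveConfig":
        return replace(self, **kw)


@dataclass
class DeriveResult:
    score_table: ScoreTable
    parsimony_curve: ParsimonyCurve
    ranking: RankedVariables
    n_variables: int


def _select_m(curve: ParsimonyCurve, tolerance: float) -> int:
    """Smallest model size within ``tolerance`` of the best validation iAUC."""
    best = max(v for _, v in curve)
    for m, v in curve:
        if v >= best - tolerance:
            return m
    return curve.points[-1][0]


def derive_score(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    config: DeriveConfig = DeriveConfig(),
) -> DeriveResult:
    """Full derivation: rank, parsimony, categorize, fine-tune, assign."""
    candidates = list(config.candidates) if config.candidates else default_candidates(train)
    ranked = rank_variables(
        train, candidates,
        n_trees=config.n_trees, max_samples=config.max_samples,
        min_samples_leaf=config.min_samples_leaf, n_repeats=config.n_repeats,
        importance_subsample=config.importance_subsample, seed=config.seed,
    )
    m_top = min(config.max_m, len(ranked))
    curve = build_parsimony_curve(
        train, validation, ranked, range(1, m_top + 1),
        quantiles=config.quantiles, penalizer=config.penalizer,
        t_from=config.t_from, t_to=config.t_to,
    )
    m = config.n_variables if config.n_variables else _select_m(curve, config.select_tolerance)
    if not 1 <= m <= len(ranked):
        raise ValueError(f"selected model size {m} outside [1, {len(ranked)}]")
    final_vars = ranked.names[:m]
    scheme = categorize_variables(train, final_vars, config.quantiles)
    overrides = {k: v for k, v in config.cutoff_overrides.items() if k in scheme.variables}
    scheme = fine_tune_cutoffs(scheme, overrides)
    table = assign_points(train, scheme, final_vars, penalizer=config.penalizer,
                          name="derived")
    meta = dict(table.metadata)
    meta["config"] = {
        "n_variables": m, "quantiles": list(config.quantiles),
        "seed": config.seed, "n_trees": config.n_trees,
        "select_tolerance": config.select_tolerance,
    }
    table = ScoreTable(name=table.name, variables=table.variables, metadata=meta)
    return DeriveResult(score_table=table, parsimony_curve=curve,
                        ranking=ranked, n_variables=m)


# ---------------------------------------------------------------------------
# sklearn-style estimator facade
# ---------------------------------------------------------------------------

class ScoreDeriver(BaseEstimator):
    """Derive an integer point-score survival model, sklearn style.

    ``fit(X, y)`` takes a covariate DataFrame and a scikit-survival
    structured array (fields event, time); pass ``validation=(X_val,
    y_val)`` to supply an explicit validation cohort, otherwise a random
    ``validation_fraction`` of the training data is held out.  After
    fitting, ``score_table_``, ``parsimony_curve_``, ``ranking_`` and
    ``n_variables_`` are available and ``predict`` returns the integer
    totals (higher = riskier).
    """

    def __init__(
        self,
        n_variables: int | None = None,
        max_m: int = 10,
        quantiles: tuple[float, ...] = (0, 0.05, 0.2, 0.8, 0.95, 1),
        cutoff_overrides: dict | None = None,
        n_trees: int = 100,
        max_samples: int | None = 1000,
        min_samples_leaf: int = 20,
        n_repeats: int = 3,
        importance_subsample: int = 2000,
        penalizer: float = 1e-4,
        t_from: float = 1.0,
        t_to: float = 90.0,
        select_tolerance: float = 0.005,
        validation_fraction: float = 0.2,
        random_state: int = 0,
    ):
        self.n_variables = n_variables
        self.max_m = max_m
        self.quantiles = quantiles
        self.cutoff_overrides = cutoff_overrides
        self.n_trees = n_trees
        self.max_samples = max_samples
        self.min_samples_leaf = min_samples_leaf
        self.n_repeats = n_repeats
        self.importance_subsample = importance_subsample
        self.penalizer = penalizer
        self.t_from = t_from
        self.t_to = t_to
        self.select_tolerance = select_tolerance
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    @staticmethod
    def _unpack_y(y) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(y, np.ndarray) and y.dtype.names:
            ev, tm = y.dtype.names  # sksurv convention: (event, time)
            return y[tm].astype(float), y[ev].astype(int)
        y = np.asarray(y)
        if y.ndim == 2 and y.shape[1] == 2:
            return y[:, 0].astype(float), y[:, 1].astype(int)
        raise ValueError("y must be a sksurv structured array or an (n, 2) [time, event] array")

    def _episode_frame(self, X: pd.DataFrame, y) -> pd.DataFrame:
        times, events = self._unpack_y(y)
        df = pd.DataFrame(X).copy()
        df[TIME_COL] = times
        df[EVENT_COL] = events
        return df

    def fit(self, X: pd.DataFrame, y, validation=None) -> "ScoreDeriver":
        df = self._episode_frame(X, y)
        if validation is not None:
            X_val, y_val = validation
            train_df, val_df = df, self._episode_frame(X_val, y_val)
        else:
            rng = np.random.default_rng(self.random_state)
            perm = rng.permutation(len(df))
            n_val = max(1, int(round(self.validation_fraction * len(df))))
            val_df = df.iloc[np.sort(perm[:n_val])]
            train_df = df.iloc[np.sort(perm[n_val:])]
        config = DeriveConfig(
            candidates=None,
            n_variables=self.n_variables,
            max_m=self.max_m,
            quantiles=tuple(self.quantiles),
            cutoff_overrides=self.cutoff_overrides or {},
            n_trees=self.n_trees,
            max_samples=self.max_samples,
            min_samples_leaf=self.min_samples_leaf,
            n_repeats=self.n_repeats,
            importance_subsample=self.importance_subsample,
            penalizer=self.penalizer,
            t_from=self.t_from,
            t_to=self.t_to,
            select_tolerance=self.select_tolerance,
            seed=self.random_state,
        )
        result = derive_score(train_df, val_df, config)
        self.score_table_ = result.score_table
        self.parsimony_curve_ = result.parsimony_curve
        self.ranking_ = result.ranking
        self.n_variables_ = result.n_variables
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "score_table_"):
            raise RuntimeError("ScoreDeriver is not fitted")
        return self.score_table_.apply(pd.DataFrame(X))

    def score(self, X: pd.DataFrame, y) -> float:
        """Harrell's C of the derived score (sklearn scoring convention)."""
        times, events = self._unpack_y(y)
        return harrell_c(self.predict(X), times, events)
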