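"""Time-to-event discrimination and classification metrics.

Implements the evaluation suite for point-based readmission scores:
Harrell's concordance index, the cumulative/dynamic time-dependent AUC(t),
the integrated AUC over a follow-up window, percentile-bootstrap confidence
intervals, Kaplan-Meier estimation, the log-rank test, and the 30-day
classification block (optimal ROC cut-off, sensitivity/specificity/PPV/NPV,
likelihood ratios).

Tie conventions (fixed so results match exhaustive pair enumeration exactly):

* C-index: a pair (i, j) is comparable when ``t_i < t_j`` and i had the
  event, or ``t_i == t_j`` with i an event and j censored.  Concordant when
  the shorter survivor has the strictly higher score; score ties count 1/2.
* AUC(t): cases are episodes with an event by ``t``; controls are episodes
  followed event-free through ``t`` (``time > t``, or censored exactly at
  ``t``); episodes censored strictly before ``t`` are excluded.  Score ties
  between a case and control count 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import hashlib
import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import rankdata

__all__ = [
    "UndefinedMetricError",
    "harrell_c",
    "auc_t",
    "iauc",
    "bootstrap_ci",
    "km_estimate",
    "logrank_test",
    "binary_outcome_at",
    "optimal_cutoff",
    "classification_at_cutoff",
    "evaluate_score",
    "evaluate_many",
    "Estimate",
    "EvalReport",
    "ClassificationBlock",
]


class UndefinedMetricError(ValueError):
    """A metric is undefined on the given data (e.g. no comparable pairs)."""


def _as_arrays(scores, times, events):
    s = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if not (s.shape == t.shape == e.shape) or s.ndim != 1:
        raise ValueError("scores, times, events must be aligned 1-d vectors")
    return s, t, e


def harrell_c(scores, times, events, *, chunk: int = 512) -> float:
    """Harrell's concordance index with score ties counted 1/2.

    Evaluated by exact pairwise comparison (chunked to bound memory);
    sums accumulate in 0.5 steps so the result is exact.
    """
    s, t, e = _as_arrays(scores, times, events)
    n = len(s)
    num = 0.0
    den = 0
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        ti = t[sl, None]
        si = s[sl, None]
        ei = e[sl, None].astype(bool)
        comparable = ((ti < t[None, :]) & ei) | (
            (ti == t[None, :]) & ei & (e[None, :] == 0)
        )
        num += np.sum(comparable & (si > s[None, :]))
        num += 0.5 * np.sum(comparable & (si == s[None, :]))
        den += int(np.sum(comparable))
    if den == 0:
        raise UndefinedMetricError("no comparable pairs for concordance index")
    return float(num / den)


def _case_control_masks(times, events, t):
    cases = (events == 1) & (times <= t)
    controls = (times > t) | ((times == t) & (events == 0))
    return cases, controls


def auc_t(scores, times, events, t: float) -> float:
    """Cumulative/dynamic AUC at horizon ``t``.

    Probability that an episode with an event by ``t`` scores above one
    followed event-free through ``t``; ties 1/2.  Computed via the rank-sum
    identity, which equals exhaustive case/control pair enumeration exactly.
    """
    s, tt, e = _as_arrays(scores, times, events)
    cases, controls = _case_control_masks(tt, e, float(t))
    n1, n0 = int(cases.sum()), int(controls.sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError(
            f"AUC({t}) undefined: {n1} cases, {n0} controls"
        )
    pooled = np.concatenate([s[cases], s[controls]])
    ranks = rankdata(pooled)  # midranks: exact in 0.5 steps
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def iauc(
    scores,
    times,
    events,
    t_from: float = 1.0,
    t_to: float = 90.0,
) -> float:
    """Integrated AUC: event-count-weighted average of AUC(t) over the grid
    of observed event times in ``[t_from, t_to]``.

    Grid points where AUC(t) is undefined (no controls remain) are dropped
    with their weight.  Raises when no events fall in the window.
    """
    s, t, e = _as_arrays(scores, times, events)
    if not t_from < t_to:
        raise ValueError("t_from must be < t_to")
    sel = (e == 1) & (t >= t_from) & (t <= t_to)
    if not sel.any():
        raise UndefinedMetricError("no events inside the iAUC window")
    grid, counts = np.unique(t[sel], return_counts=True)
    total = 0.0
    wsum = 0.0
    for tk, w in zip(grid, counts):
        try:
            a = auc_t(s, t, e, tk)
        except UndefinedMetricError:
            continue
        total += w * a
        wsum += w
    if wsum == 0:
        raise UndefinedMetricError("AUC(t) undefined at every event time in window")
    return float(total / wsum)


@dataclass(frozen=True)
class Estimate:
    """Point estimate with optional percentile-bootstrap 95% CI."""

    point: float
    lower: float = float("nan")
    upper: float = float("nan")

    def __iter__(self):
        return iter((self.point, self.lower, self.upper))


def bootstrap_ci(
    metric: Callable,
    data,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> Estimate:
    """Percentile bootstrap CI for ``metric`` over episode-level resampling.

    ``data`` is indexed positionally (ndarray rows or DataFrame rows).
    Resamples on which the metric is undefined are dropped; if more than 10%
    are undefined the interval is refused.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    is_frame = isinstance(data, pd.DataFrame)
    arr = data if is_frame else np.asarray(data)
    n = len(arr)
    point = float(metric(arr))
    stats = []
    n_undef = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        sample = arr.iloc[idx] if is_frame else arr[idx]
        try:
            stats.append(float(metric(sample)))
        except UndefinedMetricError:
            n_undef += 1
    if n_undef > 0.10 * B:
        raise UndefinedMetricError(
            f"metric undefined on {n_undef}/{B} bootstrap resamples"
        )
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return Estimate(point, float(lo), float(hi))


class KMCurve:
    """Right-continuous product-limit survival step function, S(0) = 1."""

    def __init__(self, times, events):
        t = np.asarray(times, dtype=float)
        e = np.asarray(events, dtype=int)
        if t.size == 0:
            raise ValueError("empty input to Kaplan-Meier estimate")
        if (t < 0).any():
            raise ValueError("negative event times")
        self._fitter = KaplanMeierFitter()
        self._fitter.fit(t, e)
        sf = self._fitter.survival_function_
        self.times = sf.index.to_numpy(dtype=float)
        self.survival = sf.iloc[:, 0].to_numpy(dtype=float)

    def __call__(self, t) -> np.ndarray | float:
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t_arr, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return float(out[0]) if np.isscalar(t) or np.asarray(t).ndim == 0 else out

    def readmission_probability(self, t):
        """Cumulative incidence 1 - S(t)."""
        s = self(t)
        return 1.0 - s


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit survival estimate."""
    return KMCurve(times, events)


def logrank_test(times, events, group) -> tuple[float, float]:
    """Log-rank chi-square statistic and p-value across >= 2 groups."""
    g = np.asarray(group)
    if len(np.unique(g)) < 2:
        raise ValueError("log-rank test requires at least two groups")
    res = multivariate_logrank_test(np.asarray(times, float), g, np.asarray(events, int))
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class BinaryOutcome:
    """Event-by-horizon labels; episodes censored before the horizon are
    excluded (mask False) and counted."""

    labels: np.ndarray  # 0/1 for included episodes
    mask: np.ndarray    # True where the episode is evaluable
    n_excluded: int


def binary_outcome_at(times, events, t: float) -> BinaryOutcome:
    """Dichotomize time-to-event data at horizon ``t``.

    Label 1: event by ``t``.  Label 0: followed event-free through ``t``
    (time > t, or censored exactly at t).  Censored strictly before ``t``:
    excluded.
    """
    tt = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    pos = (e == 1) & (tt <= t)
    neg = (tt > t) | ((tt == t) & (e == 0))
    mask = pos | neg
    labels = pos[mask].astype(int)
    return BinaryOutcome(labels=labels, mask=mask, n_excluded=int((~mask).sum()))


def optimal_cutoff(scores, labels) -> float:
    """Score threshold closest to the upper-left ROC corner.

    Predict-positive convention: ``score >= cutoff``.  Candidate thresholds
    are the distinct observed scores; the minimizer of
    sqrt((1-sens)^2 + (1-spec)^2) is returned, ties resolved to the lowest
    threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if y.min() == y.max():
        raise ValueError("optimal_cutoff requires both classes present")
    thresholds = np.unique(s)
    n_pos, n_neg = (y == 1).sum(), (y == 0).sum()
    # sens(c) = P(s >= c | y=1); spec(c) = P(s < c | y=0)
    sens = np.array([(s[y == 1] >= c).sum() for c in thresholds]) / n_pos
    spec = np.array([(s[y == 0] < c).sum() for c in thresholds]) / n_neg
    dist = np.hypot(1 - sens, 1 - spec)
    best = np.flatnonzero(dist == dist.min())[0]  # unique() is sorted: lowest wins
    return float(thresholds[best])


@dataclass
class ClassificationBlock:
    """Confusion-matrix summary at a fixed horizon and score cut-off."""

    horizon: float
    cutoff: float
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: Estimate
    specificity: Estimate
    ppv: Estimate
    npv: Estimate
    lr_positive: Estimate
    lr_negative: Estimate
    n_excluded: int = 0
    undefined: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("sensitivity", "specificity", "ppv", "npv",
                     "lr_positive", "lr_negative"):
            est: Estimate = getattr(self, name)
            rows.append({"metric": name, "point": est.point,
                         "ci_lower": est.lower, "ci_upper": est.upper})
        df = pd.DataFrame(rows)
        df.insert(0, "cutoff", self.cutoff)
        df.insert(0, "horizon_days", self.horizon)
        return df


def _safe_ratio(num: float, den: float, undefined: list, name: str) -> float:
    if den == 0:
        undefined.append(name)
        return float("nan")
    return num / den


def classification_at_cutoff(scores, labels, cutoff: float,
                             horizon: float = float("nan")) -> ClassificationBlock:
    """Sens/spec/PPV/NPV and likelihood ratios at ``score >= cutoff``."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = s >= cutoff
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    undefined: list[str] = []
    sens = _safe_ratio(tp, tp + fn, undefined, "sensitivity")
    spec = _safe_ratio(tn, tn + fp, undefined, "specificity")
    ppv = _safe_ratio(tp, tp + fp, undefined, "ppv")
    npv = _safe_ratio(tn, tn + fn, undefined, "npv")
    lr_pos = _safe_ratio(sens, 1 - spec, undefined, "lr_positive")
    lr_neg = _safe_ratio(1 - sens, spec, undefined, "lr_negative")
    mk = lambda x: Estimate(float(x))
    return ClassificationBlock(
        horizon=horizon, cutoff=float(cutoff), tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=mk(sens), specificity=mk(spec), ppv=mk(ppv), npv=mk(npv),
        lr_positive=mk(lr_pos), lr_negative=mk(lr_neg), undefined=undefined,
    )


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """iAUC, C-index and AUC(t) at requested horizons, with bootstrap CIs."""

    name: str
    iauc: Estimate
    cindex: Estimate
    auc: dict[float, Estimate]
    n: int
    B: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": "iAUC", "point": self.iauc.point,
             "ci_lower": self.iauc.lower, "ci_upper": self.iauc.upper},
            {"metric": "C-index", "point": self.cindex.point,
             "ci_lower": self.cindex.lower, "ci_upper": self.cindex.upper},
        ]
        for t in sorted(self.auc):
            est = self.auc[t]
            rows.append({"metric": f"AUC(t={int(t)})", "point": est.point,
                         "ci_lower": est.lower, "ci_upper": est.upper})
        df = pd.DataFrame(rows)
        df.insert(0, "score", self.name)
        return df


def _all_metrics(s, t, e, horizons, t_from, t_to):
    out = {"iauc": iauc(s, t, e, t_from, t_to), "cindex": harrell_c(s, t, e)}
    for h in horizons:
        try:
            out[f"auc_{h}"] = auc_t(s, t, e, h)
        except UndefinedMetricError:
            out[f"auc_{h}"] = float("nan")
    return out


def evaluate_many(
    scores_by_name: Mapping[str, np.ndarray],
    times,
    events,
    horizons: Sequence[float] = (7, 14, 21, 30, 60, 90),
    B: int = 1000,
    seed: int = 0,
    t_from: float = 1.0,
    t_to: float = 90.0,
) -> tuple[dict[str, EvalReport], str]:
    """Evaluate several score vectors on the same episodes with shared
    bootstrap resamples (paired comparison).

    Returns the per-score reports and a SHA-256 digest of the resample
    index matrix, so pairing can be audited across runs.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    n = len(t)
    rng = np.random.default_rng(seed)
    idx_matrix = rng.integers(0, n, size=(B, n))
    digest = hashlib.sha256(np.ascontiguousarray(idx_matrix).tobytes()).hexdigest()
    horizons = tuple(float(h) for h in horizons)
    reports: dict[str, EvalReport] = {}
    for name, sc in scores_by_name.items():
        s = np.asarray(sc, dtype=float)
        if len(s) != n:
            raise ValueError(f"score vector {name!r} not aligned with episodes")
        point = _all_metrics(s, t, e, horizons, t_from, t_to)
        boot: dict[str, list[float]] = {k: [] for k in point}
        for b in range(B):
            idx = idx_matrix[b]
            try:
                rep = _all_metrics(s[idx], t[idx], e[idx], horizons, t_from, t_to)
            except UndefinedMetricError:
                continue
            for k, v in rep.items():
                boot[k].append(v)
        def est(key: str) -> Estimate:
            vals = np.asarray(boot[key], dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size < 2:
                return Estimate(point[key])
            lo, hi = np.percentile(vals, [2.5, 97.5])
            return Estimate(point[key], float(lo), float(hi))
        reports[name] = EvalReport(
            name=name,
            iauc=est("iauc"),
            cindex=est("cindex"),
            auc={h: est(f"auc_{h}") for h in horizons},
            n=n,
            B=B,
        )
    return reports, digest


def evaluate_score(scores, times, events, name: str = "score", **kwargs) -> EvalReport:
    """Single-score convenience wrapper around :func:`evaluate_many`."""
    reports, _ = evaluate_many({name: scores}, times, events, **kwargs)
    return reports[name]


def classification_with_ci(
    scores,
    times,
    events,
    horizon: float = 30.0,
    cutoff: float | None = None,
    B: int = 1000,
    seed: int = 0,
) -> ClassificationBlock:
    """30-day-style classification block with bootstrap 95% CIs.

    Outcomes are dichotomized at ``horizon`` (censored-before-horizon
    excluded); the cut-off defaults to the optimal ROC corner point on the
    evaluable episodes; sens/spec/PPV/NPV/LRs get percentile CIs over
    episode-level resamples.
    """
    s = np.asarray(scores, dtype=float)
    out = binary_outcome_at(times, events, horizon)
    s_inc = s[out.mask]
    y = out.labels
    if cutoff is None:
        cutoff = optimal_cutoff(s_inc, y)
    block = classification_at_cutoff(s_inc, y, cutoff, horizon=horizon)
    block.n_excluded = out.n_excluded
    rng = np.random.default_rng(seed)
    n = len(y)
    names = ("sensitivity", "specificity", "ppv", "npv", "lr_positive", "lr_negative")
    boot: dict[str, list[float]] = {k: [] for k in names}
    for _ in range(B):
        idx = rng.integers(0, n, n)
        rep = classification_at_cutoff(s_inc[idx], y[idx], cutoff, horizon=horizon)
        for k in names:
            boot[k].append(getattr(rep, k).point)
    for k in names:
        vals = np.asarray(boot[k], dtype=float)
        vals = vals[np.isfinite(vals)]
        point = getattr(block, k).point
        if vals.size >= 2:
            lo, hi = np.percentile(vals, [2.5, 97.5])
            setattr(block, k, Estimate(point, float(lo), float(hi)))
    return block
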