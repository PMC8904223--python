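"""Shared fixtures and independent oracles for the test suite.

Oracles here are deliberately naive re-implementations (pure-python loops,
exhaustive enumeration) kept independent of the package's vectorized code
paths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from serap import serap_table
from serap.synthetic_cohort import CohortSpec, generate_cohort

# correlated stand-ins for truth constructs; excluded from exact
# ranking-recovery checks (see docs/methods.md)
PROXY_COVARIATES = {"admissions_last_year", "ed_visits_6m", "oncology_discharge"}


@pytest.fixture(scope="session")
def serap():
    return serap_table()


@pytest.fixture(scope="session")
def clean_cohort_factory():
    """Cohorts without missingness/outliers, with truth scores."""

    def make(n, seed, beta=0.18, **overrides):
        spec = CohortSpec(
            n_episodes=n, seed=seed, effect_per_point=beta,
            missingness_rates={}, outlier_rate=0.0, **overrides,
        )
        return generate_cohort(spec, return_truth=True)

    return make


@pytest.fixture(scope="session")
def random_survival_instance():
    """Factory for small random (scores, times, events) instances with ties."""

    def make(n, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 8, n).astype(float)  # integer scores: ties
        times = rng.integers(1, 20, n).astype(float)   # day ties
        events = rng.integers(0, 2, n)
        return scores, times, events

    return make


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_harrell_c(scores, times, events):
    """O(n^2) pair enumeration under the package's stated conventions."""
    n = len(scores)
    num = 0.0
    den = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            comparable = (times[i] < times[j] and events[i] == 1) or (
                times[i] == times[j] and events[i] == 1 and events[j] == 0
            )
            if not comparable:
                continue
            den += 1
            if scores[i] > scores[j]:
                num += 1.0
            elif scores[i] == scores[j]:
                num += 0.5
    return num / den


def brute_auc_t(scores, times, events, t):
    """Case/control pair enumeration at horizon t."""
    cases = [i for i in range(len(scores)) if events[i] == 1 and times[i] <= t]
    controls = [
        i for i in range(len(scores))
        if times[i] > t or (times[i] == t and events[i] == 0)
    ]
    if not cases or not controls:
        raise ValueError("undefined")
    num = 0.0
    for i in cases:
        for j in controls:
            if scores[i] > scores[j]:
                num += 1.0
            elif scores[i] == scores[j]:
                num += 0.5
    return num / (len(cases) * len(controls))


def brute_iauc(scores, times, events, t_from, t_to):
    """Direct weighted summation over observed event times."""
    ev_times = sorted({times[i] for i in range(len(times))
                       if events[i] == 1 and t_from <= times[i] <= t_to})
    total, wsum = 0.0, 0.0
    for tk in ev_times:
        w = sum(1 for i in range(len(times)) if events[i] == 1 and times[i] == tk)
        try:
            a = brute_auc_t(scores, times, events, tk)
        except ValueError:
            continue
        total += w * a
        wsum += w
    return total / wsum


def brute_km(times, events):
    """Hand product-limit estimate -> list of (time, survival)."""
    order = sorted(set(t for t, e in zip(times, events) if e == 1))
    s = 1.0
    out = []
    for tk in order:
        at_risk = sum(1 for t in times if t >= tk)
        d = sum(1 for t, e in zip(times, events) if t == tk and e == 1)
        s *= 1 - d / at_risk
        out.append((tk, s))
    return out
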