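"""Shared fixtures and independent oracles for the test suite."""

from itertools import combinations
from typing import List, Sequence

import numpy as np
import pytest

from gliogrow.changepoint import ChangePointConfig, segment_cost


def brute_force_changepoints(
    x: Sequence[float], v0: float, cfg: ChangePointConfig
) -> tuple:
    """Independent oracle: exhaustive enumeration of all admissible
    change-point sets, minimizing total segment cost + penalty per point.

    Returns (best_set, best_objective).  Ties resolve toward fewer change
    points, then lexicographically — the same convention as the solver, so
    random (tie-free) data must agree exactly.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    ms = cfg.min_segment
    beta = cfg.threshold_numerator / v0

    def objective(cps: List[int]) -> float:
        bounds = [0] + list(cps) + [n]
        total = beta * len(cps)
        for a, b in zip(bounds[:-1], bounds[1:]):
            total += segment_cost(x[a:b], cfg.cost_statistic)
        return total

    candidates = [k for k in range(ms, n - ms + 1)]
    best_set: List[int] = []
    best_obj = objective([]) if n >= ms else np.inf
    if n < ms:
        return [], np.inf
    for r in range(1, len(candidates) + 1):
        for combo in combinations(candidates, r):
            if any(b - a < ms for a, b in zip(combo[:-1], combo[1:])):
                continue
            obj = objective(list(combo))
            if obj < best_obj - 1e-12:
                best_obj = obj
                best_set = list(combo)
    return best_set, best_obj


def exact_mww_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Independent oracle: two-tailed Mann-Whitney p by full enumeration of
    all assignments of the pooled (tie-free) values to the two groups."""
    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1, n2 = len(x), len(y)
    m = n1 * n2

    def u_of(idx):
        r = sum(ranks[pooled[i - 1]] for i in idx)  # idx are 1-based positions
        return r - n1 * (n1 + 1) / 2

    obs_r = sum(ranks[v] for v in x)
    obs_u = obs_r - n1 * (n1 + 1) / 2
    obs_stat = min(obs_u, m - obs_u)
    count = 0
    total = 0
    for combo in combinations(range(1, n1 + n2 + 1), n1):
        u = u_of(combo)
        if min(u, m - u) <= obs_stat + 1e-12:
            count += 1
        total += 1
    return count / total


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
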