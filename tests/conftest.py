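"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's score-vector shortcut:
the naive permutation oracle recomputes the weighted log-rank statistic
from risk sets for every group labeling, and the grid-search oracle
maximizes the partial likelihood by bracketing rather than Newton steps.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from ctot.dataio import AnalysisFrame
from ctot.transform import CensoredSample


def make_two_group_frame(ct, norm, group, cutoff, levels=("0", "1")):
    return AnalysisFrame(
        ct=np.asarray(ct, dtype=float),
        normalizer_ct=np.asarray(norm, dtype=float),
        cutoff=float(cutoff),
        group=np.asarray(group, dtype=int),
        group_levels=levels,
    )


def make_samples(times, events, predictors=None):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if predictors is None:
        predictors = np.zeros_like(times)
    return [
        CensoredSample(time=float(t), event=bool(e), predictor=float(x),
                       raw_ct=float(t), normalizer_ct=0.0)
        for t, e, x in zip(times, events, predictors)
    ]


def random_censored_dataset(rng, n_max=12, n_min=4, censor_prob=0.3, allow_ties=True):
    """A small random survival-type dataset with mixed censoring."""
    n = int(rng.integers(n_min, n_max + 1))
    if allow_ties:
        times = rng.integers(1, n, size=n).astype(float)  # integer grid forces ties
    else:
        times = rng.normal(10.0, 3.0, size=n)
    events = rng.random(n) > censor_prob
    if not events.any():
        events[int(rng.integers(0, n))] = True
    n1 = int(rng.integers(1, n))
    mask = np.zeros(n, dtype=bool)
    mask[rng.choice(n, size=n1, replace=False)] = True
    return times, events, mask


def naive_fh_statistic(times, events, group1_mask, rho, gamma):
    """Weighted log-rank sum O-E recomputed from risk sets, no shortcuts."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    mask = np.asarray(group1_mask, bool)
    ev_times = np.unique(times[events])
    # pooled KM left limit, recomputed from scratch
    s_left, s = [], 1.0
    for tj in ev_times:
        s_left.append(s)
        nj = (times >= tj).sum()
        dj = (events & (times == tj)).sum()
        s *= 1.0 - dj / nj
    stat = 0.0
    for tj, sl in zip(ev_times, s_left):
        nj = (times >= tj).sum()
        dj = (events & (times == tj)).sum()
        n1j = (mask & (times >= tj)).sum()
        d1j = (mask & events & (times == tj)).sum()
        w = sl**rho * (1.0 - sl) ** gamma
        stat += w * (d1j - dj * n1j / nj)
    return stat


def naive_exact_pvalue(times, events, group1_mask, rho, gamma):
    """Two-sided exact permutation p-value by brute enumeration of all
    C(n, n1) labelings, each statistic recomputed from risk sets."""
    n = len(times)
    mask = np.asarray(group1_mask, bool)
    n1 = int(mask.sum())
    obs = naive_fh_statistic(times, events, mask, rho, gamma)
    stats_all = []
    for combo in combinations(range(n), n1):
        m = np.zeros(n, dtype=bool)
        m[list(combo)] = True
        stats_all.append(naive_fh_statistic(times, events, m, rho, gamma))
    stats_all = np.asarray(stats_all)
    eps = 1e-12 * max(1.0, np.abs(stats_all).max())
    return float((np.abs(stats_all) >= abs(obs) - eps).mean())


def grid_search_beta(samples, lo=-10.0, hi=10.0, ties="efron"):
    """Maximize the partial likelihood over beta by iterated grid
    refinement down to a 1e-5 grid, independent of Newton-Raphson."""
    from ctot.regression import partial_loglik

    def ll(b):
        return partial_loglik([b], samples, ties=ties)[0]

    width = hi - lo
    while width > 1e-5:
        grid = np.linspace(lo, hi, 41)
        vals = [ll(b) for b in grid]
        k = int(np.argmax(vals))
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        width = hi - lo
    return 0.5 * (lo + hi)


@pytest.fixture
def rng():
    return np.random.default_rng(20250902)
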