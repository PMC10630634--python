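"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's own code paths: they work
base by base on dense arrays so that interval arithmetic, run-length
bookkeeping and the transcript caller can be checked against plain
enumeration.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np
import pandas as pd
import pytest

from nasctx.core import CountMatrix


def dense_window_sum(depth: np.ndarray, start: int, end: int) -> float:
    """Base-by-base signal sum oracle."""
    return float(np.sum(depth[max(0, start) : max(0, end)]))


def overlap_bp_oracle(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    """Membership-count overlap oracle on two [start, end) ranges."""
    return sum(1 for x in range(a[0], a[1]) if b[0] <= x < b[1])


def call_units_oracle(
    depth: np.ndarray, min_depth: float, max_gap: int, min_length: int
) -> List[Tuple[int, int]]:
    """Per-base threshold-and-bridge caller: scan every position."""
    above = depth >= min_depth
    segs: List[List[int]] = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            segs.append([i, j])
            i = j
        else:
            i += 1
    merged: List[List[int]] = []
    for s, e in segs:
        if merged and s - merged[-1][1] <= max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if e - s >= min_length]


def welch_permutation_p(a: np.ndarray, b: np.ndarray, n_perm: int, seed: int) -> float:
    """Two-sided permutation p for the Welch statistic (label shuffling)."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    t_obs = abs(stats.ttest_ind(a, b, equal_var=False).statistic)
    pooled = np.concatenate([a, b])
    na = len(a)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        t = abs(stats.ttest_ind(perm[:na], perm[na:], equal_var=False).statistic)
        if t >= t_obs - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def make_count_matrix(
    counts: np.ndarray, groups_per_sample: List[str]
) -> CountMatrix:
    counts = np.asarray(counts)
    samples = [f"s{i + 1}" for i in range(counts.shape[1])]
    df = pd.DataFrame(counts, index=[f"g{i + 1}" for i in range(counts.shape[0])], columns=samples)
    return CountMatrix(df, dict(zip(samples, groups_per_sample)))


def simulate_nb_matrix(
    n_features: int,
    n_per_group: int,
    phi: float,
    seed: int,
    mean_range: Tuple[float, float] = (50.0, 500.0),
    lfc: np.ndarray | None = None,
) -> CountMatrix:
    """NB counts for a two-group (A/B) design with optional planted lfc."""
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), n_features))
    if lfc is None:
        lfc = np.zeros(n_features)
    cond = np.array([0] * n_per_group + [1] * n_per_group)
    m = mu[:, None] * 2.0 ** (lfc[:, None] * cond[None, :])
    if phi <= 0:
        counts = rng.poisson(m)
    else:
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + m))
    return make_count_matrix(counts, ["A"] * n_per_group + ["B"] * n_per_group)


@pytest.fixture(scope="session")
def default_scene_result():
    """The canonical planted-truth scene, built once per session."""
    from nasctx.simulate import default_scene

    return default_scene(seed=42)
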