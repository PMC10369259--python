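"""Shared fixtures and independent oracles for the test suite.

The oracles here recompute structural-entropy quantities by direct
edge/partition enumeration, deliberately avoiding the package's prefix-sum
and DP code paths so they can serve as ground truth.
"""

import itertools

import numpy as np
import pytest

from entropytld import ContactMatrix


def rand_sym_matrix(n, rng, density=0.7, loops=False, integer=False):
    """Random symmetric nonnegative matrix with at least one edge."""
    while True:
        a = rng.random((n, n)) * (rng.random((n, n)) < density)
        a = np.triu(a, k=1)
        a = a + a.T
        if loops:
            a += np.diag(rng.random(n) * (rng.random(n) < 0.5))
        if integer:
            a = np.round(a * 10)
        if a.sum() > 0:
            return a


def naive_partition_entropy(mat, intervals):
    """Eq.-by-eq evaluation of 2D structural entropy by direct summation.

    Boundary cuts are computed by enumerating every (inside, outside) vertex
    pair; gap bins contribute leaf-at-root terms.
    """
    mat = np.asarray(mat, dtype=float)
    n = mat.shape[0]
    d = mat.sum(axis=1)
    loops = np.diag(mat)
    two_m = d.sum()
    covered = np.zeros(n, dtype=bool)
    H = 0.0
    for a, b in intervals:
        covered[a:b] = True
        members = list(range(a, b))
        V = sum(d[i] for i in members)
        if V <= 0:
            continue
        g = sum(
            mat[i, j] for i in members for j in range(n) if not (a <= j < b)
        )
        if g > 0:
            H += -(g / two_m) * np.log2(V / two_m)
        for i in members:
            if d[i] > 0:
                H += -((d[i] - loops[i]) / two_m) * np.log2(d[i] / V)
    for i in range(n):
        if not covered[i] and d[i] > 0:
            H += -((d[i] - loops[i]) / two_m) * np.log2(d[i] / two_m)
    return H


def naive_entropy_1d(mat):
    d = np.asarray(mat, dtype=float).sum(axis=1)
    two_m = d.sum()
    p = d[d > 0] / two_m
    return float(-(p * np.log2(p)).sum())


def contiguous_partitions(n):
    """All 2^(n-1) partitions of 0..n-1 into contiguous runs."""
    for cuts in itertools.product([0, 1], repeat=n - 1):
        bounds = [0] + [i + 1 for i, c in enumerate(cuts) if c] + [n]
        yield list(zip(bounds[:-1], bounds[1:]))


def brute_force_min_entropy(mat, max_span=None):
    """Exhaustive minimum 2D entropy over contiguous partitions."""
    n = np.asarray(mat).shape[0]
    best = np.inf
    best_p = None
    for part in contiguous_partitions(n):
        if max_span is not None and any(b - a > max_span for a, b in part):
            continue
        h = naive_partition_entropy(mat, part)
        if h < best - 1e-15:
            best = h
            best_p = part
    return best, best_p


def segment_entropy_table(mat):
    """H_seg[i][j] for every contiguous segment [i, j] inclusive, by direct
    per-segment summation (no prefix sums, no DP)."""
    mat = np.asarray(mat, dtype=float)
    n = mat.shape[0]
    d = mat.sum(axis=1)
    loops = np.diag(mat)
    two_m = d.sum()
    H = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            idx = np.arange(i, j + 1)
            V = d[idx].sum()
            if V <= 0:
                H[i, j] = 0.0
                continue
            block = mat[np.ix_(idx, idx)].sum()
            g = max(V - block, 0.0)
            h = -(g / two_m) * np.log2(V / two_m) if g > 0 else 0.0
            dd = d[idx]
            dml = dd - loops[idx]
            pos = dd > 0
            h += float(-(dml[pos] / two_m * np.log2(dd[pos] / V)).sum())
            H[i, j] = h
    return H


def brute_force_min_entropy_fast(mat, max_span=None):
    """Exhaustive minimum over contiguous partitions using the segment table."""
    n = np.asarray(mat).shape[0]
    H = segment_entropy_table(mat)
    best, best_p = np.inf, None
    for part in contiguous_partitions(n):
        if max_span is not None and any(b - a > max_span for a, b in part):
            continue
        h = sum(H[a, b - 1] for a, b in part)
        if h < best - 1e-15:
            best, best_p = h, part
    return best, best_p


@pytest.fixture
def triangle():
    """Unit-weight triangle graph: the worked entropy example."""
    return ContactMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
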