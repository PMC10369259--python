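"""Structural-entropy mathematics for contact graphs.

The contact map is a weighted graph ``G``.  A height-2 encoding tree —
root, communities, bins — is equivalent to a partition ``P = {X_1..X_L}``
of the bins.  The structural entropy of ``G`` under that tree is

    H_P = sum_j [ -(g_j/2m) log2(V_j/2m)
                  - sum_{i in X_j} ((d_i - loop_i)/2m) log2(d_i/V_j) ]

where ``d_i`` is the degree of bin ``i`` (row sum, self-loop counted once),
``loop_i`` its self-loop weight, ``V_j`` the volume (degree sum) of
community ``j`` and ``g_j`` its cut — the weight of edges with exactly one
endpoint inside.  Gap bins sit directly under the root and contribute
``-((d_i - loop_i)/2m) log2(d_i/2m)`` each.  The 1D entropy ``H1`` is the
Shannon entropy of the degree distribution; the decoding information
``D = H1 - H_P`` is the uncertainty a partition removes, and
``NDI = D / H1`` normalizes it for comparison across binsizes.
All logarithms are base 2; entropies are in bits; ``0 log 0 = 0``.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .domains import DomainSet
from .matrix import ContactMatrix, DegenerateMatrixError

__all__ = [
    "entropy_1d",
    "partition_entropy",
    "segment_entropy",
    "decoding_information",
    "ndi",
    "SegmentScoreCache",
]


def _xlog2(x):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    nz = x > 0
    out[nz] = x[nz] * np.log2(x[nz])
    return out


def entropy_1d(cm: ContactMatrix) -> float:
    """1D structural entropy: Shannon entropy of the degree distribution, in bits."""
    d = cm.degrees
    two_m = d.sum()
    if two_m <= 0:
        raise DegenerateMatrixError("2m == 0: entropy undefined")
    p = d[d > 0] / two_m
    return float(-(p * np.log2(p)).sum())


class SegmentScoreCache:
    """Prefix sums enabling O(1) entropy queries on any bin range [i, i+k].

    Stores cumulative degrees, cumulative node-term pieces, and a banded
    table of block totals ``B(i, j) = sum_{a,b in [i..j]} M[a, b]`` for
    spans up to ``max_span`` bins.  The cut of a range follows from the
    once-counted degree convention: ``g(i, j) = V(i, j) - B(i, j)`` (the
    block total counts internal off-diagonal edges twice and loops once).
    """

    def __init__(self, cm: ContactMatrix, max_span=None):
        self.cm = cm
        n = cm.n_bins
        d = cm.degrees
        loops = cm.loops
        self.two_m = float(d.sum())
        if self.two_m <= 0:
            raise DegenerateMatrixError("2m == 0")
        self.n = n
        K = n - 1 if max_span is None else min(int(max_span), n - 1)
        self.max_span = K
        # prefix sums (index i+1 holds cumulative through bin i)
        self._cum_d = np.concatenate([[0.0], np.cumsum(d)])
        dml = d - loops
        self._cum_dml = np.concatenate([[0.0], np.cumsum(dml)])
        with np.errstate(divide="ignore"):
            log_d = np.where(d > 0, np.log2(np.where(d > 0, d, 1.0)), 0.0)
        self._cum_dml_logd = np.concatenate([[0.0], np.cumsum(dml * log_d)])
        # banded block totals: band[a, off] = M[a, a - off], off in [0, K]
        coo = cm.weights.tocoo()
        band = np.zeros((n, K + 1))
        sel = (coo.row - coo.col >= 0) & (coo.row - coo.col <= K)
        np.add.at(band, (coo.row[sel], (coo.row - coo.col)[sel]), coo.data[sel])
        # T[a, w] = sum_{off=1}^{w} M[a, a-off]
        T = np.zeros((n, K + 1))
        if K >= 1:
            T[:, 1:] = np.cumsum(band[:, 1:], axis=1)
        # block[i, w] = B(i, i+w), built by widening the range on the right
        diag = band[:, 0]
        self._block = np.full((n, K + 1), np.nan)
        self._block[:, 0] = diag
        prev = diag.copy()
        for w in range(1, K + 1):
            cur = np.full(n, np.nan)
            idx = np.arange(0, n - w)
            cur[idx] = prev[idx] + 2.0 * T[idx + w, w] + diag[idx + w]
            self._block[:, w] = cur
            prev = cur

    def volume(self, i, j) -> float:
        """V(i, j): degree sum over bins i..j inclusive."""
        return float(self._cum_d[j + 1] - self._cum_d[i])

    def block_total(self, i, j) -> float:
        return float(self._block[i, j - i])

    def cut(self, i, j) -> float:
        """g(i, j): weight of edges with exactly one endpoint in [i..j]."""
        return max(self.volume(i, j) - self.block_total(i, j), 0.0)

    def segment_entropy(self, i, k) -> float:
        """2D entropy of the single community of bins [i, i+k] inclusive, O(1)."""
        j = i + k
        if i < 0 or j >= self.n or k < 0:
            raise IndexError(f"segment ({i}, {i}+{k}) out of range for n={self.n}")
        if k > self.max_span:
            raise IndexError(f"segment span {k} exceeds cache max_span {self.max_span}")
        two_m = self.two_m
        V = self.volume(i, j)
        if V <= 0:
            return 0.0
        g = self.cut(i, j)
        boundary = -(g / two_m) * np.log2(V / two_m) if g > 0 else 0.0
        sum_dml = self._cum_dml[j + 1] - self._cum_dml[i]
        sum_dml_logd = self._cum_dml_logd[j + 1] - self._cum_dml_logd[i]
        node = -(sum_dml_logd - sum_dml * np.log2(V)) / two_m
        return float(boundary + node)


def segment_entropy(cache: SegmentScoreCache, i, k) -> float:
    """Module-level alias for :meth:`SegmentScoreCache.segment_entropy`."""
    return cache.segment_entropy(i, k)


def partition_entropy(cm: ContactMatrix, ds: DomainSet) -> float:
    """2D structural entropy of the contact graph under a flat partition.

    Bins not covered by any domain (gap bins) are attached directly to the
    root of the encoding tree and contribute leaf-at-root terms.
    """
    d = cm.degrees
    loops = cm.loops
    two_m = d.sum()
    if two_m <= 0:
        raise DegenerateMatrixError("2m == 0")
    n = cm.n_bins
    covered = np.zeros(n, dtype=bool)
    H = 0.0
    dense_needed = False
    w = cm.weights
    for a, b in ds.intervals:
        if b > n:
            raise IndexError(f"interval ({a}, {b}) outside matrix of {n} bins")
        covered[a:b] = True
        V = d[a:b].sum()
        if V <= 0:
            continue
        block = w[a:b, a:b].sum()
        g = max(V - block, 0.0)
        if g > 0:
            H += -(g / two_m) * np.log2(V / two_m)
        dml = d[a:b] - loops[a:b]
        dd = d[a:b]
        pos = dd > 0
        H += float(
            -np.sum(dml[pos] / two_m * np.log2(dd[pos] / V))
        )
    # gap bins: leaves directly under the root
    gap = ~covered
    if gap.any():
        dd = d[gap]
        dml = (d - loops)[gap]
        pos = dd > 0
        H += float(-np.sum(dml[pos] / two_m * np.log2(dd[pos] / two_m)))
    return float(H)


def decoding_information(cm: ContactMatrix, ds: DomainSet):
    """Decoding information D = H1 - H_P; returns (D, H1, H_P)."""
    h1 = entropy_1d(cm)
    hp = partition_entropy(cm, ds)
    return h1 - hp, h1, hp


def ndi(cm: ContactMatrix, ds: DomainSet) -> float:
    """Normalized decoding information (H1 - H_P) / H1."""
    dinfo, h1, _ = decoding_information(cm, ds)
    if h1 <= 0:
        raise DegenerateMatrixError("H1 == 0: NDI undefined")
    return float(dinfo / h1)
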