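"""Domain callers: global DP segmentation, sliding-window segmentation,
two-layer hierarchy assembly and NDI-based binsize selection.

The whole-chromosome caller finds the contiguous partition of the bins that
minimizes 2D structural entropy by dynamic programming over segment ends:

    f(i) = min_{0 <= k <= K} [ H(i, k) + f(i + k + 1) ],   f(n) = 0

where ``H(i, k)`` is the entropy contribution of a single community spanning
bins ``i..i+k`` (answered in O(1) from prefix sums) and ``K`` caps the
domain length (default 10 Mb worth of bins).  The sliding-window caller runs
the same DP inside 10-Mb windows and re-examines the last, possibly
truncated, domain of each window by restarting the next window at its first
bin — yielding a finer, locally optimal layer.  Stacking the two layers
gives a two-level hierarchy of TAD-like domains.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .domains import DomainSet, HierarchicalDomains, labels_from_domains
from .entropy import SegmentScoreCache, entropy_1d, ndi, partition_entropy
from .matrix import ContactMatrix, DegenerateMatrixError, regularize_isolated

__all__ = [
    "dedoc2_w",
    "dedoc2_s",
    "assemble_hierarchy",
    "select_binsize",
    "StructuralEntropyCaller",
    "HierarchicalCaller",
]


def _dp_segment(cache: SegmentScoreCache, max_span_bins):
    """Suffix DP over segment lengths; returns (intervals, optimal entropy).

    Ties between equal-entropy segment lengths break toward the smaller
    length, so the output is deterministic and biased toward finer domains.
    """
    n = cache.n
    K = min(max_span_bins - 1, n - 1)  # k is span-1 (segment has k+1 bins)
    f = np.empty(n + 1)
    f[n] = 0.0
    back = np.zeros(n, dtype=int)
    for i in range(n - 1, -1, -1):
        best = np.inf
        best_k = 0
        for k in range(0, min(K, n - 1 - i) + 1):
            val = cache.segment_entropy(i, k) + f[i + k + 1]
            if val < best - 1e-15:
                best = val
                best_k = k
        f[i] = best
        back[i] = best_k
    intervals = []
    i = 0
    while i < n:
        k = back[i]
        intervals.append((i, i + k + 1))
        i += k + 1
    return intervals, float(f[0])


def _filter_gap_domains(intervals, cm: ContactMatrix):
    """Drop domains made entirely of regularized gap bins (bookkeeping only)."""
    gap_bins = set(cm.meta.get("regularized_bins", []))
    if not gap_bins:
        return intervals
    kept = []
    for a, b in intervals:
        if not all(i in gap_bins for i in range(a, b)):
            kept.append((a, b))
    return kept


def dedoc2_w(cm: ContactMatrix, max_domain_bp=10_000_000) -> DomainSet:
    """Whole-chromosome caller: globally entropy-minimal contiguous partition.

    ``cm`` should be regularized (isolated bins carry self-loops) so the DP
    covers every bin.  Domain length is capped at ``max_domain_bp``.
    Domains consisting only of regularized gap bins are dropped from the
    returned set (they are layout bookkeeping, not TLD calls).
    """
    max_span_bins = max(int(max_domain_bp // cm.binsize), 1)
    cache = SegmentScoreCache(cm, max_span=max_span_bins - 1)
    intervals, opt = _dp_segment(cache, max_span_bins)
    full = DomainSet(intervals, cm.chrom, cm.binsize, n_bins=cm.n_bins)
    check = partition_entropy(cm, full)
    if abs(check - opt) > 1e-8 * max(1.0, abs(opt)):
        raise AssertionError(
            f"DP entropy {opt} disagrees with direct evaluation {check}"
        )
    kept = _filter_gap_domains(intervals, cm)
    ds = DomainSet(kept, cm.chrom, cm.binsize, n_bins=cm.n_bins)
    return ds


def dedoc2_s(cm: ContactMatrix, window_bp=10_000_000, max_domain_bp=None) -> DomainSet:
    """Sliding-window caller: entropy-minimal partitions inside 10-Mb windows.

    After segmenting a window, all domains but the last are committed and the
    window restarts at the first bin of the last (possibly truncated) domain,
    so domains straddling a window edge are re-examined whole.  A window that
    yields a single domain is committed whole and the window advances past it
    (otherwise the restart rule would never progress).
    """
    W = int(window_bp // cm.binsize)
    if W < 2:
        raise ValueError("window must span at least 2 bins")
    if max_domain_bp is None:
        max_domain_bp = window_bp
    n = cm.n_bins
    committed = []
    s = 0
    while s < n:
        e = min(s + W, n)
        sub_w = sp.csr_matrix(cm.weights[s:e, s:e])
        sub_cm = ContactMatrix(sub_w, cm.binsize, cm.chrom)
        if sub_cm.total_degree <= 0:
            # window of pure gap bins: bookkeeping domain, filtered below
            committed.append((s, e))
            s = e
            continue
        sub_cm, _ = regularize_isolated(sub_cm)
        local = dedoc2_w(sub_cm, max_domain_bp=max_domain_bp)
        doms = [(a + s, b + s) for a, b in local.intervals]
        if e == n:
            committed.extend(doms)
            break
        if len(doms) == 1:
            committed.extend(doms)
            s = doms[0][1]
        else:
            committed.extend(doms[:-1])
            s = doms[-1][0]
    kept = _filter_gap_domains(committed, cm)
    return DomainSet(kept, cm.chrom, cm.binsize, n_bins=cm.n_bins)


def assemble_hierarchy(nested: DomainSet, sub: DomainSet) -> HierarchicalDomains:
    """Nest the fine layer inside the coarse one.

    SubTLDs crossing a nested boundary are split at that boundary; each piece
    goes to the nested TLD containing its midpoint; pieces landing in gaps
    between nested TLDs are dropped; uncovered stretches inside a nested TLD
    become filler subTLDs so that every parent is tiled left to right.
    """
    if len(nested) == 0:
        raise ValueError("empty nested domain set")
    if nested.chrom != sub.chrom or nested.binsize != sub.binsize:
        raise ValueError("hierarchy layers must share chromosome and binsize")
    cutpoints = sorted({x for a, b in nested.intervals for x in (a, b)})

    def _pieces(a, b):
        pts = [a] + [x for x in cutpoints if a < x < b] + [b]
        return list(zip(pts, pts[1:]))

    def _parent_of(mid):
        for p, (na, nb) in enumerate(nested.intervals):
            if na <= mid < nb:
                return p
        return None

    assigned = {p: [] for p in range(len(nested))}
    for a, b in sub.intervals:
        for pa, pb in _pieces(a, b):
            p = _parent_of((pa + pb - 1) / 2.0)
            if p is not None:
                assigned[p].append((pa, pb))
    sub_iv, parents = [], []
    for p, (na, nb) in enumerate(nested.intervals):
        pieces = sorted(assigned[p])
        tiled = []
        cursor = na
        for pa, pb in pieces:
            if pa > cursor:
                tiled.append((cursor, pa))  # filler
            tiled.append((pa, pb))
            cursor = pb
        if cursor < nb:
            tiled.append((cursor, nb))
        for iv in tiled:
            sub_iv.append(iv)
            parents.append(p)
    sub_out = DomainSet(sub_iv, nested.chrom, nested.binsize, n_bins=nested.n_bins)
    return HierarchicalDomains(nested, sub_out, parents)


def select_binsize(matrices_by_binsize, candidates=None, max_domain_bp=10_000_000,
                   format="coo", diagonal=False):
    """Pick the binsize whose contact graph yields the highest NDI.

    ``matrices_by_binsize`` maps binsize (bp) to a ContactMatrix or a file
    path (loaded with :func:`entropytld.matrix.load_matrix`).  Each candidate
    matrix has its diagonal (intra-bin self-contacts) removed unless
    ``diagonal=True`` — self-loop mass is discounted by the community node
    terms and would otherwise push NDI up monotonically with coarsening —
    then is regularized, segmented by the whole-chromosome caller and scored
    by NDI; the argmax wins, ties going to the larger (coarser, more robust)
    binsize.  Returns ``(best_binsize, table)`` with one row per candidate.
    """
    from .matrix import drop_diagonal, load_matrix

    if candidates is None:
        candidates = sorted(matrices_by_binsize)
    if len(candidates) == 0:
        raise ValueError("no candidate binsizes")
    rows = []
    for bs in candidates:
        src = matrices_by_binsize[bs]
        try:
            cm = src if isinstance(src, ContactMatrix) else load_matrix(
                src, format=format, binsize=bs
            )
            if not diagonal:
                cm = drop_diagonal(cm)
            reg, _ = regularize_isolated(cm)
            ds = dedoc2_w(reg, max_domain_bp=max_domain_bp)
            h1 = entropy_1d(reg)
            hp = partition_entropy(reg, ds)
            rows.append({"binsize": bs, "H1": h1, "H2": hp,
                         "NDI": (h1 - hp) / h1, "n_domains": len(ds)})
        except DegenerateMatrixError as exc:
            warnings.warn(f"binsize {bs} skipped: {exc}", stacklevel=2)
    if not rows:
        raise DegenerateMatrixError("every candidate binsize was degenerate")
    table = pd.DataFrame(rows)
    best = table.sort_values(["NDI", "binsize"], ascending=[False, False])
    return int(best.iloc[0]["binsize"]), table


def _as_contact_matrix(X, binsize, chrom) -> ContactMatrix:
    if isinstance(X, ContactMatrix):
        return X
    return ContactMatrix(sp.csr_matrix(X), binsize=binsize, chrom=chrom)


class StructuralEntropyCaller:
    """Entropy-minimizing domain caller with a scikit-learn estimator API.

    Parameters
    ----------
    binsize : int, default 1
        Bin width in bp (ignored when fitting a ContactMatrix, which carries
        its own).
    max_domain_bp : int, default 10_000_000
        Length cap on a single domain.
    window_bp : int or None, default None
        ``None`` runs the global whole-chromosome DP; a window size runs the
        sliding-window caller, which yields finer domains.
    regularize : bool, default True
        Add self-loops ``r = 2m/n0`` to isolated bins before segmenting.

    Attributes
    ----------
    domains_ : DomainSet
    labels_ : ndarray of shape (n_bins,), per-bin domain labels (gap runs
        get their own labels)
    entropy_ : float, 2D structural entropy of the fitted partition (bits)
    h1_ : float, 1D structural entropy (bits)
    ndi_ : float, normalized decoding information of the partition
    """

    def __init__(self, binsize=1, max_domain_bp=10_000_000, window_bp=None,
                 regularize=True, chrom="chr"):
        self.binsize = binsize
        self.max_domain_bp = max_domain_bp
        self.window_bp = window_bp
        self.regularize = regularize
        self.chrom = chrom

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in
                ("binsize", "max_domain_bp", "window_bp", "regularize", "chrom")}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        cm = _as_contact_matrix(X, self.binsize, self.chrom)
        if self.regularize:
            cm, gaps = regularize_isolated(cm)
        else:
            gaps = cm.gap_mask()
        if self.window_bp is None:
            ds = dedoc2_w(cm, max_domain_bp=self.max_domain_bp)
        else:
            ds = dedoc2_s(cm, window_bp=self.window_bp,
                          max_domain_bp=self.max_domain_bp)
        self.matrix_ = cm
        self.gap_mask_ = gaps
        self.domains_ = ds
        self.labels_ = labels_from_domains(ds, n_bins=cm.n_bins)
        self.h1_ = entropy_1d(cm)
        self.entropy_ = partition_entropy(cm, ds)
        self.ndi_ = (self.h1_ - self.entropy_) / self.h1_
        self.n_domains_ = len(ds)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


class HierarchicalCaller:
    """Two-layer caller: global DP for nested TLDs, sliding windows for subTLDs.

    Attributes
    ----------
    hierarchy_ : HierarchicalDomains
    nested_, sub_ : DomainSet — the two layers after assembly
    labels_ : per-bin labels of the sub layer
    """

    def __init__(self, binsize=1, max_domain_bp=10_000_000,
                 window_bp=10_000_000, chrom="chr"):
        self.binsize = binsize
        self.max_domain_bp = max_domain_bp
        self.window_bp = window_bp
        self.chrom = chrom

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in
                ("binsize", "max_domain_bp", "window_bp", "chrom")}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        cm = _as_contact_matrix(X, self.binsize, self.chrom)
        cm, self.gap_mask_ = regularize_isolated(cm)
        nested = dedoc2_w(cm, max_domain_bp=self.max_domain_bp)
        sub = dedoc2_s(cm, window_bp=self.window_bp,
                       max_domain_bp=self.max_domain_bp)
        self.matrix_ = cm
        self.hierarchy_ = assemble_hierarchy(nested, sub)
        self.nested_ = self.hierarchy_.nested
        self.sub_ = self.hierarchy_.sub
        self.labels_ = labels_from_domains(self.sub_, n_bins=cm.n_bins)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
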