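"""Evaluation statistics for domain calls.

Covers label agreement (adjusted mutual information), the asymmetric
weighted similarity between domain sets, modularity and its per-domain
hierarchical variant, the distance-stratified adjusted R-squared of contact
variance explained by subTLDs, ChIP-seq peak enrichment around domain
boundaries, a size-preserving boundary shuffle for null models, and the
structural-entropy index that scores any caller's output on a matrix.
"""

from __future__ import annotations

import warnings

import numpy as np
import sklearn.metrics as skm

from .domains import DomainSet, HierarchicalDomains, labels_from_domains
from .entropy import partition_entropy
from .matrix import ContactMatrix, DegenerateMatrixError

__all__ = [
    "ami",
    "ws",
    "hierarchical_ws",
    "modularity",
    "tld_modularity",
    "tld_adj_r2",
    "boundary_enrichment",
    "shuffle_boundaries",
    "entropy_index",
    "PeakTrack",
]


class PeakTrack:
    """Sorted half-open (start_bp, end_bp) peak intervals on one chromosome."""

    def __init__(self, intervals, chrom="chr"):
        iv = sorted((int(a), int(b)) for a, b in intervals)
        for a, b in iv:
            if a < 0 or b <= a:
                raise ValueError(f"invalid peak interval ({a}, {b})")
        self.intervals = iv
        self.chrom = chrom

    def __len__(self):
        return len(self.intervals)

    @classmethod
    def from_bed(cls, path, chrom=None):
        """Read BED3/BED5/narrowPeak; extra columns ignored."""
        iv, got = [], chrom
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split()
                c, s, e = parts[0], int(parts[1]), int(parts[2])
                if chrom is not None and c != chrom:
                    continue
                got = got or c
                iv.append((s, e))
        return cls(iv, chrom=got or "chr")

    def count_in(self, start_bp, end_bp) -> int:
        """Number of peaks overlapping [start_bp, end_bp)."""
        return sum(1 for a, b in self.intervals if a < end_bp and b > start_bp)


def ami(t, k, average_method="arithmetic") -> float:
    """Adjusted mutual information between two per-bin labelings.

    ``AMI = (MI - E[MI]) / (mean(H(T), H(K)) - E[MI])`` with the
    hypergeometric expectation of MI under fixed marginals; identical
    labelings (including the degenerate one-cluster case) score 1.0.
    ``average_method`` selects the normalizer ("arithmetic" default,
    "max" for the classic strictest variant).
    """
    t = np.asarray(t)
    k = np.asarray(k)
    if t.shape != k.shape:
        raise ValueError("label vectors must have equal length")
    return float(
        skm.adjusted_mutual_info_score(t, k, average_method=average_method)
    )


def _domain_bin_sets(ds: DomainSet):
    return [set(range(a, b)) for a, b in ds.intervals]


def ws(t: DomainSet, k: DomainSet) -> float:
    """Weighted similarity WS(T, K) — asymmetric; reference calls in T.

    ``WS = sum_j S_K(T, K_j) |K_j| / sum_j |K_j|`` where
    ``S = max_i |T_i ∩ K_j| / sqrt(|T_i| |K_j|)``.  Gap bins are excluded
    (they belong to no domain in either set).
    """
    if len(k) == 0:
        raise ValueError("empty evaluated domain set K")
    if len(t) == 0:
        return 0.0
    tsets = _domain_bin_sets(t)
    num = 0.0
    den = 0.0
    for a, b in k.intervals:
        kj = set(range(a, b))
        size = len(kj)
        s = max(
            (len(ti & kj) / np.sqrt(len(ti) * size) for ti in tsets),
            default=0.0,
        )
        num += s * size
        den += size
    return float(num / den)


def _best_match(t: DomainSet, kj_set):
    """Index of the T domain with max geometric-mean-normalized overlap."""
    best, best_s = None, -1.0
    for i, (a, b) in enumerate(t.intervals):
        ti = set(range(a, b))
        s = len(ti & kj_set) / np.sqrt(len(ti) * len(kj_set))
        if s > best_s:
            best, best_s = i, s
    return best, best_s


def hierarchical_ws(t: HierarchicalDomains, k: HierarchicalDomains):
    """WS on the nested layer plus mean WS of subTLDs within matched parents.

    Each K nested TLD is paired with its best-matching T nested TLD (argmax
    of the geometric-mean overlap score); for every pair the subTLDs of both
    sides are clipped to the pair's intersection and scored by :func:`ws`;
    the mean over pairs is the within-parent similarity.
    """
    if len(t.sub) == 0 or len(k.sub) == 0:
        raise ValueError("hierarchies must carry subTLDs")
    ws_nested = ws(t.nested, k.nested)
    vals = []
    for ka, kb in k.nested.intervals:
        kj = set(range(ka, kb))
        ti, s = _best_match(t.nested, kj)
        if ti is None or s <= 0:
            continue
        ta, tb = t.nested.intervals[ti]
        lo, hi = max(ka, ta), min(kb, tb)
        if hi <= lo:
            continue
        t_clip = [(max(a, lo), min(b, hi)) for a, b in t.sub.intervals
                  if min(b, hi) > max(a, lo)]
        k_clip = [(max(a, lo), min(b, hi)) for a, b in k.sub.intervals
                  if min(b, hi) > max(a, lo)]
        if not t_clip or not k_clip:
            continue
        vals.append(ws(
            DomainSet(t_clip, t.sub.chrom, t.sub.binsize),
            DomainSet(k_clip, k.sub.chrom, k.sub.binsize),
        ))
    ws_sub_within = float(np.mean(vals)) if vals else float("nan")
    return ws_nested, ws_sub_within


def _modularity_transform(mat: np.ndarray) -> np.ndarray:
    """Zero the diagonal, then map remaining positive entries x -> log2(x+1)."""
    mp = np.array(mat, dtype=float)
    np.fill_diagonal(mp, 0.0)
    pos = mp > 0
    mp[pos] = np.log2(mp[pos] + 1.0)
    return mp


def modularity(cm: ContactMatrix, ds: DomainSet, transform=True) -> float:
    """Newman modularity of a domain partition on the (log-scaled) contact map.

    ``Q = (1/2m) sum_ij [M'_ij - k_i k_j / 2m] delta(sigma_i, sigma_j)``;
    gap bins count as singleton communities; degrees and ``m`` are
    recomputed on the transformed matrix.
    """
    mat = cm.toarray()
    mp = _modularity_transform(mat) if transform else mat
    deg = mp.sum(axis=1)
    two_m = deg.sum()
    if two_m <= 0:
        raise DegenerateMatrixError("transformed matrix has no edges")
    labels = labels_from_domains(ds, n_bins=cm.n_bins, label_gaps=False)
    # gap bins as singletons: give each its own label
    nxt = labels.max() + 1 if labels.size else 0
    for i in np.flatnonzero(labels == -1):
        labels[i] = nxt
        nxt += 1
    q = 0.0
    for lab in np.unique(labels):
        idx = labels == lab
        e_in = mp[np.ix_(idx, idx)].sum()
        a = deg[idx].sum()
        q += e_in / two_m - (a / two_m) ** 2
    return float(q)


def tld_modularity(cm: ContactMatrix, h: HierarchicalDomains) -> float:
    """Mean modularity over nested TLDs, each scored under its subTLD division.

    Each nested TLD's submatrix is treated as an independent network and its
    subTLDs (shifted to local coordinates) as the communities.
    """
    mat = cm.toarray()
    vals = []
    for p, (na, nb) in enumerate(h.nested.intervals):
        sub_iv = [(a - na, b - na) for a, b in h.children(p)]
        sub_cm = ContactMatrix(mat[na:nb, na:nb], cm.binsize, cm.chrom)
        sub_ds = DomainSet(sub_iv, cm.chrom, cm.binsize, n_bins=nb - na)
        try:
            vals.append(modularity(sub_cm, sub_ds))
        except DegenerateMatrixError:
            continue
    if not vals:
        raise DegenerateMatrixError("no nested TLD yielded a defined modularity")
    return float(np.mean(vals))


def tld_adj_r2(cm: ContactMatrix, h: HierarchicalDomains, max_dist_bins=20):
    """Distance-stratified adjusted R² of contact variance explained by subTLDs.

    For each genomic distance ``g`` (in bins), every bin pair ``(i, i+g)``
    gets a fitted value: the mean contact at distance ``g`` within the
    subTLD containing the pair, or the pooled gap-stratum mean when the pair
    spans no single subTLD.  With ``n`` pairs and ``p`` subTLDs of length
    >= g,

        adjR²(g) = 1 - [SS_res / (n - p - 1)] / [SS_tot / (n - 1)]

    Distances where ``n - p - 1 <= 0`` are undefined (NaN) and excluded from
    the mean.  Returns ``(per_distance: ndarray, mean: float)``.
    """
    mat = cm.toarray()
    n_bins = cm.n_bins
    sub_id = np.full(n_bins, -1, dtype=int)
    sizes = []
    for s_idx, (a, b) in enumerate(h.sub.intervals):
        sub_id[a:b] = s_idx
        sizes.append(b - a)
    sizes = np.asarray(sizes)
    out = np.full(max_dist_bins, np.nan)
    for g in range(1, max_dist_bins + 1):
        if g >= n_bins:
            break
        i = np.arange(n_bins - g)
        y = mat[i, i + g]
        same = (sub_id[i] >= 0) & (sub_id[i] == sub_id[i + g])
        group = np.where(same, sub_id[i], -1)
        yhat = np.empty_like(y)
        for lab in np.unique(group):
            sel = group == lab
            yhat[sel] = y[sel].mean()
        n = len(y)
        p = int((sizes >= g).sum())
        if n - p - 1 <= 0 or n < 2:
            continue
        ss_res = ((y - yhat) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        if ss_tot == 0:
            out[g - 1] = 1.0 if ss_res == 0 else np.nan
            continue
        out[g - 1] = 1.0 - (ss_res / (n - p - 1)) / (ss_tot / (n - 1))
    mean = float(np.nanmean(out)) if np.isfinite(out).any() else np.nan
    return out, mean


def boundary_enrichment(ds, peaks: PeakTrack, binsize=None,
                        background_offsets=(100_000, 500_000),
                        flank_bins=2, chrom_length_bp=None):
    """Fold change of peak density at domain boundaries vs flanking background.

    A boundary is the edge between two adjacent domains.  The boundary
    region spans ``flank_bins`` bins on each side of the edge; background
    windows of the same width are centered 100 kb and 500 kb away on both
    sides.  Fold change = peaks-per-kb in boundary regions over
    peaks-per-kb in background.  If the background holds no peaks, one
    pseudocount peak is added to both counts and the result is flagged.
    Windows are clipped to ``[0, chrom_length_bp)`` when a chromosome length
    is given, so windows running off the ends do not dilute the density.
    """
    if isinstance(ds, HierarchicalDomains):
        ds = ds.nested
    if binsize is None:
        binsize = ds.binsize
    edges = ds.boundaries_bp()
    if not edges:
        raise ValueError("no boundary edges (fewer than two adjacent domains)")
    end = np.inf if chrom_length_bp is None else chrom_length_bp
    half = flank_bins * binsize
    b_count = b_len = 0.0
    g_count = g_len = 0.0
    for e in edges:
        lo, hi = max(e - half, 0), min(e + half, end)
        b_count += peaks.count_in(lo, hi)
        b_len += hi - lo
        for off in background_offsets:
            for center in (e - off, e + off):
                lo, hi = max(center - half, 0), min(center + half, end)
                if hi <= lo:
                    continue
                g_count += peaks.count_in(lo, hi)
                g_len += hi - lo
    flagged = False
    if g_count == 0:
        b_count += 1.0
        g_count += 1.0
        flagged = True
        warnings.warn("no background peaks: +1 pseudocount applied", stacklevel=2)
    fold = (b_count / (b_len / 1000.0)) / (g_count / (g_len / 1000.0))
    return fold, flagged


def shuffle_boundaries(ds: DomainSet, n_shuffles=2500, seed=0, n_bins=None):
    """Size-preserving random relocations of a domain set.

    Each shuffle permutes the multiset of domain lengths and re-places them
    along the chromosome with a uniformly random gap composition, preserving
    the domain count and the size multiset exactly.
    """
    if len(ds) == 0:
        raise ValueError("cannot shuffle an empty domain set")
    n = n_bins if n_bins is not None else ds.span
    sizes = ds.sizes
    total = int(sizes.sum())
    if total > n:
        raise ValueError("domains longer than chromosome")
    L = len(sizes)
    gap_total = n - total
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_shuffles):
        perm = rng.permutation(sizes)
        # uniform composition of gap_total into L+1 parts (stars and bars)
        if gap_total > 0:
            bars = np.sort(rng.choice(gap_total + L, size=L, replace=False))
            parts = np.diff(np.concatenate([[-1], bars, [gap_total + L]])) - 1
        else:
            parts = np.zeros(L + 1, dtype=int)
        iv = []
        cursor = 0
        for g, s in zip(parts[:-1], perm):
            cursor += int(g)
            iv.append((cursor, cursor + int(s)))
            cursor += int(s)
        out.append(DomainSet(iv, ds.chrom, ds.binsize, n_bins=n))
    return out


def entropy_index(cm: ContactMatrix, ds: DomainSet) -> float:
    """2D structural entropy of a matrix under any caller's domain set.

    Gap bins (bins in no domain) sit directly under the root of the encoding
    tree, so external callers' outputs are scored on equal footing.
    """
    return partition_entropy(cm, ds)
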