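"""Synthetic contact-map generation for benchmarking the callers.

Two families of fixtures:

* **Planted hierarchies** — two-level block-diagonal intensity fields with
  power-law distance decay, sampled to a requested sequencing depth.  The
  ground-truth hierarchy is returned alongside, so recovery can be scored.
* **Polymer ensembles** — confined random-walk chains standing in for a 3D
  chromosome model.  Reference ("bulk") maps sample locus pairs with weight
  ``1/distance``; single-cell maps sample with weight ``max(D - distance, 0)``
  so that only loci closer than the threshold ``D`` ever contact, and a cell
  carries on the order of 1000 contacts.

Plus the two perturbations used to stress callers: binomial downsampling of
counts and distance-decay-matched noise injection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .domains import DomainSet, HierarchicalDomains
from .matrix import ContactMatrix

__all__ = [
    "PlantedHierarchy",
    "PolymerEnsemble",
    "make_planted_matrix",
    "simulate_polymer",
    "render_reference_hic",
    "render_sc_hic",
    "downsample",
    "inject_noise",
]


@dataclass
class PlantedHierarchy:
    """Two-level planted block structure with contact-intensity multipliers.

    ``block_bounds`` are level-1 cut points (including 0 and n_bins);
    ``sub_bounds`` refine them.  Intensities multiply a shared power-law
    distance decay: ``intra_sub`` within a subTLD, ``intra_block`` between
    subTLDs of one block, ``inter`` across blocks.
    """

    block_bounds: list
    sub_bounds: list
    intra_sub: float = 3.0
    intra_block: float = 1.0
    inter: float = 0.1
    decay_exponent: float = 1.0

    def __post_init__(self):
        bb, sb = sorted(self.block_bounds), sorted(self.sub_bounds)
        if not set(bb) <= set(sb):
            raise ValueError("sub_bounds must refine block_bounds")
        if min(self.intra_sub, self.intra_block, self.inter) < 0:
            raise ValueError("intensities must be nonnegative")
        self.block_bounds, self.sub_bounds = bb, sb

    @property
    def n_bins(self) -> int:
        return self.block_bounds[-1]

    def truth(self, binsize=1, chrom="chr") -> HierarchicalDomains:
        nested = DomainSet(
            list(zip(self.block_bounds[:-1], self.block_bounds[1:])),
            chrom, binsize, n_bins=self.n_bins,
        )
        sub = DomainSet(
            list(zip(self.sub_bounds[:-1], self.sub_bounds[1:])),
            chrom, binsize, n_bins=self.n_bins,
        )
        parents = []
        for a, b in sub.intervals:
            mid = (a + b - 1) / 2.0
            parents.append(next(
                p for p, (na, nb) in enumerate(nested.intervals) if na <= mid < nb
            ))
        return HierarchicalDomains(nested, sub, parents)

    @classmethod
    def random(cls, n_blocks=20, subs_per_block=(3, 5), block_bins=(9, 16),
               seed=0, **kw):
        """Random layout: ``n_blocks`` level-1 blocks of ``block_bins`` bins,
        each split into ``subs_per_block`` subTLDs of >= 2 bins."""
        rng = np.random.default_rng(seed)
        bb = [0]
        sb = [0]
        for _ in range(n_blocks):
            size = int(rng.integers(block_bins[0], block_bins[1] + 1))
            n_sub = int(rng.integers(subs_per_block[0], subs_per_block[1] + 1))
            n_sub = min(n_sub, size // 2)
            # pieces of >= 2 bins each, remainder spread multinomially
            pieces = np.full(n_sub, 2)
            extra = size - 2 * n_sub
            add = rng.multinomial(extra, np.ones(n_sub) / n_sub)
            pieces = pieces + add
            start = bb[-1]
            for p in pieces[:-1]:
                sb.append(sb[-1] + int(p))
            bb.append(start + size)
            sb.append(bb[-1])
        return cls(bb, sb, **kw)


def _planted_probability_field(ph: PlantedHierarchy) -> np.ndarray:
    n = ph.n_bins
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    decay = 1.0 / (1.0 + np.abs(i - j)) ** ph.decay_exponent
    block_id = np.searchsorted(ph.block_bounds, np.arange(n), side="right") - 1
    sub_id = np.searchsorted(ph.sub_bounds, np.arange(n), side="right") - 1
    mult = np.full((n, n), ph.inter)
    same_block = block_id[i] == block_id[j]
    mult[same_block] = ph.intra_block
    same_sub = sub_id[i] == sub_id[j]
    mult[same_sub] = ph.intra_sub
    field = decay * mult
    np.fill_diagonal(field, 0.0)  # sample off-diagonal contacts
    return field


def make_planted_matrix(ph: PlantedHierarchy, depth=1_000_000, binsize=1,
                        chrom="chr", seed=0):
    """Sample ``depth`` contacts from the planted intensity field.

    Returns ``(ContactMatrix, truth HierarchicalDomains)``.  Contacts are
    drawn multinomially over upper-triangle cells and mirrored, so the
    realized total equals ``depth`` exactly.
    """
    field = _planted_probability_field(ph)
    n = ph.n_bins
    iu, ju = np.triu_indices(n, k=1)
    probs = field[iu, ju]
    total = probs.sum()
    if total <= 0:
        raise ValueError("zero-probability contact field")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(int(depth), probs / total)
    mat = sp.coo_matrix((counts, (iu, ju)), shape=(n, n)).tocsr()
    mat = mat + mat.T
    cm = ContactMatrix(sp.csr_matrix(mat, dtype=float), binsize, chrom)
    return cm, ph.truth(binsize=binsize, chrom=chrom)


@dataclass
class PolymerEnsemble:
    """Set of 3D conformations; ``coords[c]`` is (n_monomers, 3) for cell c."""

    coords: np.ndarray  # (n_cells, n_monomers, 3)
    confinement_radius: float = np.inf
    meta: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    @property
    def n_monomers(self) -> int:
        return self.coords.shape[1]


def simulate_polymer(n_monomers=125, n_cells=100, confinement_radius=10.0,
                     step_scale=1.0, seed=0) -> PolymerEnsemble:
    """Confined random-walk chains as a stand-in chromosome-structure ensemble.

    Each chain takes isotropic Gaussian steps of RMS length ``step_scale``;
    excursions beyond the confinement sphere are radially reflected back
    inside.  Deterministic for a given seed.
    """
    if n_monomers < 2:
        raise ValueError("need at least 2 monomers")
    if confinement_radius <= 0:
        raise ValueError("confinement radius must be positive")
    rng = np.random.default_rng(seed)
    R = float(confinement_radius)
    coords = np.zeros((n_cells, n_monomers, 3))
    for c in range(n_cells):
        pos = rng.uniform(-R / 2, R / 2, size=3)
        coords[c, 0] = pos
        for m in range(1, n_monomers):
            step = rng.normal(scale=step_scale / np.sqrt(3.0), size=3)
            pos = pos + step
            r = np.linalg.norm(pos)
            if r > R:
                pos = pos * (2 * R - r) / r  # reflect at the sphere
            coords[c, m] = pos
    return PolymerEnsemble(coords, R, {"step_scale": step_scale, "seed": seed})


def _pair_distances(xyz: np.ndarray):
    n = xyz.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    d = np.linalg.norm(xyz[iu] - xyz[ju], axis=1)
    return iu, ju, d


def render_reference_hic(pe: PolymerEnsemble, depth=1_000_000, binsize=40_000,
                         chrom="chr", seed=0) -> ContactMatrix:
    """Bulk-like map: sample locus pairs over the pooled ensemble with
    weight ``1/distance``.  Coincident monomers get a tiny jitter so the
    weight stays finite.  One monomer = one bin (40-kb semantics)."""
    n = pe.n_monomers
    iu, ju = np.triu_indices(n, k=1)
    weights = np.zeros(len(iu))
    for c in range(pe.n_cells):
        _, _, d = _pair_distances(pe.coords[c])
        d = np.maximum(d, 1e-9)
        weights += 1.0 / d
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(int(depth), weights / weights.sum())
    mat = sp.coo_matrix((counts, (iu, ju)), shape=(n, n)).tocsr()
    mat = mat + mat.T
    return ContactMatrix(sp.csr_matrix(mat, dtype=float), binsize, chrom)


def render_sc_hic(conformation: np.ndarray, threshold_d=0.4, depth=1000,
                  binsize=40_000, chrom="chr", seed=0,
                  quantile=True) -> ContactMatrix:
    """Single-cell map from one conformation with a hard contact radius.

    Weights are ``max(D - distance, 0)``: pairs at distance >= D can never
    contact.  ``threshold_d`` is a quantile of the conformation's pairwise
    distances by default (the 20/40/60% quantiles are typical working
    points), or an absolute distance with ``quantile=False``.  ``depth``
    contacts (about 1000 for a realistic single cell) are sampled
    multinomially.
    """
    xyz = np.asarray(conformation, dtype=float)
    iu, ju, d = _pair_distances(xyz)
    D = float(np.quantile(d, threshold_d)) if quantile else float(threshold_d)
    w = np.maximum(D - d, 0.0)
    n = xyz.shape[0]
    if w.sum() <= 0:
        warnings.warn("threshold below minimum pairwise distance: empty matrix",
                      stacklevel=2)
        return ContactMatrix(sp.csr_matrix((n, n)), binsize, chrom,
                             {"threshold_D": D})
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(int(depth), w / w.sum())
    mat = sp.coo_matrix((counts, (iu, ju)), shape=(n, n)).tocsr()
    mat = mat + mat.T
    return ContactMatrix(sp.csr_matrix(mat, dtype=float), binsize, chrom,
                         {"threshold_D": D})


def downsample(cm: ContactMatrix, rate, seed=0) -> ContactMatrix:
    """Binomial thinning: each contact kept independently with prob ``rate``.

    Applied to the upper triangle (incl. diagonal) and mirrored, preserving
    symmetry.  Requires an integer-valued matrix.
    """
    if not (0 < rate <= 1):
        raise ValueError("rate must be in (0, 1]")
    upper = sp.triu(cm.weights, k=0).tocoo()
    if upper.nnz and not np.allclose(upper.data, np.round(upper.data)):
        raise ValueError("downsampling requires an integer-count matrix")
    if rate == 1:
        return cm.copy()
    rng = np.random.default_rng(seed)
    kept = rng.binomial(upper.data.astype(int), rate).astype(float)
    thin = sp.coo_matrix((kept, (upper.row, upper.col)), shape=cm.weights.shape)
    diag = sp.diags(thin.tocsr().diagonal())
    full = thin + thin.T - diag
    return ContactMatrix(sp.csr_matrix(full), cm.binsize, cm.chrom, dict(cm.meta))


def inject_noise(cm: ContactMatrix, noise_frac, seed=0) -> ContactMatrix:
    """Add ``round(noise_frac * total_contacts)`` unit counts as noise.

    Additions are allocated across secondary diagonals proportionally to
    each diagonal's empirical mean contact (the matrix's own distance-decay
    profile), then placed uniformly with replacement among that diagonal's
    eligible cells — cells whose row and column both carry at least one
    contact.  Placement is symmetric.
    """
    upper = sp.triu(cm.weights, k=0).tocoo()
    total = upper.data.sum()
    n_add = int(round(noise_frac * total))
    if n_add == 0:
        return cm.copy()
    n = cm.n_bins
    eligible = np.asarray(cm.weights.sum(axis=1)).ravel() > 0
    if not eligible.any():
        raise ValueError("no eligible rows/columns for noise placement")
    dense = cm.toarray()
    # per-diagonal decay profile and eligible cells
    diag_cells = {}
    diag_weight = []
    offsets = []
    for off in range(1, n):
        rows = np.arange(0, n - off)
        cols = rows + off
        ok = eligible[rows] & eligible[cols]
        if not ok.any():
            continue
        vals = dense[rows, cols]
        mean = vals.mean()  # empirical decay at this distance
        if mean <= 0:
            continue
        diag_cells[off] = (rows[ok], cols[ok])
        diag_weight.append(mean)
        offsets.append(off)
    if not offsets:
        raise ValueError("no eligible secondary-diagonal cells")
    diag_weight = np.asarray(diag_weight, dtype=float)
    rng = np.random.default_rng(seed)
    alloc = rng.multinomial(n_add, diag_weight / diag_weight.sum())
    add = np.zeros((n, n))
    for off, cnt in zip(offsets, alloc):
        if cnt == 0:
            continue
        rows, cols = diag_cells[off]
        picks = rng.integers(0, len(rows), size=cnt)  # with replacement
        np.add.at(add, (rows[picks], cols[picks]), 1.0)
    add = add + add.T
    out = ContactMatrix(sp.csr_matrix(cm.weights + sp.csr_matrix(add)),
                        cm.binsize, cm.chrom, dict(cm.meta))
    out.meta["noise_added"] = n_add
    return out
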