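"""Contact-matrix data model, text I/O, normalization and gap handling.

A :class:`ContactMatrix` holds the symmetric, nonnegative bin-by-bin contact
map of one chromosome.  The map is viewed as a weighted graph ``G(V, E)``:
bins are vertices, contact counts are edge weights, and diagonal entries are
self-loop weights.  All downstream entropy computations use the once-counted
degree convention ``d_i = sum_j M[i, j]`` (the self-loop weight enters the
row sum exactly once), so ``2m = sum_i d_i``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ContactMatrix",
    "GapMask",
    "load_matrix",
    "save_coo",
    "degree_vector",
    "regularize_isolated",
    "sqrtvc_normalize",
    "rwr_impute",
    "RWRImputer",
]


class DegenerateMatrixError(ValueError):
    """Raised when an operation receives a matrix it cannot act on (e.g. all-zero)."""


@dataclass
class ContactMatrix:
    """Symmetric nonnegative contact map for a single chromosome.

    Parameters
    ----------
    weights : scipy.sparse.csr_matrix
        ``n_bins x n_bins`` symmetric matrix of contact weights.
    binsize : int
        Bin width in bp; bin ``i`` covers ``[i*binsize, (i+1)*binsize)``.
    chrom : str
        Chromosome label.
    meta : dict
        Free-form provenance (imputation parameters, regularization log, ...).
    """

    weights: sp.csr_matrix
    binsize: int = 1
    chrom: str = "chr"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        w = sp.csr_matrix(self.weights, dtype=np.float64)
        if w.shape[0] != w.shape[1]:
            raise ValueError(f"contact matrix must be square, got {w.shape}")
        if w.nnz and w.data.min() < 0:
            raise ValueError("contact matrix entries must be nonnegative")
        if w.nnz and not np.all(np.isfinite(w.data)):
            raise ValueError("contact matrix entries must be finite")
        asym = abs(w - w.T)
        if asym.nnz and asym.data.max() > 1e-9 * max(1.0, abs(w).data.max()):
            warnings.warn(
                "asymmetric contact matrix symmetrized as (M + M.T)/2",
                stacklevel=3,
            )
            w = (w + w.T) * 0.5
        w.eliminate_zeros()
        self.weights = w
        if self.binsize <= 0:
            raise ValueError("binsize must be positive")

    @property
    def n_bins(self) -> int:
        return self.weights.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        """Per-bin degrees ``d_i`` (row sums, loop counted once)."""
        return np.asarray(self.weights.sum(axis=1)).ravel()

    @property
    def total_degree(self) -> float:
        """``2m``, the total degree of the graph."""
        return float(self.degrees.sum())

    @property
    def loops(self) -> np.ndarray:
        """Self-loop weights (the diagonal)."""
        return self.weights.diagonal()

    def gap_mask(self) -> "GapMask":
        return GapMask(self.degrees == 0)

    def toarray(self) -> np.ndarray:
        return self.weights.toarray()

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            self.weights.copy(), self.binsize, self.chrom, dict(self.meta)
        )


@dataclass
class GapMask:
    """Boolean per-bin mask; True marks isolated (zero-degree) bins."""

    isolated: np.ndarray

    def __post_init__(self):
        self.isolated = np.asarray(self.isolated, dtype=bool)

    @property
    def n_isolated(self) -> int:
        return int(self.isolated.sum())

    def __len__(self):
        return len(self.isolated)


def _read_dense(path) -> sp.csr_matrix:
    arr = np.loadtxt(path, dtype=np.float64, ndmin=2)
    if arr.shape[0] != arr.shape[1]:
        raise ValueError(f"dense matrix file is not square: {arr.shape}")
    return sp.csr_matrix(arr)


def _read_coo(path, n_bins=None) -> sp.csr_matrix:
    rows, cols, vals = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
            if i < 0 or j < 0:
                raise IndexError(f"negative bin index in COO input: ({i}, {j})")
            rows.append(i)
            cols.append(j)
            vals.append(v)
    if n_bins is None:
        n_bins = max(max(rows, default=-1), max(cols, default=-1)) + 1
        if n_bins == 0:
            raise ValueError("empty COO file and no n_bins given")
    if rows and (max(rows) >= n_bins or max(cols) >= n_bins):
        raise IndexError("bin index >= n_bins in COO input")
    m = sp.coo_matrix((vals, (rows, cols)), shape=(n_bins, n_bins)).tocsr()
    # duplicates were summed by coo construction
    return _symmetrize_coo(m)


def _symmetrize_coo(m: sp.csr_matrix) -> sp.csr_matrix:
    lower = sp.tril(m, k=-1)
    upper = sp.triu(m, k=1)
    if lower.nnz == 0 or upper.nnz == 0:
        # one-triangle input: mirror it
        off = lower + upper
        return sp.csr_matrix(off + off.T + sp.diags(m.diagonal()))
    # both triangles present: average, per the symmetrization contract
    return sp.csr_matrix((m + m.T) * 0.5)


def load_matrix(path, format="coo", binsize=1, chrom="chr", n_bins=None) -> ContactMatrix:
    """Load a single-chromosome contact matrix from disk.

    ``format`` is one of ``dense`` (whitespace-delimited n x n table),
    ``coo`` (``i j value`` triplets, 0-based; upper-triangle-only input is
    mirrored, two-triangle input is symmetrized) or ``cooler`` (requires the
    optional :mod:`cooler` package).
    """
    if format == "dense":
        w = _read_dense(path)
    elif format == "coo":
        w = _read_coo(path, n_bins=n_bins)
    elif format == "cooler":
        try:
            import cooler  # noqa: F401
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "reading .cool files requires the optional 'cooler' package"
            ) from exc
        clr = cooler.Cooler(str(path))
        w = sp.csr_matrix(clr.matrix(balance=False, sparse=True).fetch(chrom))
        binsize = clr.binsize or binsize
    else:
        raise ValueError(f"unknown format {format!r}")
    return ContactMatrix(w, binsize=binsize, chrom=chrom)


def save_coo(cm: ContactMatrix, path) -> None:
    """Write the upper triangle (including diagonal) as COO text with a header."""
    coo = sp.triu(cm.weights, k=0).tocoo()
    imputed = cm.meta.get("imputed", False)
    with open(path, "w") as fh:
        fh.write(f"# binsize={cm.binsize} chrom={cm.chrom} imputed={imputed}\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i}\t{j}\t{v:.10g}\n")


def drop_diagonal(cm: ContactMatrix) -> ContactMatrix:
    """Zero the diagonal (intra-bin self-ligation signal).

    Self-contacts carry no information about domain structure, and because
    the community node terms discount self-loop weight they systematically
    inflate NDI on coarse binnings; binsize selection removes them before
    scoring.
    """
    w = cm.weights - sp.diags(cm.weights.diagonal())
    return ContactMatrix(sp.csr_matrix(w), cm.binsize, cm.chrom, dict(cm.meta))


def coarsen(cm: ContactMatrix, factor: int) -> ContactMatrix:
    """Aggregate ``factor`` adjacent bins into one (rebinning to a coarser
    binsize).  A trailing partial bin group is kept."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return cm.copy()
    n = cm.n_bins
    n_out = -(-n // factor)
    rows = np.repeat(np.arange(n_out), factor)[:n]
    agg = sp.csr_matrix(
        (np.ones(n), (rows, np.arange(n))), shape=(n_out, n)
    )
    w = sp.csr_matrix(agg @ cm.weights @ agg.T)
    return ContactMatrix(w, cm.binsize * factor, cm.chrom, dict(cm.meta))


def degree_vector(cm: ContactMatrix):
    """Return ``(d, 2m)``: per-bin degrees and the total degree."""
    d = cm.degrees
    return d, float(d.sum())


def regularize_isolated(cm: ContactMatrix):
    """Give every isolated bin a self-loop of weight ``r = 2m / n0``.

    ``n0`` is the number of nonisolated bins and ``m`` the total edge weight,
    both computed on the input.  The added loops keep isolated bins from
    being absorbed into neighbouring communities during segmentation.

    Returns the regularized matrix together with a :class:`GapMask` recording
    which bins received the loop.
    """
    d = cm.degrees
    iso = d == 0
    n0 = int((~iso).sum())
    if n0 == 0:
        raise DegenerateMatrixError("all-zero matrix: no nonisolated bins")
    if not iso.any():
        return cm.copy(), GapMask(iso)
    r = float(d.sum()) / n0  # 2m / n0
    add = sp.diags(np.where(iso, r, 0.0))
    out = ContactMatrix(
        sp.csr_matrix(cm.weights + add), cm.binsize, cm.chrom, dict(cm.meta)
    )
    out.meta["regularized_bins"] = np.flatnonzero(iso).tolist()
    out.meta["regularization_r"] = r
    return out, GapMask(iso)


def sqrtvc_normalize(cm: ContactMatrix) -> ContactMatrix:
    """sqrtVC normalization: ``C[i,j] = M[i,j] / sqrt(d_i * d_j)``.

    Rows/columns with zero degree stay zero.  The result is symmetric
    whenever the input is.
    """
    d = cm.degrees
    with np.errstate(divide="ignore"):
        inv = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    D = sp.diags(inv)
    C = sp.csr_matrix(D @ cm.weights @ D)
    return ContactMatrix(C, cm.binsize, cm.chrom, dict(cm.meta))


def rwr_impute(cm: ContactMatrix, restart_prob=0.05, tol=1e-2, max_iter=100) -> ContactMatrix:
    """Random-walk-with-restart imputation of a sparse contact map.

    The input is sqrtVC-normalized to ``C`` and the iteration

        ``Q_t = (1 - alpha) Q_{t-1} C + alpha I``,  ``Q_0 = I``

    is run until ``||Q_t - Q_{t-1}||_2 <= tol`` (Frobenius norm) or
    ``max_iter`` sweeps.  The fixed point is ``alpha (I - (1-alpha) C)^-1``.
    Output is symmetrized defensively and carries convergence metadata.
    """
    if not (0 < restart_prob <= 1):
        raise ValueError("restart_prob must be in (0, 1]")
    alpha = float(restart_prob)
    C = sqrtvc_normalize(cm).weights
    n = cm.n_bins
    Q = sp.identity(n, format="csr")
    I = sp.identity(n, format="csr")
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        Q_next = (1.0 - alpha) * (Q @ C) + alpha * I
        diff = Q_next - Q
        delta = np.sqrt((diff.multiply(diff)).sum())
        Q = Q_next
        if delta <= tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"RWR did not converge within {max_iter} iterations", stacklevel=2
        )
    Q = sp.csr_matrix((Q + Q.T) * 0.5)
    meta = dict(cm.meta)
    meta.update(
        imputed=True, rwr_alpha=alpha, rwr_iterations=n_iter, rwr_converged=converged
    )
    return ContactMatrix(Q, cm.binsize, cm.chrom, meta)


class RWRImputer:
    """Scikit-learn style transformer wrapping :func:`rwr_impute`.

    Parameters
    ----------
    restart_prob : float, default 0.05
        Restart probability ``alpha`` of the random walk.
    tol : float, default 1e-2
        Frobenius-norm convergence tolerance on successive iterates.
    max_iter : int, default 100
        Iteration cap; exceeding it flags (not fails) the output.
    """

    def __init__(self, restart_prob=0.05, tol=1e-2, max_iter=100):
        self.restart_prob = restart_prob
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep=True):
        return {
            "restart_prob": self.restart_prob,
            "tol": self.tol,
            "max_iter": self.max_iter,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        cm = X if isinstance(X, ContactMatrix) else ContactMatrix(sp.csr_matrix(X))
        self.n_bins_ = cm.n_bins
        return self

    def transform(self, X):
        cm = X if isinstance(X, ContactMatrix) else ContactMatrix(sp.csr_matrix(X))
        out = rwr_impute(cm, self.restart_prob, self.tol, self.max_iter)
        self.converged_ = out.meta["rwr_converged"]
        self.n_iter_ = out.meta["rwr_iterations"]
        return out if isinstance(X, ContactMatrix) else out.toarray()

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
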