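"""Downstream analyses on called domains.

* **TLD cliques** — sets of >4 domains on one chromosome whose pairwise
  long-range interactions are enriched over a distance-matched background,
  found as maximal cliques of the enriched-pair graph, with a permutation
  O/E statistic (sizes, inter-domain gaps and chromosome kept, layout
  repositioned at random).
* **Boundary embedding** — cells represented as bags of boundary tokens,
  TF-IDF weighted, reduced by truncated SVD and laid out in 2D; k-means +
  AMI quantifies cluster recovery, CROC quantifies circular (cell-cycle)
  ordering as the ROC-AUC of angular closeness to each class's circular
  mean.
* **Cell-type-specific boundaries** — per-type high-frequency boundary bins
  (mean + 3 SD) with no competing high-frequency bin within +/-3 bins in
  any other type.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import TruncatedSVD
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.manifold import TSNE
from sklearn.metrics import roc_auc_score

from .domains import DomainSet
from .matrix import ContactMatrix
from .metrics import ami

__all__ = [
    "CliqueSet",
    "call_cliques",
    "clique_enrichment",
    "BoundaryEmbedder",
    "embed_cells",
    "cluster_ami",
    "croc",
    "celltype_specific_boundaries",
]


class CliqueSet:
    """Maximal cliques of mutually enriched domains on one chromosome."""

    def __init__(self, cliques, domains: DomainSet, observed=None):
        self.cliques = [sorted(c) for c in cliques]
        self.domains = domains
        self.observed = observed or [np.nan] * len(self.cliques)

    def __len__(self):
        return len(self.cliques)

    def __iter__(self):
        return iter(self.cliques)


def _inter_tld_matrix(cm: ContactMatrix, ds: DomainSet) -> np.ndarray:
    """O[p, q] = total contact weight between domains p and q (p != q)."""
    mat = cm.toarray()
    L = len(ds)
    out = np.zeros((L, L))
    for p in range(L):
        a1, b1 = ds[p]
        for q in range(p + 1, L):
            a2, b2 = ds[q]
            v = mat[a1:b1, a2:b2].sum()
            out[p, q] = out[q, p] = v
    return out


def _pair_oe(cm: ContactMatrix, ds: DomainSet, n_dist_bins=10):
    """Observed/expected per domain pair, distance-matched by midpoint gap."""
    obs = _inter_tld_matrix(cm, ds)
    L = len(ds)
    mids = np.array([(a + b) / 2.0 for a, b in ds.intervals])
    iu, ju = np.triu_indices(L, k=1)
    dist = np.abs(mids[iu] - mids[ju])
    vals = obs[iu, ju]
    # distance-matched expectation: mean observed within quantile strata
    qs = np.quantile(dist, np.linspace(0, 1, n_dist_bins + 1))
    strata = np.clip(np.searchsorted(qs, dist, side="right") - 1, 0, n_dist_bins - 1)
    expected = np.empty_like(vals)
    for s in np.unique(strata):
        sel = strata == s
        expected[sel] = vals[sel].mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(expected > 0, vals / expected, 0.0)
    return iu, ju, oe, obs


def call_cliques(cm: ContactMatrix, ds: DomainSet, sig_quantile=0.95,
                 min_size=5) -> CliqueSet:
    """Find cliques of domains with mutually enriched long-range contacts.

    A domain pair is linked when its distance-matched observed/expected
    contact exceeds the ``sig_quantile`` of all pairwise O/E values; maximal
    cliques of the link graph with more than 4 members are retained.
    """
    if len(ds) < min_size:
        warnings.warn("too few domains for clique analysis", stacklevel=2)
        return CliqueSet([], ds)
    iu, ju, oe, obs = _pair_oe(cm, ds)
    thr = np.quantile(oe, sig_quantile)
    g = nx.Graph()
    g.add_nodes_from(range(len(ds)))
    for p, q, v in zip(iu, ju, oe):
        if v > thr:
            g.add_edge(int(p), int(q))
    cliques = [c for c in nx.find_cliques(g) if len(c) >= min_size]
    observed = [float(sum(obs[p, q] for i, p in enumerate(sorted(c))
                          for q in sorted(c)[i + 1:])) for c in cliques]
    return CliqueSet(cliques, ds, observed)


def _layout_contacts(mat, starts, sizes):
    """Inter-domain contact sum of a rigid clique layout given start bins."""
    total = 0.0
    L = len(starts)
    for i in range(L):
        a1, b1 = starts[i], starts[i] + sizes[i]
        for j in range(i + 1, L):
            a2, b2 = starts[j], starts[j] + sizes[j]
            total += mat[a1:b1, a2:b2].sum()
    return total


def clique_enrichment(cm: ContactMatrix, cs: CliqueSet, n_perm=250, seed=0):
    """Permutation O/E of inter-domain contacts for every clique.

    Each permutation keeps the clique on the same chromosome, keeps the
    multiset of member sizes and of inter-domain gaps, shuffles their order
    and draws a random start position.  The expectation is the mean
    inter-domain contact sum over ``n_perm`` permuted layouts.
    """
    mat = cm.toarray()
    n = cm.n_bins
    rng = np.random.default_rng(seed)
    out = []
    for idx, clique in enumerate(cs.cliques):
        iv = sorted(cs.domains[i] for i in clique)
        sizes = np.array([b - a for a, b in iv])
        gaps = np.array([iv[i + 1][0] - iv[i][1] for i in range(len(iv) - 1)])
        span = sizes.sum() + gaps.sum()
        if span > n:
            warnings.warn(f"clique {idx} layout longer than chromosome; skipped",
                          stacklevel=2)
            out.append(np.nan)
            continue
        observed = _layout_contacts(mat, [a for a, _ in iv], sizes)
        perm_tot = 0.0
        for _ in range(n_perm):
            ps = rng.permutation(sizes)
            pg = rng.permutation(gaps) if len(gaps) else gaps
            pspan = ps.sum() + pg.sum()
            start = int(rng.integers(0, n - pspan + 1))
            starts = []
            cursor = start
            for i, s in enumerate(ps):
                starts.append(cursor)
                cursor += int(s)
                if i < len(pg):
                    cursor += int(pg[i])
            perm_tot += _layout_contacts(mat, starts, ps)
        expected = perm_tot / n_perm
        out.append(observed / expected if expected > 0 else np.nan)
    return out


class BoundaryEmbedder:
    """TF-IDF + truncated-SVD embedding of per-cell boundary documents.

    Cells are documents; tokens are boundary coordinates ("chrom:bin").
    ``fit_transform`` returns the k-dimensional coordinates and stores a 2D
    stochastic-neighbor layout in ``embedding_2d_``.

    Parameters
    ----------
    n_components : int, default 15
        Rank of the truncated SVD.
    random_state : int, default 0
        Seed for SVD and the 2D layout.
    """

    def __init__(self, n_components=15, random_state=0, tsne=True):
        self.n_components = n_components
        self.random_state = random_state
        self.tsne = tsne

    def get_params(self, deep=True):
        return {"n_components": self.n_components,
                "random_state": self.random_state, "tsne": self.tsne}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit_transform(self, documents, y=None):
        """``documents``: list of token lists (or whitespace-joined strings)."""
        docs = [" ".join(d) if not isinstance(d, str) else d for d in documents]
        keep = [i for i, d in enumerate(docs) if d.strip()]
        if len(keep) < len(docs):
            warnings.warn(f"dropped {len(docs) - len(keep)} empty documents",
                          stacklevel=2)
        docs = [docs[i] for i in keep]
        if len(docs) < 2:
            raise ValueError("need at least 2 nonempty documents")
        vec = TfidfVectorizer(token_pattern=r"\S+", lowercase=False)
        X = vec.fit_transform(docs)
        k = min(self.n_components, min(X.shape) - 1)
        svd = TruncatedSVD(n_components=max(k, 1), random_state=self.random_state)
        Z = svd.fit_transform(X)
        self.kept_indices_ = keep
        self.vocabulary_ = vec.vocabulary_
        self.svd_ = svd
        self.embedding_ = Z
        if self.tsne:
            perp = min(30.0, max(2.0, (len(docs) - 1) / 3.0))
            self.embedding_2d_ = TSNE(
                n_components=2, perplexity=perp, init="pca",
                random_state=self.random_state,
            ).fit_transform(Z)
        else:
            self.embedding_2d_ = Z[:, :2]
        return Z

    def fit(self, documents, y=None):
        self.fit_transform(documents)
        return self


def embed_cells(corpus, n_components=15, seed=0, tsne=True):
    """Embed per-cell boundary documents; returns (k-dim, 2D) coordinates."""
    be = BoundaryEmbedder(n_components=n_components, random_state=seed, tsne=tsne)
    Z = be.fit_transform(corpus)
    return Z, be.embedding_2d_


def cluster_ami(embedding, labels_true, k_clusters, seed=0) -> float:
    """k-means on the first 15 embedding dimensions, scored by AMI."""
    Z = np.asarray(embedding)
    labels_true = np.asarray(labels_true)
    if k_clusters < 2:
        raise ValueError("need at least 2 clusters")
    if Z.shape[0] < k_clusters:
        raise ValueError("fewer cells than clusters")
    Z = Z[:, : min(15, Z.shape[1])]
    km = KMeans(n_clusters=k_clusters, random_state=seed, n_init=10).fit(Z)
    return ami(labels_true, km.labels_)


def _circular_mean(theta):
    return float(np.arctan2(np.sin(theta).mean(), np.cos(theta).mean()))


def croc(embedding_2d, labels):
    """Circular ROC of a 2D embedding: per-class AUC of angular closeness.

    The embedding is centered at its centroid; each cell gets an angle
    ``theta_i``.  Per class, the circular mean ``theta*`` of the class's
    angles (the von Mises location MLE) defines the score
    ``-(|theta_i - theta*| wrapped to [0, pi])`` for every cell; the class
    CROC is the one-vs-rest ROC-AUC of that score.  Returns
    ``(per_class: dict, mean: float)``.  Rotation-invariant by construction.
    """
    Z = np.asarray(embedding_2d, dtype=float)
    labels = np.asarray(labels)
    if Z.shape[1] != 2:
        raise ValueError("embedding must be 2D")
    Zc = Z - Z.mean(axis=0)
    theta = np.arctan2(Zc[:, 1], Zc[:, 0])
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    per_class = {}
    for c in classes:
        sel = labels == c
        if sel.sum() < 2:
            warnings.warn(f"class {c!r} has < 2 members; skipped", stacklevel=2)
            continue
        theta_star = _circular_mean(theta[sel])
        diff = np.angle(np.exp(1j * (theta - theta_star)))
        score = -np.abs(diff)
        per_class[c] = float(roc_auc_score(sel.astype(int), score))
    if not per_class:
        raise ValueError("no class had enough members")
    return per_class, float(np.mean(list(per_class.values())))


def celltype_specific_boundaries(boundary_freq, window_bins=3):
    """Cell-type-specific high-frequency boundary bins.

    ``boundary_freq``: mapping type -> per-bin boundary frequency vector.
    A bin is a high-frequency boundary for a type when its frequency exceeds
    that type's mean + 3 SD; it is specific when no other type has a
    high-frequency boundary within ``window_bins`` bins on either side.
    Returns ``(specific: dict of sorted bin lists, high: dict of bool arrays)``.
    """
    types = list(boundary_freq)
    if len(types) < 2:
        raise ValueError("need at least 2 cell types")
    high = {}
    for t in types:
        f = np.asarray(boundary_freq[t], dtype=float)
        sd = f.std()
        if sd == 0:
            warnings.warn(f"type {t!r}: constant frequencies, no high-frequency "
                          "boundaries", stacklevel=2)
            high[t] = np.zeros(len(f), dtype=bool)
        else:
            high[t] = f > f.mean() + 3.0 * sd
    specific = {}
    for t in types:
        others = np.zeros_like(high[t])
        for o in types:
            if o != t:
                others |= high[o]
        spec = []
        for b in np.flatnonzero(high[t]):
            lo, hi = max(0, b - window_bins), min(len(others), b + window_bins + 1)
            if not others[lo:hi].any():
                spec.append(int(b))
        specific[t] = spec
    return specific, high
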