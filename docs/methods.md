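# Methods

## Graph model and conventions

A single-chromosome contact matrix `M` (bin width `binsize`, bins 0-based,
bin *i* covering `[i·binsize, (i+1)·binsize)`) is treated as an undirected
weighted graph: `d_i = Σ_j M[i,j]` with the self-loop weight entering the
row sum **once**, and `2m = Σ_i d_i`. The alternative convention (loops
counted twice) was rejected because Hi-C diagonals are conventionally
single-counted; all entropy formulas downstream assume the once-counted
form. Asymmetric input is symmetrized as `(M + Mᵀ)/2` with a warning;
upper-triangle-only sparse input is mirrored. Loads validate
nonnegativity, finiteness and squareness.

## Structural entropy

The 1D structural entropy is the Shannon entropy of the degree
distribution, `H¹ = −Σ_{d_i>0} (d_i/2m) log₂(d_i/2m)`; the underlying
framework never prints this formula explicitly, so the degree-distribution
form of the structural-information lineage is adopted and flagged here.
For a flat partition (a height-2 encoding tree), each community `X_j`
contributes a boundary term `−(g_j/2m) log₂(V_j/2m)` and node terms
`−((d_i−loop_i)/2m) log₂(d_i/V_j)`; `0·log 0 ≡ 0` everywhere, and terms
with `d_i = 0` are skipped (such bins exist only before regularization).
Bins covered by no domain ("gap" bins) attach directly to the root and
contribute `−((d_i−loop_i)/2m) log₂(d_i/2m)`; this leaf-at-root form is
exactly the generic encoding-tree entropy applied to a height-1 leaf, and
it is what lets the structural-entropy index score external callers whose
output leaves gaps.

The cut of a contiguous range is computed algebraically as
`g(i,j) = V(i,j) − B(i,j)`, where the block total `B` counts internal
off-diagonal edges twice and loops once; this identity follows from the
once-counted degree convention and is verified against direct edge
enumeration in the tests. Degrees, `(d−loop)` sums, `(d−loop)·log₂ d`
sums and a banded table of block totals are precomputed, so any segment's
entropy is answered in O(1).

## The callers

**Whole-chromosome caller** (global layer). Suffix dynamic programming
over segment ends with the segment length capped at 10 Mb worth of bins
(the cap bounds both domain size and runtime — `O(n · K)` segment
evaluations, linear in chromosome length for fixed cap). Ties between
equal-entropy segment lengths break toward the **smaller** length:
deterministic output, biased toward finer domains. The DP result is
asserted against a direct evaluation of the returned partition at every
call. Isolated bins are first given self-loops `r = 2m/n₀` (`n₀` =
nonisolated bin count, both computed on the input); the loop raises a gap
bin's aversion to joining a community without creating inter-bin edges.
Only isolated bins receive the loop. Domains consisting purely of
regularized gap bins are bookkeeping and are removed from the reported
call set (they remain part of the entropy-optimal layout internally).

**Sliding-window caller** (fine layer). The same DP inside 10-Mb windows.
After a window is segmented, all domains but the last are committed and
the next window starts at the first bin of the last domain, so a domain
truncated by a window edge is re-examined whole. If a window returns a
single domain this rule would never advance; that domain is then committed
whole and the window moves past it (logged). A smaller matrix yields
smaller entropy-optimal domains, which is precisely why the window layer
sits below the global layer. Whenever the chromosome fits in one window
the two callers coincide exactly (tested).

**Hierarchy assembly.** The combination of the two layers into a two-level
hierarchy is this package's construction: fine domains crossing a coarse
boundary are split at it, each piece joins the coarse domain containing
its midpoint, pieces falling into inter-domain gaps are dropped, and
uncovered stretches inside a parent become filler children, so every
parent is tiled left to right.

**Binsize selection.** For each candidate binsize the matrix is scored by
`NDI = (H¹ − H²)/H¹` with `H²` from the whole-chromosome caller; argmax
wins, ties to the coarser binsize. Two conventions had to be fixed here:
(1) the **regularized** matrix is used for both `H¹` and `H²` (the
unregularized choice is unstated upstream; using one matrix for both keeps
the NDI a true fraction); (2) the **diagonal is removed** before scoring
(`diagonal=False`). The second matters: because the community node terms
discount self-loop weight, intra-bin (diagonal) mass depresses `H²` but
not `H¹`, and since coarsening moves off-diagonal mass onto the diagonal,
NDI would otherwise increase monotonically with binsize and the selector
would always return the coarsest candidate. On diagonal-free graphs the
NDI shows the intended interior maximum — on planted-block fixtures it
peaks at binsizes where block boundaries align with bin boundaries and
collapses once coarsening shrinks blocks below one bin.

## Imputation

Random walk with restart on the sqrtVC-normalized matrix
`C[i,j] = M[i,j]/√(d_i d_j)` (zero-degree rows stay zero):
`Q_t = (1−α) Q_{t−1} C + αI` from `Q₀ = I` until
`‖Q_t − Q_{t−1}‖ ≤ 10⁻²` or `max_iter = 100`. The stop norm is
implemented as the Frobenius norm (the spectral/Frobenius choice is
unstated upstream; Frobenius is cheap, and the closed form
`α(I − (1−α)C)^{-1}` is verified to the same tolerance in tests with the
spectral norm on small matrices). The restart probability default is
α = 0.05 — a value in the range typical for contact-map smoothing; no
canonical value exists, so it is exposed on the CLI and recorded in output
metadata. Non-convergence warns and flags the output rather than failing.

## Metrics

* **AMI** uses scikit-learn's hypergeometric-adjusted implementation. The
  normalizer is the arithmetic mean of the two label entropies (sklearn's
  default), with `average_method="max"` available for the classic
  strictest variant; the degenerate one-cluster-vs-one-cluster case scores
  1.0. Label vectors include both domains and the gap stretches between
  them (each contiguous gap run gets its own label).
* **WS** excludes gap bins on both sides, per its definition; it is
  asymmetric — reference calls go in `T`, evaluated calls in `K`. The
  hierarchical variant pairs each evaluated parent with its best-matching
  reference parent by the geometric-mean overlap score and averages the
  children's WS inside each pair's intersection.
* **Modularity** first zeroes the diagonal and maps remaining positive
  entries `x → log₂(x+1)`; the `+1` avoids `log 0` on sparse cells where a
  bare "log-processing" of entries in `(0,1)` would produce negative
  weights. Degrees and `m` are recomputed on the transformed matrix. Gap
  bins are singleton communities. TLD modularity treats each parent's
  submatrix as an independent network divided by its children and averages
  over parents.
* **TLD-adjR²** stratifies bin pairs by genomic distance `g`; fitted
  values are per-subTLD means at distance `g`, with pairs spanning no
  subTLD pooled into one gap stratum per distance; `p` counts subTLDs of
  length ≥ g; distances with `n − p − 1 ≤ 0` are NaN and excluded from the
  mean.
* **Boundary enrichment** defines a boundary as the shared coordinate of
  two adjacent domains (the network-caller convention). "Two flanking
  bins" is read per side (symmetry), so the boundary region spans 4 bins;
  background windows of identical width sit 100 kb and 500 kb away on both
  sides, optionally clipped to the chromosome so end-of-chromosome windows
  do not dilute the density; a zero-peak background triggers a flagged
  ±1-peak pseudocount.
* **Boundary shuffles** permute the domain-length multiset and redraw the
  gap composition uniformly (stars and bars), preserving the count and
  size multiset exactly for every seed.

## Downstream analyses

TLD-clique edges require the pair's observed/expected inter-domain contact
(expectation from distance-matched strata of midpoint separations, decile
bins) to exceed a quantile threshold (default 0.95) of all pairwise O/E
values; maximal cliques come from Bron–Kerbosch, and only cliques of more
than 4 domains are kept. The original clique pipeline's pairwise
significance test is not fully specified in the lineage this follows; the
distance-matched O/E threshold is this package's documented stand-in. The
permutation null keeps the chromosome, the member-size multiset and the
inter-domain-gap multiset, shuffles their order and redraws the start
position; enrichment is observed over the mean of 250 permuted layouts.

Cell embeddings treat each cell's boundary set as a document
(`chrom:bin` tokens), apply TF-IDF, reduce by truncated SVD (default rank
15) and lay out in 2D by t-SNE (seeded; perplexity adapted to corpus
size). Cluster recovery is k-means on the first 15 components scored by
AMI. CROC centers the 2D embedding on its centroid, takes each cell's
angle, scores every cell by the negative absolute wrapped distance to the
class's circular mean (closer ⇒ higher — the direction is a convention
fixed here), and reports the one-vs-rest ROC-AUC per class and its mean;
the statistic is rotation-invariant by construction. Cell-type-specific
boundaries are bins whose within-type boundary frequency exceeds that
type's mean + 3 SD with no other type's high-frequency bin within ±3 bins;
the rule does **not** guarantee disjoint sets across types and none is
asserted.

## Synthetic data

The planted-hierarchy generator samples a fixed contact depth multinomially
from an intensity field `decay(|i−j|) × multiplier`, with power-law decay
`(1+|i−j|)^{−1}` (a typical Hi-C contact-frequency exponent) and
multipliers 3.0 within a subTLD, 1.0 within a nested TLD, 0.1 across
nested TLDs — a 10:1 level-1 contrast with moderate (3×) sub-domain
enrichment, chosen once as representative of mammalian TAD/subTAD contrast.
The default layout has 20 nested blocks of 9–16 bins, each tiled by up to
5 sub-blocks of ≥ 2 bins. The polymer stand-in is a confined random walk
(Gaussian steps, radial reflection at the confinement sphere), not a
restraint-based 3D model: it reproduces the statistical shape real
renderers need — short-range pairs close, long-range distances saturating
under confinement — and nothing else. Bulk rendering samples pairs with
weight `1/distance` over the pooled ensemble; single-cell rendering uses
`max(D − distance, 0)` with `D` given as a quantile of the conformation's
own pairwise distances (the 20/40/60% quantiles are the typical working
points) or as an absolute radius, at ~1000 contacts per cell.
Downsampling thins counts binomially per entry (equivalent in distribution
to resampling read pairs); noise injection adds exactly
`round(P_n · total)` unit counts, allocated across diagonals by the
matrix's own per-diagonal mean contact (a reduction of full decay-profile
estimation to its sufficient statistic for this purpose) and placed
uniformly with replacement among cells whose row and column are nonempty.

What passing these fixtures does *not* show: real single-cell maps have
locus-specific coverage biases, unmappable regions, translocations and
cell-to-cell structural variability that no block-plus-decay field or
confined random walk reproduces; recovery numbers on planted data are
upper bounds, and the shuffled-boundary null is the appropriate reference
for the ultrasparse regime.

## Problem sizes and numerical choices

The test suite and the acceptance script run on chromosomes of ~100–300
bins at 40-kb bins with 10³–10⁶ contacts, sizes at which exhaustive
enumeration (up to 2¹¹ contiguous partitions) and 2500-fold shuffle nulls
are exact and fast; the DP itself scales linearly with chromosome length
at fixed window cap. Entropy identities are asserted to 1e-12…1e-9;
DP-vs-enumeration to 1e-9 bits; the segment cache to 1e-10; stochastic
checks (multinomial ratios, chi-square calibration, null statistics) use
seeded generators with tolerances set by their own sampling error. All
randomness flows through explicit seeds; generators are bit-reproducible
given (parameters, seed).

## Known limitations

Two-level hierarchies only (no deeper nesting); single-chromosome cis
matrices only (no trans contacts, no ICE/balancing, no `.hic` format);
binsize selection searches only user-supplied candidates; the clique-edge
significance rule is a documented stand-in; cooler input requires the
optional `cooler` package.
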