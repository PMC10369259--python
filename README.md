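# entropytld

Hierarchical TAD-like domain (TLD) calling for Hi-C and single-cell Hi-C
contact matrices by global minimization of two-dimensional structural
entropy, with random-walk-with-restart imputation for ultrasparse data,
normalized-decoding-information binsize selection, synthetic benchmark
generators, and a full evaluation suite.

## The problem

Chromosomes fold into topologically associating domains (TADs): contiguous
genomic segments whose loci contact each other far more often than they
contact the outside. In single cells, Hi-C yields only ~10³–10⁵ contacts per
cell, so the per-cell analogue of a TAD — a TAD-like domain, TLD — must be
inferred from an extremely sparse bin-by-bin contact matrix. This package
targets users who need deterministic, globally optimal domain calls on such
matrices, plus the statistics to evaluate them.

## The method

The contact matrix of one chromosome is read as a weighted graph *G*: bins
are vertices, contact counts are edge weights, `d_i = Σ_j M[i,j]` is the
degree of bin *i* (self-loops counted once) and `2m = Σ_i d_i`. A flat
partition `P = {X_1, …, X_L}` of the bins into contiguous runs is scored by
its 2D structural entropy

    H_P(G) = Σ_j [ −(g_j/2m) · log₂(V_j/2m)
                   − Σ_{i∈X_j} ((d_i − loop_i)/2m) · log₂(d_i/V_j) ]

where `V_j` is the volume (degree sum) of domain *j* and `g_j` its cut (edge
weight leaving it). `H_P` is the expected code length of a random walk on
*G* under the two-level hierarchy; well-placed domain boundaries minimize
it. The whole-chromosome caller finds the exact minimizer over all
contiguous partitions by dynamic programming,

    f(i) = min_{0 ≤ k ≤ K} [ H(i, k) + f(i + k + 1) ],    f(n) = 0,

with per-segment entropies `H(i, k)` answered in O(1) from prefix sums, a
10-Mb cap on domain length, and ties broken toward shorter segments. A
sliding-window variant runs the same DP inside 10-Mb windows (restarting
each window at the last, possibly truncated, domain of the previous one) and
yields a finer layer; stacking both layers gives a two-level TLD hierarchy.

Supporting machinery:

* **Imputation** — random walk with restart,
  `Q_t = (1−α) Q_{t−1} C + αI` on the sqrtVC-normalized matrix
  `C = D^{-1/2} M D^{-1/2}`, iterated until `‖Q_t − Q_{t−1}‖ ≤ 10⁻²`.
* **Binsize selection** — the normalized decoding information
  `NDI = (H¹ − H²)/H¹` (share of degree-distribution entropy removed by the
  optimal partition) is computed per candidate binsize; the argmax wins.
* **Metrics** — adjusted mutual information, asymmetric weighted similarity
  `WS(T,K)`, modularity on log-scaled matrices, per-parent TLD modularity,
  distance-stratified adjusted R² of contact variance explained, ChIP-seq
  peak enrichment at boundaries, and a size-preserving boundary shuffle for
  null models.
* **Downstream** — TLD cliques with permutation observed/expected
  enrichment, TF-IDF + truncated-SVD embedding of per-cell boundary
  documents, k-means/AMI cluster scoring, circular-ROC (CROC) for
  cell-cycle-like orderings, and cell-type-specific boundary detection.
* **Simulation** — planted two-level block matrices with power-law distance
  decay, confined random-walk polymer ensembles rendered to bulk
  (`weight = 1/distance`) or single-cell (`weight = max(D − distance, 0)`)
  maps, binomial downsampling, and decay-matched noise injection.

## Worked example

```python
import entropytld as et
from entropytld import simulate as sim, metrics as mx

# a synthetic chromosome: 20 nested domains, 3-5 sub-domains each,
# one million contacts at 40-kb bins
ph = sim.PlantedHierarchy.random(n_blocks=20, seed=1)
cm, truth = sim.make_planted_matrix(ph, depth=1_000_000, binsize=40_000, seed=1)

caller = et.StructuralEntropyCaller(binsize=40_000).fit(cm)
print(f"H1={caller.h1_:.4f} bits  H2={caller.entropy_:.4f} bits  "
      f"NDI={caller.ndi_:.4f}  domains={caller.n_domains_}")

hier = et.HierarchicalCaller(binsize=40_000, window_bp=40_000 * 16).fit(cm)
n = cm.n_bins
ami_nested = mx.ami(et.labels_from_domains(truth.nested, n),
                    et.labels_from_domains(hier.nested_, n))
ami_sub = mx.ami(et.labels_from_domains(truth.sub, n),
                 et.labels_from_domains(hier.sub_, n))
print(f"nested AMI={ami_nested:.3f}  sub AMI={ami_sub:.3f}")
```

prints

```
H1=7.9074 bits  H2=4.0568 bits  NDI=0.4870  domains=27
nested AMI=0.937  sub AMI=0.961
```

The optimal partition removes 48.7% of the graph's degree entropy
(NDI 0.487). The caller finds 27 domains against 20 planted ones — every
planted level-1 boundary is recovered, and the extra cuts fall on genuine
level-2 boundaries — giving per-bin label agreement (AMI) of 0.94 on the
nested layer and 0.96 on the sub layer.

The same pipeline from a shell:

```bash
entropytld simulate planted -o mat.coo --truth truth.bed --seed 1
entropytld call -i mat.coo --binsize 40000 --mode hier -o tlds.bed
entropytld binsize -i mat_40k.coo mat_80k.coo --binsizes 40000,80000
```

BED output carries a level column (1 = nested TLD, 2 = subTLD).

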