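# Methods

## Expression container, QC and filtration

Expression is stored gene x cell in sparse CSR with ordered, unique gene
ids and cell barcodes, plus a per-cell annotation table. Values carry a
kind tag (`counts`, `tpm`, `log2cpm`, `log2tpm`) and only `normalize` may
change it: counts are scaled per cell to CPM (1e6) and log2(x+1)
transformed; TPM input is log-transformed without rescaling. Zeros map to
zeros, so sparsity survives normalization; a cell with zero total counts is
an error (it must be filtered first).

Five QC metrics are computed on counts/TPM: nUMI, nFeature, pctMito
(symbol prefix `MT-|mt-`), pctSpikeIn (`ERCC-|Ercc-`) and per-gene nCell.
Auto filtration bounds each metric by median ± 3 x MAD, with MAD scaled by
1.4826 (consistency with the normal; configurable). Percentage metrics are
bounded above only — a lower bound on contamination is meaningless — and
count metrics have their lower bound clipped at zero. Cells are filtered
first; gene nCell is then recomputed on the surviving cells, so filtration
is idempotent. Cells with zero counts get pct metrics defined as 0 and are
flagged.

## Mutual-information kernels

Two estimators with different jobs:

* **Fixed-grid histogram** for cell-cell distances. Each cell's gene vector
  is discretized once into b equal-width bins over its own [min, max]
  (b = round(n_genes^(1/3)), floored at 2; the maximum falls in the last
  bin; constant vectors collapse to bin 0). I and H come from the joint
  b x b histogram, both in bits — one log base throughout keeps the ratio
  I/H base-invariant — and D = 1 − I/H. Degenerate pairs with H = 0 (two
  constant cells) get D = 0: identical constant cells are maximally
  similar. The all-pairs computation is partitioned into blocks purely for
  scheduling; because discretization happens once per cell, the result is
  bit-identical for every block size (tested at sizes 1, 10, all).

* **Adaptive partitioning** for gene-gene dependency. Both vectors are
  rank-transformed with the half-offset (r − 0.5)/n (average ranks on
  ties), which makes marginals uniform, the estimate invariant under
  strictly monotone transforms, and — because the transform is symmetric
  about 0.5 — positive and negative dependence exactly exchangeable under
  midpoint quadrisection. A cell of the unit square is split at the
  midpoint of its rank interval into four quadrants only if it holds at
  least `min_points` (8) points and a chi-square goodness-of-fit test of
  the quadrant counts against equal expectation rejects at `alpha` (0.05);
  recursion also stops once both side lengths fall below 1/n (ties can
  never separate). Leaf contributions use the leaf's rank-space area as its
  marginal probability; a negative total (finite-sample noise) is floored
  at zero. On bivariate Gaussians the estimator lands within 0.1 bits of
  −½ log2(1 − ρ²) at n = 5,000 (mean over 20 seeds) and is monotone in |ρ|.

## Clustering

* **MDS mode** (auto-selected at ≤ 5,000 cells; the boundary is inclusive
  on the MDS side). Classical Torgerson MDS: double-center −½D², take the
  top-d eigenpairs (d = 19), scale eigenvectors by √eigenvalue, drop
  negative eigenvalues and zero-pad. Eigenvector signs are fixed by making
  the largest-magnitude entry positive, so embeddings are reproducible.
  Consensus k-means runs k-means++ (300-iteration cap) with per-run seeds
  base+1..base+10, builds the co-association matrix (fraction of runs
  co-clustered) and cuts an average-linkage tree of (1 − co-association)
  at k. With a single run the consensus degenerates to that run exactly.

* **GE mode** (above 5,000 cells, or forced). The similarity 1 − D ranks
  each cell's k1 = 80 nearest neighbors; edges are union-symmetrized and
  unweighted (similarity is used only for ranking). Node2vec walks
  (10 walks x length 80 per node, window 10, p = q = 1) feed a skip-gram
  model with 5 negative samples trained by SGD (walk order reshuffled per
  epoch, seeded linear-congruential RNG, so embeddings are bit-reproducible
  on one thread); isolated cells are attached to their nearest cell by
  distance first. An exact ball-tree kNN graph (k2 = 20) on the embedding
  goes to Louvain. All neighbor searches here are exact: the fixture sizes
  this package targets are far below the regime where approximate search
  pays.

* **Resolution sweep.** Louvain resolution swept over 0.1–4 (step 0.1);
  solutions matching the target cluster count are kept, ties broken by
  highest ARI against a provided truth, else by lowest resolution. This is
  the supported way to hit a known k in GE mode — at a fixed resolution
  modularity happily splits large well-separated communities.

One skip-gram caveat: a one-dimensional embedding cannot encode path-like
orderings (a rank-1 inner-product factorization of a banded co-occurrence
matrix collapses to an all-positive mode), so the tested embedding
guarantees are community separation and the monotone relation between
embedding distance and graph distance, not literal coordinate orderings.

## Network inference

Hub-constrained, ARACNe-style. Only hub x gene pairs are ever scored
(hub-hub pairs once, in canonical order); target-target edges do not exist
in this universe.

* **Metacells** (optional): k-means micro-clusters (k = ceil(cells/gamma),
  gamma defaults to 20) on the top 10 principal components; each metacell
  is the mean normalized profile of its members. Degenerate duplicates that
  collapse k-means clusters are split deterministically so exactly k
  metacells always come back.

* **MI significance.** The null is built by scoring `null_pairs` (default
  100,000) random gene pairs with one member permuted (in-kernel seeded
  Fisher-Yates). Because the rank transform makes the null distribution-
  free given n, one calibration serves any data of the same width. Most
  null pairs score exactly 0 (the root cell passes the uniformity test),
  so the exponential tail ln p = a + b·MI is fitted to the strictly
  positive null draws (at most the top 5%, at least 10 required) and
  inverted at pb (default 1e-7). The threshold is monotone in pb and
  controls the null pass rate.

* **DPI.** For every triangle whose three edges all survive thresholding,
  the minimum-MI edge is removed when mi_min < min(other two)·(1 − tol);
  removals are decided simultaneously against the original edge set, which
  makes the filter order-independent and idempotent. Default tolerance 0.

* **Poisson consensus.** `n_boot` (100) bootstrap resamples of cells (not
  genes); per-edge support counts; rate λ = total occurrences / distinct
  edges observed; upper-tail P(X ≥ support) ≤ pc (1e-2) retains an edge,
  whose MI is the mean over its supporting bootstraps. Note the practical
  consequence: with very few bootstraps and a clean signal λ ≈ n_boot and
  nothing is "surprisingly frequent" — small-n_boot runs need a permissive
  pc, which is why the default is 100.

* **Annotation.** Spearman, Pearson, least-squares slope (target on
  source) and the Pearson p-value on the inference matrix; sign =
  sign(Spearman); constant genes get zeroed correlations with a warning.
  Regulons split targets by sign (zero-sign targets go to the positive set,
  logged).

## Activity

Cells are z-normalized column-wise with the sample (n−1) standard
deviation — the R `scale()` convention, which also matches the worked
arithmetic used to pin the contract ((1,2,3) → (−1,0,1)); constant cells
map to zeros. Four means over a driver's targets: `mean` (default),
`weightedmean` (Σ wᵢzᵢ / Σ|wᵢ| with wᵢ = MIᵢ·signᵢ, keeping the result on
the z scale), `absmean`, and `maxmean` (the positive-target or
negative-target mean with the larger magnitude, sign retained, so
inhibitory programs are not averaged away). Batch mode z-normalizes each
cluster separately, applies that cluster's network, concatenates, and
imputes drivers absent from some cluster's network with the global minimum
non-NA activity. For cross-network comparisons each driver's regulon is
truncated to its top-MI n_i targets, n_i being the smallest regulon size
among the compared networks.

## Differential statistics

Welch two-sample t-test (two-sided) or Wilcoxon rank-sum; BH FDR across
the tested features; z = sign(log2FC)·Φ⁻¹(1 − p/2) with p = 1 → 0 and
underflow clamped at the smallest positive float (warned). For activity
matrices the fold-change column is a raw difference of means (activities
are z-scale, not log counts) and the pct columns count non-NA rather than
non-zero cells. Features with zero variance in both groups get p = 1,
z = 0. Type-I error is verified at 0.05 ± 0.02 over 1,000 null features
for both tests.

## Evaluation metrics

ARI/AMI/NMI as standard; accuracy = size-weighted majority fraction of
predicted labels within each true cluster, purity the same with roles
swapped; ASW is the mean silhouette of the predicted labels on an
explicitly supplied representation (the clustering embedding by default —
nothing canonical exists, so the caller decides); AvgBIO = mean(ARI, NMI,
(ASW+1)/2) so all three components live in [0, 1]. Early precision uses an
analytic random baseline (truth density in the candidate universe) rather
than sampled random networks. GSEA is the unweighted running sum (hits step
1/n_hit, every rank steps 1/n) whose signed maximum deviation is the KS
statistic of target ranks against uniform; its p-value is a two-sample KS
test of target vs non-target statistics, and the positive/negative-target
p-values combine by Fisher's method (chi-square, 4 df). Driver assignment
runs one-tailed Welch tests of each type against every other and assigns
only when all pairwise p < 1e-4.

## Synthetic fixtures

`simulate_clusters` emulates droplet data: per-cluster mean vectors with a
`de_fraction` (0.2) of genes shifted by `effect_size` (2 log2 units),
negative-binomial counts (dispersion r = 2) around library sizes uniform
in 1,000–3,000, and Bernoulli dropout (0.2). These defaults describe the
strong-separation regime the recovery guarantees refer to. It does not
model batch effects, ambient RNA, doublets or gene-gene correlation within
a cluster, so passing recovery tests demonstrates the pipeline's
correctness on its own assumptions, not performance on any real tissue.

`simulate_grn` plants hub latent activities (standard normal per cell),
targets = sign·strength·activity + N(0, noise_sd = 0.5), hub transcripts =
activity + N(0, 0.4·noise_sd) (so the noiseless limit saturates MI), and
independent background genes. The hidden-driver variant gives the first
hub a two-group latent shift (±1) while its transcript follows only the
group-invariant within-group fluctuation: differential expression stays
null, regulon inference still works, and differential activity exposes the
shift. Real hidden drivers arise from post-transcriptional regulation; the
fixture mimics the observable consequence, not the mechanism.

## Numerical and reproducibility notes

Every stochastic stage takes an explicit seed and is reproducible to the
bit on a fixed thread count; the pairwise-distance and adaptive-MI kernels
write independent slots, so parallel execution does not change results.
Histogram MI agrees with a brute-force double loop to 1e-12. D is clipped
to [0, 1] against rounding; self-distance can carry a ~1e-16 residue in
the scalar API (the matrix API zeroes the diagonal exactly). The problem
sizes used by the test suite and the acceptance script (900 x 500 cells
for clustering, 10 x 20 planted edges over 500 samples with 100
bootstraps, 20,000 null pairs) were chosen as the smallest sizes at which
the statistical guarantees are comfortably away from their noise floors.

## Known limitations

* The Poisson consensus rate λ pools all distinct observed edges; in
  near-noiseless regimes this makes uniformly supported edges look
  unremarkable (see above). Real, noisy data keeps λ well below n_boot.
* The MI-threshold calibration needs enough positive null draws; very
  small `null_pairs` raises an explicit error rather than extrapolating
  from nothing.
* Approximate (HNSW-style) neighbor search is not implemented; graphs are
  exact, which is the right trade-off below ~10,000 cells and the wrong
  one far above it.
* Activity's `mean` method can cancel balanced activating/repressing
  regulons; `weightedmean` or `maxmean` are the appropriate choices there.
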