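# miner

Mutual-information-based single-cell analysis: cell clustering on a
normalized MI distance, cluster-specific signed regulatory-network
inference, and regulon-activity estimation for **hidden-driver**
discovery — regulators whose functional output changes between cell
populations even though their own transcript does not.

The package is aimed at computational biologists working with scRNA-seq
count matrices (10x CellRanger MTX output or plain TSV tables) who want to
go beyond expression-level marker analysis: which transcription factors and
signaling genes *drive* each population, including the ones invisible to
differential expression.

## The model

**MI cell-cell distance.** For two cells C_i, C_j (columns of the
normalized gene x cell matrix), expression values are discretized into
b = ∛n equal-width bins (n = number of genes) and

    I(C_i; C_j) = Σ_x Σ_y p(x, y) log2 [ p(x, y) / (p(x) p(y)) ]
    H(C_i, C_j) = − Σ_x Σ_y p(x, y) log2 p(x, y)
    D(C_i, C_j) = 1 − I / H          (0 = identical, 1 = independent)

D is a normalized distance in [0, 1] used by two clustering modes,
dispatched automatically on dataset size: **MDS mode** (≤ 5,000 cells —
classical multidimensional scaling to 19 dimensions, then consensus
k-means over 10 seeded runs) and **GE mode** (kNN graph with k = 80,
node2vec embedding into 20 dimensions, exact kNN graph with k = 20, Louvain
communities, optionally sweeping the resolution 0.1–4 until a target
cluster count is reached).

**Network inference.** For a list of driver hubs (TFs or signaling genes),
gene-gene dependency is estimated by adaptive-partitioning MI: both vectors
are rank-transformed and the unit square is recursively quadrisected
wherever the quadrant occupancies reject uniformity (chi-square). Edges are
kept when their MI exceeds a permutation-null threshold at per-edge p-value
pb = 1e-7, pruned by the Data Processing Inequality (in a chain X → Y → Z,
I(X;Z) ≤ min(I(X;Y), I(Y;Z)), so the weakest edge of a fully connected
triangle is likely indirect), and aggregated over 100 cell bootstraps: an
edge's occurrence count is tested against a Poisson null and retained at
p ≤ 1e-2. Retained edges carry Spearman/Pearson correlations and a
regression slope; the Spearman sign splits each regulon into positive and
negative targets.

**Activity.** A driver's activity in a cell is a mean of its targets'
column-z-normalized expression (plain, MI-weighted and sign-corrected,
absolute, or the larger-magnitude of the positive/negative target means).
Differential activity uses the same machinery as differential expression
(Welch t-test or Wilcoxon, BH FDR, signed z = Φ⁻¹(1 − p/2)), which is what
exposes hidden drivers.

## Worked example

Everything runs on seeded synthetic fixtures — no downloads:

```python
from miner import (simulate_clusters, simulate_grn, normalize,
                   MICAClustering, SJARACNe, clustering_scores)

fx = simulate_clusters(n_cells=900, n_genes=500, k=3, seed=42)
expr = normalize(fx.matrix)                      # CPM + log2
est = MICAClustering(n_clusters=3, mode="auto", random_state=0)
labels = est.fit_predict(expr.dense().T)
score = clustering_scores(labels, fx.labels, est.embedding_)
print(f"mode={est.mode_}  k={est.n_clusters_}  ARI={score.ari:.3f}")

grn = simulate_grn(n_hubs=10, targets_per_hub=20, n_cells=500, seed=42)
net = SJARACNe(hubs=grn.hubs, n_boot=100, null_pairs=20_000,
               random_state=0).fit(grn.matrix)
print(f"MI threshold={net.mi_threshold_:.3f}  edges={len(net.network_)}")
print(net.network_.head(3).round(3).to_string(index=False))
```

prints

```
mode=mds  k=3  ARI=1.000
MI threshold=0.067  edges=200
source target    mi  pearson  spearman  slope  p_correlation  sign  support  p_consensus
 HUB04   T080 1.270   -0.901    -0.893 -1.012            0.0    -1      100          0.0
 HUB05   T101 1.224   -0.894    -0.883 -0.968            0.0    -1      100          0.0
 HUB05   T112 1.224   -0.895    -0.897 -0.986            0.0    -1      100          0.0
```

900 cells were clustered in MDS mode (auto dispatch, ≤ 5,000 cells) and
recover the three planted populations exactly (ARI 1.0). The inferred
consensus network retains 200 edges — exactly the planted 10 hubs x 20
targets — each with full bootstrap support (100/100) and the planted sign
(e.g. HUB04 represses T080: negative Spearman, slope ≈ −1).

The same steps are available from the shell:

```bash
miner simulate clusters --seed 42 --out fixture/
miner filter fixture/ --mode auto --out filtered.tsv
miner norm filtered.tsv --out normalized.tsv
miner cluster normalized.tsv --k 3 --seed 0 --out labels.tsv
miner network normalized.tsv --hubs hubs.txt --n-boot 100 --out net.tsv
```

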