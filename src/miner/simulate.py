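"""Seeded synthetic data: clustered count matrices and planted signed networks.

These generators supply the ground truth every other module is tested
against. ``simulate_clusters`` emulates droplet scRNA-seq counts (negative
binomial around cluster-shifted means, Bernoulli dropout, variable library
size); ``simulate_grn`` plants a signed hub->target regulatory structure,
optionally with a *hidden driver* whose own transcript is flat across groups
while its targets still follow its group-dependent latent activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix


@dataclass
class ClusterFixture:
    """Planted-cluster count matrix with true labels."""

    matrix: ExpressionMatrix
    labels: np.ndarray
    params: dict = field(default_factory=dict)


@dataclass
class GRNFixture:
    """Planted signed regulatory network with matching expression."""

    matrix: ExpressionMatrix          # log2-scale expression
    edges: pd.DataFrame               # source, target, sign, strength
    hubs: list
    group_labels: np.ndarray | None
    hidden_hub: str | None = None
    params: dict = field(default_factory=dict)


def simulate_clusters(n_cells: int = 900, n_genes: int = 500, k: int = 3,
                      de_fraction: float = 0.2, effect_size: float = 2.0,
                      dropout_rate: float = 0.2,
                      library_size: tuple = (1000, 3000),
                      dispersion: float = 2.0, seed: int = 0) -> ClusterFixture:
    """Clustered negative-binomial counts with dropout.

    Parameters
    ----------
    de_fraction
        Fraction of genes up-shifted per cluster.
    effect_size
        Shift of DE genes in log2 units (2.0 = 4-fold).
    dropout_rate
        Bernoulli zero-inflation probability applied to the counts.
    library_size
        Uniform range of per-cell total-count targets.
    dispersion
        Negative-binomial size parameter r (variance = mu + mu^2 / r).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if de_fraction <= 0:
        raise ValueError("de_fraction must be positive")
    n_de = int(round(de_fraction * n_genes))
    if n_de * 1 > n_genes:
        raise ValueError("de genes exceed total genes")
    rng = np.random.default_rng(seed)

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    cluster_means = np.tile(base, (k, 1))
    for c in range(k):
        de_genes = rng.choice(n_genes, size=n_de, replace=False)
        cluster_means[c, de_genes] *= 2.0 ** effect_size

    sizes = np.full(k, n_cells // k)
    sizes[: n_cells % k] += 1
    labels = np.repeat(np.arange(1, k + 1), sizes)
    libs = rng.uniform(library_size[0], library_size[1], size=n_cells)

    counts = np.zeros((n_genes, n_cells), dtype=np.int64)
    for i in range(n_cells):
        mu = cluster_means[labels[i] - 1]
        mu = mu / mu.sum() * libs[i]
        p = dispersion / (dispersion + mu)
        counts[:, i] = rng.negative_binomial(dispersion, p)
    if dropout_rate > 0:
        keep = rng.random(counts.shape) >= dropout_rate
        counts = counts * keep

    matrix = ExpressionMatrix(
        values=counts,
        gene_ids=[f"G{j:04d}" for j in range(n_genes)],
        gene_symbols=[f"G{j:04d}" for j in range(n_genes)],
        cell_barcodes=[f"cell_{i:05d}" for i in range(n_cells)],
        value_kind="counts",
    )
    matrix.cell_annotations["true_label"] = labels
    return ClusterFixture(matrix, labels, params=dict(
        n_cells=n_cells, n_genes=n_genes, k=k, de_fraction=de_fraction,
        effect_size=effect_size, dropout_rate=dropout_rate,
        library_size=library_size, dispersion=dispersion, seed=seed))


def simulate_grn(n_hubs: int = 10, targets_per_hub: int = 20,
                 n_background: int = 40, sign_mix: float = 0.5,
                 strength: float = 1.0, noise_sd: float = 0.5,
                 n_cells: int = 500, seed: int = 0,
                 hidden_driver: bool = False) -> GRNFixture:
    """Plant a signed hub->target network and draw matching expression.

    Each hub has a per-cell latent activity; each of its targets is
    ``sign * strength * activity + N(0, noise_sd)``. The hub's own transcript
    tracks its activity (plus noise) unless ``hidden_driver`` is set, in
    which case the first hub's transcript is replaced by group-invariant
    noise while its targets keep following the group-shifted latent activity
    (two equal cell groups, +/- 1 latent shift).
    """
    n_targets = n_hubs * targets_per_hub
    n_genes = n_hubs + n_targets + n_background
    rng = np.random.default_rng(seed)

    hub_names = [f"HUB{h:02d}" for h in range(n_hubs)]
    target_names = [f"T{t:03d}" for t in range(n_targets)]
    bg_names = [f"BG{b:03d}" for b in range(n_background)]
    genes = hub_names + target_names + bg_names

    group_labels = None
    activity = rng.normal(size=(n_hubs, n_cells))
    if hidden_driver:
        group_labels = np.repeat([1, 2], [n_cells - n_cells // 2, n_cells // 2])
        shift = np.where(group_labels == 1, -1.0, 1.0)
        within = rng.normal(scale=0.5, size=n_cells)
        activity[0] = shift + within

    # hub transcripts track their latent activity with observation noise
    # scaled to noise_sd, so the noiseless limit is exact
    hub_noise = 0.4 * noise_sd
    X = np.zeros((n_genes, n_cells))
    for h in range(n_hubs):
        X[h] = activity[h] + rng.normal(scale=hub_noise, size=n_cells)
    if hidden_driver:
        # the hidden hub's transcript follows only the group-invariant
        # within-group fluctuation: flat between groups (no DE signal) yet
        # still informative for regulon inference
        X[0] = within + rng.normal(scale=hub_noise, size=n_cells)

    edge_rows = []
    for h in range(n_hubs):
        for t in range(targets_per_hub):
            gi = n_hubs + h * targets_per_hub + t
            sign = 1 if rng.random() < sign_mix else -1
            X[gi] = sign * strength * activity[h] + rng.normal(
                scale=noise_sd, size=n_cells)
            edge_rows.append((hub_names[h], genes[gi], sign, strength))
    for b in range(n_background):
        X[n_hubs + n_targets + b] = rng.normal(size=n_cells)

    matrix = ExpressionMatrix(
        values=np.maximum(X + 6.0, 0.0),  # shift to a non-negative log2 scale
        gene_ids=genes,
        gene_symbols=genes,
        cell_barcodes=[f"cell_{i:05d}" for i in range(n_cells)],
        value_kind="log2cpm",
    )
    if group_labels is not None:
        matrix.cell_annotations["group"] = group_labels
    edges = pd.DataFrame(edge_rows, columns=["source", "target", "sign",
                                             "strength"])
    return GRNFixture(matrix, edges, hubs=hub_names,
                      group_labels=group_labels,
                      hidden_hub=hub_names[0] if hidden_driver else None,
                      params=dict(n_hubs=n_hubs,
                                  targets_per_hub=targets_per_hub,
                                  n_background=n_background,
                                  sign_mix=sign_mix, strength=strength,
                                  noise_sd=noise_sd, n_cells=n_cells,
                                  seed=seed, hidden_driver=hidden_driver))


def write_fixture_mtx(fixture: ClusterFixture, directory: str) -> None:
    """Write a cluster fixture as CellRanger-style MTX + TSVs plus truth labels."""
    import os

    import scipy.io
    import scipy.sparse as sp

    os.makedirs(directory, exist_ok=True)
    scipy.io.mmwrite(os.path.join(directory, "matrix.mtx"),
                     sp.coo_matrix(fixture.matrix.values))
    with open(os.path.join(directory, "features.tsv"), "w") as fh:
        for gid, sym in zip(fixture.matrix.gene_ids, fixture.matrix.gene_symbols):
            fh.write(f"{gid}\t{sym}\tGene Expression\n")
    with open(os.path.join(directory, "barcodes.tsv"), "w") as fh:
        for bc in fixture.matrix.cell_barcodes:
            fh.write(f"{bc}\n")
    pd.DataFrame({"barcode": fixture.matrix.cell_barcodes,
                  "true_label": fixture.labels}).to_csv(
        os.path.join(directory, "true_labels.tsv"), sep="\t", index=False)
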