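"""Sparse expression container, QC metrics, filtration and normalization.

The central object is :class:`ExpressionMatrix`, a gene x cell sparse matrix
with gene/cell annotations, modelled on the Bioconductor ExpressionSet idea:
genes are rows, cells are columns, and all QC/filtering semantics follow that
orientation. Values move through three states: raw counts (or TPM), then
CPM/log2 normalized, tracked by ``value_kind``.
"""

from __future__ import annotations

import gzip
import os
import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

MITO_PATTERN = re.compile(r"^(MT-|mt-)")
SPIKEIN_PATTERN = re.compile(r"^(ERCC-|Ercc-)")

VALUE_KINDS = ("counts", "tpm", "log2cpm", "log2tpm")


class FormatError(ValueError):
    """Malformed input table or matrix directory."""


@dataclass
class ExpressionMatrix:
    """Gene x cell expression values with annotations.

    Parameters
    ----------
    values
        Sparse (CSR) or dense gene x cell matrix; stored sparse.
    gene_ids
        Unique gene identifiers (rows).
    gene_symbols
        Gene symbols, same length as ``gene_ids``; used for mito/spike-in
        pattern matching.
    cell_barcodes
        Unique cell identifiers (columns).
    cell_annotations
        Per-cell table (cluster labels, truth labels, QC metrics).
    value_kind
        One of ``counts``, ``tpm``, ``log2cpm``, ``log2tpm``.
    """

    values: sp.csr_matrix
    gene_ids: np.ndarray
    gene_symbols: np.ndarray
    cell_barcodes: np.ndarray
    cell_annotations: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    value_kind: str = "counts"

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        self.cell_barcodes = np.asarray(self.cell_barcodes, dtype=object)
        n_genes, n_cells = self.values.shape
        if len(self.gene_ids) != n_genes or len(self.gene_symbols) != n_genes:
            raise FormatError(
                f"gene annotation length {len(self.gene_ids)} does not match "
                f"matrix rows {n_genes}"
            )
        if len(self.cell_barcodes) != n_cells:
            raise FormatError(
                f"barcode count {len(self.cell_barcodes)} does not match "
                f"matrix columns {n_cells}"
            )
        if len(set(self.cell_barcodes)) != n_cells:
            raise FormatError("duplicate cell barcodes")
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if self.cell_annotations is None:
            self.cell_annotations = pd.DataFrame(index=self.cell_barcodes)
        if self.value_kind in ("counts", "tpm") and self.values.nnz:
            if self.values.data.min() < 0:
                raise ValueError(f"negative values in {self.value_kind} matrix")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def subset(self, gene_mask=None, cell_mask=None) -> "ExpressionMatrix":
        """Return a copy restricted to the given boolean/index masks."""
        def as_indices(mask, n):
            if mask is None:
                return np.arange(n)
            mask = np.asarray(mask)
            return np.where(mask)[0] if mask.dtype == bool else mask

        gi = as_indices(gene_mask, self.n_genes)
        ci = as_indices(cell_mask, self.n_cells)
        return ExpressionMatrix(
            values=self.values[gi][:, ci],
            gene_ids=self.gene_ids[gi],
            gene_symbols=self.gene_symbols[gi],
            cell_barcodes=self.cell_barcodes[ci],
            cell_annotations=self.cell_annotations.iloc[ci].copy(),
            value_kind=self.value_kind,
        )


@dataclass
class CellQC:
    """Per-cell QC metrics (indexed like the matrix columns)."""

    nUMI: np.ndarray
    nFeature: np.ndarray
    pctMito: np.ndarray
    pctSpikeIn: np.ndarray

    def to_frame(self, barcodes) -> pd.DataFrame:
        return pd.DataFrame(
            {"nUMI": self.nUMI, "nFeature": self.nFeature,
             "pctMito": self.pctMito, "pctSpikeIn": self.pctSpikeIn},
            index=barcodes,
        )


@dataclass
class GeneQC:
    """Per-gene QC: number of cells expressing each gene."""

    nCell: np.ndarray

    def to_frame(self, gene_ids) -> pd.DataFrame:
        return pd.DataFrame({"nCell": self.nCell}, index=gene_ids)


@dataclass
class MetricBounds:
    low: float = -np.inf
    high: float = np.inf
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.enabled and self.low > self.high:
            raise ValueError(f"low bound {self.low} exceeds high bound {self.high}")


@dataclass
class FilterThresholds:
    """Cutoffs for the five QC metrics.

    ``mode='auto'`` derives bounds as median +/- 3 x MAD per metric; pctMito
    and pctSpikeIn are bounded above only (a lower bound on contamination is
    meaningless). Count metrics are clipped at zero.
    """

    nUMI: MetricBounds = field(default_factory=MetricBounds)
    nFeature: MetricBounds = field(default_factory=MetricBounds)
    pctMito: MetricBounds = field(default_factory=MetricBounds)
    pctSpikeIn: MetricBounds = field(default_factory=MetricBounds)
    nCell: MetricBounds = field(default_factory=lambda: MetricBounds(low=1.0))
    mode: str = "manual"
    mad_constant: float = 1.4826


def _open_maybe_gz(path: str):
    return gzip.open(path, "rt") if path.endswith(".gz") else open(path)


def _find_file(directory: str, names) -> str:
    for name in names:
        for suffix in ("", ".gz"):
            p = os.path.join(directory, name + suffix)
            if os.path.exists(p):
                return p
    raise FileNotFoundError(
        f"none of {names} (optionally .gz) found in {directory}"
    )


def read_mtx_dir(path: str, barcode_prefix: str = "",
                 strip_suffix: str = "") -> ExpressionMatrix:
    """Read a CellRanger-style directory (matrix.mtx + features/genes.tsv + barcodes.tsv).

    Parameters
    ----------
    path
        Directory with ``matrix.mtx(.gz)``, ``features.tsv(.gz)`` or
        ``genes.tsv(.gz)``, and ``barcodes.tsv(.gz)``.
    barcode_prefix
        Optional prefix prepended to every barcode.
    strip_suffix
        Optional suffix removed from every barcode (e.g. ``"-1"``).
    """
    mtx_path = _find_file(path, ["matrix.mtx"])
    feat_path = _find_file(path, ["features.tsv", "genes.tsv"])
    bc_path = _find_file(path, ["barcodes.tsv"])

    matrix = sp.csr_matrix(scipy.io.mmread(mtx_path))
    with _open_maybe_gz(feat_path) as fh:
        feats = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    with _open_maybe_gz(bc_path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]

    if len(feats) != matrix.shape[0]:
        raise FormatError(
            f"matrix declares {matrix.shape[0]} genes but features file has "
            f"{len(feats)} lines"
        )
    if len(barcodes) != matrix.shape[1]:
        raise FormatError(
            f"matrix declares {matrix.shape[1]} cells but barcodes file has "
            f"{len(barcodes)} lines"
        )
    if strip_suffix:
        barcodes = [b[: -len(strip_suffix)] if b.endswith(strip_suffix) else b
                    for b in barcodes]
    if barcode_prefix:
        barcodes = [barcode_prefix + b for b in barcodes]
    gene_ids = [f[0] for f in feats]
    gene_symbols = [f[1] if len(f) > 1 else f[0] for f in feats]
    return ExpressionMatrix(matrix, gene_ids, gene_symbols, barcodes,
                            value_kind="counts")


def read_table(path: str, genes_in: str = "rows",
               value_kind: str = "counts") -> ExpressionMatrix:
    """Read a dense TSV expression table (header + row names) into sparse storage."""
    if genes_in not in ("rows", "columns"):
        raise ValueError("genes_in must be 'rows' or 'columns'")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"ragged or malformed table {path}: {exc}") from exc
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(t) for t in df.dtypes]]
    if len(non_numeric):
        bad = df[non_numeric[0]]
        row = bad.index[~bad.apply(lambda v: isinstance(v, (int, float)))][:1]
        raise FormatError(
            f"non-numeric value in column {non_numeric[0]!r}"
            + (f", row {row[0]!r}" if len(row) else "")
        )
    if genes_in == "columns":
        df = df.T
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise FormatError(f"duplicate gene ids: {dupes}")
    return ExpressionMatrix(
        sp.csr_matrix(df.to_numpy()),
        gene_ids=df.index.to_numpy(),
        gene_symbols=df.index.to_numpy(),
        cell_barcodes=df.columns.to_numpy(),
        value_kind=value_kind,
    )


def compute_qc(m: ExpressionMatrix) -> tuple[CellQC, GeneQC]:
    """Compute the five QC metrics (nUMI, nFeature, pctMito, pctSpikeIn, nCell)."""
    if m.value_kind not in ("counts", "tpm"):
        raise ValueError("QC is defined on counts/TPM, not normalized values")
    X = m.values.tocsc()
    n_umi = np.asarray(X.sum(axis=0)).ravel()
    n_feature = np.asarray((X > 0).sum(axis=0)).ravel()
    mito = np.array([bool(MITO_PATTERN.match(str(s))) for s in m.gene_symbols])
    spike = np.array([bool(SPIKEIN_PATTERN.match(str(s))) for s in m.gene_symbols])
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(
            n_umi > 0,
            100.0 * np.asarray(X[mito].sum(axis=0)).ravel() / np.where(n_umi > 0, n_umi, 1),
            0.0,
        )
        pct_spike = np.where(
            n_umi > 0,
            100.0 * np.asarray(X[spike].sum(axis=0)).ravel() / np.where(n_umi > 0, n_umi, 1),
            0.0,
        )
    n_cell = np.asarray((m.values > 0).sum(axis=1)).ravel()
    if (n_umi == 0).any():
        warnings.warn(f"{int((n_umi == 0).sum())} cells have zero total counts")
    return (CellQC(n_umi, n_feature, pct_mito, pct_spike), GeneQC(n_cell))


def mad(x: np.ndarray, constant: float = 1.4826) -> float:
    """Median absolute deviation, scaled by ``constant`` (1.4826 for normal consistency)."""
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    return constant * float(np.median(np.abs(x - med)))


def auto_thresholds(metric_values, mad_constant: float = 1.4826,
                    clip_low: float | None = None) -> tuple[float, float]:
    """Median +/- 3 x MAD bounds for one QC metric.

    ``clip_low`` optionally floors the lower bound (count metrics cannot be
    negative).
    """
    x = np.asarray(metric_values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite values to derive thresholds from")
    med = float(np.median(x))
    spread = 3.0 * mad(x, mad_constant)
    low, high = med - spread, med + spread
    if clip_low is not None:
        low = max(low, clip_low)
    return low, high


def auto_filter_thresholds(m: ExpressionMatrix, cell_qc: CellQC, gene_qc: GeneQC,
                           mad_constant: float = 1.4826) -> FilterThresholds:
    """Derive auto-mode thresholds from computed QC metrics."""
    def bounds(values, upper_only=False, clip_low=None):
        low, high = auto_thresholds(values, mad_constant, clip_low=clip_low)
        return MetricBounds(low=-np.inf if upper_only else low, high=high)

    return FilterThresholds(
        nUMI=bounds(cell_qc.nUMI, clip_low=0.0),
        nFeature=bounds(cell_qc.nFeature, clip_low=0.0),
        pctMito=bounds(cell_qc.pctMito, upper_only=True),
        pctSpikeIn=bounds(cell_qc.pctSpikeIn, upper_only=True),
        nCell=bounds(gene_qc.nCell, clip_low=1.0),
        mode="auto",
        mad_constant=mad_constant,
    )


def filter_matrix(m: ExpressionMatrix, t: FilterThresholds | None = None,
                  return_report: bool = False):
    """Remove low-quality cells, then genes (nCell recomputed on surviving cells).

    A cell is kept iff every enabled cell metric lies within its bounds; a
    gene is kept iff its nCell (on surviving cells) is within bounds.
    """
    cell_qc, gene_qc = compute_qc(m)
    if t is None or t.mode == "auto":
        mad_c = t.mad_constant if t is not None else 1.4826
        t = auto_filter_thresholds(m, cell_qc, gene_qc, mad_constant=mad_c)

    keep_cell = np.ones(m.n_cells, dtype=bool)
    report: dict[str, int] = {}
    for name, values in (("nUMI", cell_qc.nUMI), ("nFeature", cell_qc.nFeature),
                         ("pctMito", cell_qc.pctMito),
                         ("pctSpikeIn", cell_qc.pctSpikeIn)):
        b: MetricBounds = getattr(t, name)
        if not b.enabled:
            continue
        ok = (values >= b.low) & (values <= b.high)
        report[f"cells_removed_{name}"] = int((~ok & keep_cell).sum())
        keep_cell &= ok
    if not keep_cell.any():
        raise ValueError(
            "all cells removed by filtration; review the thresholds"
        )
    surviving = m.subset(cell_mask=keep_cell)
    n_cell = np.asarray((surviving.values > 0).sum(axis=1)).ravel()
    if t.nCell.enabled:
        keep_gene = (n_cell >= t.nCell.low) & (n_cell <= t.nCell.high)
    else:
        keep_gene = np.ones(surviving.n_genes, dtype=bool)
    report["genes_removed_nCell"] = int((~keep_gene).sum())
    out = surviving.subset(gene_mask=keep_gene)
    if return_report:
        return out, report, t
    return out


def normalize(m: ExpressionMatrix, scale: float = 1e6, log_base: float = 2,
              pseudocount: float = 1) -> ExpressionMatrix:
    """CPM-scale each cell then log-transform; TPM input is log-transformed only.

    Zeros stay zero (pseudocount 1 with any log base maps 0 -> 0), so sparsity
    is preserved.
    """
    if m.value_kind not in ("counts", "tpm"):
        raise ValueError(f"matrix already normalized (value_kind={m.value_kind})")
    X = m.values.tocsc().astype(float)
    if m.value_kind == "counts":
        totals = np.asarray(X.sum(axis=0)).ravel()
        if (totals == 0).any():
            raise ValueError(
                "cells with zero total counts cannot be normalized; filter first"
            )
        X = X @ sp.diags(scale / totals)
        kind = "log2cpm"
    else:
        kind = "log2tpm"
    X = X.tocsr()
    X.data = np.log(X.data + pseudocount) / np.log(log_base)
    return replace(m, values=X, value_kind=kind)
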