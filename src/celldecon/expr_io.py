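"""Readers and writers for expression matrices, cell annotations, marker
tables, and proportion outputs.

Dense matrices are delimited text with a header row of sample IDs and a
leading column of gene IDs. Sparse single-cell matrices use the
MatrixMarket coordinate triplet convention (matrix.mtx + features/barcodes
lists, 1-based indices). All gene and sample identifiers are treated as
opaque strings; no symbol/Ensembl mapping is attempted.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

VALID_UNITS = ("counts", "cpm", "arbitrary")

#: full round-trip precision for text floats
_FLOAT_FMT = "%.17g"


class ExprIOError(ValueError):
    """Raised on malformed input files or contract violations."""


@dataclass
class CountsMatrix:
    """Genes x samples expression matrix.

    ``unit`` distinguishes raw counts, counts-per-million, and arbitrary
    real-valued matrices (e.g. linearly transformed expression or
    regression residuals, which may be negative).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    unit: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.unit not in VALID_UNITS:
            raise ExprIOError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.values.ndim != 2:
            raise ExprIOError("values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ExprIOError(
                f"shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ExprIOError("duplicate gene IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ExprIOError("duplicate sample IDs")
        if self.unit in ("counts", "cpm") and np.any(self.values < 0):
            raise ExprIOError(f"negative entries are not allowed for unit={self.unit!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, gene_ids: list[str]) -> "CountsMatrix":
        """Row-subset (and reorder) to the given genes."""
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise ExprIOError(f"genes not present in matrix: {missing[:5]}...")
        rows = [idx[g] for g in gene_ids]
        return CountsMatrix(self.values[rows], list(gene_ids), list(self.sample_ids), self.unit)

    def subset_samples(self, sample_ids: list[str]) -> "CountsMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise ExprIOError(f"samples not present in matrix: {missing[:5]}...")
        cols = [idx[s] for s in sample_ids]
        return CountsMatrix(self.values[:, cols], list(self.gene_ids), list(sample_ids), self.unit)


@dataclass
class CellAnnotation:
    """Per-cell metadata: cell ID, individual of origin, cell-type label."""

    table: pd.DataFrame  # columns: cell_id, individual_id, cell_type

    def __post_init__(self) -> None:
        required = ["cell_id", "individual_id", "cell_type"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ExprIOError(f"annotation table missing columns: {missing}")
        self.table = self.table[required].astype(str).reset_index(drop=True)
        if self.table["cell_id"].duplicated().any():
            dups = self.table.loc[self.table["cell_id"].duplicated(), "cell_id"].head().tolist()
            raise ExprIOError(f"duplicate cell IDs in annotation: {dups}")
        if (self.table["cell_type"].str.len() == 0).any():
            raise ExprIOError("empty cell_type labels in annotation")

    @property
    def cell_ids(self) -> list[str]:
        return self.table["cell_id"].tolist()

    @property
    def individuals(self) -> list[str]:
        """Individual IDs in order of first appearance."""
        return self.table["individual_id"].drop_duplicates().tolist()

    @property
    def cell_types(self) -> list[str]:
        """Cell-type labels in order of first appearance."""
        return self.table["cell_type"].drop_duplicates().tolist()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class MarkerSet:
    """Marker genes per cell type with specificity (log fold-change) and
    significance (p-value / FDR) from an upstream differential-expression
    analysis."""

    table: pd.DataFrame  # columns: gene_id, cell_type, log_fold_change, p_value, fdr

    def __post_init__(self) -> None:
        required = ["gene_id", "cell_type", "log_fold_change", "p_value", "fdr"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ExprIOError(f"marker table missing columns: {missing}")
        t = self.table[required].copy().reset_index(drop=True)
        t["gene_id"] = t["gene_id"].astype(str)
        t["cell_type"] = t["cell_type"].astype(str)
        for col in ("log_fold_change", "p_value", "fdr"):
            t[col] = pd.to_numeric(t[col])
        if t.duplicated(subset=["gene_id", "cell_type"]).any():
            raise ExprIOError("duplicate (gene_id, cell_type) pairs in marker table")
        for col in ("p_value", "fdr"):
            if ((t[col] < 0) | (t[col] > 1)).any():
                raise ExprIOError(f"{col} outside [0, 1]")
        self.table = t

    @property
    def gene_ids(self) -> list[str]:
        return self.table["gene_id"].drop_duplicates().tolist()

    @property
    def cell_types(self) -> list[str]:
        return self.table["cell_type"].drop_duplicates().tolist()

    def for_cell_type(self, cell_type: str) -> pd.DataFrame:
        return self.table[self.table["cell_type"] == cell_type].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


def _sep_for(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


def read_dense_matrix(
    path: str,
    orientation: str = "genes_by_samples",
    delimiter: str | None = None,
    unit: str = "counts",
) -> CountsMatrix:
    """Read a dense delimited expression matrix.

    The on-disk layout may be genes-by-samples or samples-by-genes
    (``orientation``); the returned matrix is always genes x samples.
    Duplicate gene rows are collapsed by summation with a warning;
    duplicate sample IDs are a hard error.
    """
    if orientation not in ("genes_by_samples", "samples_by_genes"):
        raise ExprIOError(f"unknown orientation {orientation!r}")
    sep = _sep_for(path, delimiter)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if orientation == "genes_by_samples" and len(header) != len(set(header)):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise ExprIOError(f"duplicate sample IDs in {path}: {dups}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "samples_by_genes":
        df = df.T
    # genes on rows now; validate numeric cell by cell for a useful message
    try:
        vals = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError):
        numeric = df.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & df.notna()
        r, c = np.argwhere(bad.values)[0]
        raise ExprIOError(
            f"non-numeric value {df.iat[r, c]!r} at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r} in {path}"
        ) from None
    if vals.columns.duplicated().any():
        dups = vals.columns[vals.columns.duplicated()].unique().tolist()
        raise ExprIOError(f"duplicate sample IDs in {path}: {dups}")
    if vals.index.duplicated().any():
        dups = vals.index[vals.index.duplicated()].unique().tolist()
        logger.warning("collapsing duplicate gene rows by summation: %s", dups[:10])
        vals = vals.groupby(level=0, sort=False).sum()
    return CountsMatrix(vals.to_numpy(dtype=float), vals.index.tolist(), vals.columns.tolist(), unit)


def write_dense_matrix(mat: CountsMatrix, path: str, delimiter: str | None = None) -> None:
    sep = _sep_for(path, delimiter)
    mat.to_frame().to_csv(path, sep=sep, float_format=_FLOAT_FMT, index_label="gene")


def read_sparse_sc(
    matrix_path: str, features_path: str, barcodes_path: str, unit: str = "counts"
) -> CountsMatrix:
    """Read a 10x-style MatrixMarket triplet export (genes = features,
    samples = barcodes). Entries absent from the triplet file are zero."""
    try:
        mat = scipy.io.mmread(matrix_path)
    except Exception as exc:  # noqa: BLE001 - surface path context
        raise ExprIOError(f"failed to parse MatrixMarket file {matrix_path}: {exc}") from exc
    features = _read_id_list(features_path)
    barcodes = _read_id_list(barcodes_path)
    mat = scipy.sparse.coo_matrix(mat)
    if mat.shape != (len(features), len(barcodes)):
        raise ExprIOError(
            f"matrix header declares shape {mat.shape} but found "
            f"{len(features)} features and {len(barcodes)} barcodes"
        )
    return CountsMatrix(mat.toarray().astype(float), features, barcodes, unit)


def write_sparse_sc(mat: CountsMatrix, matrix_path: str, features_path: str, barcodes_path: str) -> None:
    sp = scipy.sparse.coo_matrix(mat.values)
    scipy.io.mmwrite(matrix_path, sp, precision=17)
    _write_id_list(mat.gene_ids, features_path)
    _write_id_list(mat.sample_ids, barcodes_path)


def _read_id_list(path: str) -> list[str]:
    with open(path) as fh:
        # 10x feature files may carry extra tab-separated columns; keep the first
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _write_id_list(ids: list[str], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(ids) + ("\n" if ids else ""))


def read_cell_annotations(path: str, delimiter: str | None = None) -> CellAnnotation:
    sep = _sep_for(path, delimiter)
    return CellAnnotation(pd.read_csv(path, sep=sep, dtype=str))


def write_cell_annotations(ann: CellAnnotation, path: str, delimiter: str | None = None) -> None:
    ann.table.to_csv(path, sep=_sep_for(path, delimiter), index=False)


#: accepted aliases for marker-table columns (Seurat-style exports)
_MARKER_ALIASES = {
    "gene": "gene_id",
    "gene_id": "gene_id",
    "cell_type": "cell_type",
    "cluster": "cell_type",
    "avg_logFC": "log_fold_change",
    "avg_log2FC": "log_fold_change",
    "log_fold_change": "log_fold_change",
    "p_value": "p_value",
    "p_val": "p_value",
    "fdr": "fdr",
    "p_val_adj": "fdr",
}


def read_markers(path: str, delimiter: str | None = None) -> MarkerSet:
    sep = _sep_for(path, delimiter)
    df = pd.read_csv(path, sep=sep)
    df = df.rename(columns={c: _MARKER_ALIASES[c] for c in df.columns if c in _MARKER_ALIASES})
    return MarkerSet(df)


def write_markers(markers: MarkerSet, path: str, delimiter: str | None = None) -> None:
    out = markers.table.rename(
        columns={"gene_id": "gene", "log_fold_change": "avg_logFC"}
    )
    out.to_csv(path, sep=_sep_for(path, delimiter), index=False, float_format=_FLOAT_FMT)


def write_proportions(props, path: str, delimiter: str | None = None) -> None:
    """Write a ProportionMatrix as a TSV: cell types as rows, samples as
    columns, plus a trailing ``residual_norm`` row, at full float precision."""
    sep = _sep_for(path, delimiter)
    df = pd.DataFrame(
        np.vstack([props.values, np.asarray(props.residual_norm)[None, :]]),
        index=list(props.cell_types) + ["residual_norm"],
        columns=props.sample_ids,
    )
    try:
        df.to_csv(path, sep=sep, float_format=_FLOAT_FMT, index_label="cell_type")
    except OSError as exc:
        raise ExprIOError(f"failed to write proportions to {path}: {exc}") from exc


def read_proportions(path: str, delimiter: str | None = None):
    """Read back a proportion TSV written by :func:`write_proportions`."""
    from .decompose import ProportionMatrix  # local import to avoid a cycle

    sep = _sep_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    if "residual_norm" not in df.index:
        raise ExprIOError(f"{path} lacks a residual_norm row")
    resid = df.loc["residual_norm"].to_numpy(dtype=float)
    body = df.drop(index="residual_norm")
    return ProportionMatrix(
        body.to_numpy(dtype=float),
        body.index.tolist(),
        [str(c) for c in body.columns],
        resid,
    )
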