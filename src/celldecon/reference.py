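"""Gene filtering, CPM normalization, and construction of the cell-type
reference profile, observed single-cell proportions, and pseudo-bulk.

The reference profile ``Z`` (genes x cell types) holds the mean normalized
abundance of each gene within each cell type, pooled over every cell in
the single-cell dataset. Observed proportions ``p`` (cell types x
individuals) come from counting annotated cells. The pseudo-bulk
``Y = Z p`` is the expression each individual's bulk sample would show if
the reference and proportions were exact — the target the bulk
transformation aligns to.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .expr_io import CellAnnotation, CountsMatrix, MarkerSet

logger = logging.getLogger(__name__)

CPM_SCALE = 1e6
DEFAULT_MITO_PREFIXES = ("MT-",)


@dataclass
class ReferenceProfile:
    """Genes x cell-types matrix of mean normalized (CPM-scale) abundances."""

    values: np.ndarray
    gene_ids: list[str]
    cell_types: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_types = [str(c) for c in self.cell_types]
        if self.values.shape != (len(self.gene_ids), len(self.cell_types)):
            raise ValueError("reference shape does not match gene/cell-type labels")
        if np.any(self.values < 0):
            raise ValueError("negative entries in reference profile")
        zero_cols = [c for i, c in enumerate(self.cell_types) if not self.values[:, i].any()]
        if zero_cols:
            raise ValueError(f"cell types with an all-zero profile: {zero_cols}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)


@dataclass
class ScProportions:
    """Cell types x individuals matrix of observed single-cell proportions;
    each column lies on the probability simplex."""

    values: np.ndarray
    cell_types: list[str]
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_types = [str(c) for c in self.cell_types]
        self.individual_ids = [str(i) for i in self.individual_ids]
        if self.values.shape != (len(self.cell_types), len(self.individual_ids)):
            raise ValueError("proportion shape does not match labels")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("proportions outside [0, 1]")
        if self.values.shape[1] and np.any(np.abs(self.values.sum(axis=0) - 1.0) > 1e-12):
            raise ValueError("proportion columns must sum to 1 within 1e-12")


def filter_genes(
    sc: CountsMatrix,
    bulk: CountsMatrix,
    markers: MarkerSet,
    mito_prefixes: tuple[str, ...] = DEFAULT_MITO_PREFIXES,
) -> list[str]:
    """Select the genes used for decomposition.

    Keeps marker genes present in both matrices, then drops genes with
    zero variance across single cells, genes with zero total bulk
    expression, and mitochondrial genes (ID prefix match,
    case-insensitive). Output order follows the bulk gene order.
    """
    marker_genes = set(markers.gene_ids)
    sc_idx = {g: i for i, g in enumerate(sc.gene_ids)}
    prefixes = tuple(p.upper() for p in mito_prefixes)

    kept: list[str] = []
    for j, g in enumerate(bulk.gene_ids):
        if g not in marker_genes or g not in sc_idx:
            continue
        if prefixes and g.upper().startswith(prefixes):
            continue
        if bulk.values[j].sum() == 0:
            continue
        if np.var(sc.values[sc_idx[g]]) == 0:
            continue
        kept.append(g)
    if not kept:
        raise ValueError(
            "no genes survive filtering; check that gene ID conventions match "
            "between the bulk matrix, single-cell matrix, and marker table"
        )
    return kept


def cpm_normalize(counts: CountsMatrix) -> CountsMatrix:
    """Scale each sample column to sum to one million (CPM)."""
    sums = counts.values.sum(axis=0)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        names = [counts.sample_ids[i] for i in zero[:5]]
        raise ValueError(f"all-zero sample columns cannot be CPM-normalized: {names}")
    vals = counts.values * (CPM_SCALE / sums)
    return CountsMatrix(vals, counts.gene_ids, counts.sample_ids, unit="cpm")


def build_reference(
    sc_norm: CountsMatrix,
    ann: CellAnnotation,
    averaging: str = "per_cell_mean",
    min_cells_per_type: int = 1,
) -> ReferenceProfile:
    """Average relative abundances within each cell type into the
    reference profile Z.

    ``per_cell_mean`` (default) averages per-cell CPM vectors over all
    cells of a type, pooled across individuals with equal per-cell weight;
    it expects ``sc_norm`` to be CPM-normalized. ``pooled_cpm`` instead
    sums raw counts per type and CPM-scales the pooled column.
    """
    if averaging not in ("per_cell_mean", "pooled_cpm"):
        raise ValueError(f"unknown averaging mode {averaging!r}")
    if averaging == "per_cell_mean" and sc_norm.unit != "cpm":
        raise ValueError("per_cell_mean averaging expects a CPM-normalized matrix")
    col = {c: i for i, c in enumerate(sc_norm.sample_ids)}
    missing = [c for c in ann.cell_ids if c not in col]
    if missing:
        raise ValueError(f"annotated cells absent from the matrix: {missing[:5]}")
    cell_types = ann.cell_types
    cols = []
    for ct in cell_types:
        ids = ann.table.loc[ann.table["cell_type"] == ct, "cell_id"]
        if len(ids) < min_cells_per_type:
            raise ValueError(
                f"cell type {ct!r} has {len(ids)} annotated cells "
                f"(min_cells_per_type={min_cells_per_type})"
            )
        block = sc_norm.values[:, [col[c] for c in ids]]
        if averaging == "per_cell_mean":
            cols.append(block.mean(axis=1))
        else:
            pooled = block.sum(axis=1)
            total = pooled.sum()
            if total == 0:
                raise ValueError(f"cell type {ct!r} has zero total counts")
            cols.append(pooled * (CPM_SCALE / total))
    return ReferenceProfile(np.column_stack(cols), list(sc_norm.gene_ids), cell_types)


def sc_proportions(ann: CellAnnotation, cell_types: list[str] | None = None) -> ScProportions:
    """Observed cell-type proportions per individual from annotated cells."""
    if cell_types is None:
        cell_types = ann.cell_types
    individuals = ann.individuals
    counts = np.zeros((len(cell_types), len(individuals)))
    ct_idx = {c: i for i, c in enumerate(cell_types)}
    ind_idx = {i: j for j, i in enumerate(individuals)}
    for _, row in ann.table.iterrows():
        if row["cell_type"] not in ct_idx:
            raise ValueError(f"cell type {row['cell_type']!r} not in the requested list")
        counts[ct_idx[row["cell_type"]], ind_idx[row["individual_id"]]] += 1
    totals = counts.sum(axis=0)
    keep = totals > 0
    if not keep.all():
        dropped = [ind for ind, k in zip(individuals, keep) if not k]
        logger.warning("excluding individuals with zero cells: %s", dropped)
        counts = counts[:, keep]
        totals = totals[keep]
        individuals = [ind for ind, k in zip(individuals, keep) if k]
    return ScProportions(counts / totals, list(cell_types), individuals)


def pseudo_bulk(Z: ReferenceProfile, p: ScProportions) -> CountsMatrix:
    """Pseudo-bulk Y = Z p: the reference weighted by observed proportions."""
    if Z.cell_types != p.cell_types:
        extra_z = set(Z.cell_types) - set(p.cell_types)
        extra_p = set(p.cell_types) - set(Z.cell_types)
        raise ValueError(
            "cell-type mismatch between reference and proportions "
            f"(only in Z: {sorted(extra_z)}, only in p: {sorted(extra_p)}, "
            f"or ordering differs)"
        )
    return CountsMatrix(
        Z.values @ p.values, list(Z.gene_ids), list(p.individual_ids), unit="arbitrary"
    )
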