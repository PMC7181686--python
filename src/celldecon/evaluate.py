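"""Scoring and cross-validation harness.

Accuracy of proportion estimates is summarized two ways, mirroring how
deconvolution methods are conventionally benchmarked: a *global* Pearson
correlation and root-mean-square deviation pooled over every (cell type,
sample) pair, and *per-sample* metrics computed within each sample's cell
types and then averaged (mean +/- SD). Leave-one-out cross-validation
over the individuals that have both bulk and single-cell data rebuilds
the reference and transform from the remaining individuals for each fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .decompose import ProportionMatrix, decompose
from .expr_io import CellAnnotation, CountsMatrix, MarkerSet
from .reference import (
    ScProportions,
    build_reference,
    cpm_normalize,
    filter_genes,
    pseudo_bulk,
    sc_proportions,
)
from .transform import apply_transform, fit_moment_match, fit_overlap

logger = logging.getLogger(__name__)

DEFAULT_ABLATION_FRACTIONS = (0.0, 0.25, 0.5, 0.75, 0.9)


@dataclass
class EvalResult:
    R: float
    rmsd: float
    per_sample: pd.DataFrame  # columns: sample_id, R, rmsd
    n_points: int

    @property
    def per_sample_mean_R(self) -> float:
        return float(self.per_sample["R"].mean())

    @property
    def per_sample_mean_rmsd(self) -> float:
        return float(self.per_sample["rmsd"].mean())


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(scipy.stats.pearsonr(a, b).statistic)


def global_metrics(est: ProportionMatrix, truth) -> EvalResult:
    """Global and per-sample Pearson R / RMSD between estimated and
    observed proportions. ``truth`` may be a ScProportions or another
    ProportionMatrix; it is aligned to the estimate's cell-type and
    sample ordering."""
    t_samples = truth.individual_ids if isinstance(truth, ScProportions) else truth.sample_ids
    if set(est.cell_types) != set(truth.cell_types) or set(est.sample_ids) != set(t_samples):
        raise ValueError("estimate and truth must cover the same cell types and samples")
    tdf = pd.DataFrame(truth.values, index=truth.cell_types, columns=t_samples)
    T = tdf.loc[est.cell_types, est.sample_ids].to_numpy()
    E = est.values

    R = _pearson(E.ravel(), T.ravel())
    rmsd = float(np.sqrt(np.mean((E - T) ** 2)))
    rows = []
    for i, s in enumerate(est.sample_ids):
        rows.append(
            {
                "sample_id": s,
                "R": _pearson(E[:, i], T[:, i]),
                "rmsd": float(np.sqrt(np.mean((E[:, i] - T[:, i]) ** 2))),
            }
        )
    return EvalResult(R, rmsd, pd.DataFrame(rows), n_points=E.size)


def decompose_pipeline(
    sc: CountsMatrix,
    ann: CellAnnotation,
    bulk: CountsMatrix,
    markers: MarkerSet,
    mode: str = "auto",
    overlap_samples: list[str] | None = None,
    mito_prefixes: tuple[str, ...] = ("MT-",),
    clip_negative: bool = False,
) -> ProportionMatrix:
    """Full reference-based pipeline on raw inputs.

    mode: 'overlap' regresses pseudo-bulk on the overlapping bulk
    columns; 'moment' moment-matches; 'none' skips the transformation
    (raw CPM against the reference); 'auto' picks overlap when >= 2
    individuals are shared between the bulk columns and the annotated
    single-cell individuals, else moment.
    """
    genes = filter_genes(sc, bulk, markers, mito_prefixes)
    sc_f = cpm_normalize(sc.subset_genes(genes))
    bulk_f = cpm_normalize(bulk.subset_genes(genes))
    Z = build_reference(sc_f, ann)
    p_obs = sc_proportions(ann)
    Y = pseudo_bulk(Z, p_obs)

    if overlap_samples is None:
        overlap_samples = [s for s in p_obs.individual_ids if s in set(bulk.sample_ids)]
    if mode == "auto":
        mode = "overlap" if len(overlap_samples) >= 2 else "moment"

    if mode == "none":
        X_t = bulk_f
    elif mode == "moment":
        model = fit_moment_match(Y)
        X_t = apply_transform(model, bulk_f, clip_negative=clip_negative)
    elif mode == "overlap":
        if len(overlap_samples) < 2:
            raise ValueError("overlap mode requires at least 2 shared sample IDs")
        Y_ov = CountsMatrix(
            Y.values[:, [Y.sample_ids.index(s) for s in overlap_samples]],
            list(Y.gene_ids),
            list(overlap_samples),
            unit="arbitrary",
        )
        model = fit_overlap(Y_ov, bulk_f.subset_samples(list(overlap_samples)))
        X_t = apply_transform(model, bulk_f, clip_negative=clip_negative)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return decompose(Z, X_t)


def loocv(
    sc: CountsMatrix,
    ann: CellAnnotation,
    bulk_overlap: CountsMatrix,
    markers: MarkerSet,
    mode: str = "moment",
    mito_prefixes: tuple[str, ...] = ("MT-",),
) -> EvalResult:
    """Leave-one-out cross-validation over reference individuals.

    For each individual with both bulk and single-cell data, the
    reference (and transform) are rebuilt from the remaining individuals'
    cells, the held-out bulk column is decomposed, and the estimate is
    scored against the held-out individual's observed single-cell
    proportions. Metrics are aggregated over all folds.
    """
    p_all = sc_proportions(ann)
    folds = [i for i in p_all.individual_ids if i in set(bulk_overlap.sample_ids)]
    if len(folds) < 2:
        raise ValueError("leave-one-out CV requires at least 2 overlapping individuals")
    if len(folds) < 3:
        logger.warning(
            "only %d overlapping individuals; at least 3 are recommended", len(folds)
        )
    cell_types = p_all.cell_types
    # only marker genes can survive filtering; shrink the cell matrix once
    # up front so per-fold copies stay cheap
    marker_genes = set(markers.gene_ids)
    pre = [g for g in sc.gene_ids if g in marker_genes]
    if pre:
        sc = sc.subset_genes(pre)
    est_cols, truth_cols = [], []
    resids = []
    for held in folds:
        train_tab = ann.table[ann.table["individual_id"] != held]
        train_ann = CellAnnotation(train_tab.reset_index(drop=True))
        if set(train_ann.cell_types) != set(cell_types):
            raise ValueError(
                f"holding out {held} removes a cell type entirely; cannot cross-validate"
            )
        train_sc = sc.subset_samples(train_ann.cell_ids)
        overlap = [i for i in train_ann.individuals if i in set(bulk_overlap.sample_ids)]
        props = decompose_pipeline(
            train_sc,
            train_ann,
            bulk_overlap,
            markers,
            mode=mode,
            overlap_samples=overlap,
            mito_prefixes=mito_prefixes,
        )
        col = props.sample_ids.index(held)
        est_df = props.to_frame()
        est_cols.append(est_df.loc[cell_types, held].to_numpy())
        truth_cols.append(
            pd.DataFrame(p_all.values, index=p_all.cell_types, columns=p_all.individual_ids)
            .loc[cell_types, held]
            .to_numpy()
        )
        resids.append(props.residual_norm[col])
    est = ProportionMatrix(
        np.column_stack(est_cols), list(cell_types), folds, np.asarray(resids)
    )
    truth = ScProportions(np.column_stack(truth_cols), list(cell_types), folds)
    return global_metrics(est, truth)


def marker_ablation(
    decompose_fn,
    markers: MarkerSet,
    cell_type: str,
    order: str = "desc_lfc",
    fractions: tuple[float, ...] = DEFAULT_ABLATION_FRACTIONS,
) -> pd.DataFrame:
    """Re-run a decomposition while progressively removing one cell
    type's markers.

    ``decompose_fn`` maps a MarkerSet to an association metric (on
    synthetic data, typically Spearman correlation between the cell
    type's estimates and its true proportions). Markers are removed in
    order of decreasing (``desc_lfc``) or increasing (``asc_lfc``)
    log-fold change; a fraction of 1 is skipped with a warning.
    """
    if order not in ("desc_lfc", "asc_lfc"):
        raise ValueError(f"unknown order {order!r}")
    ct_rows = markers.for_cell_type(cell_type)
    if len(ct_rows) < 4:
        raise ValueError(f"cell type {cell_type!r} has fewer than 4 markers")
    ranked = ct_rows.sort_values(
        "log_fold_change", ascending=(order == "asc_lfc"), kind="stable"
    )
    n = len(ranked)
    rows = []
    for frac in fractions:
        if frac >= 1:
            logger.warning("skipping removal fraction %g (would drop all markers)", frac)
            continue
        n_drop = int(np.floor(frac * n))
        dropped = set(ranked["gene_id"].head(n_drop))
        keep = markers.table[
            (markers.table["cell_type"] != cell_type)
            | (~markers.table["gene_id"].isin(dropped))
        ]
        metric = decompose_fn(MarkerSet(keep.reset_index(drop=True)))
        rows.append({"fraction_removed": frac, "order": order, "metric": float(metric)})
    return pd.DataFrame(rows)
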