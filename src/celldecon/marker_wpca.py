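"""Marker-only (reference-free) relative abundance estimation by weighted
PCA.

When no single-cell reference profile is available but per-cell-type
marker genes (with log-fold-change specificity weights from differential
expression) are, the first principal component of the standardized,
weight-scaled marker submatrix tracks relative differences in a cell
type's abundance across bulk samples. Scores are standardized per cell
type (mean 0, SD 1): they are comparable across samples within a cell
type but carry no absolute scale and cannot be compared between cell
types.

Before the per-type wPCA the expression matrix is residualized against
its first global principal component so that scores do not reflect
dataset-wide technical variation. The number of markers used per cell
type is chosen by maximizing the ratio of the first to the second
eigenvalue of the weighted marker PCA over a search range, a proxy for a
single dominant abundance factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .expr_io import CountsMatrix, MarkerSet
from .reference import cpm_normalize

logger = logging.getLogger(__name__)

DEFAULT_RANGE = (25, 200)
DEFAULT_STEP = 5
DEFAULT_FDR = 0.05


@dataclass
class MarkerConfig:
    """Tunables for the marker-based pipeline."""

    fdr_threshold: float = DEFAULT_FDR
    count_range: tuple[int, int] = DEFAULT_RANGE
    count_step: int = DEFAULT_STEP
    global_correction: bool = True
    drop_shared_markers: bool = False
    log_transform: bool = True
    use_weights: bool = True


@dataclass
class AbundanceScores:
    """Standardized per-cell-type abundance scores across bulk samples."""

    values: np.ndarray  # cell types x samples
    cell_types: list[str]
    sample_ids: list[str]
    markers_used: dict[str, int]
    variance_explained: dict[str, float]
    direction_agreement: dict[str, float]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.cell_types, columns=self.sample_ids)


def _standardize_columns(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column z-scores (ddof=1); zero-variance columns become zero.
    Returns (standardized, nonzero-variance mask)."""
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    ok = sd > 0
    S = np.zeros_like(M, dtype=float)
    S[:, ok] = (M[:, ok] - mean[ok]) / sd[ok]
    return S, ok


def correct_global_pc(X: CountsMatrix) -> CountsMatrix:
    """Residualize every gene against the first global expression PC.

    The PC is computed on the standardized genes-as-columns matrix
    (samples as observations); each gene's original expression is then
    regressed on the PC scores (with intercept) and replaced by the
    residual. Output keeps the original gene/sample order and may be
    negative (unit becomes ``arbitrary``).
    """
    if X.n_samples < 3:
        raise ValueError("global-PC correction requires at least 3 samples")
    M = X.values.T  # samples x genes
    S, _ = _standardize_columns(M)
    # first left singular vector of S = PC1 scores of the samples
    U, s, _ = np.linalg.svd(S, full_matrices=False)
    pc1 = U[:, 0] * s[0]
    denom = float(pc1 @ pc1)
    if denom == 0:
        return CountsMatrix(X.values.copy(), list(X.gene_ids), list(X.sample_ids), "arbitrary")
    centered = M - M.mean(axis=0)
    beta = (pc1 @ centered) / denom  # per-gene regression slope on PC1
    resid = centered - np.outer(pc1, beta)
    return CountsMatrix(resid.T, list(X.gene_ids), list(X.sample_ids), unit="arbitrary")


def _weighted_pca(
    X_corr: CountsMatrix, markers: list[str], weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """Shared core: standardize marker columns, scale by weights, PCA.

    Returns (PC1 sample scores (unnormalized), eigenvalues, kept marker
    ids, kept weights). Zero-variance markers are dropped with a warning.
    """
    from sklearn.decomposition import PCA

    idx = {g: i for i, g in enumerate(X_corr.gene_ids)}
    missing = [g for g in markers if g not in idx]
    if missing:
        raise ValueError(f"markers absent from expression matrix: {missing[:5]}")
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(markers),):
        raise ValueError("one weight per marker required")
    if not np.all(np.isfinite(weights)):
        raise ValueError("non-finite marker weights")

    M = X_corr.values[[idx[g] for g in markers]].T  # samples x markers
    S, ok = _standardize_columns(M)
    if not ok.all():
        dropped = [g for g, k in zip(markers, ok) if not k]
        logger.warning("dropping zero-variance markers: %s", dropped[:10])
    if not ok.any():
        raise ValueError("all markers have zero variance across samples")
    S = S[:, ok]
    kept = [g for g, k in zip(markers, ok) if k]
    w = weights[ok]
    XW = S * w

    n_comp = min(2, min(XW.shape))
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(XW)
    eigvals = pca.explained_variance_
    ratio1 = float(pca.explained_variance_ratio_[0])
    return scores[:, 0], eigvals, kept, w, ratio1


def weighted_pc1(
    X_corr: CountsMatrix, markers: list[str], weights: np.ndarray
) -> np.ndarray:
    """First PC of the standardized, weight-scaled marker submatrix.

    The sign is oriented so the weight-weighted mean correlation between
    marker expression and the score is positive, and the score is
    standardized to mean 0 / SD 1 across samples.
    """
    score, _, kept, w, _ = _weighted_pca(X_corr, markers, weights)
    return _orient_and_standardize(score, X_corr, kept, w)[0]


def _orient_and_standardize(
    score: np.ndarray, X_corr: CountsMatrix, kept: list[str], w: np.ndarray
) -> tuple[np.ndarray, float]:
    """Apply the sign convention, standardize, and report the fraction of
    markers whose expression correlates with the score in their weight's
    direction."""
    idx = {g: i for i, g in enumerate(X_corr.gene_ids)}
    M = X_corr.values[[idx[g] for g in kept]].T
    S, ok = _standardize_columns(M)
    sc = score - score.mean()
    ssd = sc.std(ddof=1) if sc.size > 1 else 0.0
    if ssd == 0:
        raise ValueError("degenerate first PC (zero variance)")
    corr = (S.T @ (sc / ssd)) / (len(sc) - 1)  # per-marker Pearson r with score
    signal = float(np.sum(w * corr))
    if signal < 0:
        sc = -sc
        corr = -corr
    agreement = float(np.mean(np.sign(corr[ok]) == np.sign(w[ok]))) if ok.any() else np.nan
    return sc / ssd, agreement


def select_marker_count(
    X_corr: CountsMatrix,
    ranked_markers,
    count_range: tuple[int, int] = DEFAULT_RANGE,
    step: int = DEFAULT_STEP,
) -> int:
    """Choose how many top-ranked markers to use.

    ``ranked_markers`` is a marker table for one cell type sorted by
    ascending p-value (pre-filtered for significance). For each candidate
    count in the range, the ratio of the first to second eigenvalue of
    the weighted marker PCA is computed; the count maximizing the ratio
    wins, ties going to the smallest count. With fewer markers available
    than the lower end of the range, all are used with a warning.
    """
    genes = ranked_markers["gene_id"].tolist()
    weights = ranked_markers["log_fold_change"].to_numpy(dtype=float)
    n_avail = len(genes)
    lo, hi = count_range
    if n_avail < lo:
        logger.warning("only %d markers available (range starts at %d); using all", n_avail, lo)
        return n_avail
    candidates = [n for n in range(lo, hi + 1, step) if n <= n_avail]
    if n_avail < hi and n_avail not in candidates:
        candidates.append(n_avail)
    best_n, best_ratio = candidates[0], -np.inf
    for n in candidates:
        _, eigvals, _, _, _ = _weighted_pca(X_corr, genes[:n], weights[:n])
        ratio = eigvals[0] / eigvals[1] if len(eigvals) > 1 and eigvals[1] > 0 else np.inf
        if ratio > best_ratio:
            best_n, best_ratio = n, ratio
    return best_n


def marker_decompose(
    X: CountsMatrix, markers: MarkerSet, config: MarkerConfig | None = None
) -> AbundanceScores:
    """Full marker-based pipeline over all cell types.

    CPM (for raw counts) -> log1p -> global-PC correction -> per cell
    type: FDR filter, rank by p-value, eigenvalue-ratio marker-count
    selection, weighted PC1. Cell types with no significant markers in
    the matrix are omitted with a warning.
    """
    config = config or MarkerConfig()
    work = cpm_normalize(X) if X.unit == "counts" else X
    vals = np.log1p(work.values) if config.log_transform else work.values
    work = CountsMatrix(vals, list(work.gene_ids), list(work.sample_ids), unit="arbitrary")
    if config.global_correction:
        work = correct_global_pc(work)

    table = markers.table
    table = table[table["fdr"] < config.fdr_threshold]
    if config.drop_shared_markers:
        shared = table["gene_id"][table["gene_id"].duplicated(keep=False)].unique()
        table = table[~table["gene_id"].isin(shared)]
    present = set(work.gene_ids)

    rows, kept_types = [], []
    markers_used: dict[str, int] = {}
    var_explained: dict[str, float] = {}
    agreement: dict[str, float] = {}
    for ct in markers.cell_types:
        sub = table[(table["cell_type"] == ct) & table["gene_id"].isin(present)]
        sub = sub.sort_values("p_value", kind="stable").reset_index(drop=True)
        if sub.empty:
            logger.warning("cell type %r has no significant markers in the matrix; omitted", ct)
            continue
        n = select_marker_count(work, sub, config.count_range, config.count_step)
        genes = sub["gene_id"].tolist()[:n]
        w = sub["log_fold_change"].to_numpy(dtype=float)[:n]
        if not config.use_weights:
            w = np.ones_like(w)
        score, eigvals, kept, wk, ratio1 = _weighted_pca(work, genes, w)
        score, agree = _orient_and_standardize(score, work, kept, wk)
        rows.append(score)
        kept_types.append(ct)
        markers_used[ct] = len(kept)
        var_explained[ct] = ratio1
        agreement[ct] = agree
    if not rows:
        raise ValueError("no cell type has significant markers present in the matrix")
    return AbundanceScores(
        np.vstack(rows), kept_types, list(X.sample_ids), markers_used, var_explained, agreement
    )
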