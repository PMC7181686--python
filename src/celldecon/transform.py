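"""Per-gene linear transformations aligning observed bulk expression with
the reference-weighted pseudo-bulk.

Bulk RNA-seq and single-cell/single-nucleus references measure the same
transcripts with systematic, gene-specific offsets (library chemistry,
nuclear vs. whole-cell capture). Both correction modes here are per-gene
affine maps of the bulk values onto the pseudo-bulk scale:

* ``overlap`` — when individuals with both bulk and single-cell data
  exist, ordinary least squares of the pseudo-bulk Y_j on the overlapping
  bulk values X'_j (with intercept), applied forward to all bulk samples.
* ``moment_match`` — otherwise, z-score each gene across bulk samples and
  rescale to the pseudo-bulk's observed mean and a shrunken SD. The
  variance target uses a divisor of n'+1 rather than n'-1: with few
  single-cell individuals the sample variance of Y_j overstates the true
  spread, and the shrinkage estimator trades bias for a lower MSE.

Transformed values may be negative; the simplex-constrained solver
downstream accepts arbitrary real responses, so no clipping is applied by
default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expr_io import CountsMatrix

logger = logging.getLogger(__name__)

MODES = ("overlap", "moment_match")


@dataclass
class TransformModel:
    """Per-gene affine transform parameters.

    For ``overlap`` genes the forward map is x -> slope*x + intercept.
    For ``moment_match`` genes the map is
    x -> (x - mean(x)) / sd(x) * target_sd + target_mean, where mean/sd
    are computed over the bulk samples at application time (unbiased SD).
    Individual genes may fall back from overlap to moment_match when OLS
    is undefined (zero variance in the overlapping bulk values), so a
    per-gene mode vector is stored alongside the model-level mode.
    """

    mode: str
    gene_ids: list[str]
    gene_modes: np.ndarray  # per-gene: "overlap" or "moment_match"
    slope: np.ndarray
    intercept: np.ndarray
    target_mean: np.ndarray
    target_sd: np.ndarray

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        m = len(self.gene_ids)
        for name in ("gene_modes", "slope", "intercept", "target_mean", "target_sd"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (m,):
                raise ValueError(f"{name} must have one entry per gene")
            setattr(self, name, arr)
        if np.any(self.target_sd[self.gene_modes == "moment_match"] < 0):
            raise ValueError("negative target SD")

    def to_frame(self) -> pd.DataFrame:
        """Serialize as a table (gene, mode, param1, param2) where the
        parameters are slope/intercept for overlap genes and
        mean/SD for moment-matched genes."""
        p1 = np.where(self.gene_modes == "overlap", self.slope, self.target_mean)
        p2 = np.where(self.gene_modes == "overlap", self.intercept, self.target_sd)
        return pd.DataFrame(
            {"gene": self.gene_ids, "mode": self.gene_modes, "param1": p1, "param2": p2}
        )

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str) -> "TransformModel":
        df = pd.read_csv(path, sep="\t", dtype={"gene": str})
        modes = df["mode"].to_numpy()
        overlap = modes == "overlap"
        model_mode = "overlap" if overlap.any() else "moment_match"
        return cls(
            mode=model_mode,
            gene_ids=df["gene"].tolist(),
            gene_modes=modes,
            slope=np.where(overlap, df["param1"], np.nan),
            intercept=np.where(overlap, df["param2"], np.nan),
            target_mean=np.where(overlap, np.nan, df["param1"]),
            target_sd=np.where(overlap, np.nan, df["param2"]),
        )


def shrunk_variance(y: np.ndarray) -> float:
    """Shrinkage estimate of the variance of ``y``: squared deviations
    from the mean divided by n+1 (always below the unbiased estimate)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 2:
        raise ValueError(f"shrunk_variance requires at least 2 values, got {n}")
    return float(np.sum((y - y.mean()) ** 2) / (n + 1))


def fit_moment_match(Y: CountsMatrix) -> TransformModel:
    """Moment-matching targets from the pseudo-bulk: per gene, the mean of
    Y_j and the square root of its shrunken variance."""
    n = Y.n_samples
    if n < 2:
        raise ValueError("moment matching requires at least 2 pseudo-bulk samples")
    if n < 3:
        logger.warning(
            "only %d single-cell individuals; transform targets may be unreliable "
            "(at least 3 are recommended)", n,
        )
    mean = Y.values.mean(axis=1)
    var = ((Y.values - mean[:, None]) ** 2).sum(axis=1) / (n + 1)
    m = Y.n_genes
    return TransformModel(
        mode="moment_match",
        gene_ids=list(Y.gene_ids),
        gene_modes=np.full(m, "moment_match", dtype=object),
        slope=np.full(m, np.nan),
        intercept=np.full(m, np.nan),
        target_mean=mean,
        target_sd=np.sqrt(var),
    )


def fit_overlap(Y: CountsMatrix, X_overlap: CountsMatrix) -> TransformModel:
    """Per-gene OLS of pseudo-bulk on overlapping bulk expression.

    ``Y`` and ``X_overlap`` must cover the same genes and the same n' >= 2
    overlapping samples (matched by sample ID, order-insensitive). Genes
    whose bulk values have zero variance fall back to moment-matching
    parameters, since the regression slope is undefined.
    """
    if Y.gene_ids != X_overlap.gene_ids:
        raise ValueError("gene sets/order differ between pseudo-bulk and overlap bulk")
    shared = [s for s in Y.sample_ids if s in set(X_overlap.sample_ids)]
    if len(shared) != Y.n_samples or len(shared) != X_overlap.n_samples:
        raise ValueError("pseudo-bulk and overlap bulk must cover the same sample IDs")
    if len(shared) < 2:
        raise ValueError("overlap regression requires at least 2 shared samples")
    if len(shared) < 3:
        logger.warning(
            "only %d overlapping individuals; overlap regression may be unreliable "
            "(at least 3 are recommended)", len(shared),
        )
    X = X_overlap.subset_samples(list(Y.sample_ids)).values
    Yv = Y.values
    n = X.shape[1]

    xm = X.mean(axis=1)
    ym = Yv.mean(axis=1)
    xc = X - xm[:, None]
    sxx = (xc**2).sum(axis=1)
    sxy = (xc * (Yv - ym[:, None])).sum(axis=1)

    degenerate = sxx == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(degenerate, np.nan, sxy / np.where(degenerate, 1.0, sxx))
    intercept = ym - slope * xm

    gene_modes = np.where(degenerate, "moment_match", "overlap").astype(object)
    target_mean = ym
    target_sd = np.sqrt(((Yv - ym[:, None]) ** 2).sum(axis=1) / (n + 1))
    if degenerate.any():
        bad = [Y.gene_ids[i] for i in np.flatnonzero(degenerate)[:10]]
        logger.warning(
            "zero variance in overlapping bulk for %d gene(s) (e.g. %s); "
            "falling back to moment matching for these",
            int(degenerate.sum()), bad,
        )
    return TransformModel(
        mode="overlap",
        gene_ids=list(Y.gene_ids),
        gene_modes=gene_modes,
        slope=slope,
        intercept=intercept,
        target_mean=target_mean,
        target_sd=target_sd,
    )


def apply_transform(
    model: TransformModel, X: CountsMatrix, clip_negative: bool = False
) -> CountsMatrix:
    """Apply a fitted per-gene transform to a bulk matrix.

    ``X`` must cover ``model.gene_ids`` (extra genes are dropped, order
    follows the model). Moment-matched genes require at least 2 bulk
    samples; a gene with zero bulk SD is set to its constant target mean.
    """
    X = X.subset_genes(model.gene_ids)
    vals = X.values.astype(float).copy()
    out = np.empty_like(vals)

    ov = model.gene_modes == "overlap"
    if ov.any():
        out[ov] = model.slope[ov, None] * vals[ov] + model.intercept[ov, None]

    mm = ~ov
    if mm.any():
        if X.n_samples < 2:
            raise ValueError("moment matching requires at least 2 bulk samples")
        sub = vals[mm]
        xm = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        flat = sd == 0
        if flat.any():
            genes = [model.gene_ids[i] for i in np.flatnonzero(mm)[np.flatnonzero(flat)][:10]]
            logger.warning(
                "zero bulk SD for %d gene(s) (e.g. %s); set to constant target mean",
                int(flat.sum()), genes,
            )
        safe_sd = np.where(flat, 1.0, sd)
        z = (sub - xm[:, None]) / safe_sd[:, None]
        z[flat] = 0.0
        out[mm] = z * model.target_sd[mm, None] + model.target_mean[mm, None]

    if clip_negative:
        out = np.clip(out, 0.0, None)
    return CountsMatrix(out, list(model.gene_ids), list(X.sample_ids), unit="arbitrary")
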