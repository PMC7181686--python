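"""Simplex-constrained least squares decomposition.

For each bulk sample x, estimate cell-type proportions p minimizing
``||Z p - x||_2`` subject to ``p >= 0`` and ``sum(p) = 1``, where Z is the
cell-type reference profile. The two constraints are enforced jointly by a
primal active-set quadratic program on the non-negativity bounds (the
sum-to-one equality stays in the working KKT system throughout), rather
than by unconstrained NNLS followed by renormalization. A penalty-based
NNLS fallback (heavily weighted sum-to-one row appended to Z, then
renormalization) is available for cross-checking.

The per-sample residual norm ``||Z p - x||_2`` at the optimum is reported
alongside the estimates: samples containing cell populations missing from
the reference tend to show elevated — and across a cohort, multimodal —
residual norms, which :func:`residual_diagnostics` flags via a two- vs
one-component Gaussian-mixture BIC comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .expr_io import CountsMatrix
from .reference import ReferenceProfile

logger = logging.getLogger(__name__)

#: KKT / feasibility tolerance for the active-set solver
KKT_TOL = 1e-10


@dataclass
class ProportionMatrix:
    """Cell types x samples proportion estimates on the probability
    simplex, with the per-sample least-squares residual norm attached."""

    values: np.ndarray
    cell_types: list[str]
    sample_ids: list[str]
    residual_norm: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_types = [str(c) for c in self.cell_types]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.residual_norm = np.asarray(self.residual_norm, dtype=float)
        if self.values.shape != (len(self.cell_types), len(self.sample_ids)):
            raise ValueError("proportion shape does not match labels")
        if self.residual_norm.shape != (len(self.sample_ids),):
            raise ValueError("one residual norm per sample required")
        if np.any(self.values < 0):
            raise ValueError("negative proportion estimates")
        if np.any(self.residual_norm < 0):
            raise ValueError("negative residual norms")
        if self.values.size and np.any(np.abs(self.values.sum(axis=0) - 1.0) > 1e-8):
            raise ValueError("proportion columns must sum to 1 within 1e-8")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.cell_types, columns=self.sample_ids)


def _kkt_solve(Q: np.ndarray, c: np.ndarray, free: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve the equality-constrained subproblem on the free set:
    minimize 0.5 p'Qp - c'p  s.t.  sum(p_free) = 1, p_bound = 0."""
    f = np.flatnonzero(free)
    nf = f.size
    K = np.zeros((nf + 1, nf + 1))
    K[:nf, :nf] = Q[np.ix_(f, f)]
    K[:nf, nf] = 1.0
    K[nf, :nf] = 1.0
    rhs = np.concatenate([c[f], [1.0]])
    try:
        sol = np.linalg.solve(K, rhs)
    except np.linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
    p = np.zeros(Q.shape[0])
    p[f] = sol[:nf]
    return p, float(sol[nf])


def solve_simplex_lsq(
    Z: ReferenceProfile | np.ndarray, x: np.ndarray, tol: float = KKT_TOL
) -> tuple[np.ndarray, float]:
    """Minimize ``||Z p - x||_2`` over the probability simplex.

    Returns ``(p, residual)`` with ``residual = ||Z p - x||_2`` at the
    optimum. The objective is convex, so the minimum value is unique;
    with a rank-deficient design the minimizer itself may not be, in
    which case one valid minimizer is returned with a warning.
    """
    A = Z.values if isinstance(Z, ReferenceProfile) else np.asarray(Z, dtype=float)
    x = np.asarray(x, dtype=float)
    m, k = A.shape
    if x.shape != (m,):
        raise ValueError(f"x must have length {m}, got {x.shape}")
    if k == 1:
        p = np.ones(1)
        return p, float(np.linalg.norm(A[:, 0] - x))

    Q = A.T @ A
    c = A.T @ x
    if np.linalg.matrix_rank(A, tol=1e-10 * max(1.0, float(np.abs(A).max()))) < k:
        logger.warning("reference has linearly dependent columns; minimizer may not be unique")

    # primal active set on the bounds, Lawson–Hanson style safeguarded steps
    p = np.full(k, 1.0 / k)
    free = np.ones(k, dtype=bool)
    for _ in range(200 * k):
        cand, lam = _kkt_solve(Q, c, free)
        if cand[free].min() >= -tol:
            p = np.clip(cand, 0.0, None)
            # multipliers for bound variables: mu_i = (Qp - c)_i + lambda
            mu = Q @ p - c + lam
            bound = ~free
            if not bound.any() or mu[bound].min() >= -max(tol, tol * np.abs(mu).max()):
                break
            release = np.flatnonzero(bound)[np.argmin(mu[bound])]
            free[release] = True
            continue
        # partial step toward cand until the first free variable hits zero
        d = cand - p
        blocking = free & (cand < -tol) & (d < 0)
        with np.errstate(divide="ignore"):
            steps = np.where(blocking, -p / np.where(d == 0, 1.0, d), np.inf)
        t = min(1.0, float(steps.min()))
        p = p + t * d
        hit = blocking & (steps <= t + 1e-15)
        p[hit] = 0.0
        free[hit] = False
        if not free.any():  # numerical corner: restart from the best vertex
            free[np.argmin(np.diag(Q) - 2 * c)] = True
    p = np.clip(p, 0.0, None)
    s = p.sum()
    if s <= 0:
        raise RuntimeError("active-set solver failed to produce a feasible point")
    p = p / s
    resid = float(np.linalg.norm(A @ p - x))
    return p, resid


def solve_simplex_penalty(
    Z: ReferenceProfile | np.ndarray, x: np.ndarray, weight: float = 1e6
) -> tuple[np.ndarray, float]:
    """Cross-check solver: NNLS on Z with a heavily weighted sum-to-one
    row appended, followed by renormalization onto the simplex."""
    A = Z.values if isinstance(Z, ReferenceProfile) else np.asarray(Z, dtype=float)
    x = np.asarray(x, dtype=float)
    scale = max(1.0, float(np.abs(A).max()))
    Aa = np.vstack([A, np.full((1, A.shape[1]), weight * scale)])
    xa = np.concatenate([x, [weight * scale]])
    p, _ = scipy.optimize.nnls(Aa, xa)
    s = p.sum()
    if s == 0:
        p = np.full(A.shape[1], 1.0 / A.shape[1])
    else:
        p = p / s
    return p, float(np.linalg.norm(A @ p - x))


def decompose(
    Z: ReferenceProfile, X_transformed: CountsMatrix, solver: str = "active_set"
) -> ProportionMatrix:
    """Estimate proportions for every sample column independently."""
    if list(Z.gene_ids) != list(X_transformed.gene_ids):
        raise ValueError("gene sets/order differ between reference and bulk matrix")
    solve = {"active_set": solve_simplex_lsq, "penalty": solve_simplex_penalty}[solver]
    cols, resids = [], []
    for i in range(X_transformed.n_samples):
        p, r = solve(Z, X_transformed.values[:, i])
        assert p.min() >= 0 and abs(p.sum() - 1.0) <= 1e-8, "solver left the simplex"
        cols.append(p)
        resids.append(r)
    values = np.column_stack(cols) if cols else np.zeros((Z.n_cell_types, 0))
    return ProportionMatrix(
        values, list(Z.cell_types), list(X_transformed.sample_ids), np.asarray(resids)
    )


@dataclass
class ResidualSummary:
    residuals: np.ndarray
    sample_ids: list[str]
    bimodal: bool
    bic_one: float
    bic_two: float


def residual_diagnostics(props: ProportionMatrix) -> ResidualSummary:
    """Flag a possibly multimodal residual-norm distribution.

    Fits one- and two-component 1-D Gaussian mixtures to the per-sample
    residual norms and flags bimodality when the two-component model wins
    on BIC — a signature of a cell population present in some bulk
    samples but absent from the reference.
    """
    from sklearn.mixture import GaussianMixture

    r = props.residual_norm
    if r.size < 2:
        raise ValueError("residual diagnostics require at least 2 samples")
    spread = r.std()
    if spread == 0 or r.size < 4:
        return ResidualSummary(r, list(props.sample_ids), False, np.nan, np.nan)
    X = r.reshape(-1, 1)
    g1 = GaussianMixture(1, random_state=0).fit(X)
    g2 = GaussianMixture(2, n_init=5, random_state=0).fit(X)
    bic1, bic2 = g1.bic(X), g2.bic(X)
    # require separated means (beyond pooled within-component SD) so tiny
    # jitter around a single value is not called bimodal
    means = np.sort(g2.means_.ravel())
    sds = np.sqrt(g2.covariances_.ravel())
    separated = (means[1] - means[0]) > max(sds.mean(), 1e-12)
    return ResidualSummary(
        r, list(props.sample_ids), bool(bic2 < bic1 and separated), float(bic1), float(bic2)
    )
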