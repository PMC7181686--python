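"""Independent oracles used by the test suite.

These deliberately avoid the code paths they are meant to check: the
simplex minimum is found by exhaustive grid enumeration, regressions by
explicit normal equations, and principal components by a direct SVD.
"""

from functools import lru_cache

import numpy as np


@lru_cache(maxsize=8)
def simplex_grid(k: int, steps: int = 100) -> np.ndarray:
    """All compositions of ``steps`` into ``k`` parts, as an (N, k)
    integer array. steps=100 corresponds to a 0.01 proportion grid."""
    if k == 1:
        return np.array([[steps]], dtype=np.int64)
    out = np.arange(steps + 1, dtype=np.int64)[:, None]
    for _ in range(k - 2):
        rem = steps - out.sum(axis=1)
        out = np.repeat(out, rem + 1, axis=0)
        nxt = np.concatenate([np.arange(r + 1) for r in rem])
        out = np.column_stack([out, nxt])
    last = steps - out.sum(axis=1)
    return np.column_stack([out, last])


@lru_cache(maxsize=8)
def _grid_f32(k: int, steps: int = 100) -> np.ndarray:
    return simplex_grid(k, steps).astype(np.float32) / steps


def grid_min_objective(A: np.ndarray, x: np.ndarray, steps: int = 100) -> float:
    """Minimum of ||A p - x||_2^2 over the 0.01-step simplex grid.

    A float32 scan ranks candidates; the best few are re-evaluated in
    float64 from the exact integer compositions (float32-rounded points
    drift off the simplex by ~1e-7, enough to spuriously undercut the
    constrained optimum), so the returned value is the exact objective of
    a true grid point.
    """
    k = A.shape[1]
    G32 = _grid_f32(k, steps)
    Q = (A.T @ A).astype(np.float32)
    c = (A.T @ x).astype(np.float32)
    obj32 = ((G32 @ Q) * G32).sum(axis=1) - 2.0 * (G32 @ c)
    top = np.argsort(obj32)[:256]
    P = simplex_grid(k, steps)[top].astype(np.float64) / steps
    vals = ((A @ P.T) - x[:, None]) ** 2
    return float(vals.sum(axis=0).min())


def ols_two_column(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope/intercept via the explicit normal equations on the
    [1, x] design."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.inv(X.T @ X) @ X.T @ y
    return float(beta[1]), float(beta[0])


def svd_pc1_scores(M: np.ndarray) -> np.ndarray:
    """First principal-component scores (rows = observations) of an
    already column-centered matrix via direct SVD."""
    Mc = M - M.mean(axis=0)
    U, s, _ = np.linalg.svd(Mc, full_matrices=False)
    return U[:, 0] * s[0]
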