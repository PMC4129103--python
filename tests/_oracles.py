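"""Independent reference implementations used only to check the package.

Each oracle deliberately takes a different computational route from the
production code: literal loop transcriptions, numerical optimization, and
generalized eigenproblems instead of whitening.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg, optimize


def standardize_loop(raw: np.ndarray) -> np.ndarray:
    """Per-column (x - mean) / sd with the n-1 denominator, written long-hand."""
    out = np.empty_like(raw, dtype=float)
    n = raw.shape[0]
    for j in range(raw.shape[1]):
        col = raw[:, j]
        mean = sum(col) / n
        var = sum((c - mean) ** 2 for c in col) / (n - 1)
        out[:, j] = (col - mean) / np.sqrt(var)
    return out


def shrinkage_loop(V: np.ndarray) -> tuple[np.ndarray, float]:
    """Triple-loop transcription of the optimal-intensity shrinkage estimator.

    ``V`` must already be standardized.  Returns (shrunken matrix, clipped
    intensity).  The intensity is Var-of-correlation over squared correlation,
    summed over off-diagonal pairs; off-diagonals are contracted by
    ``min(1, max(0, 1 - lambda))``.
    """
    n, m = V.shape
    r = np.eye(m)
    var_r = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            w = np.array([V[k, i] * V[k, j] for k in range(n)])
            r[i, j] = w.sum() / (n - 1)
            wbar = w.mean()
            var_r[i, j] = n / (n - 1) ** 3 * sum((wk - wbar) ** 2 for wk in w)
    num = sum(var_r[i, j] for i in range(m) for j in range(m) if i != j)
    den = sum(r[i, j] ** 2 for i in range(m) for j in range(m) if i != j)
    lam = 1.0 if den == 0 else num / den
    lam = min(1.0, max(0.0, lam))
    out = np.eye(m)
    for i in range(m):
        for j in range(m):
            if i != j:
                out[i, j] = r[i, j] * min(1.0, max(0.0, 1.0 - lam))
    return out, lam


def ratio_statistic(A: np.ndarray, B: np.ndarray, Cxy: np.ndarray,
                    Sx: np.ndarray, Sy: np.ndarray) -> float:
    """(Aᵀ Cxy B)² / (Aᵀ Sx A · Bᵀ Sy B)."""
    num = float(A @ Cxy @ B) ** 2
    den = float(A @ Sx @ A) * float(B @ Sy @ B)
    return num / den


def bruteforce_max_ratio(Cxy: np.ndarray, Sx: np.ndarray, Sy: np.ndarray,
                         n_restarts: int = 40, seed: int = 0) -> float:
    """Maximize the shrinkage-correlation ratio by multi-start optimization.

    Independent of the whitening/eigenvalue route: BFGS on the concatenated
    (A, B) vector from many random starting points.
    """
    p, q = Cxy.shape
    rng = np.random.default_rng(seed)

    def neg(v):
        A, B = v[:p], v[p:]
        if np.linalg.norm(A) < 1e-8 or np.linalg.norm(B) < 1e-8:
            return 0.0
        return -ratio_statistic(A, B, Cxy, Sx, Sy)

    best = 0.0
    for _ in range(n_restarts):
        v0 = rng.standard_normal(p + q)
        res = optimize.minimize(neg, v0, method="BFGS",
                                options={"gtol": 1e-12, "maxiter": 2000})
        best = max(best, -res.fun)
    return best


def naive_statistic(Cxy: np.ndarray, Sx: np.ndarray, Sy: np.ndarray) -> float:
    """Largest generalized eigenvalue of Cxyᵀ Sx⁻¹ Cxy with metric Sy.

    Closed-form route through explicit matrix inversion, used to replay
    permutations without whitening.
    """
    M = Cxy.T @ np.linalg.solve(Sx, Cxy)
    return float(linalg.eigh(M, Sy, eigvals_only=True)[-1])


def natural_spline_truncated_power(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Textbook natural cubic spline basis via truncated powers.

    With knots ``xi_1 < ... < xi_K`` the basis is ``{1, x, N_3, ..., N_K}``
    where ``N_{k+2} = d_k - d_{K-1}`` and
    ``d_k(x) = ((x - xi_k)_+^3 - (x - xi_K)_+^3) / (xi_K - xi_k)``.
    Spans the natural cubic spline space of dimension K; linear beyond the
    boundary knots by construction.
    """
    xi = np.asarray(knots, dtype=float)
    K = xi.size

    def d(k):
        return (np.clip(x - xi[k], 0, None) ** 3
                - np.clip(x - xi[K - 1], 0, None) ** 3) / (xi[K - 1] - xi[k])

    cols = [np.ones_like(x), x] + [d(k) - d(K - 2) for k in range(K - 2)]
    return np.column_stack(cols)


def column_space(M: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Orthonormal basis of the column space (SVD with relative threshold)."""
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    return U[:, s > tol * s[0]]


def subspace_distance(M1: np.ndarray, M2: np.ndarray) -> float:
    """Spectral-norm distance between the column-space projectors."""
    U1, U2 = column_space(M1), column_space(M2)
    P1, P2 = U1 @ U1.T, U2 @ U2.T
    return float(np.linalg.norm(P1 - P2, 2))


def bh_stepup_loop(p: np.ndarray) -> np.ndarray:
    """Hand-rolled Benjamini-Hochberg: adj_i = min_{j >= rank(i)} p_(j) m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 1.0
    for idx in range(m - 1, -1, -1):
        running = min(running, p[order[idx]] * m / (idx + 1))
        adj_sorted[idx] = running
    out = np.empty(m)
    out[order] = adj_sorted
    return out
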