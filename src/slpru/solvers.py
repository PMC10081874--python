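"""Window solvers: sparse low-rank Poisson regression and least-squares baselines.

The shared engine is an ADMM over the splitting

    Z = M A   (data-fidelity prox: Poisson or squared loss)
    U = A     (weighted nuclear-norm prox)
    V = A     (weighted l2,1 prox)
    W = A     (non-negativity projection)

with scaled dual variables and penalty ``mu``. The A-update is the ridge
solve ``(M^T M + 3 I)^{-1} [M^T (Z - Gz) + (U - Gu) + (V - Gv) + (W - Gw)]``,
so every subproblem is closed-form. All four methods run through this one
engine; the baselines use the squared loss and uniform weights.

Everything is batched over a leading axis so that a whole image's windows
(or a simulation's replicates) are solved simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .core import (
    AbundanceMatrix,
    DimensionError,
    EndmemberMatrix,
    SolverConfig,
    SolverFailureError,
    Window,
    _as_array,
    poisson_nll,
    weighted_nuclear_norm,
)
from .proximal import (
    ProxWeights,
    prox_poisson,
    prox_weighted_l21,
    project_nonneg,
)

__all__ = [
    "SolveResult",
    "solve_window_slpru",
    "update_weights",
    "nls_pixel",
    "nls_batch",
    "snls_window",
    "slnls_window",
    "solve_windows_batch",
]


@dataclass
class SolveResult:
    """Outcome of one window solve."""

    A: AbundanceMatrix
    objective: float
    iterations: int
    primal_residual: float
    dual_residual: float
    converged: bool


# ---------------------------------------------------------------------------
# Weight update (inverse-magnitude reweighting)
# ---------------------------------------------------------------------------


def update_weights(A, eps_scale: float = 1e-3) -> ProxWeights:
    """Inverse-magnitude weights from a current abundance estimate.

    ``wp_i = 1 / (sigma_i(A) + eps_p)`` with ``eps_p = eps_scale * max(sigma_1, 1)``
    and ``wq_r = 1 / (||a_r||_2 + eps_q)`` with
    ``eps_q = max(eps_scale * max_r ||a_r||_2, eps_scale)``. Larger weights land
    on smaller singular values / rows, so ``wp`` pairs non-decreasingly with
    the descending spectrum, as the weighted SVT prox requires.
    """
    A = _as_array(A)
    s = np.linalg.svd(np.atleast_2d(A), compute_uv=False)
    eps_p = eps_scale * max(s[0] if s.size else 0.0, 1.0)
    wp = 1.0 / (s + eps_p)
    norms = np.linalg.norm(np.atleast_2d(A), axis=1)
    eps_q = max(eps_scale * (norms.max() if norms.size else 0.0), eps_scale)
    wq = 1.0 / (norms + eps_q)
    return ProxWeights(wp=wp, wq=wq)


def _update_weights_batch(A: np.ndarray, eps_scale: float):
    """Batched version of :func:`update_weights`; A is (B, R, N)."""
    s = np.linalg.svd(A, compute_uv=False)  # (B, k)
    eps_p = eps_scale * np.maximum(s[:, 0], 1.0)
    wp = 1.0 / (s + eps_p[:, None])
    norms = np.linalg.norm(A, axis=2)  # (B, R)
    eps_q = np.maximum(eps_scale * norms.max(axis=1), eps_scale)
    wq = 1.0 / (norms + eps_q[:, None])
    return wp, wq


# ---------------------------------------------------------------------------
# Non-negative least squares
# ---------------------------------------------------------------------------


def nls_pixel(y, M) -> np.ndarray:
    """Exact pixelwise non-negative least squares, ``argmin_{a>=0} ||y - Ma||^2``."""
    M = M.M if isinstance(M, EndmemberMatrix) else np.asarray(M, float)
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != M.shape[0]:
        raise DimensionError(f"y has {y.shape[0]} channels, M has {M.shape[0]}")
    a, _ = scipy.optimize.nnls(M, y)
    return a


def nls_batch(Y: np.ndarray, M) -> np.ndarray:
    """Columnwise NLS over a (B, C, N) batch; returns (B, R, N)."""
    M = M.M if isinstance(M, EndmemberMatrix) else np.asarray(M, float)
    B, C, N = Y.shape
    R = M.shape[1]
    out = np.empty((B, R, N))
    flat = Y.transpose(0, 2, 1).reshape(B * N, C)
    sol = np.empty((B * N, R))
    for i in range(B * N):
        sol[i], _ = scipy.optimize.nnls(M, flat[i])
    out[:] = sol.reshape(B, N, R).transpose(0, 2, 1)
    return out


# ---------------------------------------------------------------------------
# Batched ADMM engine
# ---------------------------------------------------------------------------


def _svt_weighted(X: np.ndarray, wp: np.ndarray, tau: float) -> np.ndarray:
    """Weighted singular-value thresholding via the smaller Gram matrix.

    Fast path for the inner loop; agrees with
    :func:`slpru.proximal.prox_weighted_nuclear` (asserted in the tests) but
    avoids a full batched SVD. X is (B, R, N).
    """
    B, R, N = X.shape
    if N <= R:
        G = np.matmul(X.transpose(0, 2, 1), X)  # (B, N, N)
        w, V = np.linalg.eigh(G)
        s = np.sqrt(np.maximum(w[:, ::-1], 0.0))  # descending
        V = V[:, :, ::-1]
        s_new = np.maximum(s - tau * wp[..., : s.shape[1]], 0.0)
        ratio = np.where(s > 1e-12, s_new / np.maximum(s, 1e-12), 0.0)
        return np.matmul(np.matmul(X, V) * ratio[:, None, :], V.transpose(0, 2, 1))
    G = np.matmul(X, X.transpose(0, 2, 1))  # (B, R, R)
    w, U = np.linalg.eigh(G)
    s = np.sqrt(np.maximum(w[:, ::-1], 0.0))
    U = U[:, :, ::-1]
    s_new = np.maximum(s - tau * wp[..., : s.shape[1]], 0.0)
    ratio = np.where(s > 1e-12, s_new / np.maximum(s, 1e-12), 0.0)
    return np.matmul(U * ratio[:, None, :], np.matmul(U.transpose(0, 2, 1), X))


def _objective_batch(Y, M, A, lam1, lam2, wp, wq, loss, log_guard=1e-12):
    """Penalized objective per batch element, at the supplied weights."""
    rate = np.matmul(M, A)
    if loss == "poisson":
        logs = np.log(np.maximum(rate, log_guard))
        fid = rate.sum(axis=(1, 2)) - np.sum(
            Y * logs, axis=(1, 2), where=Y > 0
        )
    else:
        fid = 0.5 * np.sum((rate - Y) ** 2, axis=(1, 2))
    obj = fid
    if lam1 > 0:
        s = np.linalg.svd(A, compute_uv=False)
        obj = obj + lam1 * np.sum(wp[:, : s.shape[1]] * s, axis=1)
    if lam2 > 0:
        norms = np.linalg.norm(A, axis=2)
        obj = obj + lam2 * np.sum(wq * norms, axis=1)
    return obj


def _admm_batch(Y, M, lam1, lam2, cfg: SolverConfig, loss, wp, wq, state=None):
    """Run ADMM to tolerance on a (B, C, N) batch with fixed weights.

    Returns ``(state, iterations, r_norm, s_norm, converged)`` where state
    carries (A, Z, U, V, W, Gz, Gu, Gv, Gw) for warm-starting.
    """
    B, C, N = Y.shape
    R = M.shape[1]
    mu = cfg.mu
    Ginv = np.linalg.inv(M.T @ M + 3.0 * np.eye(R))
    scale = np.sqrt(R * N)

    if state is None:
        A = np.zeros((B, R, N))
        Z = np.matmul(M, A)
        U = A.copy()
        V = A.copy()
        W = A.copy()
        Gz = np.zeros_like(Z)
        Gu = np.zeros_like(A)
        Gv = np.zeros_like(A)
        Gw = np.zeros_like(A)
    else:
        A, Z, U, V, W, Gz, Gu, Gv, Gw = state

    r_norm = np.inf
    s_norm = np.inf
    it = 0
    for it in range(1, cfg.max_iter + 1):
        rhs = (
            np.matmul(M.T, Z - Gz) + (U - Gu) + (V - Gv) + (W - Gw)
        )
        A = np.matmul(Ginv, rhs)

        MA = np.matmul(M, A)
        Z_old, U_old, V_old, W_old = Z, U, V, W
        if loss == "poisson":
            Z = prox_poisson(MA + Gz, Y, mu)
        else:
            Z = (Y + mu * (MA + Gz)) / (1.0 + mu)
        if lam1 > 0:
            U = _svt_weighted(A + Gu, wp, lam1 / mu)
        else:
            U = A + Gu
        if lam2 > 0:
            V = prox_weighted_l21(A + Gv, wq, lam2 / mu)
        else:
            V = A + Gv
        W = project_nonneg(A + Gw)

        Gz = Gz + MA - Z
        Gu = Gu + A - U
        Gv = Gv + A - V
        Gw = Gw + A - W

        r2 = (
            np.sum((MA - Z) ** 2, axis=(1, 2))
            + np.sum((A - U) ** 2, axis=(1, 2))
            + np.sum((A - V) ** 2, axis=(1, 2))
            + np.sum((A - W) ** 2, axis=(1, 2))
        )
        dual = (
            np.matmul(M.T, Z - Z_old) + (U - U_old) + (V - V_old) + (W - W_old)
        )
        s2 = mu**2 * np.sum(dual**2, axis=(1, 2))
        r_norm = float(np.sqrt(r2.max()))
        s_norm = float(np.sqrt(s2.max()))
        if max(r_norm, s_norm) / scale < cfg.tol:
            break

    if not np.all(np.isfinite(A)):
        raise SolverFailureError("solver diverged (non-finite iterate)", iterations=it)

    state = (A, Z, U, V, W, Gz, Gu, Gv, Gw)
    converged = max(r_norm, s_norm) / scale < cfg.tol
    return state, it, r_norm / scale, s_norm / scale, converged


def solve_windows_batch(
    Y: np.ndarray,
    M,
    method: str,
    cfg: SolverConfig,
    A0: np.ndarray | None = None,
):
    """Solve a batch of windows with the chosen method.

    Parameters
    ----------
    Y : ndarray, shape (B, C, N)
        Batch of window count matrices.
    M : EndmemberMatrix or ndarray (C, R)
    method : {"slpru", "nls", "snls", "slnls"}
    cfg : SolverConfig
        ``lambda1``/``lambda2`` are read from here. For ``snls`` only
        ``lambda2`` applies; ``nls`` ignores both.
    A0 : ndarray (B, R, N), optional
        Warm start; defaults to the pixelwise NLS solution.

    Returns
    -------
    A : ndarray, shape (B, R, N)
        Non-negative abundance estimates.
    info : dict
        iterations, primal/dual residuals (scale-free), converged flag and
        the final weights.
    """
    Mmat = M.M if isinstance(M, EndmemberMatrix) else np.asarray(M, float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 3:
        raise DimensionError("expected a (B, C, N) batch")
    if Y.shape[1] != Mmat.shape[0]:
        raise DimensionError(
            f"windows have {Y.shape[1]} channels but M has {Mmat.shape[0]} rows"
        )
    B, C, N = Y.shape
    R = Mmat.shape[1]

    if A0 is None:
        A0 = nls_batch(Y, Mmat)

    if method == "nls":
        return A0, {
            "iterations": 0,
            "primal_residual": 0.0,
            "dual_residual": 0.0,
            "converged": True,
            "wp": np.ones((B, min(R, N))),
            "wq": np.ones((B, R)),
        }

    if method == "slpru":
        loss, weighted = "poisson", True
        lam1, lam2 = cfg.lambda1, cfg.lambda2
    elif method == "slnls":
        loss, weighted = "ls", False
        lam1, lam2 = cfg.lambda1, cfg.lambda2
    elif method == "snls":
        loss, weighted = "ls", False
        lam1, lam2 = 0.0, cfg.lambda2
    else:
        raise ValueError(f"unknown method {method!r}")

    wp = np.ones((B, min(R, N)))
    wq = np.ones((B, R))
    state = (
        A0.copy(),
        np.matmul(Mmat, A0),
        A0.copy(),
        A0.copy(),
        A0.copy(),
        np.zeros((B, C, N)),
        np.zeros((B, R, N)),
        np.zeros((B, R, N)),
        np.zeros((B, R, N)),
    )

    n_passes = cfg.outer_reweights if (weighted and (lam1 > 0 or lam2 > 0)) else 1
    total_it = 0
    for p in range(n_passes):
        if p > 0:
            A_prev = project_nonneg(state[0])
            wp, wq = _update_weights_batch(A_prev, cfg.eps_scale)
        state, it, r, s, conv = _admm_batch(
            Y, Mmat, lam1, lam2, cfg, loss, wp, wq, state=state
        )
        total_it += it

    A = project_nonneg(state[0])
    return A, {
        "iterations": total_it,
        "primal_residual": r,
        "dual_residual": s,
        "converged": conv,
        "wp": wp,
        "wq": wq,
    }


def _window_matrix(Y) -> np.ndarray:
    if isinstance(Y, Window):
        return Y.Y
    return _as_array(Y)


def _single_result(Y, M, A, info, lam1, lam2, loss, cfg) -> SolveResult:
    Mmat = M.M if isinstance(M, EndmemberMatrix) else np.asarray(M, float)
    wp, wq = info["wp"][0], info["wq"][0]
    if loss == "poisson":
        fid = poisson_nll(Mmat, A, Y, log_guard=cfg.log_guard)
    else:
        fid = 0.5 * float(np.sum((Mmat @ A - Y) ** 2))
    obj = fid
    if lam1 > 0:
        obj += lam1 * weighted_nuclear_norm(A, wp)
    if lam2 > 0:
        obj += lam2 * float(np.sum(wq * np.linalg.norm(A, axis=1)))
    return SolveResult(
        A=AbundanceMatrix(A),
        objective=obj,
        iterations=info["iterations"],
        primal_residual=info["primal_residual"],
        dual_residual=info["dual_residual"],
        converged=info["converged"],
    )


def solve_window_slpru(Y, M, cfg: SolverConfig) -> SolveResult:
    """Sparse low-rank Poisson regression on one 3x3 window.

    Runs ``cfg.outer_reweights`` solve passes: the first with uniform
    weights, later passes with inverse-magnitude weights recomputed from
    the previous estimate (see :func:`update_weights`).
    """
    Ymat = _window_matrix(Y)
    A, info = solve_windows_batch(Ymat[None], M, "slpru", cfg)
    return _single_result(Ymat, M, A[0], info, cfg.lambda1, cfg.lambda2, "poisson", cfg)


def snls_window(Y, M, lam: float, cfg: SolverConfig | None = None) -> AbundanceMatrix:
    """Sparse NLS: ``min_{A>=0} 0.5||Y - MA||_F^2 + lam ||A||_{2,1}`` on a window."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    cfg = (cfg or SolverConfig()).replace(lambda1=0.0, lambda2=lam)
    Ymat = _window_matrix(Y)
    A, _ = solve_windows_batch(Ymat[None], M, "snls", cfg)
    return AbundanceMatrix(A[0])


def slnls_window(
    Y, M, lam1: float, lam2: float, cfg: SolverConfig | None = None
) -> AbundanceMatrix:
    """Sparse and low-rank NLS:
    ``min_{A>=0} 0.5||Y - MA||_F^2 + lam1 ||A||_* + lam2 ||A||_{2,1}``."""
    if lam1 < 0 or lam2 < 0:
        raise ValueError("penalties must be >= 0")
    cfg = (cfg or SolverConfig()).replace(lambda1=lam1, lambda2=lam2)
    Ymat = _window_matrix(Y)
    A, _ = solve_windows_batch(Ymat[None], M, "slnls", cfg)
    return AbundanceMatrix(A[0])
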