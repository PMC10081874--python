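"""Independent oracle implementations used only by the tests.

Everything here is written from first principles (scalar loops, numeric
1-D minimization, a primal-dual splitting algorithm) and deliberately does
not call into the package's own solver code paths, so that agreement
between package and oracle is a genuine dual-route check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar


# ---------------------------------------------------------------------------
# Scalar-loop evaluations
# ---------------------------------------------------------------------------


def poisson_nll_loop(M, A, Y, guard=1e-12):
    M, A, Y = np.asarray(M, float), np.asarray(A, float), np.asarray(Y, float)
    C, R = M.shape
    N = A.shape[1]
    total = 0.0
    for c in range(C):
        for n in range(N):
            rate = 0.0
            for r in range(R):
                rate += M[c, r] * A[r, n]
            total += rate
            if Y[c, n] > 0:
                total -= Y[c, n] * np.log(max(rate, guard))
    return total


def l21_loop(A):
    A = np.atleast_2d(np.asarray(A, float))
    total = 0.0
    for r in range(A.shape[0]):
        sq = 0.0
        for n in range(A.shape[1]):
            sq += A[r, n] ** 2
        total += np.sqrt(sq)
    return total


def rmse_loop(A, Ahat):
    A, Ahat = np.asarray(A, float), np.asarray(Ahat, float)
    sq = 0.0
    for idx in np.ndindex(A.shape):
        sq += (A[idx] - Ahat[idx]) ** 2
    return np.sqrt(sq / A.size)


def pad_then_slice_window(cube, row, col):
    """Replicate-pad a C x H x W cube explicitly and cut the 3x3 patch."""
    cube = np.asarray(cube, float)
    C, H, W = cube.shape
    out = np.empty((C, 9))
    k = 0
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            r = min(max(row + dr, 0), H - 1)
            c = min(max(col + dc, 0), W - 1)
            out[:, k] = cube[:, r, c]
            k += 1
    return out


# ---------------------------------------------------------------------------
# 1-D numeric prox minimizers
# ---------------------------------------------------------------------------


def prox_poisson_scalar_numeric(v, y, rho):
    """Minimize z - y log z + rho/2 (z - v)^2 by bounded scalar search."""

    def f(z):
        if z <= 0:
            return np.inf if y > 0 else 0.5 * rho * (z - v) ** 2
        pen = z - (y * np.log(z) if y > 0 else 0.0)
        return pen + 0.5 * rho * (z - v) ** 2

    hi = max(abs(v) + y / rho + 10.0 / rho, 10.0)
    res = minimize_scalar(f, bounds=(0.0 if y == 0 else 1e-12, hi),
                          method="bounded", options={"xatol": 1e-12})
    return res.x if f(res.x) < f(0.0) else 0.0


def prox_l21_row_numeric(v, thr):
    """Minimize 0.5||z - v||^2 + thr ||z||_2 over the ray z = t v/||v||."""
    v = np.asarray(v, float)
    nv = np.linalg.norm(v)
    if nv == 0:
        return np.zeros_like(v)

    def f(t):
        return 0.5 * (t - nv) ** 2 + thr * t

    res = minimize_scalar(f, bounds=(0.0, nv + thr + 1.0), method="bounded",
                          options={"xatol": 1e-12})
    t = res.x if f(res.x) < f(0.0) else 0.0
    return t * v / nv


def svt_numeric(V, weights, tau):
    """Weighted SVT rebuilt from an independent SVD + scalar minimizations."""
    V = np.asarray(V, float)
    U, s, Wt = np.linalg.svd(V, full_matrices=False)
    s_new = np.empty_like(s)
    for i, (sig, w) in enumerate(zip(s, weights)):

        def f(t, sig=sig, w=w):
            return tau * w * t + 0.5 * (t - sig) ** 2

        res = minimize_scalar(f, bounds=(0.0, sig + 1.0), method="bounded",
                              options={"xatol": 1e-12})
        s_new[i] = res.x if f(res.x) < f(0.0) else 0.0
    return (U * s_new) @ Wt


# ---------------------------------------------------------------------------
# Histogram threshold oracles
# ---------------------------------------------------------------------------


def otsu_brute_force(values, nbins=256):
    v = np.asarray(values, float).ravel()
    hist, edges = np.histogram(v, bins=nbins, range=(v.min(), v.max()))
    hist = hist.astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    variances = np.full(nbins, -np.inf)
    for k in range(1, nbins):
        w0, w1 = hist[:k].sum(), hist[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:k] * centers[:k]).sum() / w0
        mu1 = (hist[k:] * centers[k:]).sum() / w1
        variances[k] = w0 * w1 * (mu0 - mu1) ** 2
    best = variances.max()
    ties = [edges[k] for k in range(1, nbins)
            if variances[k] >= best - 1e-9 * abs(best)]
    return float(np.mean(ties))


def triangle_geometry(values, nbins=256):
    v = np.asarray(values, float).ravel()
    hist, edges = np.histogram(v, bins=nbins, range=(v.min(), v.max()))
    hist = hist.astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = int(np.argmax(hist))
    nz = np.flatnonzero(hist)
    lo, hi = int(nz[0]), int(nz[-1])
    end = hi if (hi - peak) >= (peak - lo) else lo
    a = np.array([peak, hist[peak]])
    b = np.array([end, hist[end]])
    chord = b - a
    norm = np.linalg.norm(chord)
    idx = list(range(min(peak, end), max(peak, end) + 1))
    dists = [
        abs(chord[0] * (hist[i] - a[1]) - chord[1] * (i - a[0])) / norm for i in idx
    ]
    best_d = max(dists)
    best = [centers[i] for i, d in zip(idx, dists)
            if d >= best_d - 1e-9 * max(best_d, 1.0)]
    return float(np.mean(best))


def welch_formula(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    mx, my = sum(x) / nx, sum(y) / ny
    vx = sum((xi - mx) ** 2 for xi in x) / (nx - 1)
    vy = sum((yi - my) ** 2 for yi in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


# ---------------------------------------------------------------------------
# Primal-dual (Chambolle-Pock) oracle for the convex window objectives
# ---------------------------------------------------------------------------


def _prox_h1(v, Y, sigma, loss):
    """argmin_z H1(z) + sigma/2 ||z - v||^2 for the two fidelity losses."""
    if loss == "poisson":
        shifted = v - 1.0 / sigma
        z = 0.5 * (shifted + np.sqrt(shifted**2 + 4.0 * Y / sigma))
        return np.where(Y > 0, z, np.maximum(shifted, 0.0))
    return (Y + sigma * v) / (1.0 + sigma)


def _prox_nuclear(v, thresholds):
    U, s, Wt = np.linalg.svd(v, full_matrices=False)
    return (U * np.maximum(s - thresholds[: s.size], 0.0)) @ Wt


def _prox_rows(v, thresholds):
    norms = np.linalg.norm(v, axis=1)
    scale = np.maximum(0.0, 1.0 - thresholds / np.maximum(norms, 1e-300))
    return v * scale[:, None]


def primal_dual_window(Y, M, lam1, lam2, wp, wq, loss="poisson", n_iter=50_000):
    """Chambolle-Pock solver for

        min_{A >= 0}  H1(M A) + lam1 ||A||_{wp,*} + lam2 sum_r wq_r ||a_r||_2

    with H1 either the Poisson fidelity ``sum[z - y log z]`` or the squared
    loss ``0.5 ||z - y||_F^2``. A different algorithm family from the
    package's ADMM, used as the convex-optimality oracle.
    """
    Y = np.asarray(Y, float)
    M = np.asarray(M, float)
    wp = np.asarray(wp, float)
    wq = np.asarray(wq, float)
    C, N = Y.shape
    R = M.shape[1]
    L = np.sqrt(np.linalg.norm(M, 2) ** 2 + 2.0)
    tau = sigma = 0.99 / L
    A = np.zeros((R, N))
    Abar = A.copy()
    p1 = np.zeros((C, N))
    p2 = np.zeros((R, N))
    p3 = np.zeros((R, N))
    for _ in range(n_iter):
        u1 = p1 + sigma * (M @ Abar)
        p1 = u1 - sigma * _prox_h1(u1 / sigma, Y, sigma, loss)
        u2 = p2 + sigma * Abar
        if lam1 > 0:
            p2 = u2 - sigma * _prox_nuclear(u2 / sigma, (lam1 / sigma) * wp)
        else:
            p2 = np.zeros_like(p2)
        u3 = p3 + sigma * Abar
        if lam2 > 0:
            p3 = u3 - sigma * _prox_rows(u3 / sigma, (lam2 / sigma) * wq)
        else:
            p3 = np.zeros_like(p3)
        A_new = np.maximum(A - tau * (M.T @ p1 + p2 + p3), 0.0)
        Abar = 2.0 * A_new - A
        A = A_new
    return A


def window_objective(Y, M, A, lam1, lam2, wp, wq, loss="poisson", guard=1e-12):
    """The convex window objective, evaluated directly."""
    Y = np.asarray(Y, float)
    M = np.asarray(M, float)
    A = np.asarray(A, float)
    rate = M @ A
    if loss == "poisson":
        fid = rate.sum() - np.sum(
            Y * np.log(np.maximum(rate, guard)), where=Y > 0
        )
    else:
        fid = 0.5 * np.sum((rate - Y) ** 2)
    s = np.linalg.svd(A, compute_uv=False)
    pen1 = lam1 * np.sum(np.asarray(wp)[: s.size] * s)
    pen2 = lam2 * np.sum(np.asarray(wq) * np.linalg.norm(A, axis=1))
    return fid + pen1 + pen2
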