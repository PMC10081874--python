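"""Closed-form proximal operators used by the splitting solvers.

All operators accept either a single matrix or a batch stacked on a leading
axis; proximal parameters broadcast accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DomainError

__all__ = [
    "ProxWeights",
    "prox_poisson",
    "prox_weighted_nuclear",
    "prox_weighted_l21",
    "project_nonneg",
]


@dataclass
class ProxWeights:
    """Weights for the weighted nuclear and weighted l2,1 penalties.

    ``wp`` pairs with singular values in descending order and must be
    non-decreasing for the weighted singular-value thresholding step to be
    an exact prox; ``wq`` holds one row weight per endmember.
    """

    wp: np.ndarray
    wq: np.ndarray

    def __post_init__(self):
        self.wp = np.asarray(self.wp, dtype=float)
        self.wq = np.asarray(self.wq, dtype=float)
        if np.any(self.wp < 0) or np.any(self.wq < 0):
            raise DomainError("prox weights must be non-negative")
        if self.wp.ndim == 1 and np.any(np.diff(self.wp) < -1e-12):
            raise DomainError(
                "wp must be non-decreasing when paired with descending "
                "singular values"
            )


def prox_poisson(V, Y, rho: float):
    """Elementwise prox of ``z -> z - y log z`` with parameter ``rho``.

    Solves ``argmin_z  z - y log z + (rho/2)(z - v)^2`` elementwise:
    ``z = ((v - 1/rho) + sqrt((v - 1/rho)^2 + 4 y / rho)) / 2``.
    Entries with ``y > 0`` are strictly positive; entries with ``y = 0``
    reduce to ``max(v - 1/rho, 0)``.
    """
    if rho <= 0:
        raise DomainError("rho must be > 0")
    V = np.asarray(V, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if np.any(Y < 0):
        raise DomainError("counts must be non-negative")
    shifted = V - 1.0 / rho
    z = 0.5 * (shifted + np.sqrt(shifted**2 + 4.0 * Y / rho))
    return np.where(Y > 0, z, np.maximum(shifted, 0.0))


def prox_weighted_nuclear(V, wp, tau: float):
    """Weighted singular-value thresholding.

    With ``V = U diag(sigma) W^T``, returns
    ``U diag(max(sigma_i - tau * wp_i, 0)) W^T``. Exact prox of
    ``tau * ||.||_{wp,*}`` when ``wp`` is non-decreasing against the
    descending singular values.
    """
    if tau < 0:
        raise DomainError("tau must be >= 0")
    V = np.asarray(V, dtype=float)
    wp = np.asarray(wp, dtype=float)
    if np.any(wp < 0):
        raise DomainError("wp must be non-negative")
    if np.any(np.diff(wp, axis=-1) < -1e-10):
        raise DomainError(
            "wp must be non-decreasing against descending singular values; "
            "the closed form is not the exact prox otherwise"
        )
    if tau == 0:
        return V.copy()
    U, s, Wt = np.linalg.svd(V, full_matrices=False)
    k = s.shape[-1]
    s_new = np.maximum(s - tau * wp[..., :k], 0.0)
    return (U * s_new[..., None, :]) @ Wt


def prox_weighted_l21(V, wq, tau: float):
    """Row-wise group soft-thresholding.

    Row ``r`` is scaled by ``max(0, 1 - tau * wq_r / ||v_r||_2)``; zero rows
    stay zero. Exact prox of ``tau * sum_r wq_r ||a_r||_2``.
    """
    if tau < 0:
        raise DomainError("tau must be >= 0")
    V = np.asarray(V, dtype=float)
    wq = np.asarray(wq, dtype=float)
    if tau == 0:
        return V.copy()
    norms = np.linalg.norm(V, axis=-1)
    scale = np.maximum(0.0, 1.0 - tau * wq / np.maximum(norms, 1e-300))
    return V * scale[..., None]


def project_nonneg(V):
    """Euclidean projection onto the non-negative orthant."""
    return np.maximum(np.asarray(V, dtype=float), 0.0)
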