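"""Rank-1 Poisson NMF for endmember extraction from reference images.

Each single-fluorophore reference image ``Ym`` (C x N counts) is factorized
as ``m a^T`` by minimizing the Poisson negative log-likelihood
``sum[(m a^T) - Ym o log(m a^T)]`` over non-negative ``m`` and ``a``, using
multiplicative updates for the generalized Kullback-Leibler objective.
The fitted spectrum is returned with unit sum, the scale folded into ``a``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    DegenerateInputError,
    EndmemberMatrix,
    SpectralImage,
    _as_array,
)

__all__ = ["Rank1Fit", "fit_rank1_pnmf", "rank1_kl_closed_form", "extract_endmembers"]

_EPS = 1e-12


@dataclass
class Rank1Fit:
    """Result of a rank-1 Poisson NMF fit."""

    m: np.ndarray
    a: np.ndarray
    objective_trace: list[float] = field(default_factory=list)

    @property
    def reconstruction(self) -> np.ndarray:
        return np.outer(self.m, self.a)


def _kl_objective(Ym: np.ndarray, rate: np.ndarray) -> float:
    # generalized-KL fidelity up to the Y-only constant; 0*log 0 := 0
    logs = np.log(np.maximum(rate, _EPS))
    return float(rate.sum() - np.sum(Ym * logs, where=Ym > 0))


def fit_rank1_pnmf(Ym, tol: float = 1e-10, max_iter: int = 500) -> Rank1Fit:
    """Fit ``Ym ~ Poisson(m a^T)`` by alternating multiplicative updates.

    Parameters
    ----------
    Ym : array-like, shape (C, N)
        Non-negative counts of a single-fluorophore reference image.
    tol : float
        Relative objective-change stopping threshold.
    max_iter : int
        Cap on full (m, a) update sweeps.

    Returns
    -------
    Rank1Fit
        ``m`` has unit sum, ``a`` carries the photon-count scale, and
        ``objective_trace`` is non-increasing.

    Notes
    -----
    For the rank-1 generalized-KL problem the multiplicative updates reach
    the closed-form optimum (outer product of the marginals) after a single
    sweep from any positive initialization; the loop mostly exists to make
    the descent property observable and guard degenerate inputs.
    """
    Ym = _as_array(Ym)
    if Ym.ndim != 2:
        raise ValueError(f"expected a C x N matrix, got shape {Ym.shape}")
    if np.any(Ym < 0):
        raise ValueError("reference counts must be non-negative")
    total = Ym.sum()
    if total <= 0:
        raise DegenerateInputError("all-zero reference image")

    C, N = Ym.shape
    m = np.full(C, 1.0 / C)
    a = np.full(N, total / N)
    trace = [_kl_objective(Ym, np.outer(m, a))]

    for _ in range(max_iter):
        rate = np.outer(m, a)
        ratio = Ym / np.maximum(rate, _EPS)
        m = m * (ratio @ a) / max(a.sum(), _EPS)
        rate = np.outer(m, a)
        ratio = Ym / np.maximum(rate, _EPS)
        a = a * (ratio.T @ m) / max(m.sum(), _EPS)
        obj = _kl_objective(Ym, np.outer(m, a))
        trace.append(obj)
        prev = trace[-2]
        if abs(prev - obj) <= tol * max(1.0, abs(prev)):
            break

    scale = m.sum()
    return Rank1Fit(m=m / scale, a=a * scale, objective_trace=trace)


def rank1_kl_closed_form(Ym):
    """Closed-form optimum of the rank-1 generalized-KL factorization.

    The minimizer of ``sum[(m a^T) - Ym o log(m a^T)]`` over non-negative
    rank-1 factors is the independence model
    ``m a^T = (row sums)(col sums)^T / total``. Returns ``(m, a)`` with ``m``
    unit-sum.
    """
    Ym = _as_array(Ym)
    total = Ym.sum()
    if total <= 0:
        raise DegenerateInputError("zero total count")
    m = Ym.sum(axis=1) / total
    a = Ym.sum(axis=0)
    return m, a


def extract_endmembers(
    refs: list[SpectralImage],
    tol: float = 1e-10,
    max_iter: int = 500,
    names: list[str] | None = None,
) -> EndmemberMatrix:
    """Extract one unit-sum endmember per reference image, order preserved."""
    columns = []
    for idx, ref in enumerate(refs):
        Ym = ref.flatten() if isinstance(ref, SpectralImage) else _as_array(ref)
        if Ym.ndim == 3:
            Ym = Ym.reshape(Ym.shape[0], -1)
        try:
            fit = fit_rank1_pnmf(Ym, tol=tol, max_iter=max_iter)
        except DegenerateInputError as exc:
            raise DegenerateInputError(
                f"reference image {idx} failed endmember extraction: {exc}"
            ) from exc
        columns.append(fit.m)
    M = np.column_stack(columns)
    return EndmemberMatrix.from_columns(M, names=names)
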