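"""Domain types and shared math for spectral unmixing.

The data model is channels-first throughout: a spectral image is a
``C x H x W`` cube of non-negative photon counts, an endmember matrix is
``C x R`` with unit-sum columns, and an abundance matrix is ``R x N``
(non-negative, in total-photon-count units).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "DimensionError",
    "DomainError",
    "DegenerateInputError",
    "FormatError",
    "SolverFailureError",
    "SpectralImage",
    "EndmemberMatrix",
    "AbundanceMatrix",
    "Window",
    "SolverConfig",
    "poisson_nll",
    "l21_norm",
    "weighted_nuclear_norm",
    "extract_windows",
    "windows_array",
]


class DimensionError(ValueError):
    """Shapes of the supplied arrays are not conformable."""


class DomainError(ValueError):
    """A value lies outside the mathematical domain of an operation."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but degenerate (e.g. all-zero counts)."""


class FormatError(ValueError):
    """A file or table does not match the expected layout."""


class SolverFailureError(RuntimeError):
    """An iterative solver diverged; carries the iteration count."""

    def __init__(self, message: str, iterations: int = 0):
        super().__init__(message)
        self.iterations = iterations


def _as_array(x) -> np.ndarray:
    """Unwrap domain types to their backing ndarray."""
    for attr in ("counts", "M", "A", "values", "Y"):
        if hasattr(x, attr):
            return np.asarray(getattr(x, attr), dtype=float)
    return np.asarray(x, dtype=float)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SpectralImage:
    """A multichannel count image.

    Parameters
    ----------
    counts : ndarray, shape (C, H, W)
        Non-negative photon counts, one spectrum per pixel.
    channel_centers : ndarray, optional
        Wavelength of each detector channel in nm, length C.
    """

    counts: np.ndarray
    channel_centers: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3:
            raise DimensionError(
                f"expected a C x H x W cube, got shape {self.counts.shape}"
            )
        if min(self.counts.shape) < 1:
            raise DimensionError("all dimensions must be >= 1")
        if np.any(self.counts < 0):
            raise DomainError("counts must be non-negative")
        if self.channel_centers is not None:
            self.channel_centers = np.asarray(self.channel_centers, dtype=float)
            if self.channel_centers.shape != (self.counts.shape[0],):
                raise DimensionError("channel_centers must have length C")

    @property
    def C(self) -> int:
        return self.counts.shape[0]

    @property
    def H(self) -> int:
        return self.counts.shape[1]

    @property
    def W(self) -> int:
        return self.counts.shape[2]

    def flatten(self) -> np.ndarray:
        """Return the C x N matrix view (N = H*W, row-major pixels)."""
        return self.counts.reshape(self.C, -1)


@dataclass
class EndmemberMatrix:
    """Reference spectra, one unit-sum column per fluorophore."""

    M: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)
        if self.M.ndim != 2:
            raise DimensionError(f"expected C x R matrix, got shape {self.M.shape}")
        if np.any(self.M < 0):
            raise DomainError("endmember spectra must be non-negative")
        sums = self.M.sum(axis=0)
        if np.any(sums <= 0):
            raise DegenerateInputError("endmember matrix has an all-zero column")
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise DomainError(
                "endmember columns must sum to 1; use EndmemberMatrix.from_columns"
                " to normalize"
            )
        if not self.names:
            self.names = [f"EM{r + 1:02d}" for r in range(self.M.shape[1])]
        if len(self.names) != self.M.shape[1]:
            raise DimensionError("one name per endmember column required")

    @classmethod
    def from_columns(cls, M, names: Sequence[str] | None = None) -> "EndmemberMatrix":
        """Build an EndmemberMatrix, rescaling each column to unit sum."""
        M = np.asarray(M, dtype=float)
        if M.ndim != 2:
            raise DimensionError(f"expected C x R matrix, got shape {M.shape}")
        sums = M.sum(axis=0)
        if np.any(sums <= 0):
            raise DegenerateInputError("cannot normalize an all-zero column")
        return cls(M / sums, list(names) if names is not None else [])

    @property
    def C(self) -> int:
        return self.M.shape[0]

    @property
    def R(self) -> int:
        return self.M.shape[1]


@dataclass
class AbundanceMatrix:
    """Non-negative abundances, one row per endmember, one column per pixel."""

    A: np.ndarray

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2:
            raise DimensionError(f"expected R x N matrix, got shape {self.A.shape}")
        if np.any(self.A < 0):
            raise DomainError("abundances must be non-negative")

    @property
    def R(self) -> int:
        return self.A.shape[0]

    @property
    def N(self) -> int:
        return self.A.shape[1]


@dataclass
class Window:
    """A 3x3 spatial patch flattened to a C x 9 count matrix.

    Columns are the row-major flattening of the padded 3x3 patch, so the
    center pixel is always column 4. ``origin`` is the (row, col) of the
    center pixel in the source image.
    """

    Y: np.ndarray
    origin: tuple[int, int]
    center_index: int = 4

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2 or self.Y.shape[1] != 9:
            raise DimensionError(f"a window is C x 9, got shape {self.Y.shape}")
        if self.center_index != 4:
            raise DomainError("center_index must be 4 for a 3x3 window")


@dataclass
class SolverConfig:
    """Tuning knobs shared by the window solvers.

    ``mu`` is the splitting penalty of the operator-splitting scheme;
    ``outer_reweights`` counts total solve passes (a uniform-weight pass
    followed by reweighted passes); ``eps_scale`` controls the damping in
    the inverse-magnitude reweighting rule; ``log_guard`` clamps the log
    argument of the Poisson likelihood.
    """

    lambda1: float = 0.0
    lambda2: float = 0.0
    mu: float = 0.01
    tol: float = 1e-6
    max_iter: int = 2000
    outer_reweights: int = 2
    eps_scale: float = 1e-3
    log_guard: float = 1e-12

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise DomainError("lambda1 and lambda2 must be >= 0")
        if self.mu <= 0:
            raise DomainError("mu must be > 0")
        if self.tol <= 0:
            raise DomainError("tol must be > 0")
        if self.max_iter < 1:
            raise DomainError("max_iter must be a positive integer")
        if self.outer_reweights < 1:
            raise DomainError("outer_reweights must be a positive integer")
        if self.eps_scale <= 0 or self.log_guard <= 0:
            raise DomainError("eps_scale and log_guard must be > 0")

    def replace(self, **kw) -> "SolverConfig":
        from dataclasses import replace

        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Objective pieces
# ---------------------------------------------------------------------------


def poisson_nll(M, A, Y, log_guard: float = 1e-12) -> float:
    """Poisson negative log-likelihood fidelity (up to the ``log Y!`` constant).

    Computes ``sum_{c,n} (MA)_{cn} - Y_{cn} * log(max((MA)_{cn}, log_guard))``
    with the convention ``0 * log 0 = 0``.
    """
    M = _as_array(M)
    A = _as_array(A)
    Y = _as_array(Y)
    if M.ndim != 2 or A.ndim != 2 or Y.ndim != 2:
        raise DimensionError("M, A, Y must be 2-D")
    if M.shape[1] != A.shape[0] or Y.shape != (M.shape[0], A.shape[1]):
        raise DimensionError(
            f"non-conformable shapes M{M.shape}, A{A.shape}, Y{Y.shape}"
        )
    if np.any(A < 0) or np.any(Y < 0):
        raise DomainError("A and Y must be non-negative")
    rate = M @ A
    logs = np.log(np.maximum(rate, log_guard))
    # 0*log 0 = 0: only accumulate the log term where Y > 0
    return float(rate.sum() - np.sum(Y * logs, where=Y > 0))


def l21_norm(A) -> float:
    """Sum of row-wise Euclidean norms (group-sparsity penalty)."""
    A = _as_array(A)
    return float(np.sum(np.linalg.norm(np.atleast_2d(A), axis=1)))


def weighted_nuclear_norm(A, wp) -> float:
    """Weighted sum of singular values, weights paired in descending-sigma order."""
    A = _as_array(A)
    wp = np.asarray(wp, dtype=float)
    if np.any(wp < 0):
        raise DomainError("singular-value weights must be non-negative")
    s = np.linalg.svd(np.atleast_2d(A), compute_uv=False)
    if wp.size < s.size:
        raise DimensionError(
            f"need at least {s.size} weights, got {wp.size}"
        )
    return float(np.sum(wp[: s.size] * s))


# ---------------------------------------------------------------------------
# Sliding windows
# ---------------------------------------------------------------------------


def windows_array(img: SpectralImage | np.ndarray) -> np.ndarray:
    """All 3x3 windows of an image as one ``(H*W, C, 9)`` array.

    Borders use replicate padding so every pixel has a centered window.
    Window ``i`` is centered at pixel ``(i // W, i % W)``.
    """
    cube = img.counts if isinstance(img, SpectralImage) else np.asarray(img, float)
    if cube.ndim != 3:
        raise DimensionError("expected a C x H x W cube")
    C, H, W = cube.shape
    padded = np.pad(cube, ((0, 0), (1, 1), (1, 1)), mode="edge")
    view = np.lib.stride_tricks.sliding_window_view(padded, (3, 3), axis=(1, 2))
    # view: (C, H, W, 3, 3) -> (H*W, C, 9)
    return np.ascontiguousarray(
        view.reshape(C, H * W, 9).transpose(1, 0, 2)
    )


def extract_windows(img: SpectralImage) -> Iterator[Window]:
    """Yield one centered 3x3 :class:`Window` per pixel, row-major order."""
    arr = windows_array(img)
    W = img.W
    for i in range(arr.shape[0]):
        yield Window(Y=arr[i], origin=(i // W, i % W))
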