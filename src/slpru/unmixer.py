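"""Whole-image unmixing via sliding 3x3 windows, and grid-search tuning.

Each pixel's abundance comes from the center column of its own centered
window solve (overlapping windows never mix estimates). Tuning evaluates a
penalty grid on single-fluorophore reference images and selects the pair
maximizing the worst-case (minimum over references) average proportion of
the correct endmember — no ground-truth abundances required.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    DimensionError,
    DomainError,
    EndmemberMatrix,
    SolverConfig,
    SpectralImage,
    windows_array,
)
from .metrics import average_proportion, otsu_threshold
from .solvers import nls_batch, solve_windows_batch

__all__ = ["AbundanceImage", "TuningReport", "unmix_image", "tune_on_references"]

METHODS = ("slpru", "nls", "snls", "slnls")


@dataclass
class AbundanceImage:
    """Per-pixel abundance planes, one per endmember."""

    values: np.ndarray
    names: list[str] = field(default_factory=list)
    scale: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise DimensionError("expected (R, H, W) abundance planes")
        if np.any(self.values < 0):
            raise DomainError("abundances must be non-negative")
        if not self.names:
            self.names = [f"EM{r + 1:02d}" for r in range(self.values.shape[0])]
        if len(self.names) != self.values.shape[0]:
            raise DimensionError("one name per abundance plane required")

    @property
    def R(self) -> int:
        return self.values.shape[0]


@dataclass
class TuningReport:
    """Grid-search record over (lambda1, lambda2) pairs."""

    grid: list[tuple[float, float]]
    per_reference_proportion: np.ndarray  # (len(grid), n_refs)
    min_proportion: np.ndarray  # (len(grid),)
    best: tuple[float, float]

    def to_dataframe(self) -> pd.DataFrame:
        n_refs = self.per_reference_proportion.shape[1]
        df = pd.DataFrame(
            self.per_reference_proportion,
            columns=[f"ref{r + 1}" for r in range(n_refs)],
        )
        df.insert(0, "lambda2", [g[1] for g in self.grid])
        df.insert(0, "lambda1", [g[0] for g in self.grid])
        df["min_proportion"] = self.min_proportion
        df["best"] = [g == self.best for g in self.grid]
        return df


def unmix_image(
    img: SpectralImage,
    M: EndmemberMatrix,
    method: str = "slpru",
    cfg: SolverConfig | None = None,
    chunk_size: int = 4096,
    normalize: bool = False,
) -> AbundanceImage:
    """Unmix a whole image, one centered 3x3 window per pixel.

    ``method="nls"`` bypasses windows entirely and solves each pixel
    independently. Windowed methods keep only the center column of each
    window estimate, so the output has one abundance vector per pixel.

    With ``normalize=True`` the counts are divided by their mean positive
    value before solving — an exact reparametrization that puts abundances
    on an O(1) scale where the standard penalty grid is meaningful; the
    divisor is recorded in ``AbundanceImage.scale`` (count units =
    ``values * scale``).
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    cfg = cfg or SolverConfig()
    Mmat = M.M if isinstance(M, EndmemberMatrix) else np.asarray(M, float)
    if img.C != Mmat.shape[0]:
        raise DimensionError(
            f"image has {img.C} channels but M has {Mmat.shape[0]} rows"
        )
    R = Mmat.shape[1]
    H, W = img.H, img.W

    counts = img.counts
    scale = 1.0
    if normalize:
        pos = counts[counts > 0]
        if pos.size == 0:
            raise DomainError("cannot normalize an all-zero image")
        scale = float(pos.mean())
        counts = counts / scale

    if method == "nls":
        A = nls_batch(counts.reshape(img.C, -1).T[:, :, None], Mmat)[:, :, 0]
        values = A.T.reshape(R, H, W)
    else:
        wins = windows_array(counts)  # (H*W, C, 9)
        centers = np.empty((H * W, R))
        for start in range(0, wins.shape[0], chunk_size):
            batch = wins[start : start + chunk_size]
            A, _ = solve_windows_batch(batch, Mmat, method, cfg)
            centers[start : start + batch.shape[0]] = A[:, :, 4]
        values = centers.T.reshape(R, H, W)

    names = M.names if isinstance(M, EndmemberMatrix) else []
    return AbundanceImage(values=values, names=list(names), scale=scale)


def _grid_pairs(method, grid1, grid2):
    if method == "nls":
        return [(0.0, 0.0)]
    if method == "snls":
        return [(0.0, l2) for l2 in sorted(set(grid2))]
    return sorted(itertools.product(sorted(set(grid1)), sorted(set(grid2))))


def tune_on_references(
    refs: list[SpectralImage],
    M: EndmemberMatrix,
    grid1,
    grid2,
    method: str = "slpru",
    cfg: SolverConfig | None = None,
    normalize: bool = True,
) -> TuningReport:
    """Grid-search penalties on reference images by worst-case proportion.

    Reference ``r`` is known to contain only endmember ``r``, but unmixing
    uses the full endmember matrix. For every (lambda1, lambda2) pair each
    reference is unmixed and its average proportion of the correct
    endmember computed over foreground pixels (total counts above the Otsu
    threshold of the summed-channel image). ``best`` maximizes the minimum
    proportion across references; ties go to the lexicographically smaller
    pair.

    By default each reference is rescaled to unit mean positive count
    before solving (proportions are scale-free; this keeps the penalty
    grid comparable across acquisitions of different brightness).
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    cfg = cfg or SolverConfig()
    pairs = _grid_pairs(method, grid1, grid2)
    if not pairs:
        raise DomainError("empty tuning grid")
    if len(refs) > M.R:
        raise DimensionError("more references than endmembers")

    # reference windows and foreground masks are grid-independent
    wins, masks, slices = [], [], []
    offset = 0
    for ref in refs:
        counts = ref.counts
        if normalize:
            pos = counts[counts > 0]
            if pos.size:
                counts = counts / pos.mean()
        w = windows_array(counts)
        wins.append(w)
        total = ref.counts.sum(axis=0)
        try:
            thr = otsu_threshold(total)
        except Exception:
            thr = -np.inf  # flat image: keep every pixel
        masks.append((total > thr).ravel())
        slices.append(slice(offset, offset + w.shape[0]))
        offset += w.shape[0]
    allwins = np.concatenate(wins, axis=0)
    A0 = nls_batch(allwins, M)

    props = np.empty((len(pairs), len(refs)))
    for i, (lam1, lam2) in enumerate(pairs):
        c = cfg.replace(lambda1=lam1, lambda2=lam2)
        A, _ = solve_windows_batch(allwins, M, method, c, A0=A0)
        centers = A[:, :, 4]  # (sum_pixels, R)
        for r, sl in enumerate(slices):
            props[i, r] = average_proportion(centers[sl].T, r, mask=masks[r])

    mins = props.min(axis=1)
    best_idx = int(np.argmax(mins))  # pairs sorted lexicographically: first wins
    return TuningReport(
        grid=pairs,
        per_reference_proportion=props,
        min_proportion=mins,
        best=pairs[best_idx],
    )
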