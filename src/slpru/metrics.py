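"""Evaluation metrics: proportions, RMSE, thresholds, morphology, Welch test."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats
import skimage.measure

from .core import DegenerateInputError, DimensionError, DomainError, _as_array

__all__ = [
    "ObjectMorphology",
    "average_proportion",
    "rmse",
    "otsu_threshold",
    "triangle_threshold",
    "circularity",
    "welch_t",
]


@dataclass
class ObjectMorphology:
    """Per-object morphology of one 8-connected component."""

    label: int
    area: int
    perimeter: float
    circularity: float


def _abundance_planes(A) -> np.ndarray:
    """Flatten AbundanceMatrix / AbundanceImage / ndarray to (R, N)."""
    arr = _as_array(A)
    if arr.ndim == 3:
        arr = arr.reshape(arr.shape[0], -1)
    if arr.ndim != 2:
        raise DimensionError("expected (R, N) or (R, H, W) abundances")
    return arr


def average_proportion(A, r0: int, mask=None) -> float:
    """Mean fraction of per-pixel total abundance assigned to endmember r0.

    At each masked pixel the proportion is ``A[r0] / sum_r A[r]``; pixels
    whose total abundance is zero are excluded (the proportion is undefined
    there).
    """
    arr = _abundance_planes(A)
    if not 0 <= r0 < arr.shape[0]:
        raise DomainError(f"endmember index {r0} out of range")
    totals = arr.sum(axis=0)
    if mask is None:
        sel = np.ones(arr.shape[1], dtype=bool)
    else:
        sel = np.asarray(mask, dtype=bool).ravel()
        if sel.shape[0] != arr.shape[1]:
            raise DimensionError("mask size does not match pixel count")
    sel = sel & (totals > 0)
    if not sel.any():
        raise DomainError("no masked pixels with positive total abundance")
    return float(np.mean(arr[r0, sel] / totals[sel]))


def rmse(A, Ahat) -> float:
    """Root mean square error ``sqrt(||A - Ahat||_F^2 / (N R))``."""
    A = _as_array(A)
    Ahat = _as_array(Ahat)
    if A.shape != Ahat.shape:
        raise DimensionError(f"shape mismatch {A.shape} vs {Ahat.shape}")
    return float(np.sqrt(np.mean((A - Ahat) ** 2)))


def _histogram(values, nbins=256):
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 2 or v.min() == v.max():
        raise DegenerateInputError("need at least two distinct values")
    hist, edges = np.histogram(v, bins=nbins, range=(v.min(), v.max()))
    return hist.astype(float), edges


def otsu_threshold(values, nbins: int = 256) -> float:
    """Histogram threshold maximizing between-class variance.

    256 uniform bins over the data range; candidate thresholds are the
    interior bin edges, ties resolved by averaging the tied edges.
    """
    hist, edges = _histogram(values, nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = hist.sum()
    w0 = np.cumsum(hist)[:-1]
    w1 = total - w0
    csum = np.cumsum(hist * centers)
    mu0 = csum[:-1] / np.maximum(w0, 1e-300)
    mu1 = (csum[-1] - csum[:-1]) / np.maximum(w1, 1e-300)
    var = w0 * w1 * (mu0 - mu1) ** 2
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        raise DegenerateInputError("degenerate histogram")
    var[~valid] = -np.inf
    # plateaus of equal variance (empty-bin gaps) are averaged
    best = np.flatnonzero(var >= var.max() - 1e-9 * abs(var.max()))
    return float(np.mean(edges[1:-1][best]))


def triangle_threshold(values, nbins: int = 256) -> float:
    """Triangle method: maximal point-to-chord distance from peak to far tail."""
    hist, edges = _histogram(values, nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = int(np.argmax(hist))
    nz = np.flatnonzero(hist)
    lo, hi = int(nz[0]), int(nz[-1])
    end = hi if (hi - peak) >= (peak - lo) else lo
    if end == peak:
        raise DegenerateInputError("histogram has no tail on either side")
    idx = np.arange(min(peak, end), max(peak, end) + 1)
    # perpendicular distance of (i, h_i) from the chord peak->end
    dx, dy = end - peak, hist[end] - hist[peak]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (idx - peak) - dx * (hist[idx] - hist[peak])) / norm
    best = idx[np.flatnonzero(dist >= dist.max() - 1e-9 * max(dist.max(), 1.0))]
    return float(np.mean(centers[best]))


def _contour_perimeter(obj_mask: np.ndarray) -> float:
    """Boundary length of the 0.5-level (sub-pixel) contour of one object.

    Marching-squares contours interpolate midway between inside and
    outside pixel centers, which tracks the pre-digitization boundary far
    better than pixel-edge counting: a 10x10 square measures ~40 and a
    radius-50 disk ~2*pi*50, matching the continuous perimeters the
    circularity formula assumes. Hole boundaries count toward the
    perimeter.
    """
    padded = np.pad(obj_mask.astype(float), 1)
    total = 0.0
    for contour in skimage.measure.find_contours(padded, 0.5):
        seg = np.diff(contour, axis=0)
        total += float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    return total


def circularity(mask) -> list[ObjectMorphology]:
    """Morphology of each 8-connected object in a binary mask.

    Perimeter is the sub-pixel contour length (see
    :func:`_contour_perimeter`); circularity is ``4 pi area / perimeter^2``
    capped at 1.0 (small digital objects can exceed 1, as in common
    imaging software).
    """
    mask = np.asarray(mask).astype(bool)
    labels = skimage.measure.label(mask, connectivity=2)
    out = []
    for prop in skimage.measure.regionprops(labels):
        perim = _contour_perimeter(prop.image)
        circ = 1.0 if perim <= 0 else min(1.0, 4.0 * np.pi * prop.area / perim**2)
        out.append(
            ObjectMorphology(
                label=int(prop.label),
                area=int(prop.area),
                perimeter=perim,
                circularity=float(circ),
            )
        )
    return out


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of freedom.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise DomainError("each sample needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise DomainError("at least one sample must have nonzero variance")
    nx, ny = x.size, y.size
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
    )
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))
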