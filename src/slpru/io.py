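"""Readers and writers: multi-page TIFF cubes and spectra/report CSVs."""

from __future__ import annotations

import json
import logging

import numpy as np
import pandas as pd
import tifffile

from .core import EndmemberMatrix, FormatError, SpectralImage
from .unmixer import AbundanceImage

__all__ = [
    "read_spectral_tiff",
    "write_spectral_tiff",
    "write_abundance_tiff",
    "read_abundance_tiff",
    "read_spectra_csv",
    "write_spectra_csv",
]

log = logging.getLogger("slpru")


def read_spectral_tiff(path) -> SpectralImage:
    """Read a channels-first spectral cube from a multi-page TIFF.

    Pages are channels. Interleaved (RGB-style, samples-last) files are
    rejected; negative pixels are clamped to 0 with a logged count.
    """
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            axes = series.axes
            arr = series.asarray()
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt / unreadable
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    if "S" in axes:
        raise FormatError(
            f"{path}: interleaved samples axis {axes!r} not supported; expected "
            "a channels-first multi-page stack (one page per spectral channel)"
        )
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(
            f"{path}: expected 2-D pages forming a C x H x W stack, "
            f"got axes {axes!r} with shape {arr.shape}"
        )
    neg = int(np.sum(arr < 0))
    if neg:
        log.warning("%s: clamped %d negative pixel(s) to 0", path, neg)
        arr = np.maximum(arr, 0.0)
    return SpectralImage(arr)


def write_spectral_tiff(img: SpectralImage, path) -> None:
    """Write a spectral cube as one float32 page per channel."""
    # explicit photometric: 3-channel cubes must not be stored as RGB
    tifffile.imwrite(path, img.counts.astype(np.float32), photometric="minisblack")


def write_abundance_tiff(A: AbundanceImage, path) -> None:
    """Write abundance planes as 32-bit float pages, one per endmember.

    Each page description carries a JSON record with the endmember name
    and the count-rescaling factor.
    """
    with tifffile.TiffWriter(path) as tw:
        for r in range(A.R):
            tw.write(
                A.values[r].astype(np.float32),
                description=json.dumps({"name": A.names[r], "scale": A.scale}),
                contiguous=False,
            )


def read_abundance_tiff(path) -> AbundanceImage:
    """Inverse of :func:`write_abundance_tiff`."""
    planes, names, scale = [], [], 1.0
    with tifffile.TiffFile(path) as tif:
        for i, page in enumerate(tif.pages):
            planes.append(np.asarray(page.asarray(), dtype=float))
            desc = page.description
            try:
                meta = json.loads(desc)
                names.append(meta.get("name", f"EM{i + 1:02d}"))
                scale = float(meta.get("scale", scale))
            except (json.JSONDecodeError, TypeError):
                names.append(f"EM{i + 1:02d}")
    if not planes:
        raise FormatError(f"{path}: empty TIFF")
    shapes = {p.shape for p in planes}
    if len(shapes) != 1:
        raise FormatError(f"{path}: inconsistent page shapes {shapes}")
    return AbundanceImage(
        values=np.maximum(np.stack(planes), 0.0), names=names, scale=scale
    )


def read_spectra_csv(path) -> EndmemberMatrix:
    """Read an endmember CSV: header of fluorophore names, one row per channel.

    Columns are renormalized to unit sum on read; the original column sums
    are logged.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] < 1 or df.shape[0] < 1:
        raise FormatError(f"{path}: empty spectra table")
    # a header row of numbers means the file has no real header
    numeric_header = all(_is_number(c) for c in df.columns)
    if numeric_header:
        raise FormatError(
            f"{path}: missing header row of fluorophore names"
        )
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.argmax(bad.values | df[col].isna().values))
            raise FormatError(
                f"{path}: non-numeric value in column {col!r}, row {row}"
            )
    M = df.to_numpy(dtype=float)
    if np.any(M < 0):
        raise FormatError(f"{path}: negative spectral values")
    log.info("%s: column sums before normalization: %s", path, M.sum(axis=0))
    return EndmemberMatrix.from_columns(M, names=list(df.columns))


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def write_spectra_csv(M: EndmemberMatrix, path) -> None:
    """Write an endmember matrix as CSV (header row of names)."""
    pd.DataFrame(M.M, columns=M.names).to_csv(path, index=False)
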