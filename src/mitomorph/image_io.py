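"""Raster and tabular I/O.

All file-format handling lives here so the computational modules only ever
see in-memory arrays.  Conventions shared by every module:

* coordinates are (row, col), 0-based, pixel centers at integer coordinates;
* intensities are kept exactly as stored on disk — contrast handling is the
  preprocessing stage's job, never the reader's.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: CSV column order for morphology tables: unit id, then the morphology
#: parameters in the analyzer's reporting order, then normalization info.
METRIC_COLUMNS = (
    "unit_id",
    "skeleton_area",
    "rod_count",
    "punctate_count",
    "network_count",
    "punctate_pct",
    "rod_pct",
    "network_pct",
    "punctate_length",
    "rod_length",
    "network_length",
    "mean_rod_length",
    "total_network_branch_count",
    "mean_network_branch_count",
    "mean_network_branch_length",
    "mean_network_length",
    "all_branch_count",
    "mean_length_all_branches",
    "mean_network_and_rod_length",
    "normalizer_kind",
    "normalizer_value",
)


class ImageFormatError(ValueError):
    """Raised when a raster file cannot be interpreted as a 2D image."""


@dataclass
class RawImage:
    """A single-channel intensity image as read from a microscope export.

    Parameters
    ----------
    pixels : ndarray
        2D non-negative integer grid.
    bit_depth : int
        8 or 16; all intensities must lie in ``[0, 2**bit_depth - 1]``.
    channel : str
        One of ``{"mito", "nuclei", "phase"}``.
    pixel_size : float, optional
        Physical edge length of one pixel in µm; ``None`` means unknown and
        all downstream lengths/areas stay in pixel units.
    source_id : str
        File name or synthetic-seed tag used to label output rows.
    """

    pixels: np.ndarray
    bit_depth: int
    channel: str = "mito"
    pixel_size: Optional[float] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 2:
            raise ImageFormatError(
                f"RawImage requires a 2D grid with >=2 rows and cols, "
                f"got shape {self.pixels.shape}"
            )
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise TypeError("RawImage pixels must be integer-typed")
        hi = 2**self.bit_depth - 1
        if self.pixels.min() < 0 or self.pixels.max() > hi:
            raise ValueError(f"intensities outside [0, {hi}]")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1


@dataclass
class BinaryMask:
    """Boolean foreground mask aligned to a source :class:`RawImage`."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != bool:
            raise TypeError("BinaryMask pixels must be boolean")
        if self.pixels.ndim != 2:
            raise ImageFormatError("BinaryMask must be 2D")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


def _infer_bit_depth(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8 or arr.dtype == bool:
        return 8
    if arr.dtype == np.uint16:
        return 16
    if np.issubdtype(arr.dtype, np.integer):
        return 8 if arr.max(initial=0) <= 255 else 16
    raise ImageFormatError(f"unsupported raster dtype {arr.dtype}")


def _resolve_channel(arr: np.ndarray, channel_policy) -> np.ndarray:
    """Reduce a possibly multi-channel array to one 2D plane.

    ``channel_policy="auto"`` picks the plane with maximal mean intensity —
    stained exports carry the signal in one plane (typically red for a
    mitochondrial stain) but channel order varies between writers.  An
    integer policy indexes the last (channel) axis directly.
    """
    arr = np.squeeze(arr)
    if arr.ndim == 2:
        return arr
    if arr.ndim != 3:
        raise ImageFormatError(f"cannot resolve a 2D plane from shape {arr.shape}")
    # channels-last is the common TIFF/PNG layout; accept channels-first too
    ax = 2 if arr.shape[2] <= 4 else 0
    if isinstance(channel_policy, int):
        idx = channel_policy
    else:
        planes = np.moveaxis(arr, ax, 0)
        idx = int(np.argmax([p.mean() for p in planes]))
    return np.moveaxis(arr, ax, 0)[idx]


def read_image(
    path,
    channel: str = "mito",
    channel_policy="auto",
    pixel_size: Optional[float] = None,
) -> RawImage:
    """Read a TIFF/PNG raster as a :class:`RawImage`, never rescaling.

    Multi-channel files are reduced to one plane per ``channel_policy``
    (``"auto"`` or an integer plane index).
    """
    path = os.fspath(path)
    try:
        if path.lower().endswith((".tif", ".tiff")):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - reported as an I/O failure
        raise IOError(f"cannot read image {path!r}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim > 3:
        raise ImageFormatError(f"{path!r}: >3 dimensions after channel resolution")
    plane = _resolve_channel(arr, channel_policy)
    if plane.dtype == bool:
        plane = plane.astype(np.uint8) * 255
    return RawImage(
        pixels=plane,
        bit_depth=_infer_bit_depth(plane),
        channel=channel,
        pixel_size=pixel_size,
        source_id=os.path.basename(path),
    )


def write_image(img: RawImage, path) -> None:
    """Write a RawImage to TIFF (or PNG by extension) without rescaling."""
    path = os.fspath(path)
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    arr = img.pixels.astype(dtype)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def write_skeleton(skel, path) -> None:
    """Write a skeleton (or any boolean mask) as a binary 0/255 8-bit TIFF."""
    pixels = np.asarray(getattr(skel, "pixels", skel))
    if pixels.dtype != bool:
        raise TypeError("write_skeleton expects a boolean skeleton")
    tifffile.imwrite(os.fspath(path), pixels.astype(np.uint8) * 255)


def read_mask(path) -> BinaryMask:
    """Read a binary TIFF written by :func:`write_skeleton` back as a mask."""
    arr = tifffile.imread(os.fspath(path))
    return BinaryMask(pixels=np.asarray(arr) > 0, source_id=os.path.basename(path))


def write_metrics_table(records: Sequence, path) -> None:
    """Write morphology records as RFC-4180 CSV, one row per analysis unit.

    Undefined (zero-denominator) values are emitted as empty cells, never 0.
    An empty record list produces a header-only file with a logged warning.
    """
    if not records:
        logger.warning("write_metrics_table: empty record list, writing header only")
        df = pd.DataFrame(columns=list(METRIC_COLUMNS))
    else:
        df = pd.DataFrame([r.as_dict() for r in records], columns=list(METRIC_COLUMNS))
    df.to_csv(os.fspath(path), index=False, float_format="%.17g")


def read_metrics_table(path) -> pd.DataFrame:
    """Re-read a metrics CSV; undefined cells come back as NaN."""
    return pd.read_csv(os.fspath(path))
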