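"""Preprocessing: CLAHE illumination correction, Otsu thresholding, denoise/blur.

The binarization chain applied to a stained micrograph before thinning is
CLAHE -> Otsu.  CLAHE (contrast-limited adaptive histogram equalization)
equalizes per-tile histograms with a clip limit and bilinear interpolation
between tile mappings, which evens out the strong illumination gradients of
widefield fluorescence images; Otsu then picks the threshold maximizing
between-class variance.  Defaults follow the analyzer's published settings:
a 10x10-pixel contextual region, a clip limit of 0.02 and 256 histogram bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, morphology

from .image_io import BinaryMask, RawImage


class DegenerateImageError(ValueError):
    """Raised when an operation is undefined on the given image (e.g. Otsu
    on a constant image, which admits no 2-class split)."""


@dataclass(frozen=True)
class ClaheParams:
    """CLAHE settings.

    kernel_size : (rows, cols) of the contextual region, in pixels.  The
        alternate reading "number of tiles per axis" is available through
        :func:`clahe`'s ``kernel_is_grid`` flag, since implementations
        disagree on this parameter's meaning.
    clip_limit : histogram clip limit as a fraction of the tile pixel count
        per bin, in (0, 1].
    n_bins : histogram bin count (>= 2).
    """

    kernel_size: Tuple[int, int] = (10, 10)
    clip_limit: float = 0.02
    n_bins: int = 256

    def __post_init__(self) -> None:
        kr, kc = self.kernel_size
        if kr < 2 or kc < 2:
            raise ValueError("kernel_size components must be >= 2")
        if not (0 < self.clip_limit <= 1):
            raise ValueError("clip_limit must be in (0, 1]")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def clahe(
    img: RawImage,
    params: Optional[ClaheParams] = None,
    kernel_is_grid: bool = False,
) -> RawImage:
    """Contrast-limited adaptive histogram equalization.

    Returns an image of identical shape and bit depth.  Deterministic.
    With ``kernel_is_grid=True`` the kernel_size is interpreted as a tile
    *grid* (kernel_size[0] x kernel_size[1] tiles) instead of a tile size
    in pixels.
    """
    params = params or ClaheParams()
    kr, kc = params.kernel_size
    h, w = img.shape
    if kernel_is_grid:
        kr, kc = max(2, h // kr), max(2, w // kc)
    if kr > h or kc > w:
        raise ValueError(
            f"CLAHE kernel {kr}x{kc} larger than image {h}x{w}"
        )
    if img.pixels.min() == img.pixels.max():
        # a flat histogram equalizes to itself; the underlying
        # implementation dithers at the bin boundary instead
        return RawImage(
            pixels=img.pixels.copy(),
            bit_depth=img.bit_depth,
            channel=img.channel,
            pixel_size=img.pixel_size,
            source_id=img.source_id,
        )
    scale = img.max_value
    f = img.pixels.astype(np.float64) / scale
    out = exposure.equalize_adapthist(
        f, kernel_size=(kr, kc), clip_limit=params.clip_limit, nbins=params.n_bins
    )
    pixels = np.rint(out * scale).astype(img.pixels.dtype)
    return RawImage(
        pixels=pixels,
        bit_depth=img.bit_depth,
        channel=img.channel,
        pixel_size=img.pixel_size,
        source_id=img.source_id,
    )


def otsu_threshold_value(values: np.ndarray, max_value: int) -> int:
    """Exact global Otsu threshold over integer intensities.

    Maximizes between-class variance over every candidate threshold
    ``t in [0, max_value - 1]`` (foreground = intensity > t); ties in the
    objective break toward the smallest t.  Exhaustive and exact — no
    histogram rebinning — so 16-bit images scan all 65535 candidates.
    """
    counts = np.bincount(values.ravel(), minlength=max_value + 1).astype(np.float64)
    total = counts.sum()
    w0 = np.cumsum(counts)[:-1]           # class-0 mass for t = 0 .. max-1
    w1 = total - w0
    csum = np.cumsum(counts * np.arange(max_value + 1))[:-1]
    grand = csum[-1] + counts[-1] * max_value
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = csum / w0
        mu1 = (grand - csum) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[~np.isfinite(sigma_b)] = -1.0  # one class empty: invalid split
    if sigma_b.max() < 0:
        raise DegenerateImageError("constant image: no 2-class split exists")
    return int(np.argmax(sigma_b))  # argmax returns the smallest maximizer


def _window_threshold_surface(
    pixels: np.ndarray, max_value: int, window: int
) -> np.ndarray:
    """Per-pixel threshold surface from Otsu on overlapping windows.

    Windows of size ``window`` are laid on a half-overlapping grid; each
    window's Otsu threshold is attached to its center and bilinearly
    interpolated between centers (edges clamped).  Windows without two
    distinct intensities inherit the global threshold.
    """
    from scipy.interpolate import RegularGridInterpolator

    h, w = pixels.shape
    step = max(1, window // 2)
    r0s = list(range(0, max(1, h - window + 1), step))
    c0s = list(range(0, max(1, w - window + 1), step))
    if r0s[-1] != max(0, h - window):
        r0s.append(max(0, h - window))
    if c0s[-1] != max(0, w - window):
        c0s.append(max(0, w - window))
    t_global = otsu_threshold_value(pixels, max_value)
    grid = np.empty((len(r0s), len(c0s)), dtype=np.float64)
    centers_r = np.array([r + min(window, h) / 2.0 for r in r0s])
    centers_c = np.array([c + min(window, w) / 2.0 for c in c0s])
    for i, r in enumerate(r0s):
        for j, c in enumerate(c0s):
            tile = pixels[r : r + window, c : c + window]
            if tile.min() == tile.max():
                grid[i, j] = t_global
            else:
                grid[i, j] = otsu_threshold_value(tile, max_value)
    interp = RegularGridInterpolator(
        (centers_r, centers_c), grid, bounds_error=False, fill_value=None
    )
    rr, cc = np.meshgrid(
        np.clip(np.arange(h), centers_r[0], centers_r[-1]),
        np.clip(np.arange(w), centers_c[0], centers_c[-1]),
        indexing="ij",
    )
    return interp(np.stack([rr, cc], axis=-1))


def otsu_threshold(
    img: RawImage,
    mode: str = "global",
    window: Optional[int] = None,
) -> BinaryMask:
    """Binarize by Otsu's between-class-variance criterion.

    mode="global": one exact threshold for the whole image (the default —
    after CLAHE normalization a single threshold is well-posed).
    mode="adaptive": a per-pixel threshold surface interpolated from Otsu
    thresholds of overlapping windows (default window = 40 px, i.e. 4x the
    default CLAHE kernel).
    """
    if img.pixels.min() == img.pixels.max():
        raise DegenerateImageError("constant image: no 2-class split exists")
    if mode == "global":
        t = otsu_threshold_value(img.pixels, img.max_value)
        fg = img.pixels > t
    elif mode == "adaptive":
        window = window or 40
        surface = _window_threshold_surface(img.pixels, img.max_value, window)
        fg = img.pixels > surface
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    return BinaryMask(pixels=fg, source_id=img.source_id)


def denoise_and_blur(img: RawImage, min_feature: int = 2, sigma: float = 2.0) -> RawImage:
    """Suppress small bright features, then Gaussian-smooth.

    Grayscale morphological opening with a disk of radius ``min_feature``
    removes features smaller than the disk; a Gaussian blur of standard
    deviation ``sigma`` then smooths intensity within the stain region.
    ``min_feature=0, sigma=0`` is the identity.
    """
    if min_feature < 0 or sigma < 0:
        raise ValueError("min_feature and sigma must be >= 0")
    pixels = img.pixels
    if min_feature > 0:
        pixels = morphology.opening(pixels, morphology.disk(min_feature))
    if sigma > 0:
        pixels = ndi.gaussian_filter(pixels.astype(np.float64), sigma)
        pixels = np.clip(np.rint(pixels), 0, img.max_value).astype(img.pixels.dtype)
    return RawImage(
        pixels=pixels,
        bit_depth=img.bit_depth,
        channel=img.channel,
        pixel_size=img.pixel_size,
        source_id=img.source_id,
    )
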