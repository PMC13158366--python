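"""Cell segmentation from the mito-stain channel, and nucleus counting.

For spatially separated ("differentiated") cells, a field is split into
per-cell regions using only the mitochondrial stain: denoise/blur, global
Otsu on the blurred image, hole filling, then a distance-transform watershed
seeded at smoothed regional maxima to declump touching cells, and a size
filter on the equivalent diameter.  This is a minimal, self-contained
equivalent of the primary-object-identification step in standard cell-image
pipelines; nuclei are not required for segmentation and are used only for
normalizing clustered (hiPSC-like) cultures, where the Hoechst channel is
counted with the same threshold + watershed chain.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .image_io import RawImage
from .preprocess import (
    DegenerateImageError,
    clahe,
    denoise_and_blur,
    otsu_threshold,
)
from .skeletonize import SkeletonImage

logger = logging.getLogger(__name__)
_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class SegmentationLabels:
    """Per-cell label image: 0 = background, 1..K = cells."""

    labels: np.ndarray
    areas: np.ndarray          # areas[k-1] = pixel count of label k
    K: int

    @property
    def shape(self) -> tuple:
        return self.labels.shape


def _watershed_split(mask: np.ndarray, min_distance: int) -> np.ndarray:
    """Split touching objects by watershed on the smoothed distance map."""
    dist = ndi.distance_transform_edt(mask)
    smooth = ndi.gaussian_filter(dist, 2.0)
    coords = peak_local_max(
        smooth, min_distance=max(1, min_distance), labels=mask, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        lab, _ = ndi.label(mask, structure=_EIGHT)
        return lab
    return watershed(-smooth, markers, mask=mask)


def _relabel(labels: np.ndarray, keep: List[int]) -> SegmentationLabels:
    out = np.zeros_like(labels, dtype=np.int32)
    areas = []
    for new, old in enumerate(sorted(keep), start=1):
        sel = labels == old
        out[sel] = new
        areas.append(int(sel.sum()))
    return SegmentationLabels(labels=out, areas=np.asarray(areas, dtype=np.int64),
                              K=len(keep))


def identify_primary_objects(
    img: RawImage,
    min_diameter: float = 40.0,
    max_diameter: float = 400.0,
    min_feature: int = 2,
    sigma: Optional[float] = None,
    exclude_border: bool = False,
    declump_distance: Optional[int] = None,
    illumination_correct: bool = True,
) -> SegmentationLabels:
    """Detect individual cells in the grayscale mito-stain image.

    Pipeline: CLAHE illumination correction (without it, a strong
    illumination gradient can raise far-corner background above near-corner
    cells and defeat a global threshold) -> denoise_and_blur -> global Otsu
    -> fill holes -> distance watershed declumping -> discard objects with
    equivalent diameter outside [min_diameter, max_diameter] (and
    border-touching ones if requested).  ``sigma`` defaults to
    min_diameter/2 so a cell's structures blur into one blob;
    ``declump_distance`` defaults to 1.5*min_diameter.  Returns K=0 with a
    warning, not an exception, when nothing survives.
    """
    if not (0 < min_diameter < max_diameter):
        raise ValueError("need 0 < min_diameter < max_diameter")
    if sigma is None:
        sigma = min_diameter / 2.0
    if declump_distance is None:
        declump_distance = int(round(1.5 * min_diameter))
    if illumination_correct:
        img = clahe(img)
    blurred = denoise_and_blur(img, min_feature=min_feature, sigma=sigma)
    try:
        mask = otsu_threshold(blurred, mode="global").pixels
    except DegenerateImageError:
        logger.warning("identify_primary_objects: degenerate image, no objects")
        return SegmentationLabels(
            labels=np.zeros(img.shape, dtype=np.int32),
            areas=np.zeros(0, dtype=np.int64), K=0,
        )
    mask = ndi.binary_fill_holes(mask)
    labels = _watershed_split(mask, min_distance=declump_distance)
    keep = []
    h, w = labels.shape
    for lbl in range(1, labels.max() + 1):
        sel = labels == lbl
        area = int(sel.sum())
        if area == 0:
            continue
        eq_diam = 2.0 * math.sqrt(area / math.pi)
        if not (min_diameter <= eq_diam <= max_diameter):
            continue
        if exclude_border:
            rows, cols = np.nonzero(sel)
            if rows.min() == 0 or cols.min() == 0 or rows.max() == h - 1 or cols.max() == w - 1:
                continue
        keep.append(lbl)
    if not keep:
        logger.warning("identify_primary_objects: no object passed the size filter")
    return _relabel(labels, keep)


def assign_skeleton_to_cells(
    skel: SkeletonImage,
    seg: SegmentationLabels,
    max_gap: int = 5,
) -> List[SkeletonImage]:
    """Split a field skeleton into one skeleton per segmented cell.

    Skeleton pixels on background are assigned to the nearest label within
    ``max_gap`` px, else dropped; the per-cell pixel counts plus dropped
    pixels always sum to the input count (exact conservation).
    """
    pixels = skel.pixels
    if pixels.shape != seg.shape:
        raise ValueError("skeleton and segmentation shapes differ")
    if seg.K == 0:
        return []
    dist, (ir, ic) = ndi.distance_transform_edt(
        seg.labels == 0, return_indices=True
    )
    nearest = seg.labels[ir, ic]
    assigned = np.where(seg.labels > 0, seg.labels,
                        np.where(dist <= max_gap, nearest, 0))
    out = []
    for k in range(1, seg.K + 1):
        out.append(
            SkeletonImage(
                pixels=pixels & (assigned == k),
                source_mask_id=f"{skel.source_mask_id}_cell{k}",
            )
        )
    return out


def count_nuclei(nuc_img: RawImage, min_nucleus_area: int = 30) -> int:
    """Count nuclei in the nuclear-stain channel.

    Gaussian blur -> global Otsu -> fill holes -> distance-transform
    watershed split of touching nuclei -> count components with area >=
    ``min_nucleus_area``.  A blank image counts 0.
    """
    blurred = denoise_and_blur(nuc_img, min_feature=0, sigma=2.0)
    try:
        mask = otsu_threshold(blurred, mode="global").pixels
    except DegenerateImageError:
        return 0
    mask = ndi.binary_fill_holes(mask)
    min_r = max(3, int(round(math.sqrt(min_nucleus_area / math.pi))))
    labels = _watershed_split(mask, min_distance=min_r)
    count = 0
    for lbl in range(1, labels.max() + 1):
        if int((labels == lbl).sum()) >= min_nucleus_area:
            count += 1
    return count
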