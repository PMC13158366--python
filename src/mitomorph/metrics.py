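"""The 18-parameter morphology record and the batch analyzer.

One :class:`MorphologyMetrics` record summarizes one analysis unit — a
segmented cell ("segmented" mode, fibroblast-like cultures) or a whole field
("aggregate" mode, clustered hiPSC-like cultures).  Definitions, with C the
set of skeleton components, P/R/N the punctate/rod/network subsets and
len(x) a component's summed geodesic branch length:

* skeleton_area        — total skeleton pixel count (x pixel_size^2 in µm²)
* class counts         — |P|, |R|, |N|
* class percentages    — 100 * |X| / |C| (count-based; a length-weighted
                         variant is selectable)
* class lengths        — sum of len(x) over the class
* mean_rod_length      — rod_length / |R|
* total_network_branch_count — total branches over networks
* mean_network_branch_count  — total_network_branch_count / |N|
* mean_network_branch_length — network_length / total_network_branch_count
* mean_network_length  — network_length / |N|
* all_branch_count     — |P| + |R| + total_network_branch_count
* mean_length_all_branches   — total length / all_branch_count
* mean_network_and_rod_length — (network_length + rod_length) / (|N| + |R|)

Any mean with a zero denominator is *missing* (None), never 0.

Normalization (applied per culture type): extensive fields — the area, the
three counts, the three class lengths and the two branch totals — divide by
the normalizer (cell surface area, or nuclei count for clustered cultures);
intensive fields (percentages and means) are left untouched.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional

from .image_io import RawImage, read_image
from .preprocess import ClaheParams, clahe, otsu_threshold
from .segment import (
    SegmentationLabels,
    assign_skeleton_to_cells,
    count_nuclei,
    identify_primary_objects,
)
from .skeletonize import SkeletonImage, zhang_suen_thin
from .skelgraph import PUNCTATE_MAX_DEFAULT, SkeletonGraph, build_graph, component_census

logger = logging.getLogger(__name__)

EXTENSIVE_FIELDS = (
    "skeleton_area",
    "punctate_count",
    "rod_count",
    "network_count",
    "punctate_length",
    "rod_length",
    "network_length",
    "total_network_branch_count",
    "all_branch_count",
)

INTENSIVE_FIELDS = (
    "punctate_pct",
    "rod_pct",
    "network_pct",
    "mean_rod_length",
    "mean_network_branch_count",
    "mean_network_branch_length",
    "mean_network_length",
    "mean_length_all_branches",
    "mean_network_and_rod_length",
)


@dataclass
class MorphologyMetrics:
    unit_id: str
    skeleton_area: float
    punctate_count: float
    rod_count: float
    network_count: float
    punctate_pct: Optional[float]
    rod_pct: Optional[float]
    network_pct: Optional[float]
    punctate_length: float
    rod_length: float
    network_length: float
    mean_rod_length: Optional[float]
    total_network_branch_count: float
    mean_network_branch_count: Optional[float]
    mean_network_branch_length: Optional[float]
    mean_network_length: Optional[float]
    all_branch_count: float
    mean_length_all_branches: Optional[float]
    mean_network_and_rod_length: Optional[float]
    normalizer_kind: str = "none"          # none | cell_area | nuclei_count
    normalizer_value: Optional[float] = None

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _safe_div(num: float, den: float) -> Optional[float]:
    return None if den == 0 else num / den


def check_invariants(m: MorphologyMetrics, atol: float = 1e-9) -> None:
    """Assert the definitional identities of a metrics record.

    Percentages sum to 100 when any component exists; mean x count = total
    identities hold; undefined fields are None exactly when their
    denominator is zero.  Raised on construction of every record, so any
    pipeline run exercises these checks.
    """
    n_comp = m.punctate_count + m.rod_count + m.network_count
    if n_comp > 0:
        assert m.punctate_pct is not None
        total_pct = m.punctate_pct + m.rod_pct + m.network_pct
        assert abs(total_pct - 100.0) <= atol, f"percentages sum to {total_pct}"
    else:
        assert m.punctate_pct is None and m.rod_pct is None and m.network_pct is None
    assert (m.mean_rod_length is None) == (m.rod_count == 0)
    assert (m.mean_network_branch_count is None) == (m.network_count == 0)
    assert (m.mean_network_length is None) == (m.network_count == 0)
    assert (m.mean_network_branch_length is None) == (m.total_network_branch_count == 0)
    assert (m.mean_length_all_branches is None) == (m.all_branch_count == 0)
    assert (m.mean_network_and_rod_length is None) == (m.network_count + m.rod_count == 0)
    if m.mean_network_branch_count is not None:
        assert math.isclose(
            m.mean_network_branch_count * m.network_count,
            m.total_network_branch_count, rel_tol=1e-12, abs_tol=1e-9,
        )
    if m.mean_network_branch_length is not None:
        assert math.isclose(
            m.mean_network_branch_length * m.total_network_branch_count,
            m.network_length, rel_tol=1e-12, abs_tol=1e-9,
        )


def compute_metrics(
    graph: SkeletonGraph,
    unit_id: str = "",
    pixel_size: Optional[float] = None,
    percent_basis: str = "count",
) -> MorphologyMetrics:
    """Reduce a classified skeleton graph to the morphology parameter set.

    Lengths and areas are in px / px² unless ``pixel_size`` (µm/px) is
    given.  ``percent_basis`` selects the denominator of the class
    percentages: share of component count (default) or of total length.
    """
    census = component_census(graph)
    s = 1.0 if pixel_size is None else pixel_size
    p_len = census.punctate_length * s
    r_len = census.rod_length * s
    n_len = census.network_length * s
    n_comp = census.punctate_count + census.rod_count + census.network_count
    if percent_basis == "count":
        denom = float(n_comp)
        shares = (census.punctate_count, census.rod_count, census.network_count)
    elif percent_basis == "length":
        denom = p_len + r_len + n_len
        shares = (p_len, r_len, n_len)
    else:
        raise ValueError(f"unknown percent_basis {percent_basis!r}")
    pcts = [
        _safe_div(100.0 * x, denom) if denom > 0 else None for x in shares
    ]
    tnbc = census.total_network_branch_count
    all_branches = census.punctate_count + census.rod_count + tnbc
    m = MorphologyMetrics(
        unit_id=unit_id,
        skeleton_area=graph.total_pixels * s * s,
        punctate_count=census.punctate_count,
        rod_count=census.rod_count,
        network_count=census.network_count,
        punctate_pct=pcts[0],
        rod_pct=pcts[1],
        network_pct=pcts[2],
        punctate_length=p_len,
        rod_length=r_len,
        network_length=n_len,
        mean_rod_length=_safe_div(r_len, census.rod_count),
        total_network_branch_count=tnbc,
        mean_network_branch_count=_safe_div(tnbc, census.network_count),
        mean_network_branch_length=_safe_div(n_len, tnbc),
        mean_network_length=_safe_div(n_len, census.network_count),
        all_branch_count=all_branches,
        mean_length_all_branches=_safe_div(p_len + r_len + n_len, all_branches),
        mean_network_and_rod_length=_safe_div(
            n_len + r_len, census.network_count + census.rod_count
        ),
    )
    check_invariants(m)
    return m


def normalize_metrics(m: MorphologyMetrics, kind: str, value: float) -> MorphologyMetrics:
    """Divide extensive fields by a normalizer; intensive fields unchanged."""
    if kind not in ("cell_area", "nuclei_count"):
        raise ValueError(f"unknown normalizer kind {kind!r}")
    if value <= 0:
        raise ValueError("normalizer value must be > 0")
    updates = {f: getattr(m, f) / value for f in EXTENSIVE_FIELDS}
    return replace(m, normalizer_kind=kind, normalizer_value=value, **updates)


# ---------------------------------------------------------------------------
# pipeline configuration and batch analysis

@dataclass
class PipelineConfig:
    """Knobs of the image -> metrics chain, with the published defaults."""

    clahe: ClaheParams = field(default_factory=ClaheParams)
    clahe_kernel_is_grid: bool = False
    threshold_mode: str = "global"
    threshold_window: Optional[int] = None
    prune: int = 0
    punctate_max: int = PUNCTATE_MAX_DEFAULT
    percent_basis: str = "count"
    # segmentation (differentiated cultures)
    min_diameter: float = 40.0
    max_diameter: float = 400.0
    denoise_min_feature: int = 2
    denoise_sigma: Optional[float] = None   # None -> min_diameter / 2
    exclude_border: bool = False
    max_gap: int = 5
    # nuclei normalization (clustered cultures)
    min_nucleus_area: int = 30


def skeletonize_image(img: RawImage, config: Optional[PipelineConfig] = None) -> SkeletonImage:
    """CLAHE -> Otsu -> Zhang-Suen thinning for one field."""
    config = config or PipelineConfig()
    eq = clahe(img, config.clahe, kernel_is_grid=config.clahe_kernel_is_grid)
    mask = otsu_threshold(eq, mode=config.threshold_mode, window=config.threshold_window)
    return zhang_suen_thin(mask, prune=config.prune)


def analyze_image(
    img: RawImage,
    config: Optional[PipelineConfig] = None,
    unit_id: Optional[str] = None,
) -> MorphologyMetrics:
    """Aggregate (whole-field) morphology analysis of one raw image."""
    config = config or PipelineConfig()
    skel = skeletonize_image(img, config)
    graph = build_graph(skel, punctate_max=config.punctate_max)
    return compute_metrics(
        graph,
        unit_id=unit_id if unit_id is not None else img.source_id,
        pixel_size=img.pixel_size,
        percent_basis=config.percent_basis,
    )


def analyze_field_segmented(
    img: RawImage,
    config: Optional[PipelineConfig] = None,
    seg: Optional[SegmentationLabels] = None,
) -> List[MorphologyMetrics]:
    """Per-cell analysis of one field: segment, split the field skeleton by
    cell label, and normalize each record by its cell's surface area."""
    config = config or PipelineConfig()
    skel = skeletonize_image(img, config)
    if seg is None:
        seg = identify_primary_objects(
            img,
            min_diameter=config.min_diameter,
            max_diameter=config.max_diameter,
            min_feature=config.denoise_min_feature,
            sigma=config.denoise_sigma,
            exclude_border=config.exclude_border,
        )
    records = []
    s2 = 1.0 if img.pixel_size is None else img.pixel_size**2
    for k, cell_skel in enumerate(
        assign_skeleton_to_cells(skel, seg, max_gap=config.max_gap), start=1
    ):
        graph = build_graph(cell_skel, punctate_max=config.punctate_max)
        m = compute_metrics(
            graph,
            unit_id=f"{img.source_id}_cell{k}",
            pixel_size=img.pixel_size,
            percent_basis=config.percent_basis,
        )
        records.append(normalize_metrics(m, "cell_area", float(seg.areas[k - 1]) * s2))
    return records


_NUCLEI_TAG = "_nuclei"


def analyze_batch(
    root,
    mode: str = "aggregate",
    config: Optional[PipelineConfig] = None,
) -> List[MorphologyMetrics]:
    """Analyze every readable TIFF/PNG under ``root``.

    segmented mode: one record per detected cell per field, normalized by
    cell area.  aggregate mode: one record per field, normalized by the
    nuclei count when a companion ``<stem>_nuclei.<ext>`` image exists.
    Unreadable files are skipped with a warning.
    """
    if mode not in ("segmented", "aggregate"):
        raise ValueError(f"unknown mode {mode!r}")
    config = config or PipelineConfig()
    root = Path(root)
    paths = sorted(
        p for p in root.iterdir()
        if p.suffix.lower() in (".tif", ".tiff", ".png")
        and _NUCLEI_TAG not in p.stem
    )
    if not paths:
        logger.warning("analyze_batch: no images under %s", root)
        return []
    records: List[MorphologyMetrics] = []
    for p in paths:
        try:
            img = read_image(p)
        except Exception as exc:  # noqa: BLE001 - batch robustness
            logger.warning("skipping unreadable file %s: %s", p, exc)
            continue
        if mode == "segmented":
            records.extend(analyze_field_segmented(img, config))
        else:
            m = analyze_image(img, config)
            nuc_path = None
            for ext in (p.suffix, ".tif", ".tiff", ".png"):
                cand = p.with_name(p.stem + _NUCLEI_TAG + ext)
                if cand.exists():
                    nuc_path = cand
                    break
            if nuc_path is not None:
                n = count_nuclei(
                    read_image(nuc_path, channel="nuclei"),
                    min_nucleus_area=config.min_nucleus_area,
                )
                if n > 0:
                    m = normalize_metrics(m, "nuclei_count", float(n))
            records.append(m)
    return records
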