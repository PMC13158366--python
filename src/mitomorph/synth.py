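"""Synthetic fluorescence micrograph generator with exact ground truth.

Emulates a Mitotracker-style stained field: sparse bright curvilinear and
branched structures on a dark background, rendered through a Gaussian PSF,
modulated by an uneven multiplicative illumination field, with shot (or
Gaussian) noise, quantized to 8 or 16 bits.  Every generated object is
recorded with its class (punctate / rod / network), generating polylines,
geometric length and branch count, so each pipeline stage can be verified
against exact truth.

Object models
-------------
* punctate — a single PSF spot (a dot);
* rod — a straight or gently curved polyline, drawn at ~2-3 px stroke width;
* network — a star-shaped tree: ``k`` branch polylines radiating from one
  junction point with a minimum angular separation so branches stay
  distinguishable after blurring.

An FCCP-like fragmentation transform derives a "stressed" scene from a
generated one: a chosen fraction of rods is replaced by pairs/triples of
punctates (each carrying an equal share of the parent rod's length in the
bookkeeping), and networks with >= 4 branches shed one branch, which
becomes a free rod.  Total bookkept length is conserved exactly while the
object count rises, so mean object length falls — the direction of the
fragmentation response to a mitochondrial uncoupler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi

from .image_io import RawImage


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed under the separation constraint;
    use a larger image or fewer objects."""


@dataclass
class ObjectShape:
    """An object's geometry as origin-centered polylines.

    For punctates the single polyline is one point; ``nominal_length``
    carries bookkept length (equal to the geometric polyline length for
    generated objects; fragmentation-derived punctates carry their share of
    the parent rod instead).
    """

    klass: str                       # "punctate" | "rod" | "network"
    polylines: List[np.ndarray]      # each (N, 2) float array of (row, col)
    nominal_length: float

    @property
    def branch_count(self) -> int:
        return len(self.polylines) if self.klass == "network" else 1

    def geometric_length(self) -> float:
        return float(
            sum(
                np.sqrt(((pl[1:] - pl[:-1]) ** 2).sum(axis=1)).sum()
                for pl in self.polylines
                if len(pl) > 1
            )
        )


@dataclass
class GroundTruthObject:
    klass: str
    polylines: List[np.ndarray]      # placed, image coordinates
    length: float                    # bookkept (nominal) length, px
    branch_count: int
    centroid: Tuple[float, float]
    cell_index: int = 0


@dataclass
class SyntheticGroundTruth:
    objects: List[GroundTruthObject]
    stroke_mask: np.ndarray                    # rendered pre-PSF foreground
    cell_labels: Optional[np.ndarray] = None   # multi-cell fields only
    nuclei_count: int = 0

    def count(self, klass: str) -> int:
        return sum(1 for o in self.objects if o.klass == klass)

    @property
    def n_punctates(self) -> int:
        return self.count("punctate")

    @property
    def n_rods(self) -> int:
        return self.count("rod")

    @property
    def n_networks(self) -> int:
        return self.count("network")

    def total_length(self) -> float:
        return sum(o.length for o in self.objects)


@dataclass
class SceneSpec:
    """Study conditions for one synthetic field.

    Defaults model a 16-bit monochrome-CCD fluorescence export: background
    ~200 counts of shot-noise-limited signal, stained structures ~3000
    counts above it (SNR ~ 50), a 1.5 px PSF sigma and a 1 + 0.5*planar
    multiplicative illumination gradient.  The 16-bit range matters: the
    256-bin CLAHE of the binarization chain resolves intensity in steps of
    1/256 of the range, so background shot noise (sd ~ 14 counts of 65535)
    stays within one bin and is not amplified — the regime in which
    CLAHE -> Otsu is well-posed, as on real exports.  When ``objects`` is
    given, those explicit shapes are placed instead of sampling counts from
    the ranges.
    """

    image_shape: Tuple[int, int] = (512, 512)
    n_punctates: int = 10
    n_rods: int = 10
    rod_length_range: Tuple[float, float] = (20.0, 40.0)
    n_networks: int = 3
    branches_per_network_range: Tuple[int, int] = (3, 5)
    branch_length_range: Tuple[float, float] = (12.0, 25.0)
    psf_sigma: float = 1.5
    background_level: float = 200.0
    amplitude: float = 3000.0
    noise_model: str = "poisson"          # "poisson" | "gaussian" | "none"
    gaussian_sd: float = 30.0
    illumination_gradient: float = 0.5    # field = 1 + g * planar ramp
    min_separation: int = 12
    bit_depth: int = 16
    rng_seed: int = 0
    objects: Optional[List[ObjectShape]] = None

    def __post_init__(self) -> None:
        if self.min_separation < 2 * (3 * self.psf_sigma):
            raise ValueError(
                "min_separation must be >= 2 * (3 * psf_sigma) to keep "
                "components distinct after thresholding"
            )
        for rng in (self.rod_length_range, self.branch_length_range):
            if rng[0] <= 0 or rng[1] < rng[0]:
                raise ValueError(f"invalid range {rng}")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")


# ---------------------------------------------------------------------------
# geometry sampling

def _polyline_length(pl: np.ndarray) -> float:
    if len(pl) < 2:
        return 0.0
    return float(np.sqrt(((pl[1:] - pl[:-1]) ** 2).sum(axis=1)).sum())


def _curved_polyline(rng: np.random.Generator, length: float, theta: float,
                     curvature_max: float = 0.015) -> np.ndarray:
    """Unit-step polyline of given arc length with gentle random curvature."""
    kappa = rng.uniform(-curvature_max, curvature_max)
    n = max(2, int(round(length)) + 1)
    pts = np.empty((n, 2))
    r, c = 0.0, 0.0
    pts[0] = (r, c)
    step = length / (n - 1)
    for i in range(1, n):
        r += step * math.sin(theta)
        c += step * math.cos(theta)
        theta += kappa * step
        pts[i] = (r, c)
    return pts - pts.mean(axis=0)


def _sample_shape(rng: np.random.Generator, klass: str, spec: SceneSpec) -> ObjectShape:
    if klass == "punctate":
        return ObjectShape("punctate", [np.zeros((1, 2))], 0.0)
    if klass == "rod":
        length = rng.uniform(*spec.rod_length_range)
        pl = _curved_polyline(rng, length, rng.uniform(0, 2 * math.pi))
        return ObjectShape("rod", [pl], _polyline_length(pl))
    if klass == "network":
        k = int(rng.integers(spec.branches_per_network_range[0],
                             spec.branches_per_network_range[1] + 1))
        # radiate k branches from the origin; the angular-separation floor
        # scales with k so adjacent arms stay resolvable after the PSF —
        # arms closer than ~50 degrees merge near the root once rendered,
        # which would displace the junction and split it in two
        base = rng.uniform(0, 2 * math.pi)
        angles = base + np.sort(rng.uniform(0, 2 * math.pi, size=k))
        min_sep = max(math.radians(40), 0.75 * 2 * math.pi / k)
        for _ in range(200):
            gaps = np.diff(np.concatenate([angles, [angles[0] + 2 * math.pi]]))
            if gaps.min() >= min_sep:
                break
            angles = base + np.sort(rng.uniform(0, 2 * math.pi, size=k))
        polylines = []
        for ang in angles:
            length = rng.uniform(*spec.branch_length_range)
            n = max(2, int(round(length)) + 1)
            t = np.linspace(0, length, n)
            pl = np.stack([t * math.sin(ang), t * math.cos(ang)], axis=1)
            polylines.append(pl)
        total = sum(_polyline_length(p) for p in polylines)
        return ObjectShape("network", polylines, total)
    raise ValueError(f"unknown class {klass!r}")


# ---------------------------------------------------------------------------
# rasterization and placement

_CROSS = np.array([(0, 0), (1, 0), (0, 1), (1, 1)])  # 2x2 footprint: 2 px stroke


def _stroke_pixels(polylines: Sequence[np.ndarray]) -> np.ndarray:
    """Integer pixels of polylines dilated to a 2 px stroke width."""
    pts = []
    for pl in polylines:
        if len(pl) == 1:
            pts.append(pl)
            continue
        seg = np.sqrt(((pl[1:] - pl[:-1]) ** 2).sum(axis=1))
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        dense_t = np.arange(0, arc[-1], 0.4)
        pts.append(np.stack([
            np.interp(dense_t, arc, pl[:, 0]),
            np.interp(dense_t, arc, pl[:, 1]),
        ], axis=1))
        pts.append(pl[-1:])
    allpts = np.rint(np.concatenate(pts)).astype(int)
    dil = (allpts[:, None, :] + _CROSS[None, :, :]).reshape(-1, 2)
    return np.unique(dil, axis=0)


def _place_objects(
    rng: np.random.Generator,
    shapes: Sequence[ObjectShape],
    spec: SceneSpec,
    allowed: Optional[np.ndarray] = None,
    max_attempts: int = 300,
) -> Tuple[List[GroundTruthObject], np.ndarray]:
    """Rejection-sample non-overlapping placements honoring min_separation.

    ``allowed`` optionally restricts stroke pixels to a region (e.g. a cell
    disk).  Returns placed truth objects and the union stroke mask.
    """
    h, w = spec.image_shape
    margin = int(math.ceil(3 * spec.psf_sigma)) + 2
    blocked = np.zeros((h, w), dtype=bool)
    stroke_mask = np.zeros((h, w), dtype=bool)
    placed: List[GroundTruthObject] = []
    if allowed is not None:
        ar, ac = np.nonzero(allowed)
        if len(ar) == 0:
            raise PlacementError("allowed region is empty")
        rlo_a, rhi_a = int(ar.min()), int(ar.max())
        clo_a, chi_a = int(ac.min()), int(ac.max())
    order = sorted(range(len(shapes)),
                   key=lambda i: -shapes[i].geometric_length())
    results: List[Optional[GroundTruthObject]] = [None] * len(shapes)
    for idx in order:
        shape = shapes[idx]
        local = _stroke_pixels(shape.polylines)
        lo, hi = local.min(axis=0), local.max(axis=0)
        rlo, rhi = margin - lo[0], h - margin - hi[0]
        clo, chi = margin - lo[1], w - margin - hi[1]
        if allowed is not None:
            rlo, rhi = max(rlo, rlo_a - lo[0]), min(rhi, rhi_a - hi[0] + 1)
            clo, chi = max(clo, clo_a - lo[1]), min(chi, chi_a - hi[1] + 1)
        if rhi <= rlo or chi <= clo:
            raise PlacementError(
                "cannot place all objects: use a larger image or fewer objects"
            )
        ok = False
        for _ in range(max_attempts):
            cr = rng.integers(rlo, rhi)
            cc = rng.integers(clo, chi)
            px = local + (cr, cc)
            if allowed is not None and not allowed[px[:, 0], px[:, 1]].all():
                continue
            if blocked[px[:, 0], px[:, 1]].any():
                continue
            ok = True
            break
        if not ok:
            raise PlacementError(
                "cannot place all objects: use a larger image or fewer objects"
            )
        stroke_mask[px[:, 0], px[:, 1]] = True
        # block a min_separation-wide halo around this object's stroke
        pad = spec.min_separation + 1
        r0 = max(0, lo[0] + cr - pad)
        r1 = min(h, hi[0] + cr + pad + 1)
        c0 = max(0, lo[1] + cc - pad)
        c1 = min(w, hi[1] + cc + pad + 1)
        patch = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        patch[px[:, 0] - r0, px[:, 1] - c0] = True
        halo = ndi.distance_transform_edt(~patch) <= spec.min_separation
        blocked[r0:r1, c0:c1] |= halo
        placed_polys = [pl + (cr, cc) for pl in shape.polylines]
        centroid = np.concatenate(placed_polys).mean(axis=0)
        results[idx] = GroundTruthObject(
            klass=shape.klass,
            polylines=placed_polys,
            length=shape.nominal_length,
            branch_count=shape.branch_count,
            centroid=(float(centroid[0]), float(centroid[1])),
        )
    for r in results:
        placed.append(r)
    return placed, stroke_mask


def _illumination_field(shape: Tuple[int, int], gradient: float) -> np.ndarray:
    h, w = shape
    rr, cc = np.meshgrid(np.linspace(0, 1, h), np.linspace(0, 1, w), indexing="ij")
    return 1.0 + gradient * (rr + cc) / 2.0


def _render(
    stroke_mask: np.ndarray,
    spec: SceneSpec,
    rng: np.random.Generator,
    extra_background: Optional[np.ndarray] = None,
) -> np.ndarray:
    signal = stroke_mask.astype(np.float64) * spec.amplitude
    signal = ndi.gaussian_filter(signal, spec.psf_sigma)
    photons = spec.background_level + signal
    if extra_background is not None:
        photons = photons + extra_background
    photons = photons * _illumination_field(spec.image_shape, spec.illumination_gradient)
    if spec.noise_model == "poisson":
        noisy = rng.poisson(photons).astype(np.float64)
    elif spec.noise_model == "gaussian":
        noisy = photons + rng.normal(0.0, spec.gaussian_sd, size=photons.shape)
    elif spec.noise_model == "none":
        noisy = photons
    else:
        raise ValueError(f"unknown noise model {spec.noise_model!r}")
    hi = 2**spec.bit_depth - 1
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    return np.clip(np.rint(noisy), 0, hi).astype(dtype)


def _scene_shapes(rng: np.random.Generator, spec: SceneSpec) -> List[ObjectShape]:
    if spec.objects is not None:
        return list(spec.objects)
    shapes = [_sample_shape(rng, "network", spec) for _ in range(spec.n_networks)]
    shapes += [_sample_shape(rng, "rod", spec) for _ in range(spec.n_rods)]
    shapes += [_sample_shape(rng, "punctate", spec) for _ in range(spec.n_punctates)]
    return shapes


def generate_scene(spec: SceneSpec) -> Tuple[RawImage, SyntheticGroundTruth]:
    """Generate one field and its exact ground truth; bitwise-reproducible
    from ``spec.rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    shapes = _scene_shapes(rng, spec)
    objects, stroke_mask = _place_objects(rng, shapes, spec)
    pixels = _render(stroke_mask, spec, rng)
    img = RawImage(
        pixels=pixels,
        bit_depth=spec.bit_depth,
        channel="mito",
        source_id=f"synthetic_seed{spec.rng_seed}",
    )
    return img, SyntheticGroundTruth(objects=objects, stroke_mask=stroke_mask)


# ---------------------------------------------------------------------------
# FCCP-like fragmentation

def fccp_transform(
    truth_or_spec,
    fragmentation: float,
    spec: Optional[SceneSpec] = None,
) -> SceneSpec:
    """Derive a fragmented ("uncoupler-treated") scene spec.

    A ``fragmentation`` fraction of rods is replaced by 2-3 punctates, each
    bookkeeping an equal share of the parent rod's length; the same fraction
    of networks with >= 4 branches sheds its last branch, which becomes a
    free rod.  Total bookkept length is conserved exactly; object count
    rises, so mean object length strictly decreases whenever any rod splits
    or branch detaches.  ``fragmentation=0`` returns the scene unchanged.
    """
    if isinstance(truth_or_spec, SceneSpec):
        base_spec = truth_or_spec
        rng = np.random.default_rng(base_spec.rng_seed)
        shapes = _scene_shapes(rng, base_spec)
    else:
        truth: SyntheticGroundTruth = truth_or_spec
        if spec is None:
            raise ValueError("pass the SceneSpec alongside a ground truth")
        base_spec = spec
        shapes = [
            ObjectShape(
                klass=o.klass,
                polylines=[pl - np.concatenate(o.polylines).mean(axis=0)
                           for pl in o.polylines],
                nominal_length=o.length,
            )
            for o in truth.objects
        ]
    if not (0 <= fragmentation <= 1):
        raise ValueError("fragmentation must be in [0, 1]")
    if fragmentation == 0:
        return replace(base_spec, objects=shapes)

    rng = np.random.default_rng((base_spec.rng_seed * 2654435761 + 17) % 2**31)
    rods = [i for i, s in enumerate(shapes) if s.klass == "rod"]
    nets = [i for i, s in enumerate(shapes) if s.klass == "network"
            and len(s.polylines) >= 4]
    n_split = int(round(fragmentation * len(rods)))
    if fragmentation > 0 and rods and n_split == 0:
        n_split = 1
    split_idx = set(rng.choice(rods, size=n_split, replace=False)) if n_split else set()
    n_detach = int(round(fragmentation * len(nets)))
    detach_idx = set(rng.choice(nets, size=n_detach, replace=False)) if n_detach else set()

    derived: List[ObjectShape] = []
    for i, s in enumerate(shapes):
        if i in split_idx:
            k = int(rng.integers(2, 4))  # pair or triple
            for _ in range(k):
                derived.append(
                    ObjectShape("punctate", [np.zeros((1, 2))], s.nominal_length / k)
                )
        elif i in detach_idx:
            kept, detached = s.polylines[:-1], s.polylines[-1]
            kept_len = sum(_polyline_length(p) for p in kept)
            derived.append(ObjectShape("network", [p.copy() for p in kept], kept_len))
            rod_pl = detached - detached.mean(axis=0)
            derived.append(ObjectShape("rod", [rod_pl], _polyline_length(detached)))
        else:
            derived.append(s)
    counts = {"punctate": 0, "rod": 0, "network": 0}
    for s in derived:
        counts[s.klass] += 1
    return replace(
        base_spec,
        objects=derived,
        n_punctates=counts["punctate"],
        n_rods=counts["rod"],
        n_networks=counts["network"],
    )


# ---------------------------------------------------------------------------
# multi-cell fields

def generate_multicell_field(
    n_cells: int,
    cell_spec: SceneSpec,
    cell_radius: float = 80.0,
    gap: float = 40.0,
    with_nuclei: bool = False,
    image_shape: Tuple[int, int] = (600, 800),
    cell_background: float = 25.0,
) -> Tuple[RawImage, Optional[RawImage], SyntheticGroundTruth]:
    """Generate a field of spatially separated cells (plus optional nuclei).

    Cells are disjoint disks of elevated background, each containing its own
    scene objects drawn from ``cell_spec``; the nuclei channel renders one
    blurred bright disk per cell.  Cell centers are placed with rejection
    sampling at pairwise distance >= 2*cell_radius + gap.
    """
    rng = np.random.default_rng(cell_spec.rng_seed)
    h, w = image_shape
    margin = cell_radius + 6
    centers: List[Tuple[float, float]] = []
    for _ in range(n_cells):
        ok = False
        for _ in range(500):
            r = rng.uniform(margin, h - margin)
            c = rng.uniform(margin, w - margin)
            if all(math.hypot(r - r0, c - c0) >= 2 * cell_radius + gap
                   for r0, c0 in centers):
                centers.append((r, c))
                ok = True
                break
        if not ok:
            raise PlacementError("cell layout does not fit: enlarge the image")

    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    cell_labels = np.zeros((h, w), dtype=np.int32)
    extra_bg = np.zeros((h, w), dtype=np.float64)
    for k, (r0, c0) in enumerate(centers, start=1):
        disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= cell_radius**2
        cell_labels[disk] = k
        extra_bg[disk] += cell_background

    field_spec = replace(cell_spec, image_shape=image_shape)
    all_objects: List[GroundTruthObject] = []
    stroke_mask = np.zeros((h, w), dtype=bool)
    # keep objects in the cytoplasm proper, off the cell rim: the rim band
    # is both biologically implausible for mitochondria and outside what an
    # intensity threshold of the blurred cell recovers as the cell region
    inner_margin = max(12.0, cell_radius / 5.0) + 3 * cell_spec.psf_sigma
    for k, (r0, c0) in enumerate(centers, start=1):
        shapes = _scene_shapes(rng, cell_spec)
        allowed = (rr - r0) ** 2 + (cc - c0) ** 2 <= (cell_radius - inner_margin) ** 2
        objs, strokes = _place_objects(rng, shapes, field_spec, allowed=allowed)
        for o in objs:
            o.cell_index = k
        all_objects.extend(objs)
        stroke_mask |= strokes

    pixels = _render(stroke_mask, field_spec, rng, extra_background=extra_bg)
    mito = RawImage(
        pixels=pixels,
        bit_depth=cell_spec.bit_depth,
        channel="mito",
        source_id=f"synthetic_multicell_seed{cell_spec.rng_seed}",
    )
    nuclei_img: Optional[RawImage] = None
    if with_nuclei:
        nuc = np.zeros((h, w), dtype=np.float64)
        nucleus_radius = max(6.0, cell_radius / 4.0)
        for r0, c0 in centers:
            jr = r0 + rng.uniform(-cell_radius / 6, cell_radius / 6)
            jc = c0 + rng.uniform(-cell_radius / 6, cell_radius / 6)
            disk = (rr - jr) ** 2 + (cc - jc) ** 2 <= nucleus_radius**2
            nuc[disk] = cell_spec.amplitude
        nuc = ndi.gaussian_filter(nuc, 2.0) + cell_spec.background_level
        noisy = rng.poisson(nuc).astype(np.float64)
        hi = 2**cell_spec.bit_depth - 1
        dtype = np.uint8 if cell_spec.bit_depth == 8 else np.uint16
        nuclei_img = RawImage(
            pixels=np.clip(np.rint(noisy), 0, hi).astype(dtype),
            bit_depth=cell_spec.bit_depth,
            channel="nuclei",
            source_id=f"synthetic_nuclei_seed{cell_spec.rng_seed}",
        )
    truth = SyntheticGroundTruth(
        objects=all_objects,
        stroke_mask=stroke_mask,
        cell_labels=cell_labels,
        nuclei_count=n_cells if with_nuclei else 0,
    )
    return mito, nuclei_img, truth
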