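# Methods

This note documents the models, numerical choices and known limitations of
the `mitomorph` pipeline and its synthetic-data generator. It states no
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Binarization chain

**CLAHE.** Contrast-limited adaptive histogram equalization evens the
illumination of widefield fluorescence images before thresholding. The
defaults are a 10×10-pixel contextual region, a clip limit of 0.02
(fraction of the region's pixel count per histogram bin) and 256 bins.
Implementations disagree about whether such a "kernel size" names a region
in pixels or a tile grid; both readings are supported
(`clahe(..., kernel_is_grid=True)` divides the image into 10×10 tiles) and
the pixel reading is the default. A flat (constant) image is returned
unchanged — equalizing a one-bin histogram is the identity, where the
underlying implementation would dither at a bin boundary.

CLAHE's regime of validity matters: with 256 bins the intensity resolution
is 1/256 of the dtype range, so background noise narrower than one bin is
compacted, while noise spanning several bins is *amplified* — local
equalization stretches pure-background tiles to full contrast, and no
global threshold can then separate sparse foreground. On 16-bit camera
exports (bin width 256 counts against a shot-noise sd of ~14 at a
200-count background) the chain is well-posed; the same scene quantized to
8 bits is not. This is why the generator's default bit depth is 16 (see
below) and why object detection also runs on CLAHE-corrected data.

**Otsu threshold.** The global threshold maximizes the between-class
variance ω₀ω₁(μ₀−μ₁)² by exhaustive scan over every integer candidate
(all 65535 for 16-bit input — no rebinning), ties broken toward the
smallest threshold; foreground is strictly above the threshold. A constant
image has no 2-class split and raises a degenerate-input error. The
`adaptive` mode computes Otsu per overlapping window (default 40 px, 4× the
CLAHE kernel) on a half-overlap grid and interpolates a per-pixel threshold
surface bilinearly between window centers, with edges clamped; windows with
fewer than two distinct values inherit the global threshold. After CLAHE
normalization the global mode is well-posed and is the default.

Otsu's bimodality assumption fails when one class nearly vanishes: below
roughly 0.2% foreground (e.g. a handful of dots on a 512² field) the
threshold falls inside the background mode. Test scenes with very few
objects therefore use proportionally smaller fields.

## Thinning

Classic Zhang–Suen two-subiteration thinning is applied verbatim: pixel p
with clockwise 8-neighbors p2..p9, B(p) foreground neighbors, A(p) the
0→1 transitions around the cycle; subpass 1 deletes iff 2 ≤ B ≤ 6, A = 1,
p2·p4·p6 = 0 and p4·p6·p8 = 0; subpass 2 with the conditions rotated
(p2·p4·p8 = 0, p2·p6·p8 = 0); deletions are simultaneous within a subpass;
the border is background; iteration runs to a fixpoint.

The raw fixpoint violates the contracts the rest of the pipeline depends
on, in four documented ways, each handled by a deterministic post-pass:

1. **Two-pixel diagonal ribbons** (which the subpasses cannot thin) and
   staircase residue, including occasional fully-set 2×2 blocks. A
   minimal-skeleton sweep deletes, in (row, col) scan order to a fixpoint,
   every pixel with ≥3 neighbors whose foreground neighbors remain mutually
   8-connected without it (a local simple-point test). The degree floor is
   essential: an unrestricted simple-point sweep cascades along a ribbon
   and consumes whole rods.
2. **Bump triangles** — a pixel whose two neighbors are mutually adjacent,
   one of them carrying a third neighbor — read as spurious junction pairs
   on diagonal lines; a companion rule collapses them.
3. **X-type crossings** leave an irreducible 2×2 block with four strands
   attached diagonally; no deletion preserves connectivity. The block is
   rectified by swapping one diagonal pair for "elbow" pixels taken from
   the source mask, so the skeleton stays a subset of the mask at
   one-pixel width with unchanged topology.
4. **Erased components** — an isolated 2×2 block is deleted in a single
   pass, and small round blobs can erode to that state and vanish. Each
   lost mask component is re-seeded as one pixel at its most interior
   point (distance-transform argmax), preserving the component count.

One known bias remains: near-45° bands erode from their ends, shortening
the measured skeleton of diagonal rods by up to ~20–30% in the worst
orientation-width combinations; across 100 random scenes the pooled mean
rod-length error is well inside 15% (recomputed by the acceptance script),
with a rare single-scene excursion above it.

An optional spur-pruning pass removes terminal branches of at most k
pixels (default off, `prune=0`); it deletes a chain walked from an
endpoint only if a junction is reached within k steps, so whole rods are
never consumed.

## Skeleton graph and classification

Components are 8-connected. Pixel degree is counted after suppressing
redundant diagonal edges — a diagonal adjacency that an axial two-step
path already covers. Without suppression the first pixel of every
axis-aligned branch has three raw neighbors and becomes a spurious
junction, truncating each branch by one step; suppression cannot
disconnect anything because the axial path remains. Endpoints have degree
1; degree ≥3 pixels are junction pixels, and mutually 8-adjacent junction
pixels merge into one junction cluster. Branches are traced from every
node through degree-2 chains, with length 1 per axial and √2 per diagonal
step; enumeration order is fixed by (row, col) scan order. Isolated pixels
are single branches of length 0; a closed loop with no nodes is one cycle
branch.

Classification: **network** iff the component has a junction cluster (a
node-free cycle is also classed network, by convention, with its single
cycle branch); otherwise **rod** if the component exceeds `punctate_max`
pixels and **punctate** if not. `punctate_max` defaults to 3 px — a
skeleton object of ≤3 pixels has no meaningful length and renders as a
dot at typical 40× magnification; the boundary is configurable because it
is a convention, not a measurement.

A genuine resolution limit: when two arms of a branch point subtend a
small angle, their rendered tubules merge near the root, the thinned
junction splits into two nearby Y-junctions, and the short segment between
them counts as an extra branch. Class assignment is unaffected (the
component still has junctions); per-network branch counts can be inflated
by one in such geometries.

## Morphology metrics

For one analysis unit (a segmented cell or a whole field), with P/R/N the
punctate/rod/network component sets:

| parameter | definition |
|---|---|
| skeleton_area | total skeleton pixels (×pixel_size² when known) |
| punctate/rod/network_count | class cardinalities |
| class percentages | 100·count/total components (count basis, default) |
| class lengths | summed component lengths per class |
| mean_rod_length | rod_length / rod_count |
| total_network_branch_count | Σ branches over networks |
| mean_network_branch_count | total_network_branch_count / network_count |
| mean_network_branch_length | network_length / total_network_branch_count |
| mean_network_length | network_length / network_count |
| all_branch_count | punctate_count + rod_count + total_network_branch_count |
| mean_length_all_branches | total length / all_branch_count |
| mean_network_and_rod_length | (network_length + rod_length) / (network_count + rod_count) |

Percentages use the component-count denominator because the percentages
are reported beside the counts; a length-weighted basis is selectable
(`percent_basis="length"`). Any mean with a zero denominator is missing
(empty CSV cell), never 0. These definitional identities are asserted
inside every `compute_metrics` call.

Normalization divides the extensive fields (area, the three counts, the
three class lengths, both branch totals) by the cell surface area (label
area, px² or µm²) in segmented mode or by the nuclei count in aggregate
mode; percentages and means are intensive and unchanged. Per-cell records
are produced by masking the field skeleton with the cell label — not by
re-thinning per cell — so segmented and aggregate analyses of one field
agree up to the straddle rule: skeleton pixels on background are assigned
to the nearest cell within `max_gap` (default 5 px) and dropped beyond it.

## Segmentation and nuclei counting

Cell detection uses only the mito channel: CLAHE (without illumination
correction, a strong gradient can raise far-corner background above
near-corner cells and defeat any global threshold), grayscale opening
(disk radius 2) plus Gaussian blur, global Otsu, hole filling, then a
watershed on the smoothed distance transform seeded at regional maxima,
and a size filter on the equivalent diameter. Defaults: diameters 40–400
px (a convention tuned on the synthetic fixtures, exposed in config), blur
sigma = min_diameter/2 so one cell blurs into one blob, declump peak
separation = 1.5·min_diameter. Nothing surviving the filter yields K = 0
with a warning, not an exception. Nuclei are counted with the same
threshold–watershed chain (blur sigma 2, minimum area 30 px²).

## Synthetic micrograph generator

The generator emulates a stained live-cell field as captured by a
monochrome CCD at 40×: sparse bright curvilinear/branched structures on a
dark background. Defaults (the study conditions of every verification
experiment):

| parameter | default | rationale |
|---|---|---|
| image | 512×512, 16-bit | CCD export; CLAHE well-posed (above) |
| background | 200 counts | dark current + haze |
| amplitude | 3000 counts | bright stain; SNR ≈ 50 vs background shot noise |
| noise | Poisson | shot-noise-limited detection |
| illumination | 1 + 0.5·planar ramp | exercises CLAHE meaningfully |
| PSF sigma | 1.5 px | diffraction-limited width at 40×/0.65 |
| stroke width | 2 px | tubule width before PSF |
| rods | length 20–40 px, gentle curvature (≤0.015 rad/px) | |
| networks | 3–5 branches of 12–25 px radiating from a root | |
| min_separation | 12 px (≥ 2·3·psf_sigma) | components stay distinct |

Placement is rejection sampling against a blocked mask (each placed
object's stroke dilated by `min_separation`); failure after bounded
retries raises a capacity error. Network arms keep an angular separation
of at least max(40°, 0.75·360°/k) — arms closer than ~50° merge near the
root once rendered and split the junction (above). In multi-cell fields,
cells are disjoint disks of elevated background (+25 counts) at pairwise
center distance ≥ 2·radius + gap, objects are placed in the cytoplasm
proper (a rim band of ~max(12, radius/5) px is kept clear — mitochondria
at the membrane are both implausible and outside what thresholding the
blurred cell recovers), and the nuclei channel renders one blurred disk
per cell.

The FCCP-style transform derives a fragmented scene: a fraction f of rods
is replaced by 2–3 punctates each carrying an equal share of the parent
rod's length in the bookkeeping (rendered as dots — a dot has no drawn
length, so conservation is a property of the bookkept inventory, which is
conserved exactly), and the same fraction of networks with ≥4 branches
sheds its last branch as a free rod. Object count rises at constant total
bookkept length, so mean object length strictly decreases; rendered and
measured, punctate count rises and mean branch length falls — the
direction of a fragmentation response, with no claim on magnitude.

What the generator does **not** emulate: out-of-focus haze and z-structure,
photobleaching, tubule brightness variation along the length, curved or
non-disk cell outlines, touching cells, debris, and camera fixed-pattern
noise. Passing the recovery experiments therefore demonstrates the
pipeline's correctness on images satisfying its assumptions — sparse,
in-focus, shot-noise-limited fields — not its robustness to every real
micrograph.

## Statistics

Descriptives are mean ± SD (n−1). Two groups: two-sided unpaired t-test,
pooled variance by default (the homoscedastic companion of ANOVA + Tukey),
Welch by flag. Three or more: one-way ANOVA, then Tukey's HSD with
adjusted p-values from the studentized-range distribution over all pairs
(Tukey–Kramer standard errors for unequal n). Significance is strict:
p < alpha, default 0.05. Zero within-group variance everywhere is reported
as p = 0 (unequal means) or p = 1 (equal) with a `degenerate` flag. The
test suite pins t, F and every Tukey p to an independent closed-form /
direct numerical-integration oracle at 1e-8; no multiple-testing
correction is applied across metrics, matching the reporting convention
the pipeline feeds.

## Problem sizes

The verification experiments run at: 1000 histograms (threshold oracle),
200 rendered masks (thinning contracts), 100 scenes (census recovery; also
fragmentation direction), 100 rods-only scenes (length recovery), 4
three-cell fields (conservation), 50 fields each for segmentation accuracy
and nuclei counting, and 12 fields per arm for the fragmentation
significance test — sizes chosen so each estimate is stable at the
percentage resolution reported.
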