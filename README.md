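# mitomorph

Quantification of mitochondrial network morphology from fluorescence
micrographs.

Mitochondria continually fuse and divide; the balance shows up in their
shapes. A fragmented (fission-dominated) population appears as dots and
short tubules, a fused one as long branched networks, and disease states or
uncoupler treatment (e.g. FCCP) shift this balance. `mitomorph` turns a
single-channel micrograph of a mitochondrial stain (Mitotracker-style) into
a per-cell or per-field table of morphology parameters, for people who need
those numbers: cell biologists comparing patient-derived lines, screeners
quantifying drug responses, and method developers who want a skeleton
pipeline they can verify end to end.

## Pipeline

1. **Illumination correction** — CLAHE (contrast-limited adaptive histogram
   equalization) with a 10×10-pixel contextual region, clip limit 0.02 and
   256 bins.
2. **Binarization** — Otsu's threshold `t* = argmax_t ω₀(t)ω₁(t)(μ₀(t)−μ₁(t))²`,
   computed exactly over every integer intensity (a windowed adaptive
   variant is available).
3. **Skeletonization** — Zhang–Suen two-subiteration thinning to a
   one-pixel-wide skeleton, with deterministic staircase/junction cleanup
   so the width and topology contracts hold.
4. **Skeleton graph** — 8-connected components; endpoints (1 neighbor) and
   junction clusters (≥3 neighbors, merged); branches traced between nodes
   with geodesic length (1 per axial step, √2 per diagonal step). Each
   component is classified **punctate** (no junctions, ≤3 px), **rod** (no
   junctions, >3 px) or **network** (≥1 junction).
5. **Metrics** — the 18-parameter record per analysis unit: skeleton area,
   class counts and percentages, class lengths, mean rod length, network
   branch counts and lengths, `all_branch_count`, mean length of all
   branches, and mean network-and-rod length. Extensive parameters can be
   normalized by cell surface area (segmented mode) or nuclei count
   (aggregate mode for clustered colonies).
6. **Statistics** — mean ± SD, unpaired t-test (pooled by default) or
   one-way ANOVA with Tukey's HSD post-hoc, significance at p < 0.05.

For spatially separated cells the field is segmented from the mito channel
alone (blur → Otsu → hole filling → distance-transform watershed
declumping → size filter) and the field skeleton is split per cell.

A synthetic-micrograph generator (`mitomorph.synth`) renders scenes of
punctates, rods and branched networks through a Gaussian PSF with uneven
illumination and shot noise, with an exact ground-truth inventory — every
stage of the pipeline is verifiable without external data. An
FCCP-style `fccp_transform` derives a fragmented version of any scene.

## Worked example

```python
from mitomorph import SceneSpec, generate_scene, analyze_image

spec = SceneSpec(rng_seed=0, n_punctates=8, n_rods=8, n_networks=2)
image, truth = generate_scene(spec)          # 512x512 16-bit field + truth
m = analyze_image(image)                     # CLAHE -> Otsu -> thin -> graph
print(m.punctate_count, m.rod_count, m.network_count)
print(round(m.mean_rod_length, 2), round(m.mean_network_branch_count, 2))
```

prints

```
8 8 2
23.38 5.0
```

— the pipeline recovered all 8 punctates, 8 rods and 2 networks of the
generated scene; the measured mean rod length (23.38 px) sits within the
drawn 20–40 px range, and the average network carries 5 branches.

The same from the command line:

```bash
mitomorph synth fields --n-fields 3 --seed 0      # TIFFs + ground truth CSV
mitomorph analyze fields metrics.csv --mode aggregate
mitomorph skeletonize fields/field000.tif skeleton.tif
mitomorph compare metrics_with_groups.csv --group-col group
```

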