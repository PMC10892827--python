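# nanopsd

Particle size and shape analysis for transmission electron microscopy (TEM)
micrographs of biogenic nanoparticles — the few-nanometre gold and cerium
particles that cyanobacteria such as *Anabaena* sp. and *Calothrix
desertica* form intracellularly.  Detecting such particles is hard: they
are 2–12 nm across, often amorphous and low-contrast, and embedded in
cellular material whose gray values overlap theirs.  `nanopsd` implements
the digital image-processing chain used for this problem and packages it
with a synthetic micrograph generator, so that every stage can be verified
against exact ground truth.

## What it computes

Given a calibrated 8-bit bright-field micrograph (nm/px from the scale
bar), the pipeline runs:

1. **Preprocessing** — optional crop, mean-filter smoothing, unsharp-mask
   sharpening.
2. **Segmentation** — histogram-percentile thresholding (TH % of the gray
   histogram; dark pixels are foreground), connected components (8-conn by
   default), interior-hole filling, exclusion of edge-touching components,
   and size restriction in px and nm².
3. **Morphometry** per particle of area *A* (px count × px area):

   - equivalent circular diameter `ECD = √(4A/π)`;
   - a second-central-moment ellipse fit with full axes *a* ≥ *b*,
     rescaled so the ellipse area equals *A*;
   - maximum Feret (caliper) diameter `D_f` over the convex hull of the
     pixel corners;
   - reciprocal aspect ratio `RAR = b/a ∈ (0, 1]`;
   - Feret major-axis ratio `FMR = D_f / a`;
   - a six-class roundness label from RAR
     (very angular 0.12–0.17 · angular 0.17–0.25 · sub-angular 0.25–0.35 ·
     sub-rounded 0.35–0.49 · rounded 0.49–0.70 · very rounded 0.70–1.00).

4. **Distributions** — global and windowed (default 500 × 500 nm²) particle
   size distributions: N, mean ± SE, fixed-width histogram with cumulative
   percentage, 10/25/75/90th percentiles, shape-class breakdown.
5. **Quality control** — the same specimen scene imaged at several
   magnifications is registered in nm space, particles are matched by
   centroid, and per-particle ECD deviations against the highest
   (reference) magnification are tabulated; threshold-sensitivity reports
   show how counts and sizes respond to TH.

The synthetic generator (`nanopsd.synthgen`) renders scenes of dark disks,
ellipses and harmonically-perturbed amorphous blobs over cell-like
backgrounds (gradient, correlated texture, membrane band), with
area-coverage antialiasing and exact analytic truth per particle — the
test bed for all of the above.

## Worked example

```python
from nanopsd import (SegmentationConfig, analyze_micrograph, random_scene,
                     render, shape_breakdown, summarize)
from nanopsd.segmentation import th_percent_for_gray

# a 300x300 nm scene of 25 particles (ECD 3.5-10 nm, contrast -80 gray)
scene = random_scene(25, 300, 300, seed=42, ecd_range_nm=(3.5, 10.0),
                     contrast_range=(-80.0, -80.0), noise_sd=5.0)
m, truth = render(scene, nm_per_px=0.5, seed=43)

# place the gray cutoff halfway between particles and background
th = th_percent_for_gray(m, 140)              # -> TH = 0.99 %
res = analyze_micrograph(m, SegmentationConfig(th_percent=th, min_area_px=30))
s = summarize(res.particles, metric="ecd_nm", bin_width=1.0)
print(f"N = {s.n}, mean ECD = {s.mean:.2f} nm, SE = {s.se:.2f} nm")
print(shape_breakdown(res.particles.shape_class))
```

prints

```
N = 25, mean ECD = 6.49 nm, SE = 0.36 nm
{'rounded': 12.0, 'very rounded': 88.0, ...}
```

i.e. all 25 generated particles are recovered; their mean equivalent
circular diameter is 6.49 nm with a standard error of 0.36 nm, and 88 % of
them classify as "very rounded" (the blob and ellipse families account for
the "rounded" remainder).  The first rows of the particle table:

```
 id   cx_nm  cy_nm  area_nm2  ecd_nm   rar   fmr  shape_class
  1  75.528 26.328     11.25   3.785 0.797 1.113 very rounded
  2 191.949 33.654     52.25   8.156 0.812 1.048 very rounded
```

## Command line

```bash
nanopsd synth     --config scene.yaml   --out-dir out/ --seed 1   # synthetic data
nanopsd analyze   --config run.yaml     --out out/                # particle table + PSD
nanopsd local-psd --config windows.yaml --out out/ --seed 1       # windowed PSDs
nanopsd qc        --config qc.yaml      --out out/                # deviation tables
```

Each command reads a YAML configuration (image path and calibration,
segmentation parameters, window list, QC series) and writes CSV tables —
tagged with a config hash for provenance — plus a histogram/cumulative/
boxplot figure for `analyze`.  Fixed config and seed give byte-identical
outputs.

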