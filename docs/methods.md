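# Methods

## Measurement model

The pipeline measures dark particles in calibrated 8-bit bright-field TEM
micrographs.  Its core assumptions:

* **Calibration** is exact and uniform: one pixel represents `nm_per_px`
  nanometres in both axes, taken from the scale bar
  (`nm_per_px = bar_length_nm / bar_length_px`, no rounding).  Scale-bar
  *detection* is manual; the user supplies the bar's pixel length.
* **Polarity**: particles are darker than their surroundings (bright-field
  contrast).  A light-foreground mode exists for robustness tests.
* **Threshold semantics.**  The threshold TH is a percentage of the gray
  histogram: a pixel is foreground iff its gray value is at most the TH-th
  percentile (linear interpolation) of the image's gray values.  This makes
  TH directly comparable across images with different brightness, makes
  foreground pixel count non-decreasing in TH, and is exactly reproducible.
  The helper `th_percent_for_gray` converts a physically chosen gray cutoff
  (e.g. halfway between particle and background gray) into the equivalent
  TH.  Note the percentile is evaluated on whatever image it is given — a
  cropped window has its own histogram, so a TH chosen globally selects the
  same *gray cutoff* in a window only when the histograms agree.
* **Regions** are connected components (8-connectivity by default, 4
  optional) of the thresholded mask.  Interior holes are filled by default
  (`include_holes`), absorbing only enclosed *background* pixels — a second
  particle sitting inside another's hole keeps its own label.  Components
  touching the image (or window) border are removed by default
  (`exclude_edges`), since their area is censored.  Components below
  `min_area_px` (default 50 px, a noise-speck guard) or outside the
  optional nm² bounds (inclusive on both ends) are discarded.  Surviving
  regions are ordered row-major by centroid with consecutive ids — a
  deterministic tie-break.

## Shape descriptors

* **Area** `A = pixel_count · nm_per_px²`; **ECD** `= √(4A/π)`, the
  diameter of the equal-area circle.
* **Ellipse fit.**  Second central moments of the pixel set, each pixel
  contributing its center plus a 1/12 variance term for its unit extent;
  eigenvalues λ₁ ≥ λ₂ give raw full axes `4√λᵢ`, which are then rescaled by
  a common factor so the ellipse area equals `A` exactly.  The 1/12 term
  makes a `w × h` rectangle reproduce the continuous-rectangle moments
  (variance `w²/12`), so its axis ratio is exactly `h/w`, and gives a
  single pixel a round ellipse of one-pixel area.  Axis ratio and
  orientation are unaffected by the rescaling.  This moment-based fit was
  chosen over least-squares boundary fits for determinism and because it is
  the convention of standard particle-analysis tools.
* **Feret diameter** is the maximum caliper opening, computed as the
  diameter of the convex hull of all pixel *outer corners* (each pixel
  contributes its 4 corners).  A single pixel therefore has `D_f = √2` px —
  caliper semantics on digitized shapes, exactly testable against the
  brute-force maximum over all corner pairs.
* **RAR** `= b/a` and **FMR** `= D_f/a` use *full* axis lengths.  With full
  axes, a perfect digitized disk gives FMR ≈ 1.  Known property: for
  strongly elongated rectangles the area-preserving fit yields `a > D_f`
  and hence FMR slightly below 1 (a 40 × 10 px rectangle gives ≈ 0.91);
  for the convex, roundish shapes this pipeline targets, FMR ≥ 1 up to
  discretization.
* **Roundness classes.**  RAR maps onto six classes with interval bounds
  0.12 / 0.17 / 0.25 / 0.35 / 0.49 / 0.70 / 1.00, lower-exclusive and
  upper-inclusive, so a boundary value (e.g. exactly 0.70) belongs to the
  lower class — the printed bounds touch, and a convention is needed.  RAR
  at or below 0.12 is outside the scale; it is tagged `"out of scale"` and
  excluded from the six-class breakdown but kept in the particle table.

## Distributions

PSD summaries report N, arithmetic mean, SE = sample SD (n − 1) / √n,
a fixed-width histogram on half-open bins `[k·w, (k+1)·w)` aligned to
multiples of the bin width, the per-bin cumulative percentage (ending at
100 for non-empty input), and the 10/25/75/90th percentiles (linear
interpolation) — the box and whiskers of the usual PSD boxplot.  Default
bin widths: 1 nm for ECD, 10 nm² for area, 0.05 for RAR/FMR.  With N = 1
the SE is reported as 0 with a flag, keeping report tables rectangular;
N = 0 yields a valid-but-empty summary.

Local PSDs crop a window (default 500 × 500 nm², the scale used to probe
intracellular hotspots), re-segment with optional per-window TH /
`min_area_px` overrides, and summarise.  Particles straddling a window
border are excluded — the same censoring rule as at the image edge; nm
coordinates remain scene-absolute through the crop.  Window positions are
user-supplied or drawn from a seeded generator, making "randomly selected
areas" reproducible.

## Quality control

A magnification series holds measurements of the *same* scene in a shared
nm frame (registration is user-supplied, or exact for synthetic renders —
automatic image registration is out of scope).  Matching is greedy
nearest-centroid, one-to-one, accepted in order of increasing distance
with ties broken by lower particle id; the default tolerance is two pixels
of the coarsest image.  The deviation table reports per-particle signed
ECD differences against a reference magnification (conventionally the
highest, where measurement is most stable) and the maximum absolute
deviation per magnification.  Particles whose reference ECD is below
3.5 nm are excluded from the deviation statistics by default: such sizes
sit at the resolution limit of coarse images (configurable).

## Synthetic scenes

The generator emulates the imaging situation the pipeline is built for,
not TEM physics (no electron scattering, defocus or CTF; no ultrathin-
section artifacts):

* **Families.**  Disks and ellipses (compact, gold-like) and amorphous
  blobs (cerium-like): a base radius perturbed by harmonics k = 2…n+1 with
  random coefficients L1-normalised to the perturbation amplitude (default
  20 %, 5 harmonics), so the radius stays positive and the centroid stays
  at the center.  Blob truth area is the exact polar integral
  `π r₀² (1 + Σ(cₖ² + sₖ²)/2)` — the dense limit of the boundary-polygon
  area — so a zero-amplitude blob is *exactly* a disk.
* **Rendering.**  Pixel gray = background + Σ contrast × coverage +
  Gaussian noise, clipped to [0, 255] and quantised.  Coverage is the
  pixel-area fraction inside the particle, estimated on a 4 × 4 subpixel
  grid — the antialiasing that makes sub-pixel size recovery meaningful.
  Background: base gray 180 with optional linear gradient, correlated
  texture (Gaussian-filtered noise with a nm correlation length) and a
  darker membrane band.  Geometry derives from the scene seed; texture and
  noise from the render seed, drawn after geometry — so the same scene can
  be re-imaged under new noise.  Particles covering less than one pixel at
  the chosen scale are flagged `sub_pixel` in the truth table.
* **What passing tests show.**  Recovery results on these scenes validate
  the measurement chain (segmentation geometry, descriptor arithmetic,
  cross-scale consistency).  They do not certify performance on real
  micrographs, whose backgrounds contain structured cellular components
  with particle-like gray values; the study's published gray statistics are
  not quantified, so synthetic defaults are plausibility choices.

## Validation studies and problem sizes

`nanopsd.validation` fixes three reference studies (run by
`scripts/acceptance.py` and the acceptance tests); thresholds are always
placed halfway between particle and background gray via
`th_percent_for_gray`:

* **Disk recovery** — 100 disks, ECD 5–12 nm at 0.5 nm/px (diameter
  ≥ 10 px), contrast −80 gray, noise SD 5, `min_area_px` 50.  Checked:
  fraction of disks with ECD within 3 % of truth, RAR ≥ 0.95 and class
  "very rounded".  Isolated noise-flipped boundary pixels can push a single
  small disk to RAR ≈ 0.93, so the criterion is a ≥ 95 % joint rate plus a
  population-mean RAR ≥ 0.95, not a per-disk bound.
* **Ellipse recovery** — 60 ellipses, ECD 8–14 nm, axis ratio 0.60–0.95
  (major axis ≥ 15 px); checked: b/a within 5 % of truth.
* **Multi-scale stability** — one 400 × 400 nm scene of 40 mixed-family
  particles (true ECD 3.5–12 nm, contrast −80, noise SD 3) rendered at
  0.1 / 0.3 / 1.5 nm/px.  These are the calibrations a standard 15 µm
  camera pixel produces at 150,000× / 50,000× / 10,000× magnification —
  the physically grounded choice for the 1:3:15 ladder.  Checked: ≥ 90 %
  of matched particles deviate ≤ 1.0 nm from the finest scale (observed:
  100 %, maximum deviation 0.4–0.8 nm across seeds, consistent with the
  ±1 nm error susceptibility expected at the coarsest magnification).
  At the coarsest scale `min_area_px` drops to 1 (a 50 px limit would be
  112 nm² there) and the nm-space floor of 5 nm² plus the 3.5 nm reference-
  ECD rule take over the noise rejection.

## Numerical and degenerate-input choices

* Crop → smooth → sharpen is the fixed preprocessing order; identity
  parameters return gray-identical images, and no step ever alters the
  calibration.
* Colour inputs are reduced to 8-bit luminance before processing.
* Pixel `(r, c)` occupies `[c, c+1) × [r, r+1)` px; centroids are
  pixel-center based; nm coordinates add the image's scene-frame origin.
* Empty segmentations, empty windows and empty summaries are valid
  results, not errors; invalid geometry (zero bar lengths, crop outside
  bounds, windows outside the image, inverted restriction intervals,
  non-positive areas) raises with the offending object named.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); fixed seed and configuration give
  byte-identical images, tables and CSVs.
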