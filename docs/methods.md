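# Methods

## Geometric model

Segmentations are planar polygons in the continuous pixel coordinate
system of each image (x along columns, y along rows, pixel centers at
integer coordinates). This is the native output of clinical contouring
tools, which operate at sub-pixel resolution; treating contours as
polygons rather than label masks makes areas, intersections and boundary
distances exact rather than grid-limited. The LV and RV endocardial
contours are simple polygons, the myocardium is an annulus (exterior
ring = epicardium, one interior ring = endocardium), and papillary
muscles may be multipolygons. A geometry that fails ring validity gets
exactly one zero-width-buffer repair pass; if it is still invalid the
operation raises instead of silently computing on a broken polygon.

### Metrics

- **Dice** is computed from exact polygon areas,
  `100 · 2|A∩B| / (|A|+|B|)`, so holes are respected and pixel spacing
  cancels. Geometrically identical contours short-circuit to exactly
  100 % (polygon overlay on identical inputs otherwise loses ~1e−14 of
  relative area to rounding), and the result is clamped to [0, 100].
  Both contours empty has no geometric value; the comparison layer
  applies the averaging convention instead (below).
- **Hausdorff distance** is reported in mm. Boundary vertices are scaled
  per axis by the pixel spacing *first* (anisotropic pixels are common in
  CMR), then every edge is subdivided so no segment exceeds `densify_mm`
  (default 0.5 mm), and the discrete symmetric Hausdorff distance over
  the point sets is returned. The discrete value is within `densify_mm`
  of the continuous boundary-to-boundary distance; densification is
  exposed because the error bound is the user's accuracy/cost dial.
- **Millilitre difference** converts an area disagreement on one slice
  into volume: `(|A| − |B|) · spacing_row · spacing_col ·
  slice_interval / 1000`, signed reader A − reader B; the absolute value
  feeds the per-slice aggregation tables.
- **Mask conversion** builds the exact union of unit pixel squares
  (pixel `(r,c)` → `[c−0.5, c+0.5] × [r−0.5, r+0.5]`), so the polygon
  area equals the foreground pixel count *exactly* and CNN-style mask
  output can enter the polygon pipeline without quantization error.
  4-connected pixels merge into one polygon; diagonal-only contact
  yields separate multipolygon parts, the natural consequence of exact
  square-union semantics.

## Case model and clinical results

Images are organized into a slice × phase grid: slice locations within
`slice_group_tolerance_mm` (default 0.5 mm, absorbing floating-point
jitter in DICOM exports) collapse into one slice; within a slice, phases
are ordered by trigger time with instance number as fallback. Two images
claiming one cell is an error, not a silent overwrite.

Volumes follow Simpson slice summation: cavity area × area-per-pixel ×
slice interval, summed over slices. The slice interval uses
`SpacingBetweenSlices` when present, else `SliceThickness`
(configurable), because gapped acquisitions under-count volume if the
thickness alone is used. End-diastole is the phase of maximal summed
cavity volume, end-systole the minimal non-zero one, ties to the lower
phase index; each ventricle is detected independently (the output
records both phase pairs, so a user who wants a single global phase pair
can see when they differ). `SV = EDV − ESV`; `EF = 100·SV/EDV`,
undefined (missing, not NaN) when EDV is zero. Myocardial mass is the
end-diastolic myocardial volume times a tissue density of 1.05 g/ml,
the standard CMR convention; both the density and the evaluation phase
are deliberate package choices exposed in the configuration.

Papillary muscles are an accounting convention, not an anatomical
ambiguity, so they are a config policy: `papillary_in_cavity` (default —
papillary contours ignored in volumes and mass) or `papillary_in_mass`
(their area is excluded from the LV cavity and their volume × density is
added to the mass).

## Reader comparison

Two cases are comparable only over identical image sets (checked by SOP
UID symmetric difference). One metric row is produced per image ×
contour type for every image that either reader segmented, plus
empty/empty convention rows on the first reader's contoured slice range
within analyzed phases. Conventions: both empty → Dice 100, no Hausdorff
sample, 0 ml difference; one-sided → Dice 0, no Hausdorff sample, the
full slice volume as difference. The two Dice averages follow from these
rows: the "all slices" mean rewards correct segmentation *decisions*,
the "contoured by both" mean isolates boundary similarity. Hausdorff
averages exclude undefined rows rather than substituting a penalty
value, and row counts are reported beside every average.

Cardiac positions are defined by the first reader: the contoured slice
range (min..max slice with any contour in any phase), ordered base →
apex, is split into basal = first ⌈n/3⌉ slices, midventricular = next
⌊n/3⌋, apical = the remainder, the extra slice of a non-divisible count
going to the basal third where interobserver variability concentrates.
Which stack end is basal defaults to the end with the larger
end-diastolic LV cavity area (the ventricle tapers toward the apex) and
can be forced via config. Rows on slices the first reader did not
contour are clamped to the nearest classified position.

## Interobserver statistics and outputs

Bland–Altman analysis uses differences oriented reader A − reader B,
the n−1 standard deviation, and limits of agreement at mean ± 1.96 SD;
with a single pair the mean is reported and the limits are missing.
Pearson correlations are computed per clinical result and undefined
(missing) under zero variance. All tables are computed before any file
is written, so an I/O failure cannot leave partial science on disk; CSVs
carry a provenance comment header (config hash, orientation convention)
and re-parse bit-exactly via `read_report_csv`. The figure set mirrors
standard interobserver reports: Bland–Altman panels per clinical result
with point size proportional to |difference|, dual Dice boxplots per
contour type, and per-result paired box + quantile–quantile plots.

## The phantom

The phantom emulates the geometry of a short-axis cine study, not its
image content. Defaults model a typical clinical acquisition: 16 slices
× 30 phases, 1.25 mm in-plane spacing, 8 mm slice thickness, basal LV
endocardial radius 25 mm, wall thickness 7 mm, RV crescent width 12 mm,
contraction amplitude α = 0.35 (EF ≈ 58 %), 120 vertices per contour.
The radius law is `r(z,t) = r0 · ((S−z)/S)^e · (1 − α·c(t))` with
`c(t) = (1 − cos 2πτ)/2` on the cyclic fraction `τ = min(t, P−t)/P`.
Computing `c` on the *cyclic* fraction makes the contraction profile
bit-exactly symmetric around mid-cycle, so with odd phase counts the two
near-extremal phases tie exactly and the lower-index tie rule makes
end-systole detection deterministic.

Ground-truth volumes use the **inscribed-polygon** area
`(n/2)·r²·sin(2π/n)` (and its annular-band analogue for the RV crescent)
rather than `πr²`: the generated contours *are* n-gons, so the pipeline
must recover the truth to floating-point accuracy (observed ~1e−15
relative), turning truth-recovery tests into exact checks instead of
discretisation-bound ones.

The simulated second reader applies, per image, a rigid translation
drawn from N(0, sd) mm; per vertex, radial jitter from the ring centroid
with N(0, sd) mm; and drops all contours on a configurable number of
basal slices — the three disagreement modes that dominate real
interobserver studies (boundary placement, boundary noise, basal slice
choice). Jittered rings that come out invalid are redrawn up to ten
times. Everything is deterministic under the seeds.

What the phantom does **not** model: image intensities and contrast
(readers here never see pixels), pathological shape variation,
through-plane motion, trabeculation, and systematic (bias-like) reader
divergence. Passing tests therefore demonstrate the correctness of the
measurement and decomposition machinery, not the clinical behaviour of
human readers.

## Problem sizes

The default test suite runs phantoms of 9 × 5 (slices × phases) for
comparison-level tests and 10 × 25 for truth-recovery and identity
checks; metric oracles use 200 random polygon pairs against a 0.01-px
rasterization count and a brute-force pairwise Hausdorff. The
reproduction script simulates a ten-case study at 16 slices × 30 phases
with per-case anatomy drawn from realistic ranges (LV radius 20–28 mm,
wall 6–9 mm, RV width 10–15 mm, α 0.30–0.45) and a second reader with
1 mm translation SD, 0.5 mm radial SD and a 50 % chance of omitting one
basal slice.

## Known limitations

- Hausdorff is discrete over densified boundaries; the reported value
  can sit up to `densify_mm` below the continuous supremum.
- Positions are thirds of the contoured slice range; no anatomical
  landmark (valve plane) detection is attempted.
- Only two-reader comparisons are modelled; repeat reads enter as
  additional cases.
- The AHA segment model, average surface distance and IoU are out of
  scope, as are vendor workspace formats (convert to the JSON annotation
  format upstream) and any GUI — figures are static files.
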