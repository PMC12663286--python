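# Methods

## The measurement problem

Negative-pressure cupping over a bony prominence (the posterior superior
iliac spine) produces a spatially structured skin response: the tissue
under the cup rim is compressed and transiently ischemic, the tissue at
the cup center is under tensile stress and accumulates blood, and the
surrounding tissue is largely unloaded. The package quantifies this
response from two modalities collected at nine timepoints (one
pre-cupping baseline, then minutes 0–7 post-cupping):

* **thermal frames** — 2-D skin-temperature grids (°C) from a long-wave
  IR camera;
* **erythema readings** — a colorimeter Erythema Index (colorimeter
  units, c.u.) measured at a single point at the center of the region of
  interest.

All analysis quantities are baseline differences: ΔT(t) = median
temperature at minute t minus the pre-cupping median, per region;
ΔE(t) = erythema at minute t minus the pre-cupping reading.

## Registration

The cup-imprint ellipse is annotated on the optical image; temperatures
live on the thermal grid. The two coordinate systems are linked by a
planar affine map estimated by least squares from ≥3 labeled corner
points (ID card / sticker) visible in both images. A full 6-DOF affine
is used (not a similarity), and the RMS fiducial residual is reported;
residuals above a configurable 2 px threshold are flagged. With exactly
three non-collinear points the fit is exact; with more it is the
ordinary least-squares solution of the [x, y, 1] design.

Ellipses are mapped analytically through the conic transformation
M′ = A⁻ᵀ M A⁻¹ (affine images of ellipses are ellipses), then
re-canonicalized to a ≥ b with rotation in [0, π); circles canonicalize
to rotation 0. Coordinates are 0-based, x = column, y = row, pixel
centers, in every file format.

## Concentric regions

From the outer cup-imprint ellipse (the 1× ellipse) two companions are
derived by exact axis scaling — 1.25× and 0.25× — sharing center and
rotation. The regions are:

| region     | definition                          | analytic area (outer axes a, b) |
|------------|-------------------------------------|---------------------------------|
| Peri-ROI   | inside 1.25×, outside 1×            | πab(1.25² − 1) = 0.5625 πab     |
| ROI Edge   | inside 1×, outside 0.25×            | πab(1 − 0.25²) = 0.9375 πab     |
| ROI Center | inside 0.25×                        | πab · 0.25² = πab/16            |

Rasterization tests each pixel center strictly (`<` on the quadratic
form), so the three masks are disjoint and partition the 1.25× interior
by construction, and counts are bit-reproducible. The strict test means
a pixel exactly on a boundary belongs to the outer region; for
integer-aligned circles this makes small regions undercount (an r = 10
circle centered on a pixel center loses 12 boundary lattice points,
−2.9%), so the 2% count-vs-area agreement should only be expected when
every ellipse semi-axis is ≳30 px. An empty ROI Center (ellipse smaller
than the pixel spacing) is an error naming the region; a 1.25× ellipse
extending past the frame is clipped with a warning.

## Region summaries

The temperature summary is the **median** with (Q1, Q3); the mean is
also emitted for diagnostics but unused by the default statistics.
Quartiles use linear interpolation between order statistics (the
"type 7" rule, the numpy/R default) — fixed because IQRs are compared
across implementations. Cohort aggregates are computed from per-subject
medians (median-of-medians), not pooled pixels; the distinction is
stated here because published cohort curves could be either.

## Statistics

* **One-sample t-tests** of each ΔT(region, minute) and ΔE(minute)
  against zero, two-sided, n−1 df, with the usual t-based CI.
* **Pearson correlation** between ΔT (ROI Center) and ΔE pooled over
  subjects and minutes 1–7 (n = 7 × n_subjects when complete), overall
  and stratified by eumelanin category. p from
  t = r√(n−2)/√(1−r²); 95% CI from the Fisher z transform,
  tanh(atanh r ± z₀.₉₇₅/√(n−3)). The CI treats pooled subject-minute
  pairs as independent; the within-subject dependence of repeated
  measures is noted as a caveat in every report rather than corrected.
  Strata with n < 4 are flagged insufficient, never dropped silently.
* **One-way ANOVA** of deltas across sex, BMI category and eumelanin
  category, by default at minutes 0 and 7 (optionally all minutes);
  classical F with (k−1, N−k) df. Within one analysis run, groups with
  fewer than 2 observations are dropped from that minute's test and
  recorded in the result.
* **Group summaries**: per-group mean, sample SD (n−1) and n, plus the
  pooled row; the pooled mean equals the sample-size-weighted mean of
  the group means.
* No multiple-testing correction is applied anywhere (matching the
  analysis plan); reports carry raw p-values with a note.

Classifier conventions: Monk Skin Tone level ≥ 6 → "darker" group;
BMI left-closed WHO cuts at 25 and 30; the six-category modified
eumelanin scale is anchored at Melanin Index 25 (below → EumelaninLow)
and 100 (at/above → EumelaninHigh) with interior cut points 40/50/70 as
explicit, documented configuration — the interior points are package
defaults, not part of the scale's published anchors, and should be
overridden if an instrument-specific mapping is available.

## Synthetic-data generator

The generator emulates the study conditions so the pipeline is testable
without any data download. Defaults:

* **Cohort**: 30 darker + 5 lighter subjects; BMI ~ N(29.41, 6.83²)
  truncated at 16; 69% female; Melanin Index ~ N(60, 10²) (darker) /
  N(35, 8²) (lighter), giving a cohort mean ≈ 56 and Intermediate Mid as
  the modal eumelanin category; MST levels drawn with the observed
  group-level weights.
* **Temperature kinetics**: per-region single-exponential relaxation
  δ(t) = δ∞ + (δ₀ − δ∞)·e^(−t/τ). The curve family is a modeling choice
  (only the minute-0 anchors and the qualitative course are reported):
  Peri-ROI (δ₀ +0.37 °C, δ∞ 0, τ 0.5 min — back to baseline within a
  minute), ROI Edge (−0.06, +0.25, 2.0 — recrosses baseline by ~1 min
  and keeps warming), ROI Center (−0.54, +0.30, 3.4 — crosses baseline
  at ≈3.5 min, inside the reported 3–4 min window). Baseline skin
  temperature 33.0 °C (typical sacral skin; not printed, configurable).
* **Between-subject spread**: a per-region additive offset on the delta,
  SD = reported cohort IQR width / 1.349 (peri 0.55, edge 0.50, center
  0.65 °C). No within-subject variance is reported, so these SDs are
  matched to the printed IQRs, not fitted. Pixel noise: i.i.d. Gaussian,
  0.1 °C (camera-noise scale). The delta map is Gaussian-smoothed
  (σ = 2 px) across region boundaries because real thermal fields are
  continuous; this biases region medians by ≲0.01 °C at the default
  geometry, covered by the 0.02 °C recovery tolerance used throughout.
* **Erythema**: ΔE(t) ~ N(group mean, group SD) per MST group at each
  minute, with the reported group vectors as defaults; baseline reading
  N(10, 2²) c.u. (only deltas matter downstream).
* **Geometry**: per subject, a random optical→thermal affine (~0.5×
  scale, ±6° rotation, small shear, translation) projects four card
  corners into the thermal frame (optional fiducial jitter, default
  0.3 px in the CLI, 0 in the library); the thermal-frame imprint
  ellipse spans about half the frame width and is mapped back to optical
  coordinates for the stored annotation. Thermal frames default to
  240×320; optical frames (480×640 RGB) are flat skin-tone patches with
  the card and imprint ring — sufficient for registration bookkeeping
  and visual checks, deliberately not photorealistic.

Setting every SD to zero makes generation deterministic and the
pipeline's recovery exact (temperature to the smoothing tolerance,
erythema to machine precision); this is the basis of the
parameter-recovery tests. What passing tests on synthetic data do *not*
establish: performance under real-world registration failure modes
(lens distortion, fiducial mislabeling), non-elliptical imprints,
non-exponential recovery kinetics, or any correlation structure between
temperature and erythema (the generator draws them independently unless
a test constructs them jointly).

## Problem sizes and numerical choices

Test and script runs use 5–35-subject cohorts at 240×320 (or smaller)
frames, chosen so the whole suite completes in well under a minute of
compute per scenario. Replicate-cohort checks (5 seeded cohorts)
back the qualitative statistical assertions so no single random
realization decides an outcome. Degenerate inputs are errors, not
warnings: collinear fiducials, singular transforms, empty regions,
zero-variance samples, mismatched timepoints. Ties in ellipse
canonicalization (a = b) set rotation to 0.

## Known limitations

* The erythema generator reproduces reported group means/SDs per minute
  but draws minutes independently — real within-subject erythema series
  are autocorrelated.
* The reported minute-2 group-level erythema cells are internally
  inconsistent with the all-subjects row they should pool to; the
  generator follows the group rows, so pooled minute-2 significance is
  borderline by construction. This is documented where it affects
  tests.
* The correlation CI ignores repeated-measures dependence (by design,
  to match the analysis plan it implements).
* One outer ellipse per subject is assumed (not re-traced per
  timepoint); the ROI is accepted as input — imprint detection from the
  optical image is out of scope.
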