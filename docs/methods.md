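# Methods

## Geometric model

A short-axis slice is represented by a pixel grid of MBF values (mL/min/g)
in continuous millimetre coordinates, origin at the grid corner, pixel
centre of `(row, col)` at `((col+0.5)·s, (row+0.5)·s)`. Angles increase
counterclockwise in this (x, y) frame; for display-oriented data (y pointing
down on screen) that corresponds to clockwise on screen. Non-myocardial
pixels carry NaN rather than zero so that any masking error propagates into
an unmistakably invalid mean instead of a quietly biased one.

**Centre.** The LV blood-pool centre is the area centroid of the
endocardial polygon. The centroid is deterministic, robust to contour-vertex
density, and lies inside any star-shaped contour; real LV endocardial
contours are star-shaped from their centroid.

**Resampling.** Maps are resampled to a common spacing (default 1.0 mm)
with bilinear interpolation on the pixel-centre lattice. Bilinear is exact
for affine fields and introduces no overshoot on step profiles beyond the
one-pixel transition band. Background pixels are excluded from the
interpolation support: they are filled with the nearest valid value before
interpolation, and output pixels whose interpolated validity falls below 1/2
are reset to background. Tiny negative undershoots are clipped to 0 to
preserve the non-negativity invariant.

**Midline.** 360 rays (1° increments) are cast from the centre; each ray
must cross the endocardial and the epicardial contour exactly once, else the
contour is rejected as non-star-shaped with the offending ray angle in the
error — a silent mis-split would corrupt every downstream layer metric. The
midline vertex on a ray is the midpoint of its two contour crossings; the
360 vertices close into the midline polygon.

**Layers.** A pixel belongs to the myocardium when its centre lies inside
the epicardial polygon (boundary inclusive) and not strictly inside the
endocardial one. Myocardial pixels inside or on the midline polygon are
ENDO, the rest EPI; ties exactly on the midline break toward ENDO. The
partition `ENDO ∪ EPI = myocardium`, `ENDO ∩ EPI = ∅` is enforced
structurally by the mask container.

**Parcellation.** Sector boundaries are anchored at the angle of the
RV-insertion landmark seen from the centre and advance counterclockwise:
six 60° sectors for basal (IDs 1–6) and mid (7–12) slices, four 90° sectors
for the apical slice (13–16). The apical-cap segment 17 is deliberately
absent from this 16-segment perfusion model. Territories follow the
standard grouping (LAD 6, RCA 5, LCX 5 segments). The landmark is a
required input; inferring it from images is out of scope.

## Metric definitions

Transmural gradients are ratios of layer *mean* MBF (sGRAD =
sMBF_ENDO/sMBF_EPI), not means of per-pixel ratios — the layer means are
the quantities with physiologic units and printed reference values, and the
ratio of means is far less noise-sensitive than a mean of ratios. Global
and coronary-territory MBF are pooled pixel means over all contributing
slices; slice-specific gradients and reserves are unweighted means of the
per-segment values of that slice (6, 6 or 4 segments). The rate-pressure
product is HR × systolic BP; rest flow is workload-normalised as
rMBF_c = rMBF/(RPP/10 000), applied at global LV level, which gives the
exact identity MPR_c = MPR × RPP/10 000 used as an algebraic self-check.
Ratios with denominators below 10⁻⁹ mL/min/g are reported as missing (NaN),
never as infinity; non-positive denominators raise.

## Synthetic data

**Phantoms.** An annulus between two concentric circles or axis-aligned
ellipses, with transmural depth t ∈ [0, 1] defined radially for circles and
by the boundary-distance ratio d_endo/(d_endo+d_epi) for ellipses. Profiles:
uniform, linear in t, or a step at t = 1/2 (the step tie t = 1/2 goes with
the inner half, matching the midline tie-break). Gaussian noise is added
inside the annulus and clipped at zero. Ground-truth layer means are
area-weighted half-annulus means: closed-form radial quadrature for circular
linear profiles, dense 0.1 mm numerical quadrature for elliptical ones,
exact constants for uniform/step. Contours are 360-gons; their maximal
deviation from the true circle/ellipse (sagitta < 2·10⁻³ mm at r = 30) is
negligible against all stated tolerances.

**Cohort simulator.** Per-subject values are drawn from truncated normal
distributions with multiplicative structure; defaults are anchored to the
summary statistics of a healthy two-centre adult reference cohort
(n = 138, 54 female):

| parameter | default | anchor |
|---|---|---|
| rest MBF mean ± SD (F / M) | 0.68 ± 0.13 / 0.56 ± 0.17 | printed global rest MBF by sex |
| stress MBF mean ± SD (F / M) | 2.41 ± 0.47 / 2.12 ± 0.53 | printed global stress MBF by sex |
| age | Uniform(19, 79) y | stated cohort age span |
| stress age slope | −0.0135 mL/min/g/y | sized so the stress-ENDO-MBF/age Spearman r lands near −0.47 |
| rest age slope | 0 | rest flow shows no age correlation |
| layer ratio, rest (basal/mid/apical) | 1.08 / 1.09 / 1.16 | slice rGRAD values |
| layer ratio, stress | 0.98 / 0.92 / 1.03 | slice sGRAD values |
| slice effects, stress | 1.04 / 0.96 / 1.00 | chosen to average exactly 1 while putting the mid-slice reserve lowest |
| slice effects, rest | 1.02 / 1.02 / 0.96 | apical rest flow lowest |
| rest–stress correlation | 0.3 | reproduces the printed MPR SD (≈1.2) from the printed flow SDs |
| territory factors (rest) | LAD 1.07, LCX 0.97, RCA 0.93 | territory-to-global flow ratios |

A whole-wall value M and a layer ratio g yield endo = M·2g/(1+g),
epi = M·2/(1+g), so the equal-area wall mean is exactly M and endo/epi is
exactly g. The marginal stress SD is preserved by shrinking the residual SD
to √(SD² − (slope·σ_age)²). Hemodynamics are sex-specific normals (floors:
HR 40 bpm, SBP 80 mmHg). The printed reference tables mix "median (±IQR) or
mean (±SD)" without marking which; all printed pairs are treated as normal
mean/SD anchors.

What the generator does **not** emulate: dynamic contrast passage and AIFs
(maps arrive already quantified), dark-rim or motion artifacts, realistic
wall-thickness variation and papillary anatomy, spatially correlated noise,
and the true inter-regional covariance of flow (unknowable from printed
summaries; territory and slice noise are independent given the subject
base). Passing tests therefore demonstrate correctness of the geometry,
aggregation and statistics on idealised inputs — not robustness to scanner
artifacts.

## Statistical conventions

Shapiro–Wilk at α = 0.05 gates, per metric and stratum, both the summary
presentation (mean ± SD when normal, median ± IQR otherwise) and the test
family (independent/paired t-test, one-way or subject-blocked
repeated-measures ANOVA, Pearson — versus Mann–Whitney U, Wilcoxon
signed-rank, Friedman, Kruskal–Wallis, Spearman). One gate decision drives
both uses, so a table never mixes presentations and tests from different
normality verdicts. For n > 5000 the gate runs on 5000 evenly spaced order
statistics (deterministic and order-invariant; the test is unreliable
beyond that n). Degenerate inputs: constant samples route to the
non-parametric branch with an undefined gate p; all-zero paired differences
report p = 1; an exactly constant non-zero paired shift reports p = 0 with
the shift's sign.

Percentiles use linear interpolation; IQR is reported as Q3 − Q1. The "95%
cohort range" proposed as the normal range is the 2.5th–97.5th percentile
interval. The CI of the median is a percentile bootstrap (2 000 resamples
by default), seeded per metric/stratum via a CRC-derived child seed so
reports are deterministic for a fixed seed and invariant to row order
(resampling operates on the sorted sample). Raw p-values are reported
throughout except the three pairwise slice contrasts, which are
Bonferroni-adjusted (×3, capped at 1). Sex comparisons need ≥ 3 subjects
per group and slice contrasts ≥ 3 subjects; below that they are omitted
rather than extrapolated.

## Problem sizes and tolerances

Default grids are 128–256 pixels per side at 0.5–1 mm (a 60 mm epicardial
diameter annulus, ~6 000–25 000 myocardial pixels per slice); phantom
validation uses 0.25–2 mm. Convergence checks average errors over 8–12
random sub-pixel grid offsets because single-alignment quantization error
aliases with the grid and is not monotone in spacing. Midline accuracy is
validated against a 0.01 mm ray-march oracle (tolerance 0.05 mm); gradient
recovery on step phantoms at 0.5 mm carries a ±0.01 tolerance. Replicate
cohort simulations use 60–200 seeded replicates at n = 138; Monte-Carlo
acceptance bands for detection rates were frozen from 300–500-replicate
pilot runs (e.g. the female/male rest-flow comparison at α = 0.001 detects
at ≈ 0.83, band ≥ 0.77).

## Known limitations

- Contours must be star-shaped from the endocardial centroid; severely
  remodelled ventricles would need a different midline construction.
- Elliptical phantoms define depth by boundary distance while the midline
  is a ray midpoint; the two differ slightly off-circle, so elliptical
  step-phantom truth carries a small model mismatch (circular phantoms are
  exact and are used wherever a sharp tolerance is asserted).
- The simulator's covariance structure is a modelling choice, not an
  estimate; normative intervals derived from simulated cohorts validate the
  machinery, not clinical reference ranges.
- Vendor map formats (DICOM in-line output) are not read directly;
  conversion to text/NIfTI plus JSON contours is the user's responsibility.
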