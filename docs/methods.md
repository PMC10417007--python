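# Methods

## Overview

`octavti` measures retinal vessel tortuosity on en face OCTA images of
the superficial capillary plexus and compares it across subject groups.
The pipeline has four stages — ridge detection, skeleton/graph
extraction, per-segment tortuosity, cohort statistics — plus a
synthetic-data module that generates images and cohorts with known
truth.  This note records the model, the parameters that matter, the
numerical choices, and what the validation does and does not show.

## Image and geometry conventions

Images are square grayscale rasters with intensities in [0, 1],
coordinates `(x, y) = (col, row)`, 0-based, origin top-left.  The
default canvas is 1024 px, standing for a 6 x 6 mm scan field; all
geometry is computed in pixels.  No physical-unit conversion is applied
anywhere because the index is built entirely from dimensionless ratios,
counts and angles.

## Ridge detection (`octavti.ridge`)

Vessels are bright curvilinear structures on a dark background and are
detected with the classic Hessian/steepest-curvature approach:

1. Gaussian derivative filters at scale `sigma` give the gradient and
   Hessian at every pixel.  `sigma` should match the vessel half-width;
   the synthetic vessels use a Gaussian cross-profile with
   `vessel_profile_sigma = 2 px` and are detected at `sigma = 2`.
2. The Hessian eigenvector with the largest-magnitude eigenvalue is the
   cross-line direction `n`.  A sub-pixel line point is emitted where
   the first directional derivative along `n` vanishes inside the pixel
   and the second directional derivative is negative (bright line) with
   magnitude at least `lower_threshold`.
3. Points with response `>= upper_threshold` seed hysteresis linking;
   lines grow through 8-neighboring points with response
   `>= lower_threshold` whose tangent turns by less than 90 degrees.
   Components smaller than `min_component_px` (default 20) are dropped.
4. The mask is thinned to a 1-px, 8-connected skeleton
   (`skimage.morphology.skeletonize`), which preserves the number of
   connected components.  Skeleton pixels remember the sub-pixel
   coordinate of the ridge point emitted there.

Two deviations from the textbook one-pass scheme, both motivated by
measurement accuracy rather than detection:

* **Boundary tolerance 0.6 px.**  The nominal acceptance test
  `|t·n| <= 0.5` leaves a one-pixel gap when the sub-pixel line sits
  exactly on a pixel boundary (both adjacent pixels attribute the point
  to the other).  Accepting up to 0.6 px closes the gap; duplicate
  emissions from neighboring pixels are removed by thinning.
* **Iterative sub-pixel refinement (3 iterations).**  The single Newton
  step from the pixel center has a bias that depends on where the line
  crosses the pixel.  On a nearly axis-aligned vessel this bias drifts
  slowly along the line and looks like gentle extra curvature, which a
  moving average cannot remove and which inflates the tangent-angle
  spread of low-curvature vessels by tens of percent.  Re-evaluating
  the derivative fields at the current estimate (cubic-spline
  interpolation) and repeating the step removes the bias; localization
  error on noise-free renders drops well below 0.1 px.

Thresholds are derived from a minimum line contrast via
`steger_thresholds(contrast, profile_sigma, sigma)`: a Gaussian-profile
line of height `h` smoothed at scale `sigma` has peak second
cross-derivative `h * p / (p^2 + sigma^2)^(3/2)`; the upper threshold is
half that value, the lower a quarter.  Detector output at line
*endpoints* is intrinsically unreliable: the ridge curls around the
rounded cap of a bright tube for roughly two profile sigmas.  This is
handled downstream (end trimming), not in the detector.

## Vessel graph (`octavti.graph`)

Skeleton pixels are classified by 8-neighborhood degree: 1 = endpoint,
`>= 3` = bifurcation; 8-connected clusters of junction pixels (a common
thinning artifact) are condensed into a single node at their centroid.
Edges are the ordered pixel chains between nodes; isolated cycles are
cut at their topmost-leftmost pixel.  Each edge becomes one centerline
segment:

* pixel chains adopt sub-pixel ridge coordinates where available;
* chains are smoothed with a centered moving average
  (`smoothing_window`, default 5, endpoints pinned) to suppress
  staircase angles from the pixel lattice;
* `end_trim` (default 4 px in the measurement workflow) removes the
  end-cap hook from chain ends that terminate at a free endpoint; ends
  at bifurcations are never trimmed;
* chains shorter than `min_segment_points` (default 10) are dropped —
  derivative-based quantities are unreliable on shorter fragments.

Manual cut points (`apply_manual_points`) replicate an operator-driven
segmentation protocol: listed coordinates snap to the nearest skeleton
pixel within 3 px and split (or, for removal, merge) edges.  The
default protocol is fully automatic; the manual hook exists for
comparability with operator-defined endpoints.

## Tortuosity (`octavti.tortuosity`)

Per segment: `VTI = 0.1 * M * N * SD_theta * (L_A / L_C)`.

Pipeline: the polyline is rigidly moved to the chord frame (first point
at the origin, chord along +x), resampled to uniform arc-length spacing
(`spacing`, default 1 px), optionally smoothed, and all quantities are
computed on the same resampled points:

* `N` — sign changes of `dy/dx` (central differences) strictly inside
  the segment; endpoints are never counted.  Where the projected `x` is
  non-monotone (strongly convoluted segments), sign changes of the
  signed curvature along arc length are used instead.  Runs of sign
  changes closer than `min_separation` (default 5 samples) are merged
  by parity — derivative jitter around a single zero otherwise counts
  as several crossings.
* `SD_theta` — population standard deviation of the unwrapped
  differences of `atan2` tangent angles between consecutive resampled
  points, reported in degrees by default (`angle_unit="rad"` switches
  the convention; this rescales VTI by 180/pi).
* `M` — mean arc/chord ratio of the pieces delimited by the critical
  points, including the leading and trailing pieces; with `N = 0` it is
  the whole-segment ratio.

`compute_vti` applies no smoothing by default: segments coming from
images are already smoothed at the graph stage, and the endpoint-pinned
moving average measurably distorts the turning profile near segment
ends (a constant-curvature arc, whose angle-step spread should vanish,
acquires a spurious SD_theta of ~0.1 degree under a width-5 window).

**Resolution dependence.**  `SD_theta` is computed between samples a
fixed 1 px apart, following the per-centerline-pixel convention of the
underlying index.  `N`, `M` and `L_A/L_C` are scale-free, but the
angle-step spread of a smooth curve halves when the same curve is
rendered at twice the resolution.  The index is therefore comparable
across images that share one acquisition geometry (here: 1024 px =
6 mm), and `spacing` must be scaled together with any rescaling of the
input geometry.  The test suite asserts exactly this invariance
(scaling curve and spacing together); asserting invariance at fixed
spacing would contradict the per-pixel convention.

Per image, the score is the unweighted arithmetic mean of the
per-segment VTI values; an image with no measurable segment is an
error, surfaced as an exclusion in the CLI workflow.

## Cohort statistics (`octavti.stats`)

Mean VTI is modeled by OLS on group indicators plus age (treatment
coding); adjusted group means are evaluated at the grand mean age
(emmeans-style), so pairwise differences reduce to coefficient
contrasts.  Pairwise comparisons use the Tukey–Kramer single-step
adjustment: `p = P(q_{k,df} >= sqrt(2)|t|)` with model-based standard
errors, and simultaneous confidence intervals from the same critical
value.  With two groups this reduces exactly to the two-sided t-test.
Degenerate exact-tie data (zero residual variance) yields p = 1 and
point-mass intervals rather than 0/0 noise.  The implementation was
cross-checked against R's `emmeans` (identical estimates, intervals and
p-values to ~1e-7).

Demographic homogeneity: Welch t (two groups) or one-way F (more) for
age; Pearson chi-squared for sex-by-group composition, switching to
Fisher's exact test for 2x2 tables with any expected count below 5.
Descriptive SDs are sample (n-1) SDs, the clinical reporting
convention.

## Synthetic data (`octavti.synthetic`)

**Curves.**  Lines, circular arcs, sinusoids, triangle-wave zigzags and
random cubic splines, each carrying analytic truth: arc length (closed
form or adaptive quadrature), chord length, and interior extremum count
where defined.  Default sampling densities keep the polyline arc length
within 0.1 % of the analytic value.

**Images.**  `background + sum of Gaussian-profile tubes + N(0,
noise_sigma)` clipped to [0, 1]; tube intensity at a pixel is
`peak * exp(-d^2 / 2 sigma_p^2)` with `d` the exact Euclidean distance
to the centerline polyline (shapely).  Defaults: 1024 px canvas, profile
sigma 2 px, peak 0.8 over background 0.05.  The ground-truth record
stores every curve's points and its VTI computed on the analytic
centerline.  Rendering is deterministic under the seed; noise-free
renders are seed-independent.

**Cohorts.**  Six subgroups matching the studied 56-eye cohort: sizes
(5, 13, 7, 7, 13, 11), mean VTI (0.33, 0.22, 0.20, 0.19, 0.20, 0.21),
VTI SDs (0.10, 0.08, 0.08, 0.03, 0.06, 0.05), mean ages (34.4, 44.5,
48.1, 38.1, 34.2, 28.5) and age SDs (15.6, 11.8, 5.64, 21.8, 9.64,
8.88).  Per-subject mean VTI is drawn from a normal truncated at 0 (the
index is non-negative by construction) and age from a normal truncated
at 16 (the study's inclusion floor), via inverse-CDF sampling with one
deterministic child seed per subject (`seed + subject index`), so any
subset is reproducible.  Truncation shifts the realized moments away
from the nominal parameters where the floor is close (late-onset-female
age: nominal 38.1, truncated mean ~44.3); convergence tests therefore
target the analytic truncated-normal moments.  In `full_images` mode
each subject additionally receives an image whose sinusoidal vessels
share an amplitude multiplier found by bisection against the package's
own `compute_vti` until the true mean VTI matches the drawn value
within 5 %.

**What the generator does not emulate.**  OCTA speckle decorrelation,
projection artifacts, signal-strength variation, capillary-scale
texture, vessel caliber variation and branching morphology are all
absent; noise is additive Gaussian only, and vessel geometry is smooth
and parametric.  Passing the end-to-end tests shows that the pipeline
measures what it defines on well-resolved, well-contrasted vessels; it
does not certify segmentation quality on clinical angiograms, where the
interactive step this pipeline replaces was performed with unreported
parameters.

## Validation design

* Analytic identities: straight line scores exactly 0; uniform arcs
  score ~0; VTI strictly increases with the number of sine periods
  along a fixed chord.
* Oracle equivalence: an independent brute-force implementation of the
  formula on 1e5 dense analytic samples (no shared resampling or
  smoothing code) agrees with `compute_vti` within 2 %.
* End-to-end: on noise-free single-vessel renders, the full pipeline
  recovers the generating curve's VTI within 10 % for at least 9 of 10
  parameter draws (amplitudes 15–40 px, periods 200–450 px, 2–3
  periods).
* Statistics: the k=2 Tukey reduction is exact; the k=3 adjusted p
  matches a 10^6-draw Monte-Carlo max-|t| null within 3 MC standard
  errors; under an all-equal six-group null at the study's group sizes
  the family-wise error over 2000 replicates stays within 0.05 plus
  2 MC standard errors; and with the study's subgroup parameters the
  classic-male vs late-onset-female contrast is significant in the
  median replicate (this last quantity is what
  `scripts/acceptance.py` recomputes).

Problem sizes (10 end-to-end images, 200 cohort replicates for the
headline contrast, 2000 for error control, 10^6 Monte-Carlo draws) were
chosen so the whole suite validates every stage at interactive
turnaround on a single core.

## Known limitations

* The absolute VTI scale depends on the angle unit (degrees here,
  following the referenced implementation) and on the 1 px angle
  sampling convention; comparisons across devices or fields of view
  require matching both.
* Junction geometry is simplified: crossing vessels become four edges
  meeting at one node; no attempt is made to pair up continuing vessels
  through a crossing, which an operator-driven protocol would do.
* The interactive binarization step this package replaces had
  unreported settings, so agreement with any specific operator's masks
  cannot be established — only agreement with ground truth on synthetic
  data.
* Cohort simulations draw per-subject mean VTI directly; they validate
  the statistical layer, not the imaging layer, and the two are joined
  only through the (slower) `full_images` mode.
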