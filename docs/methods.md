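# Methods

## The assay and its response variable

A single ant explores a rectangular arena whose paper floor is crossed
lengthwise by a thin grey line carrying a candidate trail-pheromone
solution. The recording (grayscale, 720 × 1280 px, 25 frames/s, 3 min)
is reduced to one number per ant: the distance walked while the body
centre stayed within 5 mm of the line. Groups of n = 15 ants per
preparation × concentration are then compared against a control.

## Coordinates and calibration

Arena coordinates are millimetres with the origin at the top-left
corner, x rightward and y downward, matching image row/column order.
Pixels are square; frame dimensions are `round(mm × px_per_mm)`. The
recorded 16:9 field of view is modelled as a 160 × 90 mm arena at
8 px/mm (720 × 1280); the reduced test resolution uses 2 px/mm
(180 × 320). `px_per_mm` is a required calibration input, not a
constant: the binned pixel pitch ("about 1 mm") depends on the camera
height. Binned pixel centre (r, c) maps to
`((c + 0.5)·s/px_per_mm, (r + 0.5)·s/px_per_mm)` for spatial factor s.

## Spatio-temporal binning

Videos are compressed by non-overlapping block means: 4 × 4 pixels and
4 consecutive frames by default, giving a 160 ms frame period at 25
frames/s. The bin statistic is the arithmetic *mean*, not the sum, so
the intensity scale — and therefore every segmentation threshold — is
independent of the binning factors. Trailing rows/columns/frames that
do not fill a whole bin are dropped (floor semantics), avoiding
partially-weighted bins; consequently the binned frame count is
`floor(n / temporal_factor)` and global mean intensity is preserved
exactly when dimensions divide evenly. RGB input is converted to
luminance with the standard BT.601 weights.

## Tracking

Background: per-pixel temporal median over the stack (subsampled evenly
to ≤200 frames for long videos). A single ant occupies any given pixel
in well under half the frames, so the median recovers the ant-free
scene, and the trail line — part of the static scene — cancels in the
subtraction. Segmentation: the difference image `d = background −
frame` is thresholded (default 30 grey levels), 8-connected components
with area in `[min_area_px, max_area_px]` are candidates, and the
largest wins (ties broken by summed difference intensity, which is
deterministic). The detection is the candidate's intensity-weighted
centroid with weights d. An optional exclusion mask can drop line-band
pixels from candidate seeds when the line is drawn per-experiment
rather than printed.

Assembly: runs of up to `max_gap_frames` missed detections (default 3
binned frames ≈ 0.5 s) flanked by valid detections are filled by linear
interpolation and marked; longer runs and leading/trailing misses stay
invalid and contribute no walked distance. Analysis is windowed to the
first 3 min starting at the first valid detection (the moment the ant
enters the arena).

## Trail metrics

Distance is measured to the *closed* segment (endpoint-capped), since
the line is finite on the sheet; the on-trail band is therefore a
stadium. The on-trail rule is strict: `d < 5 mm`; equality is
off-trail. A step between consecutive valid samples counts toward y
only when *both* endpoints are on-trail — a conservative attribution
that never credits band-crossing steps; the either-endpoint alternative
is a one-argument change (`step_rule="either"`). "Distance walked on
the trail" is implemented as summed displacements between on-trail
samples (not along-line progress); this is an interpretation the
package states explicitly. Occupancy heatmaps accumulate valid samples
on a 2 mm grid (a compromise between visual granularity and the binned
pixel pitch); samples on a cell edge go to the higher-index cell, and
rendering divides by the total count to give a passage probability.

## Statistics

All tests operate on Y = ln(y + 1). The one-way ANOVA is the standard
between/within decomposition (`scipy.stats.f_oneway`); with k groups of
n ants, df = (k − 1, k(n − 1)) — (12, 182) for the 13-group design and
(17, 252) for 18 groups. Dunnett comparisons are two-sided via the
multivariate-t distribution with the equicorrelation structure of
balanced many-to-one designs (`scipy.stats.dunnett`, seeded
quasi-Monte-Carlo integration, so adjusted p-values are reproducible);
the pooled error uses all groups, matching the ANOVA df. Both controls
(solvent and blank) are retained as groups, with the blank as the
Dunnett reference. The between-compound test is the classic
pooled-variance unpaired t-test; Welch is available via
`equal_var=False`. Stars follow the 0.05/0.01/0.001/0.0001 coding.

For Monte-Carlo studies of the family-wise error rate the package
computes the two-sided equicoordinate critical value once (by inverting
the equicorrelated multivariate-t rectangle probability) and compares
`max|t|` against it per replicate — the identical rejection event to
"smallest adjusted p < α", at a tiny fraction of the cost of a full
Dunnett evaluation per replicate. Tests cross-check the two routes.

## Synthetic data: what it emulates, and what it does not

The walk is a correlated random walk: per step (dt = 40 ms) the heading
receives wrapped-normal noise with sd `sqrt(dt/κ)` (κ =
`turn_concentration`, default 5; κ = 0 draws a fresh uniform heading)
and relaxes toward the bearing of the nearest trail-line point at rate
`trail_attraction` (1/s); speed is constant (default 20 mm/s) with a
per-step pause probability (default 0.02); walls reflect specularly;
the ant starts at the midpoint of the left short wall, heading inward,
where the entry tube meets the arena. These defaults are *assumptions*
chosen to produce plausible arena coverage — they are not measurements
of any ant species' locomotion, and the generator makes no attempt at
gait, antennation or pheromone-field dynamics. With zero attraction the
stationary distribution is uniform, so the on-trail fraction equals the
5 mm band's share of the arena area (a property the tests exploit);
attraction produces the tight line-following seen in real assays.

The renderer draws a dark anti-aliased ellipse (5 × 2 mm, grey level 40)
oriented along the direction of motion on a uniform background (grey
220) with the trail band at grey 150, plus optional additive Gaussian
noise. The ellipse is symmetric about its centre, so the
intensity-weighted centroid is unbiased. Real recordings differ in ways
the renderer ignores — lens distortion, illumination gradients, shadows,
legs/antennae breaking the elliptical silhouette, compression
artefacts — so passing the round-trip recovery tests demonstrates the
pipeline's correctness, not robustness to arbitrary field footage.

Ground truth for the render → track round trip is defined at the binned
temporal resolution: the true positions are block-averaged over each
run of `temporal_factor` frames, because the centroid of a time-binned
frame estimates exactly that average. Recovery on noise-free renders is
RMSE ≈ 0.15 binned pixels and on-trail distance within ~1% of truth
(the acceptance suite enforces < 1 pixel and < 5%).

Group distances are drawn so that ln(y + 1) is normal with a common
dispersion: y = expm1(N(µ_g, σ)), clipped at 0. The control mean
(ln scale) defaults to 4.0 (~55 mm median); the clip probability is
then Φ(−4/σ) < 10⁻⁷, so the statistics stage's parametric assumptions
hold by construction. The dispersion default σ = 0.75 is a power-based
choice: it places the canonical strong effect — a 1.5 ln-unit shift at
the high concentrations — at ~99% per-comparison Dunnett power for
n = 15 (non-centrality 1.5/(0.75·√(2/15)) ≈ 5.5 against a critical
value of ≈ 2.8), so simulated dose–response experiments show the
clean "significant only above threshold" pattern characteristic of
trail pheromones. Non-responders (ants that never leave the tube) can
be emitted with a configurable probability; they are excluded from the
data and tallied.

## Numerical choices and degenerate inputs

- Point-to-segment distance clamps the projection parameter to [0, 1];
  a degenerate segment (p1 = p2) is rejected at construction.
- Equal-area segmentation candidates are broken by summed difference
  intensity; a frame identical to the background yields an invalid
  detection, not an error.
- A trajectory with zero valid detections raises and is recorded as a
  per-ant failure by the pipeline; the run aborts only if a whole group
  ends up empty.
- ANOVA with zero within-group variance everywhere is rejected rather
  than returning an infinite F.
- Seeds: every stochastic component (walk, render noise, group
  sampler, Dunnett integration) takes an explicit seed; identical
  configs reproduce byte-identical CSV outputs.

## Problem sizes in the test and acceptance suites

The suites run at reduced scale chosen to exercise every code path with
tight tolerances: tracking recovery uses 10 ants × 60 s at 180 × 320
(45 × 80 after binning); the statistical calibration uses 5000
replicates of the 13-group × 15-ant null design (binomial noise ≈ 0.003,
comfortably inside the ±0.01/±0.015 assertion bands); dose–response
recovery uses 400 replicates; the geometry oracle uses 1000 random
segment/point pairs against two-stage dense sampling.

## Known limitations

- Single-animal tracking only: no identity handover, posture, or
  multi-ant scenes.
- "Distance walked on the trail" sums displacements; along-line
  progress would differ for an ant zig-zagging within the band.
- No lens-distortion or perspective correction; calibration is a single
  isotropic scale.
- Colony of origin (5 ants from each of 3 colonies) is metadata only;
  no mixed-effects modelling.
- Video containers depend on an imageio ffmpeg plugin; PNG/TIFF
  sequences are the lossless, always-available interchange format.
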