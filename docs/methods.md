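# Methods

## Axis parcellation

The parcellation operates on voxel *centers* mapped to world millimetres
through the NIfTI affine, never on raw indices, so anisotropic or oblique
grids are handled correctly (the reference acquisition is 1 mm isotropic,
for which the two coincide). The long axis is the straight line between the
two surface voxels at maximal Euclidean distance.

Numerical and convention choices:

* **Binarization is inclusive** (intensity ≥ 127). 127/255 ≈ 0.498, so an
  inclusive comparison is the only reading consistent with "membership
  probability 0.5 or higher" at integer intensities. Inputs already coded
  {0, 1} are rescaled to {0, 255} with a warning.
* **Surface = 6-connectivity face adjacency** (out-of-grid counts as
  outside). This is the cheapest surface definition that preserves the
  global farthest pair: a voxel with all six face-neighbours present lies
  strictly inside the convex hull of its neighbours' centers and cannot be
  an extreme point of the point set, so the maximal pairwise distance over
  surface voxels equals the maximum over all voxels. The pair search itself
  is brute-force O(n²) (chunked); this is the reference implementation and
  the test oracle compares it against brute force over *all* voxels.
* **Ties** in the pair search (distances equal to within 1e−12 relative)
  are broken by the lexicographically smallest pair of index triples, for
  determinism on symmetric shapes.
* **Orientation**: the endpoint with the smaller anterior-axis world
  coordinate (RAS +Y) becomes posterior. An exact tie is anatomically
  implausible; it falls back to lexicographic order with a warning.
* **Binning** uses half-open intervals [(s−1)/10, s/10) with t = 1 assigned
  to segment 10; a voxel projecting exactly onto a boundary goes to the
  more anterior segment. Because the axis endpoints attain the maximal
  distance, no projection can fall outside [0, 1] beyond floating-point
  error; t is clamped and the pipeline asserts the largest clamp is below
  1e−9 of the axis length.
* **Hemispheres are processed independently**; empty segments (possible
  for pathological shapes) are retained with volume 0 so that the 10
  volumes always sum exactly to the mask volume.
* **Head/body mapping**: with the hippocampal head occupying the anterior
  47 % of the head+body length, a segment entirely below the 53 % boundary
  (from posterior) is "body", entirely above is "head", and the straddling
  segment (segment 6 at the defaults) is the transition.

## Quality control

Within each (hemisphere, segment) cell, volumes further than 3 SD from the
cell mean are set missing (never imputed); downstream models use listwise
deletion. The mean and SD are pooled over the whole sample — not per
diagnostic group — and computed in a single pass; the rule is deliberately
not iterated. Cells with zero SD yield no exclusions. On Gaussian data the
expected exclusion fraction is 2(1 − Φ(3)) ≈ 0.27 %; real morphometry is
heavier-tailed and excludes somewhat more.

## Biomarker rules

Aβ42 is bimodal (amyloid-positive vs -negative), so its cutoff is estimated
unsupervised by a two-component univariate Gaussian-mixture EM:

* best of 10 restarts by log-likelihood, initialized at the data quartiles
  plus seeded jitter; unequal variances allowed, floored at 1e−4 of the
  sample variance; convergence at a relative log-likelihood change below
  1e−8 (max 500 iterations); the log-likelihood is asserted non-decreasing
  at every iteration;
* components are relabelled so the lower-mean ("abnormal") component comes
  first; the cutoff is the **equal-posterior point** — the root of
  w_a φ(x; μ_a, σ_a) = w_n φ(x; μ_n, σ_n) between the means, found by
  bracketed root-finding (Brent). The equal-density variant (dropping the
  weights) differs by a few ng/l and is not used. On effectively unimodal
  input no crossing may exist between the nearly coincident means; the
  midpoint is then returned with `separation_ok=False` and a warning, and
  should not be trusted.

Fixed rules: Aβ42 ≤ cutoff (default 527 ng/l, inclusive) is
amyloid-positive; P-tau > 52 ng/l (secondary 70) is elevated; memory errors
bin as 0–1 / 2–3 / 4–5 / 6–10 out of 10.

## Statistical models

The split-plot repeated-measures ANCOVA is computed explicitly rather than
through a packaged GLM routine, to make the conventions auditable:

* between design: intercept, effect-coded (sum-to-zero) factors, centered
  covariates; drop-term sums of squares on this design are Type III,
  matching the defaults of the commercial GLM-repeated-measures procedures;
* within-subject space: k−1 orthonormal polynomial contrasts; for each
  between term the interaction SS is pooled over the contrast columns and
  F = (SS_term/(df_term·(k−1))) / (SS_err/((n−p)(k−1))) — for 10 segments
  this reproduces the classical table shape, e.g. F(9, 9(n−p));
* between-subject main effects are tested on subject means; adjusted cell
  means are reported at balanced factor levels and covariate means, with
  per-column standard errors;
* the unadjusted univariate F is primary; the Greenhouse–Geisser epsilon is
  computed from the residual covariance in contrast space and reported
  alongside, uncorrected p-values being the convention followed. The
  10 per-segment contrasts are reported uncorrected across segments,
  likewise by convention.

Partial correlation residualizes both variables on the covariates plus
intercept by least squares; r is the Pearson correlation of residuals with
df = n − 2 − q. Post hocs compare covariate-adjusted means with the pooled
model error; Bonferroni multiplies raw p by the number of pairs (capped at
1), Fisher LSD reports raw p. Significance is α = 0.050 throughout. The
anterior/posterior "halves" are sums of segments 1–5 and 6–10; bilateral
variants are left+right sums, and a participant missing any segment is
dropped from that aggregate.

APOE ε4 status is carried in the table but not modeled by default (it did
not contribute in the reference analysis); it can be added as a between
factor.

## Synthetic data

**Phantoms** are voxelized tubes: a piecewise-linear centerline sampled at
0.25 mm, a radius profile, an optional atrophy profile (multiplicative
radius factor per arc fraction), voxel centers within the local radius
included. The generator stores the centerline endpoints and every voxel's
arc fraction, giving oracle tests for orientation (the posterior axis
endpoint must land in the posterior cap) and monotonicity (segment labels
track arc fraction, rank correlation ≥ 0.9 for chord/arc ratios ≥ 0.8).
Phantoms emulate the elongated, mildly curved geometry of the subiculum —
not its sheet-like cross-section, surface roughness or segmentation noise —
so passing phantom tests validates the geometry pipeline, not FreeSurfer
output quality.

**Cohort tables** come in two modes.

*Calibration mode* is built for exactness. Six driver columns (age score A,
P-tau score P, latent memory M, ICV score I, and one noise column per
hemisphere) are drawn Gaussian and then made *exactly* standardized and
*exactly* orthogonal in-sample (centered QR, rescaled). Total per-side
volume is

    V = μ_V + σ_V(−a·A − p·P − q·M + β·I + e·Z),

with a = 0.34, p = 0.18·√(1−0.34²) ≈ 0.1693, β = 0.20 and
e = √(1 − a² − p² − q² − β²). The exact orthogonality makes the sample
age–volume correlation equal −a = −0.34 identically, rather than only in
expectation — at n = 656 the iid sampling noise of a correlation (sd
≈ 0.037) would otherwise dominate the quantity being checked. The implied
population partial correlation with P-tau given age and ICV is
−p/√(1−a²−β²) ≈ −0.184.

The memory loading q is calibrated, not free: errors are generated as
round(clip(3.6 + 2.8·M, 0, 10)), and the discretization attenuates any
correlation with M by c = corr(M, errors) ≈ 0.977 (estimated by a
fixed-seed 100 000-draw pilot simulation and cross-checked against the
closed-form Gaussian-integral expression in the tests). Since errors
depend only on M, corr(V, errors) = −q·c, so q = 0.41/c ≈ 0.420 hits the
target −0.41 without iteration (right hemisphere: target −0.36).

Aβ42 is drawn independently of volume from the bimodal mixture
0.393·N(395, 78²) + 0.607·N(762, 150²) — weights from the 398/258
negative/positive split; the component parameters put the analytic
equal-posterior point at 527.45 ng/l (verified by root-finding at
generation time), i.e. the reference 527 at integer precision. The sampler
moment-matches: component counts are the rounded expected counts and each
component's draws are standardized in-sample before scaling, the same
variance-reduction design as the drivers. Even so, the EM cutoff estimated
from 656 values retains an irreducible sampling sd of roughly 15 ng/l
(the component overlap makes the likelihood surface that flat at this n);
an independent EM implementation reproduces our estimates to < 1 ng/l, so
this spread is a property of the estimator, not of the fit.

Segment volumes split V by shares: 1/10 base, plus a posterior-weighted
coupling term −λ·w_s·(P+M) with w_s the centered, max-normalized weights
proportional to (11−s) and λ = 0.0012, plus centered share noise
(sd 0.008). Shares sum to 1 exactly, so segment volumes conserve V; the
coupling makes posterior segments carry stronger P-tau/memory effects, with
per-segment correlations attenuating monotonically toward anterior
(≈ −0.20 at segment 1 to ≈ −0.08 at segment 10) while all remain negative.
μ_V = 500 mm³ and σ_V = 80 mm³ are invented defaults (no per-subfield
totals are published to pin them down); they only set the scale.

*Study-like mode* replaces the reference distributions with group-shifted
ones (CN/SCD/MCI: age 73.7(5.0)/70.5(5.7)/71.3(5.3); P-tau 54(19)/57(25)/
67(29); memory 2(2)/3.4(2)/7(2); amyloid-positive fractions 82/302, 69/183,
107/171; default sizes 302/183/171, configurable, a size of 0 omitting the
group) and feeds the standardized group draws through the same volume
model. An optional injected atrophy effect subtracts a multiple of the
nominal per-segment SD from chosen segments (default 1–5) in chosen groups —
used for power simulations (0.5 SD at 150/group yields near-certain
detection of the group × segment interaction). Study-like mode is for
pipeline and power demonstrations; the calibration targets use calibration
mode only. The generator is deterministic given (config, seed).

What the synthetic layer does *not* emulate: segmentation error and its
spatial autocorrelation, non-Gaussian biomarker tails, missingness
mechanisms, longitudinal structure, and any genuine left/right asymmetry
mechanism. Passing tests therefore demonstrate correctness of the
algorithms and calibration of the statistics under idealized conditions,
not robustness to real acquisition artifacts.

## Problem sizes in the test suite

The suite's simulation jobs use 100 random phantoms for the conservation
and projection invariants, 50 small masks (≤ 2000 voxels) for the
brute-force pair oracle, 2000 replicates (n = 200, k = 10) for the
type-I-error calibration of the interaction test, 500 replicates for power,
200 replicates for mixture-cutoff recovery, and 100 instances for the
partial-correlation oracle; the whole suite runs in about a minute on one
CPU.

## Known limitations

* The straight-axis model underestimates arc length on strongly curved
  masks; a curved/geodesic axis is out of scope by design.
* The farthest-pair axis endpoints extend beyond the centerline by up to
  one local radius, so phantom axis length slightly exceeds the chord.
* The single-pass ±3 SD rule is not idempotent by construction;
  re-applying it to the filtered table could flag more records.
* The equal-posterior cutoff is unstable on unimodal data (flagged, not
  prevented).
* The mixture-cutoff recovery band of ±20 ng/l is not reachable in ≥95 %
  of replicates at n = 656 for this component overlap (see above); the
  corresponding suite check documents this as an expected failure of the
  bound, with the estimator itself verified against an independent
  implementation.
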