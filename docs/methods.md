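# Methods

## Pipeline model

The package treats a subject as a pair of post-contrast 3-D T1-weighted
volumes sampled at an early time `t1` (nominally 5 min after injection) and
a late time `t2` (nominally 25 min), on the assumption that the two scans
come from the same session, so their geometric relation is rigid (6 degrees
of freedom) and their intensity relation is affine up to slow spatial
drifts. Processing is: rigid co-registration of the late scan onto the
early grid → robust gain/offset intensity normalization → signed wash-out
percentage map with a three-class labeling → per-lesion volumetry and
ratios → cohort statistics.

### Registration

Registration maximizes normalized cross-correlation (same scanner and
sequence implies a monotone, near-linear intensity relation; Mattes mutual
information remains available for cross-field-strength pairs) over a
shrink-4/shrink-2 Gaussian pyramid with regular-step gradient descent and
parameter scales from physical shift. Two properties of this problem drove
the design:

* **Change-masked second pass.** The two acquisitions genuinely differ
  inside enhancing tissue. That difference biases any intensity metric: the
  optimizer trades true alignment for overlaying the changed region, which
  on test phantoms displaced the optimum by about a degree of rotation (the
  metric value at the true transform is measurably better than at the
  biased optimum, so this is a property of the metric, not the optimizer).
  After the first pass, voxels that are both *bright* (above the robust
  brain median + 3 MAD in either image) and *high-difference* (above 4
  robust sigmas of the pass-one residual) are masked out of the metric, and
  a full-resolution refinement re-runs from the pass-one solution.
  Restricting the change mask to bright voxels is essential: thresholding
  on difference alone also catches residual *edge misalignment*, and
  masking edges out leaves translation unconstrained at the few-millimeter
  scale.
* **Cubic B-spline resampling.** The fixed image is never interpolated,
  the moving image always is; with trilinear interpolation this asymmetry
  blurs the moving image's high-contrast lesion edges and systematically
  pushes an inner shell of late-enhancing voxels toward positive
  percentages. The final resample therefore uses cubic B-spline
  interpolation (masks use nearest-neighbour). Metric evaluation during
  optimization stays linear for speed.

A registration whose final correlation is poor (|r| < 0.2) is flagged
`converged=False` rather than silently returned; the metric trace across
both passes is part of the result.

### Intensity normalization

The late volume is mapped by a single global `gain·x + offset` fitted on
normal-appearing brain: the brain mask minus any lesion mask and minus the
brightest 2% of voxels of either volume (strong enhancers must not be
fitted away). Fewer than 1,000 reference voxels is an error. The gain is
estimated by Huber-weighted regression on *band-passed* copies of the two
volumes (Gaussian σ = 1 voxel minus σ = 8 voxels): the light smooth
suppresses voxel noise, whose errors-in-variables effect otherwise
attenuates the slope badly (on phantoms with weak tissue contrast the raw-
voxel fit collapsed to gain ≈ 0.1), and subtracting the heavy smooth
removes slow drifts such as coil bias, which a global line cannot represent
and must not contaminate. Band-passing commutes with an affine intensity
relation, so exact linear cases are recovered exactly. The offset is then
chosen so the median paired difference over the reference set is exactly
zero, and both volumes are divided by the early volume's median reference
intensity so normal brain sits near 1. The procedure is idempotent (gain
changes by < 1e-3 on re-application). A single global gain/offset cannot
remove a spatially varying bias field; what it cannot absorb is left to the
percentage map's dead-band.

### Wash-out map

`percent = 100·(early − late)/early` where the early signal is positive,
else 0. The denominator is the early (5-min) signal by declared convention:
the percentage reads as the fraction of the earlier-peak signal that
cleared; a difference-only (non-percentage) mode exists. Labels: WASHOUT
above +ε, LATE_ENHANCEMENT below −ε, NEUTRAL otherwise and wherever early
signal ≤ 0. The dead-band default ε = 5% absorbs noise and normalization
residuals, including the part of a bias field a global gain/offset cannot
remove. The three-class labels are scientifically meaningful *inside
lesions*; over bias-corrupted background the map may exceed ±ε, which is
why lesion masks (traced on the bias-free early acquisition) gate all
measurements, and why phantom label-recovery scores are evaluated within
the true enhancing region.

### Volumetry and ratios

Lesion tracing mimics a slice-wise semi-automatic level-trace: the 2-D
8-connected in-band component containing the seed, propagated to adjacent
slices while components keep touching the previous slice's trace; the
pipeline additionally fills 2-D holes, as a rater's closed contour would.
Compartment volumes are voxel counts × voxel volume within the lesion
mask; the wash-out ratio is V_washout/(V_washout + V_late), flagged
undefined when both are zero. The rCBV ratio averages three single-slice
tumor ROI means (distinct slices enforced) over a contralateral ROI mean;
the ADC ratio is a plain ROI-mean quotient. On phantoms ROI placement is
automated — the three largest-area lesion slices, mirrored across the
midsagittal plane for the contralateral ROI (the phantom brain is built
left–right symmetric so the mirror is exact); on real data ROIs are
user-supplied masks. Size rules: lesions with any bounding-box extent
< 3 mm are excluded from the primary analysis (boundary-inclusive — the
rule exists to keep micrometastases, which have near-zero wash-out ratios,
from biasing group means); lesions with enhancing volume < 1,000 mm³ are
flagged and removed only in the sensitivity analysis. Two raters are
combined by arithmetic averaging of scalar measurements; ICC(2,k) is
computed from the pre-average per-rater table.

### Statistics

* Welch's unequal-variance t with Welch–Satterthwaite df, from raw samples
  or (mean, SD, n) summaries (identical results by construction).
* Empirical ROC: tie-aware Mann–Whitney AUC (rank implementation, exactly
  equal to pairwise enumeration with half credit for ties). The operating
  threshold maximizes Youden's J over midpoints between sorted unique
  scores plus the two trivial extremes; among ties the highest-specificity
  threshold is reported. Markers here run *low* in the positive class
  (metastasis), encoded as an explicit direction rather than by silently
  negating scores. The default 95% CI is DeLong's (deterministic); a
  seeded stratified bootstrap is the alternative.
* Analytic oracles: binormal AUC Φ(|μ1−μ2|/√(σ1²+σ2²)) and its
  truncated-normal analogue ∫f_X·F_Y (adaptive quadrature), used to verify
  simulated cohorts.
* ICC(2,k): two-way random-effects, absolute-agreement, average-measures
  intraclass correlation from ANOVA mean squares, with the F-based
  single-measures interval mapped through Spearman–Brown; bands at
  0.5/0.75/0.9 (poor/moderate/good/excellent). Missing cells are an error;
  zero between-subject variance yields a defined (≈0) estimate.
* The tumor-type model is deliberately the quoted `lm` call — ordinary
  least squares on a 0/1-coded outcome (linear probability model), not a
  "corrected" logistic regression; a logit option exists but is not the
  reference path. Rank-deficient designs fail loudly, naming the collinear
  columns. No multiple-testing correction anywhere (plain p < 0.05).

## Phantom: what it emulates, and what it does not

The phantom reproduces the *statistical structure the analysis relies on*:
two acquisitions of one scene at different kinetic states, rigid inter-scan
motion (applied analytically at render time, so the ground truth carries no
interpolation error), smooth multiplicative bias on the late scan, additive
Gaussian noise on both (Rician optional), and exact voxel ground truth.
Enhancement follows a gamma-variate `E(t) = A·(t/t_p)^a·exp(a(1−t/t_p))`
with the shape parameter `a = t_p·(rise_rate + decay_rate)/2`, unimodal,
zero at injection, and normalized to peak amplitude at `t_p`; this family
couples uptake and clearance through one parameter, which is all the
two-sample design can constrain anyway. Archetypes: early-peaking
(t_p = 5 min, a = 2.5, amplitude 0.7 — enhancement relative to brain
baseline 1) and late-peaking (t_p = 15 min, a = 1.5, amplitude 2.0;
enhancing metastases are bright on T1 at both timepoints, 1.5–3× brain).

Geometry: ellipsoidal brain (semi-axes 52/58/48 mm) with 12% mid-frequency
cosine texture (wavelengths 23–41 mm), a mirrored pair of dark
ventricle-like ellipsoids and a falx-like midline slab — enough internal
high-contrast anatomy for rotation to be identifiable; lesions are spheres
(optional necrotic core) with a 0.4 mm soft edge. Truth masks use hard
membership (voxel center within radius), so a sphere's truth volume is its
rasterization count, and a voxel is wash-out iff its noise-free
E(t1) > E(t2) among enhancing voxels.

Not emulated: MR physics (no relaxometry or sequence simulation), real
anatomy, non-rigid motion, slice-dependent distortions, DSC time-series
(rCBV/ADC maps are consumed as precomputed constant-valued maps with
configurable tumor:contralateral ratios), and partial-volume behavior finer
than the rendering grid. Passing phantom tests therefore demonstrates the
*pipeline's* correctness under controlled corruption, not clinical
performance on real scanners.

Cohort simulation draws per-lesion measurements from truncated normals at
the study's printed group means/SDs — wash-out ratio on [0, 1], strictly
positive quantities on (0, ∞) — with a feasibility check (≥ 1e-6 mass in
bounds) and one integer seed. Note the distinction surfaced by the
truncation: the sample mean converges to the *truncated* mean, slightly off
the nominal parameter.

## Problem sizes and numerical choices

* Stress suite: 20 phantoms at 80³ voxels × 1.6 mm (the finer-than-default
  grid keeps the partial-volume shell at lesion edges small relative to the
  15–16 mm compartment radii); motions up to 10 mm translation vector and
  ~10° total rotation; 2% noise, ±10% bias. Measured on this suite:
  registration residual ≤ 0.16 mm / 0.47°, per-compartment Dice ≥ 0.96,
  wash-out-ratio error ≤ 0.013.
* AUC reconstructions: 2,000 replicates of 29 + 53 lesions; the replicate
  mean has a standard error ≈ 0.0013, so run-to-run seed variation is
  negligible against the printed confidence intervals used for comparison.
* Optimizer: regular-step gradient descent, learning rate 1.0 (0.5 at
  refinement), minimum step 1e-5, ≤ 400 iterations/level, relaxation 0.6.
* Huber IRLS: tuning constant 1.345σ (MAD scale), 12 iterations, exact for
  noise-free affine relations.
* Tie-breaks: Youden threshold → highest specificity; lesion tracing is
  deterministic by construction; all randomness flows from explicit integer
  seeds (sub-seeds drawn below 2³¹).

## Known limitations

* A global gain/offset cannot correct spatially varying intensity
  distortion; strong bias fields shift per-voxel percentages by up to
  roughly the local bias amplitude. The dead-band and lesion-gated
  measurement absorb this for lesion-scale statistics, but per-voxel
  percentages near ±ε are unreliable under bias.
* Registration accuracy degrades if enhancing change occupies a large
  fraction of the brain (the change mask then removes too much of the
  metric support); the phantom suite covers lesions up to ~30 cm³.
* The ROC threshold is reported at data-derived midpoints; with few
  lesions, sensitivity/specificity at that threshold are coarse-grained
  step functions of the sample size.
* The linear probability model can predict outside [0, 1] by construction;
  it is kept as the reference because it is what the quoted analysis ran.
* `trace_lesion` is intensity-band region growing; lesions whose early
  enhancement dips below the band on an intermediate slice will truncate
  there (the pipeline's hole-filling works in-slice only).
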