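# Methods

## Signal model and preprocessing

A subject's data is a 4D series on a fixed grid with an explicit time axis in
minutes since the start of intracisternal infusion (t = 0). The default
schedule is 25 frames every 5 min from 30 to 150 min; frame times are always
supplied by the caller, never inferred from NIfTI headers, whose timing
semantics are unreliable for interleaved DCE protocols. Masks and label
volumes must share the series grid exactly — registration and resampling are
out of scope and assumed done upstream.

**Percent signal change.** A reference ROI in kinetically quiet tissue
defines the baseline. The window of `window_length` (default 6) consecutive
frames minimizing the standard deviation of the ROI-mean trace is selected
per subject (ties break to the earliest window; a cohort-fixed window can be
imposed by passing the same `ReferenceWindow`). Every voxel then maps
x → 100·(x − m)/m with a single scalar m = mean over (ROI voxels × window
frames). The scalar-baseline choice follows the reference-region convention;
a per-voxel baseline is available behind a flag but changes the meaning of
the output (it removes anatomy-driven baseline contrast along with the
offsets). Normalization is exactly invariant to global intensity rescaling,
and the ROI×window mean of the output is 0 by construction.

**Smoothing.** Each frame is convolved with a truncated isotropic Gaussian in
voxel units; the kernel support half-width equals `smooth_radius_voxels`
(default 2) and σ defaults to half the radius, so the stated support is
exact. Weights are renormalized over the brain mask, so no signal bleeds
across the mask boundary and constants are preserved inside it. Smoothing is
strictly spatial; the time axis is never filtered. Order of operations:
normalize, then smooth, then restrict to the mask.

## Denoising and clustering

Voxel time courses form a voxels × frames matrix. PCA removes the voxel-mean
time course, takes the thin SVD over the frame dimension, and retains the
smallest number of components whose cumulative explained variance reaches
`variance_threshold` (default 0.99), capped at `max_components` (default 3).
Centering is deliberate: uncentered PCA would fold the global uptake curve
into component 1. A constant matrix reconstructs to itself with zero
components and a warning.

Ward agglomerative clustering (Euclidean distance, the criterion's canonical
metric) partitions the reconstructed time courses with a flat cut at
`max_clusters` (default 15); no model-selection rule below the cap is
applied. Cluster ids are relabeled by voxel count, smallest first, making
maps comparable across runs. Clusters are *selected* for kinetic modelling
when they have at least `min_voxels` (default 100) voxels and their
group-level mean trace spans strictly more than `min_range_percent` (default
10) percentage points — the excursion scale that separates genuine
contrast dynamics from the baseline variability that kinetics-free control
cohorts exhibit. Selection is idempotent and evaluated on the group-level
trace because clusters are defined at group level.

For cross-group comparisons the selected clusters of one reference group
(configurable; by default the group with the most selected clusters) define
the voxel sets in which every subject's mean time course is extracted, so
both groups are compared over identical voxels.

## Kinetic model and fitting

f(t) = c1·(1 − e^(−t/τ_in)) + c2·(e^(−t/τ_out) − 1), gains in percent units,
time constants in minutes, f(0) = 0 with no offset term. Fitting minimizes
the sum of squared residuals over (c1, c2, log τ_in, log τ_out) with
non-negative gains (box bounds) and time constants confined to
[10⁻², 10⁴] min — below ~2 min the influx exponential is invisible at a
30-min first sample and an unbounded search can drift indefinitely along a
flat valley. Each member of a deterministic start grid
(τ_in ∈ {1, 5, 15, 40}, τ_out ∈ {30, 120} by default) is opened with the
exact non-negative linear-least-squares gains for its time constants
(variable projection), then refined by trust-region-reflective least squares
with analytic Jacobian (ftol 1e−10, up to 1000 function evaluations per
start); the best SSE wins. A seeded random-restart fallback triggers only if
every grid start fails outright. Fits never raise on data; non-convergence is
reported in the result. τ_out beyond twice the observation window is flagged
as extrapolated but not constrained (reported efflux constants do exceed the
window). Monte-Carlo sweeps in the tests and the acceptance script use a
reduced grid (τ_in ∈ {1, 5, 15}, τ_out ∈ {60}, 150 evaluations per start),
which changes individual fits negligibly at a third of the cost.

**Identifiability.** With the first sample 30 min post-injection, the data
contain essentially no information about τ_in below ~5 min
(e^(−30/2.6) ≈ 10⁻⁵): the likelihood is flat in that direction and any
least-squares estimate scatters over the unidentified range. The
Fisher-information (Cramér–Rao) bound at this 25-frame design puts the
relative sd of τ̂_in at roughly 40–170% for additive noise of 1 percent
point per frame across the τ_in ∈ [2, 25] min regime. Two consequences are
documented rather than hidden: (i) single-trace noisy recovery of τ_in at
σ = 1 has a median relative error of ~50%, an estimator-variance floor that
no least-squares fitter can beat (the package verifies its fits reach
SSE ≤ SSE(truth)); (ii) cluster-level analyses are far better conditioned,
because cluster-mean traces average ≥100 voxels and carry ~10× less noise.

**Group statistics.** Two-sided two-sample t-tests (pooled variance by
default, Welch by flag) compare per-subject fitted τ_in and τ_out per
cluster, and per-ROI trapezoid AUC of subject-level PCA-reconstructed
traces, at α = 0.05 with no multiple-testing correction. The planted-effect
simulation draws per-subject τ_in lognormally with group means 2.6 vs
13.1 min and between-subject sd equal to the reported per-group sem values
(1.5 and 2.8 min); read as the population sd·√n instead, even the
zero-fit-noise ideal power of the t-test is only ~83–89%, so the sem-as-sd
reading is taken as the intended cohort condition. Trace noise for these
cluster-level cohorts is 0.1 percent points, the cluster-mean noise implied
by ≥100-voxel clusters at the phantom's voxel-level σ = 1. Under these
conditions the influx test rejects in ~100% of cohorts and the efflux null
test stays at the nominal 5% level.

## Synthetic phantom

The phantom emulates the statistical structure the analysis assumes, not
anatomy. An ellipsoidal brain contains six disjoint ellipsoidal regions in a
3×2 caudal-to-rostral arrangement plus a quiet dorsal reference box. Voxel
raw signal is s_v(t) = b_v·(1 + (1 + γ_v)·f_r(v)(t)/100) + ε with lognormal
baseline b_v (default cv 2%, the residual within-brain baseline spread after
normalization), Gaussian gain jitter γ_v (sd 5%), and additive Gaussian noise
ε calibrated to `noise_sd_percent` (default 1) percent-signal units. Noise is
Gaussian rather than Rician: at the high SNR of percent-change data the
difference is negligible and Gaussian keeps the fitting theory clean.
Per-subject time constants are drawn lognormally around group means with
cv 30%. Subjects use independent seed substreams, so altering or adding one
subject leaves the others bit-identical.

Default group parameters put τ_in at 1–25 min and τ_out at 30–180 min — the
regime of reported in-vivo cluster estimates — with caudal regions showing a
strong influx slowdown in the disease-like group. Region gains were chosen
once so that every pair of region mean curves is well separated (Euclidean
distance ≥ ~45 percent-frames in both groups), giving clustering a
well-defined ground truth; amplitudes (up to ~60% peak enhancement) are in
the range seen near the injection site. At zero noise and heterogeneity the
pipeline's normalization inverts the generative model exactly, which the
tests exploit as an analytic oracle.

What the phantom does *not* emulate: anatomy, CSF flow physics, motion,
registration error, Rician noise floors, and spatially correlated baselines.
Passing phantom tests therefore validates the computational chain, not the
biology of any particular dataset.

**Problem sizes.** The clustering-recovery experiment uses the native
48×48×32 grid (regions of ~470 voxels) but clusters only the region voxels;
the end-to-end pipeline demonstrations use a 32×32×24 grid (~10⁴ brain
voxels), where whole-brain ward clustering is comfortable in memory; the
flat-cohort selection check uses 24×24×16. The recovery experiment runs on
unsmoothed normalized data: at these region radii (3–7 voxels) the partial
volume gradient that smoothing imprints on region edges dominates ward
distances and measures kernel size, not implementation correctness. The
flat-phantom check keeps full preprocessing, where smoothing only helps.

## Histology quantification

Thresholds operate on 256-bin histograms over the observed intensity range
(the 8-bit convention), making all quantities invariant to positive
rescaling of a channel. The Triangle threshold draws a chord from the
histogram peak (counts normalized to unit height) to the farthest non-empty
bin on the longer-tail side and thresholds at the bin farthest from the
chord; ties resolve toward the peak. The Li threshold iterates the minimum
cross-entropy update t ← (μ_f − μ_b)/(ln μ_f − ln μ_b) from the overall mean
until the change is below half a bin width. Both are validated against
exhaustive-search oracles; for Li the iterative fixed point and the discrete
argmin can sit a bin or two apart inside an empty inter-mode valley, so
agreement is asserted as segmentation equivalence (negligible histogram mass
between the two thresholds). Implementations are independent of
scikit-image, which serves as a cross-check in the tests.

Component filtering uses 8-connectivity by default (configurable to 4) and
retains components *strictly* larger than the size threshold (300 px for
vessel stains, 50 px for astrocyte stains). Vascular density is the retained
vessel-mask fraction of the plaque-free field, with plaque pixels (Triangle
threshold on the thioflavin channel, dilation margin default 0 px) excluded
from numerator and denominator alike. Total mean GFAP signal is the
unweighted mean of per-component mean intensities — absence of surviving
components is reported as missing, not zero. Fractional vessel coverage is
|GFAP mask ∩ lectin mask| / |lectin mask|, computed as a direct set
intersection; an optional hue-composite mode (red/green merge, hue window
10–80 of 255) reproduces the manual-tool realization of the same operation
and is verified to agree exactly. Downstream mixed-effects statistics are out
of scope; the module exports per-image summary quantities.

The synthetic fixture paints vessels as smoothed random-walk tubes until a
target area fraction is reached, astrocyte disks centred on vessel pixels
until a target overlap fraction is reached (plus a base population of
off-vessel astrocyte blobs that keeps the GFAP foreground fraction at a few
percent — Li's threshold collapses toward the background mode when the
foreground is a fraction of a percent), and optional plaque discs. Planted
density and coverage are recovered within ±0.01 on 512×512 images.

## Numerical and degenerate-input policy

- Degenerate smoothing radius (σ below machine epsilon) is the identity.
- Constant images are rejected by thresholding operations ("degenerate
  histogram"); featureless channels yield density 0 or a missing GFAP value
  rather than errors in the composite quantities.
- Ward merge ties follow the deterministic behavior of the linkage
  implementation for a fixed input ordering; all-identical inputs still
  conserve voxel counts across the cut.
- Equal-variance t-tests on two identical zero-variance samples report
  t = 0, p = 1.
- CSV outputs round-trip at 12 significant digits; label volumes round-trip
  bit-exactly; series storage is float32.

## Known limitations

- τ_in is unidentifiable below ~5 min at a 30-min first sample (see above);
  interpret small fitted influx constants as "fast", not as point estimates.
- The 10%-excursion selection threshold is a configurable default, not a
  fitted quantity; cohorts with different noise floors warrant re-derivation
  from their own control groups.
- The hue-composite coverage mode assumes the exact red/green composite
  construction; arbitrary pseudo-coloring breaks the 10–80 window
  correspondence (the intersection mode does not care).
- Whole-brain ward clustering is O(n²) memory in voxels; beyond ~3·10⁴
  voxels, cluster region subsets or downsample.
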