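# Methods

This note documents the models, parameter choices and numerical decisions
behind `achrf`, and what the phantom-based validation does and does not
demonstrate.

## Detection pipeline

The counter assumes an 8-bit grayscale line B-scan with the anterior (air)
side at row 0: a bright corneal band high in the frame, a dark aqueous
chamber below it, bright iris bands with a pupillary gap bridged by the
anterior lens capsule, and speckle noise everywhere. All stages are
deterministic; the parameter set is hashed into every result
(`params_digest`) so a run is reproducible from its config.

**Gaussian blur** (`gaussian_sigma_px`, default 1.0). Suppresses
single-pixel speckle before thresholding. The sigma must not exceed the
focus radius or neighbouring foci merge; 1 px matches the point-spread
width of a focus on the default pixel grid (below).

**Triangle threshold.** The Zack construction on the 256-bin histogram:
find the peak bin; pick the farthest nonempty bin on the longer-tail side
(side ties go bright, since foci are bright on a dark background); return
the bin between them maximizing the perpendicular distance to the
peak-to-tail chord. Numerical choices: the distance argmax is computed from
exact integer cross products (the chord length is a constant factor, so no
normalization is needed and no floating-point ties arise); distance ties go
to the bin closest to the peak; a single-bin histogram returns that bin; a
tail adjacent to the peak returns the peak. The implementation agrees
exactly with scikit-image's `threshold_triangle` on phantom images and with
an exhaustive rational-arithmetic search on random histograms.

**Binarization** is strict (`gray > t`), so a threshold of 255 yields an
empty mask and the true-pixel count always equals the histogram tail sum.

**Morphological cleanup** (`morph_op=open`, `morph_element=cross3`). After
blurring, speckle exceedances are spatially correlated: an isolated noise
event crosses the threshold as a compact ~2×2 block, not a single pixel. An
opening with a 2×2 square preserves such blocks by construction and was
measured to leave a false focus in ~6 % of empty-chamber phantoms; the
plus-shaped 3×3 element removes them, while any real focus bright enough to
clear the threshold has a round supra-threshold footprint at least three
pixels wide and passes unchanged. The minimum detectable focus is set by
blur + threshold, not by the element, so the choice sacrifices no
legitimate detections. With the cross element, zero false positives were
observed in 100 empty phantoms.

**AC segmentation.** "Contour detection" is operationalized as per-column
extents of large connected components rather than active contours: robust
on band-like anatomy and exactly testable. Components with area ≥
`min_structure_area_px` (500) are anatomy; anything smaller (cells,
specks) cannot perturb the boundaries. The cornea is the anterior-most
structure spanning at least half the width — if none does, the scan is
rejected as unusable, the same action an operator takes on a failed
acquisition. The iris/lens boundary takes, per column, the topmost
non-cornea structure below the posterior cornea; pupil-gap columns where
the lens capsule reflects faintly are filled by linear interpolation
(PCHIP available), which slightly under-cuts the shallow capsule arc and
therefore only shrinks the ROI conservatively. The ROI is the open band
between the boundaries minus a `roi_margin_px` (3) guard; the background
region is everything above the cornea's top extent minus the same margin —
the only area guaranteed to contain nothing but speckle. The detected
posterior-cornea boundary sits systematically ~2 px below the geometric
tissue edge (the blurred edge ramp crosses the threshold slightly beyond
the band); the margin exists to absorb exactly this bloom. At the extreme
corneal periphery, where the arc descends several pixels per column, the
bloom grows accordingly; those columns lie outside the ROI and do not
affect counting.

**Particle filter.** Components of the cleaned mask inside the ROI
(8-connected by default) are counted as foci iff `min_area_px (2) ≤ area ≤
max_area_px (50)` and the peak of the *source* (pre-blur) image over the
component strictly exceeds the outside-cornea mean `μ_out`
(`intensity_rule=mean_out`; `mean_plus_k_sd` raises the bar by `k` background
standard deviations). The peak statistic is robust to partial-volume
dimming of two-pixel foci; the area cap excludes large artifacts such as
fibrin strands or boundary bleed. A component overlapping the ROI border is
kept iff its centroid lies inside the ROI, preventing double counting of
foci split by the margin. Setting `min_area_px=1` recovers the literal
any-supra-threshold rule.

## Phantom model

The phantom exists to give every pipeline stage a known ground truth. It
renders circular-arc cornea (anterior/posterior radii 420/380 px, apex row
40, thickness 35 px), an aqueous chamber 170 px deep, iris bands
(thickness 30 px) flanking a 220 px pupillary gap bridged by a thin
anterior-lens-capsule arc, on a 512×768 grid emulating a 14 mm line scan
(~18 µm/px lateral). The iris stops 12 px short of where the descending
posterior cornea would reach it, leaving a dark angle recess; this keeps
cornea and iris as separate connected components, as in a usable scan, and
is required for boundary tracing to be a meaningful test.

Noise: a Rayleigh-distributed additive floor (scale 8 → mean ≈ 10.0,
SD ≈ 5.2 gray levels) in air and aqueous — OCT speckle is heavy-tailed and
non-negative — and Gaussian jitter (SD 15) on tissue bands around mean 200.
Exact device statistics are not knowable from published material; these
values give a realistic dark-chamber appearance with tissue contrast ~20:1.

Foci are additive isotropic Gaussian bumps, peak 180, σ = 1.0 px, placed
uniformly over the chamber eroded by the rendered bump window (4σ + 2 px)
with rejection sampling enforcing a minimum separation of 8 px. The σ of
1.0 px follows from the device point spread: leukocytes (7–9 µm) are far
below the 30–45 µm lateral resolution, so a cell images as the PSF, about
one pixel of σ on this grid. The 8 px separation exceeds the diameter of a
focus's supra-threshold footprint (~6.6 px at the default threshold), so
distinct implanted foci can never merge into one component — without this,
the unit-increment property could not hold. A focus is flagged *countable*
when its rendered pre-clip peak is at least 3 background SDs above the
background mean, or its detectable footprint exceeds two pixels — the
conventional reading of "brighter than the background noise or larger than
two pixels"; at the defaults both branches hold for every focus.

Determinism: anatomy/noise and focus placement draw from separate
substreams of the seed, so the same spec is byte-identical and adding one
focus changes the image only inside the new bump's window.

### What the phantom does not emulate

No interferometric speckle correlation (noise is i.i.d. per pixel before
blurring), no sensitivity roll-off, motion or corneal-reflex artifacts, no
hypopyon, no pigment-vs-leukocyte distinction, no intensity/size diversity
among foci (all share one peak and radius), and uniform spatial placement
(real cells may settle inferiorly; a vertical gradient would be a
straightforward extension). Passing the phantom validation therefore
demonstrates the *algorithmic* correctness of the chain on images that
satisfy its geometric assumptions, not clinical performance on device
exports.

## Statistics

SUN grades enter regressions recoded to consecutive integer steps 0–5, so
"per 1-step increase" means one position on the ordinal ladder
(0 → 0.5+ → 1+ → …).

**Agreement ICC.** The paired two-method design is always balanced, so the
two-way mixed model (method and optionally grade fixed, subject random) is
solved in closed form: within-subject differences carry the method effect
and residual variance (`σ²_e = Var(d)/2`); subject means regressed on the
grade covariate carry the subject variance
(`σ²_b = max(0, MS_means − σ²_e/2)`); `ICC = σ²_b/(σ²_b + σ²_e)`. With no
grade covariate this equals the classical consistency ICC(C,1) exactly
(verified against pingouin to 1e-10 and against the ANOVA decomposition to
1e-8). Degenerate perfect agreement (zero residual) returns 1.0.

**Mixed-effects regressions** use statsmodels MixedLM (REML) with a
per-patient random intercept; p-values are normal approximations on the
coefficient z (exact small-sample df methods are out of scope). Covariates
with no variation in the data are dropped from the design. When the fit is
degenerate — one observation per patient, a perfect noiseless fit, or
non-convergence — the fixed effects fall back to ordinary least squares
with the between-patient variance reported as zero, which is the REML
limit in those cases. Zero counts make a raw log undefined, so the log
model uses `ln(count + 1)`; the multiplicative effect per grade step is
reported as `100·(e^β − 1)` %.

**Descriptive tables** use linear-interpolation (type-7) quantiles, the
common default.

## Validation experiments and problem sizes

`achrf.experiments` packages the validation protocol; the acceptance
script and the test suite both drive it. Sizes were chosen to keep the
whole battery around a minute while leaving no sampling ambiguity: a
60-eye graded cohort (per-grade count medians near 2/10/22/27/128/474,
with IQR-like spread at the lower grades, matching a representative
uveitis cohort) for agreement; 1000 random histograms and 1000 random
64×64 masks for exact oracle equivalence; 50 phantoms for segmentation
quality (IoU vs true chamber ≥ 0.90); 50 empty phantoms and 100 paired
increment runs for specificity/sensitivity; 200 replicates for
mixed-model parameter recovery and for quiet-uveitis-vs-control power
(Poisson rates 2.4 vs 0.6, matching group medians 2 [IQR 0–4] and
0 [IQR 0–1] at n = 40/20).

## Known limitations

Real device exports may differ in bit depth, dimensions and histogram
shape from the phantom; the Triangle threshold adapts, but the fixed
defaults (area bounds, margins, minimum structure area) are tuned to the
default 512×768 geometry and should be scaled for very different grids.
The counter cannot distinguish leukocytes from pigment or other particles,
and does not subtype foci by size or brightness. Statistics assume
Gaussian residuals on (possibly log-transformed) counts; strongly skewed
raw counts are better analyzed on the log scale.
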