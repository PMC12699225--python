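# Methods

This note documents the models, conventions and numerical choices behind
each pipeline stage, what the synthetic generators do and do not emulate,
and the known limitations. Everything quantitative stated here is computed
by the test suite or `scripts/acceptance.py`.

## Acquisition model

Widefield movies interleave three LEDs at 30 Hz (10 Hz per channel): blue
(470 nm, GCaMP6f excitation), green (570 nm, haemoglobin isosbestic — total
haemoglobin / CBV), red (620 nm, deoxyhaemoglobin-weighted — BOLD-like).
The camera matrix is 260 × 348 px over a 4.4 × 5.9 mm field (~16.9 µm/px
raw, 33.7 µm/px after 2× binning). The LED cycle phase is not recoverable
from pixel statistics, so the channel order is always explicit configuration.
Trailing frames that do not complete an LED cycle are dropped, never imputed.
Each channel keeps its own acquisition timestamps; all downstream windows
are defined in seconds, not frame indices.

Two-photon stacks sample 1130 µm over 512 px (2.207 µm/px in-plane) with a
3 µm z-step; these defaults parameterise voxel volumes throughout.

## Preprocessing

**Spatial binning** is a block mean (factor 2 by default); trailing
rows/columns that do not fill a block are discarded and the pixel size is
scaled accordingly.

**Rigid registration** estimates per-frame translation against the
session's first frame by Fourier cross-correlation with sub-pixel
upsampling (factor 20). Shifts are estimated on the 570-nm channel — the
channels are near-simultaneous and vessel contrast is strongest there — and
the same shifts are applied to all three channels. Resampling uses Fourier
phase shifting (no interpolation blur, which would bias FWHM diametry);
the wrapped 2-px border is overwritten by edge replication. Estimates above
a configurable maximum (10 px) are clipped with a warning — displacements of
that size mean the rigid model has failed for the frame. Frames moving more
than 5 binned px can be excluded from trial averages via
`RigidShift.frames_ok`.

**Intensity correction** regresses the mean trace of a skull/head-bar
control region (plus intercept) out of every pixel's time series, then adds
the pixel's temporal mean back so that ΔF/F₀ and ΔR/R₀ denominators remain
physically meaningful. The operation is idempotent to numerical tolerance.
The raw control trace is regressed (an optional box-smoothing window exists,
default off).

## Evoked quantification

Per trial, F₀ is the per-pixel mean over the 2 s before onset and the epoch
runs from onset to onset + stimulus + 8 s — the response window is sized to
capture the slower haemodynamic peak within the shortest (16-s)
inter-stimulus interval. Trials are averaged time-point by time-point;
pixels with non-positive F₀ are flagged invalid and excluded from ROI
search. The activation map reduces the trial-averaged movie by the
per-pixel peak over the stimulus epoch (a mean reduction is available).

The barrel ROI grows greedily from the global activation maximum, repeatedly
adding the highest-valued pixel 8-connected to the region until it holds
100 pixels; a threshold-then-component variant exists behind a flag for
sensitivity checks. Peaks are the signed extremum of largest magnitude of
the ROI-mean trace within the epoch, in percent; the 620-nm ΔR/R₀ is
reported as-is (reflectance rise = BOLD-like positive). The coupling
readout is peak BOLD / peak GCaMP.

## Hypercapnia quantification

The temporal-mean 570-nm image inside the manually drawn brain ROI is
divided by a heavy Gaussian blur of itself (σ = 20 binned px, normalised
convolution restricted to the ROI) to flatten illumination, then K-means
with k = 2 on the 1-D flattened intensities separates hemoglobin-dark
vessels from tissue; the lower-mean cluster is removed. K-means is seeded
(default 0) and, on 1-D data, cross-checked in the tests against an exact
split-point oracle. Degenerate clustering is judged by relative
cluster-mean contrast (< 5% of the brighter cluster mean): a vessel-free
unimodal image still splits into two half-distributions with silhouette
≈ 0.5, so a silhouette criterion cannot detect the degenerate case; real
570-nm vessels are tens of percent darker while a pure-noise split differs
by ~1.6 noise SD. The silhouette of the partition is still reported as a
diagnostic.

Tissue traces are per-frame means over the retained pixels. Each CO₂ repeat
is normalised to its own 30-s pre-onset baseline; the fractional-change
epochs are averaged across the two repeats and the peak is the signed
extremum of largest magnitude inside the 90-s stimulus window. The 570-nm
trace is negated before reporting so that an absorption rise (more blood)
is positive reactivity in both channels; the convention is recorded in the
result. Gain rescaling of the raw intensities leaves the peaks unchanged
(asserted); an additive camera offset is *not* removed by fractional-change
normalisation — it attenuates the peak by baseline/(baseline + offset) — so
dark-level subtraction belongs upstream of this pipeline.

## FWHM diametry

Profiles are sampled by bilinear interpolation at 0.25× pixel steps along a
probe perpendicular to the local vessel axis, averaged over 5 parallel
lines offset 1 px along the axis (the vessel is locally straight, so this
suppresses pixel noise without blurring the cross-section). Polarity is
per-channel configuration (dark at 570 nm), never inferred.

The width estimator: light moving-average smoothing (3 samples,
edge-replicated); baseline = median of the outer 20% of samples at each end
(local, so neighbouring vessels do not bias the half level); trough depth
from a local mean around the minimum — a raw noisy minimum is extreme-value
biased low, which deepens the half level and shrinks the width; crossings
bracketed by walking outward from the extremum and refined by a local
least-squares line — a first-crossing rule alone stops at the earliest
noise excursion and is biased inward. Both averaging windows scale with the
measured tail-noise-to-contrast ratio (capped at 8% and 6% of the rough
width), so noiseless profiles keep the rough estimate's locality and the
analytic identities hold: a top-hat's FWHM equals its width, a Gaussian's
equals 2√(2 ln 2)·σ. Measurements fail (vessel skipped, logged) when the
extremum sits at the profile edge, crossings are missing, or contrast is
below 3× the tail noise.

Baseline diameters are measured on the temporal mean of the 30-s baseline
window (noise ↓ ~√n before the profile is measured). Recovery, verified in
the acceptance suite over 10–150 µm × 8 orientations × 5 sub-pixel offsets
at per-pixel SNR 10: diameter error < 2% in ≥ 95% of 280 conditions.

Percent dilation smooths the per-frame diameter series with a 3-frame
moving average (NaN-aware) so the peak cannot be a single-frame noise
excursion, normalises each repeat to its own baseline mean, averages the
repeats at the epoch level, and reports 100× the deviation of largest
magnitude with its sign. Peak-over-window estimators carry a positive noise
bias of roughly 2σ of the smoothed series (~0.8 pp at 1% diameter noise);
this is intrinsic to any "peak absolute change" definition and is why
recovery tests compare the mean over replicates. Vessels with > 20% failed
frames in the baseline or stimulus window are excluded.

The arterial median split computes the cohort median of arterial baseline
diameters (an output of the data, never an input); "large" includes the
median exactly. With all-equal diameters every vessel classifies large and
a warning is emitted.

## Two-photon quantification

Preprocessing per slice: 3 × 3 median filter, Gaussian smoothing
(σ = 0.4 px), division by a heavy blur (σ = 50 px) of the z-mean image;
then depth normalisation over Q = 4 equal-depth z-bins (configurable — the
bin count is a genuinely open choice), each rescaled to the shallowest
bin's mean.

CAA: threshold = mean + 1.5 SD of the methoxy MIP intensity within each
manually outlined vessel; CAA pixels are strictly above it; coverage pools
pixels across vessels. Two structural properties of this rule worth
knowing: it is gain-invariant (both mean and SD scale), and it can only
flag *minority*-bright fractions — for a bright fraction f the threshold
exceeds the bright level once f − 1 + 1.5√(f(1−f)) ≥ 0, i.e. f ≳ 0.36, so a
vessel more than about a third covered saturates the estimate. It also
reports a noise floor of a few percent on amyloid-free vessels (a
mean + 1.5 SD cut on pure noise flags the upper tail).

Plaques: the MIP-level CAA mask is extruded through z and zeroed (the
z-resolved geometry of wall amyloid is not recoverable from a MIP-defined
mask); candidates are strictly above 0.6 × the remaining volume maximum;
26-connected components (6 by flag) strictly larger than 15 voxels count as
plaques, and volume = retained voxels × voxel volume (2.207 × 2.207 × 3 µm³
default). Two guards: an all-zero volume returns (0, 0), and a majority
candidate set — which arises whenever no bright object exists, since 0.6 ×
a background maximum selects most of the tissue — is treated as plaque-free
with a warning (plaques are sparse by definition). Known limitation: run
after the full smoothing chain, the 0.6 threshold shaves blurred sphere
boundaries by roughly 7–11% of volume for 2.5–3.5-voxel-radius objects;
component counts and the strict > 15-voxel rule are unaffected, and on
unsmoothed volumes recovery is exact (threshold margin ≫ noise).

Session averages are arithmetic means over the session's 2–4 images.

## Statistics

`fit_lme` fits the fixed-effect formula with a random intercept per mouse
by REML (statsmodels MixedLM behind the interface; optimiser falls back
bfgs → powell → nm). With one observation per mouse the random intercept is
inestimable and the fit falls back to OLS with a warning (the two coincide
in that limit). Rank-deficient designs raise an error naming a collinear
term. Per-term Wald tests use a **between-within** denominator-df
convention, recorded in every output: a term constant within every mouse
tests against between-mouse df (n_mice − n_between terms), a
within-varying term against n_obs − n_mice − n_within terms. Under the null
generator at the study design (32 mice, ~5.4 visits), per-term rejection at
nominal 0.05 calibrates to 0.049–0.060 over 1000 simulations (acceptance
suite). The exact df convention of any given external analysis is rarely
recoverable; reporting the convention with the numbers is the portable
choice.

`johnson_neyman` solves θ(m)² = t²crit·var θ(m) in closed form (quadratic in
the moderator), handles the degenerate constant-slope cases, classifies
significance on each side, and exposes `loss_boundary()` — the root at
which significance is lost as the moderator increases, which is the
scientifically relevant crossing for an age-moderated slope. t_crit uses
the df assigned to the interaction term (override available). Vessel-level
Johnson–Neyman fits use plain OLS, matching how such conditional-effect
analyses are conventionally run at the vessel level.

`holm_adjust` implements the step-down max-cumulative rule directly;
statsmodels' implementation serves as a cross-check in the tests, never as
the implementation.

`split_contrasts` bins age at 11 months, and per size class × sex fits the
old-vs-young contrast as its own two-cell mixed model (mouse random
intercept, OLS fallback), Holm-adjusting across the whole contrast family.
Empty cells are reported as missing rows rather than dropped.

## Synthetic generators

All generators draw from a seeded `numpy.random.default_rng`; the same seed
reproduces bit-identical data, and every planted observable is recorded in
a `GroundTruth`. Planted response peaks are recorded *as sampled* (the
noiseless trace's maximum on the realised frame grid), so recovery tests
measure estimation error, not sampling phase.

**Widefield sessions** render a smooth tissue texture with a dark vessel
tree (20% of the brain ROI by default) and a bright skull rim, at a
130 × 174 px canvas — half-scale of the raw camera matrix over the same
field of view, keeping the suite desk-scale. Whisker mode injects a
flat-topped barrel footprint (super-Gaussian, ~380 px plateau so the
top-100 ROI sits inside it) with a fast gamma-variate GCaMP kernel and
slower haemodynamic kernels (1.5–1.8 s peaks — plausible defaults, not
measurements); the default is 8 trials at 16-s ISI. Hypercapnia mode
injects tissue-wide plateaus (rise 10 s, fall 30 s) at 1 Hz effective frame
rate with a 60-s rendered recovery; the paradigm metadata keeps the true
30/90/270-s structure and the quantified peak falls inside the 90-s window,
so the shortened rendered recovery does not affect it. Nuisance processes:
shared sub-pixel rigid motion (random walk), multiplicative illumination
drift written into the skull region too, and white noise with SD =
baseline × 3%/SNR (referenced to the GCaMP response scale so null sessions
keep a realistic noise floor).

**Vessel fields** render straight dark vessels (Gaussian or top-hat
cross-section, contrast 0.45) on non-overlapping grid cells at 1 µm/px —
a deliberately high-zoom idealisation: 10-µm vessels are unresolvable at
the widefield's 33.7 µm/px, and the generator's purpose is to exercise the
estimator across the stated 10–150 µm range. Diameters draw from a
lognormal with median 54 µm unless given explicitly; dilations follow the
CO₂ plateau. `gen_diameter_series` places noise directly on the diameter
series (default SD 1% of baseline), the level at which FWHM measurement
jitter appears.

**Two-photon volumes** render vertical vessel cylinders (SR101), CAA as
angular bands of known pixel fraction on the vessel disks, and bright
spherical plaques placed clear of vessels, with exponential depth decay and
white noise. Plaque cores are rendered 2× brighter than CAA so the
0.6 × max threshold cleanly separates the compartments — mirroring the
bright, dense appearance of methoxy-labelled cores. Truths record exact
rendered pixel/voxel counts.

**Cohorts** follow the study design: 8 mice per genotype × sex group, ages
3–20 months, visit counts ~ N(5.4, 3.1) clipped to [1, 12], intervals
~ N(1.52, 0.5) months; outcomes draw from the stated linear mixed model
(residual SD 0.4, mouse intercept SD 0.3 by default — plausible
session-to-session variability for percent-scale reactivity metrics). The
vessel-level generator plants the Johnson–Neyman boundary *by calibration*:
it first realises the design (mice, ages, diameters), computes the expected
OLS coefficient covariance under the marginal error variance, and chooses
the diameter coefficient so the deterministic loss-of-significance root
sits exactly at 11 months given the slope-change rate (0.008 %/µm per
month). The planted boundary is therefore "true" in the estimator's own
metric; over 200 simulated cohorts the estimated boundaries' 5th–95th
percentile interval covers it.

What the generators do **not** emulate: haemodynamic-crosstalk
contamination of GCaMP fluorescence, non-rigid motion, behavioural state,
curved or branching vessels, anisotropic PSFs, depth-dependent scatter
beyond a single exponential, or mouse attrition correlated with outcome.
Passing recovery tests therefore demonstrates correctness of the
quantification chain under its stated model, not robustness to every
artifact of real recordings.

## Problem sizes

The default suite runs the half-scale widefield canvas, 24 × 128 × 128
two-photon volumes, the 280-condition diametry grid, 200-cohort
Johnson–Neyman recovery, 1000-cohort null calibration and 200-cohort sign
recovery; the full test suite completes in ~4 minutes and
`scripts/acceptance.py` in ~1 minute on one CPU.
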