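# Methods

`kymoclear` quantifies processive protein-clearance events on single
tethered ssDNA molecules, together with a fully ground-truthed synthetic
movie generator that reproduces the statistical structure the analysis
assumes. This note records the models, the numerical choices, and the
places where the design was genuinely open.

## The assay and its forward model

A ssDNA molecule (a rolling-circle amplification product) is tethered by
its 5'-biotin end at a chromium barrier and stretched to a downstream
pedestal 13 µm away, then coated uniformly with fluorescent RPA-GFP
("green"). A 3'→5' ssDNA motor lands at a random position and strips
the coat at constant velocity *v* (nt/s) until it has covered its drawn
processivity *P* (knt), then stops permanently. The protein-free gap is
read out either as gain of a fluorescent complementary oligonucleotide
("magenta", RPA-clearance assay — hybridization is modelled as
instantaneous behind the motor) or as gain of RPA-GFP influx into the
gap (green, RAD51-clearance assay, where the filament itself is dark).
A front that reaches the barrier stalls there; its observed extent is
then a geometric clip, not the motor's processivity.

Imaging: per channel, photon gain × coverage on a one-pixel-wide line,
convolved with a Gaussian PSF (σ = 1.3 px, a ~3 px diffraction-limited
spot), plus constant background, Poisson shot noise, and additive
Gaussian read noise (an EMCCD stand-in; the camera calibration is not
otherwise specified). The green coat photobleaches single-exponentially
(default 0.005/frame); magenta oligos and influxing RPA-GFP exchange
with solution and are treated as bleach-free. Frames are instantaneous
samples every 15 s.

Population model: velocities and processivities are log-normal —
strictly positive and strongly right-skewed, matching the reported
interquartile ranges — parameterized by median and IQR with
`µ = ln(median)` and `σ = ln(q3/q1)/(2 z_0.75)`. A two-parameter
log-scale family cannot pin an asymmetric quartile pair *and* the median
simultaneously (that would need `q1·q3 = median²`); the median and the
quartile ratio are matched exactly. Initiation positions are uniform on
the molecule; start frames are uniform over the first tenth of the
movie. `sample_motors(..., stratified=True)` draws each marginal by
randomized quasi-Monte-Carlo (one draw per equal-probability stratum,
independently shuffled per variable): marginals and independence are
unchanged, but sample quantiles hug the population quantiles, which
benchmark runs use to separate pipeline error from finite-*N*
fluctuation (at N = 91 the iid sample median alone fluctuates ±15%).

Condition geometry (`condition_sim_config`): both conditions image the
13 µm tether at 0.267 µm/px and 15 s/frame; they differ in ssDNA length
— 24 knt (≈0.49 knt/px) for the RPA condition, whose median clearance
then spans ~8 px, and 12 knt (≈0.24 knt/px) for the RAD51 condition,
whose 1.3 knt median event would otherwise sit below the diffraction
limit — and in green gain (400 vs 140 photons per unit coverage),
mirroring the ~3× stronger 488 nm excitation used for the RAD51 assay.
Default gains put the clearance signal at ~5× the background noise of
the summed three-row profile.

What the generator does *not* emulate: tether drift and transverse
motion, RAD51 filament dynamics and strand capture, pausing or
re-starting motors (each motor is constant-velocity until it stops —
the source data report a single per-molecule processivity, not pause
statistics), non-uniform illumination, and heterogeneous molecule
lengths within a field. Tests passing on these simulations therefore
certify the estimator chain under the assumed noise model, not
robustness to those real-data effects.

## Front fitting

Per frame, the intensity is summed over a 3-px-wide ROI between barrier
and anchor; a per-column background (median of 3-row bands ≥5 px
outside the ROI, recomputed every frame) is subtracted. The profile is
fit with a Gaussian (amplitude, center, σ, baseline; initialized from
the 10th percentile, argmax, and second moment) or a two-edge boxcar
(exhaustive integer edge scan with closed-form levels, then sub-pixel
quadratic SSE refinement). Fits never raise; a fit "converges" when
its amplitude exceeds 3× the residual SD. First detection and
re-acquisition demand 4× (the event could be anywhere on the molecule,
so weak bumps would otherwise hijack the tracking window); after two
consecutive misses the window resets. The fit window re-centers on the
previous frame's center with width `max(21 px, 3×FWHM)`.

**PSF handling.** The true signal is a top-hat convolved with the PSF;
the fitted FWHM is a biased width estimate (+40% at 2.6 px, −11% at
8 px), and quadrature subtraction of the PSF FWHM over-corrects
flat-topped profiles by 15–30%, so it is offered but not used by
default. The `'model'` correction instead inverts a tabulated forward
map — fitted FWHM of noiseless PSF-blurred boxes, fitted with the same
windowing rule the pipeline uses — which is exact on noiseless profiles
at any width.

**Flux-anchored area reads.** Below ~2 px the fitted FWHM saturates at
the PSF width, and in the 3–6 px range the inverse map more than doubles
fit scatter. Because convolution conserves flux, the windowed intensity
sum around the localized event is proportional to the cleared width at
*any* width with near-constant noise (~0.8 px). The
photons-per-pixel-of-clearance gain is calibrated per trace as a ratio
of totals over resolved frames, and every event frame's width is then
read as `sum/gain`; frames with no converged fit (sub-detection onset
frames) borrow the nearest localized center and are flagged
`area_read`. Using one estimator for all frames avoids the selection
bias of switching estimators on a per-frame noisy width (which measured
+5–10% at regime boundaries). Reads are left unclipped — slightly
negative values under noise keep the downstream kinetic fit unbiased;
only reporting clamps at zero.

## Per-motor kinetics

**Segmentation.** The FWHM(t) series is fit with a *continuous*
flat–rise–flat ramp through the origin (the pre-event baseline of a
background-subtracted width series is structurally zero):
`w(t) = v·clip(t−c1, 0, c2−c1)`. Exhaustive SSE search over integer
changepoint pairs (closed-form weighted least squares from prefix sums,
O(1) per pair), then sub-frame refinement on a 0.1-frame grid — with
rises of only 2–5 frames, integer knee quantization alone biases the
slope by >10%. Model selection between flat (no event), flat–rise to
the movie end (censored), and flat–rise–flat is by BIC. Continuity is
what makes the short rise identifiable: a disconnected shallow line
through the plateau cannot masquerade as a censored rise. Non-converged
frames carry zero weight; one buffer frame before the first covered
frame is masked because the motor may be moving below every readout
there.

**Velocity** is the ramp's fitted slope (nt/frame ÷ 15 s). This *is*
the least-squares slope of FWHM versus time over the rising phase, but
jointly constrained by the baseline and plateau — with 3–5 informative
rise frames, a free line through the rise window alone is badly
conditioned. Negative slopes clip to zero with a flag. A velocity is
reported only when the attained level exceeds 4× the per-frame ramp
residual SD; below that the fitted duration, hence the slope, is
unconstrained. **Processivity** is the plateau level of the ramp, in
knt; for censored events the last observed FWHM (a lower bound) is
reported and flagged.

**Censoring policy.** A motor still rising at the movie end, or one
whose front ran into the 5' barrier (plateau 5'-edge within 2 px),
yields only a lower bound on its processivity. Simply dropping such
events biases the population median low — long events are
preferentially clipped — so processivity quartiles are estimated by
Kaplan–Meier over all moving events, with time-censored and
barrier-clipped events entering as right-censored observations and
survival quantiles read off by linear interpolation between steps.
Censoring sources (movie length, initiation position) are independent
of the motor's processivity, which is what Kaplan–Meier requires.
Censored events keep their velocity (speed is measured on the rise);
boundary-limited events are excluded from velocity, since their rise is
truncated mid-flight. These velocity exclusions, and the level gate,
condition only on processivity and initiation position, which the
generator draws independently of velocity — so the velocity median is
not biased by the selection. Shortening the movie can only convert
events to censored status, never raise the processivity median.

**Polarity.** For traces with stored profiles, a three-hypothesis
likelihood test: the event's frames are jointly refit with a PSF-blurred
box whose widths follow the fitted ramp while one anchor is shared
across frames — the 3' edge (growth toward the barrier, 3'→5'), the 5'
edge (growth away, 5'→3'), or the center (symmetric). Small onset
offsets (±0.6 frames) absorb residual changepoint error. The winning
hypothesis must beat the runner-up by ~2σ of the residual variance;
"center" or an insufficient margin reports `ambiguous`. This uses the
rising frames' full photon information, where the hypotheses predict
box positions differing by up to half the final width; per-edge
significance tests on the fitted series alone are underpowered at these
short rises (~25% ambiguous, occasional reversed calls). Synthetic
series without profiles fall back to the center-shift test (one-sided
growth drags the fitted center by half of every width increment).

Population summaries are medians with type-7 (linear interpolation)
quartiles, the common default; the quartile convention is not specified
by the assay description.

## Foci, intensities, survival

Focus detection: local maxima above `z·(1.4826·MAD)` over the profile
median (default z = 5, which keeps the Monte-Carlo false-positive rate
below one per hundred signal-free molecules), non-maximum suppression
within 3 px, sub-pixel parabolic refinement, plateau ties resolved to
the lower column. Counts divide by tethered length (µm, or knt when
calibrated). Intensity traces: per-frame background-subtracted ROI
total per unit length, normalized to the reference frame (normalization
is idempotent); condition aggregation is mean ± SEM *across molecules*.
Single-focus brightness: mean of the 3×3 neighbourhood minus
background. Bridge survival after a challenge is Kaplan–Meier with
right-censoring at the movie end (via `lifelines`); the bridged state
per frame is an input annotation, not auto-segmented.

## Tracking and binding fits

Linking is global minimum-cost bipartite matching per frame pair on
absolute displacement with a hard gate (`max_disp_px` per elapsed
frame; default twice the expected per-frame motion) and gap closing;
trajectory velocity is the least-squares position slope, signed
negative toward the barrier.

The equilibrium model is one-site specific binding without a Hill
coefficient, `f = Bmax·[P]/(Kd+[P])`, fit to replicate means with SEM
weights (unweighted fallback when any SEM is zero, e.g. all-clipped
zero-concentration lanes); Bmax is free. When the lower 95% bound on
Kd exceeds the highest tested concentration, the result is reported as
a lower bound ("Kd > max"). Dissociation courses normalize treated by
control pointwise (non-positive control points dropped with a log
entry) and optionally fit `A·exp(−k·t)`.

## Problem sizes and limitations

Benchmark runs use N = 91 (RPA condition) and N = 53 (RAD51 condition)
motors, one molecule per motor, 100-frame movies (25 min of imaging) —
long enough that almost every drawn motor finishes. The titration
benchmarks use a two-fold series from 1 to 512 nM plus zero, σ = 0.03,
three replicates. With true Kd at 390 nM and concentrations capped at
512 nM, the design's Fisher information bounds SE(Kd) at ~17%, so
individual fits scatter widely around the truth there; the median over
seeds is the stable summary.

Known limitations: velocities of motors whose rise spans ≲2 frames
(≳130 nt/s at 15 s/frame in the RPA geometry) are duration-quantization
limited and right-skewed; per-frame width noise at signal-to-noise 5 is
~0.8–1.1 px, so single traces track their ground truth at ~1.3 px RMS;
sub-0.3 knt clearances in the RAD51 geometry remain below any detection
route; and the polarity test assumes a single clearance event per
molecule.
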