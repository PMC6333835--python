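# Methods

This note documents the models, conventions, default parameters, and
numerical choices behind `rhythmnet`, and what the synthetic-data tests do
and do not establish about real recordings.

## Data model and conventions

A session is a trial table (CSV), per-trial LFP epochs (HDF5 groups
`/lfp/<roi>/<channel>`, microvolts, 1000 Hz native), and per-unit spike
trains (`/spikes/<unit>`, ragged millisecond times).  All times are in
milliseconds relative to the alignment event (cue or target) at t = 0;
windows are half-open `[start, stop)`.  Aborted trials are stored but
excluded from every analysis.  Phase follows the cosine convention:
phase 0 at the signal maximum, increasing with time, reported in
[−π, π) radians internally and degrees at API boundaries.

## Synthetic sessions

The generator produces the statistical structure the analyses assume, with
ground truth recorded in `meta`/`truth.json` so recovery tests never
re-derive truth from data.

* **Task** (`TaskConfig`): condition mix 78% cued / 10% catch / 12%
  non-cued (split equally between same-object and different-object
  locations); delays uniform on 500–1200 ms (fixation, bar→cue) and
  300–1600 ms (cue→target); hits require a response 150–650 ms after the
  target.  These are the task-design constants; only the abort rate
  (default 0) and baseline hit rate (default 0.5, roughly the detection
  rate for near-threshold targets) are free choices.
* **LFP** (`SignalConfig`): 1/f^χ fractal background synthesized by
  frequency-domain shaping (amplitude ∝ f^(−χ/2), random phases; exact
  target spectrum), χ = 1.5 and SD 20 µV as a typical LFP slope/scale; a
  5 Hz theta sinusoid (10 µV) with an independent random phase per trial;
  an alpha/low-beta (10–20 Hz) carrier whose envelope is
  1 + m_pac·cos(φ_theta − φ_pref) (depth 0.5, preferred phase 90°);
  optional alpha-gated gamma; 5 µV white noise; epochs −1300…+400 ms
  around the target so 3 Hz wavelets have clean support over the
  −500…−125 ms spike window.  The default alpha carrier is a sinusoid at
  the band center, which gives an analytic carrier phase for nested
  behavioral modulation; a band-noise carrier is available.
* **Spikes**: inhomogeneous Poisson with intensity ∝
  exp(κ·cos(φ_band(t) − µ)), normalized per trial to the mean rate; a
  theta gate restricts the coupling to ±90° around a gate phase and
  leaves the process homogeneous elsewhere.  Because the band phase
  advances uniformly in time, spike phases are von Mises(κ), so
  E[PPC] = (I₁(κ)/I₀(κ))² is a closed-form oracle.
* **Coupled regions**: per-trial VAR with unit-variance innovations at
  250 Hz (the modeling rate, so lag coefficients mean what the fitted
  model sees); stability is enforced via the companion spectral radius.
  A theta gate zeroes the cross-region coefficients on trials whose
  theta phase at −250 ms falls outside the gate half-cycle.
* **Behavior**: P(hit) = p₀ + m_b·cos(φ_theta(−250 ms) − φ_good), with an
  optional nested modulation by the alpha carrier phase that multiplies in
  only inside one theta half-cycle.  Outcomes are Bernoulli given phase;
  miss-trial signal structure beyond phase is not modeled.
* In the paired-region HFB generator, broadband drive is elevated in the
  delay period relative to the early-epoch baseline (as attention elevates
  HFB in vivo); this gives the z-scored HFB a positive mean in the
  analysis window, which the percent-modulation normalization requires.

What the generator does **not** emulate: evoked transients, non-stationary
rhythm frequency, electrode drift, unit contamination, eye movements,
reaction-time structure beyond the hit window, or session-to-session
heterogeneity.  Passing recovery tests therefore demonstrates estimator
correctness under the assumed signal model, not robustness to every
real-data pathology.

## Spectral estimation

Morlet wavelets w(t) = exp(i2πft)·exp(−t²/2σ_t²) with σ_t = n_cycles/(2πf)
(the standard definition, identical to MNE's), truncated to n_cycles full
cycles (±πσ_t, envelope 0.7% at the edge) and scaled so a unit-amplitude
sinusoid yields |coefficient| = 1.  Epochs are reflect-padded; output
samples whose wavelet support crosses the true epoch edge are flagged and
excluded from statistics.  Default 3 cycles for 3–60 Hz; the theta-binned
analyses use the explicit 2-cycle 5 Hz wavelet at −250 ms; HFB uses
7 cycles at 80–200 Hz in 10 Hz steps.  Note the bandwidth this implies:
at 3 cycles, a wavelet at 2f still responds with amplitude exp(−9/8) ≈ 0.32
to a tone at f, so phase-locked power from a strong oscillation leaks into
neighboring bands; recovery tests localize effects by the modulation
profile, not by significance alone.

Hanning-FFT power uses `scipy.signal.periodogram` (500 ms window → 2 Hz
resolution), reported 3–60 Hz.  IRASA resamples each epoch by h and 1/h
for h ∈ {1.10, 1.15, …, 1.90}: an oscillatory peak shifts under
resampling while the 1/f background does not, so the median over h of the
geometric mean of the h/1-over-h spectra estimates the fractal component;
the oscillatory residual is total − fractal (identity holds exactly;
fractal is clipped at 0).  The IRASA analysis is restricted to trials
whose relevant delay is ≥ 750 ms to avoid evoked contamination.  The
z-scored HFB envelope standardizes power per 10 Hz step against the
pooled baseline distribution *before* averaging across steps, which
equalizes the 1/f drop-off across the band.

## Spike metrics

Kernel rates convolve the impulse train with a unit-area Gaussian
(σ = 10 ms; single-spike peak 1000/(σ√2π) ≈ 39.9 Hz).  The responsiveness
test builds its null by drawing one random pre-cue (−350…0 ms) time-point
value of the kernel rate per trial and averaging across trials (5000
reps).  For the test to be a valid randomization test the observed
response must be measured the same way, so by default the observed
"response-value" is likewise one seeded random time point per trial inside
the 250 ms response window, trial-averaged; this makes observed and null
exchangeable under a homogeneous rate and the test exactly calibrated
(measured increased-classification rate 4.8% at nominal 5% over Poisson
units).  The alternative `statistic="mean"` (250 ms window mean) is
provided but is strongly conservative, because a point value of a
σ = 10 ms smoothed rate has roughly 7× the variance of a 250 ms mean.
Increases and decreases are one-sided tests at α/2 per event with no
cross-event correction; classification: cue-increase = visual,
target-increase = movement, both = visual-movement, any decrease (and no
increase) = decreased.  Only visual and visual-movement units enter
delay-period attention contrasts, which use per-trial means over the
500 ms pre-target window (a 450 ms variant appears in some summaries;
the window is config-exposed) and a two-sided Wilcoxon rank-sum test.

## Phase binning and the one-cycle sine fit

72 overlapping 180° bins advance in 5° steps; membership is half-open
(a sample belongs to the bin centered at c iff (φ−c) mod 360 ∈ [−90, 90)),
so every sample contributes to exactly 36 bins.  Binning is implemented as
a 5° sector histogram followed by a circular 36-sector boxcar sum — exact,
because bin edges fall on sector edges.  The one-cycle fit is the second
FFT component (amplitude 2|Y₁|/72, preferred phase −arg Y₁); with up to 4
flagged bins the same parameters come from least squares on the remaining
bins (identical on a complete grid by orthogonality; more than 4 flagged
bins is a refusal).  The 180° boxcar attenuates an underlying cosine
modulation of depth m to (2/π)·m; tests assert this limit.  Exact
rotation equivariance holds for rotations that are multiples of the 5°
step; arbitrary rotations re-quantize membership and are equivariant only
asymptotically.

## Phase-detection analysis

Pre-target phase is the wavelet angle at −250 ms (config-exposed), per
trial and frequency, on hit/miss trials only.  Per frequency, the hit-rate
phase-detection function is reduced to its sine-fit amplitude; the null
shuffles outcomes relative to phases (1500 reps, the same shuffles across
frequencies), p = (1+#{null ≥ obs})/(n_perm+1) (floor 1/1501 ≈ 0.00067),
Holm across frequencies.  The 5 Hz fit's preferred phase defines the
"good" theta bin center; the poor bin is 180° away; the theta-binned
re-analysis (9–60 Hz) runs the full spectrum separately per bin with its
own null.  Sessions with fewer than 50 analyzable trials (or bins with
fewer than 50) are refused.

## Spike–field coupling

Spike phases are the LFP wavelet angle at the nearest sample to each spike
time within −500…−125 ms pre-target, pooled over trials (PPC is pairwise
over spikes; per-trial averaging is deliberately not used).  Condition
contrasts shuffle **trial** condition labels (preserving group sizes) and
recompute ΔPPC per frequency, two-sided with Holm.  Theta-dependent PPC
assigns each spike the theta phase of the same LFP channel at its spike
time, computes PPC in each of the 72 theta bins (bins with < 10 spikes are
flagged; > 4 flagged is a refusal), fits the one-cycle amplitude, and
shuffles the spikes' theta-bin assignments for the null — the permutation
unit matches what each null must break.  The stratification control
compares the 90°- and 270°-centered half-cycles after equating
alpha/low-beta power: each spike inherits its trial's 10–20 Hz Hanning
power, a common 20-bin histogram is built, both groups are subsampled
per bin to the smaller count (1500 iterations; mean ± SD reported).
Inherent per-bin binomial loss caps retention near 87–90% even for
identical distributions at the 20-bin default.

## MVAR and Granger causality

Signals are FIR-decimated to 250 Hz and z-scored per trial and channel.
The VAR (default order 8, matching the first AIC minimum for these data
lengths; AIC for orders 1–12 is available as a diagnostic) is fitted by
least squares with the normal equations pooled across trials — this is
what makes order-8 fits of 25-sample half-theta-cycle epochs possible
(17 usable rows per trial, thousands of trials pooled).  Spectral GC uses
the Geweke formula from the transfer function and noise covariance; on
models with more than two channels each ordered pair is evaluated on the
exact bivariate submodel derived from the fitted model's analytic
autocovariance (companion-form Lyapunov equation, then a population
block-Yule-Walker fit of order max(p, 20) to absorb the subset process's
MA part).  Conditional GC derives the reduced (sink + conditioning) model
the same way, maps the reduced innovations through the full model's
transfer (Q(f) = G(f)⁻¹·H_rows(f)), orthogonalizes the source's innovation
last (Cholesky), and takes F(f) = ln[Σ_r,yy/(Σ_r,yy − |source part|²)].
This reproduces the closed cases: a chain X→Z→Y gives conditional
X→Y|Z ≈ 0 while pairwise X→Y > 0, and an irrelevant conditioning channel
leaves GC unchanged; for Y_t = X_{t−1} + ε the frequency-averaged GC is
ln 2.  Numerical guards: GC values in (−10⁻¹⁰, 0) are clamped to 0,
anything more negative raises; unstable fits carry a warning flag.

The directional permutation test re-pairs one channel's trials with the
other's, breaking cross-channel dependence while preserving each
channel's autostructure, and recomputes GC(a→b) − GC(b→a) per frequency
(two-sided, Holm).  This null is exact for independence but *tighter*
than the sampling distribution of the asymmetry when strong symmetric
coupling is present, so it can flag strongly coupled symmetric pairs;
the asymmetry estimate itself is unbiased (verified analytically and
across seeds).  Interpret rejections as "asymmetric or strongly coupled",
as with the equivalent trial-reshuffling tests in the literature.

## Phase–amplitude coupling

Phase/power samples are pooled over (trial, time) pairs on a common grid
(default −750…−200 ms in 10 ms steps), averaged per phase bin, normalized
to percent modulation ((bin − mean)/mean × 100, scale-invariant, zero-mean
across bins), and reduced to the one-cycle amplitude.  The null permutes
phase trials relative to power trials (the bin counts are invariant under
this shuffle, so each null draw is a single matrix product).  Between
regions the power series is the z-scored HFB; within a region it is
per-frequency wavelet power (9–60 Hz) against 5 Hz phase; the theta-binned
variant runs alpha/low-beta-phase → gamma-power PAC per theta half-cycle
and attention condition, each with its own null.  Percent modulation of a
z-scored series is only meaningful when its analysis-window mean is
positive (true when delay-period HFB is elevated over baseline); the
phase-providing and power-providing estimates always come from separate
wavelet transforms.

## Problem sizes and determinism

All stochastic procedures take explicit seeds and are reproducible
bit-for-bit.  The test suite validates at desk scale: 10,000 trials for
task composition; 2,000 trials for behavioral recovery; 200–800 trials and
order-8 fits for Granger; 200 runs per permutation-calibration check and
1,000 Poisson units for the responsiveness calibration; 1,500 permutations
wherever the analysis specifies them, 100–300 in auxiliary checks.  These
sizes put Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* Pairwise GC on >2-channel models uses derived bivariate submodels; a
  full spectral-factorization (nonparametric) route is out of scope.
* The wavelet cycle count trades frequency leakage against temporal
  support; at the 3-cycle default a strong oscillation is visible to
  wavelets an octave away (amplitude response 0.32 at 2f), which matters
  when interpreting broadband PAC or phase-detection significance.
* The NWB reader is not implemented; sessions are CSV + HDF5.
* Cluster-based correction, FDR, LFP–LFP coherence measures, and
  time-varying MVAR are out of scope.
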