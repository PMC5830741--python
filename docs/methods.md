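# Methods

This note documents the models implemented in `stopchrono`, the defaults
and why they were chosen, the numerical details, and what the synthetic
data can and cannot establish about real recordings.

## The scientific setting

In the stop-signal task a participant responds to a Go stimulus as fast
as possible and occasionally receives a later Stop signal. Behaviour is
modelled as an independent horse race: a Go process and a Stop process
run in parallel, and whichever finishes first determines the outcome.
The stop-signal delay (SSD) is titrated so the race is balanced (~50%
stopping), and the latent stop latency (SSRT) is estimated by the
integration method. Two cortical regions — the pre-supplementary motor
area (pre-SMA) and the inferior frontal cortex (IFC) — are the candidate
sources of the stopping command; the pipeline quantifies *when* each
becomes active inside a participant-specific temporal region of interest
(tROI) and whether one drives the other.

## Synthetic-data generator

The generator stands in for source-level MEG recordings and emulates:

- **Go finishing times**: ex-Gaussian(μ = 350, σ = 50, τ = 80 ms). The
  ex-Gaussian is the standard descriptive model for Go RT distributions
  in this literature; the defaults put the mean Go RT near 430 ms, the
  value typical of titrated stop-signal sessions in healthy adults.
- **Stop finishing times**: normal(210, 30 ms) truncated at zero. The
  210 ms centre matches the SSRT range such sessions produce. Setting the
  SD to zero gives a constant-SSRT mode in which the integration
  estimator's target is exact, used for recovery tests.
- **Stop-trial rate** 1/3 (one random third of trials), staircase step
  50 ms (three refreshes of a 60 Hz display) starting at 250 ms.
- **Epochs**: −1300 to +1300 ms around Go onset at 1200 Hz, covering a
  full fixation baseline and the response period. Background noise has a
  1/f power spectrum (exponent 1), unit variance per trial.
- **Evoked component**: a gamma-shaped deflection (t/θ)·e^(1−t/θ) with
  θ = 40 ms — fast rise, slow decay — added identically (phase-locked) to
  every stop trial from the planted onset, with peak amplitude given in
  single-trial baseline-SD units. Because the contrast averages n trials,
  the *trace-level* signal-to-noise ratio is amp/√(2/n_stop); tests state
  the trace-level SNR they use.
- **Induced component**: band-limited Gaussian noise (4th-order
  zero-phase Butterworth band-pass) whose amplitude steps up by a
  configurable fraction at the planted onset; the step is convolved with
  a 20 ms ramp so later filtering stages do not ring. The carrier phase
  is random per trial, so the component survives envelope analysis but
  averages out of the evoked trace.
- **Region structure**: the second region's onsets are shifted by
  `region_offset` — the planted latency difference the pipeline should
  recover (zero by default, matching the null pattern the group analyses
  are calibrated against).

What it does **not** emulate: sensor-level data and beamforming,
head-movement and ocular/muscle artifacts, between-subject variability in
spectral shape, non-stationary baselines, or any dependence of the
neural response on trial history. Passing ground-truth-recovery tests
therefore shows the *algorithms* behave as specified under controlled
conditions; it says nothing about effect sizes in real recordings.

## Behavioural rules

- Staircase: +50 ms after a successful stop, −50 ms after a failed one,
  floored at 0 ms. The 100 ms floor applies only to the between-block
  sham-phase adjustment, which moves the SSD ±50 ms when sham stopping
  leaves the 35–65% band.
- Calibration: a block passes when mean Go RT < 550 ms and SSD > 100 ms;
  otherwise "speed up" or "try harder to stop" feedback is indicated
  (slow responding takes precedence, since slowing inflates the SSD).
- Integration SSRT: Go RTs sorted ascending, omissions replaced by the
  maximum observed Go RT before ranking (the standard conservative
  convention; the source protocol is silent), rank = ceil(n·P(respond |
  stop)), minus mean SSD.
- tROI = [SSD + 50, mean Go RT − 50] ms, so duration + 100 = Go RT − SSD
  exactly. TMS pulses go at the nearest screen refresh to 12.5% and
  62.5% of the tROI; a half-frame tie rounds down. Pulses landing on the
  same frame are a scheduling error.
- Exclusions: Go omissions > 15%; stopping outside (0.30, 0.70) with the
  boundary itself excluded (a 0.70 stopper is out — the protocol text
  also mentions a 0.6 bound in one place; the bounds are arguments, the
  default follows the formal criterion); and, for TMS only, Go RT − SSD
  < 117 ms, implemented as the literal threshold.

## Trace analysis

- Contrast: mean(Stop) − mean(Go) per sample, with Go trials randomly
  down-sampled (seeded) to the stop count so both conditions contribute
  equal noise. The successful-vs-failed variant never down-samples, as
  titration already balances those counts.
- Baseline: final 500 ms of fixation; traces are z-scored by that
  window's mean and SD. A zero-variance baseline is a degenerate-data
  error.
- Filters: 4th-order Butterworth applied forward-backward (zero phase,
  effective 8th order). Order is a design choice — only the family and
  the zero-phase requirement are externally fixed; 4th order is the
  common default in electrophysiology toolchains.
- Envelopes: per centre frequency f (integer Hz), band-pass f ± 4 Hz,
  magnitude of the analytic signal; per-trial envelopes are averaged so
  non-phase-locked amplitude changes survive. Band edges are clipped
  into (0, Nyquist) when an 8 Hz bandwidth would cross them.
- Criterion levels: with m = mean |z| and M = max |z| over the tROI, a
  trace is excluded when m < 0.5, M < 1, or M − m < 0.5 (noise-dominated:
  peak too close to the mean). Otherwise the level is the largest
  c ∈ {0.5, 1.0, …} with m ≥ c and M ≥ c + 0.5. This "last level met"
  reading guarantees a crossing exists inside the tROI; absolute values
  are used throughout so negative-going components are treated
  symmetrically (the alternative signed convention is available via
  `use_absolute=False`).
- Latency: the first tROI sample whose |z| reaches the level. Note the
  structural lag — a trace crosses its criterion only after the
  underlying component has risen to that level, so recovered latencies
  sit systematically ~10 ms after the planted onset with the default
  kernel; the ±15 ms recovery tolerance used in validation absorbs this.

## Band restriction

Candidate (low, high) integer pairs within α 6–13, β 14–30, γ 31–130 Hz
must span ≥ 2, 4 and 12 Hz respectively. Pairs holding fewer than four
centre frequencies cannot support the 3-parameter fit and are not
candidates (this affects only span-2 α pairs). The printed form of the
peak model in the source protocol is typographically degraded; it is read
as the Gaussian y = a·exp(−((x−b)/c)²) — named a Gaussian model three
times in the text — with a parabola alternative behind the `model`
argument. The score multiplies adjusted R² (3 parameters) by the maximum
absolute deflection of the *data* spectrum. Spectra whose absolute
maximum sits on an edge are slopes: they compete among themselves but
lose to any genuine peak, and when nothing else exists the full broad
band is returned. Restricted vs unrestricted traces are compared on the
mean criterion level across the two regions (excluded traces count 0);
ties keep the broader, unrestricted band.

## Granger analysis

Unbaselined stop-trial data are used (baselining consistently violates
stationarity). Series are linearly detrended and z-normalized, then
tested with the augmented Dickey–Fuller test (constant, no trend,
Schwert-rule max lag — the reference analysis does not state a
specification) and first-differenced until stationary, with a hard
failure after `max_iters` (the analysis's own exclusion route). Orders
minimize the BIC of the bivariate VAR over [5, L − 5]; residual variances
are degrees-of-freedom corrected, since the MLE variance collapses as the
parameter count approaches the sample count and would otherwise let the
BIC favour absurd orders. Multi-trial inputs are fitted with per-trial
lag construction (no lag crosses a trial boundary) and pooled residuals,
avoiding concatenation discontinuities. Spectral causality follows
Geweke: with A(f) = I − Σ A_k e^(−2πifk/fs), H = A⁻¹ and S = HΣH*,
f_{x→y}(f) = ln(S_yy / (S_yy − (Σ_xx − Σ²_xy/Σ_yy)|H_yx|²)), averaged
over the band at 1 Hz resolution; its mean over [0, Nyquist] matches the
time-domain density (verified to 5%). Permutation surrogates shuffle the
trial pairing between the two sensors — the exact surrogate scheme in
the reference analysis is underspecified ("randomization at the sensor
level"); pairing shuffles preserve each sensor's own statistics while
destroying consistent cross-region lags. Single-trial inputs fall back
to random circular shifts.

## Bayesian inference

The JZS Bayes factor integrates the Cauchy-mixture marginal likelihood
over g with an inverse-gamma(1/2, 1/2) prior, scale r = √0.5, by adaptive
quadrature on log g (integrand evaluated in log space; the substitution
keeps both tails well-behaved). The implementation reproduces all ten
published group-level Bayes factors from their t and n to three decimals.
Informed priors follow the Dienes-calculator convention: a normal
likelihood for the observed mean difference (a t likelihood with given df
is switchable — the reference analysis does not state which was used, so
informed-prior values are validated softly rather than exactly), against
half-normal (e.g. SD 30 ms for the "direct connection offset" prior, or
half the group-mean tROI duration: 63 ms MEG, 71 ms TMS) or uniform
priors. The correlation Bayes factor uses the Wetzels–Wagenmakers
default-prior form. The sequential stopping rule recomputes the JZS BF
after each subject against thresholds (3, 1/3); because the BF quantifies
evidence for both hypotheses, optional stopping does not inflate it.

## TMS dosing

Intensity = 1.10 × (MT + 2.7·(d_target − d_motor)), clamped to
[0.70·MT, 1.30·MT] and ≤ 100 %MSO, in that order; the comfort threshold
is applied afterwards (the composition order is not externally fixed;
dose → bounds → comfort is the reading implemented). Comfort propagation
takes the smallest comfort/prescribed ratio across sites, applies it to
every site, rounds to integer %MSO (stimulators accept integers; the
worked example is consistent with nearest-integer rounding), and flags
exclusion when any applied value drops below 80% of its prescription.
Target aggregation averages virtual-sensor coordinates within the
majority hemisphere, defaulting to the right on an even split.

## Problem sizes and validation scope

The validation suite uses 19-subject synthetic cohorts of 360 trials
(three 120-trial blocks), 50-subject cohorts for band-selection rates,
and 20 replicate runs for Granger direction recovery — the cohort and
session sizes of the study design the generator emulates, with epoch
grids at 600 Hz over −0.6..1.0 s for the heavier spectral computations.
Published group behavioural summaries (SSRT ≈ 210 ms, proportion stopped
≈ 0.56) are generator calibration defaults only; they cannot be and are
not reproduced as test assertions, since they belong to the deposited
recordings. Quantities that are recomputed exactly are the published
Bayes factors (from printed t, n), the tROI arithmetic (63 ms; the TMS
analogue gives 70 ms from rounded group means against a printed 71
computed from unrounded ones), and the comfort-propagation worked
example.

## Known limitations

- The criterion-latency method reports onset + rise-to-criterion lag,
  not the generative onset; comparisons between conditions are unbiased
  only insofar as rise shapes match.
- The informed-prior likelihood convention (normal vs t) changes values
  by a few percent; both are provided, neither is asserted as "the"
  reference choice.
- Spectral Granger assumes the fitted VAR is adequate in the band of
  interest; no nonparametric spectral factorization is provided.
- The generator's two regions carry independent noise; genuinely shared
  (volume-conducted) noise, which inflates between-region coupling
  estimates in real source-space data, is out of scope.
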