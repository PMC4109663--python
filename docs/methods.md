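# Methods

## Signal model and estimator

Each epoch spans 500 ms before to 1000 ms after a stimulus flash at
200 Hz: n_pre = 100 prestimulus and n_post = 200 poststimulus samples, in
µV. After baseline correction (the prestimulus mean is subtracted from the
whole sweep, so AR identification sees zero-mean data; the operation is
idempotent) the poststimulus sweep is modeled as y = u + v.

The ERP u carries an integrated-white-noise prior of order m = 2: u is a
priori two cumulative sums of white noise with variance λ², equivalently
the roughness penalty ‖F u‖² with F the second-difference operator. F is
built with zero initial conditions, which makes it an invertible
lower-triangular Toeplitz matrix (F⁻¹ is the double cumulative sum) and
keeps the prior proper. The background v is an AR(p) process whose
coefficients and innovation variance σ² are re-identified on every epoch's
prestimulus segment: least-squares (covariance method) fits for
p = 1..p_max (default 10), order chosen by FPE(p) = σ̂²_p (N+p+1)/(N−p−1)
with σ̂²_p = RSS/(N−p), N = 100. Unstable fits are stabilized by
reflecting offending roots inside the unit circle. The whitener A is the
lower-triangular banded Toeplitz operator with unit diagonal and −a_k on
the k-th subdiagonal; the noise covariance is modeled as σ²(AᵀA)⁻¹. This
truncated-Toeplitz whitening ignores the p-sample startup transient of the
exact AR covariance; at n = 200 and p ≤ 10 the effect is confined to the
first few samples and is accepted as a modeling choice.

The estimate is the MAP/Tikhonov solution
û = (AᵀA + γFᵀF)⁻¹AᵀA y with γ = σ²/λ², computed by symmetric banded
Cholesky solves (bandwidth max(p, m)), which keeps per-epoch tuning at a
few milliseconds. γ = 0 returns y exactly.

### Choosing γ

During calibration γ is tuned per epoch by the discrepancy criterion:
WRSS(γ) = (y−û)ᵀAᵀA(y−û) = n·σ². WRSS is nondecreasing in γ, so a
bisection on log₁₀γ over [10⁻⁴, 10⁸] (relative tolerance 10⁻³, at most 60
iterations) finds the root whenever it is bracketed; otherwise the nearest
bound is returned flagged `converged=False` (WRSS(γ_hi) < nσ² means even
maximal smoothing leaves less whitened residual energy than the noise
model predicts). For testing the smoother uses the fixed γ* = median of
all calibration γ values (targets and nontargets), making it a fixed
linear filter — the median is robust to the minority of clamped epochs.

### The γ→∞ limit

Because F is invertible (the first two rows penalize the level and slope
initial conditions), the strict γ→∞ limit of û is 0, not the weighted
affine fit: the affine coefficients themselves carry penalty energy. What
survives asymptotically is the *shape*: the estimate aligns with the
directions of minimal ‖F·‖/‖·‖, which at n = 200 drives ‖Fû‖/‖û‖ below
10⁻⁴ at γ = 10¹² — the operational "affine/flat limit" property the tests
assert. Asserting literal equality with the affine least-squares fit would
contradict the zero-initial-condition construction and is deliberately not
done.

## Features and classifier

Each estimated ERP yields 78 features: per 200-ms window (five windows)
the max/min amplitudes, their latencies (ms, ties to the earliest sample)
and the mean power; global max amplitude/latency and min amplitude; and
the 50 level-2 Haar approximation coefficients (200 → 100 → 50, no
padding). The historical feature list behind the published count of 78 was
never enumerated; this inventory is a documented stand-in that preserves
the count and the described feature families, and is exposed as
`FEATURE_NAMES` so alternatives can be slotted in.

The classifier is an RBF-kernel SVM with class weights inversely
proportional to class frequency (the paradigm is 3:1 nontarget:target).
Features are z-scored with training statistics (zero-variance columns map
to 0). C ∈ {4⁻²..4⁶} and kernel width ∈ {4⁻⁷..4¹} are selected by mean
validation accuracy over 20 stratified 80/20 splits of the calibration
data, ties going to the smallest C then the smallest width; accuracy is
the selection metric because it is the protocol's reported metric. Hard
labels are produced (no score thresholding).

## Protocol emulation

A study has one calibration day (8 sessions) and four testing days
(T1–T4, default 4 sessions each). Sessions are consecutive randomized
blocks of the four arrows, one target per block; a session is 4 blocks
with the last truncated right after its target flash, giving 13–16
flashes. The original closed-loop testing sessions ended on image-reach or
a 92-flash timeout, which depends on feedback a fixed offline dataset
cannot reproduce, so generated testing sessions reuse the calibration
session structure; the closed-loop dynamics are available separately in
`simulate_session` (one step per detected P300 — toward the flashed arrow,
wrong arrows included — four steps to reach an image, 92-flash cap).

Day-by-day evaluation is incremental: before day T_i the whole pipeline
(per-epoch γ tuning → γ*, feature standardization, SVM selection and
fit) is retrained on all preceding sessions, then every flash of T_i is
classified with γ* fixed. Accuracy is per-stimulus (correct
target/nontarget decisions over all flashes of the day, in percent).

Summary statistics use the Hazen percentile convention — linear
interpolation between order statistics at probability points (k−0.5)/n,
clamped at the extremes — which reproduces three of the four published T4
quartile pairs to one printed decimal (the published patient
single-channel 75th percentile of 83.7 is not reproduced by any standard
convention we tried and is left as an inherited inconsistency; likewise
the published T2 patient single-channel maximum of 92.2 conflicts with
its own table column, whose maximum is 95.1). The paired Wilcoxon
signed-rank test is exact (full dynamic-programming null distribution) up
to n = 25, with zero differences dropped and average ranks for ties; a
tie-corrected normal approximation covers larger n. The Wolpaw rate is
B = log₂N + P log₂P + (1−P) log₂((1−P)/(N−1)) bits per selection, scaled
by 60/seconds-per-selection, with the P→0,1 limits by continuity.

## Synthetic data

The generator emulates what the analysis assumes about the recordings,
not a full physical simulation:

* Background EEG: a fixed stable AR(4) with an alpha-like 10 Hz spectral
  peak (pole radius 0.88) and two real low-pass poles (0.6, 0.5), the
  innovation variance set so the stationary RMS is ~12 µV — a typical
  scalp amplitude for a 0.15–30 Hz acquisition band. A burn-in of
  10·max(p, 50) samples is discarded per realization. An optional slow
  sinusoidal drift term (default off) models residual baseline wander.
* Target ERP: a Gaussian bump, per-subject latency ~N(450 ms, 30 ms) and
  FWHM ~N(250 ms, 20 ms), truncated at ±3 FWHM. Estimator accuracy
  depends on SNR rather than on the exact wave shape, so one smooth
  unimodal template suffices.
* SNR: defined as the poststimulus-window power ratio in dB and imposed
  exactly per epoch by rescaling the template against the realized noise
  power of that window (so generated epochs are usable as their own
  ground truth). The default study range of 0–6 dB places the pipeline in
  the published accuracy regime (roughly 70–100% per day); −30 dB serves
  as the no-information control.

What the generator does **not** model: eye blinks and other artifacts,
inter-channel structure (this is a single-channel pipeline), habituation
or feedback-driven adaptation across days, and non-stationarity beyond
the per-epoch AR re-identification. Passing tests therefore demonstrate
the correctness and the denoising behavior of the algorithms under the
assumed signal model, not clinical-grade performance on real EEG.

## Test problem sizes and numerical conventions

The oracle-equivalence check compares the banded solver against a dense
stacked least-squares solution on 100 random instances (n ≤ 50, tolerance
10⁻⁸ in max norm). Denoising gain is measured on 200 generated target
epochs at each of −6, 0 and 6 dB. AR/FPE recovery uses 200 simulated
AR(2) prestimulus segments of length 100. The end-to-end checks run one
synthetic subject through the full four-day protocol at 6 dB (every
testing day must exceed 75% accuracy) and at −30 dB (pooled accuracy must
fall inside the no-information band, i.e. between the 95% binomial lower
bound of the 50% random-guess baseline and the 95% binomial upper bound
of the majority-class baseline — a classifier given no usable signal may
legitimately land anywhere between guessing and always answering
"nontarget"). These sizes were chosen to make Monte-Carlo margins
comfortable while keeping the default suite around a minute of runtime.

Degenerate inputs are handled explicitly: zero innovation variance yields
zero noise; all-zero feature columns standardize to zero; single-class
training sets raise; epochs too close to a recording edge are rejected
with a warning; non-finite inputs to the smoother raise.
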