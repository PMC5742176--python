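# Methods

`blinkrv` analyzes the dynamics of spontaneous eye blinking. Its pipeline has
four stages: synthesize (or read) frontal EEG, detect blinks and stack the
inter-blink intervals into a blink-rate-variability (BRV) series, estimate the
multifractal scale exponent α of that series, and run cohort-level statistics
relating resting-state α to cognitive test scores. This note records the
models, the tunable parameters and their defaults, the numerical choices, and
what the synthetic data can and cannot establish.

## The scale exponent and the sub-band estimator

Many physiological interval series have power spectra S(f) ∝ 1/f^γ. The
scale exponent α = (γ + 1)/2 (valid for γ > −1) summarizes the same scaling
in the fluctuation domain: α = 0.5, 1.0, 1.5 for white, pink and brown noise.
`blinkrv` estimates α with a variant of multifractal detrended fluctuation
analysis (MFDFA) in which the per-window polynomial fit of classical DFA is
replaced by a *linear* operation: subtracting a Gaussian-smoothed copy of the
profile, a low-pass whose pass-band tracks the analysis scale. The steps, for
a series of length n and each scale l in the scale set:

1. **Profile.** Cumulatively sum the mean-centered series. This integration
   step is what pins white noise to α = 0.5 and brown noise to α = 1.5; it is
   exposed as `integrate` (default on).
2. **Sub-band detrend.** Subtract `gaussian_filter1d(x, σ(l))` from the
   profile, with σ(l) = l/4 and the kernel truncated at ±4σ. The kernel FWHM
   is then ≈ 0.59·l, so the retained fluctuation band is proportional to the
   scale. Because Gaussian smoothing is symmetric it reproduces constants and
   (away from boundaries) linear trends exactly, so the subtraction acts like
   order-1 detrending while remaining linear in the input.
3. **Window variances.** Split the detrended profile into overlapping
   sub-windows of length 2l advancing by l (50% overlap), giving
   N_l = ⌊n/l⌋ − 1 windows, and record the population variance σ²_k(l) of
   each.
4. **Partition function and spectra.** χ(q, l) = Σ_k [σ²_k(l)]^{q/2}; with
   weights μ_k(q, l) = [σ²_k]^{q/2}/χ (which sum to one by construction),
   the mass exponent, Hölder exponents and singularity spectrum are
   least-squares slopes against ln l over the retained scales:
   τ(q) = slope of ln χ; α(q) = ½ · slope of Σ_k μ_k ln σ²_k;
   f(q) = slope of Σ_k μ_k ln μ_k.

The factor ½ in α(q) converts variance to fluctuation units (ln σ² = 2 ln σ)
and is exposed as `calibration_c`; with it, the Legendre relation
f = qα − τ holds on the q-grid up to regression linearity, and the
white/pink/brown taxonomy comes out on the nose (ensemble means at n = 4096:
0.513 for white, 1.486 for integrated white). The headline scalar is
α = α(q = 0), the peak position of the singularity spectrum; at q = 0 the
weights are uniform, so α(0) is ½ times the slope of the mean log
window-variance. Each regression reports R².

**Scale set.** The default is {8, 10, 12, 14, 16, 20, 22, 26, 32, 38, 46,
54, 64} (window half-lengths in series samples). For BRV input the "sample"
axis is the interval index: the series is analyzed as an ordered sequence,
not resampled in time.

**Scale retention.** A scale is kept only if it yields at least
`min_windows` sub-windows and its kernel fits inside the series; fewer than
five retained scales is an error. The library default `min_windows = 4`
favors variance quality. The pipeline and the `mfdfa` CLI verb use
`min_windows = 1` instead: BRV series are short (a 5-min session at 9–50
blinks/min gives ~45–250 intervals), and requiring four windows per scale
would make sessions below ~16 blinks/min unanalyzable even though such
subjects occur in real cohorts. On simulated target-0.9 series the two
settings agree to ±0.03 in the mean at n = 89; single-window variances at
the largest scales mainly widen the estimate's spread.

**Degenerate windows.** Zero-variance windows make [σ²]^{q/2} diverge for
q < 0; they are dropped from the sums with a warning (for q = 0 they still
count in χ(0, l) = N_l, which the code preserves as an exact integer
identity).

**Classical oracle.** `classical_mfdfa` implements standard MFDFA
(non-overlapping windows of length 2l taken from both ends, per-window
polynomial detrending of order 1, generalized Hurst exponents h(q), and
τ = qh − 1 with α by central differences). It exists as an independent
cross-check: on fractional noise the two routes agree to well under 0.1 in
the mean, and both report a spectrum width above 0.3 on a binomial cascade.

## Blink detection

Blinks are read from the frontopolar channels Fp1/Fp2, which carry the
largest eyelid deflections. The detector: zero-phase Butterworth band-pass
0.5–10 Hz (order 4), adaptive threshold k·MAD of the filtered trace with
k = 4, plus an absolute floor of 20 µV, local-maximum picking with a 250 ms
refractory period, and (by default) Fp1/Fp2 coincidence within 50 ms. The
absolute floor matters on very clean recordings: with MAD near zero, filter
ringing around a pulse (a few µV) would otherwise clear a purely relative
threshold, while genuine frontal blinks are an order of magnitude larger.
All constants live in `DetectionParams`/`RunConfig`. Detection is
amplitude-scale equivariant when the signal and the floor are scaled
together.

Quality control replaces manual/video review: a session passes if its BRV
series has at least `qc_min_intervals` (default 30) intervals; failing
subjects are flagged excluded with a reason, never silently dropped. A
series too short for five analysis scales is likewise recorded as an
exclusion.

## Synthetic data

The generators emulate the study conditions so every stage can be tested
without recordings:

* **Colored noise** is synthesized spectrally: complex Gaussian amplitudes
  scaled by (2 sin(πf))^{−γ/2} — the frequency response of γ/2 discrete
  integration steps — then inverse-transformed and rescaled to the target
  SD. This coincides with f^{−γ/2} in the low-frequency scaling band (slope
  tests fit f ≤ 1/8 cycles/sample) and makes γ = 2 exactly a random walk,
  so first differences of brown noise are white. Valid for γ > −1;
  deterministic per seed.
* **Blink intervals** with a target exponent α* are built from colored noise
  with γ = 2α* − 1, mapped through exp(0.25·z) and affinely rescaled to the
  target mean 60/rate with a refractory floor (default 0.2 s). The lognormal
  map guarantees positivity without clipping; with the log-SD kept small it
  is nearly affine, so the exponent survives (ensemble mean 0.99 recovered
  for a target of 1.0 at ~2000 intervals). This construction is a stand-in,
  not a claim about blink physiology.
* **EEG** is two channels of independent pink background noise (γ = 1,
  15 µV SD — a typical resting spectrum) plus a raised-cosine pulse
  (100 µV peak, 300 ms full width) on both channels at each blink time,
  sampled at 250 Hz. Blink morphology in real recordings is asymmetric and
  variable; the template is deliberately simple. No saccades, EMG, line
  noise or electrode drift are modeled — so the detection benchmark
  (F1 ≈ 0.99 at 100 µV pulses over 15 µV noise) bounds performance under
  clean conditions only, and subject-level α values from real EEG depend on
  detection and filter choices in ways the synthetic benchmark cannot
  certify.

The cohort harness (`simulate_cohort`) assigns a fraction 9/24 of subjects
to a high-scoring group, draws one blink rate per subject from a lognormal
with mean 18.27 and SD 10.44 blinks/min (floored at 7.5), and gives the
groups resting-state α targets 0.94 vs 0.72 with a null contrast (0.62) in
the test session — the group structure the cohort statistics are designed to
detect. Sessions are 5 min (rest) and 10 min (test); series lengths are
left unequal, as the durations dictate (an `EffectSpec` field can equalize
targets instead). Replicated runs give empirical power ≈ 0.9 at that
contrast and a type-I rate compatible with 0.05 under the null. By default
the harness feeds interval series straight to the estimator; `via_eeg=True`
routes every session through EEG synthesis and detection (used for
single-subject and smoke tests; the many-replicate loops would spend their
time re-verifying detection already benchmarked separately).

## Cohort statistics

The bundled reference table (`data/table1.csv`, SHA-256 pinned) holds the
24-subject cohort: per-session blink rate and α plus an IQ-type score out of
13. All statistics are recomputed from the table at run time:

* **Median split**: subjects scoring strictly above the sample median (mean
  of central order statistics for even n) form the high group — 9 vs 15 at
  threshold 4 on the reference data.
* **One-way ANOVA** (scipy `f_oneway`) for group contrasts, df (1, n−2), and
  for rest-vs-test session comparisons treating sessions as groups,
  df (1, 2n−2). Two constant equal groups give F = 0; constant unequal
  groups raise rather than returning an infinite F.
* **Pearson correlation** of resting α with score, two-sided p via the
  t-transform, with the least-squares line (slope, intercept, R²).
* **Shapiro–Wilk** normality checks (scipy, 3 ≤ n ≤ 5000).
* **Summaries** use (n−1)-denominator SDs; grouped normal (mean, SD) pairs
  are emitted for density plotting.

No multiple-testing correction is applied. Note one property of the
reference table: it stores values to two decimals, and a between-group F
statistic is sensitive at that precision — the group contrast in resting α
computes to F(1, 22) = 6.34, p = 0.020 from the rounded table, whereas
full-precision inputs can yield values a couple of percent away. The
package always reports what the data it is given imply. Relatedly, the
session-comparison F statistics printed with inconsistent p-values in some
secondary sources are simply recomputed here (rest vs test α:
F(1, 46) = 9.34, p = 0.0037 on the reference table), and the group means in
the table are taken as authoritative over prose restatements.

## Reproducibility and problem sizes

Every stochastic routine takes an explicit seed; derived seeds come from
`numpy.random.SeedSequence`, and identical config + seed reproduces reports
byte-for-byte. The calibration script (`scripts/acceptance.py`) uses
ensembles of 200 series of length 4096 — large enough that the ensemble
means of α sit well inside their tolerance bands — and the cross-method
benchmark in the test suite uses 100 series of length 2048 per Hurst value.

Known limitations: α confidence beyond the fit R² is not provided; no
wavelet-leader or box-counting alternatives; no time-resolved α; the EEG
reader accepts any consistently µV-scaled CSV and does not handle vendor
binary formats.
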