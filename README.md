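# blinkrv

Analysis of **eye-blink rate variability (BRV)** — the ordered series of
intervals between consecutive spontaneous blinks, the ocular analogue of
heart-rate variability. The package detects blinks in frontal (Fp1/Fp2) EEG,
stacks the inter-blink intervals into a BRV series, estimates its
**multifractal scale exponent α**, and runs the cohort statistics that relate
resting-state α to performance on a cognitive test. A synthetic-data module
generates colored noise, blink-interval series with a prescribed exponent,
and two-channel EEG with embedded blink waveforms, so the whole pipeline is
testable without any recordings.

It is aimed at researchers working on physiological interval series
(blinks, heartbeats, saccades) who need a seeded, scriptable implementation
of fluctuation-scaling analysis end to end: signal → events → intervals →
exponent → group statistics.

## The estimator

For a series with power spectrum S(f) ∝ 1/f^γ, the scale exponent
α = (γ + 1)/2 characterizes its fluctuation scaling: α = 0.5, 1.0, 1.5 for
white, pink and brown noise. `blinkrv` estimates α by a sub-band variant of
multifractal detrended fluctuation analysis (MFDFA): the mean-centered
series is integrated to a profile; at each scale l in
{8, 10, …, 64} the profile is high-passed by subtracting a Gaussian-smoothed
copy (σ(l) = l/4) — a linear surrogate for polynomial detrending; variances
σ²ₖ(l) over 50%-overlapping windows of length 2l form the partition function

    χ(q, l) = Σₖ [σ²ₖ(l)]^(q/2)  ∝  l^τ(q)

from which τ(q), the Hölder exponents α(q) and the singularity spectrum
f(q) = qα(q) − τ(q) follow as log-log regression slopes. The headline
scalar is α = α(q = 0), the peak of the singularity spectrum. A classical
polynomial-detrended MFDFA is included as an independent cross-check.
See `docs/methods.md` for the full formulation, defaults and caveats.

## Worked example

Simulate a 5-minute two-channel recording whose blink train carries a target
exponent of 0.9, detect the blinks, and estimate α from the recovered
intervals:

```console
$ blinkrv simulate --out-dir demo --seed 7 --duration 300 --alpha-target 0.9
wrote demo/eeg.csv (75000 samples, 91 blinks)

$ blinkrv detect --input demo/eeg.csv --out demo/events.csv
91 blinks, 18.20 blinks/min -> demo/events.csv

$ blinkrv mfdfa --input demo/intervals.csv
{
  "alpha0": 0.9192552324440164,
  "fit_r2": 0.9926219032244221,
  "n_scales_used": 10,
  "n_samples": 90
}
```

All 91 embedded blinks are recovered from the noisy EEG (18.2 blinks/min
over 300 s), and the estimated exponent 0.92 sits close to the generating
target 0.9, with an R² of 0.99 on the scaling regression over ten scales.

Cohort statistics are recomputed from the bundled 24-subject reference
table (per-session blink rate, α, and a 13-point test score per subject):

```console
$ blinkrv reproduce --out report.json
```

The report contains, among other quantities: the resting-α group ANOVA
F(1, 22) = 6.34, p = 0.020 (high-scoring group mean α 0.94 ± 0.25 vs
0.72 ± 0.18); the correlation of resting α with test score r = 0.429,
R² = 0.184; and the 9/15 median split — i.e. subjects whose resting-state
blink dynamics are closer to pink noise tended to score higher, while plain
blink *rate* shows no group difference (F = 0.139, p = 0.71).

The same operations are available as library functions
(`blinkrv.detect_blinks`, `blinkrv.alpha0`, `blinkrv.reproduce`, …), and
`blinkrv simulate-cohort` runs a seeded power/recovery harness over a
synthetic cohort with a prescribed group contrast.

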