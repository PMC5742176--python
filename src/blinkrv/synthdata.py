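"""Synthetic data: colored noise, blink-interval series, and frontal EEG.

Stand-ins for the study conditions so the whole pipeline is testable without
any recordings: 5–10 min two-channel (Fp1/Fp2) EEG at 250 Hz with smooth
blink deflections superimposed on 1/f background noise, and inter-blink
interval series constructed to carry a prescribed scale exponent.

Colored noise is produced by spectral synthesis — Gaussian Fourier amplitudes
scaled by f^(-gamma/2), inverse-transformed — which gives the exact target
spectrum in O(n log n).  Interval positivity is enforced by an
exponential-of-scaled-noise (lognormal) transform rather than clipping, with
the noise SD kept small relative to the mean so the transform is nearly
affine and leaves the scale exponent intact.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .blink_extraction import BRVSeries, EEGRecording


@dataclass(frozen=True)
class NoiseSpec:
    """Colored-noise recipe: S(f) ~ 1/f^gamma, length n, RNG seed."""

    gamma: float
    n: int
    seed: int
    sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 64:
            raise ValueError(f"series length n must be >= 64, got {self.n}")
        if self.gamma <= -1:
            raise ValueError(
                f"spectral exponent gamma must exceed -1, got {self.gamma}"
            )
        if self.sd <= 0:
            raise ValueError("sd must be positive")


@dataclass(frozen=True)
class BlinkTrainSpec:
    """Blink-interval recipe targeting a mean rate and a scale exponent.

    ``log_sd`` is the SD of the log-intervals before rescaling; small values
    keep the lognormal transform close to affine so that the interval series
    inherits the exponent of the underlying colored noise
    (gamma = 2 * alpha_target - 1).
    """

    duration: float           # session length, seconds
    mean_rate: float          # target blink rate, blinks/min
    alpha_target: float       # target scale exponent of the interval series
    seed: int
    min_interval: float = 0.2  # refractory floor, seconds
    log_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.mean_rate <= 0:
            raise ValueError("mean_rate must be positive")
        if self.min_interval <= 0:
            raise ValueError("min_interval must be positive")
        if 60.0 / self.mean_rate <= self.min_interval:
            raise ValueError(
                f"infeasible rate/floor: mean interval {60.0 / self.mean_rate:.3f} s "
                f"must exceed the floor {self.min_interval} s"
            )
        if self.alpha_target <= 0:
            raise ValueError("alpha_target must be positive (gamma > -1)")


@dataclass(frozen=True)
class EEGSynthSpec:
    """Two-channel EEG recipe: blink pulses on colored background noise."""

    duration: float                      # seconds
    blink_times: tuple[float, ...]       # event times, seconds
    seed: int
    fs: float = 250.0                    # sampling rate, Hz
    template_amplitude: float = 100.0    # peak height, microvolts
    template_width: float = 300.0        # full width, milliseconds
    noise_gamma: float = 1.0             # pink background
    noise_sd: float = 15.0               # microvolts

    def __post_init__(self) -> None:
        object.__setattr__(self, "blink_times", tuple(float(t) for t in self.blink_times))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.template_width <= 0:
            raise ValueError("template_width must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if any(t < 0 or t >= self.duration for t in self.blink_times):
            raise ValueError("all blink_times must lie in [0, duration)")


def generate_colored_noise(spec: NoiseSpec) -> np.ndarray:
    """Zero-mean series whose power spectrum decays as 1/f^gamma.

    Spectral synthesis: complex Gaussian amplitudes at the positive rfft
    frequencies scaled by ``(2 sin(pi f))^(-gamma/2)`` — the discrete-time
    frequency response of gamma/2 integration steps, which coincides with
    ``f^(-gamma/2)`` in the low-frequency scaling band and makes gamma = 2
    exactly a random walk (its first differences are white).  DC is zeroed,
    the result inverse-transformed and rescaled to sample SD ``spec.sd``.
    Bit-identical for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    freqs = np.fft.rfftfreq(n, d=1.0)
    amp = np.zeros(freqs.size)
    amp[1:] = (2.0 * np.sin(np.pi * freqs[1:])) ** (-spec.gamma / 2.0)
    re = rng.standard_normal(freqs.size)
    im = rng.standard_normal(freqs.size)
    spectrum = amp * (re + 1j * im)
    spectrum[0] = 0.0
    if n % 2 == 0:
        spectrum[-1] = amp[-1] * re[-1]  # Nyquist bin must be real
    x = np.fft.irfft(spectrum, n=n)
    x -= x.mean()
    s = x.std()
    if s > 0:
        x *= spec.sd / s
    return x


def generate_blink_intervals(
    spec: BlinkTrainSpec, session_label: str = "rest"
) -> "BRVSeries":
    """Strictly positive inter-blink intervals with a target scale exponent.

    Construction: colored noise with gamma = 2*alpha_target - 1 (unit SD),
    mapped through ``exp(log_sd * z)`` and affinely rescaled so the sample
    mean equals 60/mean_rate and every interval stays above the refractory
    floor.  The blink count is ``round(duration * mean_rate / 60)``; the
    series holds count - 1 intervals.
    """
    from .blink_extraction import BRVSeries

    n_blinks = int(round(spec.duration * spec.mean_rate / 60.0))
    n_int = n_blinks - 1
    if n_int < 2:
        raise ValueError(
            f"spec implies only {n_blinks} blinks; need at least 3 for a series"
        )
    noise_spec = NoiseSpec(
        gamma=2.0 * spec.alpha_target - 1.0, n=max(n_int, 64), seed=spec.seed
    )
    z = generate_colored_noise(noise_spec)[:n_int]
    raw = np.exp(spec.log_sd * z)
    mean_iv = 60.0 / spec.mean_rate
    intervals = spec.min_interval + (mean_iv - spec.min_interval) * raw / raw.mean()
    return BRVSeries(intervals=intervals, session_label=session_label)


def raised_cosine_pulse(
    t: np.ndarray, center: float, amplitude: float, width_s: float
) -> np.ndarray:
    """Smooth unimodal blink template with compact support of ``width_s``."""
    arg = (t - center) / width_s
    out = np.zeros_like(t)
    mask = np.abs(arg) <= 0.5
    out[mask] = 0.5 * amplitude * (1.0 + np.cos(2.0 * np.pi * arg[mask]))
    return out


def synthesize_eeg(spec: EEGSynthSpec) -> "EEGRecording":
    """Two-channel (Fp1, Fp2) EEG with a blink pulse at every event time.

    Each channel carries independent colored background noise; the same
    raised-cosine pulse is added to both channels at each blink time.
    Blink times closer together than the template width raise a warning but
    are still rendered additively.
    """
    from .blink_extraction import EEGRecording

    n = int(round(spec.fs * spec.duration))
    t = np.arange(n) / spec.fs
    width_s = spec.template_width / 1000.0

    times = np.sort(np.asarray(spec.blink_times, dtype=float))
    if times.size >= 2 and np.any(np.diff(times) < width_s):
        warnings.warn(
            "blink templates overlap (events closer than the template width); "
            "rendering additively",
            RuntimeWarning,
            stacklevel=2,
        )
    pulses = np.zeros(n)
    for c in times:
        pulses += raised_cosine_pulse(t, c, spec.template_amplitude, width_s)

    child_seeds = np.random.SeedSequence(spec.seed).generate_state(2)
    channels = {}
    for name, child in zip(("Fp1", "Fp2"), child_seeds):
        if spec.noise_sd > 0:
            noise = generate_colored_noise(
                NoiseSpec(gamma=spec.noise_gamma, n=max(n, 64),
                          seed=int(child), sd=spec.noise_sd)
            )[:n]
        else:
            noise = np.zeros(n)
        channels[name] = noise + pulses
    return EEGRecording(fs=spec.fs, channels=channels)


# ---------------------------------------------------------------------------
# Writers (CSV + JSON sidecar with the generating spec)
# ---------------------------------------------------------------------------

def _write_sidecar(path: Path, spec) -> None:
    sidecar = path.with_suffix(".json")
    payload = {"spec_type": type(spec).__name__, "spec": asdict(spec)}
    sidecar.write_text(json.dumps(payload, indent=2) + "\n")


def write_eeg_csv(rec: "EEGRecording", path: str | Path, spec: EEGSynthSpec | None = None) -> Path:
    """Write a two-channel recording as CSV (time_s, Fp1_uV, Fp2_uV)."""
    path = Path(path)
    n = rec.n_samples
    df = pd.DataFrame(
        {
            "time_s": np.arange(n) / rec.fs + rec.start_offset,
            "Fp1_uV": rec.channels["Fp1"],
            "Fp2_uV": rec.channels["Fp2"],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")  # round-trips exactly
    if spec is not None:
        _write_sidecar(path, spec)
    return path


def write_intervals_csv(brv: "BRVSeries", path: str | Path, spec: BlinkTrainSpec | None = None) -> Path:
    """Write an interval series as a single-column CSV (interval_s)."""
    path = Path(path)
    pd.DataFrame({"interval_s": brv.intervals}).to_csv(
        path, index=False, float_format="%.17g"
    )
    if spec is not None:
        _write_sidecar(path, spec)
    return path


def read_intervals_csv(path: str | Path) -> "BRVSeries":
    """Read a single-column interval series written by `write_intervals_csv`."""
    from .blink_extraction import BRVSeries

    df = pd.read_csv(path, float_precision="round_trip")
    col = "interval_s" if "interval_s" in df.columns else df.columns[0]
    return BRVSeries(intervals=df[col].to_numpy(dtype=float))


def binomial_cascade(n_levels: int, p: float = 0.3) -> np.ndarray:
    """Deterministic binomial multiplicative cascade of 2**n_levels points.

    The classic multifractal test measure: mass is split p / (1-p) at every
    dyadic refinement.  Known mass exponents tau(q) = -log2(p^q + (1-p)^q),
    giving a singularity spectrum of width log2((1-p)/p) — a strongly
    multifractal fixture for spectrum estimators.
    """
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    x = np.array([1.0])
    for _ in range(n_levels):
        x = np.concatenate([p * x, (1.0 - p) * x])
    return x
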