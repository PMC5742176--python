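"""Multifractal detrended fluctuation analysis with Gaussian sub-band detrending.

The estimator characterizes how the fluctuation magnitude of a series grows
with observation scale.  Instead of the classical per-window polynomial fit,
the trend at scale ``l`` is removed by subtracting a Gaussian-smoothed copy of
the (integrated) series, a *linear* operator whose pass-band tracks the scale.
Per-window variances ``sigma2_k(l)`` over overlapping sub-windows of length
``2*l`` feed a partition function

    chi(q, l) = sum_k [sigma2_k(l)]^(q/2)  ~  l^tau(q)

from which the mass exponent ``tau(q)``, the Holder exponents ``alpha(q)`` and
the singularity spectrum ``f(q)`` are obtained as log-log regression slopes
over the scale set.  The headline scalar is ``alpha(q=0)`` — the peak position
of the multifractal spectrum — with the color-noise taxonomy alpha = 0.5 / 1.0
/ 1.5 for white / pink / brown noise, equivalently alpha = (gamma + 1) / 2 for
a power spectrum S(f) ~ 1/f^gamma (gamma > -1).

A classical polynomial-detrended MFDFA (``classical_mfdfa``) is provided as an
independent oracle for cross-method checks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import linregress

logger = logging.getLogger(__name__)

#: Scale set used throughout: window half-lengths l, in series samples.
DEFAULT_SCALES: tuple[int, ...] = (8, 10, 12, 14, 16, 20, 22, 26, 32, 38, 46, 54, 64)

#: Default moment-order grid for full-spectrum estimation.
DEFAULT_Q_GRID: tuple[float, ...] = tuple(np.arange(-3.0, 3.0 + 1e-9, 0.25))

#: Gaussian kernel spread as a fraction of the scale: sigma(l) = SIGMA_FACTOR * l.
DEFAULT_SIGMA_FACTOR = 0.25

#: Kernel truncation, in units of sigma.
KERNEL_TRUNCATE = 4.0

#: Calibration constant applied to the ln(sigma2) regression slope so that
#: alpha is expressed in fluctuation (sigma) units: ln sigma2 = 2 ln sigma.
DEFAULT_CALIBRATION_C = 0.5

#: Minimum sub-window count for a scale to be retained.
MIN_WINDOWS_PER_SCALE = 4

#: Minimum number of retained scales for a regression.
MIN_SCALES = 5


class InsufficientScalesError(ValueError):
    """Fewer than MIN_SCALES scales are usable for the series length."""


class DegenerateSeriesError(ValueError):
    """All sub-window variances vanish; no scaling can be estimated."""


@dataclass(frozen=True)
class ScaleSet:
    """Ordered window half-lengths ``l`` (series samples)."""

    scales: tuple[int, ...] = DEFAULT_SCALES

    def __post_init__(self) -> None:
        s = tuple(int(l) for l in self.scales)
        object.__setattr__(self, "scales", s)
        if len(s) == 0:
            raise ValueError("scale set is empty")
        if any(b <= a for a, b in zip(s, s[1:])):
            raise ValueError("scales must be strictly increasing")
        if s[0] < 4:
            raise ValueError("smallest scale must be >= 4")

    def retained(self, n: int, min_windows: int = MIN_WINDOWS_PER_SCALE) -> tuple[int, ...]:
        """Scales whose sub-window count N_l = floor(n/l) - 1 reaches ``min_windows``."""
        return tuple(l for l in self.scales if n // l - 1 >= min_windows)

    def __iter__(self):
        return iter(self.scales)

    def __len__(self) -> int:
        return len(self.scales)


@dataclass
class FluctuationTable:
    """Per-scale sub-window variances sigma2_k(l), k = 1..N_l."""

    variances: dict[int, np.ndarray]

    def n_l(self, l: int) -> int:
        return len(self.variances[l])

    @property
    def scales(self) -> tuple[int, ...]:
        return tuple(self.variances)


@dataclass
class PartitionFunction:
    """chi(q, l) on a (q, l) grid; chi(0, l) equals N_l exactly."""

    q: np.ndarray
    scales: np.ndarray
    chi: np.ndarray  # shape (len(q), len(scales))


@dataclass
class MultifractalSpectrum:
    """tau(q), alpha(q), f(q) and per-q regression diagnostics."""

    q: np.ndarray
    tau: np.ndarray
    alpha: np.ndarray
    f: np.ndarray
    r_squared: np.ndarray      # R^2 of the ln chi vs ln l regression, per q
    scales_used: tuple[int, ...] = ()
    h: np.ndarray | None = None  # generalized Hurst exponents (classical route)

    def at_q(self, q0: float) -> tuple[float, float, float]:
        i = int(np.argmin(np.abs(self.q - q0)))
        return float(self.tau[i]), float(self.alpha[i]), float(self.f[i])


@dataclass
class ScalingExponent:
    """The headline scalar alpha = alpha(q=0) with fit diagnostics."""

    alpha0: float
    fit_r2: float
    n_scales_used: int


# ---------------------------------------------------------------------------
# Elementary steps
# ---------------------------------------------------------------------------

def alpha_from_gamma(gamma: float) -> float:
    """Scale exponent implied by a 1/f^gamma spectrum: alpha = (gamma + 1)/2.

    Valid for gamma > -1; gamma = 0, 1, 2 give the white/pink/brown values
    0.5, 1.0, 1.5.
    """
    if gamma <= -1:
        raise ValueError(f"alpha = (gamma+1)/2 requires gamma > -1, got {gamma}")
    return (gamma + 1.0) / 2.0


def profile(series: Sequence[float]) -> np.ndarray:
    """Integrated series: cumulative sum of the mean-centered input.

    Standard DFA profile step; it is what pins the color-noise taxonomy
    (white -> 0.5, brown -> 1.5) to the regression slopes.
    """
    x = np.asarray(series, dtype=float)
    return np.cumsum(x - x.mean())


def default_sigma_of_l(l: int) -> float:
    """Default kernel-spread rule sigma(l) = l/4 (FWHM ~ 0.59 l)."""
    return DEFAULT_SIGMA_FACTOR * l


def subband_detrend(
    series: Sequence[float],
    l: int,
    sigma_of_l: Callable[[int], float] = default_sigma_of_l,
) -> np.ndarray:
    """High-pass the series at scale ``l`` by Gaussian-kernel subtraction.

    Returns ``x - G_sigma(l) * x`` where ``G`` is a Gaussian smoothing kernel
    of spread ``sigma_of_l(l)`` truncated at +/- 4 sigma.  The operation is
    linear in the input and exactly removes constants (and, by kernel
    symmetry, linear trends away from the boundaries).
    """
    x = np.asarray(series, dtype=float)
    sigma = float(sigma_of_l(l))
    if sigma <= 0:
        raise ValueError("kernel sigma must be positive")
    radius = int(KERNEL_TRUNCATE * sigma + 0.5)
    if 2 * radius + 1 > x.size:
        raise ValueError(
            f"Gaussian kernel ({2 * radius + 1} taps) longer than series ({x.size})"
        )
    smooth = gaussian_filter1d(x, sigma, truncate=KERNEL_TRUNCATE, mode="reflect")
    return x - smooth


def window_variances(fluct: Sequence[float], l: int) -> np.ndarray:
    """Population variances over overlapping sub-windows of length ``2*l``.

    Windows advance by step ``l`` (50% overlap), giving
    ``N_l = floor(n / l) - 1`` windows.
    """
    x = np.asarray(fluct, dtype=float)
    n = x.size
    n_l = n // l - 1
    if n_l < 1:
        raise ValueError(f"scale l={l} too large for series of length {n}")
    windows = np.lib.stride_tricks.sliding_window_view(x, 2 * l)[::l][:n_l]
    return windows.var(axis=1)


def fluctuation_table(
    series: Sequence[float],
    scales: ScaleSet | Sequence[int] = DEFAULT_SCALES,
    *,
    integrate: bool = True,
    sigma_of_l: Callable[[int], float] = default_sigma_of_l,
    min_windows: int = MIN_WINDOWS_PER_SCALE,
) -> FluctuationTable:
    """Sub-band detrend at every retained scale and tabulate window variances.

    ``min_windows`` sets the smallest sub-window count for which a scale is
    kept; the conservative default of 4 favors variance quality, while 1
    admits short physiological series (a few dozen intervals) at the cost of
    noisier large-scale variances.
    """
    scale_set = scales if isinstance(scales, ScaleSet) else ScaleSet(tuple(scales))
    x = profile(series) if integrate else np.asarray(series, dtype=float)

    def kernel_fits(l: int) -> bool:
        radius = int(KERNEL_TRUNCATE * float(sigma_of_l(l)) + 0.5)
        return 2 * radius + 1 <= x.size

    retained = tuple(l for l in scale_set.retained(x.size, min_windows) if kernel_fits(l))
    if len(retained) < MIN_SCALES:
        raise InsufficientScalesError(
            f"only {len(retained)} usable scales for series of length {x.size} "
            f"(need >= {MIN_SCALES})"
        )
    table: dict[int, np.ndarray] = {}
    for l in retained:
        fluct = subband_detrend(x, l, sigma_of_l)
        table[l] = window_variances(fluct, l)
    return FluctuationTable(table)


def partition_function(
    table: FluctuationTable, q: float | Sequence[float]
) -> PartitionFunction:
    """chi(q, l) = sum_k [sigma2_k(l)]^(q/2) for every retained scale.

    For q = 0 each summand is 1, so chi(0, l) = N_l exactly.  Zero-variance
    windows are dropped (with a warning) for q < 0, where 0^(q/2) diverges.
    """
    qs = np.atleast_1d(np.asarray(q, dtype=float))
    scales = np.array(table.scales)
    chi = np.empty((qs.size, scales.size))
    for j, l in enumerate(scales):
        v = table.variances[l]
        for i, qi in enumerate(qs):
            chi[i, j] = _chi_one(v, qi, l)
    return PartitionFunction(qs, scales, chi)


def _chi_one(v: np.ndarray, q: float, l: int) -> float:
    if q < 0 and np.any(v == 0):
        n_zero = int(np.sum(v == 0))
        warnings.warn(
            f"dropping {n_zero} zero-variance window(s) at scale {l} for q={q}",
            RuntimeWarning,
            stacklevel=3,
        )
        v = v[v > 0]
        if v.size == 0:
            raise DegenerateSeriesError(f"all windows degenerate at scale {l}")
    with np.errstate(divide="ignore"):
        return float(np.sum(v ** (q / 2.0)))


def mu_weights(table: FluctuationTable, q: float, l: int) -> np.ndarray:
    """Normalized weights mu_k = [sigma2_k]^(q/2) / chi(q, l); sum to 1."""
    v = table.variances[l]
    if q < 0:
        v = v[v > 0]
    chi = _chi_one(table.variances[l], q, l)
    if chi <= 0:
        raise DegenerateSeriesError(f"chi({q}, {l}) is not positive")
    return v ** (q / 2.0) / chi


# ---------------------------------------------------------------------------
# Spectrum estimation
# ---------------------------------------------------------------------------

def estimate_spectrum(
    series: Sequence[float],
    scales: ScaleSet | Sequence[int] = DEFAULT_SCALES,
    q_grid: Sequence[float] = DEFAULT_Q_GRID,
    *,
    integrate: bool = True,
    sigma_of_l: Callable[[int], float] = default_sigma_of_l,
    calibration_c: float = DEFAULT_CALIBRATION_C,
    min_windows: int = MIN_WINDOWS_PER_SCALE,
) -> MultifractalSpectrum:
    """Estimate tau(q), alpha(q) and f(q) over the retained scale set.

    The small-scale limits are evaluated as ordinary least-squares slopes
    against ``ln l`` over the retained scales:

    * ``tau(q)``  — slope of ``ln chi(q, l)``;
    * ``alpha(q)`` — ``calibration_c`` times the slope of
      ``sum_k mu_k ln sigma2_k``;
    * ``f(q)``   — slope of ``sum_k mu_k ln mu_k``.

    With ``calibration_c = 0.5`` (converting variance to fluctuation units)
    the identity ``f = q alpha - tau`` holds on the grid up to regression
    linearity, and white/pink/brown noise map to alpha = 0.5 / 1.0 / 1.5.
    """
    table = fluctuation_table(
        series, scales, integrate=integrate, sigma_of_l=sigma_of_l,
        min_windows=min_windows,
    )
    used = table.scales
    ln_l = np.log(np.array(used, dtype=float))
    qs = np.asarray(q_grid, dtype=float)

    tau = np.empty(qs.size)
    alpha = np.empty(qs.size)
    f = np.empty(qs.size)
    r2 = np.empty(qs.size)
    for i, q in enumerate(qs):
        ln_chi = np.empty(len(used))
        a_num = np.empty(len(used))   # sum mu ln sigma2
        f_num = np.empty(len(used))   # sum mu ln mu
        for j, l in enumerate(used):
            v = table.variances[l]
            ln_chi[j] = np.log(_chi_one(v, q, l))
            mu = mu_weights(table, q, l)
            vq = v[v > 0] if q < 0 else v
            # windows with mu = 0 (zero variance at q > 0) contribute nothing
            pos = vq > 0
            a_num[j] = float(np.sum(mu[pos] * np.log(vq[pos])))
            mpos = mu > 0
            f_num[j] = float(np.sum(mu[mpos] * np.log(mu[mpos])))
        fit_tau = linregress(ln_l, ln_chi)
        fit_a = linregress(ln_l, a_num)
        fit_f = linregress(ln_l, f_num)
        tau[i] = fit_tau.slope
        alpha[i] = calibration_c * fit_a.slope
        f[i] = fit_f.slope
        r2[i] = fit_tau.rvalue ** 2
    return MultifractalSpectrum(qs, tau, alpha, f, r2, scales_used=used)


def alpha0(
    series: Sequence[float],
    scales: ScaleSet | Sequence[int] = DEFAULT_SCALES,
    *,
    integrate: bool = True,
    sigma_of_l: Callable[[int], float] = default_sigma_of_l,
    calibration_c: float = DEFAULT_CALIBRATION_C,
    min_windows: int = MIN_WINDOWS_PER_SCALE,
) -> ScalingExponent:
    """The scale exponent alpha = alpha(q = 0), the peak of the spectrum.

    At q = 0 the weights are uniform (mu_k = 1/N_l), so alpha(0) is
    ``calibration_c`` times the slope of the mean log window-variance against
    ``ln l``.  ``fit_r2`` reports the quality of that regression.
    """
    table = fluctuation_table(
        series, scales, integrate=integrate, sigma_of_l=sigma_of_l,
        min_windows=min_windows,
    )
    used = table.scales
    ln_l = np.log(np.array(used, dtype=float))
    a_num = np.empty(len(used))
    for j, l in enumerate(used):
        v = table.variances[l]
        pos = v[v > 0]
        if pos.size == 0:
            raise DegenerateSeriesError(f"all windows degenerate at scale {l}")
        a_num[j] = np.log(pos).sum() / v.size
    fit = linregress(ln_l, a_num)
    exponent = float(calibration_c * fit.slope)
    if not np.isfinite(exponent):
        raise DegenerateSeriesError("alpha(0) is not finite")
    return ScalingExponent(exponent, float(fit.rvalue ** 2), len(used))


# ---------------------------------------------------------------------------
# Classical polynomial-detrended MFDFA (independent oracle)
# ---------------------------------------------------------------------------

def classical_mfdfa(
    series: Sequence[float],
    scales: ScaleSet | Sequence[int] = DEFAULT_SCALES,
    q_grid: Sequence[float] = DEFAULT_Q_GRID,
    poly_order: int = 1,
    *,
    integrate: bool = True,
) -> MultifractalSpectrum:
    """Standard MFDFA with per-window least-squares polynomial detrending.

    The profile is split into non-overlapping windows of length ``2*l`` (both
    from the start and from the end of the series, as is conventional), a
    polynomial of ``poly_order`` is subtracted per window, and the generalized
    Hurst exponents ``h(q)`` are the slopes of ``ln F_q(l)`` vs ``ln l`` with

        F_q = ( mean_k [F2_k]^(q/2) )^(1/q),   F_0 = exp( mean_k ln F2_k / 2 ).

    Exposed here as an independent cross-check of the sub-band route; the two
    agree on monofractal inputs.  tau(q) = q h(q) - 1; alpha(q) = dtau/dq by
    central differences; f = q alpha - tau.
    """
    scale_set = scales if isinstance(scales, ScaleSet) else ScaleSet(tuple(scales))
    x = profile(series) if integrate else np.asarray(series, dtype=float)
    n = x.size
    qs = np.asarray(q_grid, dtype=float)

    used: list[int] = []
    f2_by_scale: list[np.ndarray] = []
    for l in scale_set:
        s = 2 * l
        n_seg = n // s
        if n_seg < 2:
            continue
        t = np.arange(s, dtype=float)
        f2 = []
        for chunk in (x[: n_seg * s], x[n - n_seg * s:]):
            seg = chunk.reshape(n_seg, s)
            coef = np.polynomial.polynomial.polyfit(t, seg.T, poly_order)
            resid = seg - np.polynomial.polynomial.polyval(t, coef).reshape(n_seg, s)
            f2.append(np.mean(resid**2, axis=1))
        used.append(l)
        f2_by_scale.append(np.concatenate(f2))
    if len(used) < MIN_SCALES:
        raise InsufficientScalesError(
            f"only {len(used)} usable scales for series of length {n}"
        )
    ln_s = np.log(2.0 * np.array(used, dtype=float))

    h = np.empty(qs.size)
    r2 = np.empty(qs.size)
    for i, q in enumerate(qs):
        ln_fq = np.empty(len(used))
        for j, f2 in enumerate(f2_by_scale):
            pos = f2[f2 > 0]
            if pos.size == 0:
                raise DegenerateSeriesError("all windows degenerate")
            if q == 0:
                ln_fq[j] = 0.5 * np.mean(np.log(pos))
            else:
                ln_fq[j] = np.log(np.mean(pos ** (q / 2.0))) / q
        fit = linregress(ln_s, ln_fq)
        h[i] = fit.slope
        r2[i] = fit.rvalue ** 2
    tau = qs * h - 1.0
    alpha = np.gradient(tau, qs) if qs.size > 1 else h.copy()
    f = qs * alpha - tau
    return MultifractalSpectrum(qs, tau, alpha, f, r2, scales_used=tuple(used), h=h)
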