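"""Electrochemical model fitting.

Four models recur in the study's electrochemistry:

* square-wave voltammetry peak currents decay exponentially with pulse
  frequency, I_peak(f) = I0·e^(−αf), with characteristic frequency
  f_c = 1/α;
* the impedance spectrum follows a Randles equivalent circuit,
  Z(ω) = Rs + Rct/(1 + jωRctCdl) + W/√(jω);
* capacitance relaxes exponentially, C(t) = C0·e^(−kt), with memory
  duration τ = 1/k, and the same decay shape is fitted (with an offset)
  to the capacitance autocorrelation;
* slow drift is tested by a pooled-variance two-sample t-test between
  early and late segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import DegenerateFitWarning, FitError, UsageError
from .signal_io import TimeSeries

__all__ = [
    "DecayFit",
    "EISSummary",
    "TTestResult",
    "fit_exponential_decay",
    "percent_attenuation",
    "randles_impedance",
    "relaxation_frequency",
    "eis_summary",
    "memory_from_autocorrelation",
    "fit_dynamic_decay",
    "early_late_ttest",
]


@dataclass(frozen=True)
class DecayFit:
    """Parameters of an exponential-decay fit y = y0·e^(−rate·x) [+ offset].

    ``characteristic`` is 1/rate — the characteristic frequency f_c for
    a current-vs-frequency fit, or the memory duration τ for a
    capacitance-vs-time fit (inf when the rate is pinned at 0).
    """

    y0: float
    rate: float
    offset: float
    r2: float

    @property
    def characteristic(self) -> float:
        return 1.0 / self.rate if self.rate > 0 else float("inf")


@dataclass(frozen=True)
class EISSummary:
    """Descriptive statistics of an impedance spectrum."""

    n: int
    mean_zre: float
    sd_zre: float
    ci95_zre: tuple[float, float]
    mean_zim: float
    sd_zim: float
    mean_logmag: float   # log10 Ω
    sd_logmag: float
    ci95_logmag: tuple[float, float]
    mean_phase: float    # degrees
    sd_phase: float


@dataclass(frozen=True)
class TTestResult:
    """Two-sample pooled-variance t-test between two segments."""

    t_stat: float
    p_value: float
    n1: int
    n2: int
    delta: float  # mean(late) − mean(early), in the input's unit


def _r2(y: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return max(0.0, min(1.0, 1.0 - ss_res / ss_tot))


def fit_exponential_decay(x, y, with_offset: bool = False) -> DecayFit:
    """Nonlinear least-squares fit of y = y0·e^(−rate·x) [+ offset].

    Initialisation: offset ← min(y) (offset variant) or 0;
    y0 ← max(y) − offset; rate ← slope of a log-linear regression of
    the positive part of (y − offset) on x.  A constant input yields a
    degenerate fit (rate 0) with a warning rather than an error.

    Raises
    ------
    FitError
        If the optimiser fails to converge after bounded restarts.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    min_pts = 4 if with_offset else 3
    if len(x) < min_pts or len(x) != len(y):
        raise UsageError(
            f"need ≥{min_pts} (x, y) points for this variant, got {len(x)}"
        )
    if np.allclose(y, y[0]):
        warnings.warn(
            "constant input: degenerate fit with rate 0",
            DegenerateFitWarning,
            stacklevel=2,
        )
        return DecayFit(y0=float(y[0]), rate=0.0, offset=0.0, r2=1.0)

    offset0 = float(y.min()) if with_offset else 0.0
    y0_0 = float(y.max()) - offset0
    pos = y - offset0 > 0
    if pos.sum() >= 2 and np.ptp(x[pos]) > 0:
        slope, _ = np.polyfit(x[pos], np.log(y[pos] - offset0 + 1e-300), 1)
        rate0 = max(-slope, 1e-12)
    else:
        rate0 = 1.0 / max(np.ptp(x), 1.0)
    if y0_0 <= 0:
        y0_0 = max(abs(float(y.max())), 1e-12)

    if with_offset:
        def model(x, y0, rate, c):
            return y0 * np.exp(-rate * x) + c
        p0 = [y0_0, rate0, offset0]
    else:
        def model(x, y0, rate):
            return y0 * np.exp(-rate * x)
        p0 = [y0_0, rate0]

    last_err = None
    for attempt, scale in enumerate((1.0, 0.1, 10.0)):
        try:
            p0_try = list(p0)
            p0_try[1] = p0[1] * scale
            popt, _ = optimize.curve_fit(model, x, y, p0=p0_try, maxfev=20000)
            break
        except RuntimeError as err:  # pragma: no cover - rare
            last_err = err
    else:  # pragma: no cover
        raise FitError(f"exponential fit failed to converge: {last_err}")

    if with_offset:
        y0, rate, offset = map(float, popt)
    else:
        (y0, rate), offset = map(float, popt), 0.0
    if rate < 0:
        # re-fit with rate clamped non-negative
        bounds = ([-np.inf, 0.0] + ([-np.inf] if with_offset else []),
                  [np.inf] * (3 if with_offset else 2))
        popt, _ = optimize.curve_fit(
            model, x, y, p0=[y0_0, 1e-12] + ([offset0] if with_offset else []),
            bounds=bounds, maxfev=20000,
        )
        if with_offset:
            y0, rate, offset = map(float, popt)
        else:
            (y0, rate), offset = map(float, popt), 0.0
    if rate == 0:
        warnings.warn(
            "rate pinned at 0: degenerate fit", DegenerateFitWarning, stacklevel=2
        )
    fitted = model(x, *popt)
    return DecayFit(y0=y0, rate=rate, offset=offset, r2=_r2(y, fitted))


def percent_attenuation(i_low_f: float, i_high_f: float) -> float:
    """Percent drop in peak current from the low- to the high-frequency end."""
    if i_low_f <= 0:
        raise UsageError("low-frequency reference current must be positive")
    return 100.0 * (i_low_f - i_high_f) / i_low_f


def randles_impedance(Rs: float, Rct: float, Cdl: float, W: float, f: float) -> complex:
    """Randles-circuit impedance Z(ω) = Rs + Rct/(1+jωRctCdl) + W/√(jω).

    ω = 2πf; the Warburg term uses the principal square root.  With
    W = 0 the locus over frequency is a semicircle of diameter Rct in
    the (Z′, −Z″) plane, with apex (Rs + Rct/2, Rct/2) at
    f = 1/(2πRctCdl).
    """
    if f <= 0:
        raise UsageError("frequency must be positive")
    if min(Rs, Rct, Cdl, W) < 0:
        raise UsageError("circuit parameters must be non-negative")
    omega = 2.0 * np.pi * f
    z = Rs + Rct / (1.0 + 1j * omega * Rct * Cdl)
    if W > 0:
        z = z + W / np.sqrt(1j * omega)
    return complex(z)


def relaxation_frequency(Rct: float, Cdl: float) -> float:
    """Relaxation frequency f0 = 1/(2π·Rct·Cdl), Hz."""
    if Rct <= 0 or Cdl <= 0:
        raise UsageError("Rct and Cdl must be positive")
    return 1.0 / (2.0 * np.pi * Rct * Cdl)


def eis_summary(spectrum) -> EISSummary:
    """Descriptive statistics of an impedance table (f_Hz, Zre_ohm, Zim_ohm).

    Reports means/SDs of Z′, Z″, log10|Z| and the phase angle in
    degrees, with 95% CIs as mean ± 1.96·sd/√n.  The Bode magnitude is
    reported explicitly as log10 Ω.
    """
    zre = np.asarray(spectrum["Zre_ohm"], dtype=float)
    zim = np.asarray(spectrum["Zim_ohm"], dtype=float)
    if len(zre) < 2:
        raise UsageError("eis_summary needs at least 2 spectrum rows")
    z = zre + 1j * zim
    logmag = np.log10(np.abs(z))
    phase = np.degrees(np.angle(z))
    n = len(zre)

    def ci(mean, sd):
        half = 1.96 * sd / np.sqrt(n)
        return (float(mean - half), float(mean + half))

    return EISSummary(
        n=n,
        mean_zre=float(zre.mean()),
        sd_zre=float(zre.std(ddof=1)),
        ci95_zre=ci(zre.mean(), zre.std(ddof=1)),
        mean_zim=float(zim.mean()),
        sd_zim=float(zim.std(ddof=1)),
        mean_logmag=float(logmag.mean()),
        sd_logmag=float(logmag.std(ddof=1)),
        ci95_logmag=ci(logmag.mean(), logmag.std(ddof=1)),
        mean_phase=float(phase.mean()),
        sd_phase=float(phase.std(ddof=1)),
    )


def memory_from_autocorrelation(series: TimeSeries, max_lag_fraction: float = 0.25) -> DecayFit:
    """Memory duration from the autocorrelation of a recording.

    The biased sample autocorrelation of the mean-removed series is
    computed over lags 0..n·max_lag_fraction and fitted with
    R(lag) = A·e^(−lag/τ) + C; ``characteristic`` is τ in seconds.
    For an AR(1) process with coefficient φ, τ ≈ −1/ln(φ).
    """
    if series.n < 256:
        raise UsageError("memory_from_autocorrelation needs at least 256 samples")
    x = series.values - series.values.mean()
    n = series.n
    max_lag = int(n * max_lag_fraction)
    full = np.correlate(x, x, mode="full")[n - 1 :]
    acf = full[: max_lag + 1] / full[0]
    lags = np.arange(max_lag + 1) * series.dt
    fit = fit_exponential_decay(lags, acf, with_offset=True)
    return fit


def fit_dynamic_decay(series: TimeSeries) -> DecayFit:
    """Fit C(t) = C0·e^(−kt) to a capacitance recording; τ = 1/k.

    The time axis is shifted to start at 0 so C0 is the initial value.
    """
    if series.n < 16:
        raise UsageError("fit_dynamic_decay needs at least 16 samples")
    if (series.values <= 0).mean() > 0.5:
        raise UsageError("fit_dynamic_decay expects predominantly positive values")
    t = series.times - series.times[0]
    return fit_exponential_decay(t, series.values, with_offset=False)


def early_late_ttest(series: TimeSeries, split_fraction: float = 0.5) -> TTestResult:
    """Pooled-variance two-sample t-test between early and late segments.

    The first ``split_fraction`` of samples forms the early segment and
    the last ``split_fraction`` the late one; ``delta`` is
    mean(late) − mean(early).
    """
    if not 0 < split_fraction <= 0.5:
        raise UsageError("split_fraction must be in (0, 0.5]")
    k = int(series.n * split_fraction)
    if k < 2:
        raise UsageError("each segment needs at least 2 samples")
    early = series.values[:k]
    late = series.values[-k:]
    if early.std() == 0 and late.std() == 0 and early.mean() == late.mean():
        return TTestResult(t_stat=0.0, p_value=1.0, n1=k, n2=k, delta=0.0)
    t_stat, p = stats.ttest_ind(late, early, equal_var=True)
    return TTestResult(
        t_stat=float(t_stat),
        p_value=float(p),
        n1=k,
        n2=k,
        delta=float(late.mean() - early.mean()),
    )
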