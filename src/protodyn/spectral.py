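"""Spectral analysis: Welch PSD, log-log power-law slope, spectrogram,
total signal energy, magnitude-squared coherence, and cross-correlation.

The recordings' spectra are strongly colored — log10 PSD falls roughly
linearly in log10 f with slopes steeper than brown noise (−2) — so the
central estimator here is an ordinary least-squares fit of
log10(PSD) on log10(f) over a fixed band (default 0.01–0.5 Hz).
Welch defaults throughout: Hann taper, 50% overlap, linear detrend per
segment, 1024-point segments at 1 Hz sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .errors import UsageError
from .signal_io import TimeSeries

__all__ = [
    "SpectralEstimate",
    "SlopeFit",
    "CoherenceResult",
    "Spectrogram",
    "estimate_psd",
    "fit_psd_slope",
    "spectrogram",
    "total_energy",
    "msc",
    "cross_correlation",
]

DEFAULT_BAND = (0.01, 0.5)  # Hz, the study's fit band
DEFAULT_NPERSEG = 1024
DB_FLOOR = -120.0  # dB floor guarding log10(0)


@dataclass(frozen=True)
class SpectralEstimate:
    """One-sided Welch PSD (DC bin removed)."""

    freqs: np.ndarray   # Hz, strictly increasing, > 0
    psd: np.ndarray     # (unit)²/Hz
    nperseg: int
    noverlap: int
    window: str
    df: float           # frequency resolution, Hz


@dataclass(frozen=True)
class SlopeFit:
    """OLS fit of log10(PSD) = slope·log10(f) + intercept over a band."""

    slope: float
    intercept: float
    stderr: float
    band: tuple[float, float]
    n_points: int


@dataclass(frozen=True)
class CoherenceResult:
    """Magnitude-squared coherence C_xy(f) = |G_xy|²/(G_xx·G_yy) ∈ [0, 1]."""

    freqs: np.ndarray
    msc: np.ndarray
    n_segments: int


@dataclass(frozen=True)
class Spectrogram:
    """Short-time PSD in dB re 1 (unit)²/Hz on a time–frequency grid."""

    times: np.ndarray     # s, segment centres
    freqs: np.ndarray     # Hz
    psd: np.ndarray       # linear scale, shape (freq, time)
    psd_db: np.ndarray    # 10·log10(psd), floored at DB_FLOOR
    window: int           # samples per segment
    df: float
    dt: float             # hop between segment centres, s


def _segment_count(n: int, nperseg: int, noverlap: int) -> int:
    step = nperseg - noverlap
    return max(0, 1 + (n - nperseg) // step)


def estimate_psd(
    series: TimeSeries,
    nperseg: int | None = None,
    window: str = "hann",
    overlap: float = 0.5,
) -> SpectralEstimate:
    """One-sided averaged-periodogram (Welch) PSD of a recording.

    Satisfies Parseval to within a few percent: ``sum(psd)·df`` matches
    the variance of the detrended, tapered series.
    """
    if nperseg is None:
        nperseg = min(DEFAULT_NPERSEG, series.n // 2)
    if series.n < 2 * nperseg - int(overlap * nperseg):
        raise UsageError(
            f"series too short ({series.n} samples) for two {nperseg}-sample segments"
        )
    noverlap = int(overlap * nperseg)
    freqs, psd = signal.welch(
        series.values,
        fs=series.fs,
        window=window,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="linear",
    )
    return SpectralEstimate(
        freqs=freqs[1:],
        psd=psd[1:],
        nperseg=nperseg,
        noverlap=noverlap,
        window=window,
        df=float(freqs[1] - freqs[0]),
    )


def fit_psd_slope(
    spec: SpectralEstimate, band: tuple[float, float] = DEFAULT_BAND
) -> SlopeFit:
    """OLS power-law fit of the PSD on a log-log scale, restricted to a band.

    Only in-band points with strictly positive PSD enter the fit; at
    least three are required.  The slope's standard error comes from the
    OLS covariance.  Multiplying the signal by a constant shifts the
    intercept but leaves the slope unchanged.
    """
    f_lo, f_hi = band
    mask = (spec.freqs >= f_lo) & (spec.freqs <= f_hi) & (spec.psd > 0)
    if mask.sum() < 3:
        raise UsageError(
            f"need ≥3 positive PSD points in band {band}, got {int(mask.sum())}"
        )
    logf = np.log10(spec.freqs[mask])
    logp = np.log10(spec.psd[mask])
    res = stats.linregress(logf, logp)
    return SlopeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        stderr=float(res.stderr),
        band=(f_lo, f_hi),
        n_points=int(mask.sum()),
    )


def spectrogram(series: TimeSeries, window: int = DEFAULT_NPERSEG) -> Spectrogram:
    """Short-time Fourier PSD of a recording, in dB re 1 (unit)²/Hz.

    1024-point Hann segments with 50% overlap by default; frequency
    resolution fs/window.  Zero-power cells are floored at −120 dB.
    """
    if window > series.n:
        raise UsageError(f"window {window} longer than series ({series.n} samples)")
    noverlap = window // 2
    freqs, times, sxx = signal.spectrogram(
        series.values,
        fs=series.fs,
        window="hann",
        nperseg=window,
        noverlap=noverlap,
        detrend="linear",
        scaling="density",
        mode="psd",
    )
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(sxx)
    db = np.maximum(db, DB_FLOOR)
    dt = float(times[1] - times[0]) if len(times) > 1 else window / series.fs
    return Spectrogram(
        times=times + series.times[0],
        freqs=freqs,
        psd=sxx,
        psd_db=db,
        window=window,
        df=float(freqs[1] - freqs[0]),
        dt=dt,
    )


def total_energy(spec: Spectrogram) -> float:
    """Total signal energy: double Riemann sum of the linear-scale PSD
    over the time–frequency grid with Δf·Δt weights.

    Scales quadratically with signal amplitude.
    """
    if spec.psd.size == 0:
        raise UsageError("empty spectrogram")
    return float(spec.psd.sum() * spec.df * spec.dt)


def msc(
    x: TimeSeries,
    y: TimeSeries,
    nperseg: int | None = None,
    window: str = "hann",
    overlap: float = 0.5,
) -> CoherenceResult:
    """Magnitude-squared coherence of two recordings on a common axis.

    Welch cross- and auto-spectra share the same segmentation.  At least
    two averaging segments are required: single-segment MSC is
    identically 1 and is refused.  For independent signals the expected
    bias level is ≈ 1/n_segments.  MSC is symmetric in its arguments.
    """
    if x.n != y.n or not np.allclose(x.times, y.times, rtol=1e-9):
        raise UsageError("x and y must share a common time axis (align first)")
    if nperseg is None:
        nperseg = min(DEFAULT_NPERSEG, x.n // 2)
    noverlap = int(overlap * nperseg)
    n_seg = _segment_count(x.n, nperseg, noverlap)
    if n_seg < 2:
        raise UsageError(
            "MSC needs at least 2 averaging segments (single-segment MSC ≡ 1)"
        )
    freqs, coh = signal.coherence(
        x.values,
        y.values,
        fs=x.fs,
        window=window,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="linear",
    )
    coh = np.clip(coh, 0.0, 1.0)
    return CoherenceResult(freqs=freqs, msc=coh, n_segments=n_seg)


def cross_correlation(
    input: TimeSeries, response: TimeSeries, max_lag: int | None = None
):
    """Discrete cross-correlation R_xy(τ) over lags up to ±n/2.

    Each lag is normalised by its overlap length, so R at lag τ is the
    mean of x(t)·y(t+τ) over the overlapping samples.  Returns
    ``(lags_s, values, peak_lag_s)``.
    """
    if input.n != response.n or not np.allclose(
        input.times, response.times, rtol=1e-9
    ):
        raise UsageError("series must share a common time axis")
    x, y = input.values, response.values
    n = input.n
    if max_lag is None:
        max_lag = n // 2
    full = signal.correlate(y, x, mode="full")
    lags = signal.correlation_lags(n, n, mode="full")
    keep = np.abs(lags) <= max_lag
    lags = lags[keep]
    vals = full[keep] / (n - np.abs(lags))
    peak_lag = int(lags[np.argmax(vals)])
    dt = input.dt
    return lags * dt, vals, peak_lag * dt
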