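"""Descriptive and oscillation metrics of a recording.

Summaries follow the study's reporting layout: count, mean, sample SD,
min/quartiles/max, peak-to-peak amplitude (max − min), the dominant
frequency picked from an averaged-periodogram PSD, its period, and the
coefficient of variation.  The quantum-dot amplification factor is the
ratio of two peak-to-peak amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import signal

from .errors import DataError, UsageError
from .signal_io import TimeSeries

__all__ = [
    "OscillationSummary",
    "summarize",
    "dominant_frequency",
    "coefficient_of_variation",
    "amplification_factor",
    "welch_nperseg",
]


@dataclass(frozen=True)
class OscillationSummary:
    """One row of the descriptive/oscillation-metrics table."""

    count: int
    mean: float
    sd: float
    min: float
    q25: float
    median: float
    q75: float
    max: float
    amplitude: float      # max − min, mV
    dominant_freq: float  # Hz
    period: float         # s
    cv: float             # dimensionless; NaN when the mean is 0

    def as_dict(self) -> dict:
        return asdict(self)


def welch_nperseg(n: int) -> int:
    """Welch segment length: min(4096, n/4) rounded down to a power of two."""
    target = min(4096, n // 4)
    return 1 << max(int(np.log2(target)), 1)


def dominant_frequency(series: TimeSeries) -> tuple[float, float]:
    """Dominant frequency and period from the averaged-periodogram PSD.

    The series is linearly detrended per segment (Hann taper, 50%
    overlap); the zero-frequency bin is excluded before peak picking.

    Returns
    -------
    (freq, period) : frequency of the PSD maximum in Hz and 1/freq in s.
    """
    if series.n < 64:
        raise UsageError("dominant_frequency needs at least 64 samples")
    if np.allclose(series.values, series.values[0]):
        raise DataError("dominant frequency undefined for a constant series")
    nperseg = welch_nperseg(series.n)
    freqs, psd = signal.welch(
        series.values,
        fs=series.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="linear",
    )
    # exclude the DC bin
    k = 1 + int(np.argmax(psd[1:]))
    f = float(freqs[k])
    return f, 1.0 / f


def summarize(series: TimeSeries) -> OscillationSummary:
    """Descriptive statistics plus oscillation metrics for one recording."""
    if series.n < 16:
        raise UsageError("summarize needs at least 16 samples")
    v = series.values
    q25, med, q75 = np.percentile(v, [25, 50, 75])
    vmin, vmax = float(v.min()), float(v.max())
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    try:
        freq, period = dominant_frequency(series)
    except DataError:
        freq, period = float("nan"), float("nan")
    cv = sd / mean if mean != 0 else (0.0 if sd == 0 else float("nan"))
    return OscillationSummary(
        count=series.n,
        mean=mean,
        sd=sd,
        min=vmin,
        q25=float(q25),
        median=float(med),
        q75=float(q75),
        max=vmax,
        amplitude=vmax - vmin,
        dominant_freq=freq,
        period=period,
        cv=cv,
    )


def coefficient_of_variation(values) -> float:
    """CV = sample SD / mean (SD with denominator n−1)."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    if mean == 0:
        raise DataError("coefficient of variation undefined for zero mean")
    return float(values.std(ddof=1) / mean)


def amplification_factor(a_ref: float, a_test: float) -> float:
    """Amplitude amplification k = A_test / A_ref (e.g. QD vs bare film)."""
    if a_ref <= 0:
        raise UsageError("reference amplitude must be positive")
    return a_test / a_ref
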