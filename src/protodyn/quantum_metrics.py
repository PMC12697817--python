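"""Coherence statistics: binned Shannon entropy, the quantum-Fisher-
information proxy, and Hilbert-transform envelope/phase analysis.

The QFI proxy is a classical surrogate for frequency sensitivity,

    F_Q(f) ≈ 4 · Var(V) · S(f),   S(f) = 1/(2πf)²,

so it is strictly decreasing in f and homogeneous of degree one in the
variance.  When several recordings are compared, their QFI curves are
normalised by the single global maximum across the whole set, which
makes the normalised peaks equal the variance ratios var_i / max_j var_j
— independent of the frequency grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .errors import DegenerateRangeWarning, UsageError
from .signal_io import TimeSeries

__all__ = [
    "EntropyResult",
    "QFIResult",
    "HilbertResult",
    "shannon_entropy",
    "qfi",
    "qfi_curve",
    "qfi_curve_from_variances",
    "hilbert_analysis",
]


@dataclass(frozen=True)
class EntropyResult:
    """Shannon entropy of the amplitude histogram, in bits."""

    entropy: float
    bins: int
    bin_edges: np.ndarray


@dataclass(frozen=True)
class QFIResult:
    """QFI-proxy curve of one recording on a frequency grid."""

    label: str
    variance: float                 # mV²
    freqs: np.ndarray               # Hz
    qfi: np.ndarray                 # mV²·s²
    qfi_normalized: np.ndarray      # in [0, 1] across the compared set
    qfi_at_f0: float | None         # value at the dominant frequency, if given
    mean_normalized: float


@dataclass(frozen=True)
class HilbertResult:
    """Analytic-signal envelope and unwrapped instantaneous phase."""

    envelope: TimeSeries
    phase: np.ndarray        # rad, unwrapped
    phase_slope: float       # rad/s, OLS slope of phase vs time
    phase_variance: float    # rad², after removing the linear trend


def shannon_entropy(values, bins: int = 50) -> EntropyResult:
    """Binned Shannon entropy H = −Σ p_i log2 p_i, in bits.

    The histogram spans [min, max] with equal-width bins and
    probabilities p_i = count_i / n; empty bins contribute zero.
    Entropy is bounded by log2(bins) and is invariant under affine
    transforms of the data (the edges transform with it).  Constant
    input yields 0 bits with a degenerate-range warning.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise UsageError("shannon_entropy needs at least 2 samples")
    if bins < 1:
        raise UsageError("bins must be ≥ 1")
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        warnings.warn(
            "constant input: entropy is 0 over a degenerate range",
            DegenerateRangeWarning,
            stacklevel=2,
        )
        edges = np.linspace(vmin - 0.5, vmax + 0.5, bins + 1)
        return EntropyResult(entropy=0.0, bins=bins, bin_edges=edges)
    counts, edges = np.histogram(values, bins=bins, range=(vmin, vmax))
    p = counts / counts.sum()
    p = p[p > 0]
    h = float(-(p * np.log2(p)).sum())
    return EntropyResult(entropy=h, bins=bins, bin_edges=edges)


def qfi(variance: float, f: float) -> float:
    """QFI proxy 4·Var(V)/(2πf)² in mV²·s²."""
    if f <= 0:
        raise UsageError("frequency must be positive")
    if variance < 0:
        raise UsageError("variance must be non-negative")
    return 4.0 * variance / (2.0 * np.pi * f) ** 2


def qfi_curve_from_variances(
    variances: dict[str, float],
    freqs,
    f0: dict[str, float] | None = None,
) -> list[QFIResult]:
    """QFI-proxy curves for a set of variances on a shared frequency grid.

    Normalisation divides every curve by the single global maximum over
    the whole set, so each normalised peak equals var_i / max_j var_j.
    """
    if not variances:
        raise UsageError("empty variance set")
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise UsageError("all grid frequencies must be positive")
    curves = {
        label: np.array([qfi(var, f) for f in freqs])
        for label, var in variances.items()
    }
    global_max = max(c.max() for c in curves.values())
    results = []
    for label, var in variances.items():
        c = curves[label]
        norm = c / global_max if global_max > 0 else c
        at_f0 = qfi(var, f0[label]) if f0 and label in f0 else None
        results.append(
            QFIResult(
                label=label,
                variance=var,
                freqs=freqs,
                qfi=c,
                qfi_normalized=norm,
                qfi_at_f0=at_f0,
                mean_normalized=float(norm.mean()),
            )
        )
    return results


def qfi_curve(series_set: list[TimeSeries], freqs) -> list[QFIResult]:
    """QFI-proxy curves of recordings, from their sample variances."""
    if not series_set:
        raise UsageError("empty series set")
    variances = {
        s.label or f"series{i}": float(s.values.var(ddof=1))
        for i, s in enumerate(series_set)
    }
    return qfi_curve_from_variances(variances, freqs)


def hilbert_analysis(series: TimeSeries) -> HilbertResult:
    """Amplitude envelope and instantaneous phase via the analytic signal.

    The envelope is the modulus of the discrete Hilbert analytic signal;
    the phase is the unwrapped argument.  Phase variance is computed on
    the residual after removing the best linear trend (for a pure tone
    the trend slope is 2πf0 and the residual variance is ≈ 0).

    The series should be baseline-subtracted first.
    """
    if series.n < 64:
        raise UsageError("hilbert_analysis needs at least 64 samples")
    analytic = sp_signal.hilbert(series.values)
    envelope = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic))
    coeffs = np.polyfit(series.times, phase, 1)
    resid = phase - np.polyval(coeffs, series.times)
    return HilbertResult(
        envelope=series.with_values(envelope, label=f"{series.label} envelope"),
        phase=phase,
        phase_slope=float(coeffs[0]),
        phase_variance=float(resid.var()),
    )
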