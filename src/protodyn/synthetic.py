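"""Seeded synthetic recordings with the statistical structure of the study data.

The spontaneous activity of proteinoid–quantum-dot films is, to first
order, a slow baseline-offset sinusoid (dominant frequency 0.03–0.11 Hz,
tens to hundreds of mV peak-to-peak) riding on strongly colored noise
whose one-sided power spectral density falls as f^(−β) with β ≈ 3–4.
The generators here emulate exactly that structure — plus the
exponential decays seen in square-wave-voltammetry peak currents and in
capacitance relaxation, and the Randles-circuit impedance spectra — so
every analysis stage can be exercised without the raw recordings.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UsageError
from .signal_io import TimeSeries

__all__ = [
    "OscillationSpec",
    "DecaySpec",
    "gen_colored_noise",
    "gen_oscillation",
    "gen_decay_series",
    "gen_randles_spectrum",
]


@dataclass(frozen=True)
class OscillationSpec:
    """Parameters of one synthetic spontaneous-oscillation recording.

    Defaults emulate a representative recording: 1 Hz sampling, a
    0.06 Hz dominant tone of ~325 mV peak-to-peak over a positive
    baseline, with steep (β = 3.5) colored noise.
    """

    fs: float = 1.0          # Hz
    duration: float = 4096.0  # s
    f0: float = 0.06         # Hz, dominant frequency
    amp: float = 325.0       # mV, peak-to-peak of the sinusoid
    baseline: float = 24.0   # mV
    drift_rate: float = 0.0  # mV/s
    noise_beta: float = 3.5  # spectral exponent
    noise_sd: float = 10.0   # mV
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.f0 < self.fs / 2:
            raise UsageError(f"f0 must lie in (0, fs/2); got {self.f0}")
        if self.amp < 0 or self.noise_sd < 0:
            raise UsageError("amp and noise_sd must be non-negative")
        if self.noise_beta < 0:
            raise UsageError("noise_beta must be non-negative")


@dataclass(frozen=True)
class DecaySpec:
    """Parameters of a noisy exponential decay y(x) = y0·exp(−rate·x)."""

    y0: float
    rate: float
    grid: tuple
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.y0 <= 0:
            raise UsageError("y0 must be positive")
        if self.rate < 0:
            raise UsageError("rate must be non-negative")
        if self.noise_sd < 0:
            raise UsageError("noise_sd must be non-negative")


def gen_colored_noise(n: int, fs: float, beta: float, sd: float, seed: int) -> TimeSeries:
    """Zero-mean Gaussian noise whose one-sided PSD ∝ f^(−beta) in expectation.

    Spectral synthesis: independent complex-Gaussian Fourier coefficients
    are scaled by f^(−beta/2), the DC bin is zeroed (zero mean by
    construction), the spectrum inverted, and the result rescaled to the
    target standard deviation.

    Parameters
    ----------
    n : number of samples (≥ 16)
    fs : sampling rate, Hz
    beta : spectral exponent (0 = white, 2 = brown, ~3–4 in the study)
    sd : target sample standard deviation, same unit as the signal
    seed : RNG seed; the output is bit-reproducible per seed
    """
    if n < 16:
        raise UsageError("n must be at least 16")
    if beta < 0:
        raise UsageError("beta must be non-negative")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    coeffs = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-beta / 2.0)
    x = np.fft.irfft(coeffs * scale, n=n)
    s = x.std()
    if sd > 0 and s > 0:
        x *= sd / s
    elif sd == 0:
        x = np.zeros(n)
    times = np.arange(n) / fs
    return TimeSeries(times, x, unit="mV", label=f"colored-noise beta={beta}")


def gen_oscillation(spec: OscillationSpec) -> TimeSeries:
    """Synthetic spontaneous-oscillation recording.

    x(t) = baseline + drift_rate·t + (amp/2)·sin(2π f0 t) + colored noise.
    """
    n = int(round(spec.duration * spec.fs))
    if n < 16:
        raise UsageError("duration·fs must give at least 16 samples")
    t = np.arange(n) / spec.fs
    x = spec.baseline + spec.drift_rate * t + (spec.amp / 2.0) * np.sin(
        2 * np.pi * spec.f0 * t
    )
    if spec.noise_sd > 0:
        noise = gen_colored_noise(n, spec.fs, spec.noise_beta, spec.noise_sd, spec.seed)
        x = x + noise.values
    return TimeSeries(t, x, unit="mV", label=f"oscillation f0={spec.f0}Hz")


def gen_decay_series(spec: DecaySpec, kind: str = "exponential") -> pd.DataFrame:
    """Sample y_i = y0·exp(−rate·x_i) + N(0, noise_sd²) on the given grid.

    Returns a two-column DataFrame ``(x, y)``.  Used to emulate both the
    SWV peak-current-vs-frequency table and capacitance-vs-time decay.
    """
    if kind != "exponential":
        raise UsageError(f"unknown decay kind {kind!r}")
    x = np.asarray(spec.grid, dtype=float)
    y = spec.y0 * np.exp(-spec.rate * x)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise_sd, size=len(x))
    return pd.DataFrame({"x": x, "y": y})


def gen_randles_spectrum(
    Rs: float, Rct: float, Cdl: float, W: float, freqs
) -> pd.DataFrame:
    """Forward-model impedance spectrum of a Randles equivalent circuit.

    Z(ω) = Rs + Rct/(1 + jωRctCdl) + W/√(jω), ω = 2πf, principal root.
    With W = 0 the (Z′, −Z″) locus is a semicircle of diameter Rct
    centred at Rs + Rct/2.

    Returns a DataFrame with columns ``f_Hz``, ``Zre_ohm``, ``Zim_ohm``.
    """
    from .electrochem import randles_impedance

    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise UsageError("all frequencies must be positive")
    z = np.array([randles_impedance(Rs, Rct, Cdl, W, f) for f in freqs])
    return pd.DataFrame({"f_Hz": freqs, "Zre_ohm": z.real, "Zim_ohm": z.imag})
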