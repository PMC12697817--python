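"""Time-series I/O and preprocessing.

Recordings are uniformly sampled scalar signals (potential in mV,
capacitance in F, impedance in Ω) read from two-column CSV files.  This
module defines the :class:`TimeSeries` carrier every downstream stage
consumes, plus the preprocessing the analysis assumes: alignment of
several recordings onto a common time axis, baseline subtraction over an
initial window, and IQR-based outlier flagging.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, UsageError

__all__ = [
    "TimeSeries",
    "BaselineReport",
    "read_timeseries",
    "write_timeseries",
    "interpolate_common_axis",
    "subtract_baseline",
    "iqr_outlier_flags",
]

#: relative tolerance on uniformity of the sampling step
_DT_RTOL = 1e-9


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled scalar signal.

    Parameters
    ----------
    times :
        Sample times in seconds, strictly increasing with a constant step.
    values :
        Signal values, one per time point; finite after construction.
    unit :
        Physical unit tag of the values: ``"mV"``, ``"V"``, ``"F"`` or ``"Ω"``.
    label :
        Free-text identifier carried through reports.
    """

    times: np.ndarray
    values: np.ndarray
    unit: str = "mV"
    label: str = ""
    missing_mask: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1:
            raise UsageError("times and values must be 1-D")
        if len(times) != len(values):
            raise UsageError(
                f"length mismatch: {len(times)} times vs {len(values)} values"
            )
        if len(times) < 2:
            raise UsageError("a TimeSeries needs at least 2 samples")
        steps = np.diff(times)
        bad = np.flatnonzero(steps <= 0)
        if bad.size:
            raise DataError(f"time axis not strictly increasing at index {bad[0] + 1}")
        dt = float(np.median(steps))
        if not np.allclose(steps, dt, rtol=_DT_RTOL, atol=0.0):
            worst = int(np.argmax(np.abs(steps - dt))) + 1
            raise DataError(f"non-uniform sampling step at index {worst}")
        if not np.all(np.isfinite(values)):
            raise DataError("values must be finite after missing-value handling")

    @property
    def dt(self) -> float:
        """Sampling step in seconds."""
        return float(self.times[1] - self.times[0])

    @property
    def fs(self) -> float:
        """Sampling rate in Hz (1/dt)."""
        return 1.0 / self.dt

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        """Span of the time axis in seconds."""
        return float(self.times[-1] - self.times[0])

    def with_values(self, values: np.ndarray, **kw) -> "TimeSeries":
        return replace(self, values=np.asarray(values, dtype=float), **kw)


@dataclass(frozen=True)
class BaselineReport:
    """Result of baseline subtraction over an initial window."""

    baseline: float
    window_samples: int
    adjusted: TimeSeries


def read_timeseries(
    path,
    time_column: str = "time_s",
    value_column: str = "value",
    unit: str = "mV",
    label: str | None = None,
) -> TimeSeries:
    """Read a two-column CSV recording into a :class:`TimeSeries`.

    Non-numeric cells are treated as missing: interior gaps are linearly
    interpolated from their neighbours, leading/trailing gaps are filled
    with the nearest finite value.  The sampling rate is inferred from
    the median time step.

    Raises
    ------
    FormatError
        If a named column is absent or fewer than two rows are present.
    DataError
        If the time axis is not strictly increasing (the message names
        the first offending row).
    """
    df = pd.read_csv(path)
    for col in (time_column, value_column):
        if col not in df.columns:
            raise FormatError(f"column {col!r} not found in {path}")
    if len(df) < 2:
        raise FormatError(f"{path}: need at least 2 rows, got {len(df)}")

    times = pd.to_numeric(df[time_column], errors="coerce").to_numpy(dtype=float)
    if np.isnan(times).any():
        raise DataError(
            f"non-numeric time cell at index {int(np.flatnonzero(np.isnan(times))[0])}"
        )
    values = pd.to_numeric(df[value_column], errors="coerce").to_numpy(dtype=float)
    missing = ~np.isfinite(values)
    if missing.all():
        raise DataError("no finite values in value column")
    if missing.any():
        good = np.flatnonzero(~missing)
        values = np.interp(np.arange(len(values)), good, values[good])

    return TimeSeries(
        times,
        values,
        unit=unit,
        label=label if label is not None else str(path),
        missing_mask=missing if missing.any() else None,
    )


def write_timeseries(
    series: TimeSeries, path, time_column: str = "time_s", value_column: str = "value"
) -> None:
    """Write a :class:`TimeSeries` back out in the same CSV dialect."""
    pd.DataFrame({time_column: series.times, value_column: series.values}).to_csv(
        path, index=False
    )


def interpolate_common_axis(series_list: list[TimeSeries]) -> list[TimeSeries]:
    """Resample every series onto the time axis of the longest one.

    Values are linearly interpolated; outside a series' native span the
    nearest endpoint value is held (clamped), mirroring ``np.interp``.
    Values at time points shared with the target axis are preserved
    exactly.  A single-element list is returned unchanged.
    """
    if not series_list:
        raise UsageError("interpolate_common_axis needs at least one series")
    if len(series_list) == 1:
        return list(series_list)
    longest = max(series_list, key=lambda s: s.duration)
    out = []
    for s in series_list:
        if s is longest:
            out.append(s)
            continue
        vals = np.interp(longest.times, s.times, s.values)
        out.append(TimeSeries(longest.times, vals, unit=s.unit, label=s.label))
    return out


def subtract_baseline(series: TimeSeries, window_seconds: float = 10.0) -> BaselineReport:
    """Remove the mean of the first ``window_seconds`` of the recording.

    The baseline is the NaN-aware mean of all samples with
    ``t < t0 + window_seconds`` (samples flagged as originally missing
    are ignored); the adjusted series is ``values - baseline``.
    Idempotent: re-applying it leaves the adjusted series unchanged.
    """
    if window_seconds <= 0:
        raise UsageError("window_seconds must be positive")
    if series.duration < window_seconds:
        raise UsageError(
            f"series spans {series.duration} s, shorter than the "
            f"{window_seconds} s baseline window"
        )
    in_window = series.times < series.times[0] + window_seconds
    window_vals = series.values[in_window]
    if series.missing_mask is not None:
        keep = ~series.missing_mask[in_window]
        if keep.any():
            window_vals = window_vals[keep]
    baseline = float(np.mean(window_vals))
    adjusted = series.with_values(series.values - baseline)
    return BaselineReport(
        baseline=baseline, window_samples=int(in_window.sum()), adjusted=adjusted
    )


def iqr_outlier_flags(values, k: float = 1.5) -> np.ndarray:
    """Flag values more than ``k``·IQR outside the quartiles.

    Quartiles use the linear-interpolation convention.  Returns a boolean
    mask; the mask is invariant under affine transforms of the data.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 4:
        raise UsageError("iqr_outlier_flags needs at least 4 values")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return (values < lo) | (values > hi)
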