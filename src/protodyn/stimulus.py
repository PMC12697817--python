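"""ASCII pulse-train stimulus: encoding, timing, decoding, and response modulation.

The study drove the proteinoid film with a binary voltage waveform
spelling out text: each character is transmitted MSB-first as eight
10-second bit slots (5 V for a 1, 0 V for a 0) followed by a 10-second
pause, i.e. a 90-second cycle per character and an effective input
frequency of 1/90 ≈ 0.0111 Hz.  The film's natural oscillation is
modelled as amplitude-modulated by the input,
A_mod(t) = A_nat·[1 + k·V_input(t)].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FormatError, UsageError
from .signal_io import TimeSeries

__all__ = [
    "StimulusProgram",
    "ModulationModel",
    "char_to_bits",
    "total_duration_ms",
    "stimulus_waveform",
    "decode_waveform",
    "character_cycle_frequency",
    "modulate_response",
]


@dataclass(frozen=True)
class StimulusProgram:
    """A text message plus the pulse timing that turns it into a waveform."""

    message: str
    pulse_ms: int = 10_000
    pause_ms: int = 10_000
    v_high: float = 5.0
    v_low: float = 0.0
    repeats: int = 1

    def __post_init__(self) -> None:
        if not self.message:
            raise UsageError("message must be non-empty")
        for ch in self.message:
            if ord(ch) > 127:
                raise UsageError(f"non-ASCII character {ch!r} in message")
        if self.pulse_ms <= 0 or self.pause_ms <= 0:
            raise UsageError("pulse_ms and pause_ms must be positive")
        if self.repeats < 1:
            raise UsageError("repeats must be ≥ 1")


@dataclass(frozen=True)
class ModulationModel:
    """Amplitude-modulation law A_mod(t) = A_nat·[1 + k·V_input(t)]."""

    a_nat: float
    k_mod: float

    def __post_init__(self) -> None:
        if self.a_nat < 0:
            raise UsageError("a_nat must be non-negative")


def char_to_bits(c: str) -> list[int]:
    """8-bit MSB-first binary code of a 7-bit ASCII character.

    'T' → 01010100, 'o' → 01101111, ' ' → 00100000.
    """
    if len(c) != 1 or ord(c) > 127:
        raise UsageError(f"expected a single 7-bit ASCII character, got {c!r}")
    return [(ord(c) >> shift) & 1 for shift in range(7, -1, -1)]


def total_duration_ms(program: StimulusProgram) -> int:
    """Total transmission time: repeats · N_chars · (8·pulse + pause) ms."""
    per_char = 8 * program.pulse_ms + program.pause_ms
    return program.repeats * len(program.message) * per_char


def character_cycle_frequency(program: StimulusProgram) -> float:
    """Effective input frequency in Hz: one character per (8·pulse + pause)."""
    return 1000.0 / (8 * program.pulse_ms + program.pause_ms)


def stimulus_waveform(program: StimulusProgram, fs: float) -> TimeSeries:
    """Render the program as a piecewise-constant voltage series.

    Each character contributes eight bit slots of ``pulse_ms`` (v_high
    when the bit is 1) followed by one pause slot of ``pause_ms`` at
    v_low.  The sample count is ``total_duration_ms/1000 · fs``.
    """
    if fs <= 0:
        raise UsageError("fs must be positive")
    slots: list[tuple[float, float]] = []  # (level, duration_s)
    for _ in range(program.repeats):
        for ch in program.message:
            for bit in char_to_bits(ch):
                slots.append(
                    (program.v_high if bit else program.v_low, program.pulse_ms / 1000.0)
                )
            slots.append((program.v_low, program.pause_ms / 1000.0))

    total_s = total_duration_ms(program) / 1000.0
    n = int(round(total_s * fs))
    t = np.arange(n) / fs
    values = np.empty(n)
    edges = np.cumsum([0.0] + [d for _, d in slots])
    idx = np.searchsorted(edges, t, side="right") - 1
    levels = np.array([lv for lv, _ in slots])
    values = levels[np.clip(idx, 0, len(slots) - 1)]
    return TimeSeries(t, values, unit="V", label=f"stimulus {program.message!r}")


def decode_waveform(
    series: TimeSeries,
    pulse_ms: int = 10_000,
    pause_ms: int = 10_000,
    v_high: float = 5.0,
    v_low: float = 0.0,
) -> str:
    """Decode a slot-aligned stimulus waveform back to its text message.

    Each bit slot is decided by thresholding its mean level at
    (v_high + v_low)/2; a slot sitting exactly at the threshold is
    refused rather than guessed.

    Raises
    ------
    FormatError
        If the series length is not a whole number of character frames,
        or a slot level is exactly at the decision threshold.
    """
    fs = series.fs
    pulse_n = pulse_ms / 1000.0 * fs
    pause_n = pause_ms / 1000.0 * fs
    if abs(pulse_n - round(pulse_n)) > 1e-9 or abs(pause_n - round(pause_n)) > 1e-9:
        raise FormatError("slot durations are not whole numbers of samples")
    pulse_n, pause_n = int(round(pulse_n)), int(round(pause_n))
    frame = 8 * pulse_n + pause_n
    if series.n % frame != 0:
        raise FormatError(
            f"series length {series.n} is not a multiple of the "
            f"{frame}-sample character frame"
        )
    threshold = (v_high + v_low) / 2.0
    chars = []
    for start in range(0, series.n, frame):
        code = 0
        for b in range(8):
            slot = series.values[start + b * pulse_n : start + (b + 1) * pulse_n]
            level = float(np.mean(slot))
            if level == threshold:
                raise FormatError(
                    f"ambiguous slot level {level} V exactly at threshold"
                )
            code = (code << 1) | int(level > threshold)
        chars.append(chr(code))
    return "".join(chars)


def modulate_response(
    natural: TimeSeries, input_wave: TimeSeries, model: ModulationModel
) -> TimeSeries:
    """Amplitude-modulate the natural response by the input waveform.

    output(t) = natural(t) · [1 + k_mod · input(t)].  Both series must
    already share a time axis (use
    :func:`protodyn.signal_io.interpolate_common_axis` first).
    """
    if natural.n != input_wave.n or not np.allclose(
        natural.times, input_wave.times, rtol=1e-9
    ):
        raise UsageError("natural and input series must share a common time axis")
    out = natural.values * (1.0 + model.k_mod * input_wave.values)
    return natural.with_values(out, label=f"{natural.label} (modulated)")
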