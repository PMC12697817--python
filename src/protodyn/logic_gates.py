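"""Threshold Boolean-logic extraction from electrochemical features.

Analog features (square-wave-voltammetry peak currents at several pulse
frequencies, early/late mean capacitance) are binarized against a
high percentile threshold — value ≥ threshold → 1 — and fed to a
seven-gate panel over the resulting quintuple (A, B, C, D, E):
per-input NOT, AND, OR, NAND, NOR, a left-fold XOR chain
(((A≠B)≠(C≠D))≠E, equal to bit parity), and XNOR = ¬XOR ("even number
of true inputs").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UsageError

__all__ = ["GateInputs", "GateTable", "binarize", "gate_panel", "percentile_thresholds"]


@dataclass(frozen=True)
class GateInputs:
    """Ordered binary quintuple plus the thresholds that produced it."""

    states: tuple[int, int, int, int, int]
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.states) != 5 or any(s not in (0, 1) for s in self.states):
            raise UsageError("states must be a quintuple of 0/1")


@dataclass(frozen=True)
class GateTable:
    """Outputs of the seven-gate panel."""

    not_outputs: tuple[int, int, int, int, int]
    and_: int
    or_: int
    nand: int
    nor: int
    xor: int
    xnor: int


def percentile_thresholds(reference, hi_pct: float = 75.0, lo_pct: float = 25.0):
    """(hi, lo) linear-interpolation percentiles of a reference value list."""
    reference = np.asarray(reference, dtype=float)
    if len(reference) < 2:
        raise UsageError("need at least 2 reference values")
    hi, lo = np.percentile(reference, [hi_pct, lo_pct])
    return float(hi), float(lo)


def binarize(
    features: dict[str, float],
    thresholds: dict[str, tuple[float, float]],
    families: dict[str, str],
    order: list[str] | None = None,
) -> GateInputs:
    """Binarize named features against per-family (hi, lo) thresholds.

    A feature maps to state 1 iff its value ≥ the hi threshold of its
    family; the lo threshold is retained as provenance only (the rule is
    monotone: raising a value never flips 1 → 0).

    Parameters
    ----------
    features : feature name → analog value (exactly 5, order significant)
    thresholds : family name → (hi, lo) threshold pair
    families : feature name → family name (e.g. "current", "capacitance")
    order : explicit feature ordering for the (A..E) quintuple;
        defaults to the dict insertion order.
    """
    names = order if order is not None else list(features)
    if len(names) != 5:
        raise UsageError(f"gate panel needs exactly 5 features, got {len(names)}")
    states = []
    prov = {}
    for name in names:
        fam = families.get(name)
        if fam is None or fam not in thresholds:
            raise UsageError(f"no threshold family for feature {name!r}")
        hi, lo = thresholds[fam]
        if lo > hi:
            raise UsageError(f"family {fam!r}: lo threshold exceeds hi")
        state = int(features[name] >= hi)
        states.append(state)
        prov[name] = {"value": features[name], "family": fam, "hi": hi, "lo": lo}
    return GateInputs(states=tuple(states), provenance=prov)


def gate_panel(inputs: GateInputs) -> GateTable:
    """Evaluate the seven-gate panel on a binary quintuple.

    XOR is the left-fold chain (((A≠B)≠(C≠D))≠E — identically the
    parity of the input bits; XNOR is its negation.
    """
    a, b, c, d, e = inputs.states
    and_ = a & b & c & d & e
    or_ = max(inputs.states)
    xor = ((a ^ b) ^ (c ^ d)) ^ e
    return GateTable(
        not_outputs=tuple(1 - s for s in inputs.states),
        and_=and_,
        or_=or_,
        nand=1 - and_,
        nor=1 - or_,
        xor=xor,
        xnor=1 - xor,
    )
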