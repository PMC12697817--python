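"""Toroid morphometry: rim thickness and descriptive particle-size tables.

Particles are ring-shaped; each record carries an outer diameter, a
central-cavity diameter and optionally an aspect ratio (all from SEM
image measurement, which is upstream of this package).  Rim thickness is
(outer − cavity)/2, so outer = cavity + 2·rim holds per record.
Statistics are computed per record and then aggregated — the mean of
per-particle rims, not the rim of mean diameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UsageError
from .oscillation_stats import coefficient_of_variation

__all__ = ["ToroidRecord", "rim_thickness", "morphometry_table"]


@dataclass(frozen=True)
class ToroidRecord:
    """One measured toroidal particle (diameters in nm)."""

    outer_d: float
    cavity_d: float
    aspect: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.cavity_d < self.outer_d:
            raise UsageError(
                f"need 0 < cavity ({self.cavity_d}) < outer ({self.outer_d})"
            )


def rim_thickness(rec: ToroidRecord) -> float:
    """Rim thickness t = (D_outer − D_cavity)/2, nm."""
    return (rec.outer_d - rec.cavity_d) / 2.0


def morphometry_table(records: list[ToroidRecord]) -> pd.DataFrame:
    """Descriptive statistics per morphological parameter.

    Rows: outer diameter, cavity diameter, rim thickness, cavity/outer
    ratio and (when present) aspect ratio.  Columns: mean, sample SD,
    min, max, CV.
    """
    if len(records) < 2:
        raise UsageError("morphometry_table needs at least 2 records")
    cols = {
        "outer_nm": np.array([r.outer_d for r in records]),
        "cavity_nm": np.array([r.cavity_d for r in records]),
        "rim_nm": np.array([rim_thickness(r) for r in records]),
        "cavity_ratio": np.array([r.cavity_d / r.outer_d for r in records]),
    }
    aspects = [r.aspect for r in records if r.aspect is not None]
    if len(aspects) == len(records):
        cols["aspect"] = np.array(aspects)
    rows = []
    for name, v in cols.items():
        rows.append(
            {
                "parameter": name,
                "mean": v.mean(),
                "sd": v.std(ddof=1),
                "min": v.min(),
                "max": v.max(),
                "cv": coefficient_of_variation(v),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
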