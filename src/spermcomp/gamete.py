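"""Sperm quantification and competitive mixing designs.

Concentration is estimated from hemocytometer (Thoma chamber) counts:
cells counted in a known chamber volume, times the dilution factor, averaged
over replicate subsamples. Chamber geometry varies between instruments, so
the counting volume is an explicit input rather than a hard-coded grid
constant.

Total sperm production per male is approximated from the gonadosomatic index
(GSI, gonad mass / body mass): GSI x body mass gives gonad mass in grams,
converted to semen volume at a density of 1 g/mL, times the semen
concentration. Literature GSI defaults: 11.9% for the brook lamprey
(L. planeri, LP) and 4.64% for the river lamprey (L. fluviatilis, LF).

The two competitive mixing designs put two males' semen in one dish:

* ``equal_volume``: the same semen volume from each male (3 µL + 3 µL).
* ``equal_number``: volumes chosen so both males contribute the same sperm
  count within a fixed 6 µL total, i.e. v_LF * c_LF = v_LP * c_LP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GSI_LF",
    "GSI_LP",
    "ChamberCount",
    "MixDesign",
    "concentration",
    "total_sperm",
    "equal_number_volumes",
]

# literature gonadosomatic indices (fraction of body mass)
GSI_LF = 0.0464
GSI_LP = 0.119

UL_PER_ML = 1000.0


@dataclass(frozen=True)
class ChamberCount:
    """One replicate count in a counting chamber of known volume."""

    cells_counted: int
    chamber_volume_ul: float
    dilution_factor: float = 1.0
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.cells_counted < 0:
            raise ValueError("cells_counted must be >= 0")
        if not self.chamber_volume_ul > 0:
            raise ValueError("chamber_volume_ul must be > 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")


@dataclass(frozen=True)
class MixDesign:
    """Semen volumes (µL) of the two competing males in one dish."""

    experiment: str  # "equal_volume" | "equal_number"
    v_lf_ul: float
    v_lp_ul: float
    total_ul: float

    def __post_init__(self) -> None:
        if self.experiment not in ("equal_volume", "equal_number"):
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.v_lf_ul < 0 or self.v_lp_ul < 0:
            raise ValueError("volumes must be >= 0")
        if abs(self.v_lf_ul + self.v_lp_ul - self.total_ul) > 1e-9 * max(self.total_ul, 1.0):
            raise ValueError("volumes must sum to the total")


def concentration(counts: Iterable[ChamberCount] | Sequence[ChamberCount]) -> float:
    """Sperm concentration in sperm/mL, averaged over replicate chamber counts."""
    counts = list(counts)
    if not counts:
        raise ValueError("need at least one chamber count")
    per_ml = [
        c.cells_counted / c.chamber_volume_ul * c.dilution_factor * UL_PER_ML
        for c in counts
    ]
    return float(np.mean(per_ml))


def total_sperm(body_mass_g: float, gsi: float, conc_per_ml: float) -> float:
    """Estimated total sperm produced by a male.

    GSI x body mass gives gonad mass (g), taken as semen volume (mL) at unit
    density, multiplied by the semen concentration (sperm/mL).
    """
    if not 0 < gsi < 1:
        raise ValueError(f"gsi must lie strictly in (0, 1), got {gsi}")
    if not body_mass_g > 0:
        raise ValueError("body_mass_g must be > 0")
    if not conc_per_ml > 0:
        raise ValueError("conc_per_ml must be > 0")
    return gsi * body_mass_g * conc_per_ml


def equal_number_volumes(
    conc_lf: float, conc_lp: float, total_ul: float = 6.0
) -> MixDesign:
    """Volumes giving each male the same sperm count within a fixed total.

    Solves v_LF * c_LF = v_LP * c_LP with v_LF + v_LP = total, i.e.
    v_LF = total * c_LP / (c_LF + c_LP). Concentrations may be in any common
    unit (per µL or per mL); only their ratio matters.
    """
    if not (conc_lf > 0 and conc_lp > 0):
        raise ValueError("both concentrations must be > 0")
    if not total_ul > 0:
        raise ValueError("total_ul must be > 0")
    v_lf = total_ul * conc_lp / (conc_lf + conc_lp)
    return MixDesign("equal_number", v_lf_ul=v_lf, v_lp_ul=total_ul - v_lf, total_ul=total_ul)
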