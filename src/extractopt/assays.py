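"""Colorimetric assay arithmetic: rutin calibration, flavonoid yield, and
radical-scavenging percentages.

Total flavonoids are quantified by the NaNO2-Al(NO3)3-NaOH method against a
rutin standard curve (absorbance at 510 nm, linear in concentration).  The
yield chain converts the absorbance of a 200 uL extract aliquot developed in
a 10 mL reaction volume back to mg flavonoid per g of dry plant material.

Radical-scavenging activity (DPPH 520 nm, ABTS 730 nm, hydroxyl/salicylate
510 nm) uses the universal form

    scavenging % = (1 - (A_sample - A_background) / A_control) * 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "YieldParams",
    "ScavengingRecord",
    "fit_calibration",
    "flavonoid_yield",
    "scavenging_rate",
]


@dataclass
class CalibrationCurve:
    slope: float          # absorbance per mg/mL
    intercept: float
    r_squared: float
    standard: str = "rutin"


@dataclass
class YieldParams:
    """Volumes/masses of the extraction and assay workflow (mL and g)."""
    reaction_volume: float = 10.0
    aliquot_volume: float = 0.2
    extract_volume: float = 10.0
    sample_mass: float = 0.5
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("reaction_volume", "aliquot_volume", "extract_volume",
                     "sample_mass", "dilution_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class ScavengingRecord:
    a_sample: float
    a_control: float
    a_background: float = 0.0
    assay: str = "DPPH"
    concentration: float | None = None   # mg/mL

    def __post_init__(self) -> None:
        if self.a_control <= 0:
            raise ValueError("control absorbance must be > 0")
        if self.a_sample < 0 or self.a_background < 0:
            raise ValueError("absorbances must be nonnegative")


def fit_calibration(concentrations, absorbances,
                    standard: str = "rutin") -> CalibrationCurve:
    """OLS line absorbance = slope * concentration + intercept."""
    conc = np.asarray(concentrations, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if len(conc) < 3:
        raise ValueError("need >= 3 standards")
    if len(np.unique(conc)) < 2:
        raise ValueError("standards must span >= 2 distinct concentrations")
    res = stats.linregress(conc, a)
    if res.slope <= 0:
        raise ValueError("nonpositive slope: invalid colorimetric curve")
    return CalibrationCurve(float(res.slope), float(res.intercept),
                            float(res.rvalue ** 2), standard)


def flavonoid_yield(a510: float, curve: CalibrationCurve,
                    params: YieldParams) -> float:
    """Yield in mg/g dry material from the 510 nm absorbance of the assay mix.

    conc_in_reaction = (A - intercept)/slope; the aliquot dilution
    (reaction/aliquot volume, times any extra dilution) recovers the extract
    concentration, and extract_volume/sample_mass converts to per-gram yield.
    """
    conc_reaction = (a510 - curve.intercept) / curve.slope
    if conc_reaction < 0:
        warnings.warn("absorbance below calibration intercept: yield clamped to 0",
                      stacklevel=2)
        return 0.0
    conc_extract = (conc_reaction * params.reaction_volume / params.aliquot_volume
                    * params.dilution_factor)
    return conc_extract * params.extract_volume / params.sample_mass


def scavenging_rate(rec: ScavengingRecord) -> float:
    """Percent radical scavenging; at most 100 (complete quenching), negative
    values (pro-oxidant readings) pass through."""
    pct = (1.0 - (rec.a_sample - rec.a_background) / rec.a_control) * 100.0
    return min(pct, 100.0)
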