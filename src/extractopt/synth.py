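"""Synthetic data with known ground truth for every pipeline stage.

Raw measurements behind the published tables are not deposited, so each
stage's estimator is validated against data generated from the model it
assumes, at the parameter values the study reports:

* response surfaces default to the published quadratic coefficients
  (intercept 6.1889 mg/g, ethanol linear 0.2457, ...) with gaussian replicate
  noise, default sd 0.05 mg/g — the magnitude of the printed replicate SDs;
* screening responses are first-order with planted main effects on a
  Plackett-Burman layout;
* extraction time-courses come from the integrated second-order model,
  defaults Cs = 6.31 mg/g and k = 0.33 (the ultrasound-assisted estimates),
  with multiplicative noise (colorimetric error scales with concentration);
* assay absorbances invert the calibration/yield chain exactly, so a
  noiseless forward-then-estimate round trip is the identity.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assays import CalibrationCurve, YieldParams
from .designs import DesignMatrix, ResponseVector
from .kinetics import TimeCourse, _model as _second_order
from .rsm import QuadraticFit, quadratic_model_matrix

__all__ = [
    "SurfaceTruth",
    "KineticsTruth",
    "simulate_bbd_responses",
    "simulate_pbd_responses",
    "simulate_kinetics",
    "simulate_assays",
]

# published quadratic surface in coded units: intercept, linear, quad, cross
PUBLISHED_QUADRATIC_COEFFICIENTS = np.array([
    6.1889, 0.0699, 0.2457, 0.0097,
    -0.2391, -0.3280, -0.6114,
    0.0598, 0.0501, 0.0104,
])


@dataclass
class SurfaceTruth:
    coefficients: np.ndarray = field(
        default_factory=lambda: PUBLISHED_QUADRATIC_COEFFICIENTS.copy())
    noise_sd: float = 0.05      # mg/g, matches printed replicate SDs
    seed: int = 0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (10,):
            raise ValueError("need 10 coefficients (1 + 3 + 3 + 3)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def as_fit(self) -> QuadraticFit:
        """Wrap the true surface as a (residual-free) quadratic fit object."""
        b = self.coefficients
        empty = np.zeros(0)
        return QuadraticFit(float(b[0]), b[1:4].copy(), b[4:7].copy(),
                            b[7:10].copy(), 1.0, empty, empty)


@dataclass
class KineticsTruth:
    cs: float = 6.31            # mg/g
    k: float = 0.33             # g mg^-1 min^-1
    times: np.ndarray = field(
        default_factory=lambda: np.arange(5.0, 65.0, 5.0))
    noise_model: str = "multiplicative"
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.cs <= 0 or self.k <= 0:
            raise ValueError("cs and k must be > 0")
        if self.noise_model not in ("additive", "multiplicative"):
            raise ValueError("noise_model must be additive or multiplicative")


def simulate_bbd_responses(truth: SurfaceTruth,
                           design: DesignMatrix) -> ResponseVector:
    """Quadratic surface evaluated at the design points plus i.i.d. gaussian
    noise (centre replicates each get independent noise, so pure error > 0)."""
    if design.n_factors != 3:
        raise ValueError("surface truth is defined over 3 factors")
    mean = quadratic_model_matrix(design.runs) @ truth.coefficients
    rng = np.random.default_rng(truth.seed)
    y = mean + rng.normal(0.0, truth.noise_sd, size=len(mean))
    return ResponseVector(np.clip(y, 0.0, None))


def simulate_pbd_responses(effects: dict[str, float], design: DesignMatrix,
                           intercept: float = 5.07, noise_sd: float = 0.05,
                           seed: int = 0) -> ResponseVector:
    """First-order truth on a screening design; factors absent from
    ``effects`` (dummy columns) contribute nothing."""
    if design.design_kind != "pbd":
        raise ValueError("expected a Plackett-Burman design")
    unknown = set(effects) - set(design.factor_names)
    if unknown:
        raise ValueError(f"effects for unknown factors: {sorted(unknown)}")
    beta = np.array([effects.get(n, 0.0) for n in design.factor_names])
    mean = intercept + design.runs @ beta
    rng = np.random.default_rng(seed)
    y = mean + rng.normal(0.0, noise_sd, size=len(mean))
    return ResponseVector(np.clip(y, 0.0, None))


def simulate_kinetics(truth: KineticsTruth, label: str = "") -> TimeCourse:
    """Time-course from the integrated second-order model with additive or
    multiplicative gaussian noise, clamped to nonnegative concentrations."""
    c = _second_order(truth.times, truth.cs, truth.k)
    rng = np.random.default_rng(truth.seed)
    if truth.noise_sd > 0:
        eps = rng.normal(0.0, truth.noise_sd, size=len(c))
        c = c * (1.0 + eps) if truth.noise_model == "multiplicative" else c + eps
    return TimeCourse(truth.times, np.clip(c, 0.0, None), label=label)


def simulate_assays(yields: np.ndarray, curve: CalibrationCurve,
                    params: YieldParams | None = None,
                    scavenging_percents: dict[str, float] | None = None,
                    control_absorbance: float = 0.8,
                    noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Forward-model assay absorbances from planted yields and scavenging
    percentages; the noiseless output inverts exactly through the assay
    estimators.  Returns rows ``assay, concentration_mg_per_ml, a_sample,
    a_control, a_background, true_value``."""
    params = params or YieldParams()
    rng = np.random.default_rng(seed)
    rows = []
    for yld in np.atleast_1d(np.asarray(yields, dtype=float)):
        conc_extract = yld * params.sample_mass / params.extract_volume
        conc_reaction = (conc_extract / params.dilution_factor
                         * params.aliquot_volume / params.reaction_volume)
        a = curve.intercept + curve.slope * conc_reaction
        rows.append({"assay": "flavonoid_yield", "concentration_mg_per_ml": np.nan,
                     "a_sample": a + rng.normal(0, noise_sd) if noise_sd else a,
                     "a_control": np.nan, "a_background": 0.0,
                     "true_value": yld})
    for assay, pct in (scavenging_percents or {}).items():
        a_sample = control_absorbance * (1.0 - pct / 100.0)
        if noise_sd:
            a_sample += rng.normal(0, noise_sd)
        rows.append({"assay": assay, "concentration_mg_per_ml": 5.0,
                     "a_sample": max(a_sample, 0.0),
                     "a_control": control_absorbance, "a_background": 0.0,
                     "true_value": pct})
    return pd.DataFrame(rows)
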