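"""Two- and three-level experimental designs and coded/actual factor transforms.

Screening uses the 12-run Plackett-Burman design (PBD): an orthogonal
two-level array in which each column is balanced between -1 and +1, so main
effects are estimated independently.  Response-surface work uses the
three-factor Box-Behnken design (BBD): the 12 edge midpoints of the coded
cube plus replicated centre points, which supports a full quadratic model
without corner runs.

Factors live on a coded scale; the affine map ``actual = center + step * coded``
converts between coded and physical units (e.g. temperature in degrees C).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignMatrix",
    "ResponseVector",
    "plackett_burman_design",
    "box_behnken_design",
    "decode_levels",
    "code_levels",
    "bbd_factors",
]

# First row of the standard cyclic 12-run Plackett-Burman generator; rows
# 2..11 are successive right cyclic shifts and row 12 is all -1.
_PB12_GENERATOR = np.array([1, 1, -1, 1, 1, 1, -1, -1, -1, 1, -1], dtype=float)


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor.

    ``role='dummy'`` marks an unassigned (virtual) screening column used only
    to estimate error; dummy factors carry no physical center/step.
    """

    name: str
    role: Literal["real", "dummy"] = "real"
    center: float | None = None
    step: float | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.role == "dummy":
            if self.center is not None or self.step is not None:
                raise ValueError(f"dummy factor {self.name!r} is coded-only")
        elif self.step is not None and self.step <= 0:
            raise ValueError(f"factor {self.name!r}: step must be > 0")


@dataclass
class DesignMatrix:
    """Coded design: rows are runs, columns are factors."""

    factors: list[FactorSpec]
    runs: np.ndarray
    design_kind: Literal["pbd", "bbd", "custom"] = "custom"

    def __post_init__(self) -> None:
        self.runs = np.asarray(self.runs, dtype=float)
        if self.runs.ndim != 2 or self.runs.shape[1] != len(self.factors):
            raise ValueError(
                f"runs must be (n_runs, {len(self.factors)}); got {self.runs.shape}"
            )

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.runs, columns=self.factor_names,
                            index=pd.RangeIndex(1, self.n_runs + 1, name="run"))


@dataclass
class ResponseVector:
    """Measured responses (mg/g flavonoid yield), one per run."""

    values: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if np.any(self.values < 0):
            raise ValueError("yields must be nonnegative")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.values.shape or np.any(self.sd < 0):
                raise ValueError("sd must be nonnegative and match values")

    def __len__(self) -> int:
        return len(self.values)


def plackett_burman_design(n_factors: int,
                           factors: Sequence[FactorSpec] | None = None) -> DesignMatrix:
    """Standard cyclic 12-run Plackett-Burman design for up to 11 factors.

    Every column is balanced (six +1, six -1) and any two columns are
    orthogonal, so each main effect is estimated free of the others.
    """
    if not 1 <= n_factors <= 11:
        raise ValueError(
            f"n_factors must be in 1..11 for the 12-run Plackett-Burman design; "
            f"got {n_factors}"
        )
    rows = [np.roll(_PB12_GENERATOR, i) for i in range(11)]
    rows.append(-np.ones(11))
    full = np.array(rows)
    if factors is None:
        factors = [FactorSpec(f"X{i + 1}", role="dummy") for i in range(n_factors)]
    else:
        factors = list(factors)
        if len(factors) != n_factors:
            raise ValueError("len(factors) must equal n_factors")
    return DesignMatrix(factors, full[:, :n_factors], design_kind="pbd")


def bbd_factors() -> list[FactorSpec]:
    """The three ultrasound-extraction factors at their experimental ranges:
    temperature 50-70 degC, ethanol 40-80 %, ultrasonic power 200-250 W."""
    return [
        FactorSpec("X1", center=60.0, step=10.0, units="degC"),
        FactorSpec("X2", center=60.0, step=20.0, units="%"),
        FactorSpec("X3", center=225.0, step=25.0, units="W"),
    ]


def box_behnken_design(n_center: int = 3,
                       factors: Sequence[FactorSpec] | None = None) -> DesignMatrix:
    """Three-factor Box-Behnken design: 12 edge runs plus ``n_center`` centre
    replicates (the centre replicates supply the pure-error estimate)."""
    if n_center < 1:
        raise ValueError("n_center must be >= 1")
    factors = bbd_factors() if factors is None else list(factors)
    if len(factors) != 3:
        raise ValueError("only the 3-factor Box-Behnken design is supported")
    edges = []
    for (i, j) in combinations(range(3), 2):
        for a in (-1.0, 1.0):
            for b in (-1.0, 1.0):
                row = [0.0, 0.0, 0.0]
                row[i], row[j] = a, b
                edges.append(row)
    runs = np.vstack([np.array(edges), np.zeros((n_center, 3))])
    return DesignMatrix(factors, runs, design_kind="bbd")


def _real_centers_steps(design: DesignMatrix) -> tuple[np.ndarray, np.ndarray]:
    centers, steps = [], []
    for f in design.factors:
        if f.role != "real" or f.center is None or f.step is None:
            raise ValueError(
                f"factor {f.name!r} has no physical scale (dummy or unset center/step)"
            )
        centers.append(f.center)
        steps.append(f.step)
    return np.array(centers), np.array(steps)


def decode_levels(design: DesignMatrix, point: Sequence[float]) -> np.ndarray:
    """Coded -> actual units: ``actual_i = center_i + step_i * coded_i``.

    Coded values outside [-1, 1] are allowed (optimizers may return fractional
    codes slightly outside the fitted box) but draw a warning.
    """
    point = np.asarray(point, dtype=float)
    centers, steps = _real_centers_steps(design)
    if point.shape != centers.shape:
        raise ValueError("point length must match factor count")
    if np.any(np.abs(point) > 1.0 + 1e-12):
        warnings.warn("coded point outside [-1, 1]: extrapolating beyond the design box",
                      stacklevel=2)
    return centers + steps * point


def code_levels(design: DesignMatrix, actual: Sequence[float]) -> np.ndarray:
    """Inverse of :func:`decode_levels`."""
    actual = np.asarray(actual, dtype=float)
    centers, steps = _real_centers_steps(design)
    if actual.shape != centers.shape:
        raise ValueError("point length must match factor count")
    return (actual - centers) / steps
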