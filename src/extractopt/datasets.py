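"""Bundled experiment tables for the walnut-bark flavonoid extraction study.

Two small CSV fixtures ship with the package:

* ``table1_pbd`` — the 12-run, 8-column Plackett-Burman screening layout with
  mean yields and replicate SDs.  Note: refitting this printed matrix does not
  reproduce the first-order equation reported alongside it in the source study
  (the printed grand mean is 5.0692 against a reported intercept of 5.0680 and
  the leading coefficient refits to roughly 0.26 against a reported 0.6033);
  the printed matrix and equation are mutually inconsistent, so screening
  correctness is established on synthetic-recovery tests instead.
* ``table2_bbd`` — the 15-run, 3-factor Box-Behnken layout (temperature,
  ethanol concentration, ultrasonic power) with mean yields and SDs.  This one
  does refit to the published quadratic model within rounding tolerance.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .designs import DesignMatrix, FactorSpec, ResponseVector, bbd_factors

__all__ = ["load_table1_pbd", "load_table2_bbd", "read_design_csv", "write_design_csv"]


def _fixture(name: str) -> pd.DataFrame:
    with resources.files("extractopt.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def read_design_csv(path: str | Path,
                    factors: list[FactorSpec] | None = None,
                    design_kind: str = "custom") -> tuple[DesignMatrix, ResponseVector | None]:
    """Read a ``run,<factors...>[,Y[,Y_sd]]`` CSV into a design and responses."""
    df = pd.read_csv(path)
    return _from_frame(df, factors, design_kind)


def _from_frame(df, factors, design_kind):
    cols = [c for c in df.columns if c not in ("run", "Y", "Y_sd")]
    if factors is None:
        factors = [FactorSpec(c, role="dummy") for c in cols]
    elif [f.name for f in factors] != cols:
        raise ValueError(f"factor names {[f.name for f in factors]} != CSV columns {cols}")
    design = DesignMatrix(factors, df[cols].to_numpy(float), design_kind=design_kind)
    y = None
    if "Y" in df.columns:
        sd = df["Y_sd"].to_numpy(float) if "Y_sd" in df.columns else None
        y = ResponseVector(df["Y"].to_numpy(float), sd=sd)
    return design, y


def write_design_csv(path: str | Path, design: DesignMatrix,
                     y: ResponseVector | None = None) -> None:
    df = design.to_frame().reset_index()
    if y is not None:
        df["Y"] = np.asarray(y.values)
        if y.sd is not None:
            df["Y_sd"] = np.asarray(y.sd)
    df.to_csv(path, index=False)


def load_table1_pbd() -> tuple[DesignMatrix, ResponseVector]:
    """The printed 12x8 screening matrix and mean yields (verbatim)."""
    design, y = _from_frame(_fixture("table1_pbd.csv"), None, "pbd")
    assert y is not None
    return design, y


def load_table2_bbd() -> tuple[DesignMatrix, ResponseVector]:
    """The printed 15-run Box-Behnken matrix and mean yields (verbatim)."""
    design, y = _from_frame(_fixture("table2_bbd.csv"), bbd_factors(), "bbd")
    assert y is not None
    return design, y
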