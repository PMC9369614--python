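"""First-order screening analysis of Plackett-Burman experiments.

The screening model is ``Y = b0 + sum_i b_i X_i`` over the coded +/-1 columns.
On an orthogonal two-level design each coefficient is half the difference
between the mean response at +1 and at -1, and the intercept is the grand
mean.  Factor importance is ranked by the standardized effect |t| =
|coefficient| / SE(coefficient) (the Pareto-chart convention), and a factor
is called significant when its standardized effect exceeds the two-sided
t critical value at level alpha on the residual degrees of freedom — the
"red line" of a Pareto chart.  Unassigned (dummy) columns fold into the
residual and provide the error estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .designs import DesignMatrix, ResponseVector

__all__ = ["ScreeningFit", "fit_first_order", "pareto_effects"]


@dataclass
class ScreeningFit:
    intercept: float
    coefficients: dict[str, float]
    standardized_effects: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    residual_df: int
    threshold: float
    alpha: float = 0.05


def fit_first_order(design: DesignMatrix, y: ResponseVector,
                    alpha: float = 0.05) -> ScreeningFit:
    """Ordinary least squares of the responses on the coded +/-1 columns."""
    values = np.asarray(y.values, dtype=float)
    if len(values) != design.n_runs:
        raise ValueError(
            f"{len(values)} responses for {design.n_runs} runs"
        )
    if design.n_runs <= design.n_factors + 1:
        raise ValueError("need more runs than factors + 1 for a residual estimate")
    X = sm.add_constant(design.runs)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix: columns are linearly dependent")
    res = sm.OLS(values, X).fit()
    names = design.factor_names
    residual_df = int(res.df_resid)
    threshold = float(stats.t.ppf(1 - alpha / 2, residual_df))
    return ScreeningFit(
        intercept=float(res.params[0]),
        coefficients={n: float(b) for n, b in zip(names, res.params[1:])},
        standardized_effects={n: float(abs(t)) for n, t in zip(names, res.tvalues[1:])},
        p_values={n: float(p) for n, p in zip(names, res.pvalues[1:])},
        r_squared=float(res.rsquared),
        residual_df=residual_df,
        threshold=threshold,
        alpha=alpha,
    )


def pareto_effects(fit: ScreeningFit,
                   alpha: float | None = None) -> list[tuple[str, float, bool]]:
    """Factors ranked by decreasing standardized effect, flagged significant
    when the effect exceeds the t critical value at ``alpha``."""
    if fit.residual_df < 1:
        raise ValueError(
            "no residual degrees of freedom: include dummy columns to estimate error"
        )
    if alpha is None:
        alpha = fit.alpha
        threshold = fit.threshold
    else:
        threshold = float(stats.t.ppf(1 - alpha / 2, fit.residual_df))
    ranked = sorted(fit.standardized_effects.items(), key=lambda kv: -kv[1])
    return [(name, eff, eff > threshold) for name, eff in ranked]
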