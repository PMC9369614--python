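"""Quadratic response-surface fitting, ANOVA decomposition, and diagnostics.

The model over three coded factors is the full 10-term quadratic

    Y = b0 + b1 x1 + b2 x2 + b3 x3
        + b11 x1^2 + b22 x2^2 + b33 x3^2
        + b12 x1 x2 + b13 x1 x3 + b23 x2 x3

fitted by ordinary least squares in coded units.  The ANOVA follows the
convention of classical RSM software: per-term sums of squares are partial
(drop-one) SS, while the linear / quadratic / cross-product group SS are
drop-group partial SS.  At Box-Behnken points the linear and cross columns
are mutually orthogonal, so the three group SS partition the model SS exactly
— but the per-term quadratic SS do *not* sum to the quadratic group SS,
because the pure-quadratic columns are correlated with the intercept and with
each other.  Both behaviours are intentional and tested.

Pure error comes from replicated runs (the centre replicates in a BBD); the
residual splits into lack-of-fit and pure error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.stats.outliers_influence import OLSInfluence

from .designs import DesignMatrix, ResponseVector

__all__ = [
    "QuadraticFit",
    "Diagnostics",
    "quadratic_model_matrix",
    "fit_quadratic",
    "anova_decompose",
    "studentized_diagnostics",
    "polynomial_optimum",
]

TERM_NAMES = ["X1", "X2", "X3", "X1^2", "X2^2", "X3^2", "X1*X2", "X1*X3", "X2*X3"]
_LINEAR, _QUAD, _CROSS = [0, 1, 2], [3, 4, 5], [6, 7, 8]


def quadratic_model_matrix(points: np.ndarray) -> np.ndarray:
    """Full quadratic model matrix: intercept, 3 linear, 3 pure-quadratic,
    3 cross-product columns (pairs 12, 13, 23)."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    x1, x2, x3 = p[:, 0], p[:, 1], p[:, 2]
    return np.column_stack([
        np.ones(len(p)), x1, x2, x3,
        x1 * x1, x2 * x2, x3 * x3,
        x1 * x2, x1 * x3, x2 * x3,
    ])


@dataclass
class QuadraticFit:
    intercept: float
    linear: np.ndarray        # (b1, b2, b3)
    quad: np.ndarray          # (b11, b22, b33)
    cross: np.ndarray         # (b12, b13, b23)
    r_squared: float
    fitted: np.ndarray
    residuals: np.ndarray

    @property
    def coefficients(self) -> np.ndarray:
        """All 10 coefficients in model-matrix column order."""
        return np.concatenate([[self.intercept], self.linear, self.quad, self.cross])

    def predict(self, points: np.ndarray) -> np.ndarray:
        return quadratic_model_matrix(points) @ self.coefficients


@dataclass
class Diagnostics:
    studentized_residuals: np.ndarray
    normal_quantile_pairs: np.ndarray   # (expected, observed) rows
    outlier_flags: np.ndarray


def fit_quadratic(design: DesignMatrix, y: ResponseVector) -> QuadraticFit:
    """Least-squares fit of the 10-term quadratic polynomial in coded units."""
    if design.n_factors != 3:
        raise ValueError("quadratic response surface requires exactly 3 factors")
    values = np.asarray(y.values, dtype=float)
    if len(values) != design.n_runs:
        raise ValueError(f"{len(values)} responses for {design.n_runs} runs")
    X = quadratic_model_matrix(design.runs)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "rank-deficient model matrix: need >= 10 distinct support points"
        )
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    fitted = X @ beta
    residuals = values - fitted
    ss_tot = float(np.sum((values - values.mean()) ** 2))
    ss_err = float(np.sum(residuals ** 2))
    r2 = 1.0 - ss_err / ss_tot if ss_tot > 0 else 1.0
    return QuadraticFit(
        intercept=float(beta[0]),
        linear=beta[1:4].copy(),
        quad=beta[4:7].copy(),
        cross=beta[7:10].copy(),
        r_squared=r2,
        fitted=fitted,
        residuals=residuals,
    )


def _sse(X: np.ndarray, y: np.ndarray, cols: list[int]) -> float:
    b, *_ = np.linalg.lstsq(X[:, cols], y, rcond=None)
    return float(np.sum((y - X[:, cols] @ b) ** 2))


def _pure_error(design: DesignMatrix, values: np.ndarray) -> tuple[float, int]:
    """Pure-error SS and df from exactly replicated coded runs."""
    df_pe, ss_pe = 0, 0.0
    groups: dict[tuple, list[float]] = {}
    for row, v in zip(design.runs, values):
        groups.setdefault(tuple(np.round(row, 12)), []).append(v)
    for vals in groups.values():
        if len(vals) > 1:
            arr = np.asarray(vals)
            ss_pe += float(np.sum((arr - arr.mean()) ** 2))
            df_pe += len(arr) - 1
    return ss_pe, df_pe


def anova_decompose(fit: QuadraticFit, design: DesignMatrix,
                    y: ResponseVector) -> pd.DataFrame:
    """ANOVA table with per-term, group, model, error, lack-of-fit, pure-error
    and total rows (columns: source, df, SS, MS, F, p)."""
    values = np.asarray(y.values, dtype=float)
    X = quadratic_model_matrix(design.runs)
    n, p = X.shape
    ss_err = float(np.sum(fit.residuals ** 2))
    ss_tot = float(np.sum((values - values.mean()) ** 2))
    ss_model = ss_tot - ss_err
    df_model, df_err = p - 1, n - p
    ms_err = ss_err / df_err if df_err > 0 else np.nan

    rows = []

    def add(source, df, ss, with_f=True, denom_ms=ms_err, denom_df=df_err):
        ms = ss / df if df > 0 else np.nan
        if with_f and df > 0 and denom_ms and np.isfinite(denom_ms) and denom_ms > 0:
            F = ms / denom_ms
            pval = float(stats.f.sf(F, df, denom_df))
        else:
            F, pval = np.nan, np.nan
        rows.append({"source": source, "df": df, "SS": ss, "MS": ms, "F": F, "p": pval})

    # per-term drop-one partial SS
    for k, name in enumerate(TERM_NAMES):
        cols = [c for c in range(p) if c != k + 1]
        add(name, 1, _sse(X, values, cols) - ss_err)

    add("Model", df_model, ss_model)

    # drop-group partial SS; these partition SS(model) at BBD points
    for label, idx in (("Linear", _LINEAR), ("Quadratic", _QUAD),
                       ("Cross-product", _CROSS)):
        cols = [0] + [c for c in range(1, p) if (c - 1) not in idx]
        add(label, len(idx), _sse(X, values, cols) - ss_err)

    add("Error", df_err, ss_err, with_f=False)

    ss_pe, df_pe = _pure_error(design, values)
    if df_pe > 0:
        ss_lof, df_lof = ss_err - ss_pe, df_err - df_pe
        ms_pe = ss_pe / df_pe
        add("Lack of fit", df_lof, ss_lof, denom_ms=ms_pe, denom_df=df_pe)
        add("Pure error", df_pe, ss_pe, with_f=False)
    add("Total", n - 1, ss_tot, with_f=False)
    return pd.DataFrame(rows)


def studentized_diagnostics(fit: QuadraticFit, design: DesignMatrix,
                            y: ResponseVector,
                            flag_at: float | None = None) -> Diagnostics:
    """Internally studentized residuals r_i / (s sqrt(1 - h_ii)) for the
    normal-probability plot, with outlier flags from the externally
    (deletion) studentized residuals.

    Flagging uses the deletion form because the internal form is bounded by
    sqrt(n - p): with 15 runs and 10 model terms it can never exceed 2.24,
    so a gross outlier would be mathematically invisible at any threshold of
    3 or more.  The default flag limit is the Bonferroni-corrected two-sided
    t critical value t(0.05 / 2n, n - p - 1) — the "red boundary" convention
    of RSM software — so a well-behaved fit shows no flags while a grossly
    corrupted run is caught.  Saturated points (h_ii = 1) come back NaN and
    are never flagged.
    """
    values = np.asarray(y.values, dtype=float)
    X = quadratic_model_matrix(design.runs)
    n, p = X.shape
    res = sm.OLS(values, X).fit()
    infl = OLSInfluence(res)
    lev = infl.hat_matrix_diag
    ok = lev < 1 - 1e-10
    with np.errstate(divide="ignore", invalid="ignore"):
        stud = np.where(ok, infl.resid_studentized_internal, np.nan)
        ext = np.where(ok, infl.resid_studentized_external, np.nan)
    m = np.isfinite(stud)
    expected = stats.norm.ppf((np.arange(1, m.sum() + 1) - 0.375) / (m.sum() + 0.25))
    pairs = np.column_stack([expected, np.sort(stud[m])])
    if flag_at is None:
        flag_at = float(stats.t.ppf(1 - 0.05 / (2 * n), max(n - p - 1, 1)))
    flags = np.abs(np.nan_to_num(ext)) > flag_at
    return Diagnostics(stud, pairs, flags)


def polynomial_optimum(fit: QuadraticFit,
                       box: tuple[float, float] | np.ndarray = (-1.0, 1.0)
                       ) -> tuple[np.ndarray, float]:
    """Maximize the fitted quadratic over the coded box.

    Solves the stationary point analytically and polishes with bounded
    quasi-Newton restarts from a coarse lattice, so boundary maxima of
    indefinite surfaces are found too.
    """
    bounds = np.asarray(box, dtype=float)
    if bounds.ndim == 1:
        bounds = np.tile(bounds, (3, 1))
    b = fit.coefficients
    # gradient: g + 2 H x with H holding quad on the diagonal, cross/2 off it
    H = np.array([
        [2 * b[4], b[7], b[8]],
        [b[7], 2 * b[5], b[9]],
        [b[8], b[9], 2 * b[6]],
    ])
    g = b[1:4]
    starts = [np.zeros(3)]
    try:
        stat = np.linalg.solve(H, -g)
        starts.append(np.clip(stat, bounds[:, 0], bounds[:, 1]))
    except np.linalg.LinAlgError:
        pass
    mesh = np.meshgrid(*[np.linspace(lo, hi, 3) for lo, hi in bounds], indexing="ij")
    starts.extend(np.column_stack([m.ravel() for m in mesh]))

    def neg(x):
        return -float(fit.predict(x[None, :])[0])

    best_x, best_v = None, np.inf
    for s in starts:
        r = optimize.minimize(neg, s, method="L-BFGS-B",
                              bounds=list(map(tuple, bounds)))
        if r.fun < best_v:
            best_x, best_v = r.x, r.fun
    return np.clip(best_x, bounds[:, 0], bounds[:, 1]), -best_v
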