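"""Quadratic response-surface fit, ANOVA structure, diagnostics, optimum."""

import numpy as np
import pytest

from extractopt.designs import ResponseVector, box_behnken_design
from extractopt.rsm import (
    anova_decompose,
    fit_quadratic,
    polynomial_optimum,
    quadratic_model_matrix,
    studentized_diagnostics,
)
from extractopt.synth import PUBLISHED_QUADRATIC_COEFFICIENTS, SurfaceTruth, simulate_bbd_responses

from conftest import grid_argmax


def row(anova, source):
    return anova.set_index("source").loc[source]


class TestFitQuadratic:
    def test_refit_of_published_table_matches_published_model(self, table2):
        design, y = table2
        fit = fit_quadratic(design, y)
        assert fit.intercept == pytest.approx(6.1889, abs=0.005)
        assert fit.linear[1] == pytest.approx(0.2457, abs=0.005)  # ethanol
        assert fit.r_squared == pytest.approx(0.9751, abs=0.005)

    def test_noiseless_surface_recovered_exactly(self):
        design = box_behnken_design(n_center=3)
        y = simulate_bbd_responses(SurfaceTruth(noise_sd=0.0), design)
        fit = fit_quadratic(design, y)
        assert np.max(np.abs(fit.coefficients - PUBLISHED_QUADRATIC_COEFFICIENTS)) <= 1e-10
        assert np.max(np.abs(fit.residuals)) <= 1e-10

    def test_fitted_plus_residuals_reconstruct_observations(self, table2):
        design, y = table2
        fit = fit_quadratic(design, y)
        assert np.allclose(fit.fitted + fit.residuals, y.values, atol=1e-12)

    def test_rank_deficient_support_rejected(self):
        design = box_behnken_design(n_center=3)
        from extractopt.designs import DesignMatrix
        flat = DesignMatrix(design.factors, np.zeros((15, 3)), "custom")
        with pytest.raises(ValueError, match="rank"):
            fit_quadratic(flat, ResponseVector(np.ones(15)))


@pytest.fixture(scope="module")
def anova_published(table2):
    design, y = table2
    fit = fit_quadratic(design, y)
    return anova_decompose(fit, design, y)


class TestAnova:

    def test_group_ss_partition_model_ss(self, anova_published):
        a = anova_published
        groups = sum(row(a, g)["SS"] for g in ("Linear", "Quadratic", "Cross-product"))
        assert groups == pytest.approx(row(a, "Model")["SS"], abs=1e-9)

    def test_model_plus_error_is_total(self, anova_published):
        a = anova_published
        assert row(a, "Model")["SS"] + row(a, "Error")["SS"] == pytest.approx(
            row(a, "Total")["SS"], abs=1e-9)
        assert row(a, "Model")["df"] + row(a, "Error")["df"] == row(a, "Total")["df"]

    def test_error_splits_into_lack_of_fit_and_pure_error(self, anova_published):
        a = anova_published
        assert row(a, "Lack of fit")["SS"] + row(a, "Pure error")["SS"] == \
            pytest.approx(row(a, "Error")["SS"], abs=1e-9)
        assert row(a, "Pure error")["df"] == 2

    def test_published_table_reproduced_within_rounding(self, anova_published):
        """The printed ANOVA used unrounded responses; refitting the 2-decimal
        means reproduces it within a few percent."""
        a = anova_published
        assert row(a, "X2")["SS"] == pytest.approx(0.4831, rel=0.02)
        assert row(a, "Error")["SS"] == pytest.approx(0.0596, rel=0.10)
        assert row(a, "Model")["F"] == pytest.approx(21.7385, rel=0.10)
        assert row(a, "Pure error")["SS"] == pytest.approx(0.0042, abs=1e-9)

    def test_linear_and_cross_terms_sum_to_group_but_quadratic_does_not(
            self, anova_published):
        """Linear and cross columns are orthogonal at BBD points so their
        partial SS add up to the group SS; the correlated pure-quadratic
        columns violate that additivity — as in the published table."""
        a = anova_published
        lin = sum(row(a, t)["SS"] for t in ("X1", "X2", "X3"))
        cross = sum(row(a, t)["SS"] for t in ("X1*X2", "X1*X3", "X2*X3"))
        quad = sum(row(a, t)["SS"] for t in ("X1^2", "X2^2", "X3^2"))
        assert lin == pytest.approx(row(a, "Linear")["SS"], abs=1e-9)
        assert cross == pytest.approx(row(a, "Cross-product")["SS"], abs=1e-9)
        assert abs(quad - row(a, "Quadratic")["SS"]) > 0.1

    def test_orthogonal_term_ss_equal_coef_squared_times_column_ss(self, table2):
        design, y = table2
        fit = fit_quadratic(design, y)
        a = anova_decompose(fit, design, y)
        X = quadratic_model_matrix(design.runs)
        for j, term in [(1, "X1"), (2, "X2"), (3, "X3"),
                        (7, "X1*X2"), (8, "X1*X3"), (9, "X2*X3")]:
            expected = fit.coefficients[j] ** 2 * np.sum(X[:, j] ** 2)
            assert row(a, term)["SS"] == pytest.approx(expected, abs=1e-9)

    def test_no_replicates_omits_pure_error_rows(self):
        design = box_behnken_design(n_center=1)
        y = simulate_bbd_responses(SurfaceTruth(noise_sd=0.05, seed=3), design)
        a = anova_decompose(fit_quadratic(design, y), design, y)
        assert "Pure error" not in set(a["source"])
        assert "Lack of fit" not in set(a["source"])

    def test_additivity_invariants_on_random_noisy_fits(self):
        design = box_behnken_design(n_center=3)
        for seed in range(5):
            y = simulate_bbd_responses(SurfaceTruth(noise_sd=0.1, seed=seed), design)
            a = anova_decompose(fit_quadratic(design, y), design, y)
            groups = sum(row(a, g)["SS"]
                         for g in ("Linear", "Quadratic", "Cross-product"))
            assert groups == pytest.approx(row(a, "Model")["SS"], abs=1e-9)
            assert (a["SS"] >= -1e-12).all()


class TestDiagnostics:
    def test_published_fit_has_no_outliers(self, table2):
        design, y = table2
        fit = fit_quadratic(design, y)
        diag = studentized_diagnostics(fit, design, y)
        assert diag.outlier_flags.sum() == 0
        assert len(diag.studentized_residuals) == 15

    def test_noiseless_fit_has_zero_residuals(self):
        design = box_behnken_design(n_center=3)
        y = simulate_bbd_responses(SurfaceTruth(noise_sd=0.0), design)
        fit = fit_quadratic(design, y)
        assert np.nanmax(np.abs(fit.residuals)) <= 1e-10

    def test_corrupted_run_is_flagged(self):
        design = box_behnken_design(n_center=3)
        y = simulate_bbd_responses(SurfaceTruth(noise_sd=0.02, seed=11), design)
        vals = y.values.copy()
        vals[4] += 1.0                       # +1 mg/g on run 5
        bad = ResponseVector(vals)
        fit = fit_quadratic(design, bad)
        diag = studentized_diagnostics(fit, design, bad)
        # the corrupted run is flagged; its opposite edge run may be dragged
        # past the threshold too because deleting either one frees the fit
        assert diag.outlier_flags[4]
        assert diag.outlier_flags.sum() <= 2
        assert not diag.outlier_flags[[0, 1, 2, 3, 5, 6, 8, 9, 10, 11]].any()


class TestPolynomialOptimum:
    def test_published_surface_optimum(self):
        fit = SurfaceTruth(noise_sd=0.0).as_fit()
        point, value = polynomial_optimum(fit)
        assert np.allclose(point, [0.20, 0.39, 0.02], atol=0.01)
        assert value == pytest.approx(6.244, abs=1e-3)

    def test_concave_bowl_and_monotone_edge_cases(self):
        from extractopt.rsm import QuadraticFit
        e = np.zeros(0)
        bowl = QuadraticFit(2.0, np.zeros(3), -np.ones(3), np.zeros(3), 1.0, e, e)
        p, v = polynomial_optimum(bowl)
        assert np.allclose(p, 0, atol=1e-6) and v == pytest.approx(2.0)
        ramp = QuadraticFit(0.0, np.ones(3), np.zeros(3), np.zeros(3), 1.0, e, e)
        p, v = polynomial_optimum(ramp)
        assert np.allclose(p, 1.0, atol=1e-6) and v == pytest.approx(3.0)

    def test_agrees_with_grid_brute_force_on_random_quadratics(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            coeffs = np.concatenate([
                [rng.normal(5, 1)], rng.normal(0, 0.3, 3),
                rng.normal(-0.3, 0.3, 3), rng.normal(0, 0.1, 3)])
            from extractopt.rsm import QuadraticFit
            e = np.zeros(0)
            fit = QuadraticFit(coeffs[0], coeffs[1:4], coeffs[4:7],
                               coeffs[7:10], 1.0, e, e)
            p, v = polynomial_optimum(fit)
            gp, gv = grid_argmax(coeffs)
            assert abs(v - gv) <= 1e-6
            assert np.max(np.abs(p - gp)) <= 1e-3 + 1e-9
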