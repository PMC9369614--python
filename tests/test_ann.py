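"""Surrogate network: data split, LM training, degree of approximation."""

import numpy as np
import pytest

from extractopt.ann import (
    DaScore,
    TrainConfig,
    degree_of_approximation,
    select_hidden_nodes,
    split_data,
    train_network,
)
from extractopt.designs import ResponseVector, box_behnken_design


class TestSplitData:
    @pytest.mark.parametrize("n,sizes", [(15, (11, 2, 2)), (20, (14, 3, 3))])
    def test_largest_remainder_sizes(self, n, sizes):
        s = split_data(n, seed=1)
        assert (len(s.train), len(s.validation), len(s.test)) == sizes
        assert sorted(np.concatenate([s.train, s.validation, s.test])) == list(range(n))

    def test_deterministic_under_seed(self):
        a, b = split_data(15, seed=5), split_data(15, seed=5)
        assert np.array_equal(a.train, b.train)
        assert np.array_equal(a.validation, b.validation)
        c = split_data(15, seed=6)
        assert not np.array_equal(a.train, c.train)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="size 0"):
            split_data(5, (0.9, 0.05, 0.05), seed=0)
        with pytest.raises(ValueError, match="sum to 1"):
            split_data(15, (0.5, 0.2, 0.2), seed=0)


class TestTrainNetwork:
    def test_affine_target_learned_to_numerical_tolerance(self):
        design = box_behnken_design(n_center=3)
        y = ResponseVector(5.0 + design.runs @ np.array([0.3, 0.5, -0.2]))
        split = split_data(15, seed=0)
        model = train_network(split, design, y, hidden_nodes=2,
                              config=TrainConfig(seed=0))
        mse = float(np.mean((model.predict(design.runs)[split.train]
                             - y.values[split.train]) ** 2))
        assert mse <= 1e-6

    def test_constant_response_predicted_constant(self):
        design = box_behnken_design(n_center=3)
        y = ResponseVector(np.full(15, 6.0))
        model = train_network(split_data(15, seed=1), design, y, 3,
                              TrainConfig(seed=1))
        pred = model.predict(design.runs)
        assert np.max(np.abs(pred - 6.0)) <= 1e-6

    def test_bit_reproducible_under_fixed_seed(self, table2):
        design, y = table2
        split = split_data(15, seed=4)
        m1 = train_network(split, design, y, 10, TrainConfig(seed=4))
        m2 = train_network(split, design, y, 10, TrainConfig(seed=4))
        assert np.array_equal(m1.w1, m2.w1) and np.array_equal(m1.w2, m2.w2)
        assert m1.b2 == m2.b2

    def test_descaling_round_trip_is_identity(self, table2):
        design, y = table2
        model = train_network(split_data(15, seed=2), design, y, 5,
                              TrainConfig(seed=2))
        pts = np.random.default_rng(0).uniform(-1, 1, (20, 3))
        scaled_back = ((model.predict(pts) - model.y_mean) / model.y_std
                       * model.y_std + model.y_mean)
        assert np.max(np.abs(scaled_back - model.predict(pts))) <= 1e-10

    def test_good_surrogates_exist_among_random_restarts(self, table2):
        """Restarts vary in quality because of the tiny validation subset;
        the best of ten should track the smooth response closely."""
        design, y = table2
        best = max(
            np.corrcoef(
                train_network(split_data(15, seed=s), design, y, 10,
                              TrainConfig(seed=s)).predict(design.runs),
                y.values)[0, 1]
            for s in range(10))
        assert best >= 0.90

    def test_non_finite_response_rejected(self, table2):
        design, _ = table2
        bad = ResponseVector(np.ones(15))
        bad.values[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            train_network(split_data(15, seed=0), design, bad, 3)


class TestDegreeOfApproximation:
    def _score(self, rmse_c, rmse_t, n_c=11, n_t=4, c=3.0):
        n = n_c + n_t
        err = n_c / n * rmse_c + n_t / n * rmse_t + abs(rmse_c - rmse_t)
        return DaScore(1, rmse_c, rmse_t, n_c, n_t, c, err,
                       c / err if err else float("inf"))

    def test_equal_errors_collapse_to_weighted_mean(self):
        s = self._score(0.1, 0.1)
        assert s.error_score == pytest.approx(0.1)
        assert s.da == pytest.approx(30.0)

    def test_asymmetric_errors_penalized(self):
        s = self._score(0.0, 0.2)
        assert s.error_score == pytest.approx(4 / 15 * 0.2 + 0.2)
        assert s.da == pytest.approx(3.0 / (4 / 15 * 0.2 + 0.2), rel=1e-6)
        assert s.da == pytest.approx(11.84, abs=0.01)

    def test_perfect_model_reports_infinite_da(self):
        design = box_behnken_design(n_center=3)
        y = ResponseVector(np.full(15, 5.5))
        model = train_network(split_data(15, seed=0), design, y, 2,
                              TrainConfig(seed=0))
        score = degree_of_approximation(model, design, y)
        assert score.da == float("inf") or score.da > 1e6

    def test_computed_from_model_split(self, table2):
        design, y = table2
        model = train_network(split_data(15, seed=3), design, y, 10,
                              TrainConfig(seed=3))
        s = degree_of_approximation(model, design, y)
        assert (s.n_c, s.n_t, s.n) == (11, 4, 15)
        assert s.error_score == pytest.approx(
            11 / 15 * s.rmse_calibration + 4 / 15 * s.rmse_test
            + abs(s.rmse_calibration - s.rmse_test))
        assert s.da == pytest.approx(3.0 / s.error_score)

    def test_da_and_error_score_rank_identically(self, table2):
        design, y = table2
        scores = [degree_of_approximation(
            train_network(split_data(15, seed=s), design, y, h,
                          TrainConfig(seed=s)), design, y)
            for h, s in [(2, 0), (5, 1), (10, 2)]]
        by_da = sorted(scores, key=lambda s: -s.da)
        by_err = sorted(scores, key=lambda s: s.error_score)
        assert [s.hidden_nodes for s in by_da] == [s.hidden_nodes for s in by_err]


class TestSelectHiddenNodes:
    def test_returns_width_with_maximal_median_da(self, table2):
        design, y = table2
        best, trace = select_hidden_nodes(design, y, widths=[2, 6, 10],
                                          seeds=range(3))
        assert best in trace
        assert trace[best] == max(trace.values())

    def test_tie_breaks_to_smaller_width(self, table2):
        design, y = table2
        _, trace = select_hidden_nodes(design, y, widths=[4, 8], seeds=range(2))
        if trace[4] == trace[8]:
            best, _ = select_hidden_nodes(design, y, widths=[4, 8], seeds=range(2))
            assert best == 4

    def test_empty_width_range_rejected(self, table2):
        design, y = table2
        with pytest.raises(ValueError, match="empty"):
            select_hidden_nodes(design, y, widths=[], seeds=[0])
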