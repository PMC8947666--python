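"""Voting combination, simplex-grid weight search and forecast scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from metalrisk.ensemble import (
    VotingWeights,
    level_indicator,
    mae,
    optimize_weights,
    prediction_accuracy,
    rmse,
    simplex_grid,
    vote_combine,
)
from metalrisk.risklevels import ClusterModel, order_levels

from test_risklevels import PUBLISHED_CENTERS, _published_model


class TestVoteCombine:
    def test_vertex_weight_recovers_submodel(self):
        f1, f2, f3 = np.arange(5.0), np.ones(5), np.zeros(5)
        out = vote_combine([f1, f2, f3], VotingWeights((1.0, 0.0, 0.0)))
        np.testing.assert_array_equal(out, f1)

    def test_identical_forecasts_invariant_to_weights(self):
        f = np.linspace(0, 1, 4)
        out = vote_combine([f, f.copy(), f.copy()], VotingWeights((0.2, 0.3, 0.5)))
        np.testing.assert_allclose(out, f)

    def test_hand_combination(self):
        out = vote_combine(
            [np.array([1.0]), np.array([2.0]), np.array([3.0])],
            VotingWeights((0.5, 0.3, 0.2)),
        )
        assert out[0] == pytest.approx(1.7)

    def test_invalid_weights_and_shapes(self):
        with pytest.raises(ValueError, match="sum to 1"):
            VotingWeights((0.5, 0.2))
        with pytest.raises(ValueError, match="non-negative"):
            VotingWeights((1.5, -0.5))
        with pytest.raises(ValueError, match="align"):
            vote_combine([np.zeros(3), np.zeros(4)], [0.5, 0.5])

    @given(arrays(float, (3, 5), elements=st.floats(-5, 5)))
    def test_order_preservation(self, arr):
        """If all sub-forecasts increase at a point, the combination increases."""
        w = [0.2, 0.5, 0.3]
        bumped = arr + 0.7
        lo = vote_combine(list(arr), w)
        hi = vote_combine(list(bumped), w)
        assert (hi > lo).all()


class TestSimplexGrid:
    def test_counts_match_stars_and_bars(self):
        assert len(simplex_grid(3, 0.1)) == 66
        assert len(simplex_grid(3, 0.05)) == 231

    def test_rows_are_on_the_simplex(self):
        g = simplex_grid(3, 0.1)
        assert (g >= 0).all()
        np.testing.assert_allclose(g.sum(axis=1), 1.0, atol=1e-12)
        assert len(np.unique(g, axis=0)) == len(g)

    def test_step_must_divide_one(self):
        with pytest.raises(ValueError, match="divide"):
            simplex_grid(3, 0.3)


class TestScores:
    def test_perfect_prediction_scores_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert rmse(a, a) == 0.0 and mae(a, a) == 0.0

    def test_hand_values(self):
        assert rmse([1, 2, 3], [2, 1, 4]) == pytest.approx(1.0)
        assert mae([1, 2, 3], [2, 1, 4]) == pytest.approx(1.0)
        assert rmse([0, 0], [3, 4]) == pytest.approx(3.53553, abs=1e-5)
        assert mae([0, 0], [3, 4]) == pytest.approx(3.5)

    @given(
        arrays(float, 6, elements=st.floats(-10, 10)),
        arrays(float, 6, elements=st.floats(-10, 10)),
    )
    def test_rmse_dominates_mae(self, a, b):
        assert rmse(a, b) >= mae(a, b) - 1e-12

    def test_empty_inputs_error(self):
        with pytest.raises(ValueError):
            rmse([], [])
        with pytest.raises(ValueError):
            prediction_accuracy([])

    def test_prediction_accuracy_counts(self):
        assert prediction_accuracy([1] * 5) == 1.0
        assert prediction_accuracy([0] * 4) == 0.0
        assert prediction_accuracy([1] * 19 + [0] * 2) == pytest.approx(0.90476, abs=1e-5)


class TestLevelIndicator:
    def test_identical_triples_agree(self):
        model = _published_model()
        p = np.array([0.2, 0.2, 0.2])
        assert level_indicator(p, p.copy(), model) == 1

    def test_opposite_centers_disagree(self):
        model = _published_model()
        assert (
            level_indicator(PUBLISHED_CENTERS[0], PUBLISHED_CENTERS[3], model) == 0
        )

    def test_unequal_points_in_same_basin_agree(self):
        model = _published_model()
        a = PUBLISHED_CENTERS[1] + 0.01
        b = PUBLISHED_CENTERS[1] - 0.01
        assert model.classify(a)[0] == model.classify(b)[0] == "Medium-Risk"
        assert level_indicator(a, b, model) == 1


class TestOptimizeWeights:
    def _setup(self, seed=0, days=10):
        model = _published_model()
        rng = np.random.default_rng(seed)
        actuals = rng.uniform(0, 0.8, (days, 3))
        good = actuals + rng.normal(0, 0.01, actuals.shape)  # tracks the truth
        bad1 = rng.uniform(0, 0.8, (days, 3))
        bad2 = rng.uniform(0, 0.8, (days, 3))
        return model, actuals, [good, bad1, bad2]

    def test_accurate_submodel_attracts_the_weight(self):
        model, actuals, forecasts = self._setup()
        w = optimize_weights(forecasts, actuals, model, grid_step=0.1)
        assert w.weights[0] >= 0.8
        assert w.pa == pytest.approx(1.0)

    def test_grid_optimality_beats_every_vertex(self):
        model, actuals, forecasts = self._setup(seed=5)
        w = optimize_weights(forecasts, actuals, model, grid_step=0.1)
        actual_levels = [model.classify(p)[0] for p in actuals]
        for i in range(3):
            hits = [
                int(model.classify(p)[0] == a)
                for p, a in zip(forecasts[i], actual_levels)
            ]
            assert w.pa >= prediction_accuracy(hits)

    def test_all_tied_pa_breaks_tie_by_mse(self):
        model = _published_model()
        actuals = np.tile(PUBLISHED_CENTERS[0], (5, 1))
        near = actuals + 0.001  # same level, tiny error
        far = actuals + 0.02  # same level, larger error
        w = optimize_weights([near, far], actuals, model, grid_step=0.5)
        assert w.pa == 1.0
        assert w.weights == (1.0, 0.0)  # lowest-MSE candidate wins the tie

    def test_empty_window_errors(self):
        model = _published_model()
        with pytest.raises(ValueError, match="empty"):
            optimize_weights([np.zeros((0, 3))], np.zeros((0, 3)), model)
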