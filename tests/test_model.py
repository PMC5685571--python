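"""Random-forest SWL model, evaluation, baseline and importance."""

import numpy as np
import pandas as pd
import pytest

from swbtext.model import (
    DEFAULT_GRID,
    ForestConfig,
    SWLForestRegressor,
    baseline_predict,
    evaluate,
    fit_forest,
    grid_search,
    simulate_oob_fraction,
    variable_importance,
)


def _planted(rng, n=300, p=6):
    X = rng.normal(size=(n, p))
    y = np.sin(X[:, 0]) * 2 + 0.2 * rng.normal(size=n)
    return X, y


class TestEvaluate:
    def test_perfect_prediction(self):
        res = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.pearson_r == pytest.approx(1.0)
        assert res.rmse == 0.0

    def test_constant_shift(self):
        res = evaluate([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.pearson_r == pytest.approx(1.0)
        assert res.rmse == pytest.approx(1.0)

    def test_hand_computed_rmse(self):
        res = evaluate([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert res.pearson_r == pytest.approx(1.0)
        assert res.rmse == pytest.approx(np.sqrt(14 / 3))

    def test_constant_vector_flagged_not_zero(self):
        res = evaluate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(res.pearson_r) and np.isnan(res.p_value)
        assert res.rmse > 0

    def test_matches_independent_formulas(self, rng):
        from scipy import stats

        pred, truth = rng.normal(size=40), rng.normal(size=40)
        res = evaluate(pred, truth)
        assert res.pearson_r == pytest.approx(stats.pearsonr(pred, truth).statistic)
        assert res.rmse == pytest.approx(
            np.sqrt(np.mean((np.asarray(pred) - truth) ** 2))
        )

    def test_rejects_bad_shapes(self):
        with pytest.raises(ValueError):
            evaluate([1.0, 2.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            evaluate([1.0, 2.0], [1.0, 2.0])


class TestBaseline:
    def test_bounded_jittered_median(self, rng):
        y = rng.normal(4, 1, 101)
        out = baseline_predict(y, 50, seed=0)
        med = np.median(y)
        assert ((out >= med) & (out <= med + 0.001)).all()

    def test_deterministic(self):
        a = baseline_predict([1.0, 2.0, 9.0], 5, seed=3)
        assert np.array_equal(a, baseline_predict([1.0, 2.0, 9.0], 5, seed=3))

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            baseline_predict([], 5)


class TestForest:
    def test_constant_target_predicts_constant(self, rng):
        X, _ = _planted(rng, n=50)
        model = fit_forest(X, np.full(50, 3.3), ForestConfig(50, 2, 0))
        assert np.allclose(model.predict(X), 3.3)
        assert np.isnan(model.oob_r_)

    def test_same_seed_identical_predictions(self, rng):
        X, y = _planted(rng, n=120)
        m1 = fit_forest(X, y, ForestConfig(100, 2, 5))
        m2 = fit_forest(X, y, ForestConfig(100, 2, 5))
        assert np.array_equal(m1.oob_prediction_, m2.oob_prediction_)
        assert np.array_equal(m1.predict(X), m2.predict(X))

    def test_predictions_bounded_by_training_targets(self, rng):
        X, y = _planted(rng, n=200)
        model = fit_forest(X, y, ForestConfig(100, 3, 0))
        pred = model.predict(rng.normal(size=(50, X.shape[1])) * 3)
        assert pred.min() >= y.min() and pred.max() <= y.max()

    def test_ntry_cannot_exceed_feature_count(self, rng):
        X, y = _planted(rng, n=30, p=2)
        with pytest.raises(ValueError, match="ntry"):
            fit_forest(X, y, ForestConfig(10, 3, 0))

    def test_estimator_follows_sklearn_conventions(self, rng):
        from sklearn.base import clone

        est = SWLForestRegressor(ntree=10, ntry=2, random_state=0)
        params = est.get_params()
        assert params["ntree"] == 10 and params["ntry"] == 2
        clone(est)  # must be cloneable for model selection
        X, y = _planted(rng, n=40)
        assert est.fit(X, y).score(X, y) > 0


class TestGridSearch:
    def test_single_config(self, rng):
        X, y = _planted(rng, n=60)
        cfg = ForestConfig(20, 2, 0)
        best, table = grid_search(X, y, (cfg,))
        assert best == cfg and len(table) == 1

    def test_default_grid_is_eight_cells(self):
        assert len(DEFAULT_GRID) == 8
        assert {c.ntree for c in DEFAULT_GRID} == {500, 1000, 1500, 2000}
        assert {c.ntry for c in DEFAULT_GRID} == {2, 3}

    def test_degenerate_target_ties_break_to_smallest(self, rng):
        X, _ = _planted(rng, n=30)
        grid = tuple(ForestConfig(nt, mt, 0) for nt in (30, 20) for mt in (3, 2))
        best, _ = grid_search(X, np.ones(30), grid)
        assert (best.ntree, best.ntry) == (20, 2)

    def test_best_by_oob_r(self, rng):
        X, y = _planted(rng, n=150)
        grid = (ForestConfig(10, 1, 0), ForestConfig(150, 2, 0))
        best, table = grid_search(X, y, grid)
        assert best.ntree == 150
        assert table["oob_r"].max() == pytest.approx(
            table.set_index(["ntree", "ntry"]).loc[(150, 2), "oob_r"]
        )


class TestImportance:
    def test_planted_feature_ranks_first_and_noise_near_zero(self, rng):
        X, y = _planted(rng, n=400, p=5)
        X = pd.DataFrame(X, columns=[f"f{i}" for i in range(5)])
        model = fit_forest(X, y, ForestConfig(200, 2, 0))
        imp = variable_importance(model, X, y, seed=0)
        assert imp.iloc[0]["feature"] == "f0"
        noise_imp = imp.set_index("feature").loc[["f3", "f4"], "importance"]
        assert (noise_imp.abs() < 0.1 * imp["importance"].max()).all()

    def test_deterministic_given_seed(self, rng):
        X, y = _planted(rng, n=100, p=4)
        model = fit_forest(X, y, ForestConfig(50, 2, 0))
        a = variable_importance(model, X, y, seed=1)
        b = variable_importance(model, X, y, seed=1)
        pd.testing.assert_frame_equal(a, b)


def test_oob_fraction_small_n():
    mean, fracs = simulate_oob_fraction(10, rounds=2000, seed=0)
    assert len(fracs) == 2000
    assert mean == pytest.approx((1 - 1 / 10) ** 10, abs=0.01)


def test_oob_fraction_rejects_bad_args():
    with pytest.raises(ValueError):
        simulate_oob_fraction(0)
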