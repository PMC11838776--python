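"""Logistic fitting (plain and hierarchical), prediction and Wald screening."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from ptspo import FeatureSpec, ModelBundle, TSPOLogit
from ptspo.errors import (CollinearityError, InsufficientDataError,
                          PredictionError, SeparationError)

from .oracles import grid_search_deviance


def _sim_logit(n, beta, seed=0, groups=None, offsets=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(beta)))
    eta = X @ np.asarray(beta)
    if groups is not None:
        eta = eta + np.asarray([offsets[g] for g in groups])
    y = (rng.random(n) < expit(eta)).astype(float)
    return X, y


class TestPlainFit:
    def test_symmetric_toy_gives_null_coefficients(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([0.0, 1.0, 0.0, 1.0])
        res = TSPOLogit(y, X, ["x"]).fit()
        np.testing.assert_allclose(res.params_array, 0.0, atol=1e-10)
        np.testing.assert_allclose(res.predict(X), 0.5)

    def test_deviance_matches_grid_oracle(self):
        X, y = _sim_logit(40, [1.2, -0.7], seed=5)
        res = TSPOLogit(y, X, ["a", "b"]).fit()
        oracle_dev, oracle_beta = grid_search_deviance(X, y)
        assert res.deviance == pytest.approx(oracle_dev, abs=1e-6)
        np.testing.assert_allclose(res.params_array, oracle_beta, atol=1e-3)

    def test_matches_statsmodels_glm(self):
        X, y = _sim_logit(200, [0.8, -1.1, 0.3], seed=9)
        res = TSPOLogit(y, X, ["a", "b", "c"]).fit()
        sm_res = sm.GLM(y, sm.add_constant(X),
                        family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(res.params_array, sm_res.params, rtol=1e-6)
        np.testing.assert_allclose(res.bse.to_numpy(), sm_res.bse, rtol=1e-4)
        assert res.deviance == pytest.approx(sm_res.deviance, rel=1e-8)

    def test_perfect_separation_raises_named_error(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        with pytest.raises(SeparationError, match="x"):
            TSPOLogit(y, X, ["x"]).fit()
        res = TSPOLogit(y, X, ["x"]).fit(ridge=1e-4)  # ridge rescue
        assert np.all(np.isfinite(res.params_array))

    def test_rank_deficiency_and_constant_feature(self):
        X, y = _sim_logit(50, [1.0], seed=2)
        dup = np.column_stack([X, X])
        with pytest.raises(CollinearityError):
            TSPOLogit(y, dup, ["a", "b"]).fit()
        const = np.column_stack([X, np.full(50, 3.0)])
        with pytest.raises(CollinearityError, match="constant"):
            TSPOLogit(y, const, ["a", "b"])

    def test_single_class_rejected(self):
        with pytest.raises(InsufficientDataError):
            TSPOLogit(np.ones(10), np.random.default_rng(0).normal(size=(10, 1)))


class TestPrediction:
    def test_closed_form_probabilities(self):
        X, y = _sim_logit(80, [1.0], seed=3)
        res = TSPOLogit(y, X, ["x"]).fit()
        res.params[:] = [0.0, 0.0]
        assert res.predict(np.array([[0.0]]))[0] == pytest.approx(0.5)
        res.params[:] = [2.0, 0.0]
        assert res.predict(np.array([[123.0]]))[0] == pytest.approx(
            1 / (1 + np.exp(-2)), abs=1e-4)
        assert res.predict(np.array([[0.0]]))[0] == pytest.approx(0.8808, abs=1e-4)

    def test_predict_reproduces_fitted_probabilities(self):
        X, y = _sim_logit(120, [0.9, -0.4], seed=11)
        res = TSPOLogit(y, X, ["a", "b"]).fit()
        eta = res.params_array[0] + X @ res.params_array[1:]
        np.testing.assert_allclose(res.predict(X), expit(eta), atol=1e-10)

    def test_affine_reparameterization_leaves_probabilities_unchanged(self):
        X, y = _sim_logit(150, [1.1, -0.6], seed=13)
        res1 = TSPOLogit(y, X, ["a", "b"]).fit()
        X2 = X.copy()
        X2[:, 0] = (X[:, 0] - 2.0) / 5.0  # min-max style affine rescale
        res2 = TSPOLogit(y, X2, ["a", "b"]).fit()
        assert res2.params["a"] == pytest.approx(5.0 * res1.params["a"], rel=1e-6)
        np.testing.assert_allclose(res1.predict(X), res2.predict(X2), atol=1e-8)

    def test_positive_coefficient_monotonicity(self):
        X, y = _sim_logit(300, [2.0], seed=17)
        res = TSPOLogit(y, X, ["tac50"]).fit()
        assert res.params["tac50"] > 0
        grid = np.linspace(-2, 2, 30)[:, None]
        p = res.predict(grid)
        assert np.all(np.diff(p) > 0)

    def test_missing_feature_is_prediction_error(self):
        X, y = _sim_logit(60, [1.0], seed=19)
        res = TSPOLogit(y, X, ["x"]).fit()
        with pytest.raises(PredictionError):
            res.predict(pd.DataFrame({"other": [1.0]}))


class TestHierarchicalFit:
    def test_recovers_fixed_effects_and_offsets(self):
        rng = np.random.default_rng(42)
        offs = {"a": -0.8, "b": 0.0, "c": 0.8}
        groups = np.array(list(offs))[rng.integers(0, 3, 2000)]
        X, y = _sim_logit(2000, [1.0, -1.5], seed=42, groups=groups, offsets=offs)
        res = TSPOLogit(y - 0, X, ["x1", "x2"], groups=groups).fit()
        truth = np.array([0.0, 1.0, -1.5])
        z = np.abs(res.params_array - truth) / res.bse.to_numpy()
        assert np.all(z < 3.0)
        assert res.random_sd == pytest.approx(np.std(list(offs.values())), rel=0.5)
        # centred random intercepts
        assert abs(res.random_effects.mean()) < 1e-6

    def test_single_dataset_equals_plain_fit(self):
        X, y = _sim_logit(300, [0.7, 0.4], seed=23)
        groups = np.array(["only"] * 300)
        with pytest.warns(UserWarning, match="single dataset"):
            hier = TSPOLogit(y, X, ["a", "b"], groups=groups).fit(hierarchical=True)
        plain = TSPOLogit(y, X, ["a", "b"]).fit()
        np.testing.assert_allclose(hier.params_array, plain.params_array,
                                   atol=1e-8)

    def test_null_offsets_give_small_random_sd(self):
        rng = np.random.default_rng(31)
        groups = np.array(["a", "b", "c"])[rng.integers(0, 3, 1500)]
        X, y = _sim_logit(1500, [1.0], seed=31)
        res = TSPOLogit(y, X, ["x"], groups=groups).fit()
        assert res.random_sd < 0.1

    def test_unseen_dataset_predicts_at_population_level(self):
        rng = np.random.default_rng(7)
        offs = {"a": -0.5, "b": 0.5}
        groups = np.array(list(offs))[rng.integers(0, 2, 600)]
        X, y = _sim_logit(600, [1.0], seed=7, groups=groups, offsets=offs)
        res = TSPOLogit(y, X, ["x"], groups=groups).fit()
        x0 = np.array([[0.3]])
        p_pop = res.predict(x0)
        p_new = res.predict(x0, dataset="never-seen")
        assert p_pop[0] == pytest.approx(p_new[0])
        assert res.predict(x0, dataset="a")[0] < p_pop[0] < res.predict(x0, dataset="b")[0]


class TestWaldScreen:
    def test_threshold_behaviour(self):
        X, y = _sim_logit(400, [3.0, 0.0], seed=37)
        res = TSPOLogit(y, X, ["strong", "null"]).fit()
        kept = res.wald_screen(1.96)
        assert "strong" in kept and "null" not in kept
        assert set(res.wald_screen(0.0)) == {"strong", "null"}


class TestBundle:
    def test_roundtrip_predictions_identical(self, tmp_path, small_design):
        design, spec = small_design
        feats = spec.feature_names
        model = TSPOLogit.from_design(design, features=feats, feature_spec=spec)
        res = model.fit(ridge=1e-4)
        bundle = res.to_bundle(seed=7)
        bundle.save(tmp_path / "bundle.json")
        back = ModelBundle.load(tmp_path / "bundle.json")
        p1 = bundle.predict(design)["p_tspo"]
        p2 = back.predict(design)["p_tspo"]
        np.testing.assert_allclose(p1, p2, atol=1e-12)
        assert back.feature_spec.grid_minutes == spec.grid_minutes
        assert back.method == res.method

    def test_summary_mentions_key_fields(self, small_design):
        design, spec = small_design
        res = TSPOLogit.from_design(design, features=spec.feature_names,
                                    feature_spec=spec).fit(ridge=1e-4)
        text = res.summary()
        assert "deviance" in text and "Wald z" in text
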