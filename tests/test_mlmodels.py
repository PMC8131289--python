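"""RF and ARD-GP regressors: interpolation, relevance ranking, determinism."""

import numpy as np
import pandas as pd
import pytest

from kpuubrain.mlmodels import (
    Algorithm,
    ERFeatures,
    ModelSpec,
    Response,
    SchemaMismatchError,
    gp_hyperparams,
    predict,
    predict_er_then_kpuu,
    top_features,
    train,
)


def _frame(X, prefix="d"):
    return pd.DataFrame(X, columns=[f"{prefix}{i}" for i in range(X.shape[1])])


@pytest.fixture(scope="module")
def linear_gp_fit():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(60, 5))
    y = 2.0 * X[:, 2]  # depends on one descriptor only, zero noise
    frame = _frame(X)
    spec = ModelSpec(algorithm=Algorithm.GP, seed=0, n_restarts=1)
    model = train(spec, frame, None, y)
    return frame, y, model


class TestGPTraining:
    def test_interpolates_noise_free_linear_response(self, linear_gp_fit):
        frame, y, model = linear_gp_fit
        pred = predict(model, frame)
        assert np.sqrt(np.mean((pred - y) ** 2)) < 1e-3

    def test_relevant_descriptor_gets_smallest_length_scale(self, linear_gp_fit):
        frame, y, model = linear_gp_fit
        hp = gp_hyperparams(model)
        assert int(np.argmin(hp.gamma)) == 2
        assert top_features(model, k=1)[0][0] == "d2"

    def test_marginal_likelihood_envelope_monotone(self, linear_gp_fit):
        _, _, model = linear_gp_fit
        trace = np.asarray(model.nlml_trace)
        assert trace.size > 1
        # the best-so-far negative log marginal likelihood never rises
        env = np.minimum.accumulate(trace)
        assert np.all(np.diff(env) <= 1e-9)
        assert env[-1] <= trace[0]

    def test_predictive_variance_grows_off_support(self, linear_gp_fit):
        frame, _, model = linear_gp_fit
        _, sd_train = predict(model, frame.iloc[[0]], return_std=True)
        far = frame.iloc[[0]] + 25.0
        _, sd_far = predict(model, far, return_std=True)
        assert sd_far[0] > sd_train[0]

    def test_constant_response_predicts_constant(self):
        rng = np.random.default_rng(3)
        frame = _frame(rng.normal(size=(20, 3)))
        y = np.full(20, 0.7)
        for alg in (Algorithm.GP, Algorithm.RF):
            model = train(ModelSpec(algorithm=alg, seed=1, n_trees=50), frame, None, y)
            probe = _frame(rng.normal(size=(5, 3)))
            assert np.allclose(predict(model, probe), 0.7, atol=1e-8)


class TestRF:
    def test_seeded_determinism(self, rng):
        frame = _frame(rng.normal(size=(50, 4)))
        y = rng.normal(size=50)
        spec = ModelSpec(algorithm=Algorithm.RF, seed=7, n_trees=50)
        p1 = predict(train(spec, frame, None, y), frame)
        p2 = predict(train(spec, frame, None, y), frame)
        assert np.array_equal(p1, p2)

    def test_predictions_bounded_by_training_range(self, rng):
        frame = _frame(rng.normal(size=(60, 4)))
        y = rng.normal(size=60)
        model = train(ModelSpec(algorithm=Algorithm.RF, seed=0, n_trees=50),
                      frame, None, y)
        probe = _frame(rng.normal(0, 10, size=(40, 4)))
        pred = predict(model, probe)
        assert pred.min() >= y.min() - 1e-12 and pred.max() <= y.max() + 1e-12

    def test_ensemble_variance_shrinks_with_more_trees(self, rng):
        frame = _frame(rng.normal(size=(80, 4)))
        y = frame["d0"].to_numpy() + rng.normal(0, 0.5, 80)
        probe = _frame(rng.normal(size=(1, 4)))

        def spread(n_trees):
            preds = [predict(train(ModelSpec(algorithm=Algorithm.RF, seed=s,
                                             n_trees=n_trees), frame, None, y),
                             probe)[0] for s in range(8)]
            return np.var(preds)

        assert spread(400) < spread(10)


class TestInterfaces:
    def test_schema_mismatch_is_explicit(self, rng):
        frame = _frame(rng.normal(size=(30, 3)))
        y = rng.normal(size=30)
        model = train(ModelSpec(algorithm=Algorithm.RF, seed=0, n_trees=20),
                      frame, None, y)
        wrong = frame.rename(columns={"d2": "other"})
        with pytest.raises(SchemaMismatchError, match="other"):
            predict(model, wrong)

    def test_top_features_truncates_gracefully(self, linear_gp_fit):
        _, _, model = linear_gp_fit
        assert len(top_features(model, k=50)) == 5

    def test_er_features_ignored_for_er_response(self):
        spec = ModelSpec(response=Response.LOG_ER_MDR1, er_features=ERFeatures.BOTH)
        assert spec.er_features is ERFeatures.NONE

    def test_er_feature_columns_standardized_with_train_stats(self, rng):
        frame = _frame(rng.normal(size=(40, 3)))
        extra = pd.DataFrame({"log_er_mdr1": rng.normal(1.0, 0.5, 40)},
                             index=frame.index)
        y = rng.normal(size=40)
        spec = ModelSpec(algorithm=Algorithm.RF, er_features=ERFeatures.MDR1_ONLY,
                         seed=0, n_trees=20)
        model = train(spec, frame, extra, y)
        mu, sd = model.er_scaling["log_er_mdr1"]
        v = extra["log_er_mdr1"].to_numpy()
        assert mu == pytest.approx(v.mean())
        assert sd == pytest.approx(v.std(ddof=1))
        assert model.feature_names[-1] == "log_er_mdr1"


class TestTwoStagePipeline:
    def _setup(self, rng, er_noise=0.0):
        X = rng.normal(size=(70, 4))
        log_er_m = X[:, 0]
        log_er_b = X[:, 1]
        y = -0.3 * log_er_m - 0.2 * log_er_b + 0.05 * X[:, 2]
        frame = _frame(X)
        extra = pd.DataFrame({"log_er_mdr1": log_er_m, "log_er_bcrp": log_er_b},
                             index=frame.index)
        kpuu_model = train(
            ModelSpec(algorithm=Algorithm.GP, er_features=ERFeatures.BOTH,
                      seed=0, n_restarts=1), frame, extra, y)
        er_models = {
            key: train(ModelSpec(algorithm=Algorithm.GP,
                                 response=Response(f"log_er_{key}"),
                                 seed=0, n_restarts=1),
                       frame, None, er + rng.normal(0, er_noise, 70))
            for key, er in (("mdr1", log_er_m), ("bcrp", log_er_b))
        }
        return frame, extra, y, kpuu_model, er_models

    def test_substitution_identity_with_perfect_er_models(self, rng):
        frame, extra, _, kpuu_model, er_models = self._setup(rng)
        # noise-free GP ER models interpolate the measured ERs on the
        # training set, so the two-stage output matches the measured-ER path
        direct = predict(kpuu_model, frame, extra)
        two_stage = predict_er_then_kpuu(er_models, kpuu_model, frame)
        assert np.allclose(direct, two_stage, atol=1e-3)

    def test_missing_er_model_is_explicit(self, rng):
        frame, _, _, kpuu_model, er_models = self._setup(rng)
        del er_models["bcrp"]
        with pytest.raises(ValueError, match="bcrp"):
            predict_er_then_kpuu(er_models, kpuu_model, frame)

    def test_no_er_feature_model_rejected(self, rng):
        frame = _frame(rng.normal(size=(30, 3)))
        y = rng.normal(size=30)
        model = train(ModelSpec(algorithm=Algorithm.RF, seed=0, n_trees=20),
                      frame, None, y)
        with pytest.raises(ValueError, match="no ER features"):
            predict_er_then_kpuu({}, model, frame)


class TestValidationErrors:
    def test_nan_features_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        X[4, 1] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            train(ModelSpec(algorithm=Algorithm.RF, n_trees=10), _frame(X),
                  None, rng.normal(size=20))

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            train(ModelSpec(algorithm=Algorithm.RF, n_trees=10),
                  _frame(rng.normal(size=(2, 3))), None, np.zeros(2))
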