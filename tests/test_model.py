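"""Scoring, probability link and linear-discriminant fitting."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import almaentropy as ae
from almaentropy.errors import DataError, NumericalError
from almaentropy.model import AlmaModel, fit_lda, predict_table

finite_floats = st.floats(min_value=-5, max_value=5, allow_nan=False)
feature_vectors = st.lists(finite_floats, min_size=5, max_size=5).map(np.array)


class TestScore:
    def test_zero_vector_returns_exact_intercept(self, reference):
        assert reference.score(np.zeros(5)) == 1.139556

    def test_unit_quality_vector(self, reference):
        s = reference.score(np.array([1.0, 0, 0, 0, 0]))
        assert s == pytest.approx(1.139556 - 0.403994, abs=1e-12)

    def test_zero_coefficient_model_returns_intercept(self):
        m = AlmaModel(intercept=0.25, coef=np.zeros(5))
        assert m.score(np.ones(5)) == 0.25

    @settings(derandomize=True, max_examples=50)
    @given(f=feature_vectors, g=feature_vectors,
           alpha=st.floats(min_value=0, max_value=1))
    def test_score_is_affine(self, reference, f, g, alpha):
        mixed = alpha * f + (1 - alpha) * g
        expected = alpha * reference.score(f) + (1 - alpha) * reference.score(g)
        assert reference.score(mixed) == pytest.approx(expected, abs=1e-9)


class TestProbability:
    def test_symmetry_about_midpoint(self, reference):
        for s in (0.3, 1.2, -2.0):
            assert reference.probability(s) + reference.probability(-s) == (
                pytest.approx(1.0)
            )

    def test_saturation(self, reference):
        assert reference.probability(50.0) == pytest.approx(1.0)
        assert reference.probability(-50.0) == pytest.approx(0.0, abs=1e-12)

    def test_monotone(self, reference):
        grid = np.linspace(-3, 3, 50)
        p = reference.probability(grid)
        assert np.all(np.diff(p) > 0)

    def test_fitted_model_crosses_half_at_decision_boundary(self):
        rng = np.random.default_rng(3)
        X = np.r_[rng.normal(0, 1, (200, 5)), rng.normal(1.5, 1, (200, 5))]
        y = np.r_[np.zeros(200), np.ones(200)].astype(int)
        model = fit_lda(X, y)
        # solve a point on the boundary: score == 0 under the logistic link
        direction = model.coef / (model.coef @ model.coef)
        boundary = -model.intercept * direction
        assert model.probability(model.score(boundary)) == pytest.approx(0.5)


class TestFitLda:
    def test_separating_coefficient_sign(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(400, 5))
        y = (X[:, 2] > 0).astype(int)
        model = fit_lda(X, y)
        assert model.coef[2] > 0
        assert abs(model.coef[2]) > np.abs(np.delete(model.coef, 2)).max()

    def test_null_labels_give_small_canonical_correlation(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(2000, 5))
        y = rng.integers(0, 2, size=2000)
        model = fit_lda(X, y)
        assert abs(model.meta["Rc"]) < 0.1

    def test_one_class_input_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 5))
        with pytest.raises(DataError, match="both classes"):
            fit_lda(X, np.ones(20, dtype=int))

    def test_too_few_records_rejected(self):
        with pytest.raises(DataError, match="at least 6"):
            fit_lda(np.zeros((4, 5)), np.array([0, 1, 0, 1]))

    def test_singular_covariance_advises_shrinkage(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(60, 1))
        X = np.hstack([base] * 5)  # rank-1 features
        y = (base.ravel() > 0).astype(int)
        with pytest.raises(NumericalError, match="shrinkage"):
            fit_lda(X, y)
        model = fit_lda(X, y, shrinkage=1e-3)  # regularized fit succeeds
        assert np.isfinite(model.coef).all()

    def test_classifier_predict_uses_strict_cutoff(self):
        rng = np.random.default_rng(4)
        X = np.r_[rng.normal(0, 1, (50, 5)), rng.normal(2, 1, (50, 5))]
        y = np.r_[np.zeros(50), np.ones(50)].astype(int)
        clf = ae.AlmaClassifier(cutoff=1.0).fit(X, y)
        assert clf.predict(X).sum() == 0  # p can never strictly exceed 1


class TestModelSerialization:
    def test_json_round_trip(self, tmp_path, reference):
        path = tmp_path / "model.json"
        ae.save_model(reference, path)
        loaded = ae.load_model(path)
        assert loaded.intercept == reference.intercept
        assert np.array_equal(loaded.coef, reference.coef)

    def test_reference_coefficients_exact(self, reference):
        assert reference.intercept == 1.139556
        assert np.array_equal(
            reference.coef,
            [-0.403994, 0.199322, 0.434889, -0.020189, -0.001660],
        )

    def test_missing_key_rejected(self):
        with pytest.raises(DataError, match="coef"):
            AlmaModel.from_dict({"intercept": 1.0})


class TestPredictTable:
    def test_same_compound_different_targets_different_scores(
        self, reference, toy_endpoints
    ):
        fz = ae.AlmaFeaturizer().fit(toy_endpoints)
        pair = toy_endpoints.iloc[[0, 0]].copy().reset_index(drop=True)
        pair.loc[1, "target_id"] = "t2"
        out = predict_table(reference, pair, fz)
        ma_t1 = fz.ma_lookup_["target_id"]["t1"]
        ma_t2 = fz.ma_lookup_["target_id"]["t2"]
        assert ma_t1 != ma_t2
        assert out.loc[0, "score"] != out.loc[1, "score"]

    def test_all_zero_features_predict_active(self, reference, toy_endpoints):
        fz = ae.AlmaFeaturizer().fit(toy_endpoints)
        out = predict_table(reference, toy_endpoints, fz)
        # the intercept 1.139556 sits above the logistic midpoint
        assert reference.probability(reference.score(np.zeros(5))) > 0.5

    def test_empty_input_gives_empty_output(self, reference, toy_endpoints):
        fz = ae.AlmaFeaturizer().fit(toy_endpoints)
        out = predict_table(reference, toy_endpoints.iloc[:0], fz)
        assert len(out) == 0
        assert {"score", "proba", "label_pred"} <= set(out.columns)

    def test_fit_predict_confusion_counts_all_records(self, small_synth):
        frame, _, _ = small_synth
        fz = ae.AlmaFeaturizer().fit(frame)
        model = fit_lda(fz.transform(frame), frame["label"].astype(int))
        pred = predict_table(model, frame, fz)
        cm = ae.confusion(frame["label"].astype(int).tolist(),
                          pred["label_pred"].tolist())
        assert cm.total == len(frame)
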