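"""Normalization, data splitting, Bayesian-regularized training and scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canopyaroma.ann import (
    AROMA_SCALE_MAX,
    BayesRegNetRegressor,
    NormalizationSpec,
    fit_report,
    normalize_minmax,
    pooled_score,
    predict_aromas,
    score_model,
    select_architecture,
    split_data,
    train_br_ann,
)
from canopyaroma.synthetic import TeacherMapping, gen_aroma_dataset


class TestNormalization:
    def test_endpoints_and_midpoint(self):
        X = np.array([[0.0], [2.0], [4.0]])
        Xn, spec = normalize_minmax(X)
        assert Xn.ravel() == pytest.approx([-1.0, 0.0, 1.0])

    def test_spec_reuse_on_new_data(self):
        _, spec = normalize_minmax(np.array([[0.0], [4.0]]))
        assert spec.transform(np.array([[2.0]]))[0, 0] == pytest.approx(0.0)
        assert spec.transform(np.array([[8.0]]))[0, 0] == pytest.approx(3.0)

    def test_constant_column_maps_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant column"):
            Xn, spec = normalize_minmax(np.full((4, 2), 7.0))
        assert np.all(Xn == 0.0)
        assert np.all(spec.inverse_transform(Xn) == 7.0)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_round_trip_is_identity(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 100, (12, 4))
        Xn, spec = normalize_minmax(X)
        assert np.allclose(spec.inverse_transform(Xn), X, atol=1e-9)
        assert Xn.min() >= -1.0 and Xn.max() <= 1.0


class TestSplit:
    def test_field_sample_arithmetic(self):
        X = np.zeros((173, 6))
        (Xtr, _), (Xte, _) = split_data(X, np.zeros((173, 6)), 0.85, seed=0)
        assert Xtr.shape[0] == 147 and Xte.shape[0] == 26

    def test_ties_round_toward_training(self):
        (Xtr, _), (Xte, _) = split_data(np.zeros((10, 2)), np.zeros((10, 2)), 0.85)
        assert Xtr.shape[0] == 8 and Xte.shape[0] == 2

    def test_same_seed_reproduces_split(self):
        X = np.arange(40.0).reshape(20, 2)
        y = np.arange(20.0).reshape(20, 1)
        a = split_data(X, y, seed=9)
        b = split_data(X, y, seed=9)
        assert np.array_equal(a[0][0], b[0][0]) and np.array_equal(a[1][1], b[1][1])

    def test_split_is_disjoint_and_exhaustive(self):
        X = np.arange(31.0)[:, None]
        (Xtr, _), (Xte, _) = split_data(X, X.copy(), seed=2)
        merged = np.sort(np.concatenate([Xtr, Xte]).ravel())
        assert np.array_equal(merged, X.ravel())

    def test_too_few_samples_raise(self):
        with pytest.raises(ValueError, match="at least 2"):
            split_data(np.zeros((1, 2)), np.zeros((1, 2)))


class TestTraining:
    def test_noiseless_linear_target_is_memorized(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, (100, 6))
        y = X @ rng.normal(0, 1, (6, 6)).T
        model = BayesRegNetRegressor(
            hidden_size=10, max_epochs=300, n_init=1, random_state=0
        ).fit(X, y)
        assert score_model(model, X, y, "training").r >= 0.999

    def test_seeded_end_to_end_determinism(self):
        X, y, _ = gen_aroma_dataset(60, seed=5)
        reports = []
        for _ in range(2):
            train, test = split_data(X, y, seed=5)
            model = BayesRegNetRegressor(
                hidden_size=3, max_epochs=150, n_init=1, random_state=5
            ).fit(*train)
            reports.append(fit_report(model, train, test))
        assert reports[0] == reports[1]

    def test_stronger_regularization_shrinks_weights(self):
        X, y, _ = gen_aroma_dataset(60, seed=1)
        norms = [
            BayesRegNetRegressor(
                hidden_size=5, max_epochs=100, n_init=1, random_state=1,
                fixed_alpha_beta=(ratio, 1.0),
            )
            .fit(X, y)
            .weight_norm_
            for ratio in (1e-3, 1e-1, 10.0)
        ]
        assert norms[0] > norms[1] > norms[2]

    def test_teacher_network_recovery_noiseless(self):
        X, y, _ = gen_aroma_dataset(120, TeacherMapping(noise_sd=0.0), seed=2)
        train, test = split_data(X, y, seed=2)
        model = train_br_ann(train, hidden_size=10, seed=2, max_epochs=400)
        assert score_model(model, *test, stage="testing").r >= 0.99

    def test_non_finite_training_data_rejected(self):
        X = np.full((20, 6), np.nan)
        with pytest.raises(ValueError, match="finite"):
            BayesRegNetRegressor().fit(X, np.zeros((20, 6)))


class TestScoring:
    def test_perfect_predictions(self):
        y = np.arange(12.0).reshape(4, 3)
        s = pooled_score(y, y)
        assert s.r == pytest.approx(1.0) and s.mse == 0.0

    def test_hand_computed_toy(self):
        # predictions (0,2,4) against targets (0,1,2): perfectly correlated
        # but biased, MSE = (0 + 1 + 4)/3
        s = pooled_score(np.array([[0.0], [2.0], [4.0]]), np.array([[0.0], [1.0], [2.0]]))
        assert s.r == pytest.approx(1.0)
        assert s.mse == pytest.approx(5.0 / 3.0)

    def test_observation_count_is_six_per_sample(self):
        X, y, _ = gen_aroma_dataset(30, seed=0)
        model = BayesRegNetRegressor(hidden_size=3, max_epochs=30, n_init=1).fit(X, y)
        s = score_model(model, X, y)
        assert s.samples == 30 and s.observations == 180

    def test_constant_predictions_flagged_degenerate(self):
        s = pooled_score(np.full((5, 2), 3.0), np.arange(10.0).reshape(5, 2))
        assert s.degenerate and s.r == 0.0


class TestSelection:
    def test_single_candidate_returned_unconditionally(self):
        X, y, _ = gen_aroma_dataset(40, seed=3)
        train, test = split_data(X, y, seed=3)
        model, report = select_architecture(train, test, (5,), seed=3, max_epochs=60)
        assert model.hidden_size == 5
        assert set(report.per_size) == {5}

    def test_parsimony_tie_break_on_low_rank_linear_data(self):
        # a rank-2 linear map is within reach of every candidate size, so
        # all reach near-identical test R and parsimony picks the smallest
        rng = np.random.default_rng(4)
        X = rng.uniform(-1, 1, (80, 6))
        W = rng.normal(0, 1, (6, 2)) @ rng.normal(0, 1, (2, 6))
        y = X @ W.T
        train, test = split_data(X, y, seed=4)
        model, _ = select_architecture(train, test, (3, 5, 7, 10), seed=4, max_epochs=200)
        assert model.hidden_size == 3

    def test_empty_candidates_raise(self):
        with pytest.raises(ValueError, match="non-empty"):
            select_architecture((None, None), (None, None), ())


class TestPrediction:
    def test_trained_toy_reproduces_targets(self):
        X, y, _ = gen_aroma_dataset(60, TeacherMapping(noise_sd=0.0), seed=6)
        model = train_br_ann((X, y), hidden_size=10, seed=6, max_epochs=300)
        assert np.allclose(predict_aromas(model, X), np.clip(y, 0, AROMA_SCALE_MAX), rtol=0.05, atol=500)

    def test_predictions_clamped_to_map_scale(self):
        X, y, _ = gen_aroma_dataset(40, seed=7)
        model = train_br_ann((X, y), hidden_size=3, seed=7, max_epochs=50)
        wild = X * 3.0
        with pytest.warns(UserWarning, match="outside"):
            preds = predict_aromas(model, wild)
        assert preds.min() >= 0.0 and preds.max() <= AROMA_SCALE_MAX

    def test_shape_mismatch_raises(self):
        X, y, _ = gen_aroma_dataset(20, seed=8)
        model = train_br_ann((X, y), hidden_size=3, seed=8, max_epochs=20)
        with pytest.raises(ValueError):
            model.predict(np.zeros((4, 3)))


def test_json_round_trip_preserves_predictions(tmp_path):
    X, y, _ = gen_aroma_dataset(40, seed=9)
    model = train_br_ann((X, y), hidden_size=5, seed=9, max_epochs=60)
    path = tmp_path / "model.json"
    model.to_json(path)
    clone = BayesRegNetRegressor.from_json(path)
    assert np.allclose(clone.predict(X), model.predict(X))
    assert clone.hidden_size == 5
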