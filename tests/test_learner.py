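import numpy as np
import pytest

from suspect.core import SAV, FeatureMatrix, Label, SelectionConfig, SvmConfig
from suspect.errors import DegenerateInputError, SchemaError, ValidationError
from suspect.learner import (
    TrainedModel,
    apply_scaler,
    fit_scaler,
    grid_search_cv,
    mrmr_select,
    mutual_information,
    predict_score,
    sigest_gamma,
    stability_select,
    train_svm,
)


def make_matrix(values, names=None, labels=None):
    values = np.asarray(values, float)
    names = names or [f"f{i}" for i in range(values.shape[1])]
    labels = labels if labels is not None else [i % 2 for i in range(len(values))]
    savs = [
        SAV(f"P{i}", i + 1, "A", "V", Label.DISEASE if y else Label.NEUTRAL)
        for i, y in enumerate(labels)
    ]
    return FeatureMatrix(savs, names, values, ~np.isfinite(values))


class TestScaler:
    def test_endpoints_map_to_unit_interval(self):
        m = make_matrix([[2.0], [4.0]])
        scaled = apply_scaler(fit_scaler(m), m)
        assert scaled[:, 0].tolist() == [0.0, 1.0]

    def test_constant_column_maps_to_zero(self):
        m = make_matrix([[3.0], [3.0], [3.0]], labels=[1, 0, 1])
        scaled = apply_scaler(fit_scaler(m), m)
        assert (scaled == 0).all()

    def test_out_of_range_clipped(self):
        train = make_matrix([[2.0], [4.0]])
        scaler = fit_scaler(train)
        assert apply_scaler(scaler, np.array([[5.0]]))[0, 0] == 1.0
        assert apply_scaler(scaler, np.array([[1.0]]))[0, 0] == 0.0

    def test_schema_mismatch(self):
        scaler = fit_scaler(make_matrix([[1.0], [2.0]], names=["x"]))
        with pytest.raises(SchemaError):
            apply_scaler(scaler, make_matrix([[1.0], [2.0]], names=["y"]))


class TestMrmr:
    def test_perfect_copy_wins(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        X = rng.standard_normal((200, 10))
        X[:, 3] = y
        assert mrmr_select(X, y, k=1) == ["f3"]

    def test_redundant_duplicate_penalised(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 400)
        strong = y + 0.05 * rng.standard_normal(400)
        weak = y + 1.0 * rng.standard_normal(400)
        X = np.column_stack([strong, strong.copy(), weak, rng.standard_normal(400)])
        picks = mrmr_select(X, y, k=2, alpha=0.5, feature_names=["dup1", "dup2", "weak", "noise"])
        assert picks[0] in ("dup1", "dup2")
        assert picks[1] == "weak"  # the exact duplicate is fully redundant

    def test_k_exhausts_features(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((100, 3))
        y = rng.integers(0, 2, 100)
        assert len(mrmr_select(X, y, k=10)) == 3

    def test_alpha_zero_is_pure_relevance_ranking(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 300)
        X = np.column_stack(
            [y + s * rng.standard_normal(300) for s in (0.2, 0.6, 1.5, 3.0)]
        )
        picks = mrmr_select(X, y, k=4, alpha=0.0)
        # oracle: rank by marginal MI, computed independently below
        from suspect.learner import discretize_column

        mis = [
            mutual_information(discretize_column(X[:, j]), y) for j in range(4)
        ]
        expected = [f"f{j}" for j in np.argsort(mis)[::-1]]
        assert picks == expected

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).standard_normal((50, 3))
        with pytest.raises(DegenerateInputError):
            mrmr_select(X, np.ones(50, int), k=1)


class TestStabilitySelection:
    def test_dominant_feature_always_chosen(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 200)
        X = rng.standard_normal((200, 5))
        X[:, 2] = y
        m = make_matrix(X, labels=y)
        rep = stability_select(m, y, SelectionConfig(n_subsets=20, k_per_iteration=2), seed=0)
        assert rep.frequencies["f2"] == 1.0
        assert "f2" in rep.chosen

    def test_deterministic_under_seed(self, small_dataset):
        m, labels = small_dataset
        cfg = SelectionConfig(n_subsets=8, k_per_iteration=10)
        a = stability_select(m, labels, cfg, seed=9)
        b = stability_select(m, labels, cfg, seed=9)
        assert a.frequencies == b.frequencies
        assert a.per_subset == b.per_subset

    def test_keep_threshold_excludes_sub_threshold_features(self, small_dataset):
        m, labels = small_dataset
        cfg = SelectionConfig(n_subsets=10, k_per_iteration=12)
        rep = stability_select(m, labels, cfg, seed=2)
        assert rep.chosen == [f for f in m.feature_names if rep.frequencies[f] >= 1.0]
        for f in m.feature_names:
            if rep.frequencies[f] < 1.0:
                assert f not in rep.chosen

    def test_frequencies_are_multiples_of_inverse_subsets(self, small_dataset):
        m, labels = small_dataset
        rep = stability_select(m, labels, SelectionConfig(n_subsets=4, k_per_iteration=5), seed=1)
        for f in rep.frequencies.values():
            assert (f * 4) == pytest.approx(round(f * 4))


class TestSvm:
    def separable(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        X = rng.standard_normal((n, 2)) * 0.3
        X[y == 1] += 5.0
        return make_matrix(X, labels=y), y

    def test_separable_training_accuracy(self):
        m, y = self.separable()
        model = train_svm(m, y, seed=0)
        pred = predict_score(model, m)
        calls = (pred["score"] > 50).astype(int).to_numpy()
        assert (calls == y).mean() == 1.0

    def test_default_parameters_recorded(self):
        m, y = self.separable()
        model = train_svm(m, y, seed=0)
        assert model.config.C == 128 and model.config.gamma == 0.01

    def test_deterministic_predictions(self):
        m, y = self.separable()
        p1 = predict_score(train_svm(m, y, seed=5), m)["score"]
        p2 = predict_score(train_svm(m, y, seed=5), m)["score"]
        assert (p1 == p2).all()

    def test_single_class_rejected(self):
        m, _ = self.separable()
        with pytest.raises(DegenerateInputError):
            train_svm(m, np.zeros(m.n_savs, int))

    def test_score_is_probability_times_100(self):
        m, y = self.separable()
        pred = predict_score(train_svm(m, y, seed=0), m)
        np.testing.assert_allclose(pred["score"], 100 * pred["probability"])
        assert ((pred["score"] >= 0) & (pred["score"] <= 100)).all()

    def test_boundary_call_is_neutral(self):
        # call is disease strictly above the cutoff
        m, y = self.separable()
        model = train_svm(m, y, seed=0)
        pred = predict_score(model, m, cutoff=100.0)
        assert (pred["call"] == "neutral").all()

    def test_row_order_invariance(self):
        m, y = self.separable(n=60, seed=3)
        model = train_svm(m, y, seed=1)
        pred = predict_score(model, m)
        perm = np.random.default_rng(0).permutation(m.n_savs)
        pred_perm = predict_score(model, m.select_rows(perm))
        np.testing.assert_allclose(
            pred["score"].to_numpy()[perm], pred_perm["score"].to_numpy()
        )

    def test_schema_superset_allowed_mismatch_rejected(self):
        m, y = self.separable(n=40)
        model = train_svm(m, y, seed=0)
        extra = FeatureMatrix(
            m.savs,
            m.feature_names + ["extra"],
            np.column_stack([m.values, np.zeros(m.n_savs)]),
            np.column_stack([m.missing_mask, np.zeros((m.n_savs, 1), bool)]),
        )
        predict_score(model, extra)  # superset schema is fine
        with pytest.raises(SchemaError):
            predict_score(model, m.select_features(["f0"]))

    def test_missing_values_imputed_with_training_mean(self):
        m, y = self.separable(n=40)
        model = train_svm(m, y, seed=0)
        values = m.values.copy()
        mask = m.missing_mask.copy()
        mask[0, :] = True
        holed = FeatureMatrix(m.savs, m.feature_names, values, mask)
        pred = predict_score(model, holed)
        assert np.isfinite(pred["score"]).all()

    def test_model_serialisation_roundtrip(self, tmp_path):
        m, y = self.separable(n=60)
        model = train_svm(m, y, seed=0)
        path = tmp_path / "model.bin"
        model.save(path)
        back = TrainedModel.load(path)
        np.testing.assert_allclose(
            predict_score(back, m)["score"], predict_score(model, m)["score"]
        )


class TestGridSearch:
    def test_single_candidate(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 20)
        X = rng.standard_normal((40, 2)) + y[:, None]
        m = make_matrix(X, labels=y)
        out = grid_search_cv(m, y, C_grid=[1.0], folds=4, seed=0)
        assert out["C"] == 1.0 and out["gamma"] > 0

    def test_degenerate_distances(self):
        X = np.ones((30, 3))
        with pytest.raises(DegenerateInputError):
            sigest_gamma(X, seed=0)

    def test_too_few_per_class_for_folds(self):
        rng = np.random.default_rng(1)
        y = np.array([1] * 3 + [0] * 37)
        m = make_matrix(rng.standard_normal((40, 2)), labels=y)
        with pytest.raises(DegenerateInputError):
            grid_search_cv(m, y, C_grid=[1.0], folds=10, seed=0)
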