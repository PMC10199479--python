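"""Metrics, nested cross-validation behaviour, and final-model training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from depp import (
    FeatureTable,
    ModelConfig,
    SchemaMismatchError,
    ValidationError,
    compute_metrics,
    final_rf_config,
    load_grid,
    metrics_from_predictions,
    nested_cv_evaluate,
    toy_feature_table,
    train_final_model,
)
from depp.model import build_pipeline

# a small, fast forest for harness-behaviour tests (the shipped 1500-tree
# configuration is exercised by the session-scoped final_model fixture)
FAST_RF = ModelConfig(
    algorithm="rf",
    hyperparameters={"n_estimators": 40, "criterion": "entropy"},
)


class TestComputeMetrics:
    def test_accuracy_is_fraction_of_correct_calls(self):
        metrics = compute_metrics(tp=45, fp=5, tn=45, fn=5)
        assert metrics.accuracy == pytest.approx(0.90)

    def test_recall_is_fraction_of_recovered_positives(self):
        metrics = compute_metrics(tp=9, fp=7, tn=13, fn=11)
        assert metrics.recall == pytest.approx(0.45)

    def test_recall_is_missing_not_zero_without_positives(self):
        metrics = compute_metrics(tp=0, fp=0, tn=10, fn=0)
        assert metrics.accuracy == 1.0
        assert metrics.recall is None
        assert metrics.rates["tnr"] == 1.0

    def test_zero_total_and_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            compute_metrics(0, 0, 0, 0)
        with pytest.raises(ValidationError):
            compute_metrics(-1, 0, 1, 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        pairs=st.lists(
            st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=1, max_size=60
        )
    )
    def test_matches_bruteforce_tally_over_labelled_predictions(self, pairs):
        """Oracle: walk the (truth, call) list and count the four outcomes."""
        y_true = [t for t, _ in pairs]
        y_pred = [p for _, p in pairs]
        tp = sum(1 for t, p in pairs if t == 1 and p == 1)
        fp = sum(1 for t, p in pairs if t == 0 and p == 1)
        tn = sum(1 for t, p in pairs if t == 0 and p == 0)
        fn = sum(1 for t, p in pairs if t == 1 and p == 0)
        metrics = metrics_from_predictions(y_true, y_pred)
        assert (metrics.tp, metrics.fp, metrics.tn, metrics.fn) == (tp, fp, tn, fn)
        assert metrics.accuracy == pytest.approx((tp + tn) / len(pairs))
        if tp + fn:
            assert metrics.recall == pytest.approx(tp / (tp + fn))
        else:
            assert metrics.recall is None


class TestNestedCV:
    def test_separable_table_is_learned_perfectly(self):
        table = toy_feature_table(n_pos=20, n_neg=20, seed=0, shift=10.0)
        result = nested_cv_evaluate(
            table, "rf", n_trials=2, n_splits=4, base_config=FAST_RF
        )
        assert result.mean_accuracy == 1.0
        assert result.mean_recall == 1.0
        assert len(result.fold_metrics) == 8

    def test_separable_table_also_learned_by_untuned_svm(self):
        table = toy_feature_table(n_pos=20, n_neg=20, seed=0, shift=10.0)
        result = nested_cv_evaluate(table, "svm", n_trials=1, n_splits=4)
        assert result.mean_accuracy == 1.0

    def test_signal_free_table_scores_at_chance(self):
        """Permutation-null: without class signal accuracy stays near 0.5,
        confirming outer test folds cannot leak into model selection."""
        table = toy_feature_table(n_pos=50, n_neg=50, seed=1, shift=0.0, n_features=16)
        result = nested_cv_evaluate(
            table, "rf", n_trials=20, n_splits=4, base_config=FAST_RF
        )
        assert len(result.fold_metrics) == 80
        assert abs(result.mean_accuracy - 0.5) <= 0.1

    def test_grid_search_reports_modal_parameters(self):
        table = toy_feature_table(n_pos=12, n_neg=12, seed=2, shift=10.0)
        grid = {"n_estimators": [10, 20], "max_depth": [3, None]}
        result = nested_cv_evaluate(
            table, "rf", grid=grid, n_trials=1, n_splits=3, base_config=FAST_RF
        )
        assert set(result.modal_params) == {"n_estimators", "max_depth"}
        assert all(len(p) == 2 for p in result.best_params_per_fold)

    def test_single_point_grid_skips_the_inner_search(self):
        table = toy_feature_table(n_pos=8, n_neg=8, seed=3, shift=10.0)
        result = nested_cv_evaluate(
            table, "rf", grid={"n_estimators": [15]}, n_trials=1, n_splits=2
        )
        assert result.best_params_per_fold[0]["n_estimators"] == 15

    def test_too_few_rows_per_class_is_instructive_error(self):
        table = toy_feature_table(n_pos=3, n_neg=3, seed=0)
        with pytest.raises(ValidationError, match="n_splits"):
            nested_cv_evaluate(table, "rf", n_trials=1, n_splits=4)

    def test_unlabelled_table_rejected(self):
        table = toy_feature_table(n_pos=4, n_neg=4, seed=0)
        unlabelled = FeatureTable(features=table.features)
        with pytest.raises(ValidationError):
            nested_cv_evaluate(unlabelled, "rf", n_trials=1, n_splits=2)

    def test_trial_seeding_makes_the_harness_fully_deterministic(self):
        table = toy_feature_table(n_pos=12, n_neg=12, seed=4, shift=0.5)
        first = nested_cv_evaluate(
            table, "rf", n_trials=3, n_splits=3, base_config=FAST_RF
        )
        second = nested_cv_evaluate(
            table, "rf", n_trials=3, n_splits=3, base_config=FAST_RF
        )
        assert [m.accuracy for m in first.fold_metrics] == [
            m.accuracy for m in second.fold_metrics
        ]

    def test_bundled_grids_have_expected_breadth(self):
        assert len(load_grid("svm", "full")) == 2
        full_rf = load_grid("rf", "full")[0]
        assert full_rf["n_estimators"] == list(range(100, 2001, 100))
        assert None in full_rf["max_depth"]
        with pytest.raises(ValidationError):
            load_grid("rf", "gigantic")


class TestModelConfig:
    def test_hyperparameter_keys_must_match_algorithm(self):
        with pytest.raises(ValidationError):
            ModelConfig(algorithm="svm", hyperparameters={"n_estimators": 10})
        with pytest.raises(ValidationError):
            ModelConfig(algorithm="rf", hyperparameters={"kernel": "rbf"})

    def test_shipped_final_configuration(self):
        config = final_rf_config()
        assert config.algorithm == "rf"
        hp = config.hyperparameters
        assert hp["n_estimators"] == 1500
        assert hp["max_depth"] == 30
        assert hp["min_samples_leaf"] == 3
        assert hp["criterion"] == "entropy"
        assert hp["max_features"] == "sqrt"
        assert config.preprocessing == ("polynomial", "minmax")

    def test_pipeline_applies_polynomial_then_minmax(self):
        pipeline = build_pipeline(final_rf_config())
        assert [name for name, _ in pipeline.steps] == [
            "polynomial", "minmax", "clf"
        ]


@pytest.fixture(scope="module")
def small_table():
    return toy_feature_table(n_pos=15, n_neg=15, seed=5, shift=2.0)


@pytest.fixture(scope="module")
def model(small_table):
    return train_final_model(small_table, FAST_RF)


class TestFinalModel:

    def test_probabilities_lie_in_unit_interval(self, model, small_table):
        proba = model.predict_proba(small_table)
        assert len(proba) == small_table.n
        assert np.all((proba >= 0) & (proba <= 1))
        assert proba[: small_table.labels.sum()].mean() > 0.5

    def test_same_seed_trains_identical_models(self, small_table):
        probe = toy_feature_table(n_pos=5, n_neg=5, seed=99, shift=2.0)
        a = train_final_model(small_table, FAST_RF).predict_proba(probe)
        b = train_final_model(small_table, FAST_RF).predict_proba(probe)
        np.testing.assert_array_equal(a, b)

    def test_serialization_round_trip_preserves_predictions(
        self, model, small_table, tmp_path
    ):
        from depp import TrainedModel

        path = tmp_path / "model.bin"
        model.save(path)
        loaded = TrainedModel.load(path)
        np.testing.assert_array_equal(
            loaded.predict_proba(small_table), model.predict_proba(small_table)
        )
        assert loaded.feature_names == model.feature_names
        assert loaded.training_hash == model.training_hash

    def test_schema_mismatch_names_first_bad_column(self, model, small_table):
        shuffled = small_table.features[list(small_table.features.columns[::-1])]
        with pytest.raises(SchemaMismatchError, match="f023"):
            model.predict_proba(shuffled)

    def test_duplicate_rows_score_identically(self, model, small_table):
        twice = small_table.features.iloc[[0, 0]]
        proba = model.predict_proba(twice)
        assert proba[0] == proba[1]

    def test_empty_table_gives_empty_output(self, model, small_table):
        empty = small_table.features.iloc[:0]
        assert model.predict_proba(empty).size == 0

    def test_single_class_table_rejected(self):
        table = toy_feature_table(n_pos=6, n_neg=6, seed=6)
        positives_only = FeatureTable(
            features=table.features.iloc[:6], labels=[1] * 6
        )
        with pytest.raises(ValidationError):
            train_final_model(positives_only, FAST_RF)

    def test_importance_recovers_the_driving_dipeptide_feature(self):
        """When class is a threshold on one grouped-dipeptide frequency,
        that feature tops the forest's importance ranking (no polynomial
        expansion, so importances align with the input descriptors)."""
        rng = np.random.default_rng(12)
        from depp import feature_names
        import pandas as pd

        names = list(feature_names())
        X = pd.DataFrame(
            rng.random((60, len(names))),
            index=[f"r{i}" for i in range(60)],
            columns=names,
        )
        driver = names.index("15")
        labels = (X.iloc[:, driver] > 0.5).astype(int).to_numpy()
        table = FeatureTable(features=X, labels=labels)
        config = ModelConfig(
            algorithm="rf",
            hyperparameters={"n_estimators": 200, "criterion": "entropy"},
            preprocessing=("minmax",),
        )
        model = train_final_model(table, config)
        importances = model.pipeline.named_steps["clf"].feature_importances_
        assert int(np.argmax(importances)) == driver
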