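"""Risk model: preprocessing contract, LOOCV tuning, OCRI bounds, benchmarking."""

import numpy as np
import pytest

from ocri.amplify import FeatureVector, transform_cohort
from ocri.exceptions import ValidationError
from ocri.io import FeatureMatrix
from ocri.model import (
    MODEL_NAMES,
    benchmark_models,
    compute_ocri,
    fit_preprocessing,
    score_matrix,
    stratify_cohort,
    tune_and_train_svm,
)
from ocri.synthetic import default_profiles, simulate_case


class TestPreprocessing:
    def test_train_medians_become_zero(self, separable_matrix):
        prep = fit_preprocessing(separable_matrix)
        x = prep.transform(separable_matrix.values)
        assert np.allclose(np.median(x, axis=0), 0.0, atol=1e-12)

    def test_constant_column_floored(self):
        values = np.full((6, 16), 0.25)
        values[:3, 0] = 0.1  # one informative column, rest constant
        m = FeatureMatrix(
            [f"c{i}" for i in range(6)], ["normal"] * 3 + ["oscc"] * 3, values
        )
        prep = fit_preprocessing(m)
        assert np.all(prep.scale >= 1e-8)
        x = prep.transform(values)
        assert np.allclose(x[:, 1:], 0.0)

    def test_frozen_parameters_apply_to_new_data(self, separable_matrix):
        prep = fit_preprocessing(separable_matrix)
        probe = separable_matrix.values[:5] + 0.3
        expected = (probe - prep.center) / prep.scale
        assert np.array_equal(prep.transform(probe), expected)

    def test_single_class_rejected(self):
        m = FeatureMatrix(["a", "b"], ["normal", "normal"], np.full((2, 16), 0.1))
        with pytest.raises(ValidationError, match="single class"):
            fit_preprocessing(m)


class TestTuneAndTrain:
    def test_nine_cost_grid_searched(self, trained_model):
        assert len(trained_model.cost_grid) == 9
        assert trained_model.cost_grid[0] == 0.25
        assert trained_model.cost_grid[-1] == 64.0
        assert set(trained_model.loocv_accuracy) == set(trained_model.cost_grid)
        assert trained_model.cost in trained_model.cost_grid

    def test_separable_data_reaches_perfect_training_accuracy(
        self, separable_matrix
    ):
        model = tune_and_train_svm(separable_matrix, seed=0)
        assert max(model.loocv_accuracy.values()) == 1.0

    def test_determinism(self, separable_matrix):
        a = tune_and_train_svm(separable_matrix, seed=1)
        b = tune_and_train_svm(separable_matrix, seed=1)
        assert a.cost == b.cost and a.sigma == b.sigma
        probe = separable_matrix
        assert np.array_equal(score_matrix(a, probe), score_matrix(b, probe))

    def test_too_few_cases_rejected(self):
        m = FeatureMatrix(
            [f"c{i}" for i in range(6)],
            ["normal"] * 3 + ["oscc"] * 3,
            np.full((6, 16), 0.1),
        )
        with pytest.raises(ValidationError, match=">= 10"):
            tune_and_train_svm(m, seed=0)

    def test_non_training_labels_rejected(self):
        m = FeatureMatrix(
            [f"c{i}" for i in range(12)],
            ["normal"] * 6 + ["olk"] * 6,
            np.full((12, 16), 0.1),
        )
        with pytest.raises(ValidationError):
            tune_and_train_svm(m, seed=0)


class TestOCRI:
    def test_bounds_on_fuzz_inputs(self, trained_model):
        rng = np.random.default_rng(8)
        fuzz = FeatureMatrix(
            [f"f{i}" for i in range(10_000)],
            ["unknown"] * 10_000,
            rng.uniform(0.0001, 1.0, (10_000, 16)),
        )
        scores = score_matrix(trained_model, fuzz)
        assert np.all((scores >= 0.0) & (scores <= 1.0))

    def test_wrong_length_rejected(self, trained_model):
        fv = FeatureVector(bins=np.full(16, 0.1), case_id="x")
        fv.bins = np.full(4, 0.1)  # corrupt after construction
        with pytest.raises(ValidationError):
            compute_ocri(trained_model, fv)

    def test_oscc_profile_cases_score_high(self, trained_model):
        profile = default_profiles()["oscc"]
        cases = [
            simulate_case(profile.spec(800, seed=200 + k), case_id=f"p{k}")
            for k in range(20)
        ]
        vectors, skipped = transform_cohort(cases, seed=77)
        assert not skipped
        high = sum(compute_ocri(trained_model, v).ocri > 0.5 for v in vectors)
        assert high >= 18

    def test_normal_centroid_scores_low(self, trained_model, two_class_features):
        labels = np.array(two_class_features.labels)
        centroid = two_class_features.values[labels == "normal"].mean(axis=0)
        fv = FeatureVector(bins=np.maximum(centroid, 0.0001), case_id="centroid")
        assert compute_ocri(trained_model, fv).ocri < 0.5

    def test_training_normals_mostly_below_threshold(
        self, trained_model, two_class_features
    ):
        table = stratify_cohort(trained_model, two_class_features)
        normals = table[table["label"] == "normal"]
        assert (normals["ocri"] < 0.5).mean() >= 0.9

    def test_stratify_sorted_and_empty(self, trained_model):
        empty = FeatureMatrix([], [], np.empty((0, 16)))
        table = stratify_cohort(trained_model, empty)
        assert len(table) == 0


@pytest.fixture(scope="module")
def report(separable_matrix):
    return benchmark_models(separable_matrix, seed=4)


class TestBenchmark:
    def test_shape_six_models_fifty_resamples(self, report):
        assert report.n_resamples == 50
        assert set(report.records["model"]) == set(MODEL_NAMES)
        assert len(report.records) == 6 * 50
        assert {"roc", "sensitivity", "specificity"} <= set(report.records.columns)
        assert report.records[["roc", "sensitivity", "specificity"]].le(1).all().all()

    def test_separable_cohort_is_learned(self, report):
        assert report.medians.loc["svm", "roc"] >= 0.95

    def test_determinism_and_identical_folds(self, separable_matrix, report):
        again = benchmark_models(separable_matrix, seed=4)
        assert report.records.equals(again.records)
        for a, b in zip(report.fold_test_indices, again.fold_test_indices):
            assert np.array_equal(a, b)

    def test_label_permutation_null(self, separable_matrix):
        rng = np.random.default_rng(10)
        labels = list(separable_matrix.labels)
        rng.shuffle(labels)
        shuffled = FeatureMatrix(
            separable_matrix.case_ids, labels, separable_matrix.values
        )
        report = benchmark_models(shuffled, seed=10)
        for model in MODEL_NAMES:
            assert 0.35 <= report.medians.loc[model, "roc"] <= 0.65

    def test_too_small_inputs_rejected(self):
        m = FeatureMatrix(
            [f"c{i}" for i in range(20)],
            ["normal"] * 10 + ["oscc"] * 10,
            np.full((20, 16), 0.1),
        )
        with pytest.raises(ValidationError, match=">= 40"):
            benchmark_models(m, seed=0)
        m2 = FeatureMatrix(
            [f"c{i}" for i in range(45)],
            ["normal"] * 40 + ["oscc"] * 5,
            np.full((45, 16), 0.1),
        )
        with pytest.raises(ValidationError, match="fewer than 10"):
            benchmark_models(m2, seed=0)
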