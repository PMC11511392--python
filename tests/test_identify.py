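"""Splitting, SVM training and experiment aggregation."""

import numpy as np
import pytest

from physioid.features import FeatureMatrix
from physioid.fusion import FusionConfig
from physioid.identify import (ConfusionCounts, ExperimentDesign, SvmConfig,
                               SvmModel, evaluate, run_experiment,
                               split_dataset, train_svm)

FAST_SVM = SvmConfig(C_grid=(1.0, 100.0), gamma_grid=(0.01, 0.1), cv_folds=3)


class TestSplit:
    def test_seven_three_split_counts(self):
        labels = np.repeat(np.arange(25), 20)
        train, test = split_dataset(labels, ratio=0.7, seed=0)
        assert train.size == 350 and test.size == 150
        counts = np.bincount(labels[test])
        assert np.all(counts == 6)
        assert np.intersect1d(train, test).size == 0

    def test_deterministic_per_seed(self):
        labels = np.repeat(np.arange(5), 10)
        a = split_dataset(labels, seed=3)
        b = split_dataset(labels, seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        c = split_dataset(labels, seed=4)
        assert not np.array_equal(a[1], c[1])

    def test_degenerate_ratio_rejected(self):
        labels = np.repeat([0, 1], 5)
        with pytest.raises(ValueError, match="ratio"):
            split_dataset(labels, ratio=1.0)

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            split_dataset(np.array([0, 0, 1]), ratio=0.5)


class _Stub:
    """Duck-typed predictor for evaluating the confusion arithmetic."""

    def __init__(self, outputs):
        self.outputs = np.asarray(outputs)
        self.n_features = 1

    def predict(self, X):
        return self.outputs


class TestEvaluate:
    def test_all_correct_gives_unit_accuracy(self):
        y = np.array([0, 0, 1, 1, 2])
        counts, acc = evaluate(_Stub(y), np.zeros((5, 1)), y)
        assert acc == 1.0
        assert counts.per_class[0] == {"tp": 2, "fp": 0, "fn": 0, "tn": 3}

    def test_all_wrong_gives_zero_accuracy(self):
        y = np.zeros(10, dtype=int)
        counts, acc = evaluate(_Stub(np.ones(10, dtype=int)), np.zeros((10, 1)), y)
        assert acc == 0.0
        assert counts.per_class[1]["fp"] == 10

    def test_per_class_counts_sum_to_test_size(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 4, size=40)
        pred = rng.integers(0, 4, size=40)
        counts, _ = evaluate(_Stub(pred), np.zeros((40, 1)), y)
        for c, d in counts.per_class.items():
            assert d["tp"] + d["fp"] + d["fn"] + d["tn"] == 40

    def test_balanced_accuracy_identity(self):
        """With balanced classes, pooled accuracy equals the mean of the
        per-class recalls."""
        rng = np.random.default_rng(1)
        y = np.repeat(np.arange(4), 25)
        pred = np.where(rng.random(100) < 0.3, rng.integers(0, 4, 100), y)
        counts, acc = evaluate(_Stub(pred), np.zeros((100, 1)), y)
        recalls = [d["tp"] / (d["tp"] + d["fn"])
                   for d in counts.per_class.values()]
        assert acc == pytest.approx(np.mean(recalls))


class TestTrainSvm:
    def test_separable_classes_fit_perfectly(self, rng):
        X = np.vstack([rng.normal(size=(30, 3)),
                       rng.normal(size=(30, 3)) + 10.0])
        y = np.repeat([0, 1], 30)
        model = train_svm(X, y, FAST_SVM)
        assert np.mean(model.predict(X) == y) == 1.0
        assert "C" in model.best_params

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            train_svm(rng.normal(size=(10, 2)), np.zeros(10), FAST_SVM)

    def test_dimension_mismatch_rejected(self, rng):
        X = np.vstack([rng.normal(size=(20, 3)),
                       rng.normal(size=(20, 3)) + 5.0])
        model = train_svm(X, np.repeat([0, 1], 20), FAST_SVM)
        with pytest.raises(ValueError, match="dimension"):
            model.predict(rng.normal(size=(5, 4)))


def _toy_matrices(rng, n_subjects=4, windows=10, d=6, sep=4.0):
    y = np.repeat(np.arange(n_subjects), windows)
    mats = {}
    for m in ("ECG", "PPG", "RESP"):
        centers = rng.normal(scale=sep, size=(n_subjects, d))
        X = centers[y] + rng.normal(size=(y.size, d))
        mats[m] = FeatureMatrix(X, y, [f"f{i}" for i in range(d)],
                                window_ids=np.tile(np.arange(windows), n_subjects))
    return mats


class TestRunExperiment:
    FUSION = FusionConfig(pca_k=4, lda_k=3, mcca_k=3)

    def test_single_repeat_mean_identity(self, rng):
        mats = _toy_matrices(rng)
        res = run_experiment(mats, ExperimentDesign("single", ("ECG",)),
                             n_repeats=1, seed=0, svm=FAST_SVM)
        assert res.mean_accuracy == res.per_repeat_accuracy[0]

    def test_mean_recomputable_from_repeats(self, rng):
        mats = _toy_matrices(rng)
        res = run_experiment(mats, ExperimentDesign("tri", ("ECG", "PPG", "RESP"),
                                                    "mcca"),
                             n_repeats=3, seed=0, svm=FAST_SVM, fusion=self.FUSION)
        assert res.mean_accuracy == pytest.approx(
            np.mean(res.per_repeat_accuracy))
        assert len(res.seeds) == 3
        assert all(0 <= a <= 1 for a in res.per_subject_accuracy.values())

    def test_deterministic_given_seed(self, rng):
        mats = _toy_matrices(rng)
        d = ExperimentDesign("dual", ("ECG", "PPG"), "serial")
        r1 = run_experiment(mats, d, n_repeats=2, seed=5, svm=FAST_SVM)
        r2 = run_experiment(mats, d, n_repeats=2, seed=5, svm=FAST_SVM)
        assert r1.per_repeat_accuracy == r2.per_repeat_accuracy

    @pytest.mark.parametrize("method", ["serial", "parallel", "cca", "pca+cca"])
    def test_dual_methods_run(self, rng, method):
        mats = _toy_matrices(rng)
        res = run_experiment(mats, ExperimentDesign("dual", ("ECG", "PPG"), method),
                             n_repeats=1, seed=1, svm=FAST_SVM, fusion=self.FUSION)
        assert 0.0 <= res.mean_accuracy <= 1.0

    def test_label_relabeling_symmetry(self, rng):
        mats = _toy_matrices(rng)
        res1 = run_experiment(mats, ExperimentDesign("single", ("ECG",)),
                              n_repeats=2, seed=2, svm=FAST_SVM)
        relabeled = {
            m: FeatureMatrix(fm.X, fm.labels + 100, fm.feature_names,
                             fm.window_ids)
            for m, fm in mats.items()
        }
        res2 = run_experiment(relabeled, ExperimentDesign("single", ("ECG",)),
                              n_repeats=2, seed=2, svm=FAST_SVM)
        assert res1.per_repeat_accuracy == res2.per_repeat_accuracy

    def test_missing_modality_rejected(self, rng):
        mats = _toy_matrices(rng)
        del mats["RESP"]
        with pytest.raises(ValueError, match="RESP"):
            run_experiment(mats, ExperimentDesign("tri", ("ECG", "PPG", "RESP"),
                                                  "mcca"), n_repeats=1)

    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ExperimentDesign("dual", ("ECG", "PPG"), "averaging")


def test_synthetic_cohort_identifiable_single_modality(small_matrices):
    """Even one modality identifies the small cohort far above chance."""
    res = run_experiment(small_matrices, ExperimentDesign("single", ("ECG",)),
                         n_repeats=2, seed=0, svm=FAST_SVM)
    assert res.mean_accuracy > 0.8
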