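import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from drsmargin.errors import UndefinedMetricError
from drsmargin.models import (
    compute_auc,
    cross_validate,
    design_matrix,
    evaluate,
    make_patient_folds,
    train_classifier,
)
from drsmargin.preprocessing import WavelengthGrid, preprocess_set
from drsmargin.synthetic import SyntheticDatasetSpec, generate_dataset


def brute_force_auc(scores, labels):
    """Exhaustive pairwise concordance probability, ties counted half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestPatientFolds:
    def test_ten_patients_partition_into_five_disjoint_pairs(self):
        pats = np.repeat([f"P{i}" for i in range(10)], 7)
        labs = np.where(np.arange(70) % 2 == 0, "normal", "tumour")
        fa = make_patient_folds(pats, labs, k=5, seed=0)
        per_fold = {}
        for p, f in fa.patient_to_fold.items():
            per_fold.setdefault(f, set()).add(p)
        assert len(per_fold) == 5
        assert all(len(v) == 2 for v in per_fold.values())
        all_patients = set().union(*per_fold.values())
        assert len(all_patients) == 10  # pairwise disjoint

    def test_fewer_patients_than_folds_rejected(self):
        pats = np.repeat(["A", "B", "C", "D"], 5)
        with pytest.raises(ValueError):
            make_patient_folds(pats, ["normal"] * 20, k=5)

    def test_balanced_patients_give_near_global_class_fractions(self):
        rng = np.random.default_rng(0)
        pats = np.repeat([f"P{i:02d}" for i in range(20)], 40)
        labs = np.tile(np.array(["normal", "tumour"]).repeat(20), 20)
        fa = make_patient_folds(pats, labs, k=5, seed=1)
        global_frac = np.mean(labs == "tumour")
        for f in range(5):
            idx = fa.test_indices(f)
            frac = np.mean(labs[idx] == "tumour")
            assert abs(frac - global_frac) <= 0.1

    def test_every_spectrum_assigned_exactly_once(self):
        pats = np.repeat([f"P{i}" for i in range(8)], 11)
        fa = make_patient_folds(pats, ["tumour"] * 88, k=5, seed=2)
        counts = np.zeros(88, dtype=int)
        for f in range(5):
            counts[fa.test_indices(f)] += 1
        assert np.all(counts == 1)


class TestTrainClassifier:
    def _data(self, seed=0, n=80, d=12):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, d))
        y = rng.integers(0, 2, n)
        X[y == 1, 0] += 2.0
        return X, y

    def test_unknown_kind_rejected(self):
        X, y = self._data()
        with pytest.raises(ValueError, match="cnn2d"):
            train_classifier("cnn2d", X, y)

    def test_single_class_training_rejected(self):
        X, _ = self._data()
        with pytest.raises(ValueError):
            train_classifier("rf", X, np.ones(len(X), dtype=int))

    @pytest.mark.parametrize("kind", ["rf", "xgb", "lgbm", "mlp", "svm"])
    def test_baselines_fit_and_expose_probabilities(self, kind):
        X, y = self._data()
        model = train_classifier(kind, X, y, seed=0)
        p = model.predict_proba(X)
        assert p.shape == (len(X), 2)

    @pytest.mark.parametrize("kind", ["rf", "lgbm"])
    def test_same_seed_same_probabilities(self, kind):
        X, y = self._data(seed=5)
        a = train_classifier(kind, X, y, seed=7).predict_proba(X)
        b = train_classifier(kind, X, y, seed=7).predict_proba(X)
        np.testing.assert_array_equal(a, b)


class TestMetrics:
    def test_auc_example_three_of_four_pairs_concordant(self):
        assert compute_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation_auc_one(self):
        assert compute_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_single_class_auc_undefined(self):
        with pytest.raises(UndefinedMetricError):
            compute_auc([0.1, 0.2], [1, 1])

    def test_accuracy_nine_of_ten(self):
        class Fixed:
            def predict_proba(self, X):
                p = np.array([0.9] * 5 + [0.1] * 4 + [0.9])
                return np.column_stack([1 - p, p])

        y = np.array([1] * 5 + [0] * 5)
        rep = evaluate(Fixed(), np.zeros((10, 1)), y)
        assert rep.accuracy == pytest.approx(0.9)
        assert rep.sensitivity == pytest.approx(1.0)
        assert rep.specificity == pytest.approx(0.8)

    def test_metrics_bounded(self):
        rng = np.random.default_rng(0)

        class Rand:
            def predict_proba(self, X):
                p = rng.uniform(size=len(X))
                return np.column_stack([1 - p, p])

        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        rep = evaluate(Rand(), np.zeros((50, 1)), y)
        for v in (rep.accuracy, rep.sensitivity, rep.specificity, rep.auc):
            assert 0.0 <= v <= 1.0

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(
        scores=st.lists(
            st.floats(0, 1, allow_nan=False, width=16), min_size=2, max_size=30
        ),
        seed=st.integers(0, 1000),
    )
    def test_auc_equals_pairwise_concordance(self, scores, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, len(scores))
        if labels.sum() in (0, len(labels)):
            labels[0], labels[-1] = 0, 1
        auc = compute_auc(np.array(scores), labels)
        assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)


@pytest.fixture(scope="module")
def processed_study():
    ds = generate_dataset(
        SyntheticDatasetSpec(n_patients=10, spectra_per_class_per_patient=15, seed=21),
        WavelengthGrid(445, 1005, 700),
    )
    processed, _ = preprocess_set(ds, grid=WavelengthGrid(450, 1000, 500))
    return design_matrix(processed, "intensities")


class TestCrossValidation:
    def test_no_patient_leakage_in_any_fold(self, processed_study):
        X, y, patients = processed_study
        fa = make_patient_folds(patients, y.astype(str), k=5, seed=0)
        for f in range(5):
            tr = set(patients[fa.train_indices(f)])
            te = set(patients[fa.test_indices(f)])
            assert not tr & te

    def test_rf_separates_default_contrast(self, processed_study):
        X, y, patients = processed_study
        reports = cross_validate(X, y, patients, kinds=["rf"], k=5, seed=0)
        assert reports["rf"].auc >= 0.95
        lo, hi = reports["rf"].ci["auc"]
        assert lo <= reports["rf"].auc <= hi

    def test_permuted_labels_give_chance_auc(self, processed_study):
        X, y, patients = processed_study
        rng = np.random.default_rng(0)
        y_perm = rng.permutation(y)
        reports = cross_validate(X, y_perm, patients, kinds=["rf"], k=5, seed=0)
        assert 0.35 <= reports["rf"].auc <= 0.65

    def test_summary_mentions_all_metrics(self, processed_study):
        X, y, patients = processed_study
        rep = cross_validate(X, y, patients, kinds=["rf"], k=5, seed=0)["rf"]
        text = rep.summary()
        for word in ("accuracy", "sensitivity", "specificity", "auc", "confusion"):
            assert word in text
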