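import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import msfa_design as m
from msfa_design.merit_classify import (
    ClassifierSpec,
    FeatureTable,
    ModelError,
    UndefinedAngleError,
    class_mean_references,
    stratified_folds,
)


def table(X, labels, patients=None, class_names=None):
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if patients is None:
        patients = np.array(["P0"] * len(labels), dtype=object)
    if class_names is None:
        class_names = tuple(dict.fromkeys(labels))
    return FeatureTable(X, labels, np.asarray(patients, dtype=object), class_names)


class TestKnn:
    def test_duplicate_point_k1(self):
        train = table([[0.0], [1.0], [2.0]], ["A", "B", "C"])
        test = table([[1.0]], ["B"])
        res = m.knn_classify(train, test, k=1)
        assert res.predicted[0] == "B" and res.accuracy == 1.0

    def test_three_of_five_majority(self):
        train = table([[0.0]] * 3 + [[1.0]] * 2, ["A"] * 3 + ["B"] * 2)
        test = table([[0.4]], ["A"])
        res = m.knn_classify(train, test, k=5)
        assert res.predicted[0] == "A"

    def test_k_equals_train_size_votes_globally(self):
        train = table([[0.0], [0.1], [5.0]], ["A", "A", "B"])
        test = table([[4.9], [10.0]], ["B", "B"])
        res = m.knn_classify(train, test, k=3)
        assert list(res.predicted) == ["A", "A"]

    def test_empty_train_raises(self):
        train = table(np.zeros((0, 1)), [])
        test = table([[0.0]], ["A"], class_names=("A",))
        with pytest.raises(ModelError):
            m.knn_classify(train, test, k=1)

    def test_training_set_self_accuracy_is_one(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(30, 3))
        labels = np.array(list("ABC") * 10, dtype=object)
        t = table(X, labels)
        assert m.knn_classify(t, t, k=1).accuracy == 1.0

    def test_matches_brute_force_oracle(self):
        """Independent distance-sort implementation on random points."""
        rng = np.random.default_rng(42)
        Xtr = rng.uniform(size=(50, 4))
        ytr = rng.choice(["A", "B", "C"], size=50)
        Xte = rng.uniform(size=(25, 4))
        train = table(Xtr, ytr, class_names=("A", "B", "C"))
        test = table(Xte, np.array(["A"] * 25), class_names=("A", "B", "C"))
        k = 5
        got = m.knn_classify(train, test, k=k).predicted
        order = {c: i for i, c in enumerate(("A", "B", "C"))}
        for i in range(25):
            d = np.sqrt(((Xtr - Xte[i]) ** 2).sum(axis=1))
            nn = np.argsort(d, kind="stable")[:k]
            votes = {}
            for j in nn:
                votes.setdefault(ytr[j], []).append(d[j])
            want = min(votes, key=lambda c: (-len(votes[c]),
                                             float(np.mean(votes[c])), order[c]))
            assert got[i] == want


class TestSvm:
    def test_separable_clouds_classify_perfectly(self):
        rng = np.random.default_rng(1)
        Xa = rng.normal(0.0, 0.05, size=(40, 2))
        Xb = rng.normal(5.0, 0.05, size=(40, 2))
        train = table(np.vstack([Xa[:30], Xb[:30]]), ["A"] * 30 + ["B"] * 30)
        test = table(np.vstack([Xa[30:], Xb[30:]]), ["A"] * 10 + ["B"] * 10)
        assert m.svm_classify(train, test).accuracy == 1.0

    def test_train_on_test_beats_majority(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(60, 3))
        y = np.array(["A"] * 40 + ["B"] * 20, dtype=object)
        t = table(X, y)
        res = m.svm_classify(t, t)
        assert res.accuracy >= 40 / 60

    def test_refit_is_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(size=(40, 2))
        y = np.array(["A", "B"] * 20, dtype=object)
        t = table(X, y)
        a = m.svm_classify(t, t).predicted
        b = m.svm_classify(t, t).predicted
        assert list(a) == list(b)

    def test_single_class_raises(self):
        t = table([[0.0], [1.0]], ["A", "A"])
        with pytest.raises(ModelError):
            m.svm_classify(t, t)


class TestSamAngle:
    def test_self_angle_zero(self):
        v = np.array([0.3, 0.5, 0.9])
        # arccos loses ~sqrt(eps) precision at its endpoint
        assert m.sam_angle(v, v) == pytest.approx(0.0, abs=1e-7)

    def test_orthogonal_is_half_pi(self):
        assert m.sam_angle([1.0, 0.0], [0.0, 1.0]) == pytest.approx(np.pi / 2)

    def test_45_degrees(self):
        assert m.sam_angle([1.0, 1.0], [1.0, 0.0]) == pytest.approx(np.pi / 4)

    def test_zero_vector_raises(self):
        with pytest.raises(UndefinedAngleError):
            m.sam_angle([0.0, 0.0], [1.0, 0.0])

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.01, max_value=10.0), min_size=3, max_size=8),
        st.lists(st.floats(min_value=0.01, max_value=10.0), min_size=3, max_size=8),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_invariance(self, t, r, a):
        n = min(len(t), len(r))
        t, r = np.array(t[:n]), np.array(r[:n])
        assert m.sam_angle(t, a * r) == pytest.approx(m.sam_angle(t, r), abs=1e-7)


class TestSamClassify:
    def test_exact_reference_copies_are_perfect(self):
        refs = {"A": np.array([1.0, 0.0, 0.0]),
                "B": np.array([0.0, 1.0, 0.0]),
                "C": np.array([1.0, 1.0, 0.5])}
        X = np.array([refs[c] for c in "ABCABC"])
        test = table(X, list("ABCABC"), class_names=("A", "B", "C"))
        assert m.sam_classify(refs, test).accuracy == 1.0

    def test_scale_invariant_classification(self):
        refs = {"A": np.array([1.0, 0.2]), "B": np.array([0.2, 1.0])}
        X = 7.0 * np.array([refs["A"], refs["B"]])
        test = table(X, ["A", "B"], class_names=("A", "B"))
        assert m.sam_classify(refs, test).accuracy == 1.0

    def test_tie_resolves_to_first_class(self):
        refs = {"A": np.array([1.0, 1.0]), "B": np.array([1.0, 1.0])}
        test = table([[2.0, 2.0]], ["B"], class_names=("A", "B"))
        assert m.sam_classify(refs, test).predicted[0] == "A"

    def test_class_mean_references(self):
        t = table([[0.0, 1.0], [2.0, 3.0], [10.0, 10.0]], ["A", "A", "B"])
        refs = class_mean_references(t)
        np.testing.assert_allclose(refs["A"], [1.0, 2.0])
        np.testing.assert_allclose(refs["B"], [10.0, 10.0])


class TestAccuracyAndCi:
    def test_fraction_correct(self):
        assert m.accuracy(["A", "B", "B", "A"], ["A", "B", "B", "B"]) == 0.75
        assert m.accuracy(["A"], ["A"]) == 1.0
        assert m.accuracy(["A"], ["B"]) == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            m.accuracy(["A"], ["A", "B"])

    def test_equal_patient_means_zero_halfwidth(self):
        vals = [0.8, 0.8, 0.8, 0.8]
        pats = ["P1", "P1", "P2", "P2"]
        mean, hw = m.per_patient_ci(vals, pats)
        assert mean == pytest.approx(0.8)
        assert hw == pytest.approx(0.0)

    def test_two_patient_textbook_value(self):
        # patient means 0.8 and 0.9: t_{0.975,1} * sd / sqrt(2)
        # = 12.7062 * 0.070711 / 1.41421 = 0.63531
        mean, hw = m.per_patient_ci([0.8, 0.9], ["P1", "P2"])
        assert mean == pytest.approx(0.85)
        assert hw == pytest.approx(0.6353, abs=2e-4)

    def test_degenerate_level(self):
        mean, hw = m.per_patient_ci([0.8, 0.9], ["P1", "P2"], level=0)
        assert hw == 0.0

    def test_single_patient_raises(self):
        with pytest.raises(ModelError):
            m.per_patient_ci([0.5, 0.6], ["P1", "P1"])

    def test_within_patient_averaging(self):
        # P1 items average to 0.5, P2 to 1.0 -> mean of means 0.75
        mean, _ = m.per_patient_ci([0.0, 1.0, 1.0, 1.0], ["P1", "P1", "P2", "P2"])
        assert mean == pytest.approx(0.75)


def test_stratified_folds_partition_and_balance():
    labels = ["A"] * 50 + ["B"] * 25
    folds = stratified_folds(labels, n_folds=5, rng_seed=0)
    assert len(folds) == 5
    all_test = np.concatenate([te for _, te in folds])
    assert sorted(all_test) == list(range(75))
    for tr, te in folds:
        te_labels = np.asarray(labels, dtype=object)[te]
        assert np.sum(te_labels == "A") == 10
        assert np.sum(te_labels == "B") == 5


def test_accuracy_bounds_on_real_features(small_dataset, fs3):
    train, test = m.split_train_test(small_dataset, rng_seed=0)
    tr = FeatureTable.from_dataset(train, fs3)
    te = FeatureTable.from_dataset(test, fs3)
    for res in (
        m.knn_classify(tr, te, k=5),
        m.svm_classify(tr, te),
        m.sam_classify(class_mean_references(tr), te),
    ):
        assert 0.0 <= res.accuracy <= 1.0
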