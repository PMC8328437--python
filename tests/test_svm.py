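import numpy as np
import pytest

from morphsvm.svm import (
    ModelConfigError,
    ModelIOError,
    ModelStateError,
    PairwiseLinearSVM,
    fit_platt,
    load_model,
    n_binary_learners,
    one_vs_one_coding,
    pairwise_coupling,
    save_model,
)


def make_blobs(rng, n_classes=3, n_per_class=20, dim=2, spread=0.3, sep=4.0):
    """Well-separated Gaussian clouds, one per class."""
    X, y = [], []
    for c in range(n_classes):
        angle = 2 * np.pi * c / n_classes
        center = sep * np.array([np.cos(angle), np.sin(angle)])
        center = np.concatenate([center, np.zeros(dim - 2)])
        X.append(center + spread * rng.normal(size=(n_per_class, dim)))
        y += [f"class{c}"] * n_per_class
    return np.vstack(X), np.array(y)


class TestCoding:
    @pytest.mark.parametrize("n, expected", [(2, 1), (3, 3), (5, 10)])
    def test_learner_count(self, n, expected):
        assert n_binary_learners(n) == expected

    def test_fewer_than_two_classes_rejected(self):
        with pytest.raises(ModelConfigError):
            n_binary_learners(1)

    def test_coding_matrix_columns(self):
        M = one_vs_one_coding(4)
        assert M.shape == (4, 6)
        for col in M.T:
            assert (col == 1).sum() == 1 and (col == -1).sum() == 1
            assert (col == 0).sum() == 2


class TestFit:
    def test_separable_training_accuracy(self, rng):
        X, y = make_blobs(rng, n_classes=2)
        clf = PairwiseLinearSVM().fit(X, y)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_five_classes_ten_learners(self, rng):
        X, y = make_blobs(rng, n_classes=5)
        clf = PairwiseLinearSVM().fit(X, y)
        assert clf.weights_.shape == (10, 2)
        assert clf.coding_.shape == (5, 10)

    def test_sample_order_irrelevant(self, rng):
        X, y = make_blobs(rng, n_classes=3)
        perm = rng.permutation(len(y))
        a = PairwiseLinearSVM().fit(X, y)
        b = PairwiseLinearSVM().fit(X[perm], y[perm])
        T, _ = make_blobs(np.random.default_rng(5), n_classes=3)
        assert np.array_equal(a.predict(T), b.predict(T))

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ModelConfigError):
            PairwiseLinearSVM().fit(X, np.array(["a"] * 10))

    def test_dimension_mismatch_rejected(self, rng):
        X, y = make_blobs(rng)
        clf = PairwiseLinearSVM().fit(X, y)
        with pytest.raises(ModelConfigError, match="dimension"):
            clf.predict(np.zeros((1, 5)))


class TestPredict:
    def test_two_class_equals_decision_sign(self, rng):
        X, y = make_blobs(rng, n_classes=2)
        clf = PairwiseLinearSVM().fit(X, y)
        T = rng.normal(scale=3.0, size=(50, 2))
        d = clf.decision_function(T)[:, 0]
        # column 0: +1 = classes_[0], -1 = classes_[1]
        expected = np.where(d >= 0, clf.classes_[0], clf.classes_[1])
        assert np.array_equal(clf.predict(T), expected)

    def test_vote_tally_matches_pairwise_replay(self, rng):
        X, y = make_blobs(rng, n_classes=4, n_per_class=15)
        clf = PairwiseLinearSVM().fit(X, y)
        T = rng.normal(scale=3.0, size=(100, 2))
        D = clf.decision_function(T)
        pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        preds = clf.predict(T)
        for s in range(len(T)):
            votes = np.zeros(4)
            for col, (i, j) in enumerate(pairs):
                votes[i if D[s, col] >= 0 else j] += 1
            top = votes.max()
            winners = {clf.classes_[k] for k in np.flatnonzero(votes == top)}
            assert preds[s] in winners

    def test_training_point_deep_in_cloud(self, rng):
        X, y = make_blobs(rng, n_classes=3, spread=0.1)
        clf = PairwiseLinearSVM().fit(X, y)
        assert clf.predict(X[:1])[0] == y[0]

    def test_relabeling_permutes_predictions(self, rng):
        X, y = make_blobs(rng, n_classes=3)
        mapping = {"class0": "zebra", "class1": "ant", "class2": "moth"}
        T = rng.normal(scale=3.0, size=(40, 2))
        a = PairwiseLinearSVM().fit(X, y).predict(T)
        b = PairwiseLinearSVM().fit(X, np.array([mapping[v] for v in y])).predict(T)
        assert [mapping[v] for v in a] == list(b)

    def test_duplicated_samples_same_boundary(self, rng):
        X, y = make_blobs(rng, n_classes=2)
        T = rng.normal(scale=3.0, size=(60, 2))
        a = PairwiseLinearSVM().fit(X, y).predict(T)
        b = PairwiseLinearSVM().fit(np.vstack([X, X]), np.concatenate([y, y])).predict(T)
        assert np.array_equal(a, b)


class TestPosterior:
    def test_simplex_contract(self, rng):
        X, y = make_blobs(rng, n_classes=3)
        clf = PairwiseLinearSVM().fit(X, y)
        P = clf.predict_proba(rng.normal(scale=5.0, size=(30, 2)))
        assert np.all(P >= 0)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)

    def test_argmax_consistent_with_predict(self, rng):
        X, y = make_blobs(rng, n_classes=3, n_per_class=30)
        clf = PairwiseLinearSVM().fit(X, y)
        T, _ = make_blobs(np.random.default_rng(99), n_classes=3, n_per_class=40)
        agree = (clf.classes_[np.argmax(clf.predict_proba(T), axis=1)]
                 == clf.predict(T)).mean()
        assert agree >= 0.95

    def test_equidistant_point_near_half(self, rng):
        # symmetric 2-class problem: midpoint between the means
        mean0, mean1 = np.array([-2.0, 0.0]), np.array([2.0, 0.0])
        X = np.vstack([mean0 + 0.4 * rng.normal(size=(50, 2)),
                       mean1 + 0.4 * rng.normal(size=(50, 2))])
        y = np.array(["a"] * 50 + ["b"] * 50)
        clf = PairwiseLinearSVM().fit(X, y)
        p = clf.predict_proba(np.zeros((1, 2)))[0]
        assert abs(p[0] - 0.5) < 0.05

    def test_uncalibrated_model_raises(self, rng):
        X, y = make_blobs(rng)
        clf = PairwiseLinearSVM(fit_posterior=False).fit(X, y)
        with pytest.raises(ModelStateError):
            clf.predict_proba(X[:2])

    def test_platt_recovers_separation_direction(self, rng):
        d = np.concatenate([rng.normal(-2, 1, 200), rng.normal(2, 1, 200)])
        y = np.array([-1] * 200 + [1] * 200)
        A, B = fit_platt(d, y)
        p_hi = 1 / (1 + np.exp(A * 3 + B))
        p_lo = 1 / (1 + np.exp(A * -3 + B))
        assert p_hi > 0.9 > 0.1 > p_lo

    def test_pairwise_coupling_consistent_input(self):
        # pairwise probabilities generated from a known simplex vector
        p = np.array([0.5, 0.3, 0.2])
        R = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                if i != j:
                    R[i, j] = p[i] / (p[i] + p[j])
        assert np.allclose(pairwise_coupling(R), p, atol=1e-6)


class TestSerialization:
    def test_roundtrip_identical_predictions(self, rng, tmp_path):
        X, y = make_blobs(rng, n_classes=3)
        clf = PairwiseLinearSVM().fit(X, y, fingerprint={"descriptor": "hog"})
        save_model(clf, tmp_path / "m.json")
        loaded = load_model(tmp_path / "m.json")
        T = rng.normal(scale=4.0, size=(50, 2))
        assert np.array_equal(clf.predict(T), loaded.predict(T))
        assert np.allclose(clf.predict_proba(T), loaded.predict_proba(T))

    def test_fingerprint_mismatch_rejected(self, rng, tmp_path):
        X, y = make_blobs(rng)
        clf = PairwiseLinearSVM().fit(X, y, fingerprint={"descriptor": "hog"})
        save_model(clf, tmp_path / "m.json")
        with pytest.raises(ModelIOError, match="fingerprint"):
            load_model(tmp_path / "m.json",
                       expected_fingerprint={"descriptor": "lbp"})

    def test_corrupt_file_rejected(self, tmp_path):
        bad = tmp_path / "m.json"
        bad.write_text("{'nope")
        with pytest.raises(ModelIOError):
            load_model(bad)
        bad.write_text('{"format": "other"}')
        with pytest.raises(ModelIOError):
            load_model(bad)
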