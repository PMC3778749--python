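import numpy as np
import pytest

from connectoscan.classify import (
    CLASSIFIERS,
    GaussianNaiveBayes,
    MaxMarginClassifier,
    PearsonKnnClassifier,
)


def _blobs(rng, n_per=10, d=3, sep=20.0, p=8):
    """Two well-separated Gaussian blobs (distance ≫ spread)."""
    mu_a = rng.normal(size=p)
    mu_b = mu_a + sep * rng.normal(size=p) / np.sqrt(p)
    Xa = mu_a + rng.normal(size=(n_per, p))
    Xb = mu_b + rng.normal(size=(n_per, p))
    X = np.vstack([Xa, Xb])
    y = np.array(["A"] * n_per + ["B"] * n_per)
    return X, y


class TestMaxMargin:
    def test_symmetric_pair_gives_midplane(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([-1, 1])
        m = MaxMarginClassifier(C=1e6).fit(X, y)
        # both points on the margin, boundary at the midpoint
        d = m.decision_function(np.array([[0.0]]))
        assert d[0] == pytest.approx(0.0, abs=1e-6)
        assert m.predict(np.array([[0.3], [-0.3]])).tolist() == [1, -1]

    def test_separable_blobs_perfect_training_accuracy(self):
        X, y = _blobs(np.random.default_rng(0))
        m = MaxMarginClassifier().fit(X, y)
        assert np.all(m.predict(X) == y)

    def test_duplicated_dataset_same_boundary(self):
        X, y = _blobs(np.random.default_rng(1), sep=5.0)
        m1 = MaxMarginClassifier().fit(X, y)
        m2 = MaxMarginClassifier().fit(np.vstack([X, X]), np.concatenate([y, y]))
        probe = np.random.default_rng(2).normal(size=(20, X.shape[1]))
        assert np.allclose(
            m1.decision_function(probe), m2.decision_function(probe), atol=1e-4
        )

    def test_point_on_hyperplane_predicts_positive_class(self):
        X = np.array([[-1.0], [1.0]])
        m = MaxMarginClassifier(C=1e6).fit(X, np.array([-1, 1]))
        assert m.predict(np.array([[0.0]]))[0] == 1

    def test_dimension_mismatch_rejected(self):
        X, y = _blobs(np.random.default_rng(3))
        m = MaxMarginClassifier().fit(X, y)
        with pytest.raises(ValueError, match="dimension"):
            m.predict(np.ones((1, X.shape[1] + 2)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            MaxMarginClassifier().fit(np.ones((3, 2)), np.zeros(3))


class TestPearsonKnn:
    def test_unanimous_training_class_wins(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 5))
        m = PearsonKnnClassifier(k=3).fit(X, np.array(["A"] * 6))
        assert m.predict(rng.normal(size=(1, 5)))[0] == "A"

    def test_identical_vector_k1(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 7))
        y = np.array(["A", "B", "A", "B", "A", "B"])
        m = PearsonKnnClassifier(k=1).fit(X, y)
        for i in range(6):
            assert m.predict(X[i][None])[0] == y[i]

    def test_majority_of_six(self):
        # four highly-correlated A neighbours vs two B: A wins 4-2
        base = np.linspace(0, 1, 6)
        X = np.vstack(
            [base + 0.01 * k for k in range(4)] + [-base, -base + 0.02]
        )
        y = np.array(["A", "A", "A", "A", "B", "B"])
        m = PearsonKnnClassifier(k=6).fit(X, y)
        assert m.predict(base[None])[0] == "A"

    def test_blobs_perfect_training_accuracy(self):
        X, y = _blobs(np.random.default_rng(4), sep=30.0)
        m = PearsonKnnClassifier(k=1).fit(X, y)
        assert np.all(m.predict(X) == y)

    def test_scale_invariance_per_subject(self):
        X, y = _blobs(np.random.default_rng(5), sep=10.0)
        m = PearsonKnnClassifier(k=6).fit(X, y)
        probe = np.random.default_rng(6).normal(size=(10, X.shape[1]))
        a = m.predict(probe)
        b = m.predict(3.7 * probe + 2.0)  # Pearson is affine-invariant
        assert np.array_equal(a, b)

    def test_constant_vector_warns_and_correlates_zero(self):
        X = np.vstack([np.linspace(0, 1, 5), -np.linspace(0, 1, 5)])
        y = np.array(["A", "B"])
        m = PearsonKnnClassifier(k=2).fit(X, y)
        with pytest.warns(UserWarning, match="constant"):
            m.predict(np.ones((1, 5)))

    def test_k_larger_than_train_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            PearsonKnnClassifier(k=6).fit(np.random.rand(4, 3), np.array([0, 0, 1, 1]))


class TestGaussianNB:
    def test_point_at_class_mean_with_equal_priors(self):
        rng = np.random.default_rng(0)
        Xa = rng.normal(0.0, 1.0, size=(10, 3))
        Xb = rng.normal(5.0, 1.0, size=(10, 3))
        X = np.vstack([Xa, Xb])
        y = np.array([0] * 10 + [1] * 10)
        m = GaussianNaiveBayes().fit(X, y)
        assert m.predict(Xa.mean(axis=0)[None])[0] == 0
        assert m.predict(Xb.mean(axis=0)[None])[0] == 1

    def test_prior_dominance_with_identical_likelihoods(self):
        # both classes share the same feature distribution; 9:1 priors
        rng = np.random.default_rng(1)
        base = rng.normal(size=(20, 2))
        X = np.vstack([base[:18], base[:2]])
        y = np.array([0] * 18 + [1] * 2)
        m = GaussianNaiveBayes().fit(X, y)
        m.means_[1] = m.means_[0]
        m.vars_[1] = m.vars_[0]
        probe = rng.normal(size=(10, 2))
        assert np.all(m.predict(probe) == 0)

    def test_exact_tie_breaks_to_larger_prior_then_lower_class(self):
        # single feature, symmetric means 0 and 2, equal variances: x = 1
        # is an exact tie; equal priors -> lower class index wins
        X = np.array([[-1.0], [1.0], [1.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        m = GaussianNaiveBayes().fit(X, y)
        assert m.means_[0][0] == pytest.approx(0.0)
        assert m.means_[1][0] == pytest.approx(2.0)
        assert m.predict(np.array([[1.0]]))[0] == 0
        # larger prior wins the tie
        X2 = np.array([[-1.0], [1.0], [0.0], [1.0], [3.0]])
        y2 = np.array([0, 0, 0, 1, 1])
        m2 = GaussianNaiveBayes().fit(X2, y2)
        m2.means_ = np.array([[0.0], [2.0]])
        m2.vars_ = np.array([[1.0], [1.0]])
        assert m2.predict(np.array([[1.0]]))[0] == 0  # prior 3/5 vs 2/5

    def test_zero_variance_feature_floored_with_warning(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0], [1.0, 3.0]])
        y = np.array([0, 0, 1, 1])
        with pytest.warns(UserWarning, match="variance"):
            m = GaussianNaiveBayes().fit(X, y)
        assert np.all(m.vars_ > 0)

    def test_blobs_perfect_training_accuracy(self):
        X, y = _blobs(np.random.default_rng(7), sep=25.0)
        m = GaussianNaiveBayes().fit(X, y)
        assert np.all(m.predict(X) == y)


class TestLabelSymmetry:
    @pytest.mark.parametrize("name", list(CLASSIFIERS))
    def test_swapping_labels_swaps_predictions(self, name):
        X, y = _blobs(np.random.default_rng(9), sep=8.0)
        probe = np.random.default_rng(10).normal(size=(15, X.shape[1])) + X.mean(0)
        kwargs = {"k": 3} if name == "knn" else {}
        m1 = CLASSIFIERS[name](**kwargs).fit(X, y)
        swap = {"A": "B", "B": "A"}
        y2 = np.array([swap[l] for l in y])
        m2 = CLASSIFIERS[name](**kwargs).fit(X, y2)
        p1 = m1.predict(probe)
        p2 = m2.predict(probe)
        assert np.array_equal(np.array([swap[l] for l in p1]), p2)
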