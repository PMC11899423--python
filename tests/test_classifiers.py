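import numpy as np
import pytest
from sklearn.naive_bayes import GaussianNB as SkGaussianNB
from sklearn.neighbors import KNeighborsClassifier

from nirclda.classifiers import (FeatureSet, GaussianNaiveBayes,
                                 KNNClassifier, evaluate, knn_predict,
                                 nb_fit, nb_predict)
from nirclda.exceptions import FitError, ParameterError, SchemaError


class TestKNN:
    def test_coinciding_point_k1(self):
        train = FeatureSet(np.array([[0.0], [1.0], [2.0]]),
                           labels=["a", "b", "c"])
        test = FeatureSet(np.array([[1.0]]))
        assert knn_predict(train, test, k=1)[0] == "b"

    def test_majority_vote_enumeration(self):
        train = FeatureSet(np.array([[0.0], [1.0], [10.0]]),
                           labels=["A", "A", "B"])
        test = FeatureSet(np.array([[0.4]]))
        assert knn_predict(train, test, k=3)[0] == "A"

    def test_k_equals_n_gives_global_majority(self):
        rng = np.random.default_rng(0)
        train = FeatureSet(rng.normal(size=(9, 2)),
                           labels=["A"] * 5 + ["B"] * 4)
        test = FeatureSet(rng.normal(size=(6, 2)) + 100)
        assert all(p == "A" for p in knn_predict(train, test, k=9))

    def test_vote_tie_broken_by_inverse_distance(self):
        # k=2: one neighbour per class; the nearer one (A at 0.1) wins
        train = FeatureSet(np.array([[0.0], [1.0]]), labels=["B", "A"])
        test = FeatureSet(np.array([[0.9]]))
        assert knn_predict(train, test, k=2)[0] == "A"

    def test_exact_tie_takes_lowest_class_index(self):
        train = FeatureSet(np.array([[-1.0], [1.0]]), labels=["z", "a"])
        test = FeatureSet(np.array([[0.0]]))
        assert knn_predict(train, test, k=2)[0] == "a"

    def test_k_out_of_range(self):
        train = FeatureSet(np.zeros((3, 1)), labels=["a", "b", "c"])
        with pytest.raises(ParameterError):
            knn_predict(train, FeatureSet(np.zeros((1, 1))), k=4)

    def test_agrees_with_sklearn_when_unambiguous(self):
        rng = np.random.default_rng(1)
        Xtr = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(6, 1, (30, 3))])
        ytr = np.array(["a"] * 30 + ["b"] * 30)
        Xte = np.vstack([rng.normal(0, 1, (20, 3)), rng.normal(6, 1, (20, 3))])
        ours = KNNClassifier(k=5).fit(Xtr, ytr).predict(Xte)
        ref = KNeighborsClassifier(n_neighbors=5).fit(Xtr, ytr).predict(Xte)
        np.testing.assert_array_equal(ours, ref)


class TestGaussianNB:
    def test_balanced_priors(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 2))
        y = np.repeat(["a", "b", "c", "d"], 10)
        model = GaussianNaiveBayes().fit(X, y)
        np.testing.assert_allclose(model.priors_, 0.25)

    def test_constant_feature_hits_variance_floor(self):
        X = np.array([[1.0, 0.0], [1.0, 1.0], [5.0, 0.0], [5.0, 1.0]])
        y = np.array(["a", "a", "b", "b"])
        model = GaussianNaiveBayes().fit(X, y)
        assert np.all(model.var_[:, 0] > 0)  # floored, not zero
        np.testing.assert_allclose(model.theta_[:, 0], [1.0, 5.0])

    def test_parameter_recovery(self):
        rng = np.random.default_rng(42)
        X = np.concatenate([rng.normal(-2, 1, 500), rng.normal(2, 1, 500)])
        y = np.array(["neg"] * 500 + ["pos"] * 500)
        model = GaussianNaiveBayes().fit(X[:, None], y)
        np.testing.assert_allclose(model.theta_.ravel(), [-2, 2], atol=0.15)

    def test_midpoint_and_boundary(self):
        model = GaussianNaiveBayes()
        model.classes_ = np.array(["m1", "p1"])
        model.priors_ = np.array([0.5, 0.5])
        model.theta_ = np.array([[-1.0], [1.0]])
        model.var_ = np.array([[1.0], [1.0]])
        model.n_features_in_ = 1
        assert model.predict(np.array([[0.0]]))[0] == "m1"  # tie -> lowest
        assert model.predict(np.array([[0.1]]))[0] == "p1"

    def test_prior_shift_moves_boundary(self):
        """With priors (0.9, 0.1) the boundary sits at ln(9)/2 ~ 1.0986/... ,
        shifted toward the rare positive class."""
        model = GaussianNaiveBayes()
        model.classes_ = np.array(["m1", "p1"])
        model.priors_ = np.array([0.9, 0.1])
        model.theta_ = np.array([[-1.0], [1.0]])
        model.var_ = np.array([[1.0], [1.0]])
        model.n_features_in_ = 1
        boundary = 0.5 * np.log(0.9 / 0.1)  # closed form for unit variances
        assert model.predict(np.array([[boundary - 0.01]]))[0] == "m1"
        assert model.predict(np.array([[boundary + 0.01]]))[0] == "p1"

    def test_agrees_with_density_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 3)) + np.repeat([0, 3, 6], 20)[:, None]
        y = np.repeat(["a", "b", "c"], 20)
        model = GaussianNaiveBayes().fit(X, y)
        Xte = rng.normal(3, 3, size=(40, 3))
        pred = model.predict(Xte)
        from scipy.stats import norm

        for i in range(40):
            post = [
                np.log(model.priors_[j])
                + norm.logpdf(Xte[i], model.theta_[j],
                              np.sqrt(model.var_[j])).sum()
                for j in range(3)
            ]
            assert pred[i] == model.classes_[int(np.argmax(post))]

    def test_agrees_with_sklearn_on_separated_data(self):
        rng = np.random.default_rng(4)
        Xtr = np.vstack([rng.normal(0, 1, (40, 2)), rng.normal(5, 1, (40, 2))])
        ytr = np.array(["a"] * 40 + ["b"] * 40)
        Xte = rng.uniform(-2, 7, size=(30, 2))
        ours = GaussianNaiveBayes().fit(Xtr, ytr).predict(Xte)
        ref = SkGaussianNB().fit(Xtr, ytr).predict(Xte)
        assert np.mean(ours == ref) > 0.95

    def test_small_class_rejected(self):
        X = np.zeros((3, 1))
        y = np.array(["a", "a", "b"])
        with pytest.raises(FitError):
            GaussianNaiveBayes().fit(X, y)

    def test_affine_rescaling_invariance(self):
        """Per-feature affine rescaling applied to train and test leaves the
        posterior argmax unchanged."""
        rng = np.random.default_rng(5)
        Xtr = rng.normal(size=(60, 3)) + np.repeat([0, 2, 4], 20)[:, None]
        ytr = np.repeat(["a", "b", "c"], 20)
        Xte = rng.normal(2, 2, size=(25, 3))
        scale = np.array([2.0, 0.5, 10.0])
        shift = np.array([-1.0, 3.0, 0.0])
        base = GaussianNaiveBayes().fit(Xtr, ytr).predict(Xte)
        scaled = GaussianNaiveBayes().fit(Xtr * scale + shift,
                                          ytr).predict(Xte * scale + shift)
        np.testing.assert_array_equal(base, scaled)


class TestEvaluate:
    def test_perfect_prediction(self):
        truth = np.repeat(["a", "b", "c", "d"], 20)
        acc, cm = evaluate(truth, truth)
        assert acc == 1.0
        np.testing.assert_array_equal(np.diag(cm.counts), [20, 20, 20, 20])
        assert cm.counts.sum() == 80

    def test_single_error_accuracy(self):
        truth = np.repeat(["a", "b", "c", "d"], 20)
        pred = truth.copy()
        pred[0] = "b"
        acc, cm = evaluate(pred, truth)
        np.testing.assert_allclose(acc, 79 / 80)
        assert cm.counts[0, 1] == 1

    def test_row_sums_match_truth_counts(self):
        rng = np.random.default_rng(6)
        truth = rng.choice(["a", "b", "c"], size=50)
        pred = rng.choice(["a", "b", "c"], size=50)
        acc, cm = evaluate(pred, truth, class_order=["a", "b", "c"])
        for i, c in enumerate(["a", "b", "c"]):
            assert cm.counts[i].sum() == (truth == c).sum()
        np.testing.assert_allclose(np.trace(cm.counts) / cm.total, acc)

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            evaluate([], [])

    def test_unknown_label_rejected(self):
        with pytest.raises(SchemaError):
            evaluate(["a"], ["q"], class_order=["a", "b"])

    def test_nb_functional_surface(self):
        rng = np.random.default_rng(7)
        train = FeatureSet(
            np.concatenate([rng.normal(0, 1, 20), rng.normal(5, 1, 20)])[:, None],
            labels=["a"] * 20 + ["b"] * 20)
        model = nb_fit(train)
        pred = nb_predict(model, FeatureSet(np.array([[0.0], [5.0]])))
        np.testing.assert_array_equal(pred, ["a", "b"])
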