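import numpy as np
import pytest

from funcbench.classifiers import (
    TrainingError,
    default_grid,
    pnn_scores,
    predict,
    train,
    tune,
)
from funcbench.records import NEGATIVE, POSITIVE


def labels(bits):
    return np.array(bits, dtype=bool)


@pytest.fixture
def separable(rng):
    """Two tight clusters far apart in 5 dimensions."""
    pos = rng.normal(0.0, 0.05, size=(20, 5)) + 1.0
    neg = rng.normal(0.0, 0.05, size=(20, 5)) - 1.0
    X = np.vstack([pos, neg])
    y = labels([True] * 20 + [False] * 20)
    return X, y


def test_knn_k1_reproduces_training_labels(separable):
    X, y = separable
    model = train("knn", X, y, {"k": 1})
    assert (predict(model, X) == y).all()


def test_pnn_stores_all_training_vectors(separable):
    X, y = separable
    model = train("pnn", X, y, {"sigma": 1.0})
    assert model.train_X.shape == X.shape


def test_svm_separates_separable_toy_set(separable):
    X, y = separable
    model = train("svm", X, y, {"C": 1.0, "gamma": 0.1})
    assert (predict(model, X) == y).all()


def test_single_class_training_rejected(separable):
    X, _ = separable
    with pytest.raises(TrainingError):
        train("knn", X, labels([True] * len(X)), {"k": 1})


def test_pnn_scores_match_explicit_sum():
    X = np.array([[0.0], [1.0], [2.0]])
    y = labels([True, True, False])
    model = train("pnn", X, y, {"sigma": 1.0})
    x = np.array([0.5])
    s = pnn_scores(model, x)
    exp_pos = (np.exp(-0.25 / 2) + np.exp(-0.25 / 2)) / 2
    exp_neg = np.exp(-2.25 / 2) / 1
    assert s[POSITIVE] == pytest.approx(exp_pos)
    assert s[NEGATIVE] == pytest.approx(exp_neg)


def test_pnn_equal_scores_tie_resolves_negative():
    X = np.array([[0.0], [1.0]])
    model = train("pnn", X, labels([False, True]), {"sigma": 1.0})
    s = pnn_scores(model, np.array([0.5]))
    assert s[POSITIVE] == pytest.approx(s[NEGATIVE])
    assert not predict(model, np.array([0.5]))[0]


def test_pnn_invalid_sigma_rejected(separable):
    X, y = separable
    with pytest.raises(TrainingError, match="sigma"):
        train("pnn", X, y, {"sigma": 0.0})


def test_knn_majority_and_even_tie_rule():
    X = np.array([[0.0], [0.1], [0.2], [10.0]])
    y = labels([True, True, False, False])
    model = train("knn", X, y, {"k": 3})
    assert predict(model, np.array([0.05]))[0]  # votes {+,+,-}
    even = train("knn", X, y, {"k": 2})
    # nearest two of 0.15 are one positive, one negative -> tie -> negative
    assert not predict(even, np.array([0.15]))[0]


def test_knn_with_k_equal_n_predicts_majority_everywhere(rng):
    X = rng.normal(size=(9, 3))
    y = labels([True] * 3 + [False] * 6)
    model = train("knn", X, y, {"k": 9})
    assert not predict(model, rng.normal(size=(20, 3))).any()


def test_training_order_invariance(rng, separable):
    X, y = separable
    perm = rng.permutation(len(y))
    queries = rng.normal(0, 1.2, size=(50, 5))
    for algo, params in (("knn", {"k": 3}), ("pnn", {"sigma": 0.5})):
        a = predict(train(algo, X, y, params), queries)
        b = predict(train(algo, X[perm], y[perm], params), queries)
        assert (a == b).all()


def test_pnn_duplicating_training_points_changes_nothing(separable, rng):
    X, y = separable
    queries = rng.normal(0, 1.2, size=(50, 5))
    a = predict(train("pnn", X, y, {"sigma": 0.5}), queries)
    b = predict(
        train("pnn", np.vstack([X, X]), np.concatenate([y, y]), {"sigma": 0.5}),
        queries,
    )
    assert (a == b).all()


def test_pnn_small_sigma_limit_is_one_nearest_neighbor(rng):
    X = rng.uniform(size=(60, 8))
    y = labels(rng.random(60) < 0.5)
    queries = rng.uniform(size=(100, 8))
    nn1 = predict(train("knn", X, y, {"k": 1}), queries)
    parzen = predict(train("pnn", X, y, {"sigma": 1e-6}), queries)
    assert (parzen == nn1).all()


def test_dimension_mismatch_rejected(separable):
    X, y = separable
    model = train("knn", X, y, {"k": 1})
    with pytest.raises(ValueError, match="dimension"):
        predict(model, np.zeros((1, 7)))


class TestTune:
    def test_singleton_grid_returns_that_point(self, separable):
        X, y = separable
        res = tune("knn", X, y, X, y, grid=[{"k": 5}])
        assert res.best_parameters == {"k": 5}
        assert len(res.table) == 1

    def test_grid_recovers_separating_parameters(self, separable, rng):
        X, y = separable
        test_X = np.vstack(
            [rng.normal(0, 0.05, (10, 5)) + 1, rng.normal(0, 0.05, (10, 5)) - 1]
        )
        test_y = labels([True] * 10 + [False] * 10)
        res = tune("svm", X, y, test_X, test_y)
        best = [r for r in res.table if r["mcc"] == 1.0]
        assert best, "some grid point must separate the separable set"
        assert res.table[0].keys() >= {"C", "gamma", "mcc"}

    def test_tie_breaks_by_grid_order_and_is_deterministic(self, separable):
        X, y = separable
        grid = [{"k": 1}, {"k": 3}]  # both perfect on the training data
        a = tune("knn", X, y, X, y, grid=grid)
        b = tune("knn", X, y, X, y, grid=grid)
        assert a.best_parameters == b.best_parameters == {"k": 1}


def test_default_grids_shapes(separable):
    X, _ = separable
    assert [g["k"] for g in default_grid("knn", X)] == [1, 3, 5, 7, 9, 11]
    sigmas = [g["sigma"] for g in default_grid("pnn", X)]
    assert len(sigmas) == 7 and all(s > 0 for s in sigmas)
    assert len(default_grid("svm", X)) == 16
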