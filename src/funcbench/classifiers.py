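"""Feature-based classifiers: KNN, PNN (Parzen) and SVM.

Each family is an independent binary problem. Hyperparameters are tuned by
maximizing MCC on the held-out testing set, then the final model is
re-trained on the union of training and testing with the chosen
parameters and scored once on the independent set.

Tie rules are deliberately conservative for false-discovery control: a KNN
even-vote tie and a PNN equal-density tie both resolve to the negative
class.

KNN and the RBF-kernel SVM are standard algorithms and lean on
scikit-learn for the neighbor search and the SVM fit; the vote/tie logic
and the Parzen classifier are implemented here. The PNN scores class c as

    g_c(x) = (1/n_c) * sum_i exp(-||x - t_i||^2 / (2 sigma^2))

over the n_c training vectors t_i of class c, computed in log space so
that the sigma -> 0 limit degenerates exactly to 1-nearest-neighbor
instead of underflowing to a tie.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.special import logsumexp
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

from .features import MinMaxScaler
from .metrics import confusion_counts, mcc
from .records import NEGATIVE, POSITIVE

ALGORITHMS = ("knn", "pnn", "svm")


class TrainingError(ValueError):
    pass


@dataclass
class TrainedModel:
    """A fitted binary classifier plus the exact parameters that built it."""

    algorithm: str
    parameters: dict[str, Any]
    fitted_state: Any
    scaler: MinMaxScaler | None = None
    labels: np.ndarray | None = None  # boolean, True = positive (knn/pnn)
    train_X: np.ndarray | None = None


def _as_bool_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    return arr == POSITIVE


def train(
    algorithm: str,
    X: np.ndarray,
    labels,
    parameters: dict[str, Any],
    scaler: MinMaxScaler | None = None,
) -> TrainedModel:
    """Fit one classifier on an already-scaled feature matrix."""
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    y = _as_bool_labels(labels)
    if y.all() or not y.any():
        raise TrainingError("training set must contain both classes")
    X = np.asarray(X, dtype=float)
    params = dict(parameters)

    if algorithm == "knn":
        k = int(params["k"])
        if not 1 <= k <= len(y):
            raise TrainingError(f"k={k} out of range for {len(y)} samples")
        nn = NearestNeighbors(n_neighbors=k).fit(X)
        return TrainedModel("knn", params, nn, scaler, y, X)

    if algorithm == "pnn":
        sigma = float(params["sigma"])
        if sigma <= 0:
            raise TrainingError(f"sigma must be positive, got {sigma}")
        return TrainedModel("pnn", params, None, scaler, y, X)

    svc = SVC(
        kernel=params.get("kernel", "rbf"),
        C=float(params.get("C", 1.0)),
        gamma=params.get("gamma", "scale"),
        class_weight=params.get("class_weight"),
    )
    svc.fit(X, y)
    return TrainedModel("svm", params, svc, scaler, y, X)


def pnn_log_scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Log class-conditional Parzen densities, shape (n, 2): [neg, pos]."""
    if model.algorithm != "pnn":
        raise ValueError("model is not a PNN")
    sigma = float(model.parameters["sigma"])
    d2 = cdist(np.atleast_2d(X), model.train_X, "sqeuclidean")
    log_k = -d2 / (2.0 * sigma * sigma)
    out = np.empty((log_k.shape[0], 2))
    for col, mask in enumerate((~model.labels, model.labels)):
        out[:, col] = logsumexp(log_k[:, mask], axis=1) - np.log(mask.sum())
    return out


def pnn_scores(model: TrainedModel, x: np.ndarray) -> dict[str, float]:
    """Per-class Parzen density estimates for a single feature vector."""
    log_neg, log_pos = pnn_log_scores(model, np.atleast_2d(x))[0]
    return {NEGATIVE: float(np.exp(log_neg)), POSITIVE: float(np.exp(log_pos))}


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Boolean predictions (True = positive) for scaled feature vectors."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if model.train_X is not None and X.shape[1] != model.train_X.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} != trained {model.train_X.shape[1]}"
        )
    if model.algorithm == "knn":
        k = int(model.parameters["k"])
        _, idx = model.fitted_state.kneighbors(X, n_neighbors=k)
        votes = model.labels[idx].sum(axis=1)
        # strict majority required: even-vote ties resolve negative
        return votes * 2 > k
    if model.algorithm == "pnn":
        scores = pnn_log_scores(model, X)
        return scores[:, 1] > scores[:, 0]
    return model.fitted_state.predict(X).astype(bool)


def predict_labels(model: TrainedModel, X: np.ndarray) -> list[str]:
    return [POSITIVE if p else NEGATIVE for p in predict(model, X)]


def default_grid(algorithm: str, train_X: np.ndarray) -> list[dict[str, Any]]:
    """Conventional, bounded tuning grids.

    PNN widths span 0.01-10 times the median pairwise training distance so
    the grid adapts to the scaled feature geometry.
    """
    if algorithm == "knn":
        n = len(train_X)
        return [{"k": k} for k in (1, 3, 5, 7, 9, 11) if k <= n] or [{"k": n}]
    if algorithm == "pnn":
        med = float(np.median(pdist(train_X)))
        if med <= 0:
            med = 1.0
        return [{"sigma": med * f} for f in (0.01, 0.03, 0.1, 0.3, 1.0, 3.0, 10.0)]
    return [
        {"C": C, "gamma": g}
        for C in (0.1, 1.0, 10.0, 100.0)
        for g in (0.001, 0.01, 0.1, 1.0)
    ]


@dataclass
class TuningResult:
    best_parameters: dict[str, Any]
    table: list[dict[str, Any]] = field(default_factory=list)


def tune(
    algorithm: str,
    train_X: np.ndarray,
    train_y,
    test_X: np.ndarray,
    test_y,
    grid: list[dict[str, Any]] | None = None,
) -> TuningResult:
    """Pick the grid point maximizing testing-set MCC (ties: grid order).

    Returns the full parameter/score table for audit alongside the choice.
    An undefined MCC (degenerate prediction) scores as -inf so any defined
    score beats it.
    """
    if grid is None:
        grid = default_grid(algorithm, train_X)
    if not grid:
        raise ValueError("empty tuning grid")
    test_truth = _as_bool_labels(test_y)
    best, best_score = None, -np.inf
    table = []
    for params in grid:
        model = train(algorithm, train_X, train_y, params)
        pred = predict(model, test_X)
        score = mcc(confusion_counts(pred, test_truth))
        score = -np.inf if np.isnan(score) else score
        table.append({**params, "mcc": score})
        if score > best_score:
            best, best_score = params, score
    return TuningResult(best_parameters=dict(best), table=table)
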