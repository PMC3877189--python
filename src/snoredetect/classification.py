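"""Discrete AdaBoost over decision stumps, forward feature selection, and
per-recording decision-score thresholds.

Snores are coded +1 and non-snores -1.  Each boosting round performs an
exhaustive decision-stump search (best feature, threshold and polarity by
weighted error); learner weights follow ``alpha = 0.5*ln((1-eps)/eps)``.
The decision score of an event is the alpha-normalized weighted vote
``S = sum(alpha_t h_t(x)) / sum(alpha_t)`` in [-1, 1], so a snore-like
event scores toward +1.

Because snoring style differs between subjects, a per-recording score
threshold S_TH is located at the valley of the (assumed bimodal) score
histogram in a narrow region around zero; when no convincing valley
exists, zero is used.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import GroupKFold, KFold

MODEL_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class WeakLearner:
    """One decision stump: vote ``polarity`` if ``x[feature] > threshold`` else ``-polarity``."""

    feature: int
    threshold: float
    polarity: int  # +1 or -1
    alpha: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(X[:, self.feature] > self.threshold, self.polarity, -self.polarity)


@dataclass
class AdaBoostModel:
    learners: list[WeakLearner]
    feature_names: list[str]
    imputation_medians: np.ndarray
    seed: int = 0
    k: int = 0

    def __post_init__(self) -> None:
        self.imputation_medians = np.asarray(self.imputation_medians, dtype=float)
        if self.k == 0:
            self.k = len(self.learners)

    @property
    def alpha_total(self) -> float:
        return sum(w.alpha for w in self.learners)

    def impute(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float).copy()
        mask = ~np.isfinite(X)
        if mask.any():
            X[mask] = np.take(self.imputation_medians, np.nonzero(mask)[1])
        return X


@dataclass
class DecisionThreshold:
    s_th: float
    method: str  # "valley" or "default-zero"
    histogram: np.ndarray | None = None
    bin_centers: np.ndarray | None = None


def _impute_train(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float).copy()
    medians = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        finite = np.isfinite(col)
        medians[j] = np.median(col[finite]) if finite.any() else 0.0
        col[~finite] = medians[j]
    return X, medians


def _best_stump(X_sorted: np.ndarray, order: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[int, float, int, float]:
    """Exhaustive weighted-error stump search.

    ``X_sorted``/``order`` are precomputed per-feature sorted values and
    argsort indices (shape (d, n)).  Returns (feature, threshold, polarity,
    weighted error); ties broken by lower feature index, then lower
    threshold.
    """
    d, n = X_sorted.shape
    best = (0, -np.inf, 1, np.inf)
    total_weight = float(np.sum(w))
    total_neg = float(np.sum(w[y < 0]))
    for j in range(d):
        idx = order[j]
        wy = (w * y)[idx]
        cum = np.concatenate(([0.0], np.cumsum(wy)))  # cum_pos(i) - cum_neg(i)
        vals = X_sorted[j]
        # candidate cut after position i is valid only if vals[i-1] < vals[i]
        valid = np.concatenate(([True], vals[1:] > vals[:-1], [True]))
        # polarity +1 (predict +1 for x > thr): err = misclassified positives
        # below the cut + misclassified negatives above it
        err_plus = total_neg + cum
        err_minus = total_weight - err_plus
        err_plus = np.where(valid, err_plus, np.inf)
        err_minus = np.where(valid, err_minus, np.inf)
        i_plus = int(np.argmin(err_plus))
        i_minus = int(np.argmin(err_minus))
        candidates = [
            (float(err_plus[i_plus]), i_plus, 1),
            (float(err_minus[i_minus]), i_minus, -1),
        ]
        for e, i, pol in candidates:
            if e < best[3] - 1e-12:
                if i == 0:
                    thr = vals[0] - 1.0
                elif i == n:
                    thr = vals[-1] + 1.0
                else:
                    thr = 0.5 * (vals[i - 1] + vals[i])
                best = (j, float(thr), pol, e)
    return best


def train_adaboost(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 300,
    feature_names: list[str] | None = None,
    seed: int = 0,
) -> AdaBoostModel:
    """Discrete AdaBoost with exhaustive decision-stump search per round.

    ``y`` must contain both classes coded +1 (snore) and -1 (non-snore).
    Missing feature values (NaN) are median-imputed; the medians are stored
    in the model for scoring time.  Training is deterministic given the
    input order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n, d) with one label per row")
    if not (np.any(y > 0) and np.any(y < 0)):
        raise ValueError("training data must contain both classes (+1 and -1)")
    X, medians = _impute_train(X)
    n, d = X.shape
    names = feature_names if feature_names is not None else [f"f{j}" for j in range(d)]

    order = np.argsort(X, axis=0, kind="stable").T  # (d, n)
    X_sorted = np.take_along_axis(X.T, order, axis=1)

    w = np.full(n, 1.0 / n)
    learners: list[WeakLearner] = []
    for _ in range(k):
        j, thr, pol, err = _best_stump(X_sorted, order, y, w)
        if err >= 0.5:
            warnings.warn(f"stopping early at round {len(learners)}: best stump error {err:.3f} >= 0.5")
            break
        eps = min(max(err, 1e-10), 1.0 - 1e-10)
        alpha = 0.5 * math.log((1.0 - eps) / eps)
        stump = WeakLearner(j, thr, pol, alpha)
        learners.append(stump)
        pred = stump.predict(X)
        w = w * np.exp(-alpha * y * pred)
        w /= w.sum()
    return AdaBoostModel(learners=learners, feature_names=list(names), imputation_medians=medians, seed=seed, k=k)


def score(model: AdaBoostModel, X: np.ndarray) -> np.ndarray:
    """Decision scores S in [-1, 1] for rows of ``X`` (NaNs imputed)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    X = model.impute(X)
    total = model.alpha_total
    if total <= 0:
        return np.zeros(X.shape[0])
    s = np.zeros(X.shape[0])
    for learner in model.learners:
        s += learner.alpha * learner.predict(X)
    return s / total


def _cv_accuracy(X: np.ndarray, y: np.ndarray, cols: list[int], k: int, n_folds: int, groups: np.ndarray | None) -> float:
    Xs = X[:, cols]
    if groups is not None:
        n_groups = np.unique(groups).size
        folds = min(n_folds, n_groups)
        splitter = GroupKFold(n_splits=folds)
        split = splitter.split(Xs, y, groups)
    else:
        splitter = KFold(n_splits=min(n_folds, y.size))
        split = splitter.split(Xs, y)
    correct = 0
    for train_idx, test_idx in split:
        if np.unique(y[train_idx]).size < 2:
            continue
        model = train_adaboost(Xs[train_idx], y[train_idx], k=k)
        pred = np.where(score(model, Xs[test_idx]) > 0, 1.0, -1.0)
        correct += int(np.sum(pred == y[test_idx]))
    return correct / y.size


def forward_feature_selection(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 100,
    n_folds: int = 10,
    groups: np.ndarray | None = None,
    max_features: int | None = None,
    patience: int | None = None,
) -> tuple[list[int], list[float]]:
    """Greedy forward selection under cross-validated AdaBoost accuracy.

    At every step the feature whose addition maximizes ``n_folds``-fold CV
    accuracy (folds grouped by recording when ``groups`` is given) of a
    k-order AdaBoost is added; ties break toward the lower feature index.
    Returns the selected indices at the criterion-curve maximum and the
    full criterion curve.  ``patience`` stops the search after that many
    steps without improvement; ``max_features`` caps the subset size.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    X, _ = _impute_train(X)
    d = X.shape[1]
    if groups is not None and np.unique(groups).size < n_folds:
        warnings.warn(
            f"only {np.unique(groups).size} groups available; folds reduced accordingly"
        )
    budget = max_features if max_features is not None else d
    selected: list[int] = []
    curve: list[float] = []
    remaining = list(range(d))
    best_so_far = -np.inf
    stale = 0
    while remaining and len(selected) < budget:
        step_best = (-np.inf, None)
        for j in remaining:
            acc = _cv_accuracy(X, y, selected + [j], k, n_folds, groups)
            if acc > step_best[0] + 1e-12:
                step_best = (acc, j)
        acc, j = step_best
        selected.append(j)
        remaining.remove(j)
        curve.append(acc)
        if acc > best_so_far + 1e-12:
            best_so_far = acc
            stale = 0
        else:
            stale += 1
            if patience is not None and stale >= patience:
                break
    peak = int(np.argmax(curve)) + 1
    return selected[:peak], curve


def individual_threshold(
    scores: np.ndarray,
    n_bins: int = 50,
    smooth_order: int = 5,
    search_region: float = 0.25,
    prominence: float = 0.05,
    min_scores: int = 30,
) -> DecisionThreshold:
    """Per-recording decision threshold at the histogram valley near zero.

    The score histogram (``n_bins`` over [-1, 1]) is smoothed with an
    order-``smooth_order`` moving average; the minimum within
    ±``search_region`` is accepted as S_TH only when both in-region
    neighbours exceed it by the relative ``prominence``; otherwise the
    default zero threshold is returned.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < min_scores:
        return DecisionThreshold(0.0, "default-zero")
    counts, edges = np.histogram(scores, bins=n_bins, range=(-1.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    kernel = np.ones(smooth_order) / smooth_order
    smoothed = np.convolve(counts.astype(float), kernel, mode="same")
    region = np.nonzero(np.abs(centers) <= search_region)[0]
    if region.size < 3:
        return DecisionThreshold(0.0, "default-zero", smoothed, centers)
    interior = region[1:-1]
    best_i = interior[int(np.argmin(smoothed[interior]))]
    v = smoothed[best_i]
    left, right = smoothed[best_i - 1], smoothed[best_i + 1]
    floor = v * (1.0 + prominence) if v > 0 else 0.0
    if left > floor and right > floor:
        return DecisionThreshold(float(centers[best_i]), "valley", smoothed, centers)
    return DecisionThreshold(0.0, "default-zero", smoothed, centers)


def classify_events(model: AdaBoostModel, X: np.ndarray, s_th: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """(scores, labels): label snore (+1) iff S strictly exceeds s_th."""
    s = score(model, X)
    labels = np.where(s > s_th, 1, -1)
    return s, labels


def save_model(path: str | Path, model: AdaBoostModel) -> None:
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "k": model.k,
        "seed": model.seed,
        "feature_names": model.feature_names,
        "imputation_medians": model.imputation_medians.tolist(),
        "learners": [
            {"feature": w.feature, "threshold": w.threshold, "polarity": w.polarity, "alpha": w.alpha}
            for w in model.learners
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> AdaBoostModel:
    try:
        payload = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, OSError) as exc:
        raise ValueError(f"cannot load model from {path}: {exc}") from exc
    if payload.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"model schema version {payload.get('schema_version')} != {MODEL_SCHEMA_VERSION}"
        )
    learners = [
        WeakLearner(int(w["feature"]), float(w["threshold"]), int(w["polarity"]), float(w["alpha"]))
        for w in payload["learners"]
    ]
    return AdaBoostModel(
        learners=learners,
        feature_names=list(payload["feature_names"]),
        imputation_medians=np.array(payload["imputation_medians"]),
        seed=int(payload.get("seed", 0)),
        k=int(payload["k"]),
    )
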