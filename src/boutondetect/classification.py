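"""SVM classification of candidate boutons from Gabor descriptors.

A support vector machine with a polynomial kernel of order 3 separates
bouton from non-bouton descriptors.  Raw decision values are affinely
scaled to [-1, 1] using the min/max observed on the training partition,
and a fixed operating threshold on the scaled score (default -0.0399,
the value selected on validation ROC analysis) turns scores into labels.
The scaler is persisted with the model so classification is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import joblib
import numpy as np
from sklearn.svm import SVC

#: Operating threshold on the scaled decision score.
DEFAULT_THRESHOLD = -0.0399

_MODEL_FORMAT_VERSION = 1


@dataclass
class ClassifierParams:
    """SVM hyperparameters and the operating threshold.

    kernel is ``"polynomial"`` (default, order ``degree``) or
    ``"gaussian"``; C is the margin-violation cost; gamma applies to the
    gaussian kernel (``None`` = the 1/(V * var) scale heuristic).
    """

    kernel: str = "polynomial"
    degree: int = 3
    C: float = 1.0
    gamma: float | None = None
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if self.kernel not in ("polynomial", "gaussian"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.kernel == "polynomial" and self.degree < 1:
            raise ValueError("polynomial degree must be >= 1")
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")

    def _svc(self) -> SVC:
        gamma = self.gamma if self.gamma is not None else "scale"
        if self.kernel == "polynomial":
            # coef0=1 gives the inhomogeneous polynomial kernel (u.v + 1)^d.
            return SVC(kernel="poly", degree=self.degree, C=self.C, coef0=1.0,
                       gamma=gamma)
        return SVC(kernel="rbf", C=self.C, gamma=gamma)


@dataclass
class LabelledFeatureSet:
    """Descriptors with binary labels (1 = bouton, 0 = non-bouton)."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2 or len(self.features) != len(self.labels):
            raise ValueError("features must be 2D with one label per row")


@dataclass
class TrainedClassifier:
    """Fitted SVM plus the score scaler and training metadata."""

    model: SVC
    scaler: tuple[float, float]
    params: ClassifierParams
    n_train_per_class: dict[int, int] = field(default_factory=dict)
    seed: int | None = None
    validation_accuracy: float | None = None

    @property
    def n_features(self) -> int:
        return int(self.model.n_features_in_)


def _balanced_downsample(
    data: LabelledFeatureSet, rng: np.random.Generator
) -> LabelledFeatureSet:
    """Down-sample the majority class so both classes are equal-sized."""
    idx_pos = np.flatnonzero(data.labels == 1)
    idx_neg = np.flatnonzero(data.labels == 0)
    n = min(len(idx_pos), len(idx_neg))
    keep = np.sort(
        np.concatenate(
            [
                rng.choice(idx_pos, n, replace=False),
                rng.choice(idx_neg, n, replace=False),
            ]
        )
    )
    return LabelledFeatureSet(data.features[keep], data.labels[keep])


def _partition(
    data: LabelledFeatureSet, seed: int, split: float, balance: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic balanced train/validation partition."""
    rng = np.random.default_rng(seed)
    if balance:
        data = _balanced_downsample(data, rng)
    n = len(data.labels)
    perm = rng.permutation(n)
    n_train = max(2, int(round(split * n)))
    tr, va = perm[:n_train], perm[n_train:]
    return data.features[tr], data.labels[tr], data.features[va], data.labels[va]


def train(
    data: LabelledFeatureSet,
    params: ClassifierParams | None = None,
    split_seed: int = 0,
    split: float = 0.8,
    balance: bool = True,
    calibrate_threshold: bool = False,
) -> TrainedClassifier:
    """Fit the SVM on a train/validation split of the labelled set.

    The split is 80/20 by default (matching a 720/180 partition of 900
    patches); the majority class is down-sampled first so training is
    balanced.  Raw decision values on the training partition define the
    [-1, 1] score scaling.  Fully deterministic given ``split_seed``.

    With ``calibrate_threshold`` the operating threshold is re-derived on
    the validation partition (F1-optimal over a 1000-point scaled-score
    grid) instead of keeping the configured default.  Because the min-max
    score scaling depends on the training set's score spread, a fixed
    scaled threshold does not transfer between datasets; calibration is
    the recommended path when training on new data.
    """
    if params is None:
        params = ClassifierParams()
    classes = np.unique(data.labels)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    X_tr, y_tr, X_va, y_va = _partition(data, split_seed, split, balance)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training partition lost a class; reseed or rebalance")

    model = params._svc()
    model.fit(X_tr, y_tr)
    raw = model.decision_function(X_tr)
    scaler = (float(raw.min()), float(raw.max()))
    if scaler[1] <= scaler[0]:
        raise ValueError("degenerate decision scores on the training partition")

    val_acc = None
    if len(y_va) > 0:
        val_acc = float(np.mean(model.predict(X_va) == y_va))
    counts = {int(c): int(np.sum(y_tr == c)) for c in classes}
    clf = TrainedClassifier(model, scaler, params, counts, split_seed, val_acc)
    if calibrate_threshold:
        if len(y_va) == 0:
            raise ValueError("threshold calibration needs a validation partition")
        scores = scale_scores(model.decision_function(X_va), scaler)
        clf.params = replace(params, threshold=select_threshold(scores, y_va))
    return clf


def select_threshold(
    scaled_scores: np.ndarray, labels: np.ndarray, n_grid: int = 1000
) -> float:
    """F1-optimal operating threshold over an even grid of scaled scores.

    Scans ``n_grid`` thresholds on [-1, 1] and returns the one
    maximizing F1 of ``scaled_score >= threshold`` against ``labels``;
    ties go to the largest threshold (fewest positives).
    """
    grid = np.linspace(-1.0, 1.0, n_grid)
    best_t, best_f1 = grid[0], -1.0
    for t in grid:
        f1 = _binary_f1((scaled_scores >= t).astype(int), labels)
        if f1 >= best_f1:
            best_f1, best_t = f1, t
    return float(best_t)


def scale_scores(raw, scaler: tuple[float, float]) -> np.ndarray:
    """Affine map sending scaler min -> -1 and max -> 1 (no clipping)."""
    lo, hi = scaler
    if hi <= lo:
        raise ValueError("scaler max must exceed min")
    return (2.0 * (np.asarray(raw, dtype=np.float64) - lo) / (hi - lo)) - 1.0


def classify(
    model: TrainedClassifier, features: np.ndarray, threshold: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Label candidates at the operating threshold.

    Returns ``(labels, scaled_scores)``; label is 1 (bouton) iff the
    scaled score >= threshold.  Scores accompany labels so downstream
    threshold sweeps need no re-classification.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[1] != model.n_features:
        raise ValueError(
            f"feature length {features.shape} does not match model ({model.n_features})"
        )
    if threshold is None:
        threshold = model.params.threshold
    if len(features) == 0:
        return np.zeros(0, dtype=int), np.zeros(0)
    scores = scale_scores(model.model.decision_function(features), model.scaler)
    return (scores >= threshold).astype(int), scores


def grid_search(
    data: LabelledFeatureSet,
    grid: dict[str, list] | None = None,
    seed: int = 0,
) -> ClassifierParams:
    """Exhaustive hyperparameter search maximizing validation F1.

    Ties are broken toward smaller C, then lower polynomial degree, so
    the simplest competitive model wins.
    """
    if grid is None:
        grid = {"degree": [2, 3], "C": [0.1, 1.0, 10.0]}
    degrees = grid.get("degree", [3])
    costs = grid.get("C", [1.0])
    if not degrees or not costs:
        raise ValueError("empty hyperparameter grid")

    _, _, X_va, y_va = _partition(data, seed, 0.8, balance=True)
    best: tuple[float, float, int] | None = None
    best_params: ClassifierParams | None = None
    for degree in degrees:
        for C in costs:
            params = ClassifierParams(degree=int(degree), C=float(C))
            clf = train(data, params, split_seed=seed)
            f1 = _binary_f1(clf.model.predict(X_va), y_va) if len(y_va) else 0.0
            key = (-f1, C, degree)
            if best is None or key < best:
                best, best_params = key, params
    assert best_params is not None
    return best_params


def _binary_f1(pred: np.ndarray, truth: np.ndarray) -> float:
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def save_model(path: str | Path, model: TrainedClassifier) -> None:
    """Persist model + scaler + params as a versioned joblib archive."""
    joblib.dump(
        {
            "format_version": _MODEL_FORMAT_VERSION,
            "model": model.model,
            "scaler": model.scaler,
            "params": asdict(model.params),
            "n_train_per_class": model.n_train_per_class,
            "seed": model.seed,
            "validation_accuracy": model.validation_accuracy,
        },
        Path(path),
    )


def load_model(path: str | Path) -> TrainedClassifier:
    blob = joblib.load(Path(path))
    version = blob.get("format_version")
    if version != _MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model archive version {version!r} != supported {_MODEL_FORMAT_VERSION}"
        )
    return TrainedClassifier(
        blob["model"],
        tuple(blob["scaler"]),
        ClassifierParams(**blob["params"]),
        blob["n_train_per_class"],
        blob["seed"],
        blob["validation_accuracy"],
    )
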