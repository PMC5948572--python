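"""Per-position supervised fall detectors and multi-sensor decision fusion.

Four classifier families are wrapped behind a common surface: RBF-kernel
SVM, k-nearest neighbors (k = 9, Euclidean distance), Gaussian Naive
Bayes and a Gini decision tree. Distance/kernel methods (SVM, k-NN)
operate on train-set z-scored features; trees and Naive Bayes see raw
features. Decisions from several positions are combined with an AND
(alarm only if every position alarms) or OR policy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from fallban.types import FEATURE_NAMES, Position

ALGORITHMS = ("svm", "knn", "naive_bayes", "decision_tree")

#: Algorithms whose features are standardized before fitting.
_STANDARDIZED = {"svm", "knn"}

FALL, ADL = "fall", "adl"

_MODEL_FORMAT_VERSION = 1


@dataclass
class TrainedDetector:
    """A fitted per-position classifier over a feature subset."""

    algorithm: str
    position: Position | None
    feature_subset: tuple[str, ...]
    model: object
    mean: np.ndarray | None = None  # standardizer, None when unstandardized
    sd: np.ndarray | None = None

    def _matrix(self, features) -> np.ndarray:
        """Assemble and optionally standardize the design matrix."""
        if isinstance(features, pd.DataFrame):
            missing = [f for f in self.feature_subset if f not in features.columns]
            if missing:
                raise KeyError(f"missing feature(s): {', '.join(missing)}")
            x = features[list(self.feature_subset)].to_numpy(dtype=float)
        else:
            try:
                x = np.array(
                    [[features[f] for f in self.feature_subset]], dtype=float
                )
            except KeyError as exc:
                raise KeyError(f"missing feature: {exc.args[0]}") from None
        if self.mean is not None:
            x = (x - self.mean) / self.sd
        return x

    def predict(self, features) -> np.ndarray:
        """Decisions ('fall'/'adl') for a feature table or single mapping.

        k-NN votes that tie (possible only with an even, reduced k) go
        to 'fall', favoring sensitivity.
        """
        x = self._matrix(features)
        if self.algorithm == "knn":
            proba = self.model.predict_proba(x)
            fall_col = list(self.model.classes_).index(FALL)
            return np.where(proba[:, fall_col] >= 0.5, FALL, ADL)
        return np.asarray(self.model.predict(x))

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        joblib.dump({"format_version": _MODEL_FORMAT_VERSION, "detector": self}, path)
        return path

    @staticmethod
    def load(path: str | Path) -> "TrainedDetector":
        payload = joblib.load(path)
        if payload.get("format_version") != _MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model file version")
        return payload["detector"]


def _make_model(algorithm: str, n_train: int):
    if algorithm == "svm":
        # non-linear default: RBF kernel, C=1, gamma = 1/(n_feat * var)
        return SVC(kernel="rbf", C=1.0, gamma="scale")
    if algorithm == "knn":
        k = 9
        if k > n_train:
            warnings.warn(f"reducing k from 9 to training size {n_train}")
            k = n_train
        return KNeighborsClassifier(n_neighbors=k, metric="euclidean")
    if algorithm == "naive_bayes":
        return GaussianNB()
    if algorithm == "decision_tree":
        return DecisionTreeClassifier(criterion="gini", random_state=0)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def train_detector(
    algorithm: str,
    table: pd.DataFrame,
    feature_subset: tuple[str, ...] | None = None,
    position: Position | None = None,
) -> TrainedDetector:
    """Fit one detector on the rows of a single position's feature table.

    ``table`` needs a ``label`` column plus the feature columns.
    Features with zero training spread are dropped (with a warning) for
    standardized algorithms.
    """
    feature_subset = tuple(feature_subset or FEATURE_NAMES)
    if not feature_subset:
        raise ValueError("feature subset must be non-empty")
    y = table["label"].to_numpy()
    classes = set(y)
    if classes != {FALL, ADL}:
        raise ValueError(
            f"training set must contain both classes, got {sorted(classes)}"
        )
    x = table[list(feature_subset)].to_numpy(dtype=float)

    mean = sd = None
    if algorithm in _STANDARDIZED:
        mean = x.mean(axis=0)
        sd = x.std(axis=0)
        degenerate = sd == 0
        if degenerate.any():
            dropped = [f for f, d in zip(feature_subset, degenerate) if d]
            warnings.warn(f"dropping zero-variance feature(s): {dropped}")
            keep = ~degenerate
            if not keep.any():
                raise ValueError("all features have zero training variance")
            feature_subset = tuple(
                f for f, k in zip(feature_subset, keep) if k
            )
            x, mean, sd = x[:, keep], mean[keep], sd[keep]
        x = (x - mean) / sd

    model = _make_model(algorithm, len(y))
    model.fit(x, y)
    return TrainedDetector(
        algorithm=algorithm,
        position=position,
        feature_subset=feature_subset,
        model=model,
        mean=mean,
        sd=sd,
    )


def predict_trial(detector: TrainedDetector, features) -> str:
    """Classify a single trial's features at the detector's position."""
    return str(detector.predict(features)[0])


@dataclass(frozen=True)
class FusionRule:
    """Decision-combination policy over a set of positions."""

    positions: tuple[Position, ...]
    policy: str = "AND"

    def __post_init__(self) -> None:
        if not 1 <= len(self.positions) <= 5:
            raise ValueError("fusion requires 1-5 positions")
        if self.policy not in ("AND", "OR"):
            raise ValueError("policy must be 'AND' or 'OR'")


def fuse_decisions(decisions: dict[Position, str], rule: FusionRule) -> str:
    """Combine per-position decisions.

    AND: fall only if every considered position says fall (conservative
    toward false alarms). OR: fall if any position says fall.
    """
    missing = [p for p in rule.positions if p not in decisions]
    if missing:
        raise KeyError(f"missing decision for position(s): {missing}")
    votes = [decisions[p] == FALL for p in rule.positions]
    is_fall = all(votes) if rule.policy == "AND" else any(votes)
    return FALL if is_fall else ADL
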