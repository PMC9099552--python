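"""End-to-end detection: difference representation, BrAC labeling, models.

The detector never looks at a single session in isolation.  It computes the
228-feature vector of the sober baseline session and of the suspect
session, subtracts them elementwise (after − before) — a per-subject
normalization that cancels stable individual gait style — and feeds the
difference to a binary classifier.  Ground-truth labels come from the
suspect session's breathalyzer reading compared against a legal BrAC
threshold (220, 240 or 380 µg alcohol per liter of breath, depending on
jurisdiction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from scipy.special import expit
from sklearn.ensemble import AdaBoostClassifier, GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureVector, N_FEATURES, canonical_feature_names, extract_features
from .signal_model import GaitSample, SubjectPair

__all__ = [
    "Label",
    "EstimatorKind",
    "DifferenceVector",
    "LabeledInstance",
    "DetectionModel",
    "BRAC_THRESHOLDS",
    "difference",
    "label_from_brac",
    "build_dataset",
    "is_intoxicated",
    "instances_to_matrix",
    "save_model",
    "load_model",
]

#: Legal BrAC thresholds (µg/L breath) in common use worldwide.
BRAC_THRESHOLDS = (220.0, 240.0, 380.0)


class Label(str, Enum):
    SOBER = "sober"
    INTOXICATED = "intoxicated"


class EstimatorKind(str, Enum):
    ADABOOST = "adaboost"
    GBM = "gbm"
    LOGISTIC = "logistic"
    NAIVE_BAYES = "naive_bayes"
    SVM = "svm"


@dataclass(frozen=True)
class DifferenceVector:
    """Elementwise after-minus-before feature differences, canonically ordered."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "names", tuple(self.names))
        if len(self.names) != N_FEATURES or len(vals) != N_FEATURES:
            raise ValueError(f"difference vector must have exactly {N_FEATURES} entries")
        if list(self.names) != canonical_feature_names():
            raise ValueError("difference names are not in canonical order")


def difference(f_after: FeatureVector, f_before: FeatureVector) -> DifferenceVector:
    """after − before, elementwise; both vectors must share the canonical order."""
    if f_after.names != f_before.names:
        raise ValueError("feature name order mismatch between after and before vectors")
    return DifferenceVector(names=f_after.names, values=f_after.values - f_before.values)


def label_from_brac(brac: float, threshold: float) -> Label:
    """Intoxicated iff the BrAC reading reaches the threshold.

    Equality at the threshold labels as intoxicated (safety-first
    convention for the boundary the strict less/greater rule leaves open).
    """
    if brac < 0:
        raise ValueError("brac must be non-negative")
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    return Label.INTOXICATED if brac >= threshold else Label.SOBER


@dataclass(frozen=True)
class LabeledInstance:
    """A subject's difference vector with its BrAC-threshold label."""

    subject_id: str
    difference: DifferenceVector
    brac_after: float
    threshold: float
    label: Label

    def __post_init__(self) -> None:
        if self.label is not label_from_brac(self.brac_after, self.threshold):
            raise ValueError(
                f"label {self.label.value!r} inconsistent with brac_after="
                f"{self.brac_after} at threshold {self.threshold}"
            )


def build_dataset(
    pairs: Sequence[SubjectPair], threshold: float
) -> list[LabeledInstance]:
    """One labeled difference instance per subject pair.

    Labeling uses the after-session breathalyzer result only; the before
    reading is part of the experimental protocol (subjects arrive sober)
    and is not consulted.
    """
    ids = [p.subject_id for p in pairs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subject_ids: {dupes}")
    instances = []
    for pair in pairs:
        diff = difference(
            extract_features(pair.sample_after), extract_features(pair.sample_before)
        )
        brac = pair.sample_after.brac
        instances.append(
            LabeledInstance(
                subject_id=pair.subject_id,
                difference=diff,
                brac_after=brac,
                threshold=threshold,
                label=label_from_brac(brac, threshold),
            )
        )
    return instances


def instances_to_matrix(
    instances: Sequence[LabeledInstance],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack instances into (X, y, subject_ids) with y=1 for intoxicated."""
    X = np.vstack([inst.difference.values for inst in instances])
    y = np.array([1 if inst.label is Label.INTOXICATED else 0 for inst in instances])
    return X, y, [inst.subject_id for inst in instances]


def _make_estimator(kind: EstimatorKind, seed: int | None):
    if kind is EstimatorKind.ADABOOST:
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=100,
            random_state=seed,
        )
    if kind is EstimatorKind.GBM:
        # many weak trees with a low learning rate
        return GradientBoostingClassifier(
            n_estimators=500, learning_rate=0.01, max_depth=1, random_state=seed
        )
    if kind is EstimatorKind.LOGISTIC:
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(max_iter=1000, random_state=seed)),
            ]
        )
    if kind is EstimatorKind.NAIVE_BAYES:
        return GaussianNB()
    if kind is EstimatorKind.SVM:
        return Pipeline(
            [("scale", StandardScaler()), ("clf", SVC(kernel="linear", random_state=seed))]
        )
    raise ValueError(f"unknown estimator kind: {kind}")


@dataclass
class DetectionModel:
    """A trained classifier plus a confidence threshold on its [0, 1] score.

    ``score`` is the model's confidence that the difference vector reflects
    intoxication; for the margin-based SVM the signed distance to the
    hyperplane is squashed through a logistic function, which is monotone
    and therefore inert for rank-based metrics.
    """

    estimator_kind: EstimatorKind
    confidence_threshold: float = 0.5
    seed: int | None = None
    feature_names: tuple[str, ...] = field(
        default_factory=lambda: tuple(canonical_feature_names())
    )
    _estimator: object | None = None
    _fitted: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValueError("confidence_threshold must lie in [0, 1]")
        if self._estimator is None:
            self._estimator = _make_estimator(self.estimator_kind, self.seed)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DetectionModel":
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"X has {X.shape[1]} columns; model expects {len(self.feature_names)}"
            )
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self._estimator.fit(X, y)
        self._fitted = True
        return self

    def score(self, x: np.ndarray) -> float:
        """Confidence in [0, 1] that a single difference vector is intoxicated."""
        return float(self.score_many(np.atleast_2d(x))[0])

    def score_many(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise ValueError("model has not been fitted")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"X has {X.shape[1]} columns; model expects {len(self.feature_names)}"
            )
        est = self._estimator
        if hasattr(est, "predict_proba"):
            return est.predict_proba(X)[:, 1]
        return expit(est.decision_function(X))


def is_intoxicated(
    model: DetectionModel, s_sober: GaitSample, s_suspect: GaitSample
) -> bool:
    """The full decision procedure: features → difference → score > threshold."""
    diff = difference(extract_features(s_suspect), extract_features(s_sober))
    return model.score(diff.values) > model.confidence_threshold


def save_model(model: DetectionModel, path: Path | str) -> None:
    if not model._fitted:
        raise ValueError("refusing to save an unfitted model")
    joblib.dump(
        {
            "estimator_kind": model.estimator_kind.value,
            "confidence_threshold": model.confidence_threshold,
            "feature_names": list(model.feature_names),
            "estimator": model._estimator,
        },
        path,
    )


def load_model(path: Path | str) -> DetectionModel:
    blob = joblib.load(path)
    names = tuple(blob["feature_names"])
    if list(names) != canonical_feature_names():
        raise ValueError("model artifact's feature names disagree with this version")
    model = DetectionModel(
        estimator_kind=EstimatorKind(blob["estimator_kind"]),
        confidence_threshold=float(blob["confidence_threshold"]),
        feature_names=names,
        _estimator=blob["estimator"],
    )
    model._fitted = True
    return model
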