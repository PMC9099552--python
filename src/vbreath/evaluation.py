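"""Leave-one-user-out evaluation, ROC metrics, operating-point policies, ablations.

With one difference instance per subject, the natural cross-validation unit
is the subject: each fold trains on n−1 subjects and scores the held-out
one, which rules out identity leakage.  Because each fold yields a single
prediction, per-fold ROC curves are undefined; all metrics here are
computed over the pooled out-of-fold scores.

Two deployment policies are evaluated besides the AUC:

* **FPR at TPR = 1.0** — lower the decision threshold until every truly
  intoxicated subject is flagged, and report the fraction of sober
  subjects swept up with them (the cost of never missing a drunk user).
* **TPR at FPR = 0** — raise the threshold until no sober subject is
  flagged, and report the fraction of intoxicated subjects still caught
  (the yield of never raising a false alarm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from .features import parse_feature_name
from .pipeline import (
    DetectionModel,
    EstimatorKind,
    Label,
    LabeledInstance,
    instances_to_matrix,
)
from .signal_model import Device, Sensor

__all__ = [
    "ScoredSubject",
    "EvalResult",
    "AblationSpec",
    "compute_auc",
    "fpr_at_full_tpr",
    "tpr_at_zero_fpr",
    "leave_one_user_out",
    "run_ablation",
]


@dataclass(frozen=True)
class ScoredSubject:
    subject_id: str
    score: float
    label: Label


@dataclass(frozen=True)
class EvalResult:
    """Pooled out-of-fold scores and the metrics derived from them."""

    threshold: float
    estimator_kind: EstimatorKind
    pooled_scores: tuple[ScoredSubject, ...]
    auc: float
    confusion: np.ndarray  # [[TP, FN], [FP, TN]] at score > 0.5
    policy_fpr_at_full_tpr: float
    policy_tpr_at_zero_fpr: float

    def __post_init__(self) -> None:
        conf = np.asarray(self.confusion, dtype=int)
        object.__setattr__(self, "confusion", conf)
        if conf.shape != (2, 2):
            raise ValueError("confusion must be 2x2")
        if conf.sum() != len(self.pooled_scores):
            raise ValueError("confusion entries must sum to the number of subjects")
        for name in ("auc", "policy_fpr_at_full_tpr", "policy_tpr_at_zero_fpr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "estimator_kind": self.estimator_kind.value,
            "auc": self.auc,
            "confusion": self.confusion.tolist(),
            "fpr_at_full_tpr": self.policy_fpr_at_full_tpr,
            "tpr_at_zero_fpr": self.policy_tpr_at_zero_fpr,
            "pooled_scores": [
                {"subject_id": s.subject_id, "score": s.score, "label": s.label.value}
                for s in self.pooled_scores
            ],
        }


def _split_scores(
    scores_with_labels: Iterable[tuple[float, Label]],
) -> tuple[np.ndarray, np.ndarray]:
    pos, neg = [], []
    for score, label in scores_with_labels:
        (pos if label is Label.INTOXICATED else neg).append(float(score))
    return np.asarray(pos), np.asarray(neg)


def compute_auc(scores_with_labels: Iterable[tuple[float, Label]]) -> float:
    """Probability a random intoxicated score exceeds a random sober score.

    Mann–Whitney formulation with ties counted one half; requires both
    labels to be present.
    """
    pos, neg = _split_scores(scores_with_labels)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC is undefined without both labels present")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def fpr_at_full_tpr(scores_with_labels: Iterable[tuple[float, Label]]) -> float:
    """FPR once the threshold is lowered until every intoxicated subject is caught.

    The decision threshold is set at the minimum intoxicated score
    (inclusive), so TPR = 1; the return value is the fraction of sober
    subjects at or above that threshold.
    """
    pos, neg = _split_scores(scores_with_labels)
    if len(pos) == 0:
        raise ValueError("policy undefined without intoxicated instances")
    if len(neg) == 0:
        return 0.0
    return float(np.mean(neg >= pos.min()))


def tpr_at_zero_fpr(scores_with_labels: Iterable[tuple[float, Label]]) -> float:
    """TPR once the threshold is raised until no sober subject is flagged.

    The decision threshold sits strictly above the maximum sober score;
    the return value is the fraction of intoxicated subjects above it.
    """
    pos, neg = _split_scores(scores_with_labels)
    if len(neg) == 0:
        raise ValueError("policy undefined without sober instances")
    if len(pos) == 0:
        return 0.0
    return float(np.mean(pos > neg.max()))


@dataclass(frozen=True)
class AblationSpec:
    """Restriction of the feature set by device, sensor, and/or family.

    ``mode="only"`` keeps features matching all three subsets;
    ``mode="all_except"`` keeps the complement of that selection.
    """

    devices: frozenset[Device] = frozenset(Device)
    sensors: frozenset[Sensor] = frozenset(Sensor)
    families: frozenset[str] = frozenset({"spectral", "statistical", "histogram", "gait"})
    mode: str = "only"

    def __post_init__(self) -> None:
        object.__setattr__(self, "devices", frozenset(Device(d) for d in self.devices))
        object.__setattr__(self, "sensors", frozenset(Sensor(s) for s in self.sensors))
        object.__setattr__(self, "families", frozenset(self.families))
        if self.mode not in ("only", "all_except"):
            raise ValueError("mode must be 'only' or 'all_except'")

    def selected_indices(self, names: Sequence[str]) -> np.ndarray:
        keep = []
        for i, name in enumerate(names):
            device, sensor, _axis, family, _idx = parse_feature_name(name)
            match = (
                device in self.devices
                and sensor in self.sensors
                and family in self.families
            )
            if match == (self.mode == "only"):
                keep.append(i)
        idx = np.asarray(keep, dtype=int)
        if len(idx) == 0:
            raise ValueError("ablation spec selects no features")
        return idx


def _metrics_from_scores(
    threshold: float, estimator_kind: EstimatorKind, scored: list[ScoredSubject]
) -> EvalResult:
    pairs = [(s.score, s.label) for s in scored]
    preds = np.array([s.score > 0.5 for s in scored])
    truth = np.array([s.label is Label.INTOXICATED for s in scored])
    tp = int(np.sum(preds & truth))
    fn = int(np.sum(~preds & truth))
    fp = int(np.sum(preds & ~truth))
    tn = int(np.sum(~preds & ~truth))
    return EvalResult(
        threshold=threshold,
        estimator_kind=estimator_kind,
        pooled_scores=tuple(scored),
        auc=compute_auc(pairs),
        confusion=np.array([[tp, fn], [fp, tn]]),
        policy_fpr_at_full_tpr=fpr_at_full_tpr(pairs),
        policy_tpr_at_zero_fpr=tpr_at_zero_fpr(pairs),
    )


def leave_one_user_out(
    instances: Sequence[LabeledInstance],
    estimator_kind: EstimatorKind | str,
    seed: int = 0,
    feature_indices: np.ndarray | None = None,
) -> EvalResult:
    """One fold per subject; metrics over the pooled out-of-fold scores.

    Each fold fits a fresh model on the other n−1 subjects and scores the
    held-out one.  Requires at least 3 instances and both labels present
    overall (AUC is undefined on a single class).
    """
    estimator_kind = EstimatorKind(estimator_kind)
    if len(instances) < 3:
        raise ValueError("need at least 3 instances for leave-one-user-out")
    X, y, ids = instances_to_matrix(instances)
    if len(np.unique(y)) < 2:
        raise ValueError("dataset contains a single class; AUC is undefined")
    if feature_indices is not None:
        X = X[:, feature_indices]
        names = tuple(
            np.asarray(instances[0].difference.names)[feature_indices].tolist()
        )
    else:
        names = instances[0].difference.names

    threshold = instances[0].threshold
    scored: list[ScoredSubject] = []
    n = len(instances)
    for k in range(n):
        train = np.arange(n) != k
        if len(np.unique(y[train])) < 2:
            # a fold whose training half is single-class cannot be fitted;
            # score the held-out subject at indifference
            scored.append(ScoredSubject(ids[k], 0.5, instances[k].label))
            continue
        model = DetectionModel(
            estimator_kind=estimator_kind, seed=seed, feature_names=names
        )
        model.fit(X[train], y[train])
        scored.append(
            ScoredSubject(ids[k], model.score(X[k]), instances[k].label)
        )
    return _metrics_from_scores(threshold, estimator_kind, scored)


def run_ablation(
    instances: Sequence[LabeledInstance],
    spec: AblationSpec,
    estimator_kind: EstimatorKind | str,
    seed: int = 0,
) -> EvalResult:
    """Leave-one-user-out on the feature subset an AblationSpec selects."""
    if not instances:
        raise ValueError("no instances")
    idx = spec.selected_indices(instances[0].difference.names)
    return leave_one_user_out(instances, estimator_kind, seed, feature_indices=idx)
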