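"""Binary-classification evaluation: ROC/AUC with bootstrap CIs,
sensitivity, specificity and the confusion matrix.

AUC is the area under the receiver operating characteristic curve, equal to
the Mann–Whitney probability that a random case outscores a random control
(ties counted half).  Confidence intervals come from a stratified percentile
bootstrap: cases and controls are resampled within class, so every resample
retains both classes.  Sensitivity and specificity are reported at a fixed
operating threshold (default 0.5 on the case probability) or at the
Youden-optimal point.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "EvalReport", "roc_auc", "bootstrap_ci", "confusion_and_rates",
    "evaluate_scores", "youden_threshold",
]


@dataclasses.dataclass
class EvalReport:
    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    confusion: np.ndarray  # rows: true (control, case); cols: predicted
    threshold: float
    threshold_policy: str
    n_pos: int
    n_neg: int
    roc_fpr: np.ndarray | None = None
    roc_tpr: np.ndarray | None = None
    roc_thresholds: np.ndarray | None = None

    def __post_init__(self):
        tn, fp, fn, tp = self.confusion.ravel()
        if tn + fp + fn + tp != self.n_pos + self.n_neg:
            raise ValueError("confusion counts must sum to n_pos + n_neg")
        for point, (lo, hi) in [
            (self.auc, self.auc_ci),
            (self.sensitivity, self.sensitivity_ci),
            (self.specificity, self.specificity_ci),
        ]:
            if not (lo - 1e-12 <= point <= hi + 1e-12):
                raise ValueError("CI must contain its point estimate")

    def to_dict(self) -> dict:
        d = {
            "auc": self.auc, "auc_ci": list(self.auc_ci),
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
            "confusion": self.confusion.tolist(),
            "threshold": self.threshold,
            "threshold_policy": self.threshold_policy,
            "n_pos": self.n_pos, "n_neg": self.n_neg,
        }
        return d

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def save_roc_csv(self, path: str | Path) -> None:
        if self.roc_fpr is None:
            raise ValueError("report carries no ROC curve")
        lines = ["fpr,tpr,threshold"]
        for f, t, th in zip(self.roc_fpr, self.roc_tpr, self.roc_thresholds):
            lines.append(f"{f},{t},{th}")
        Path(path).write_text("\n".join(lines) + "\n")


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.int64)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("AUC is undefined with a single class present")
    return labels


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (Mann–Whitney form, ties count half)."""
    labels = _check_binary(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def sensitivity_at(scores, labels, threshold: float) -> float:
    scores = np.asarray(scores); labels = np.asarray(labels)
    pos = labels == 1
    return float((scores[pos] >= threshold).mean())


def specificity_at(scores, labels, threshold: float) -> float:
    scores = np.asarray(scores); labels = np.asarray(labels)
    neg = labels == 0
    return float((scores[neg] < threshold).mean())


def youden_threshold(scores, labels) -> float:
    """Threshold maximising sensitivity + specificity − 1."""
    labels = _check_binary(labels)
    fpr, tpr, thr = roc_curve(labels, scores)
    j = tpr - fpr
    return float(thr[int(np.argmax(j))])


def bootstrap_ci(scores, labels, statistic, n_boot: int = 2000,
                 seed: int = 0, alpha: float = 0.05) -> tuple[float, float]:
    """Stratified percentile bootstrap CI for ``statistic(scores, labels)``.

    Resampling is within-class, so both classes are always represented.
    Deterministic given ``seed``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([
            rng.choice(pos, size=pos.size, replace=True),
            rng.choice(neg, size=neg.size, replace=True),
        ])
        stats[b] = statistic(scores[idx], labels[idx])
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def confusion_and_rates(scores, labels, threshold: float = 0.5):
    """(confusion 2×2, sensitivity, specificity) at a threshold.

    Confusion layout follows the usual convention: rows are true class
    (control, case), columns predicted class; sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    pred = (scores >= threshold).astype(np.int64)
    cm = _sk_confusion(labels, pred, labels=[0, 1])
    tn, fp, fn, tp = cm.ravel()
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return cm, float(sens), float(spec)


def evaluate_scores(scores, labels, *, threshold: float | None = 0.5,
                    threshold_policy: str = "fixed",
                    n_boot: int = 2000, seed: int = 0) -> EvalReport:
    """Full evaluation report for per-image case probabilities.

    ``threshold_policy`` is ``"fixed"`` (use ``threshold``) or ``"youden"``
    (pick the Youden-J optimal operating point from the scores).
    """
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if threshold_policy == "youden":
        threshold = youden_threshold(scores, labels)
    elif threshold_policy != "fixed":
        raise ValueError("threshold_policy must be 'fixed' or 'youden'")
    def _bracket(ci, point):
        # percentile intervals can exclude the point estimate by a hair on
        # tiny samples; widen minimally so the report invariant holds
        return (min(ci[0], point), max(ci[1], point))

    auc = roc_auc(scores, labels)
    auc_ci = _bracket(
        bootstrap_ci(scores, labels, roc_auc, n_boot=n_boot, seed=seed), auc)
    cm, sens, spec = confusion_and_rates(scores, labels, threshold)
    sens_ci = _bracket(bootstrap_ci(
        scores, labels, lambda s, y: sensitivity_at(s, y, threshold),
        n_boot=n_boot, seed=seed + 1), sens)
    spec_ci = _bracket(bootstrap_ci(
        scores, labels, lambda s, y: specificity_at(s, y, threshold),
        n_boot=n_boot, seed=seed + 2), spec)
    fpr, tpr, thr = roc_curve(labels, scores)
    return EvalReport(
        auc=auc, auc_ci=auc_ci,
        sensitivity=sens, sensitivity_ci=sens_ci,
        specificity=spec, specificity_ci=spec_ci,
        confusion=cm, threshold=float(threshold),
        threshold_policy=threshold_policy,
        n_pos=int((labels == 1).sum()), n_neg=int((labels == 0).sum()),
        roc_fpr=fpr, roc_tpr=tpr, roc_thresholds=thr,
    )
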