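"""Classifier evaluation: confusion metrics at a probability cutoff, ROC
curves, AUC and its confidence interval.

Boundary and tie conventions are explicit: a score exactly at the cutoff is
a positive call, and tied case/control scores contribute 1/2 to the AUC
(Mann-Whitney convention), so the AUC equals the trapezoidal area under the
tie-aware ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_auc_score, roc_curve


@dataclass
class ConfusionMetrics:
    """Integer confusion counts at a fixed probability cutoff."""

    tp: int
    fp: int
    tn: int
    fn: int
    cutoff: float = 0.5

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def _check_scores_labels(scores, labels, probabilities=True):
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=float).ravel()
    if scores.size == 0:
        raise ValueError("empty score vector")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    if not np.all((labels == 0) | (labels == 1)):
        raise ValueError("labels must be binary 0/1")
    if probabilities and (scores.min() < 0 or scores.max() > 1):
        raise ValueError("scores must be probabilities in [0, 1]")
    return scores, labels.astype(int)


def confusion_at_cutoff(scores, labels, cutoff: float = 0.5) -> ConfusionMetrics:
    """Exact confusion counts; score >= cutoff is a positive call."""
    scores, labels = _check_scores_labels(scores, labels)
    calls = scores >= cutoff
    return ConfusionMetrics(
        tp=int(np.sum(calls & (labels == 1))),
        fp=int(np.sum(calls & (labels == 0))),
        tn=int(np.sum(~calls & (labels == 0))),
        fn=int(np.sum(~calls & (labels == 1))),
        cutoff=cutoff,
    )


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci_low: float | None = None
    ci_high: float | None = None
    ci_method: str | None = None


def roc_auc(scores, labels) -> ROCResult:
    """ROC operating points and the Mann-Whitney AUC, ties counting 1/2."""
    scores, labels = _check_scores_labels(scores, labels, probabilities=False)
    if labels.min() == labels.max():
        raise ValueError("both classes required for a ROC curve")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def _delong_auc_variance(scores, labels) -> tuple[float, float]:
    """AUC and its DeLong variance via midrank placements."""
    x = scores[labels == 1]  # cases
    y = scores[labels == 0]  # controls
    m, n = len(x), len(y)
    tz = rankdata(np.concatenate([x, y]))
    tx = rankdata(x)
    ty = rankdata(y)
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (tz[:m] - tx) / n            # placements of cases among controls
    v01 = 1.0 - (tz[m:] - ty) / m      # placements of controls among cases
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def auc_ci(
    scores,
    labels,
    method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """95% (by default) CI for the AUC: DeLong normal interval or a
    stratified bootstrap percentile interval, truncated to [0, 1]."""
    scores, labels = _check_scores_labels(scores, labels, probabilities=False)
    if labels.min() == labels.max():
        raise ValueError("both classes required")
    if method == "delong":
        auc, var = _delong_auc_variance(scores, labels)
        z = norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(var)
        return (max(0.0, auc - half), min(1.0, auc + half))
    if method == "bootstrap":
        if n_boot < 100:
            from .io import log
            log.warning("n_boot=%d is small; interval will be noisy", n_boot)
        rng = np.random.default_rng(seed)
        pos = np.flatnonzero(labels == 1)
        neg = np.flatnonzero(labels == 0)
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            idx = np.concatenate([
                rng.choice(pos, len(pos), replace=True),
                rng.choice(neg, len(neg), replace=True),
            ])
            aucs[b] = roc_auc_score(labels[idx], scores[idx])
        lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
        return (float(max(0.0, lo)), float(min(1.0, hi)))
    raise ValueError(f"unknown CI method {method!r}")
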