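"""Classifier evaluation: AUROC, bootstrap resampling, confusion, PPV.

AUROC is computed through the Mann-Whitney identity — the probability
that a randomly drawn positive outscores a randomly drawn negative, with
ties counted one half — which permits a fully vectorised 10,000-draw
bootstrap over the test set.  Two classifiers' bootstrap AUROC
distributions are compared with Student's t-test.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import stats

__all__ = [
    "BootstrapResult",
    "ConfusionMatrix",
    "auroc",
    "bootstrap_auroc",
    "confusion",
    "ppv",
    "sensitivity",
    "specificity",
    "compare_bootstrap",
    "save_report",
]

DEFAULT_N_ITER = 10_000


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined (single-class input, empty cell)."""


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap distribution of AUROC over resampled test sets."""

    auroc_samples: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    sd: float
    n_iter: int
    seed: int
    n_skipped: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.mean <= self.ci_high:
            raise ValueError("confidence interval does not bracket the mean")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _validate_pairs(labels: np.ndarray, scores: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValueError("labels and scores must be 1-D arrays of equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    return labels.astype(int), scores


def auroc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Tie-aware AUROC via the Mann-Whitney rank identity."""
    labels, scores = _validate_pairs(labels, scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC is undefined when only one class is present")
    ranks = stats.rankdata(scores)
    pos_rank_sum = ranks[labels == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def bootstrap_auroc(
    labels: np.ndarray,
    scores: np.ndarray,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap the test-set AUROC.

    Each of ``n_iter`` iterations draws ``n`` indices with replacement
    (``n`` the test-set size) and recomputes AUROC.  Resamples
    containing a single class (AUROC undefined) are discarded and
    counted in ``n_skipped``.  The confidence interval is the 2.5/97.5
    percentile of the retained samples.
    """
    labels, scores = _validate_pairs(labels, scores)
    if labels.sum() in (0, len(labels)):
        raise UndefinedMetricError("AUROC is undefined when only one class is present")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(labels)
    idx = rng.integers(0, n, size=(n_iter, n))
    lab = labels[idx]
    sco = scores[idx]
    n_pos = lab.sum(axis=1)
    valid = (n_pos > 0) & (n_pos < n)
    n_skipped = int(n_iter - valid.sum())
    lab, sco, n_pos = lab[valid], sco[valid], n_pos[valid]
    ranks = stats.rankdata(sco, axis=1)
    pos_rank_sum = (ranks * lab).sum(axis=1)
    n_neg = n - n_pos
    samples = (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return BootstrapResult(
        auroc_samples=samples,
        mean=float(samples.mean()),
        ci_low=float(np.percentile(samples, 2.5)),
        ci_high=float(np.percentile(samples, 97.5)),
        sd=float(samples.std(ddof=1)) if len(samples) > 1 else 0.0,
        n_iter=n_iter,
        seed=seed,
        n_skipped=n_skipped,
    )


def confusion(labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> ConfusionMatrix:
    """Confusion counts of hard predictions ``score > threshold``."""
    labels, scores = _validate_pairs(labels, scores)
    pred = scores > threshold
    pos = labels == 1
    return ConfusionMatrix(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def ppv(cm: ConfusionMatrix) -> float:
    """Positive predictive value TP / (TP + FP)."""
    if cm.tp + cm.fp == 0:
        raise UndefinedMetricError("PPV undefined: no positive predictions")
    return cm.tp / (cm.tp + cm.fp)


def sensitivity(cm: ConfusionMatrix) -> float:
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive labels")
    return cm.tp / (cm.tp + cm.fn)


def specificity(cm: ConfusionMatrix) -> float:
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative labels")
    return cm.tn / (cm.tn + cm.fp)


def compare_bootstrap(
    a: BootstrapResult, b: BootstrapResult, welch: bool = False
) -> Tuple[float, float]:
    """Student's t-test between two bootstrap AUROC distributions.

    Returns ``(t_statistic, two_sided_p)`` with the classic
    equal-variance form by default (``welch=True`` for unequal
    variances).  The sign of ``t`` follows ``mean(a) - mean(b)``.
    """
    xa, xb = a.auroc_samples, b.auroc_samples
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("need at least two retained samples per distribution")
    if xa.std() == 0.0 and xb.std() == 0.0:
        raise ValueError("degenerate comparison: both distributions have zero variance")
    t, p = stats.ttest_ind(xa, xb, equal_var=not welch)
    return float(t), float(p)


def save_report(
    path: os.PathLike | str,
    labels: np.ndarray,
    scores: np.ndarray,
    boot: BootstrapResult,
    samples_csv: os.PathLike | str | None = None,
) -> dict:
    """Write a JSON evaluation report (and optionally the bootstrap samples)."""
    cm = confusion(labels, scores)
    report = {
        "auroc": auroc(labels, scores),
        "bootstrap_mean": boot.mean,
        "bootstrap_ci": [boot.ci_low, boot.ci_high],
        "bootstrap_sd": boot.sd,
        "n_iter": boot.n_iter,
        "n_skipped": boot.n_skipped,
        "confusion": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
        "ppv": ppv(cm) if cm.tp + cm.fp > 0 else None,
        "sensitivity": sensitivity(cm) if cm.tp + cm.fn > 0 else None,
        "specificity": specificity(cm) if cm.tn + cm.fp > 0 else None,
    }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
    if samples_csv is not None:
        np.savetxt(samples_csv, boot.auroc_samples, delimiter=",", header="auroc", comments="")
    return report
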