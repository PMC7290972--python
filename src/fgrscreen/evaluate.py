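"""Diagnostic-performance evaluation and minimal-sample-size power analysis.

Confusion metrics follow the standard definitions (sensitivity TP/(TP+FN),
specificity TN/(TN+FP), PPV TP/(TP+FP), NPV TN/(TN+FN), Youden
J = sensitivity + specificity − 1). Rates with a zero denominator are
undefined and reported as NaN, never as zero. Reported values are rounded
half-up to two decimals to match clinical reporting conventions; raw values
are always retained.

The ROC/AUC uses the rank (Mann-Whitney) formulation on graded scores —
here the cumulative 0–3 score — with ties credited 0.5, which equals the
probability that a random FGR spectrum outscores a random CTRL spectrum.

The power analysis returns the minimal per-group sample size for a
two-sided two-sample comparison of means at a given standardised effect
size d, using the normal-approximation closed form
``n = ceil(2 (z_{1−α/2} + z_{power})² / d²)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import FgrScreenError

__all__ = [
    "ConfusionMetrics",
    "PowerSpec",
    "confusion_metrics",
    "roc_auc",
    "youden_index",
    "min_sample_size",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero at ``decimals`` places (0.745 → 0.75)."""
    if math.isnan(x):
        return x
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _rate(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts with derived diagnostic rates (NaN when undefined)."""

    tp: int
    fp: int
    tn: int
    fn: int
    rounding: int = 2

    @property
    def sensitivity(self) -> float:
        return _rate(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return _rate(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return _rate(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return _rate(self.tn, self.tn + self.fn)

    @property
    def fpr(self) -> float:
        return 1.0 - self.specificity

    @property
    def fnr(self) -> float:
        return 1.0 - self.sensitivity

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0

    @property
    def accuracy(self) -> float:
        return _rate(self.tp + self.tn, self.tp + self.tn + self.fp + self.fn)

    _RATES = (
        "sensitivity", "specificity", "ppv", "npv",
        "fpr", "fnr", "youden_j", "accuracy",
    )

    def rounded(self) -> dict[str, float]:
        """Rates rounded half-up at the configured number of decimals."""
        return {k: round_half_up(getattr(self, k), self.rounding) for k in self._RATES}

    def to_dict(self) -> dict:
        out = {"TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn}
        out.update({k: getattr(self, k) for k in self._RATES})
        return out


def confusion_metrics(
    calls: Sequence[str],
    truth_labels: Sequence[str],
    positive_label: str = "FGR",
    rounding: int = 2,
) -> ConfusionMetrics:
    """Tabulate calls against gold-standard labels.

    Indeterminate calls must be excluded by the caller; every entry is
    counted. The result is invariant to any joint reordering of the pair
    lists.
    """
    if len(calls) != len(truth_labels):
        raise FgrScreenError(
            f"calls ({len(calls)}) and truth labels ({len(truth_labels)}) "
            "differ in length"
        )
    tp = fp = tn = fn = 0
    for call, truth in zip(calls, truth_labels):
        if truth == positive_label:
            if call == positive_label:
                tp += 1
            else:
                fn += 1
        else:
            if call == positive_label:
                fp += 1
            else:
                tn += 1
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn, rounding=rounding)


def roc_auc(
    scores: Sequence[float],
    truth_labels: Sequence[str],
    positive_label: str = "FGR",
) -> tuple[float, list[tuple[float, float, float]]]:
    """ROC analysis on graded scores.

    Returns ``(auc, points)`` where ``points`` are ``(threshold, fpr, tpr)``
    triples, one per distinct score (positive = score strictly above the
    threshold), framed by the (1, 1) and (0, 0) extremes. The AUC is the
    tie-aware rank statistic: U / (n_pos · n_neg).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(truth_labels)
    if len(scores) != len(labels):
        raise FgrScreenError("scores and truth labels differ in length")
    if not np.all(np.isfinite(scores)):
        raise FgrScreenError("scores must be finite")
    pos = labels == positive_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise FgrScreenError("ROC analysis requires both classes to be present")
    ranks = stats.rankdata(scores)  # average ranks credit ties 0.5
    u = float(ranks[pos].sum()) - n_pos * (n_pos + 1) / 2.0
    auc = u / (n_pos * n_neg)

    points: list[tuple[float, float, float]] = []
    thresholds = [-np.inf, *np.unique(scores)]
    for t in thresholds:
        called_pos = scores > t
        tpr = float(np.sum(called_pos & pos)) / n_pos
        fpr = float(np.sum(called_pos & ~pos)) / n_neg
        points.append((float(t), fpr, tpr))
    return auc, points


def youden_index(sensitivity: float, specificity: float) -> float:
    """J = sensitivity + specificity − 1; both inputs must lie in [0, 1]."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= v <= 1.0:
            raise FgrScreenError(f"{name} must be in [0, 1], got {v}")
    return sensitivity + specificity - 1.0


@dataclass(frozen=True)
class PowerSpec:
    """Inputs to the two-sample minimal-sample-size computation."""

    effect_size: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise FgrScreenError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.power < 1.0:
            raise FgrScreenError(f"power must be in (0, 1), got {self.power}")
        if not self.effect_size > 0:
            raise FgrScreenError(
                f"effect_size must be positive, got {self.effect_size}"
            )


def min_sample_size(spec: PowerSpec) -> int:
    """Minimal n per group to detect effect size d between two means.

    Normal approximation for a two-sided two-sample test:
    ``n = ceil(2 (z_{1−α/2} + z_{power})² / d²)``, at least 1. Within one
    unit of the noncentral-t iteration used by dedicated power software at
    moderate effect sizes.
    """
    z_alpha = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    z_power = stats.norm.ppf(spec.power)
    n = 2.0 * (z_alpha + z_power) ** 2 / spec.effect_size**2
    return max(1, math.ceil(n))
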