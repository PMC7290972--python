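"""Youden-index training of per-quotient cut-off values.

For each assessment quotient the training procedure is a one-dimensional
threshold scan: the pooled training values (both classes) are ranked, two
sentinel values are appended — the minimum minus 1 and the maximum plus 1 —
so that "all negative" and "all positive" thresholds are reachable, and the
candidate cut-offs are the midpoints between neighbouring ranked values. At
each candidate c a spectrum is called FGR-positive when its quotient value
is strictly above c (FGR quotients run high, so the scan direction is
fixed), sensitivity and specificity are tabulated, and the Youden index
J = sensitivity + specificity − 1 is computed. The candidate maximising J
(ties: the smallest such candidate, favouring sensitivity) is the trained
"best cut-off".

Two independently trained cut-off sets can be combined into per-quotient
(lower, upper) pairs for three-regime dual scoring. The combination of the
two published training sets — "O" (4.2 / 5.0 / 4.0) and "W" (3.4 / 7.0 /
5.1) for quotients A / B / C — ships as the ``paper_OW`` preset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateCutoffError, FgrScreenError
from .scoring import QUOTIENT_NAMES

__all__ = [
    "LabeledQuotients",
    "ScanRow",
    "CutoffSet",
    "DualCutoffs",
    "augment_with_sentinels",
    "candidate_cutoffs",
    "youden_scan",
    "train_cutoff_set",
    "combine_cutoffs",
    "PRESET_O",
    "PRESET_W",
    "paper_ow_preset",
]


@dataclass(frozen=True)
class LabeledQuotients:
    """One training observation: a quotient value with its class label."""

    spectrum_id: str
    quotient_name: str
    value: float
    label: str  # FGR | CTRL

    def __post_init__(self):
        if self.label not in ("FGR", "CTRL"):
            raise FgrScreenError(f"label must be FGR or CTRL, got {self.label!r}")
        if not self.value > 0:
            raise FgrScreenError(f"quotient value must be positive, got {self.value}")


@dataclass(frozen=True)
class ScanRow:
    """One row of the threshold-scan audit table."""

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    youden_j: float


@dataclass(frozen=True)
class QuotientCutoff:
    """Trained optimum for one quotient, with scan diagnostics."""

    cutoff: float
    jmax: float
    sensitivity: float
    specificity: float
    scan: tuple[ScanRow, ...] = field(repr=False, default=())


@dataclass(frozen=True)
class CutoffSet:
    """One trained cut-off per quotient (single-threshold scoring)."""

    A: QuotientCutoff
    B: QuotientCutoff
    C: QuotientCutoff
    training_label: str = ""

    def cutoff(self, name: str) -> float:
        return getattr(self, name).cutoff

    def cutoffs(self) -> dict[str, float]:
        return {q: self.cutoff(q) for q in QUOTIENT_NAMES}

    @classmethod
    def from_values(cls, a: float, b: float, c: float, training_label: str = "") -> "CutoffSet":
        """Build a set from bare cut-off values (e.g. published presets);
        scan diagnostics are filled with NaN."""
        nan = float("nan")
        mk = lambda v: QuotientCutoff(v, nan, nan, nan)
        return cls(A=mk(a), B=mk(b), C=mk(c), training_label=training_label)

    def to_json(self, path) -> None:
        payload = {
            "training_label": self.training_label,
            "cutoffs": self.cutoffs(),
            "diagnostics": {
                q: {
                    "jmax": getattr(self, q).jmax,
                    "sensitivity": getattr(self, q).sensitivity,
                    "specificity": getattr(self, q).specificity,
                }
                for q in QUOTIENT_NAMES
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path) -> "CutoffSet":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        cut = payload["cutoffs"]
        diag = payload.get("diagnostics", {})
        nan = float("nan")
        return cls(
            **{
                q: QuotientCutoff(
                    cut[q],
                    diag.get(q, {}).get("jmax", nan),
                    diag.get(q, {}).get("sensitivity", nan),
                    diag.get(q, {}).get("specificity", nan),
                )
                for q in QUOTIENT_NAMES
            },
            training_label=payload.get("training_label", ""),
        )


@dataclass(frozen=True)
class DualCutoffs:
    """Per-quotient (lower, upper) threshold pairs for three-regime scoring."""

    A: tuple[float, float]
    B: tuple[float, float]
    C: tuple[float, float]
    training_label: str = ""

    def __post_init__(self):
        for q in QUOTIENT_NAMES:
            lo, hi = getattr(self, q)
            if not lo < hi:
                raise DegenerateCutoffError(
                    f"quotient {q}: lower cut-off {lo:g} must be below upper {hi:g}"
                )

    def bounds(self, name: str) -> tuple[float, float]:
        return getattr(self, name)

    def to_json(self, path) -> None:
        payload = {
            "training_label": self.training_label,
            "bounds": {q: list(self.bounds(q)) for q in QUOTIENT_NAMES},
        }
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path) -> "DualCutoffs":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            **{q: tuple(payload["bounds"][q]) for q in QUOTIENT_NAMES},
            training_label=payload.get("training_label", ""),
        )


# published cut-off presets: training set "O" and the earlier set "W"
PRESET_O = CutoffSet.from_values(4.2, 5.0, 4.0, training_label="O")
PRESET_W = CutoffSet.from_values(3.4, 7.0, 5.1, training_label="W")


def paper_ow_preset() -> DualCutoffs:
    """The combined O/W dual cut-offs: A (3.4, 4.2), B (5.0, 7.0), C (4.0, 5.1)."""
    return combine_cutoffs(PRESET_O, PRESET_W)


# ---------------------------------------------------------------------------
# scan machinery
# ---------------------------------------------------------------------------

def augment_with_sentinels(values: Sequence[float]) -> list[float]:
    """Rank the values and append the sentinels min−1 and max+1.

    The sentinels guarantee candidate thresholds below every observation
    and above every observation, so the scan always considers the
    "call everything positive" and "call everything negative" extremes.
    """
    if len(values) == 0:
        raise FgrScreenError("cannot augment an empty value list")
    ordered = sorted(float(v) for v in values)
    return [ordered[0] - 1.0, *ordered, ordered[-1] + 1.0]


def candidate_cutoffs(augmented: Sequence[float]) -> list[float]:
    """Midpoints between each pair of neighbouring ranked values."""
    if len(augmented) < 2:
        raise FgrScreenError("need at least two values to form candidate cut-offs")
    arr = list(augmented)
    if any(b < a for a, b in zip(arr, arr[1:])):
        raise FgrScreenError("candidate_cutoffs requires a sorted (ranked) input")
    return [(a + b) / 2.0 for a, b in zip(arr, arr[1:])]


def youden_scan(
    data: Iterable[LabeledQuotients],
) -> tuple[float, float, float, float, list[ScanRow]]:
    """Scan all candidate cut-offs for one quotient and return the optimum.

    Returns ``(best_cutoff, jmax, sensitivity, specificity, scan_table)``.
    A value is called FGR-positive when strictly above the candidate. Ties
    in J are broken toward the smallest candidate.
    """
    data = list(data)
    values = np.array([d.value for d in data], dtype=float)
    labels = np.array([d.label for d in data])
    if not np.all(np.isfinite(values)):
        raise FgrScreenError("quotient values must be finite")
    n_pos = int(np.sum(labels == "FGR"))
    n_neg = int(np.sum(labels == "CTRL"))
    if n_pos == 0 or n_neg == 0:
        raise FgrScreenError(
            "cannot compute sensitivity/specificity: both FGR and CTRL "
            "training observations are required"
        )
    candidates = candidate_cutoffs(augment_with_sentinels(values))
    scan: list[ScanRow] = []
    best: ScanRow | None = None
    for c in candidates:
        positive = values > c
        tp = int(np.sum(positive & (labels == "FGR")))
        fp = int(np.sum(positive & (labels == "CTRL")))
        fn = n_pos - tp
        tn = n_neg - fp
        sens = tp / n_pos
        spec = tn / n_neg
        row = ScanRow(c, tp, fp, tn, fn, sens, spec, sens + spec - 1.0)
        scan.append(row)
        if best is None or row.youden_j > best.youden_j:
            best = row
    assert best is not None
    return best.cutoff, best.youden_j, best.sensitivity, best.specificity, scan


def train_cutoff_set(
    quotient_table: pd.DataFrame,
    labels: pd.Series | Sequence[str] | None = None,
    training_label: str = "",
) -> CutoffSet:
    """Train one cut-off per quotient from a labelled quotient table.

    ``quotient_table`` needs columns ``A``, ``B``, ``C`` and, unless
    ``labels`` is given separately, a ``label`` column with FGR/CTRL. A
    ``spectrum_id`` column is used for audit trails when present.
    """
    table = quotient_table.reset_index(drop=True)
    if labels is None:
        if "label" not in table.columns:
            raise FgrScreenError("quotient table lacks a 'label' column")
        labels = table["label"]
    labels = pd.Series(list(labels)).reset_index(drop=True)
    if len(labels) != len(table):
        raise FgrScreenError("labels and quotient table differ in length")
    ids = (
        table["spectrum_id"].astype(str)
        if "spectrum_id" in table.columns
        else pd.Series([str(i) for i in range(len(table))])
    )
    trained = {}
    for q in QUOTIENT_NAMES:
        if q not in table.columns:
            raise FgrScreenError(f"quotient table lacks column {q!r}")
        obs = [
            LabeledQuotients(ids[i], q, float(table[q][i]), str(labels[i]))
            for i in range(len(table))
        ]
        cutoff, jmax, sens, spec, scan = youden_scan(obs)
        trained[q] = QuotientCutoff(cutoff, jmax, sens, spec, tuple(scan))
    return CutoffSet(**trained, training_label=training_label)


def combine_cutoffs(set1: CutoffSet, set2: CutoffSet) -> DualCutoffs:
    """Combine two cut-off sets into per-quotient (lower, upper) pairs.

    Per quotient the lower bound is the smaller of the two cut-offs and the
    upper the larger; equal cut-offs collapse the middle regime and raise
    :class:`DegenerateCutoffError`. The operation is symmetric in its
    arguments.
    """
    bounds = {}
    for q in QUOTIENT_NAMES:
        c1, c2 = set1.cutoff(q), set2.cutoff(q)
        if c1 == c2:
            raise DegenerateCutoffError(
                f"quotient {q}: both sets give the cut-off {c1:g}; "
                "no three-regime scoring is possible"
            )
        bounds[q] = (min(c1, c2), max(c1, c2))
    label = "+".join(sorted(s for s in (set1.training_label, set2.training_label) if s))
    return DualCutoffs(**bounds, training_label=label)
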