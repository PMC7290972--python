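"""Quotient formation, cut-off scoring and patient-level classification.

Within one spectrum the five marker ion-signal areas are reduced to three
assessment quotients, which normalise away absolute intensity:

    A = area(8916) / area(8205)
    B = area(8766) / (area(9422) + area(9713))
    C = area(8916) / (area(8766) + area(9422) + area(9713))

Each quotient is scored against trained cut-offs, either in *single* mode
(one cut-off: score 1 when the value is strictly above it, else 0) or in
*dual* mode (two cut-offs opening three regimes: ≤ lower → 0.0, in between
→ 0.5, > upper → 1.0). The three scores are summed to a cumulative score
between 0 and 3; a spectrum with cumulative score strictly above the
discriminator (default 1.0) is called FGR, otherwise CTRL. Replicate
spectra of one patient are consolidated by unanimity — disagreeing
replicates make the patient indeterminate, and indeterminate patients are
excluded from performance statistics.

Boundary semantics are deliberately strict and unsymmetric ("below or
equal" scores low, "higher than" scores high); comparisons are on raw
floats with no epsilon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import FgrScreenError

__all__ = [
    "QUOTIENT_NAMES",
    "QuotientSet",
    "ScoreRecord",
    "PatientCall",
    "compute_quotients",
    "score_single",
    "score_dual",
    "classify_spectrum",
    "aggregate_patient",
]

QUOTIENT_NAMES = ("A", "B", "C")

# numerator / denominator marker m/z per quotient
_QUOTIENT_DEFS: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "A": ((8916.0,), (8205.0,)),
    "B": ((8766.0,), (9422.0, 9713.0)),
    "C": ((8916.0,), (8766.0, 9422.0, 9713.0)),
}

#: Default cumulative-score discriminator separating CTRL (≤) from FGR (>).
DISCRIMINATOR = 1.0


@dataclass(frozen=True)
class QuotientSet:
    """The three assessment quotients of one spectrum."""

    spectrum_id: str
    A: float
    B: float
    C: float

    def value(self, name: str) -> float:
        return getattr(self, name)


@dataclass(frozen=True)
class ScoreRecord:
    """Per-spectrum scores, cumulative score and class call."""

    spectrum_id: str
    score_A: float
    score_B: float
    score_C: float
    cumulative: float
    call: str  # CTRL | FGR
    patient_id: str | None = None


@dataclass(frozen=True)
class PatientCall:
    """Consolidated call for one patient across replicate spectra."""

    patient_id: str
    replicate_calls: tuple[str, ...]
    final: str  # CTRL | FGR | indeterminate


def compute_quotients(
    marker_areas: Mapping[float, float], spectrum_id: str = ""
) -> QuotientSet:
    """Form quotients A, B, C from the five marker areas of one spectrum.

    ``marker_areas`` maps marker m/z to integrated area; extra entries
    (e.g. calibrants) are ignored. Zero or missing denominator areas raise.
    """
    values = {}
    for name, (num_mzs, den_mzs) in _QUOTIENT_DEFS.items():
        missing = [m for m in (*num_mzs, *den_mzs) if m not in marker_areas]
        if missing:
            raise FgrScreenError(
                f"quotient {name}: missing marker areas for m/z {missing}"
            )
        den = sum(marker_areas[m] for m in den_mzs)
        if den <= 0:
            raise FgrScreenError(
                f"quotient {name}: denominator area sum is {den:g}, must be positive"
            )
        values[name] = sum(marker_areas[m] for m in num_mzs) / den
    return QuotientSet(spectrum_id=spectrum_id, **values)


def score_single(value: float, cutoff: float) -> int:
    """Single cut-off score: 1 when ``value`` is strictly above the cut-off."""
    return 1 if value > cutoff else 0


def score_dual(value: float, lower: float, upper: float) -> float:
    """Dual cut-off score over the three regimes below / between / above.

    ≤ lower → 0.0; above lower but ≤ upper → 0.5; above upper → 1.0.
    """
    if lower >= upper:
        raise ValueError(f"lower cut-off {lower:g} must be below upper {upper:g}")
    if value <= lower:
        return 0.0
    if value <= upper:
        return 0.5
    return 1.0


def classify_spectrum(
    quotients: QuotientSet,
    cutoffs,
    mode: str = "dual",
    discriminator: float = DISCRIMINATOR,
    patient_id: str | None = None,
) -> ScoreRecord:
    """Score one spectrum's quotients and call it CTRL or FGR.

    ``cutoffs`` is a :class:`~fgrscreen.cutoffs.CutoffSet` in ``single``
    mode or a :class:`~fgrscreen.cutoffs.DualCutoffs` in ``dual`` mode. The
    call is FGR iff the cumulative score exceeds the discriminator.
    """
    scores = {}
    for name in QUOTIENT_NAMES:
        value = quotients.value(name)
        if mode == "single":
            try:
                cutoff = cutoffs.cutoff(name)
            except AttributeError as exc:
                raise FgrScreenError(
                    "single mode requires a CutoffSet with one cut-off per quotient"
                ) from exc
            scores[name] = float(score_single(value, cutoff))
        elif mode == "dual":
            try:
                lower, upper = cutoffs.bounds(name)
            except AttributeError as exc:
                raise FgrScreenError(
                    "dual mode requires DualCutoffs with lower/upper per quotient"
                ) from exc
            scores[name] = score_dual(value, lower, upper)
        else:
            raise ValueError(f"unknown scoring mode {mode!r}")
    cumulative = scores["A"] + scores["B"] + scores["C"]
    return ScoreRecord(
        spectrum_id=quotients.spectrum_id,
        score_A=scores["A"],
        score_B=scores["B"],
        score_C=scores["C"],
        cumulative=cumulative,
        call="FGR" if cumulative > discriminator else "CTRL",
        patient_id=patient_id,
    )


def aggregate_patient(records: Iterable[ScoreRecord], patient_id: str) -> PatientCall:
    """Consolidate replicate spectrum calls into one patient call.

    All replicates must agree for a definite call; any disagreement yields
    ``indeterminate`` (such patients are excluded from confusion
    statistics, mirroring how conflicting replicate measurements cannot
    support a clinical call).
    """
    calls = tuple(r.call for r in records)
    if not calls:
        raise FgrScreenError(f"patient {patient_id}: no score records to aggregate")
    final = calls[0] if all(c == calls[0] for c in calls) else "indeterminate"
    return PatientCall(patient_id=patient_id, replicate_calls=calls, final=final)
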