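"""End-to-end orchestration: simulate → preprocess → train → score → evaluate.

The run layout mirrors the study design the assay is meant for: the first
measurement series (MS1) of the CTRL and FGR patients forms the training
set on which per-quotient cut-offs are learned; every remaining spectrum —
later series of CTRL/FGR patients plus all SGA spectra — forms the test
set. In dual scoring mode the freshly trained cut-offs are combined with
the earlier published set "W" into (lower, upper) pairs, exactly as a
laboratory would fold an existing reference threshold into a new training
round; alternatively the published combined cut-offs ship as the
``paper_OW`` preset and can be applied without any training.

All artifacts (ground truth, marker-area table, quotients, cut-offs,
scores, patient calls, metrics, ROC points, run manifest) are written as
CSV/JSON into the run directory; reruns with the same configuration and
seed reproduce them byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cutoffs import PRESET_W, CutoffSet, DualCutoffs, combine_cutoffs, paper_ow_preset, train_cutoff_set
from .errors import FgrScreenError, StageError
from .preprocess import MARKER_MZS, MarkerPanel, preprocess_spectrum
from .scoring import (
    DISCRIMINATOR,
    QUOTIENT_NAMES,
    ScoreRecord,
    aggregate_patient,
    classify_spectrum,
    compute_quotients,
)
from .simulate import SimulationConfig, simulate_cohort, write_ground_truth
from .spectrum import Spectrum
from .evaluate import confusion_metrics, roc_auc

__all__ = [
    "PeakExtractionConfig",
    "RunConfig",
    "preprocess_cohort",
    "quotient_table",
    "score_table",
    "run_pipeline",
]

_AREA_COLUMNS = [f"mz_{int(m)}" for m in MARKER_MZS]


@dataclass(frozen=True)
class PeakExtractionConfig:
    """Parameters of marker quantification and QC."""

    match_tolerance_da: float = 10.0
    window_da: float = 25.0
    baseline: str = "linear_endpoints"
    saa_factor: float = 2.0

    def panel(self) -> MarkerPanel:
        return MarkerPanel(match_tolerance_da=self.match_tolerance_da)


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    outdir: str | Path = "fgrscreen_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    extraction: PeakExtractionConfig = field(default_factory=PeakExtractionConfig)
    cutoff_source: str = "train"  # train | paper_OW
    mode: str = "dual"  # single | dual
    level: str = "patient"  # patient | spectrum
    discriminator: float = DISCRIMINATOR
    seed: int | None = None  # overrides simulation.seed when set

    def __post_init__(self):
        if self.cutoff_source not in ("train", "paper_OW"):
            raise FgrScreenError(f"unknown cutoff_source {self.cutoff_source!r}")
        if self.mode not in ("single", "dual"):
            raise FgrScreenError(f"unknown scoring mode {self.mode!r}")
        if self.level not in ("patient", "spectrum"):
            raise FgrScreenError(f"unknown aggregation level {self.level!r}")
        if self.seed is not None:
            self.simulation = dataclasses.replace(self.simulation, seed=int(self.seed))


# ---------------------------------------------------------------------------
# stage helpers (also backing the CLI subcommands)
# ---------------------------------------------------------------------------

def preprocess_cohort(
    spectra: list[Spectrum], extraction: PeakExtractionConfig = PeakExtractionConfig()
) -> pd.DataFrame:
    """Recalibrate, quantify and QC every spectrum.

    Returns the marker-area table with one row per spectrum: annotation
    columns, one ``mz_<marker>`` area column per panel marker (NaN for
    excluded spectra), ``qc_status`` and ``qc_detail``.
    """
    panel = extraction.panel()
    rows = []
    for sp in spectra:
        try:
            areas, qc = preprocess_spectrum(
                sp,
                panel,
                window_da=extraction.window_da,
                baseline=extraction.baseline,
                saa_factor=extraction.saa_factor,
            )
        except FgrScreenError as exc:
            raise StageError("preprocess", sp.spectrum_id, exc) from exc
        row = {
            "spectrum_id": sp.spectrum_id,
            "patient_id": sp.patient_id,
            "series_id": sp.series_id,
            "cohort": sp.cohort,
            "qc_status": qc.status,
            "qc_detail": qc.detail,
        }
        for mz in MARKER_MZS:
            row[f"mz_{int(mz)}"] = areas[mz].area if areas is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def quotient_table(areas: pd.DataFrame) -> pd.DataFrame:
    """Compute quotients A, B, C for every QC-passing row of an area table."""
    passed = areas[areas["qc_status"] == "pass"].reset_index(drop=True)
    rows = []
    for _, row in passed.iterrows():
        marker_areas = {mz: float(row[f"mz_{int(mz)}"]) for mz in MARKER_MZS}
        q = compute_quotients(marker_areas, spectrum_id=str(row["spectrum_id"]))
        rows.append(
            {
                "spectrum_id": row["spectrum_id"],
                "patient_id": row["patient_id"],
                "series_id": row["series_id"],
                "cohort": row["cohort"],
                "A": q.A,
                "B": q.B,
                "C": q.C,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["spectrum_id", "patient_id", "series_id", "cohort", *QUOTIENT_NAMES],
    )


def score_table(
    quotients: pd.DataFrame,
    cutoffs: CutoffSet | DualCutoffs,
    mode: str,
    discriminator: float = DISCRIMINATOR,
) -> pd.DataFrame:
    """Score every spectrum of a quotient table."""
    from .scoring import QuotientSet

    rows = []
    for _, row in quotients.iterrows():
        q = QuotientSet(str(row["spectrum_id"]), float(row["A"]), float(row["B"]), float(row["C"]))
        rec = classify_spectrum(
            q, cutoffs, mode=mode, discriminator=discriminator,
            patient_id=row.get("patient_id"),
        )
        rows.append(
            {
                "spectrum_id": rec.spectrum_id,
                "patient_id": rec.patient_id,
                "series_id": row.get("series_id"),
                "cohort": row.get("cohort"),
                "score_A": rec.score_A,
                "score_B": rec.score_B,
                "score_C": rec.score_C,
                "cumulative": rec.cumulative,
                "call": rec.call,
            }
        )
    return pd.DataFrame(rows)


def patient_calls(scores: pd.DataFrame) -> pd.DataFrame:
    """Consolidate per-spectrum calls into per-patient calls by unanimity."""
    rows = []
    for patient_id, group in scores.groupby("patient_id", sort=True):
        recs = [
            ScoreRecord(
                spectrum_id=r["spectrum_id"],
                score_A=r["score_A"], score_B=r["score_B"], score_C=r["score_C"],
                cumulative=r["cumulative"], call=r["call"], patient_id=patient_id,
            )
            for _, r in group.iterrows()
        ]
        call = aggregate_patient(recs, str(patient_id))
        rows.append(
            {
                "patient_id": patient_id,
                "cohort": group["cohort"].iloc[0],
                "n_spectra": len(recs),
                "mean_cumulative": float(group["cumulative"].mean()),
                "final": call.final,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end run
# ---------------------------------------------------------------------------

def _nan_to_none(obj):
    """Undefined rates are serialized as nulls (empty fields), never as 0."""
    if isinstance(obj, dict):
        return {k: _nan_to_none(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_nan_to_none(v) for v in obj]
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def _truth_label(cohort: str) -> str:
    """Gold standard: FGR is positive; SGA classifies with the controls."""
    return "FGR" if cohort == "FGR" else "CTRL"


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return the run report.

    Writes all intermediate artifacts plus ``report.json`` and a manifest
    into ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    spectra, records = simulate_cohort(config.simulation)
    write_ground_truth(records, outdir / "ground_truth.csv")

    areas = preprocess_cohort(spectra, config.extraction)
    areas.to_csv(outdir / "marker_areas.csv", index=False)
    excluded = areas[areas["qc_status"] != "pass"]

    quotients = quotient_table(areas)
    quotients.to_csv(outdir / "quotients.csv", index=False)

    is_training = (quotients["series_id"] == "MS1") & quotients["cohort"].isin(["CTRL", "FGR"])
    training = quotients[is_training].reset_index(drop=True)
    testset = quotients[~is_training].reset_index(drop=True)

    if config.cutoff_source == "paper_OW":
        cutoffs: CutoffSet | DualCutoffs = paper_ow_preset()
        trained = None
        if config.mode == "single":
            raise FgrScreenError("the paper_OW preset is a dual cut-off set")
    else:
        if training.empty:
            raise StageError("train", "-", FgrScreenError("empty training set"))
        trained = train_cutoff_set(
            training.assign(label=training["cohort"].map(_truth_label)),
            training_label="trained",
        )
        cutoffs = trained if config.mode == "single" else combine_cutoffs(trained, PRESET_W)
    cutoffs.to_json(outdir / "cutoffs.json")

    scores = score_table(testset, cutoffs, config.mode, config.discriminator)
    scores.to_csv(outdir / "scores.csv", index=False)

    calls_df = patient_calls(scores)
    calls_df.to_csv(outdir / "patient_calls.csv", index=False)
    indeterminate = calls_df[calls_df["final"] == "indeterminate"]

    if config.level == "patient":
        determinate = calls_df[calls_df["final"] != "indeterminate"]
        cm = confusion_metrics(
            list(determinate["final"]),
            [_truth_label(c) for c in determinate["cohort"]],
        )
    else:
        cm = confusion_metrics(
            list(scores["call"]), [_truth_label(c) for c in scores["cohort"]]
        )
    auc, roc_points = roc_auc(
        list(scores["cumulative"]), [_truth_label(c) for c in scores["cohort"]]
    )
    pd.DataFrame(roc_points, columns=["threshold", "fpr", "tpr"]).to_csv(
        outdir / "roc_points.csv", index=False
    )

    report = {
        "n_spectra_simulated": len(spectra),
        "n_excluded": int(len(excluded)),
        "exclusions": {
            str(r["spectrum_id"]): r["qc_status"] for _, r in excluded.iterrows()
        },
        "n_training_spectra": int(len(training)),
        "n_test_spectra": int(len(testset)),
        "n_indeterminate_patients": int(len(indeterminate)),
        "indeterminate_patients": sorted(indeterminate["patient_id"].tolist()),
        "cutoffs": (
            {q: list(cutoffs.bounds(q)) for q in QUOTIENT_NAMES}
            if isinstance(cutoffs, DualCutoffs)
            else cutoffs.cutoffs()
        ),
        "level": config.level,
        "metrics": {**cm.to_dict(), "auc": auc},
        "metrics_rounded": cm.rounded(),
    }
    (outdir / "report.json").write_text(
        json.dumps(_nan_to_none(report), indent=2, sort_keys=True), encoding="utf-8"
    )
    manifest = {
        "version": __version__,
        "seed": config.simulation.seed,
        "mode": config.mode,
        "level": config.level,
        "cutoff_source": config.cutoff_source,
        "discriminator": config.discriminator,
        "simulation": {
            k: v for k, v in dataclasses.asdict(config.simulation).items()
            if not isinstance(v, dict)
        },
        "extraction": dataclasses.asdict(config.extraction),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return report
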