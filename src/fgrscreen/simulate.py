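"""Synthetic MALDI-ToF serum profile spectra with known ground truth.

The generator emulates the statistical structure the screening analysis
assumes: three cohorts (CTRL, SGA, FGR) of patients, each measured in
replicate series (MS1, MS2, optionally MS3/MS4), with profile spectra on a
regular m/z grid spanning 4,000–20,000 Da carrying ≈60 Gaussian protein ion
signals — the five apolipoprotein C-II/C-III markers, the two internal
calibrants, and randomly placed background peaks — on a smooth baseline
with additive noise and a small affine mass-axis drift.

Marker ion-signal areas are drawn log-normally. The FGR effect raises the
log-mean areas of the pro-apoC-II (m/z 8916) and apoC-III_0 (m/z 8766)
signals, which jointly elevates all three assessment quotients A, B and C;
SGA patients are drawn from the CTRL distribution, reflecting that
constitutionally small fetuses are biochemically unremarkable. Two QC
artifacts can be injected per patient: serum amyloid A1 contamination
(strong extra signals at m/z 11,527.0 / 11,683.5) and calibration failure
(calibrant signals suppressed below detectability).

All randomness flows through one seeded ``numpy`` generator, so identical
configurations produce bit-identical cohorts.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .preprocess import CALIBRANT_MZS, MARKER_MZS, QC_MZS
from .scoring import compute_quotients
from .spectrum import Spectrum

__all__ = [
    "SimulationConfig",
    "GroundTruthRecord",
    "simulate_cohort",
    "simulate_spectrum",
    "write_ground_truth",
    "read_ground_truth",
]

# grid and nuisance-signal constants (documented package choices, not knobs
# of the study design): 1 Da linear-mode grid, exponentially decaying
# chemical baseline, log-normal background and calibrant abundances
_MZ_MIN, _MZ_MAX, _MZ_STEP = 4000.0, 20000.0, 1.0
_BASELINE_AMP, _BASELINE_SCALE = 10.0, 4000.0
_CALIBRANT_LOG_MEAN = math.log(3000.0)
_BACKGROUND_LOG_MEAN, _BACKGROUND_LOG_SD = math.log(500.0), 0.8
_REPLICATE_LOG_SD = 0.05  # series-to-series jitter within one patient
_EXCLUSION_DA = 50.0      # keep background peaks clear of panel signals
_SAA_APEX_FACTOR = 3.0    # SAA apex relative to the tallest marker apex

_DEFAULT_CTRL_MEANS = {
    8205.0: math.log(2000.0),
    8766.0: math.log(1500.0),
    8916.0: math.log(5000.0),
    9422.0: math.log(300.0),
    9713.0: math.log(200.0),
}
# FGR effect: +ln 3 on m/z 8916 and +ln 2 on m/z 8766 (≥ 2 log-SD at the
# default marker_area_sd of 0.2), which raises quotients A, B and C jointly
_DEFAULT_FGR_MEANS = {
    **_DEFAULT_CTRL_MEANS,
    8916.0: math.log(15000.0),
    8766.0: math.log(3000.0),
}


@dataclass
class SimulationConfig:
    """Cohort-level simulation parameters.

    ``marker_area_means_*`` are natural-log mean areas per marker m/z;
    ``marker_area_sd`` is the shared log-scale standard deviation.
    """

    n_ctrl: int = 14
    n_sga: int = 14
    n_fgr: int = 14
    series_per_patient: int = 2
    marker_area_means_ctrl: dict[float, float] = field(
        default_factory=lambda: dict(_DEFAULT_CTRL_MEANS)
    )
    marker_area_means_fgr: dict[float, float] = field(
        default_factory=lambda: dict(_DEFAULT_FGR_MEANS)
    )
    marker_area_sd: float = 0.2
    n_background_peaks: int = 53
    noise_sd: float = 2.0
    calibration_drift_max: float = 5e-4
    peak_width_sigma: float = 4.0
    p_saa_contamination: float = 0.0
    p_calibration_failure: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_ctrl", "n_sga", "n_fgr", "n_background_peaks"):
            if int(getattr(self, name)) != getattr(self, name) or getattr(self, name) < 0:
                raise ConfigError(f"{name} must be a non-negative integer")
        if not 1 <= self.series_per_patient <= 4:
            raise ConfigError("series_per_patient must be between 1 and 4")
        for name in ("marker_area_sd", "noise_sd", "calibration_drift_max"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.peak_width_sigma <= 0:
            raise ConfigError("peak_width_sigma must be positive")
        for name in ("p_saa_contamination", "p_calibration_failure"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.p_saa_contamination + self.p_calibration_failure > 1.0:
            raise ConfigError(
                "p_saa_contamination + p_calibration_failure must not exceed 1"
            )
        for name in ("marker_area_means_ctrl", "marker_area_means_fgr"):
            means = getattr(self, name)
            missing = [m for m in MARKER_MZS if m not in means]
            if missing:
                raise ConfigError(f"{name} lacks markers {missing}")
        ctrl_q = self.expected_quotients("CTRL")
        fgr_q = self.expected_quotients("FGR")
        for q in ("A", "B", "C"):
            if getattr(fgr_q, q) <= getattr(ctrl_q, q):
                raise ConfigError(
                    "marker_area_means_fgr must imply a higher expected quotient "
                    f"{q} than marker_area_means_ctrl "
                    f"(got {getattr(fgr_q, q):.3f} vs {getattr(ctrl_q, q):.3f})"
                )

    def expected_quotients(self, cohort: str):
        """Assessment quotients implied by the configured median areas."""
        means = (
            self.marker_area_means_fgr
            if cohort == "FGR"
            else self.marker_area_means_ctrl
        )
        return compute_quotients(
            {mz: math.exp(mu) for mz, mu in means.items()}, spectrum_id=f"expected-{cohort}"
        )


@dataclass(frozen=True)
class GroundTruthRecord:
    """True signal content of one simulated spectrum."""

    patient_id: str
    cohort: str  # CTRL | SGA | FGR
    series_id: str  # MS1..MS4
    true_marker_areas: dict[float, float]  # marker and calibrant m/z -> area
    injected_artifact: str = "none"  # none | saa | calibration_failure

    def __post_init__(self):
        if self.injected_artifact not in ("none", "saa", "calibration_failure"):
            raise ConfigError(f"unknown artifact {self.injected_artifact!r}")
        if any(a <= 0 for a in self.true_marker_areas.values()):
            raise ConfigError("true areas must be positive")


def _add_gaussian(grid: np.ndarray, intensity: np.ndarray, center: float,
                  area: float, sigma: float) -> None:
    """Add a Gaussian of given integrated area in place (±8σ support)."""
    lo, hi = np.searchsorted(grid, [center - 8 * sigma, center + 8 * sigma])
    x = grid[lo:hi]
    intensity[lo:hi] += area / (sigma * math.sqrt(2 * math.pi)) * np.exp(
        -0.5 * ((x - center) / sigma) ** 2
    )


def simulate_spectrum(
    record: GroundTruthRecord,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Spectrum:
    """Render one profile spectrum from its ground-truth record.

    The spectrum is a sum of Gaussian ion signals (configured areas, shared
    width) over an exponentially decaying baseline, plus background peaks,
    additive Gaussian noise clipped at zero, and a per-spectrum affine
    mass-axis drift bounded by ``calibration_drift_max``.
    """
    missing = [m for m in (*MARKER_MZS, *CALIBRANT_MZS) if m not in record.true_marker_areas]
    if missing:
        raise ConfigError(f"ground-truth record lacks areas for m/z {missing}")

    grid = np.arange(_MZ_MIN, _MZ_MAX + _MZ_STEP, _MZ_STEP)
    intensity = _BASELINE_AMP * np.exp(-(grid - _MZ_MIN) / _BASELINE_SCALE)

    sigma = config.peak_width_sigma
    for mz in MARKER_MZS:
        _add_gaussian(grid, intensity, mz, record.true_marker_areas[mz], sigma)
    if record.injected_artifact != "calibration_failure":
        for mz in CALIBRANT_MZS:
            _add_gaussian(grid, intensity, mz, record.true_marker_areas[mz], sigma)

    # background peaks: uniform positions clear of all panel signals
    protected = np.array([*MARKER_MZS, *CALIBRANT_MZS, *QC_MZS])
    n_placed = 0
    while n_placed < config.n_background_peaks:
        pos = rng.uniform(_MZ_MIN + 100.0, _MZ_MAX - 100.0)
        if np.min(np.abs(protected - pos)) < _EXCLUSION_DA:
            continue
        area = math.exp(rng.normal(_BACKGROUND_LOG_MEAN, _BACKGROUND_LOG_SD))
        _add_gaussian(grid, intensity, pos, area, sigma)
        n_placed += 1

    if record.injected_artifact == "saa":
        max_marker_area = max(record.true_marker_areas[m] for m in MARKER_MZS)
        for mz in QC_MZS:
            _add_gaussian(grid, intensity, mz, _SAA_APEX_FACTOR * max_marker_area, sigma)

    if config.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, config.noise_sd, size=grid.shape)
        intensity = np.clip(intensity, 0.0, None)

    mz_axis = grid
    if config.calibration_drift_max > 0:
        d = config.calibration_drift_max
        slope_err = rng.uniform(-d, d)
        offset = 1000.0 * rng.uniform(-d, d)
        mz_axis = (1.0 + slope_err) * grid + offset

    return Spectrum(
        mz_axis,
        intensity,
        patient_id=record.patient_id,
        series_id=record.series_id,
        cohort=record.cohort,
    )


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[Spectrum], list[GroundTruthRecord]]:
    """Simulate a full cohort: one spectrum per (patient, measurement series).

    Marker areas are drawn log-normally per patient (SGA from the CTRL
    distribution), with small log-normal series-to-series jitter. QC
    artifacts are assigned per patient — as with real contaminated or
    uncalibratable sera, every replicate of an affected patient carries the
    artifact.
    """
    rng = np.random.default_rng(config.seed)
    spectra: list[Spectrum] = []
    records: list[GroundTruthRecord] = []
    cohort_sizes = (("CTRL", config.n_ctrl), ("SGA", config.n_sga), ("FGR", config.n_fgr))
    for cohort, n in cohort_sizes:
        means = (
            config.marker_area_means_fgr
            if cohort == "FGR"
            else config.marker_area_means_ctrl
        )
        for i in range(n):
            patient_id = f"{cohort}-{i + 1:03d}"
            u = rng.uniform()
            if u < config.p_saa_contamination:
                artifact = "saa"
            elif u < config.p_saa_contamination + config.p_calibration_failure:
                artifact = "calibration_failure"
            else:
                artifact = "none"
            patient_log_areas = {
                mz: rng.normal(means[mz], config.marker_area_sd) for mz in MARKER_MZS
            }
            patient_log_areas.update(
                {mz: rng.normal(_CALIBRANT_LOG_MEAN, config.marker_area_sd)
                 for mz in CALIBRANT_MZS}
            )
            for s in range(config.series_per_patient):
                jitter = {
                    mz: rng.normal(0.0, _REPLICATE_LOG_SD) for mz in patient_log_areas
                }
                record = GroundTruthRecord(
                    patient_id=patient_id,
                    cohort=cohort,
                    series_id=f"MS{s + 1}",
                    true_marker_areas={
                        mz: math.exp(mu + jitter[mz])
                        for mz, mu in patient_log_areas.items()
                    },
                    injected_artifact=artifact,
                )
                records.append(record)
                spectra.append(simulate_spectrum(record, config, rng))
    return spectra, records


# ---------------------------------------------------------------------------
# ground-truth tables
# ---------------------------------------------------------------------------

_GT_FIXED_COLS = ("patient_id", "cohort", "series_id", "injected_artifact")
_GT_AREA_MZS = (*CALIBRANT_MZS, *MARKER_MZS)


def write_ground_truth(records: list[GroundTruthRecord], path) -> None:
    """Write ground-truth records to CSV (header always present; areas at
    full float precision so the table round-trips losslessly)."""
    path = Path(path)
    header = [*_GT_FIXED_COLS, *(f"area_{mz:g}" for mz in sorted(_GT_AREA_MZS))]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec in records:
            writer.writerow(
                [
                    rec.patient_id,
                    rec.cohort,
                    rec.series_id,
                    rec.injected_artifact,
                    *(repr(rec.true_marker_areas[mz]) for mz in sorted(_GT_AREA_MZS)),
                ]
            )


def read_ground_truth(path) -> list[GroundTruthRecord]:
    """Read a ground-truth CSV written by :func:`write_ground_truth`."""
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            areas = {
                float(col[len("area_"):]): float(val)
                for col, val in row.items()
                if col.startswith("area_")
            }
            records.append(
                GroundTruthRecord(
                    patient_id=row["patient_id"],
                    cohort=row["cohort"],
                    series_id=row["series_id"],
                    true_marker_areas=areas,
                    injected_artifact=row["injected_artifact"],
                )
            )
    return records
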