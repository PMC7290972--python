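"""Spectrum preprocessing: internal recalibration, marker quantification, QC.

Every spectrum passes three steps before quotients can be formed:

1. **Internal recalibration** — the m/z axis is corrected by a two-point
   linear fit anchored on the apolipoprotein C-I (m/z 6631.6) and
   transthyretin (m/z 13,762.4) ion signals, which are present in every
   serum profile spectrum of this assay. A missing calibrant, or a fitted
   slope deviating from unity by more than 1%, marks the spectrum as
   uncalibratable and it is excluded.
2. **Marker integration** — the five apolipoprotein C-II/C-III ion signals
   (m/z 8205, 8766, 8916, 9422, 9713) are located by apex search inside a
   matching window and quantified as the trapezoidal integral over a fixed
   window after linear-endpoint baseline subtraction.
3. **QC screening** — spectra dominated by serum amyloid A1 signals
   (m/z 11,527.0 and 11,683.5), which indicate an atypical serum protein
   composition, are excluded; so are spectra that failed recalibration.

Integration parameters (±10 Da matching tolerance, ±25 Da integration
window, chord baseline clipped at zero) are package defaults chosen for
1 Da linear-mode grids and are fully configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, FormatError, MarkerMissingError
from .spectrum import Spectrum

__all__ = [
    "MARKER_MZS",
    "CALIBRANT_MZS",
    "QC_MZS",
    "MarkerPanel",
    "CalibrationModel",
    "PeakArea",
    "QCResult",
    "recalibrate",
    "integrate_peak",
    "extract_marker_areas",
    "qc_check",
    "preprocess_spectrum",
]

#: The five marker ion signals: apolipoprotein C-II (8205), apoC-III_0
#: (8766), pro-apoC-II (8916), apoC-III_1 (9422), apoC-III_2 (9713).
MARKER_MZS: tuple[float, ...] = (8205.0, 8766.0, 8916.0, 9422.0, 9713.0)

#: Internal calibrants: apolipoprotein C-I and transthyretin (average masses).
CALIBRANT_MZS: tuple[float, float] = (6631.6, 13762.4)

#: Serum amyloid A1 ion signals used for contamination QC.
QC_MZS: tuple[float, float] = (11527.0, 11683.5)


@dataclass(frozen=True)
class MarkerPanel:
    """Ion-signal panel and matching tolerance for one assay configuration."""

    marker_mzs: tuple[float, ...] = MARKER_MZS
    calibrant_mzs: tuple[float, float] = CALIBRANT_MZS
    qc_mzs: tuple[float, float] = QC_MZS
    match_tolerance_da: float = 10.0

    def __post_init__(self):
        if self.match_tolerance_da <= 0:
            raise ValueError("match_tolerance_da must be positive")


@dataclass(frozen=True)
class CalibrationModel:
    """Affine mass-axis correction ``mz_corrected = slope * mz + intercept``."""

    slope: float
    intercept: float

    def apply(self, mz: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(mz, dtype=float) + self.intercept


@dataclass(frozen=True)
class PeakArea:
    """One quantified ion signal."""

    target_mz: float
    apex_mz: float
    area: float
    apex_intensity: float
    warning: str | None = None


@dataclass(frozen=True)
class QCResult:
    """Outcome of spectrum-level quality control."""

    status: str  # pass | exclude_saa | exclude_calibration
    detail: str = ""

    def __post_init__(self):
        if self.status not in ("pass", "exclude_saa", "exclude_calibration"):
            raise ValueError(f"unknown QC status {self.status!r}")
        if self.status != "pass" and not self.detail:
            raise ValueError("exclusion statuses require a non-empty detail")


# ---------------------------------------------------------------------------
# apex search
# ---------------------------------------------------------------------------

def _window_slice(spectrum: Spectrum, lo: float, hi: float) -> slice:
    """Indices of the closed window [lo, hi] on the m/z grid."""
    i0 = int(np.searchsorted(spectrum.mz, lo, side="left"))
    i1 = int(np.searchsorted(spectrum.mz, hi, side="right"))
    return slice(i0, i1)

def _find_apex(
    spectrum: Spectrum, target_mz: float, tolerance: float, snr: float = 5.0
) -> tuple[float, float] | None:
    """Locate the apex of the ion signal nearest ``target_mz``.

    Returns ``(apex_mz, apex_intensity)`` or None when no credible signal
    is present. Detection uses the integrated excess over the chord between
    the window edges, which must exceed ``snr`` times its expected noise
    level (robust successive-difference noise estimate); integrating pools
    the signal across the window, so even low peaks well below any single
    noise spike remain detectable while flat, baseline-only or pure-noise
    windows are rejected. The noise level is estimated from successive
    differences over the whole spectrum — ion signals occupy a small
    fraction of a profile spectrum, so the median reflects the noise floor,
    not the peaks. The criterion is a ratio of intensities, hence invariant
    under uniform intensity scaling.
    """
    sl = _window_slice(spectrum, target_mz - tolerance, target_mz + tolerance)
    if sl.stop - sl.start < 3:
        return None
    k0 = sl.start + int(np.argmax(spectrum.intensity[sl]))
    apex_guess = spectrum.mz[k0]
    # evaluate the detection statistic in a window re-centred on the apex,
    # so a signal sitting near the edge of the matching window is not cut
    # by the baseline chord
    sl = _window_slice(spectrum, apex_guess - tolerance, apex_guess + tolerance)
    n = sl.stop - sl.start
    if n < 3:
        return None
    mz = spectrum.mz[sl]
    inten = spectrum.intensity[sl]
    chord = inten[0] + (inten[-1] - inten[0]) * (mz - mz[0]) / (mz[-1] - mz[0])
    excess = float(np.trapezoid(inten - chord, mz))
    noise_per_point = (
        1.4826 * float(np.median(np.abs(np.diff(spectrum.intensity)))) / math.sqrt(2.0)
    )
    dx = float(mz[-1] - mz[0]) / (n - 1)
    if excess <= snr * noise_per_point * math.sqrt(n) * dx or excess <= 0.0:
        return None
    # the reported apex stays within the matching window around the target
    return float(apex_guess), float(spectrum.intensity[k0])


# ---------------------------------------------------------------------------
# recalibration
# ---------------------------------------------------------------------------

def recalibrate(
    spectrum: Spectrum, panel: MarkerPanel = MarkerPanel()
) -> tuple[Spectrum, CalibrationModel]:
    """Internally recalibrate the m/z axis on the two calibrant ion signals.

    The apex nearest each calibrant reference mass (within the panel's
    matching tolerance) is located, and the unique affine map sending the
    two observed apex positions to the reference masses is applied to the
    whole axis. After the transform both calibrant apexes coincide with
    their reference masses exactly (up to float rounding).

    Raises
    ------
    CalibrationError
        If either calibrant is not found, or |slope - 1| > 0.01.
    """
    ref_lo, ref_hi = sorted(panel.calibrant_mzs)
    found = []
    for ref in (ref_lo, ref_hi):
        apex = _find_apex(spectrum, ref, panel.match_tolerance_da)
        if apex is None:
            raise CalibrationError(
                f"calibrant ion signal at m/z {ref:g} not found within "
                f"±{panel.match_tolerance_da:g} Da"
            )
        found.append(apex[0])
    obs_lo, obs_hi = found
    if obs_hi <= obs_lo:
        raise CalibrationError("calibrant apexes are not ordered; cannot fit axis")
    slope = (ref_hi - ref_lo) / (obs_hi - obs_lo)
    intercept = ref_lo - slope * obs_lo
    if abs(slope - 1.0) > 0.01:
        raise CalibrationError(
            f"fitted calibration slope {slope:.5f} deviates from 1 by more than 1%"
        )
    model = CalibrationModel(slope=slope, intercept=intercept)
    return spectrum.with_mz(model.apply(spectrum.mz)), model


# ---------------------------------------------------------------------------
# peak integration
# ---------------------------------------------------------------------------

def integrate_peak(
    spectrum: Spectrum,
    target_mz: float,
    window_da: float = 25.0,
    baseline: str = "linear_endpoints",
    match_tolerance_da: float | None = None,
) -> PeakArea:
    """Integrate the ion signal at ``target_mz`` over ``target ± window_da``.

    The apex is the intensity maximum inside the window (restricted to
    ``± match_tolerance_da`` of the target when given). With
    ``baseline='linear_endpoints'`` the chord between the window-edge
    intensities is subtracted and the residual clipped at zero before
    trapezoidal integration; ``baseline='none'`` integrates raw intensity.
    """
    if baseline not in ("linear_endpoints", "none"):
        raise ValueError(f"unknown baseline mode {baseline!r}")
    lo, hi = target_mz - window_da, target_mz + window_da
    if lo < spectrum.mz[0] or hi > spectrum.mz[-1]:
        raise FormatError(
            f"integration window [{lo:g}, {hi:g}] exceeds spectrum range "
            f"[{spectrum.mz[0]:g}, {spectrum.mz[-1]:g}]"
        )
    sl = _window_slice(spectrum, lo, hi)
    mz = spectrum.mz[sl]
    inten = spectrum.intensity[sl].copy()
    if len(mz) < 2:
        raise FormatError("integration window contains fewer than two samples")

    warning = None
    if np.all(inten == 0):
        warning = "all-zero window"

    if baseline == "linear_endpoints":
        chord = inten[0] + (inten[-1] - inten[0]) * (mz - mz[0]) / (mz[-1] - mz[0])
        signal = np.clip(inten - chord, 0.0, None)
    else:
        signal = inten
    area = float(np.trapezoid(signal, mz))

    tol = window_da if match_tolerance_da is None else match_tolerance_da
    apex_sl = _window_slice(spectrum, target_mz - tol, target_mz + tol)
    apex_mz_arr = spectrum.mz[apex_sl]
    apex_int_arr = spectrum.intensity[apex_sl]
    if len(apex_mz_arr) == 0:
        raise FormatError("apex search window is empty")
    k = int(np.argmax(apex_int_arr))
    return PeakArea(
        target_mz=float(target_mz),
        apex_mz=float(apex_mz_arr[k]),
        area=area,
        apex_intensity=float(apex_int_arr[k]),
        warning=warning,
    )


def extract_marker_areas(
    spectrum: Spectrum,
    panel: MarkerPanel = MarkerPanel(),
    window_da: float = 25.0,
    baseline: str = "linear_endpoints",
) -> dict[float, PeakArea]:
    """Quantify all five marker ion signals of a recalibrated spectrum.

    Raises
    ------
    MarkerMissingError
        If a marker has no credible apex within the matching tolerance or
        integrates to zero area.
    """
    areas: dict[float, PeakArea] = {}
    for target in panel.marker_mzs:
        apex = _find_apex(spectrum, target, panel.match_tolerance_da)
        if apex is None:
            raise MarkerMissingError(target)
        peak = integrate_peak(
            spectrum,
            target,
            window_da=window_da,
            baseline=baseline,
            match_tolerance_da=panel.match_tolerance_da,
        )
        if peak.area <= 0:
            raise MarkerMissingError(target, f"marker at m/z {target:g} has zero area")
        areas[target] = peak
    return areas


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def qc_check(
    spectrum: Spectrum,
    panel: MarkerPanel = MarkerPanel(),
    marker_areas: dict[float, PeakArea] | None = None,
    saa_factor: float = 2.0,
    calibration_failed: bool = False,
    calibration_detail: str = "",
) -> QCResult:
    """Screen a spectrum for exclusion-worthy artifacts.

    ``exclude_calibration`` when recalibration raised upstream;
    ``exclude_saa`` when the apex intensity at *both* serum amyloid A1
    positions exceeds ``saa_factor`` times the median marker apex intensity;
    otherwise ``pass``. The SAA rule is intensity-ratio based and therefore
    invariant under uniform intensity scaling.
    """
    if calibration_failed:
        return QCResult(
            "exclude_calibration",
            calibration_detail or "spectrum could not be internally recalibrated",
        )
    if marker_areas:
        median_marker_apex = float(
            np.median([p.apex_intensity for p in marker_areas.values()])
        )
    else:
        median_marker_apex = 0.0
    saa_intensities = []
    for qc_mz in panel.qc_mzs:
        apex = _find_apex(spectrum, qc_mz, panel.match_tolerance_da)
        saa_intensities.append(apex[1] if apex is not None else 0.0)
    if median_marker_apex > 0 and all(
        s > saa_factor * median_marker_apex for s in saa_intensities
    ):
        return QCResult(
            "exclude_saa",
            "serum amyloid A1 ion signals at m/z "
            f"{panel.qc_mzs[0]:g} and {panel.qc_mzs[1]:g} dominate the marker signals "
            f"(apex {saa_intensities[0]:.1f}/{saa_intensities[1]:.1f} vs median marker "
            f"apex {median_marker_apex:.1f})",
        )
    return QCResult("pass")


def preprocess_spectrum(
    spectrum: Spectrum,
    panel: MarkerPanel = MarkerPanel(),
    window_da: float = 25.0,
    baseline: str = "linear_endpoints",
    saa_factor: float = 2.0,
) -> tuple[dict[float, PeakArea] | None, QCResult]:
    """Run recalibration, marker extraction and QC on one spectrum.

    Returns ``(marker_areas, qc_result)``; ``marker_areas`` is None when the
    spectrum is excluded.
    """
    try:
        recal, _model = recalibrate(spectrum, panel)
    except CalibrationError as exc:
        return None, qc_check(
            spectrum, panel, None, saa_factor,
            calibration_failed=True, calibration_detail=str(exc),
        )
    areas = extract_marker_areas(recal, panel, window_da=window_da, baseline=baseline)
    qc = qc_check(recal, panel, areas, saa_factor)
    if qc.status != "pass":
        return None, qc
    return areas, qc
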