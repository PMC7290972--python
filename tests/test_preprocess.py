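import dataclasses
import math

import numpy as np
import pytest

from fgrscreen import (
    CalibrationError,
    FormatError,
    MARKER_MZS,
    MarkerPanel,
    MarkerMissingError,
    SimulationConfig,
    extract_marker_areas,
    integrate_peak,
    qc_check,
    recalibrate,
    simulate_spectrum,
)
from fgrscreen.preprocess import CALIBRANT_MZS, preprocess_spectrum
from fgrscreen.simulate import GroundTruthRecord
from fgrscreen.spectrum import Spectrum

from conftest import make_gaussian_spectrum


def _panel_spectrum(marker_area=1000.0, calibrant_area=1000.0, skip=(), **kwargs):
    peaks = {mz: marker_area for mz in MARKER_MZS if mz not in skip}
    peaks.update({mz: calibrant_area for mz in CALIBRANT_MZS if mz not in skip})
    return make_gaussian_spectrum(peaks, **kwargs)


class TestRecalibration:
    def test_identity_when_already_calibrated(self):
        # calibrant reference masses are non-integer, so build the grid to
        # contain them exactly
        mz = np.sort(np.concatenate([
            np.arange(4000.0, 20000.0, 1.0), np.array(CALIBRANT_MZS)
        ]))
        intensity = np.zeros_like(mz)
        sp = Spectrum(mz, intensity)
        for c in CALIBRANT_MZS:
            intensity += 100.0 * np.exp(-0.5 * ((mz - c) / 4.0) ** 2)
        sp = Spectrum(mz, intensity)
        _, model = recalibrate(sp)
        assert model.slope == pytest.approx(1.0, abs=1e-9)
        assert model.intercept == pytest.approx(0.0, abs=1e-6)

    def test_two_point_fit_exact(self):
        # apexes deliberately offset: observed at 6640.0 and 13770.0
        sp = make_gaussian_spectrum({6640.0: 1000.0, 13770.0: 1000.0})
        recal, model = recalibrate(sp)
        assert model.apply(np.array([6640.0]))[0] == pytest.approx(6631.6, abs=1e-9)
        assert model.apply(np.array([13770.0]))[0] == pytest.approx(13762.4, abs=1e-9)
        for ref in CALIBRANT_MZS:
            window = (recal.mz > ref - 10) & (recal.mz < ref + 10)
            apex = recal.mz[window][np.argmax(recal.intensity[window])]
            assert apex == pytest.approx(ref, abs=0.01)

    def test_idempotent(self):
        sp = _panel_spectrum()
        once, _ = recalibrate(sp)
        _, model2 = recalibrate(once)
        assert model2.slope == pytest.approx(1.0, abs=1e-6)
        assert model2.intercept == pytest.approx(0.0, abs=1e-2)

    def test_missing_calibrant_raises(self):
        sp = _panel_spectrum(skip=(CALIBRANT_MZS[0],))
        with pytest.raises(CalibrationError, match="6631.6"):
            recalibrate(sp)

    def test_excessive_slope_raises(self):
        # with a generous matching tolerance the calibrants are still found,
        # but the implied axis stretch of ~1.9% exceeds the 1% plausibility
        # bound and must be rejected
        sp = make_gaussian_spectrum({6700.0: 1000.0, 13700.0: 1000.0})
        with pytest.raises(CalibrationError, match="slope"):
            recalibrate(sp, MarkerPanel(match_tolerance_da=100.0))

    def test_simulated_calibration_failure_raises(self):
        cfg = SimulationConfig(seed=3)
        areas = {mz: 1000.0 for mz in (*MARKER_MZS, *CALIBRANT_MZS)}
        rec = GroundTruthRecord("P", "CTRL", "MS1", areas, "calibration_failure")
        sp = simulate_spectrum(rec, cfg, np.random.default_rng(0))
        with pytest.raises(CalibrationError):
            recalibrate(sp)


class TestIntegration:
    @pytest.mark.parametrize("sigma", [2.0, 4.0, 8.0])
    def test_gaussian_area_within_1pct(self, sigma):
        """Closed-form oracle: a unit-area Gaussian integrated over ≥ ±6σ
        must give back 1.0 within 1%."""
        sp = make_gaussian_spectrum({9000.0: 1.0}, sigma=sigma)
        peak = integrate_peak(sp, 9000.0, window_da=max(25.0, 6 * sigma))
        assert peak.area == pytest.approx(1.0, rel=0.01)
        assert peak.apex_mz == 9000.0

    def test_flat_zero_spectrum(self):
        sp = make_gaussian_spectrum({})
        peak = integrate_peak(sp, 9000.0)
        assert peak.area == 0.0
        assert peak.warning == "all-zero window"

    def test_constant_baseline_removed_by_chord(self):
        clean = integrate_peak(make_gaussian_spectrum({9000.0: 5.0}), 9000.0)
        raised = integrate_peak(
            make_gaussian_spectrum({9000.0: 5.0}, baseline=50.0), 9000.0
        )
        assert raised.area == pytest.approx(clean.area, rel=0.02)

    def test_no_baseline_mode_keeps_offset(self):
        raised = integrate_peak(
            make_gaussian_spectrum({9000.0: 5.0}, baseline=50.0),
            9000.0, baseline="none",
        )
        # 50 units over a 50 Da window adds ~2500 area
        assert raised.area == pytest.approx(5.0 + 50.0 * 50.0, rel=0.01)

    def test_window_outside_range_raises(self):
        sp = make_gaussian_spectrum({9000.0: 1.0})
        with pytest.raises(FormatError, match="window"):
            integrate_peak(sp, 4010.0, window_da=25.0)


class TestMarkerExtraction:
    def test_recovers_all_five_markers(self):
        sp = _panel_spectrum(marker_area=123.0)
        recal, _ = recalibrate(sp)
        areas = extract_marker_areas(recal)
        assert set(areas) == set(MARKER_MZS)
        for mz in MARKER_MZS:
            assert areas[mz].area == pytest.approx(123.0, rel=0.01)

    def test_missing_marker_named_in_error(self):
        sp = _panel_spectrum(skip=(8205.0,))
        recal, _ = recalibrate(sp)
        with pytest.raises(MarkerMissingError, match="8205") as err:
            extract_marker_areas(recal)
        assert err.value.marker_mz == 8205.0

    def test_intensity_scaling_scales_areas_linearly(self):
        sp = _panel_spectrum(marker_area=50.0)
        recal, _ = recalibrate(sp)
        base = extract_marker_areas(recal)
        scaled = extract_marker_areas(recal.scaled(10.0))
        for mz in MARKER_MZS:
            assert scaled[mz].area == pytest.approx(10.0 * base[mz].area, rel=1e-9)


class TestQc:
    def _simulated(self, artifact, seed=0):
        cfg = SimulationConfig(seed=3)
        areas = {mz: 1000.0 for mz in (*MARKER_MZS, *CALIBRANT_MZS)}
        rec = GroundTruthRecord("P", "CTRL", "MS1", areas, artifact)
        return simulate_spectrum(rec, cfg, np.random.default_rng(seed))

    @pytest.mark.parametrize(
        "artifact, expected",
        [("none", "pass"), ("saa", "exclude_saa"),
         ("calibration_failure", "exclude_calibration")],
    )
    def test_artifact_statuses(self, artifact, expected):
        areas, qc = preprocess_spectrum(self._simulated(artifact))
        assert qc.status == expected
        assert (areas is None) == (expected != "pass")
        if expected != "pass":
            assert qc.detail

    @pytest.mark.parametrize("k", [0.5, 3.0, 20.0])
    def test_qc_status_scale_invariant(self, k):
        for artifact in ("none", "saa"):
            sp = self._simulated(artifact)
            _, qc = preprocess_spectrum(sp)
            _, qc_scaled = preprocess_spectrum(sp.scaled(k))
            assert qc_scaled.status == qc.status

    def test_pass_for_clean_panel_spectrum(self):
        recal, _ = recalibrate(_panel_spectrum())
        areas = extract_marker_areas(recal)
        assert qc_check(recal, MarkerPanel(), areas).status == "pass"
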