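"""Baseline correction, calibrant matching, recalibration and QC tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualbead.preprocess import (CalibrantSet, apply_recalibration,
                                 assess_quality, fit_recalibration,
                                 match_calibrants, preprocess_cohort,
                                 preprocess_spectrum, rpc18_calibrants,
                                 subtract_baseline, summarize_exclusions,
                                 wcx_calibrants, QCReport, INVALID_FIT)
from dualbead.spectra import Spectrum
from dualbead.synthetic import render_spectrum, rpc18_config


def _flat_spectrum(c, n=2000, lo=1000.0, step=0.1):
    mz = lo + step * np.arange(n)
    return Spectrum(mz, np.full(n, float(c)))


def _brute_force_baseline(intensity, w, sm):
    """Independent naive moving-minimum + moving-average estimate."""
    n = len(intensity)
    mins = np.empty(n)
    for i in range(n):
        a, b = max(0, i - w // 2), min(n, i + w // 2 + w % 2)
        mins[i] = intensity[a:b].min()
    smoothed = np.empty(n)
    for i in range(n):
        a, b = max(0, i - sm // 2), min(n, i + sm // 2 + sm % 2)
        smoothed[i] = mins[a:b].mean()
    return smoothed


class TestSubtractBaseline:
    def test_constant_spectrum_becomes_zero(self):
        s = _flat_spectrum(7.5)
        out = subtract_baseline(s, window_da=20.0, smooth_da=4.0)
        assert np.allclose(out.intensity, 0.0)

    def test_narrow_peak_height_preserved(self):
        mz = 1000.0 + 0.1 * np.arange(4000)
        sigma = 0.5
        intensity = 100.0 * np.exp(-0.5 * ((mz - 1200.0) / sigma) ** 2)
        out = subtract_baseline(Spectrum(mz, intensity), window_da=40.0,
                                smooth_da=5.0)
        assert out.intensity.max() == pytest.approx(100.0, rel=0.02)

    def test_decaying_exponential_residual_bound(self):
        # brute-force oracle of the morphological estimate; the residual of
        # a pure baseline is ~A(1 - exp(-w/2L)) at the left edge
        L = 500.0  # decay length in Da
        mz = 1000.0 + 0.5 * np.arange(8000)
        A = 200.0
        intensity = A * np.exp(-(mz - 1000.0) / L)
        for w_da, bound in ((L / 10, 0.05), (L / 5, 0.10)):
            out = subtract_baseline(Spectrum(mz, intensity), window_da=w_da,
                                    smooth_da=w_da / 5)
            assert out.intensity.max() < bound * A
            # agrees with the independent naive implementation
            w_pts = int(round(w_da / 0.5))
            sm_pts = int(round(w_da / 5 / 0.5))
            oracle = np.maximum(
                intensity - _brute_force_baseline(intensity, w_pts, sm_pts), 0)
            assert out.intensity.max() == pytest.approx(oracle.max(), rel=0.1)

    def test_window_wider_than_span_rejected(self):
        s = _flat_spectrum(1.0, n=100, step=0.1)  # span 10 Da
        with pytest.raises(ValueError, match="wider"):
            subtract_baseline(s, window_da=50.0, smooth_da=5.0)
        with pytest.raises(ValueError):
            subtract_baseline(s, window_da=2.0, smooth_da=5.0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_never_negative_and_never_increases(self, seed):
        rng = np.random.default_rng(seed)
        mz = 1000.0 + 0.2 * np.arange(500)
        intensity = np.abs(rng.normal(5.0, 3.0, 500).cumsum() / 10.0)
        out = subtract_baseline(Spectrum(mz, intensity), window_da=10.0,
                                smooth_da=2.0)
        assert np.all(out.intensity >= 0.0)
        assert np.all(out.intensity <= intensity + 1e-9)


def _calibrant_spectrum(config, shift_ppm=0.0, per_peak_shift=None,
                        height=1000.0):
    cal = rpc18_calibrants()
    peaks = []
    for i, m in enumerate(cal.calibrant_mz):
        d = per_peak_shift[i] if per_peak_shift else shift_ppm
        peaks.append((m * (1 + d * 1e-6), height))
    return render_spectrum(peaks, config, rng=np.random.default_rng(0))


@pytest.fixture(scope="module")
def cfg():
    return rpc18_config(mz_min=1400, mz_max=3000, noise_cv=0.0,
                        baseline_amplitude=0.0)


class TestMatchCalibrants:
    def test_uniform_80ppm_shift_matches_all_five(self, cfg):
        s = _calibrant_spectrum(cfg, shift_ppm=80.0)
        matches = match_calibrants(s, rpc18_calibrants())
        assert len(matches) == 5
        for expected, observed in matches:
            assert observed / expected - 1 == pytest.approx(80e-6, abs=5e-6)

    def test_single_peak_outside_tolerance_unmatched(self, cfg):
        # one calibrant displaced by 500 ppm while the others sit exactly:
        # the coarse alignment finds no net shift, so the 100 ppm window
        # at 1465.8 excludes it
        s = _calibrant_spectrum(cfg, per_peak_shift=[500.0, 0, 0, 0, 0])
        matches = match_calibrants(s, rpc18_calibrants())
        matched = {m[0] for m in matches}
        assert 1465.8 not in matched
        assert len(matches) == 4

    def test_large_uniform_shift_recovered_by_coarse_alignment(self, cfg):
        s = _calibrant_spectrum(cfg, shift_ppm=300.0)
        assert len(match_calibrants(s, rpc18_calibrants())) == 5
        # without the alignment pass the stated tolerances apply absolutely
        assert len(match_calibrants(s, rpc18_calibrants(), coarse_ppm=1e-9)) <= 1

    def test_empty_spectrum_matches_nothing(self, cfg):
        s = Spectrum(cfg.grid(), np.zeros(len(cfg.grid())))
        assert match_calibrants(s, rpc18_calibrants()) == []


class TestRecalibration:
    def test_exact_matches_give_identity(self):
        matches = [(m, m) for m in rpc18_calibrants().calibrant_mz]
        fit = fit_recalibration(matches)
        assert fit.valid
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)

    def test_two_matches_invalid(self):
        fit = fit_recalibration([(1465.8, 1465.9), (1778.1, 1778.2)])
        assert not fit.valid

    def test_planted_drift_recovered_within_5ppm(self):
        d = 150e-6
        matches = [(m, m * (1 + d)) for m in rpc18_calibrants().calibrant_mz]
        fit = fit_recalibration(matches)
        for m, obs in matches:
            corrected = fit.slope * obs + fit.intercept
            assert abs(corrected / m - 1) < 5e-6

    def test_idempotent_on_corrected_data(self, tiny_rpc18_config):
        cfg = rpc18_config(mz_min=1400, mz_max=3000, noise_cv=0.0,
                           baseline_amplitude=0.0)
        s = _calibrant_spectrum(cfg, shift_ppm=120.0)
        corrected, fit1 = preprocess_spectrum(s, rpc18_calibrants())
        assert fit1.valid
        fit2 = fit_recalibration(match_calibrants(corrected,
                                                  rpc18_calibrants()))
        assert fit2.slope == pytest.approx(1.0, abs=1e-5)
        assert fit2.intercept == pytest.approx(0.0, abs=0.05)


class TestQuality:
    def _report(self, tic, fit=None, median=1000.0):
        return assess_quality(None, fit or INVALID_FIT, 0.05, median, tic=tic)

    def test_all_zero_spectrum_excluded_as_no_signal(self):
        r = self._report(0.0)
        assert r.excluded and r.reason == "no_signal"

    def test_normal_spectrum_with_valid_fit_kept(self):
        fit = fit_recalibration([(m, m) for m in (1465.8, 1778.1, 1865.2)])
        r = self._report(900.0, fit)
        assert not r.excluded and r.reason == "none"

    def test_calibration_failure_excludes_by_default(self):
        r = self._report(900.0, INVALID_FIT)
        assert r.excluded and r.reason == "calibration_failure"
        r2 = assess_quality(None, INVALID_FIT, 0.05, 1000.0, tic=900.0,
                            exclude_on_calibration_failure=False)
        assert not r2.excluded

    def test_ordering_invariance(self, tiny_rpc18_config, tiny_cohort):
        spectra = tiny_cohort.spectra_for("RPC18")
        _, r1 = preprocess_cohort(spectra, rpc18_calibrants())
        _, r2 = preprocess_cohort(spectra[::-1], rpc18_calibrants())
        d1 = {r.spectrum_id: r.excluded for r in r1}
        d2 = {r.spectrum_id: r.excluded for r in r2}
        assert d1 == d2


def _qc(platform, excluded):
    return QCReport(spectrum_id="s", platform_id=platform, sample_id="x",
                    replicate_index=1, tic=1.0, n_matched_calibrants=5,
                    no_signal=False, excluded=excluded, reason="no_signal"
                    if excluded else "none")


class TestSummarizeExclusions:
    def test_reproduces_study_percentages(self):
        reports = [_qc("WCX", i < 33) for i in range(1228)]
        reports += [_qc("RPC18", i < 8) for i in range(1228)]
        with pytest.warns(UserWarning, match="WCX"):
            table = summarize_exclusions(reports)
        assert table.loc["WCX", "pct"] == 2.7
        assert table.loc["RPC18", "pct"] == 0.7

    def test_zero_exclusions(self):
        table = summarize_exclusions([_qc("WCX", False) for _ in range(50)])
        assert table.loc["WCX", "pct"] == 0.0

    def test_half_up_rounding(self):
        # 25/1000 = exactly 2.5% -> stays 2.5, no warning boundary crossed
        table = summarize_exclusions([_qc("X", i < 25) for i in range(1000)])
        assert table.loc["X", "pct"] == 2.5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_exclusions([])


class TestEndToEndDrift:
    def test_planted_drifts_corrected_below_10ppm(self):
        from dualbead.experiments import drift_recovery_study
        result = drift_recovery_study()
        assert result["max_drift_ppm"] == 300.0
        assert result["residual_rms_ppm"] <= 10.0
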