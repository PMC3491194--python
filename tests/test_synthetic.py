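"""Simulator unit and property tests: envelopes, rendering, cohorts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dualbead.spectra import Spectrum
from dualbead.synthetic import (ConfigurationError, EffectSpec,
                                default_effects, default_platform_configs,
                                generate_cohort, generate_peak_cohort,
                                isotope_envelope, render_spectrum,
                                rpc18_config, wcx_config)


class TestIsotopeEnvelope:
    def test_poisson_ratio_oracle(self):
        # independent oracle: the Poisson rate itself is the first ratio
        lam = 4.75e-4 * 1465.8
        env = isotope_envelope(1465.8, 2)
        assert env[1] / env[0] == pytest.approx(lam, abs=1e-12)
        assert env[1] == pytest.approx(0.696, abs=1e-3)

    def test_small_mass_limit_is_monoisotopic(self):
        env = isotope_envelope(1e-6, 4)
        assert env[0] == 1.0
        assert np.all(env[1:] < 1e-8)

    def test_single_isotope_is_unity(self):
        assert isotope_envelope(3000.0, 1).tolist() == [1.0]

    def test_invalid_mass_rejected(self):
        with pytest.raises(ValueError):
            isotope_envelope(0.0, 3)
        with pytest.raises(ValueError):
            isotope_envelope(-5.0, 3)

    @given(mass=st.floats(min_value=600.0, max_value=12000.0),
           n=st.integers(min_value=2, max_value=6))
    @settings(max_examples=50, deadline=None)
    def test_envelope_matches_poisson_pmf(self, mass, n):
        env = isotope_envelope(mass, n)
        lam = 4.75e-4 * mass
        expected = stats.poisson.pmf(np.arange(n), lam)
        expected /= expected[0]
        assert np.allclose(env, expected, rtol=1e-9)
        assert env[0] == 1.0


class TestRenderSpectrum:
    def test_zero_everything_gives_zero_spectrum(self):
        cfg = rpc18_config(mz_min=1000, mz_max=1100, noise_cv=0.0,
                           baseline_amplitude=0.0, noise_floor=0.0)
        s = render_spectrum([], cfg, rng=np.random.default_rng(0))
        assert np.all(s.intensity == 0.0)

    def test_peak_height_preserved_on_grid(self):
        # closed-form Gaussian evaluated on the grid: apex ~ h within 1%
        cfg = wcx_config(mz_min=1000, mz_max=4000, noise_cv=0.0,
                         baseline_amplitude=0.0)
        h = 250.0
        s = render_spectrum([(2500.0, h)], cfg, rng=np.random.default_rng(0))
        fwhm = cfg.fwhm(2500.0)
        mask = np.abs(s.mz - 2500.0) <= fwhm
        assert s.intensity[mask].max() == pytest.approx(h, rel=0.01)

    def test_drift_shifts_apex_multiplicatively(self):
        cfg = rpc18_config(mz_min=2800, mz_max=3000, noise_cv=0.0,
                           baseline_amplitude=0.0)
        rng = np.random.default_rng(0)
        s0 = render_spectrum([(2931.5, 100.0)], cfg, drift_ppm=0.0, rng=rng)
        s1 = render_spectrum([(2931.5, 100.0)], cfg, drift_ppm=300.0, rng=rng)
        apex0 = s0.mz[np.argmax(s0.intensity)]
        apex1 = s1.mz[np.argmax(s1.intensity)]
        assert apex1 - apex0 == pytest.approx(2931.5 * 300e-6, abs=0.02)

    def test_rendered_isotope_ratios_match_envelope(self):
        # noise-free cluster apexes reproduce the envelope within grid error
        cfg = rpc18_config(mz_min=1400, mz_max=1500, noise_cv=0.0,
                           baseline_amplitude=0.0)
        s = render_spectrum([(1465.8, 1000.0)], cfg,
                            rng=np.random.default_rng(0))
        env = isotope_envelope(1465.8, cfg.n_isotopes)
        from dualbead.synthetic import ISOTOPE_SPACING
        for k, rel in enumerate(env):
            mask = np.abs(s.mz - (1465.8 + k * ISOTOPE_SPACING)) < 0.25
            assert s.intensity[mask].max() == pytest.approx(1000.0 * rel,
                                                            rel=0.05)

    def test_all_peaks_outside_range_warns(self):
        cfg = rpc18_config(mz_min=1000, mz_max=1100, noise_cv=0.0)
        with pytest.warns(UserWarning, match="no peak"):
            render_spectrum([(5000.0, 10.0)], cfg,
                            rng=np.random.default_rng(0))

    def test_failed_spot_is_near_zero(self):
        cfg = rpc18_config(mz_min=1000, mz_max=1100)
        s = render_spectrum([(1050.0, 1e4)], cfg, failed=True,
                            rng=np.random.default_rng(0))
        assert s.intensity.max() < 5 * cfg.noise_floor + 1e-9


class TestGenerateCohort:
    def test_full_scale_spectrum_count(self, tiny_configs, tiny_effects):
        co = generate_cohort(3, 4, 4, tiny_configs, tiny_effects, seed=0)
        assert co.n_spectra("WCX") == 28
        assert co.n_spectra("RPC18") == 28
        assert len(co.labels) == 7

    def test_determinism(self, tiny_configs, tiny_effects):
        a = generate_cohort(3, 3, 2, tiny_configs, tiny_effects, seed=5)
        b = generate_cohort(3, 3, 2, tiny_configs, tiny_effects, seed=5)
        for sa, sb in zip(a.spectra, b.spectra):
            assert np.array_equal(sa.intensity, sb.intensity)
            assert np.array_equal(sa.mz, sb.mz)
        assert a.drifts_ppm == b.drifts_ppm

    def test_adding_samples_keeps_earlier_ones(self, tiny_configs, tiny_effects):
        small = generate_cohort(2, 2, 2, tiny_configs, tiny_effects, seed=9)
        big = generate_cohort(2, 3, 2, tiny_configs, tiny_effects, seed=9)
        for sa, sb in zip(small.spectra, big.spectra):
            assert sa.spectrum_id == sb.spectrum_id
            assert np.array_equal(sa.intensity, sb.intensity)

    def test_effect_outside_range_raises_with_peak_name(self, tiny_configs):
        bad = {"WCX": [EffectSpec("way_out", 90000.0, 5.0)],
               "RPC18": []}
        with pytest.raises(ConfigurationError, match="way_out"):
            generate_cohort(2, 2, 1, {"WCX": tiny_configs["WCX"]},
                            {"WCX": bad["WCX"]}, seed=0)

    def test_failure_rate_within_binomial_bounds(self):
        # expected count = p x n within 99% binomial bounds over seeds
        cfg = rpc18_config(mz_min=1000, mz_max=1020, spot_failure_prob=0.1)
        eff = [EffectSpec("p1", 1010.0, 5.0)]
        n_spectra = n_failed = 0
        for seed in range(10):
            co = generate_cohort(10, 10, 2, {"RPC18": cfg}, {"RPC18": eff},
                                 seed=seed)
            n_spectra += len(co.spectra)
            n_failed += sum(co.failures.values())
        lo, hi = stats.binom.ppf([0.005, 0.995], n_spectra, 0.1)
        assert lo <= n_failed <= hi

    def test_replicates_share_biology(self):
        # noise-free, drift-free replicates of one sample are identical
        cfg = rpc18_config(mz_min=1000, mz_max=1050, noise_cv=0.0,
                           calibration_drift_ppm_sd=0.0, spot_failure_prob=0.0)
        eff = [EffectSpec("p1", 1020.0, 5.0, biological_cv=0.8)]
        co = generate_cohort(2, 2, 3, {"RPC18": cfg}, {"RPC18": eff}, seed=4)
        by_sample = {}
        for s in co.spectra:
            by_sample.setdefault(s.sample_id, []).append(s.intensity)
        for reps in by_sample.values():
            for r in reps[1:]:
                assert np.allclose(reps[0], r)


class TestPeakCohort:
    def test_shapes_and_determinism(self):
        eff = default_effects(scenario="standard")
        m1, y1 = generate_peak_cohort(5, 7, eff, seed=3)
        m2, y2 = generate_peak_cohort(5, 7, eff, seed=3)
        assert m1["WCX"].shape == (12, 48)
        assert m1["RPC18"].shape == (12, 42)
        assert m1["WCX"].equals(m2["WCX"])
        assert (y1 == y2).all()

    def test_null_scenario_has_no_planted_effects(self):
        eff = default_effects(scenario="null")
        assert all(e.case_log2_fold_change == 0.0
                   for effs in eff.values() for e in effs)

    def test_fold_change_recovery(self):
        # planted log2 fold changes recovered by group mean differences
        eff = default_effects(scenario="standard")
        mats, labels = generate_peak_cohort(400, 400, eff, seed=21,
                                            technical_cv=0.0)
        y = (labels == "case").to_numpy()
        for pid in ("WCX", "RPC18"):
            logs = np.log(mats[pid].to_numpy())
            diff = (logs[y].mean(axis=0) - logs[~y].mean(axis=0)) / math.log(2)
            planted = np.array([e.case_log2_fold_change for e in eff[pid]])
            informative = planted != 0
            assert np.allclose(diff[informative], planted[informative],
                               rtol=0.2, atol=0.1)

    def test_default_panels_match_study_scale(self):
        eff = default_effects()
        assert len(eff["WCX"]) == 48
        assert len(eff["RPC18"]) == 42
        n_wcx = sum(e.case_log2_fold_change != 0 for e in eff["WCX"])
        n_rpc = sum(e.case_log2_fold_change != 0 for e in eff["RPC18"])
        assert (n_wcx, n_rpc) == (10, 16)
        # effect directions follow the clinical t-value signs
        assert all(e.case_log2_fold_change <= 0 for e in eff["WCX"])
        assert all(e.case_log2_fold_change >= 0 for e in eff["RPC18"])
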