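"""Reusable simulation studies on synthetic cohorts.

These functions define the package's standard calibration experiments —
null-cohort AUC calibration, the fusion-benefit study on complementary
cohorts, planted-marker recovery, and type-I control of the per-peak t
test — with one frozen protocol so the test suite and the reproduction
script measure exactly the same quantities.

Protocol: cohorts of 100 samples at the study prevalence (34 cases / 66
controls), peak-matrix-level generation (the biological + technical layer
of the simulator, i.e. what the classifier sees after preprocessing,
quantification and replicate averaging), and double CV with a stratified
5-fold outer loop repeated over 3 partitions.  Cohort seed and CV seed
are both the experiment seed.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom

from .classify import CvConfig, combine_mix, double_cv_probabilities
from .markers import ttest_peaks, weighted_coefficients
from .metrics import auc_score, compute_report
from .preprocess import match_calibrants, preprocess_spectrum, rpc18_calibrants
from .synthetic import (EffectSpec, default_effects, generate_peak_cohort,
                        render_spectrum, rpc18_config)

__all__ = [
    "simulation_cv_config",
    "null_auc_study",
    "fusion_benefit_study",
    "marker_recovery_study",
    "ttest_type1_study",
    "drift_recovery_study",
]

N_CASES, N_CONTROLS = 34, 66  # study prevalence 105/307 at n = 100


def simulation_cv_config(seed: int, **overrides) -> CvConfig:
    """The frozen double-CV protocol used by the simulation studies."""
    base = dict(outer_scheme="kfold", outer_folds=5, outer_repeats=3,
                combiner_repeats=3, seed=seed)
    base.update(overrides)
    return CvConfig(**base)


def _platform_probabilities(seed: int, scenario: str):
    effects = default_effects(scenario=scenario)
    mats, labels = generate_peak_cohort(N_CASES, N_CONTROLS, effects, seed=seed)
    y = (labels == "case").astype(int).to_numpy()
    cfg = simulation_cv_config(seed)
    p1 = double_cv_probabilities(mats["WCX"], y, cfg, platform_id="WCX")
    p2 = double_cv_probabilities(mats["RPC18"], y, cfg, platform_id="RPC18")
    p_mix, _ = combine_mix(p1, p2, y, cfg)
    return p1, p2, p_mix, y


def null_auc_study(seeds=range(1, 21)) -> dict:
    """Mean double-CV AUC per platform and for MIX on null cohorts.

    With no planted effects the held-out probabilities must carry no
    discrimination: each mean should sit near 0.5.
    """
    aucs = {"WCX": [], "RPC18": [], "MIX": []}
    for seed in seeds:
        p1, p2, pm, y = _platform_probabilities(seed, "null")
        for key, vec in (("WCX", p1), ("RPC18", p2), ("MIX", pm)):
            aucs[key].append(auc_score(vec.p, y))
    return {key: float(np.mean(v)) for key, v in aucs.items()}


def fusion_benefit_study(seeds=range(1, 21)) -> dict:
    """How often MIX beats both platforms' deviance on complementary cohorts.

    Each platform carries half of its marker effects, scaled so both hold
    equal independent signal; fusing the two probability vectors should
    then lower the deviance below either single platform in nearly every
    cohort.
    """
    wins = 0
    seeds = list(seeds)
    for seed in seeds:
        p1, p2, pm, y = _platform_probabilities(seed, "complementary")
        d1 = compute_report(p1, y).deviance
        d2 = compute_report(p2, y).deviance
        dm = compute_report(pm, y).deviance
        wins += dm < min(d1, d2)
    return {"wins": int(wins), "n_seeds": len(seeds)}


def _single_marker_effects(n_peaks: int = 30, marker_index: int = 7,
                           log2_fc: float = 1.0, cv: float = 0.35):
    return {"P": [EffectSpec(f"pk{j:02d}", 1000.0 + 10.0 * j, 5.0,
                             case_log2_fold_change=log2_fc if j == marker_index else 0.0,
                             biological_cv=cv)
                  for j in range(n_peaks)]}


def marker_recovery_study(seeds=range(1, 21)) -> dict:
    """Does the planted marker top the weighted-coefficient ranking?

    One strong marker (log2 FC = 1 at biological CV 0.35) among 29
    uninformative peaks; recovery means its absolute weighted coefficient
    is the largest of the panel.
    """
    hits = 0
    seeds = list(seeds)
    for seed in seeds:
        effects = _single_marker_effects()
        mats, labels = generate_peak_cohort(N_CASES, N_CONTROLS, effects,
                                            seed=seed)
        y = (labels == "case").astype(int).to_numpy()
        scores = weighted_coefficients(mats["P"], y, simulation_cv_config(seed))
        best = max(scores, key=lambda s: abs(s.weighted_coefficient))
        hits += best.peak_id == "pk07"
    return {"hits": int(hits), "n_seeds": len(seeds)}


def ttest_type1_study(seeds=range(1, 21), alpha: float = 0.05) -> dict:
    """Fraction of null peaks flagged at p < alpha, with 99% binomial bounds."""
    effects = default_effects(scenario="null")
    n_sig = n_tot = 0
    for seed in seeds:
        mats, labels = generate_peak_cohort(N_CASES, N_CONTROLS, effects,
                                            seed=seed)
        y = (labels == "case").astype(int).to_numpy()
        for r in ttest_peaks(np.log1p(mats["RPC18"]), y):
            n_sig += int(r.significant)
            n_tot += 1
    lo, hi = binom.ppf([0.005, 0.995], n_tot, alpha)
    return {"n_significant": int(n_sig), "n_tests": int(n_tot),
            "rate": n_sig / n_tot, "bound_low": int(lo), "bound_high": int(hi)}


def drift_recovery_study(drifts_ppm=(-300, -200, -120, -60, 60, 120, 200, 300),
                         seed: int = 0) -> dict:
    """Residual calibration error after correcting planted drifts.

    Noise-free reflectron spectra are rendered with known multiplicative
    mass-axis drifts, recalibrated against the five calibrant peptides,
    and the corrected calibrant positions compared with their true
    masses.  Returns the RMS residual in ppm over all drifts.
    """
    cfg = rpc18_config(noise_cv=0.0, spot_failure_prob=0.0,
                       calibration_drift_ppm_sd=0.0)
    eff = default_effects({"RPC18": cfg}, scenario="null")["RPC18"]
    peaks = [(e.center_mz, float(np.exp(e.base_log_intensity))) for e in eff]
    cal = rpc18_calibrants()
    rng = np.random.default_rng(seed)
    residuals = []
    for drift in drifts_ppm:
        s = render_spectrum(peaks, cfg, drift_ppm=float(drift), rng=rng)
        corrected, fit = preprocess_spectrum(s, cal)
        if not fit.valid:
            raise RuntimeError(f"calibration failed at {drift} ppm")
        for expected, observed in match_calibrants(corrected, cal):
            residuals.append((observed - expected) / expected * 1e6)
    rms = float(np.sqrt(np.mean(np.square(residuals))))
    return {"residual_rms_ppm": rms, "max_drift_ppm": float(max(map(abs, drifts_ppm)))}
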