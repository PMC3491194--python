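"""Synthetic paired WCX / RPC18 serum-profiling cohorts with known truth.

The simulator emulates the structure of a dual magnetic-bead MALDI-TOF
case-control study: every serum sample is processed on two platforms,

* **WCX** — weak-cation-exchange eluates acquired in positive-ion linear
  mode, broad unresolved peaks over 960–11,024 Da;
* **RPC18** — reversed-phase C18 eluates acquired in reflectron mode,
  isotopically resolved peptide clusters over 600–4,000 Da;

each spotted in quadruplicate, so a 307-sample cohort yields 1,228
profiles per platform.  The generative model is deliberately simple but
covers every feature the downstream pipeline must survive:

* per-sample biological peak intensities (log-normal, shared across that
  sample's replicates) with class effects as log2 fold changes on chosen
  marker peaks,
* Gaussian peak shapes with FWHM growing affinely in m/z; RPC18 peaks are
  rendered as isotope clusters spaced 1.00235 Da with a Poisson
  (averagine-style) envelope,
* an exponentially decaying chemical baseline,
* multiplicative per-grid-point technical noise,
* a per-spectrum multiplicative mass-calibration drift (ppm), and
* occasional spotting failures that leave a near-empty noise floor.

Randomness is hierarchical (cohort → sample → spectrum) so the same seed
reproduces a cohort bit for bit and adding samples never perturbs earlier
ones.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import Spectrum, write_manifest, write_xy

__all__ = [
    "ISOTOPE_SPACING",
    "ConfigurationError",
    "PlatformConfig",
    "EffectSpec",
    "SyntheticCohort",
    "isotope_envelope",
    "render_spectrum",
    "generate_cohort",
    "generate_peak_cohort",
    "wcx_config",
    "rpc18_config",
    "default_platform_configs",
    "default_effects",
    "WCX_CALIBRANT_MZ",
    "RPC18_CALIBRANT_MZ",
    "write_cohort",
]

#: Average mass spacing between adjacent isotopes of a singly charged peptide (Da).
ISOTOPE_SPACING = 1.00235

#: Slope of the averagine-style Poisson rate per Da of monoisotopic mass.
_AVERAGINE_LAMBDA_PER_DA = 4.75e-4

#: Internal calibration peptides (Da), visually selected on the real platforms.
WCX_CALIBRANT_MZ = (1866.1, 3158.0, 4643.6, 5903.7, 6631.1, 7765.5, 9290.9)
RPC18_CALIBRANT_MZ = (1465.8, 1778.1, 1865.2, 2602.5, 2931.5)

# Marker masses used for the default discriminating panels.  They follow the
# published discriminating peaks of the two bead chemistries (WCX proteins up
# to ~10 kDa, RPC18 peptides — fibrinogen-alpha, complement C3f and ITIH4
# fragments — below 4 kDa).  5,920 is moved to 5,950 so its quantification
# window cannot collide with the 5,903.7 calibrant window.
_WCX_MARKER_MZ = (2024.0, 2770.0, 3328.0, 3956.0, 4480.0, 4963.0, 5248.0,
                  5950.0, 8939.0, 10270.0)
_RPC18_MARKER_MZ = (1206.6, 1211.7, 1449.7, 1465.8, 1691.8, 1778.1, 1865.2,
                    2021.1, 2271.2, 2602.5, 2768.3, 2931.5, 3156.5, 3190.4,
                    3261.5, 3954.0)

# Parent-protein grouping of the marker peaks: fragments of one protein
# share a latent abundance factor.  The RPC18 grouping follows the
# fibrinogen-alpha / ITIH4 / complement-C3f fragment families of the
# reversed-phase serum peptidome; the WCX proteins are split into two
# co-varying families.
_WCX_MARKER_GROUP = {2024.0: 1, 2770.0: 1, 3328.0: 1, 3956.0: 1, 4480.0: 1,
                     4963.0: 2, 5248.0: 2, 5950.0: 2, 8939.0: 2, 10270.0: 2}
_RPC18_MARKER_GROUP = {1206.6: 1, 1211.7: 1, 1449.7: 1, 1465.8: 1, 2768.3: 1,
                       2931.5: 1, 3261.5: 1,           # FGA-like fragments
                       2021.1: 2, 2271.2: 2, 3156.5: 2, 3190.4: 2, 3954.0: 2,
                       1691.8: 3, 1778.1: 3, 1865.2: 3, 2602.5: 3}


class ConfigurationError(ValueError):
    """A cohort configuration is internally inconsistent."""


@dataclass(frozen=True)
class PlatformConfig:
    """Acquisition model of one bead/instrument platform.

    ``fwhm_intercept``/``fwhm_slope`` define the peak full width at half
    maximum as an affine function of m/z (Da).  ``baseline_amplitude`` and
    ``baseline_decay`` (1/Da) shape the chemical baseline
    ``A·exp(−decay·(mz−mz_min))``.  ``noise_cv`` is the coefficient of
    variation of the multiplicative technical noise, and
    ``calibration_drift_ppm_sd`` the standard deviation of the per-spectrum
    mass-axis drift.  ``noise_floor`` is the tiny residual intensity left on
    a failed spot.
    """

    platform_id: str
    mz_min: float
    mz_max: float
    grid_step: float
    fwhm_intercept: float
    fwhm_slope: float
    isotopically_resolved: bool
    baseline_amplitude: float = 0.0
    baseline_decay: float = 0.0
    noise_cv: float = 0.0
    calibration_drift_ppm_sd: float = 0.0
    spot_failure_prob: float = 0.0
    noise_floor: float = 0.0
    n_isotopes: int = 3

    def __post_init__(self):
        if not self.mz_min < self.mz_max:
            raise ConfigurationError("mz_min must be < mz_max")
        if self.grid_step <= 0:
            raise ConfigurationError("grid_step must be positive")
        if not 0.0 <= self.spot_failure_prob <= 1.0:
            raise ConfigurationError("spot_failure_prob must lie in [0, 1]")

    def fwhm(self, mz):
        return self.fwhm_intercept + self.fwhm_slope * np.asarray(mz, float)

    def grid(self) -> np.ndarray:
        """Shared nominal m/z grid of the platform."""
        return _grid_cache(self.mz_min, self.mz_max, self.grid_step)

    def baseline(self) -> np.ndarray:
        """Chemical baseline evaluated on the nominal grid."""
        g = self.grid()
        if self.baseline_amplitude == 0.0:
            return np.zeros_like(g)
        return self.baseline_amplitude * np.exp(
            -self.baseline_decay * (g - self.mz_min))


_GRIDS: dict[tuple, np.ndarray] = {}


def _grid_cache(lo: float, hi: float, step: float) -> np.ndarray:
    key = (lo, hi, step)
    g = _GRIDS.get(key)
    if g is None:
        n = int(math.floor((hi - lo) / step)) + 1
        g = lo + step * np.arange(n)
        g.setflags(write=False)
        _GRIDS[key] = g
    return g


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth description of one planted peak.

    ``base_log_intensity`` is the natural-log mean peak height;
    ``case_log2_fold_change`` shifts cases up (positive) or down (negative);
    ``biological_cv`` is the between-subject SD on the log scale (shared by
    all four replicates of a sample).  ``factor_loading`` correlates the
    peak's biological variation with a latent per-sample factor shared by
    the peaks of the same ``factor_group`` — marker peptides in serum
    profiles are largely cleavage fragments of a few parent proteins
    (fibrinogen alpha, complement C3f and ITIH4 in the reversed-phase
    peptidome), and fragments of one protein co-vary strongly, which is
    what the group factors emulate.
    """

    peak_id: str
    center_mz: float
    base_log_intensity: float
    case_log2_fold_change: float = 0.0
    biological_cv: float = 0.3
    factor_loading: float = 0.0
    factor_group: int = 0

    def __post_init__(self):
        if self.biological_cv < 0:
            raise ConfigurationError(f"peak {self.peak_id}: biological_cv must be >= 0")
        if not -1.0 <= self.factor_loading <= 1.0:
            raise ConfigurationError(f"peak {self.peak_id}: factor_loading must lie in [-1, 1]")


@dataclass
class SyntheticCohort:
    """A generated dual-platform cohort together with its ground truth."""

    spectra: list  # list[Spectrum], all platforms interleaved
    labels: pd.Series  # sample_id -> "case" / "control"
    effects: dict  # platform_id -> list[EffectSpec]
    drifts_ppm: dict  # spectrum_id -> planted drift
    failures: dict  # spectrum_id -> bool
    seed: int

    def spectra_for(self, platform_id: str):
        return [s for s in self.spectra if s.platform_id == platform_id]

    def n_spectra(self, platform_id: str) -> int:
        return sum(1 for s in self.spectra if s.platform_id == platform_id)

    @property
    def y(self) -> np.ndarray:
        """0/1 labels aligned with ``labels`` (1 = case)."""
        return (self.labels.to_numpy() == "case").astype(int)


def isotope_envelope(monoisotopic_mass: float, n_isotopes: int = 3) -> np.ndarray:
    """Relative isotope abundances of a singly charged peptide.

    Uses the averagine-style Poisson approximation: the abundance of the
    k-th isotope is proportional to a Poisson pmf with rate
    ``λ = 4.75e-4 × mass``, adequate for peptides below ~4 kDa.  The
    returned vector is normalized so the monoisotopic element equals 1.
    """
    if monoisotopic_mass <= 0:
        raise ValueError("monoisotopic mass must be positive")
    n_isotopes = int(n_isotopes)
    if n_isotopes < 1:
        raise ValueError("n_isotopes must be >= 1")
    lam = _AVERAGINE_LAMBDA_PER_DA * monoisotopic_mass
    k = np.arange(n_isotopes)
    # Poisson pmf ratio to k=0: lam^k / k!
    return lam ** k / np.array([math.factorial(int(i)) for i in k], dtype=float)


def _add_gaussian(y: np.ndarray, grid: np.ndarray, center: float,
                  height: float, fwhm: float) -> bool:
    """Add one Gaussian peak in place; return False if it misses the grid."""
    sigma = fwhm / 2.3548200450309493
    lo = np.searchsorted(grid, center - 5.0 * sigma)
    hi = np.searchsorted(grid, center + 5.0 * sigma)
    if lo >= hi:
        return False
    x = grid[lo:hi]
    y[lo:hi] += height * np.exp(-0.5 * ((x - center) / sigma) ** 2)
    return True


def render_spectrum(realized_peaks, config: PlatformConfig, drift_ppm: float = 0.0,
                    failed: bool = False, rng=None, *, sample_id: str = "",
                    replicate_index: int = 1) -> Spectrum:
    """Render one spectrum from realized per-peak intensities.

    Parameters
    ----------
    realized_peaks : sequence of (center_mz, height)
        Per-peak apex intensities already realized for this sample
        (non-negative).
    drift_ppm : float
        Multiplicative mass-calibration error; every reported m/z value is
        the nominal grid times ``1 + drift_ppm × 1e-6``.
    failed : bool
        Spotting failure — the spectrum is a near-zero noise floor only.
    """
    grid = config.grid()
    factor = 1.0 + drift_ppm * 1e-6
    if rng is None:
        rng = np.random.default_rng(0)
    if failed:
        intensity = np.abs(rng.normal(0.0, config.noise_floor, grid.shape)) \
            if config.noise_floor > 0 else np.zeros_like(grid)
        return Spectrum.on_grid(grid, intensity, drift_factor=factor,
                                platform_id=config.platform_id,
                                sample_id=sample_id,
                                replicate_index=replicate_index)

    intensity = config.baseline().copy()
    any_in_range = len(realized_peaks) == 0
    for center, height in realized_peaks:
        if height < 0:
            raise ValueError("realized peak intensities must be non-negative")
        if config.isotopically_resolved:
            env = isotope_envelope(center, config.n_isotopes)
            hit = False
            for k, rel in enumerate(env):
                c = center + k * ISOTOPE_SPACING
                hit |= _add_gaussian(intensity, grid, c, height * rel,
                                     config.fwhm(c))
        else:
            hit = _add_gaussian(intensity, grid, center, height,
                                config.fwhm(center))
        any_in_range |= hit
    if not any_in_range:
        warnings.warn(f"{config.platform_id}: no peak falls inside "
                      f"[{config.mz_min}, {config.mz_max}] Da", stacklevel=2)
    if config.noise_cv > 0:
        intensity *= rng.normal(1.0, config.noise_cv, grid.shape)
        np.maximum(intensity, 0.0, out=intensity)
    return Spectrum.on_grid(grid, intensity, drift_factor=factor,
                            platform_id=config.platform_id,
                            sample_id=sample_id,
                            replicate_index=replicate_index)


def _realize_heights(effects, is_case: bool, rng) -> np.ndarray:
    logs = np.array([e.base_log_intensity for e in effects])
    cvs = np.array([e.biological_cv for e in effects])
    fcs = np.array([e.case_log2_fold_change for e in effects])
    rhos = np.array([e.factor_loading for e in effects])
    groups = np.array([e.factor_group for e in effects])
    # one latent parent-protein factor per group, shared by this sample's
    # replicates; drawn in fixed group order for determinism
    u_by_group = {g: rng.standard_normal() for g in sorted(set(groups))}
    u = np.array([u_by_group[g] for g in groups])
    eps = rng.standard_normal(len(effects))
    z = rhos * u + np.sqrt(1.0 - rhos ** 2) * eps
    return np.exp(logs + cvs * z + math.log(2.0) * fcs * (1 if is_case else 0))


def _check_effects(config: PlatformConfig, effects) -> None:
    for e in effects:
        if not (config.mz_min <= e.center_mz <= config.mz_max):
            raise ConfigurationError(
                f"peak {e.peak_id} at {e.center_mz} Da lies outside the "
                f"{config.platform_id} range [{config.mz_min}, {config.mz_max}]")


def generate_cohort(n_cases: int, n_controls: int, replicates: int,
                    configs: dict, effects: dict, seed: int) -> SyntheticCohort:
    """Generate a paired multi-platform cohort of rendered spectra.

    ``configs`` and ``effects`` map platform ids to a
    :class:`PlatformConfig` and a list of :class:`EffectSpec`.  Biological
    intensities are drawn once per sample and platform and shared across
    that sample's replicates; drift, spotting failure and technical noise
    are per spectrum.  Identical inputs and seed give a bit-identical
    cohort.
    """
    if n_cases < 1 or n_controls < 1 or replicates < 1:
        raise ValueError("counts must be >= 1")
    platforms = list(configs)
    for pid in platforms:
        _check_effects(configs[pid], effects[pid])

    n = n_cases + n_controls
    width = max(4, len(str(n)))
    sample_ids = [f"S{i + 1:0{width}d}" for i in range(n)]
    labels = pd.Series(["case"] * n_cases + ["control"] * n_controls,
                       index=sample_ids, name="label")

    root = np.random.SeedSequence(seed)
    sample_seqs = root.spawn(n)
    spectra, drifts, failures = [], {}, {}
    for i, sid in enumerate(sample_ids):
        is_case = i < n_cases
        plat_seqs = sample_seqs[i].spawn(len(platforms))
        for pid, pseq in zip(platforms, plat_seqs):
            cfg = configs[pid]
            eff = effects[pid]
            children = pseq.spawn(replicates + 1)
            bio_rng = np.random.default_rng(children[0])
            heights = _realize_heights(eff, is_case, bio_rng)
            peaks = [(e.center_mz, h) for e, h in zip(eff, heights)]
            for r in range(replicates):
                rng = np.random.default_rng(children[r + 1])
                drift = rng.normal(0.0, cfg.calibration_drift_ppm_sd)
                failed = bool(rng.random() < cfg.spot_failure_prob)
                s = render_spectrum(peaks, cfg, drift_ppm=drift, failed=failed,
                                    rng=rng, sample_id=sid,
                                    replicate_index=r + 1)
                spectra.append(s)
                drifts[s.spectrum_id] = float(drift)
                failures[s.spectrum_id] = failed
    return SyntheticCohort(spectra=spectra, labels=labels, effects=dict(effects),
                           drifts_ppm=drifts, failures=failures, seed=seed)


def generate_peak_cohort(n_cases: int, n_controls: int, effects: dict,
                         seed: int, replicates: int = 4,
                         technical_cv: float = 0.1):
    """Generate replicate-averaged peak matrices directly, skipping rendering.

    Models the biological layer of :func:`generate_cohort` plus log-normal
    technical replicate noise, then averages the replicates — the input the
    classifier stage sees after preprocessing and quantification.  Used for
    classifier-level simulations where spectra themselves are not needed.

    Returns ``(matrices, labels)`` where ``matrices`` maps platform id to a
    samples × peaks :class:`pandas.DataFrame`.
    """
    if n_cases < 1 or n_controls < 1 or replicates < 1:
        raise ValueError("counts must be >= 1")
    platforms = list(effects)
    n = n_cases + n_controls
    width = max(4, len(str(n)))
    sample_ids = [f"S{i + 1:0{width}d}" for i in range(n)]
    labels = pd.Series(["case"] * n_cases + ["control"] * n_controls,
                       index=sample_ids, name="label")

    root = np.random.SeedSequence(seed)
    sample_seqs = root.spawn(n)
    rows = {pid: [] for pid in platforms}
    for i in range(n):
        is_case = i < n_cases
        plat_seqs = sample_seqs[i].spawn(len(platforms))
        for pid, pseq in zip(platforms, plat_seqs):
            rng = np.random.default_rng(pseq)
            heights = _realize_heights(effects[pid], is_case, rng)
            if technical_cv > 0:
                reps = heights * np.exp(technical_cv * rng.standard_normal(
                    (replicates, len(heights))))
                heights = reps.mean(axis=0)
            rows[pid].append(heights)
    matrices = {
        pid: pd.DataFrame(np.vstack(rows[pid]), index=sample_ids,
                          columns=[e.peak_id for e in effects[pid]])
        for pid in platforms
    }
    return matrices, labels


# --------------------------------------------------------------------------
# Default study conditions


def wcx_config(**overrides) -> PlatformConfig:
    """Linear-mode WCX platform defaults (960–11,024 Da, 1 Da grid)."""
    base = dict(platform_id="WCX", mz_min=960.0, mz_max=11024.0, grid_step=1.0,
                fwhm_intercept=2.0, fwhm_slope=1.5e-3,
                isotopically_resolved=False, baseline_amplitude=20.0,
                baseline_decay=5e-4, noise_cv=0.08,
                calibration_drift_ppm_sd=150.0, spot_failure_prob=0.02,
                noise_floor=0.1, n_isotopes=1)
    base.update(overrides)
    return PlatformConfig(**base)


def rpc18_config(**overrides) -> PlatformConfig:
    """Reflectron RPC18 platform defaults (600–4,000 Da, 0.02 Da grid)."""
    base = dict(platform_id="RPC18", mz_min=600.0, mz_max=4000.0,
                grid_step=0.02, fwhm_intercept=0.05, fwhm_slope=5e-5,
                isotopically_resolved=True, baseline_amplitude=10.0,
                baseline_decay=1e-3, noise_cv=0.08,
                calibration_drift_ppm_sd=80.0, spot_failure_prob=0.02,
                noise_floor=0.02, n_isotopes=3)
    base.update(overrides)
    return PlatformConfig(**base)


def default_platform_configs(**overrides) -> dict:
    """Both platform configs; ``overrides`` maps platform id to kwargs."""
    return {"WCX": wcx_config(**overrides.get("WCX", {})),
            "RPC18": rpc18_config(**overrides.get("RPC18", {}))}


def _fill_panel(existing, lo, hi, min_gap, total):
    """Deterministically pad a peak panel with evenly spread filler masses."""
    chosen = list(existing)
    for m in np.linspace(lo, hi, 4 * total):
        if len(chosen) >= total:
            break
        if all(abs(m - c) >= min_gap for c in chosen):
            chosen.append(float(m))
    return sorted(chosen)


def default_effects(configs=None, scenario: str = "standard",
                    log2_fold_change: float = 0.6,
                    biological_cv: float = 0.35,
                    marker_factor_loading: float = 0.7) -> dict:
    """Default planted-effect panels for both platforms.

    The panels mirror the real study's scale: 48 WCX and 42 RPC18 peaks,
    the internal calibrants among them, with case effects on 10 WCX marker
    peaks (negative, cases lower) and 16 RPC18 marker peaks (positive,
    cases higher).  Marker peaks within a platform share a latent
    disease-axis factor (loading 0.7) because discriminating serum
    peptides are largely cleavage products of the same few proteins and
    co-vary; the factors of the two platforms are independent, which is
    what makes the platforms complementary.  The effect size defaults to
    \\|log2 FC\\| = 0.6 at a biological CV of 0.35, which puts each
    platform's discriminability in the AUC ≈ 0.85–0.9 regime reported for
    the clinical cohorts.

    Scenarios
    ---------
    ``standard``      : all marker peaks carry their effect.
    ``complementary`` : each platform keeps effects on only half of its
                        markers (5 WCX, 8 RPC18), so the two platforms carry
                        weaker, independent information — the fusion test bed.
    ``null``          : no effects at all; labels are pure noise.

    Panels are filtered to each platform's m/z range, so narrowed ranges
    (e.g. in quick demos) keep a consistent subset.
    """
    if scenario not in ("standard", "complementary", "null"):
        raise ConfigurationError(f"unknown scenario {scenario!r}")
    if configs is None:
        configs = default_platform_configs()

    wcx_panel = _fill_panel(set(_WCX_MARKER_MZ) | set(WCX_CALIBRANT_MZ),
                            1100.0, 10700.0, 45.0, 48)
    rpc_panel = _fill_panel(set(_RPC18_MARKER_MZ), 650.0, 3950.0, 8.0, 42)

    marker_frac = {"standard": 1.0, "complementary": 0.5, "null": 0.0}[scenario]
    plat_specs = [
        ("WCX", wcx_panel, _WCX_MARKER_MZ, WCX_CALIBRANT_MZ, -1.0,
         _WCX_MARKER_GROUP),
        ("RPC18", rpc_panel, _RPC18_MARKER_MZ, RPC18_CALIBRANT_MZ, +1.0,
         _RPC18_MARKER_GROUP)]
    n_inf = {pid: int(round(marker_frac * len(markers)))
             for pid, _, markers, *_ in plat_specs}
    max_inf = max(n_inf.values())
    out = {}
    for pid, panel, markers, calibrants, sign, groups in plat_specs:
        cfg = configs.get(pid)
        if cfg is None:
            continue
        n_informative = n_inf[pid]
        informative = set(markers[:n_informative])
        # in the complementary scenario each platform keeps half its
        # markers; per-peak effects are scaled so both platforms carry the
        # same total planted signal, mirroring the near-equal
        # single-platform performance of the clinical cohorts
        fc_scale = 1.0
        if scenario == "complementary" and n_informative > 0:
            fc_scale = math.sqrt(max_inf / n_informative)
        effects = []
        for j, m in enumerate(panel):
            if not (cfg.mz_min + 10 <= m <= cfg.mz_max - 10):
                continue
            base = 6.8 if m in calibrants else 5.0 + 1.1 * math.sin(2.3 * j)
            fc = sign * log2_fold_change * fc_scale if m in informative else 0.0
            effects.append(EffectSpec(
                peak_id=f"{pid}_{m:.1f}", center_mz=m,
                base_log_intensity=base, case_log2_fold_change=fc,
                biological_cv=biological_cv,
                factor_loading=marker_factor_loading if m in markers else 0.0,
                factor_group=groups.get(m, 0)))
        out[pid] = effects
    return out


# --------------------------------------------------------------------------
# Disk export


def write_cohort(cohort: SyntheticCohort, outdir) -> Path:
    """Write a cohort as .dat XY files, a TSV manifest and a truth JSON."""
    outdir = Path(outdir)
    spectra_dir = outdir / "spectra"
    spectra_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.spectra:
        rel = Path("spectra") / f"{s.spectrum_id}.dat"
        write_xy(s, outdir / rel)
        rows.append({"sample_id": s.sample_id,
                     "label": cohort.labels[s.sample_id],
                     "platform": s.platform_id,
                     "replicate": s.replicate_index,
                     "path": str(rel)})
    write_manifest(pd.DataFrame(rows), outdir / "manifest.tsv")
    truth = {
        "seed": cohort.seed,
        "effects": {pid: [dataclasses.asdict(e) for e in eff]
                    for pid, eff in cohort.effects.items()},
        "drifts_ppm": cohort.drifts_ppm,
        "failures": cohort.failures,
        "labels": cohort.labels.to_dict(),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    return outdir
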