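"""Peak quantification: corrected spectra → samples × peaks matrix.

Each platform carries a *reference peak set*: fixed m/z windows compiled
once per study (48 signals for WCX with 5–30 Da windows matching the
broad linear-mode peak widths; 42 signals for RPC18 with a fixed 0.49 Da
window per isotope).  Quantification takes the apex (maximum) intensity
inside each half-open window; for isotopically resolved platforms the
per-isotope intensities are summed into a single cluster value after an
isotope-distribution QC against the expected envelope.  Replicate spectra
of a sample are averaged (excluded replicates dropped) into the final
peak matrix used for classification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import Spectrum
from .synthetic import ISOTOPE_SPACING, isotope_envelope

__all__ = [
    "ReferencePeak",
    "ReferencePeakSet",
    "PeakMatrix",
    "quantify_peak",
    "quantify_spectrum",
    "isotope_qc",
    "average_replicates",
    "reference_peaks_from_effects",
    "read_refset_tsv",
    "write_refset_tsv",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferencePeak:
    peak_id: str
    center_mz: float
    window_da: float
    n_isotopes: int = 1


@dataclass(frozen=True)
class ReferencePeakSet:
    """Quantification windows of one platform.

    Windows of distinct peaks (including their isotope windows) must not
    overlap, so every grid point belongs to at most one peak.
    """

    platform_id: str
    peaks: tuple

    def __post_init__(self):
        spans = []
        for p in self.peaks:
            if p.window_da <= 0 or p.n_isotopes < 1:
                raise ValueError(f"peak {p.peak_id}: invalid window/isotope count")
            lo = p.center_mz - p.window_da / 2
            hi = p.center_mz + (p.n_isotopes - 1) * ISOTOPE_SPACING + p.window_da / 2
            spans.append((lo, hi, p.peak_id))
        spans.sort()
        for (lo1, hi1, id1), (lo2, hi2, id2) in zip(spans, spans[1:]):
            if lo2 < hi1:
                raise ValueError(f"windows of peaks {id1} and {id2} overlap")

    @property
    def peak_ids(self):
        return [p.peak_id for p in self.peaks]

    def __len__(self):
        return len(self.peaks)


@dataclass
class PeakMatrix:
    """Replicate-averaged intensities: one row per sample, one column per peak."""

    values: pd.DataFrame
    platform_id: str
    n_replicates_used: pd.Series

    @property
    def sample_ids(self):
        return self.values.index

    @property
    def peak_ids(self):
        return self.values.columns

    def to_csv(self, path):
        self.values.to_csv(path, index_label="sample_id", float_format="%.10g")

    @classmethod
    def from_csv(cls, path, platform_id=""):
        df = pd.read_csv(path, index_col="sample_id",
                         float_precision="round_trip").astype(float)
        return cls(values=df, platform_id=platform_id,
                   n_replicates_used=pd.Series(np.nan, index=df.index))


def _window_max(mz, intensity, lo, hi) -> float:
    i0, i1 = np.searchsorted(mz, [lo, hi])  # half-open [lo, hi)
    if i0 >= i1:
        return 0.0
    return float(intensity[i0:i1].max())


def quantify_peak(s: Spectrum, peak: ReferencePeak,
                  per_isotope: bool = False):
    """Apex intensity of one peak (isotope apexes summed for clusters).

    Isotope ``k`` is read in the half-open window
    ``[center + k·1.00235 − w/2, center + k·1.00235 + w/2)``; a window
    containing no grid point contributes 0.  With ``per_isotope=True`` the
    individual isotope intensities are returned instead of their sum.
    """
    mz, intensity = s.mz, s.intensity
    if peak.center_mz + peak.window_da / 2 < mz[0] or \
            peak.center_mz - peak.window_da / 2 > mz[-1]:
        log.warning("peak %s at %.2f Da lies outside the spectrum range",
                    peak.peak_id, peak.center_mz)
    vals = np.array([
        _window_max(mz, intensity,
                    peak.center_mz + k * ISOTOPE_SPACING - peak.window_da / 2,
                    peak.center_mz + k * ISOTOPE_SPACING + peak.window_da / 2)
        for k in range(peak.n_isotopes)
    ])
    return vals if per_isotope else float(vals.sum())


def quantify_spectrum(s: Spectrum, refset: ReferencePeakSet,
                      isotope_qc_max_rel_dev: float | None = None) -> pd.Series:
    """All reference peaks of one spectrum as a Series indexed by peak id.

    When ``isotope_qc_max_rel_dev`` is given, multi-isotope clusters whose
    observed isotope ratios deviate from the expected envelope by more
    than that relative amount are demoted to NaN (missing for this
    replicate); replicate averaging later ignores them.
    """
    out = {}
    for p in refset.peaks:
        vals = quantify_peak(s, p, per_isotope=True)
        total = float(vals.sum())
        if isotope_qc_max_rel_dev is not None and p.n_isotopes >= 2:
            ok, _ = isotope_qc(vals, isotope_envelope(p.center_mz, p.n_isotopes),
                               isotope_qc_max_rel_dev)
            if not ok:
                total = float("nan")
        out[p.peak_id] = total
    return pd.Series(out, name=s.spectrum_id)


def isotope_qc(intensities_per_isotope, expected_envelope,
               max_rel_dev: float, min_expected_ratio: float = 0.1):
    """Check observed isotope ratios against the expected envelope.

    Fails iff any observed ratio ``I_k / I_0`` deviates from the expected
    envelope ratio by more than ``max_rel_dev`` (relative).  Isotopes whose
    expected ratio falls below ``min_expected_ratio`` are not tested: a
    heavy isotope carrying a few percent of the monoisotopic abundance
    sits at the noise floor and has no diagnostic power.  Single-isotope
    peaks pass vacuously; an empty first isotope fails outright.

    Returns ``(passed, reason)``.
    """
    obs = np.asarray(intensities_per_isotope, float)
    env = np.asarray(expected_envelope, float)
    if len(obs) < 2:
        return True, "single isotope"
    if obs[0] <= 0:
        return False, "empty cluster"
    ratios = obs[1:] / obs[0]
    expected = env[1:len(obs)] / env[0]
    informative = expected >= min_expected_ratio
    rel_dev = np.abs(ratios[informative] / expected[informative] - 1.0)
    if rel_dev.size and np.any(rel_dev > max_rel_dev):
        return False, f"isotope ratio deviates {rel_dev.max():.2f} > {max_rel_dev}"
    return True, "ok"


def average_replicates(peak_vectors: pd.DataFrame, qc_reports,
                       platform_id: str = "") -> PeakMatrix:
    """Mean over non-excluded replicates, per sample and peak.

    ``peak_vectors`` holds one row per spectrum with a (sample_id,
    replicate) MultiIndex or with the QC reports supplying the identity.
    Samples whose every replicate was excluded are dropped with an error
    log naming them.  Peak values demoted to NaN by isotope QC are ignored
    in the mean; a peak missing in all surviving replicates of a sample is
    reported as 0 with a warning.
    """
    by_id = {r.spectrum_id: r for r in qc_reports}
    keep_rows, samples = [], []
    for sid_spec, row in peak_vectors.iterrows():
        r = by_id.get(sid_spec)
        if r is None:
            raise KeyError(f"no QC report for spectrum {sid_spec}")
        if not r.excluded:
            keep_rows.append(row)
            samples.append(r.sample_id)
    dropped = sorted({r.sample_id for r in qc_reports}
                     - set(samples))
    if dropped:
        log.error("samples dropped (no surviving replicate): %s",
                  ", ".join(dropped))
    if not keep_rows:
        raise ValueError("no spectra survived QC")
    df = pd.DataFrame(keep_rows)
    df.index = pd.Index(samples, name="sample_id")
    grouped = df.groupby(level=0, sort=False)
    means = grouped.mean()  # NaN-aware: isotope-QC demotions ignored
    n_used = grouped.size().astype(int)
    if means.isna().any().any():
        n_holes = int(means.isna().sum().sum())
        warnings.warn(f"{n_holes} sample/peak cells had no surviving "
                      "replicate measurement; reported as 0", stacklevel=2)
        means = means.fillna(0.0)
    return PeakMatrix(values=means, platform_id=platform_id,
                      n_replicates_used=n_used)


def reference_peaks_from_effects(effects, config) -> ReferencePeakSet:
    """Build the platform's reference file from planted-effect positions.

    WCX windows scale with the local peak width (2.5 × FWHM, clipped to
    the 5–30 Da range used for broad linear-mode peaks) and quantify a
    single apex; RPC18 uses the fixed 0.49 Da isotope window and sums the
    configured number of isotopes.
    """
    peaks = []
    for e in effects:
        if config.isotopically_resolved:
            w, n_iso = 0.49, config.n_isotopes
        else:
            w = float(np.clip(2.5 * config.fwhm(e.center_mz), 5.0, 30.0))
            n_iso = 1
        peaks.append(ReferencePeak(e.peak_id, e.center_mz, w, n_iso))
    return ReferencePeakSet(config.platform_id, tuple(peaks))


def write_refset_tsv(refset: ReferencePeakSet, path) -> None:
    pd.DataFrame([{
        "peak_id": p.peak_id, "platform": refset.platform_id,
        "center_mz": p.center_mz, "window_da": p.window_da,
        "n_isotopes": p.n_isotopes,
    } for p in refset.peaks]).to_csv(path, sep="\t", index=False)


def read_refset_tsv(path) -> dict:
    """Read reference peak sets, returned as a dict keyed by platform."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = {}
    for pid, grp in df.groupby("platform"):
        peaks = tuple(ReferencePeak(str(r.peak_id), float(r.center_mz),
                                    float(r.window_da), int(r.n_isotopes))
                      for r in grp.itertuples())
        out[str(pid)] = ReferencePeakSet(str(pid), peaks)
    return out
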