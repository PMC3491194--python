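"""Baseline correction, internal recalibration and spectrum-level QC.

Raw profiles pass through three steps before quantification:

1. **Baseline subtraction** — a morphological estimate (moving minimum
   followed by a moving-average smoother) is subtracted and the result
   clipped at zero.
2. **Internal recalibration** — platform-specific calibrant peptides are
   located in the spectrum and an affine correction
   ``mz' = slope·mz + intercept`` is fit by ordinary least squares of the
   expected on the observed apex positions.  At least three matched
   calibrants are required for a valid fit; fewer leaves the spectrum
   unalignable.  Matching is two-stage: a coarse wide-window pass
   estimates the median relative shift (the alignment step), then the
   per-calibrant ppm tolerances apply around the shifted positions.
3. **Quality control** — spectra without signal (spotting failures,
   total ion current below a small fraction of the cohort median) and,
   optionally, spectra whose calibration failed are excluded.  A cohort
   whose exclusion rate exceeds 2.5 % triggers a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d, uniform_filter1d

from .spectra import Spectrum

__all__ = [
    "CalibrantSet",
    "RecalibrationFit",
    "QCReport",
    "rpc18_calibrants",
    "wcx_calibrants",
    "subtract_baseline",
    "match_calibrants",
    "fit_recalibration",
    "apply_recalibration",
    "assess_quality",
    "summarize_exclusions",
    "preprocess_spectrum",
    "preprocess_cohort",
]

#: Default morphological baseline windows (Da), per platform.
BASELINE_WINDOW_DA = {"WCX": 500.0, "RPC18": 5.0}
BASELINE_SMOOTH_DA = {"WCX": 100.0, "RPC18": 1.0}

#: Exclusion-rate level above which a cohort warning is raised.
MAX_EXPECTED_EXCLUSION_RATE = 0.025


@dataclass(frozen=True)
class CalibrantSet:
    """Internal calibration peptides of one platform with ppm tolerances."""

    platform_id: str
    calibrant_mz: tuple
    tolerance_ppm: tuple

    def __post_init__(self):
        if len(self.calibrant_mz) != len(self.tolerance_ppm):
            raise ValueError("calibrant_mz and tolerance_ppm lengths differ")


def rpc18_calibrants() -> CalibrantSet:
    """The five reflectron-mode calibrant peptides.

    Tolerances interpolate linearly in m/z from 100 ppm at 1,465.8 Da to
    300 ppm at 2,931.5 Da, the highest calibrant mass.
    """
    mz = (1465.8, 1778.1, 1865.2, 2602.5, 2931.5)
    lo_m, hi_m, lo_t, hi_t = 1465.8, 2931.5, 100.0, 300.0
    tol = tuple(np.clip(lo_t + (hi_t - lo_t) * (m - lo_m) / (hi_m - lo_m),
                        lo_t, hi_t) for m in mz)
    return CalibrantSet("RPC18", mz, tol)


def wcx_calibrants(tolerance_ppm: float = 1000.0) -> CalibrantSet:
    """The seven linear-mode calibrant peaks with a uniform tolerance.

    Linear-mode mass accuracy is far coarser than reflectron mode; the
    default window is ±1000 ppm, configurable.
    """
    mz = (1866.1, 3158.0, 4643.6, 5903.7, 6631.1, 7765.5, 9290.9)
    return CalibrantSet("WCX", mz, tuple([tolerance_ppm] * len(mz)))


@dataclass(frozen=True)
class RecalibrationFit:
    """Affine mass-axis correction ``mz' = slope·mz + intercept``."""

    slope: float
    intercept: float
    n_matched: int
    residual_rms_ppm: float

    @property
    def valid(self) -> bool:
        """A fit needs at least three matched calibrants."""
        return self.n_matched >= 3


INVALID_FIT = RecalibrationFit(1.0, 0.0, 0, float("nan"))


@dataclass
class QCReport:
    """Per-spectrum exclusion decision."""

    spectrum_id: str
    platform_id: str
    sample_id: str
    replicate_index: int
    tic: float
    n_matched_calibrants: int
    no_signal: bool
    excluded: bool
    reason: str  # none | no_signal | calibration_failure


def subtract_baseline(s: Spectrum, window_da: float, smooth_da: float) -> Spectrum:
    """Morphological baseline removal.

    The baseline is a moving average (width ``smooth_da``) of a moving
    minimum (width ``window_da``) of the intensity; the output is
    ``max(0, intensity − baseline)`` on the unchanged m/z axis.  The
    minimum window must be wider than the widest peak for peak heights to
    survive, and narrower than the spectrum span.
    """
    if not window_da > smooth_da > 0:
        raise ValueError("require window_da > smooth_da > 0")
    mz = s.mz
    span = mz[-1] - mz[0]
    if window_da >= span:
        raise ValueError(f"baseline window {window_da} Da is wider than the "
                         f"spectrum span {span:.1f} Da")
    step = float(np.median(np.diff(mz)))
    w = max(1, int(round(window_da / step)))
    sm = max(1, int(round(smooth_da / step)))
    baseline = uniform_filter1d(
        minimum_filter1d(s.intensity, size=w, mode="nearest"),
        size=sm, mode="nearest")
    corrected = np.maximum(s.intensity - baseline, 0.0)
    return s.with_intensity(corrected)


def _parabolic_apex(mz, intensity, i):
    """Sub-grid apex position via a 3-point parabola around index ``i``."""
    if i <= 0 or i >= len(mz) - 1:
        return float(mz[i])
    y0, y1, y2 = intensity[i - 1], intensity[i], intensity[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not a local maximum in the quadratic sense
        return float(mz[i])
    delta = 0.5 * (y0 - y2) / denom
    step = 0.5 * (mz[i + 1] - mz[i - 1])
    return float(mz[i] + np.clip(delta, -0.5, 0.5) * step)


def _apex_in_window(mz, intensity, lo, hi, floor, min_rel=0.5):
    """Lowest-m/z local maximum above half the window maximum.

    For isotopically resolved peptides above ~2.1 kDa the second isotope
    is taller than the monoisotopic peak, so a plain argmax in a window
    wide enough to hold the cluster would return the wrong isotope; the
    monoisotopic peak is the lowest-mass member within a factor two of
    the apex (true up to ~4.2 kDa).  Neighbours outside the window are
    consulted so a peak flank cut by the window edge is not mistaken for
    a maximum.
    """
    i0, i1 = np.searchsorted(mz, [lo, hi])
    if i0 >= i1:
        return None
    wmax = float(intensity[i0:i1].max())
    if wmax <= floor:
        return None
    thresh = max(floor, min_rel * wmax)
    n = len(intensity)
    for j in range(i0, i1):
        v = intensity[j]
        if v < thresh:
            continue
        left = intensity[j - 1] if j > 0 else -np.inf
        right = intensity[j + 1] if j + 1 < n else -np.inf
        if v >= left and v >= right:
            return _parabolic_apex(mz, intensity, j)
    return None


def match_calibrants(s: Spectrum, c: CalibrantSet, coarse_ppm: float | None = None):
    """Locate calibrant apexes in a baseline-corrected spectrum.

    Returns a list of ``(expected_mz, observed_apex_mz)`` pairs; calibrants
    whose window holds no apex above the local noise floor are simply
    absent.  A first coarse pass (window ``coarse_ppm``, default twice the
    widest stated tolerance) estimates the median relative shift of the
    spectrum, and the stated per-calibrant tolerances are then applied
    around the shifted positions, so drifts larger than the tightest
    tolerance remain recoverable.
    """
    mz = s.mz
    intensity = s.intensity
    # noise floor: robust scale of the spectrum plus a small fraction of
    # its maximum, so bare Gaussian tails never count as peaks
    floor = max(3.0 * float(np.median(np.abs(intensity))),
                5e-3 * float(intensity.max(initial=0.0)))
    if coarse_ppm is None:
        coarse_ppm = 2.0 * max(c.tolerance_ppm)

    # coarse alignment pass
    shifts = []
    for m in c.calibrant_mz:
        half = m * coarse_ppm * 1e-6
        apex = _apex_in_window(mz, intensity, m - half, m + half, floor)
        if apex is not None:
            shifts.append(apex / m - 1.0)
    shift = float(np.median(shifts)) if shifts else 0.0

    matches = []
    for m, tol in zip(c.calibrant_mz, c.tolerance_ppm):
        center = m * (1.0 + shift)
        half = m * tol * 1e-6
        apex = _apex_in_window(mz, intensity, center - half, center + half, floor)
        if apex is not None:
            matches.append((float(m), apex))
    return matches


def fit_recalibration(matches) -> RecalibrationFit:
    """OLS affine fit of expected on observed calibrant positions.

    With fewer than three matches the fit is invalid and the caller must
    flag a calibration failure.
    """
    if len(matches) < 3:
        return RecalibrationFit(1.0, 0.0, len(matches), float("nan"))
    expected = np.array([m[0] for m in matches])
    observed = np.array([m[1] for m in matches])
    slope, intercept = np.polyfit(observed, expected, 1)
    corrected = slope * observed + intercept
    rms = float(np.sqrt(np.mean(((corrected - expected) / expected) ** 2)) * 1e6)
    return RecalibrationFit(float(slope), float(intercept), len(matches), rms)


def apply_recalibration(s: Spectrum, fit: RecalibrationFit) -> Spectrum:
    """Relabel the m/z axis with a valid affine correction."""
    if not fit.valid:
        return s
    return s.with_mz(fit.slope * s.mz + fit.intercept)


def assess_quality(s: Spectrum | None, fit: RecalibrationFit,
                   tic_floor_fraction: float, cohort_median_tic: float, *,
                   tic: float | None = None,
                   exclude_on_calibration_failure: bool = True) -> QCReport:
    """Decide whether one spectrum enters statistical analysis.

    ``no_signal`` flags total ion current below ``tic_floor_fraction``
    times the cohort median TIC (computed over the same platform after
    baseline correction); an invalid calibration fit optionally also
    excludes.  ``tic`` may be supplied directly when the spectrum itself
    is no longer held in memory.
    """
    if tic is None:
        if s is None:
            raise ValueError("either a spectrum or its TIC is required")
        tic = s.tic()
    no_signal = tic < tic_floor_fraction * cohort_median_tic
    if no_signal:
        excluded, reason = True, "no_signal"
    elif exclude_on_calibration_failure and not fit.valid:
        excluded, reason = True, "calibration_failure"
    else:
        excluded, reason = False, "none"
    return QCReport(
        spectrum_id=s.spectrum_id if s is not None else "",
        platform_id=s.platform_id if s is not None else "",
        sample_id=s.sample_id if s is not None else "",
        replicate_index=s.replicate_index if s is not None else 0,
        tic=float(tic), n_matched_calibrants=fit.n_matched,
        no_signal=bool(no_signal), excluded=excluded, reason=reason)


def _round_half_up_pct(n_excluded: int, n_total: int) -> float:
    pct = Decimal(100 * n_excluded) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_exclusions(reports) -> pd.DataFrame:
    """Per-platform exclusion counts and half-up-rounded percentages.

    Returns a DataFrame indexed by platform with columns ``n_total``,
    ``n_excluded`` and ``pct`` (one decimal).  Warns when any platform's
    exclusion rate exceeds the 2.5 % level expected of a healthy run.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("no QC reports to summarize")
    rows = {}
    for r in reports:
        st = rows.setdefault(r.platform_id, [0, 0])
        st[0] += 1
        st[1] += int(r.excluded)
    out = pd.DataFrame(
        {pid: {"n_total": tot, "n_excluded": exc,
               "pct": _round_half_up_pct(exc, tot)}
         for pid, (tot, exc) in rows.items()}).T
    out = out.astype({"n_total": int, "n_excluded": int, "pct": float})
    out.index.name = "platform"
    for pid, row in out.iterrows():
        if row["n_excluded"] / row["n_total"] > MAX_EXPECTED_EXCLUSION_RATE:
            warnings.warn(
                f"{pid}: exclusion rate {row['pct']:.1f}% exceeds the "
                f"expected maximum of 2.5%", stacklevel=2)
    return out


def preprocess_spectrum(s: Spectrum, calibrants: CalibrantSet,
                        window_da: float | None = None,
                        smooth_da: float | None = None):
    """Baseline-correct and recalibrate one spectrum.

    Returns ``(corrected_spectrum, fit)``; the corrected spectrum has the
    recalibrated axis when the fit is valid.
    """
    pid = s.platform_id or calibrants.platform_id
    if window_da is None:
        window_da = BASELINE_WINDOW_DA.get(pid, 10.0)
    if smooth_da is None:
        smooth_da = BASELINE_SMOOTH_DA.get(pid, window_da / 5.0)
    corrected = subtract_baseline(s, window_da, smooth_da)
    matches = match_calibrants(corrected, calibrants)
    fit = fit_recalibration(matches)
    return apply_recalibration(corrected, fit), fit


def preprocess_cohort(spectra, calibrants: CalibrantSet,
                      tic_floor_fraction: float = 0.05,
                      exclude_on_calibration_failure: bool = True,
                      window_da: float | None = None,
                      smooth_da: float | None = None):
    """Process a list of same-platform spectra and QC them jointly.

    Returns ``(corrected_spectra, reports)`` aligned with the input order.
    Exclusion decisions depend on the cohort only through the median TIC,
    so they are invariant to spectrum ordering.
    """
    corrected, fits = [], []
    for s in spectra:
        cs, fit = preprocess_spectrum(s, calibrants, window_da, smooth_da)
        corrected.append(cs)
        fits.append(fit)
    tics = np.array([cs.tic() for cs in corrected])
    median_tic = float(np.median(tics)) if len(tics) else 0.0
    reports = [
        assess_quality(cs, fit, tic_floor_fraction, median_tic,
                       exclude_on_calibration_failure=exclude_on_calibration_failure)
        for cs, fit in zip(corrected, fits)
    ]
    return corrected, reports


def qc_table(reports) -> pd.DataFrame:
    """QC reports as a flat table (spectrum_id, n_matched, tic, excluded, reason)."""
    return pd.DataFrame([{
        "spectrum_id": r.spectrum_id, "platform": r.platform_id,
        "sample_id": r.sample_id, "replicate": r.replicate_index,
        "n_matched": r.n_matched_calibrants, "tic": r.tic,
        "no_signal": r.no_signal, "excluded": r.excluded, "reason": r.reason,
    } for r in reports])
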