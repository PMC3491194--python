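"""Marker selection: discriminant weights, cut-offs and per-peak t tests.

Ranks the reference peaks by a *weighted discriminant coefficient*: the
double-CV discriminant direction of each outer training fold is
back-projected from component space to peak space and weighted by each
peak's pooled within-class standard deviation, then averaged over folds.
The coefficient measures how much one peak contributes to the canonical
discriminant, on a dimensionless (standardized) scale; peaks whose
absolute coefficient clears a platform cut-off form the reduced panel,
on which the within-platform rule can be recalibrated to check that
performance survives selection.  An independent two-sample Student's t
test (pooled variance) supplies the per-peak univariate statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .classify import (CvConfig, _as_matrix, _fit_rule, _outer_folds,
                       _resolve_priors, _select_components)
from .metrics import PerformanceReport, compute_report

__all__ = [
    "PeakScore",
    "MarkerTestResult",
    "weighted_coefficients",
    "select_peaks",
    "recalibrate_selected",
    "ttest_peaks",
    "WCX_COEFFICIENT_CUTOFF",
    "RPC18_COEFFICIENT_CUTOFF",
]

#: Cut-offs used on the clinical platforms' weighted-coefficient scale
#: (±2 kept 10 of 48 WCX peaks; ±3.75 kept 16 of 42 RPC18 peaks).  The
#: scale of the coefficient depends on effect sizes, so synthetic runs
#: choose their own cut-off.
WCX_COEFFICIENT_CUTOFF = 2.0
RPC18_COEFFICIENT_CUTOFF = 3.75


@dataclass
class PeakScore:
    peak_id: str
    weighted_coefficient: float
    selected: bool = False


@dataclass
class MarkerTestResult:
    """Two-sample t test of one peak on the case−control mean difference."""

    peak_id: str
    t_value: float
    sd: float  # pooled standard deviation
    p_value: float
    ci_low: float
    ci_high: float
    significant: bool  # p < 0.05


def weighted_coefficients(X, y, cfg: CvConfig,
                          platform_id: str | None = None):
    """Per-peak discriminant weights averaged over the outer CV folds.

    For each outer training fold the PCA dimension is tuned by the inner
    loop, the canonical discriminant direction (unit pooled within-class
    variance, cases projecting higher) is back-projected to standardized
    peak space and multiplied by the peak's pooled within-class SD in that
    space.  Scores negate exactly under a label flip (with a
    label-symmetric outer scheme such as leave-one-out).
    """
    ids, Xv = _as_matrix(X)
    peak_ids = list(getattr(X, "peak_ids", None)
                    if getattr(X, "peak_ids", None) is not None
                    else getattr(X, "columns", range(Xv.shape[1])))
    y = np.asarray(y, int)
    if cfg.log_transform:
        if np.any(Xv < 0):
            raise ValueError("log_transform requires non-negative "
                             "intensities; disable it for general features")
        Xv = np.log1p(Xv)
    rng = np.random.default_rng(cfg.seed)
    priors = _resolve_priors(cfg, y)
    folds = _outer_folds(y, cfg, rng)
    total = np.zeros(Xv.shape[1])
    for tr, _ in folds:
        k = _select_components(Xv[tr], y[tr], cfg, rng, priors)
        model = _fit_rule(Xv[tr], y[tr], k, priors)
        if model.n_components == 0:
            continue  # a null-model fold contributes zero weight
        w_comp = model.discriminant_direction()
        beta = model.components.T @ w_comp  # standardized peak space
        Z = (Xv[tr] - model.feature_mean) / model.feature_scale
        ytr = y[tr]
        d0 = Z[ytr == 0] - Z[ytr == 0].mean(axis=0)
        d1 = Z[ytr == 1] - Z[ytr == 1].mean(axis=0)
        pooled_sd = np.sqrt((np.sum(d0 ** 2, axis=0) +
                             np.sum(d1 ** 2, axis=0)) / len(ytr))
        total += beta * pooled_sd
    mean_scores = total / len(folds)
    return [PeakScore(str(pid), float(sc))
            for pid, sc in zip(peak_ids, mean_scores)]


def select_peaks(scores, cutoff: float):
    """Peaks whose \\|weighted coefficient\\| clears the cut-off, order kept."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    selected = []
    for s in scores:
        s.selected = abs(s.weighted_coefficient) >= cutoff
        if s.selected:
            selected.append(s.peak_id)
    if not selected:
        warnings.warn(f"no peak reaches the cut-off {cutoff}; "
                      "recalibration on the reduced panel will be skipped",
                      stacklevel=2)
    return selected


def recalibrate_selected(X, selected_peak_ids, y, cfg: CvConfig,
                         threshold: float = 0.5) -> PerformanceReport:
    """Full double-CV rerun of the within-platform rule on a reduced panel."""
    import pandas as pd

    from .classify import double_cv_probabilities

    if len(selected_peak_ids) < 2:
        raise ValueError("at least two selected peaks are required")
    values = X if isinstance(X, pd.DataFrame) else X.values
    reduced = values.loc[:, list(selected_peak_ids)]
    pv = double_cv_probabilities(reduced, y, cfg,
                                 platform_id=getattr(X, "platform_id", ""))
    return compute_report(pv, y, threshold=threshold,
                          rule=f"{pv.platform_id}-reduced")


def ttest_peaks(X, y, welch: bool = False, alpha: float = 0.05):
    """Independent two-sample t test per peak (case − control).

    Pooled-variance Student's t by default (Welch optional), two-sided p
    from the t distribution with n₁+n₂−2 df, and a 95 % CI on the raw
    mean difference.  A peak with zero pooled variance yields NaN
    statistics with a warning.
    """
    ids, Xv = _as_matrix(X)
    peak_ids = list(getattr(X, "peak_ids", None)
                    if getattr(X, "peak_ids", None) is not None
                    else getattr(X, "columns", range(Xv.shape[1])))
    y = np.asarray(y, int)
    case = Xv[y == 1]
    ctrl = Xv[y == 0]
    n1, n0 = case.shape[0], ctrl.shape[0]
    if n1 < 2 or n0 < 2:
        raise ValueError("each class needs at least two samples")
    df = n1 + n0 - 2
    results = []
    for j, pid in enumerate(peak_ids):
        x1, x0 = case[:, j], ctrl[:, j]
        diff = float(x1.mean() - x0.mean())
        sp2 = ((n1 - 1) * x1.var(ddof=1) + (n0 - 1) * x0.var(ddof=1)) / df
        if sp2 == 0:
            warnings.warn(f"peak {pid}: zero pooled variance, t undefined",
                          stacklevel=2)
            results.append(MarkerTestResult(str(pid), float("nan"),
                                            0.0, float("nan"), float("nan"),
                                            float("nan"), False))
            continue
        sd = float(np.sqrt(sp2))
        if welch:
            t, p = stats.ttest_ind(x1, x0, equal_var=False)
            se = float(np.sqrt(x1.var(ddof=1) / n1 + x0.var(ddof=1) / n0))
            dof = stats.ttest_ind(x1, x0, equal_var=False).df
        else:
            t, p = stats.ttest_ind(x1, x0, equal_var=True)
            se = sd * float(np.sqrt(1 / n1 + 1 / n0))
            dof = df
        tcrit = float(stats.t.ppf(0.975, dof))
        results.append(MarkerTestResult(
            peak_id=str(pid), t_value=float(t), sd=sd, p_value=float(p),
            ci_low=diff - tcrit * se, ci_high=diff + tcrit * se,
            significant=bool(p < alpha)))
    return results
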