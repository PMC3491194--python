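"""Classification performance panel and the two-platform quadrant accounting.

For any probability vector the panel reports Brier score, deviance,
sensitivity, specificity, total recognition rate and AUC.  The quadrant
summary cross-tabulates the two platforms' calls per sample in the
(x = p_RPC18, y = p_WCX) plane and counts how many discordant samples the
combined rule recovers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .classify import CvProbabilityVector, deviance

__all__ = [
    "PerformanceReport",
    "QuadrantSummary",
    "auc_score",
    "compute_report",
    "recognition_from_sens_spec",
    "quadrant_summary",
]


@dataclass
class PerformanceReport:
    """The metric panel of one diagnostic rule."""

    rule: str
    sensitivity: float
    specificity: float
    brier: float
    deviance: float
    total_recognition_rate: float
    auc: float
    threshold: float
    n_cases: int
    n_controls: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "rule", "sensitivity", "specificity", "brier", "deviance",
            "total_recognition_rate", "auc", "threshold", "n_cases",
            "n_controls")}


def auc_score(p, y) -> float:
    """Mann–Whitney AUC with half credit for ties.

    Equals the probability that a random case scores above a random
    control, counting exact ties as 1/2; invariant under strictly
    monotone transforms of ``p``.
    """
    p = np.asarray(p, float)
    y = np.asarray(y, int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    r = rankdata(p)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def compute_report(p, y, threshold: float = 0.5,
                   rule: str = "") -> PerformanceReport:
    """Full metric panel for one probability vector.

    A sample is called "case" when ``p >= threshold`` (samples exactly at
    the threshold are cases).  Sensitivity/specificity are NaN with a
    warning when the relevant class is absent.  The Brier score is the
    mean squared error between probability and 0/1 label; the deviance
    uses natural logs on clipped probabilities.
    """
    if isinstance(p, CvProbabilityVector):
        rule = rule or p.platform_id
        p = p.p
    p = np.asarray(p, float)
    y = np.asarray(y, int)
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    call = p >= threshold
    n1 = int(y.sum())
    n0 = len(y) - n1
    tp = int(np.sum(call & (y == 1)))
    tn = int(np.sum(~call & (y == 0)))
    if n1 == 0 or n0 == 0:
        warnings.warn("one class is absent; sensitivity/specificity undefined",
                      stacklevel=2)
    sens = tp / n1 if n1 else float("nan")
    spec = tn / n0 if n0 else float("nan")
    return PerformanceReport(
        rule=rule,
        sensitivity=sens,
        specificity=spec,
        brier=float(np.mean((p - y) ** 2)),
        deviance=deviance(p, y),
        total_recognition_rate=(tp + tn) / len(y),
        auc=auc_score(p, y),
        threshold=threshold,
        n_cases=n1,
        n_controls=n0,
    )


def recognition_from_sens_spec(sens: float, spec: float, n_cases: int,
                               n_controls: int, decimals: int = 2) -> float:
    """Total recognition rate implied by a sensitivity/specificity pair.

    The class-size-weighted mean
    ``(sens·n_cases + spec·n_controls) / (n_cases + n_controls)``,
    half-up rounded to ``decimals`` for reporting.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("class counts must be positive")
    for v in (sens, spec):
        if not 0.0 <= v <= 1.0:
            raise ValueError("sensitivity/specificity must lie in [0, 1]")
    num = Decimal(str(sens)) * n_cases + Decimal(str(spec)) * n_controls
    val = num / (n_cases + n_controls)
    q = Decimal(1).scaleb(-decimals)
    return float(val.quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class QuadrantSummary:
    """Per-class quadrant counts in the (p_RPC18, p_WCX) plane.

    Quadrants follow the scatter-plot layout: 1 = upper-left (WCX calls
    case, RPC18 does not), 2 = upper-right (both call case), 3 =
    lower-left (neither), 4 = lower-right (RPC18 only).  Samples in
    quadrants 1 and 4 are discordant between the platforms; a discordant
    sample is *recovered* when the combined rule classifies it correctly.
    """

    counts: dict = field(default_factory=dict)  # class -> {1..4: n}
    discordant: dict = field(default_factory=dict)  # class -> n in Q1+Q4
    recovered: dict = field(default_factory=dict)  # class -> n recovered

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in self.counts:
            row = {"class": cls}
            row.update({f"q{q}": self.counts[cls][q] for q in (1, 2, 3, 4)})
            row["discordant"] = self.discordant[cls]
            row["recovered"] = self.recovered[cls]
            rows.append(row)
        return pd.DataFrame(rows)


def _quadrant(call_rpc18: bool, call_wcx: bool) -> int:
    if call_wcx:
        return 2 if call_rpc18 else 1
    return 4 if call_rpc18 else 3


def quadrant_summary(p_wcx, p_rpc18, p_combined, y,
                     threshold: float = 0.5) -> QuadrantSummary:
    """Cross-tabulate the two platforms' calls and the combined recoveries."""
    vecs = []
    for v in (p_wcx, p_rpc18, p_combined):
        vecs.append(v.p if isinstance(v, CvProbabilityVector) else
                    np.asarray(v, float))
    pw, pr, pc = vecs
    y = np.asarray(y, int)
    if not len(pw) == len(pr) == len(pc) == len(y):
        raise ValueError("probability vectors and labels must be aligned")
    out = QuadrantSummary()
    for cls, is_case in (("case", 1), ("control", 0)):
        m = y == is_case
        counts = {q: 0 for q in (1, 2, 3, 4)}
        disc = rec = 0
        for cw, cr, cc in zip(pw[m] >= threshold, pr[m] >= threshold,
                              pc[m] >= threshold):
            q = _quadrant(cr, cw)
            counts[q] += 1
            if q in (1, 4):
                disc += 1
                if bool(cc) == bool(is_case):
                    rec += 1
        out.counts[cls] = counts
        out.discordant[cls] = disc
        out.recovered[cls] = rec
    return out
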