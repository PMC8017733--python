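"""Empirical ROC analysis: Mann-Whitney AUC, DeLong variance, Youden cut-offs.

The AUC is computed as the normalized Mann-Whitney U statistic — the
probability that a randomly chosen culture-positive patient outscores a
randomly chosen culture-negative one, with ties counted one half. Standard
errors and the covariance of two AUCs measured on the same patients use the
DeLong structural-component (placement-value) decomposition, which also
yields the paired z-test for comparing dependent curves.

Orientation is fixed to "higher score = more likely BSI". Threshold
semantics are declared per curve: ``>`` (predict positive if score > t,
natural for a continuous marker) or ``>=`` (natural for an integer score).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["RocCurve", "CutoffResult", "DelongComparison",
           "roc_curve", "delong_compare", "youden_cutoff"]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray   # sorted ascending, distinct observed scores
    sens_at: np.ndarray      # P(score ?op? t | positive) per threshold
    spec_at: np.ndarray      # P(not score ?op? t | negative)
    auc: float
    auc_se: float
    auc_ci95: tuple[float, float]
    n_pos: int
    n_neg: int
    orientation: str         # ">" or ">="


@dataclass(frozen=True)
class CutoffResult:
    threshold: float
    youden_j: float
    sens: float
    spec: float
    orientation: str


@dataclass(frozen=True)
class DelongComparison:
    auc_a: float
    auc_b: float
    diff: float
    se_diff: float
    z: float
    p: float


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values via midranks.

    V10[i] = fraction of negatives below positive i (ties half);
    V01[j] = fraction of positives above negative j (ties half);
    AUC = mean(V10) = 1 - mean(V01) ... both means equal the AUC.
    """
    m, n = len(pos), len(neg)
    combined = np.concatenate([pos, neg])
    r_all = stats.rankdata(combined)          # midranks in pooled sample
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n             # per-positive placements
    v01 = 1.0 - (r_all[m:] - r_neg) / m       # per-negative placements
    auc = float(v10.mean())
    return v10, v01, auc


def roc_curve(scores_pos, scores_neg, orientation: str = ">",
              threshold_style: str = "observed") -> RocCurve:
    """Empirical ROC curve of a marker for positives vs negatives.

    Sensitivity/specificity pairs are reported at every distinct observed
    score value (``threshold_style="observed"``) or at midpoints between
    adjacent distinct values (``"midpoint"``, the convention behind quoted
    cut-offs like 19.25) under the declared threshold semantics; the (0,0)
    and (1,1) endpoints are implied by thresholds outside the observed range.
    """
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score groups must be non-empty")
    if not (np.isfinite(pos).all() and np.isfinite(neg).all()):
        raise ValueError("scores must be finite")
    if orientation not in (">", ">="):
        raise ValueError("orientation must be '>' or '>='")

    v10, v01, auc = _placements(pos, neg)
    if np.unique(np.concatenate([pos, neg])).size == 1:
        warnings.warn("all scores identical across both groups; AUC = 0.5", stacklevel=2)
    m, n = pos.size, neg.size
    var = v10.var(ddof=1) / m if m > 1 else 0.0
    var += v01.var(ddof=1) / n if n > 1 else 0.0
    se = math.sqrt(var)
    ci = (max(0.0, auc - _Z95 * se), min(1.0, auc + _Z95 * se))

    thresholds = np.unique(np.concatenate([pos, neg]))
    if threshold_style == "midpoint":
        if thresholds.size < 2:
            raise ValueError("midpoint thresholds need at least two distinct scores")
        thresholds = (thresholds[:-1] + thresholds[1:]) / 2.0
    elif threshold_style != "observed":
        raise ValueError("threshold_style must be 'observed' or 'midpoint'")
    if orientation == ">":
        sens_at = np.array([(pos > t).mean() for t in thresholds])
        spec_at = np.array([(neg <= t).mean() for t in thresholds])
    else:
        sens_at = np.array([(pos >= t).mean() for t in thresholds])
        spec_at = np.array([(neg < t).mean() for t in thresholds])
    return RocCurve(thresholds, sens_at, spec_at, auc, se, ci, m, n, orientation)


def delong_compare(pos_a, neg_a, pos_b, neg_b) -> DelongComparison:
    """DeLong test for two dependent AUCs measured on the same patients.

    ``pos_a``/``pos_b`` must be paired per positive patient (same order),
    likewise the negative arrays; complete-case pairing is the caller's
    responsibility.
    """
    pos_a = np.asarray(pos_a, dtype=float)
    neg_a = np.asarray(neg_a, dtype=float)
    pos_b = np.asarray(pos_b, dtype=float)
    neg_b = np.asarray(neg_b, dtype=float)
    if pos_a.shape != pos_b.shape or neg_a.shape != neg_b.shape:
        raise ValueError("scores must be paired on the same records")
    m, n = pos_a.size, neg_a.size
    if m < 2 or n < 2:
        raise ValueError("need at least 2 positives and 2 negatives after pairing")

    v10a, v01a, auc_a = _placements(pos_a, neg_a)
    v10b, v01b, auc_b = _placements(pos_b, neg_b)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)   # 2x2 over positives
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)   # 2x2 over negatives
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    se = math.sqrt(max(var_diff, 0.0))
    if se == 0.0:
        z = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    else:
        z = diff / se
    p = 1.0 if z == 0.0 else 2.0 * stats.norm.sf(abs(z))
    return DelongComparison(auc_a, auc_b, diff, se, z, float(min(p, 1.0)))


def youden_cutoff(curve: RocCurve) -> CutoffResult:
    """Threshold maximizing Youden's J = sens + spec - 1.

    Ties broken toward higher sensitivity, then toward the lower threshold.
    """
    j = curve.sens_at + curve.spec_at - 1.0
    best = 0
    for i in range(1, len(curve.thresholds)):
        if (j[i] > j[best] + 1e-12
                or (abs(j[i] - j[best]) <= 1e-12
                    and (curve.sens_at[i] > curve.sens_at[best] + 1e-12
                         or (abs(curve.sens_at[i] - curve.sens_at[best]) <= 1e-12
                             and curve.thresholds[i] < curve.thresholds[best])))):
            best = i
    return CutoffResult(
        threshold=float(curve.thresholds[best]),
        youden_j=float(j[best]),
        sens=float(curve.sens_at[best]),
        spec=float(curve.spec_at[best]),
        orientation=curve.orientation,
    )
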