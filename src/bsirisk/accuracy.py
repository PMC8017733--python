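"""Diagnostic-accuracy metrics with confidence intervals.

A binary decision rule (e.g. NLCR > 12) is evaluated against the blood-culture
reference standard via a 2x2 confusion matrix. Records whose predictor is
missing are excluded complete-case per rule and accounted for explicitly.

Interval methods (selectable through :class:`CiConfig`):

* sensitivity / specificity — Clopper-Pearson exact binomial intervals;
* PPV / NPV — standard logit (Mercaldo) intervals;
* LR+ / LR− — log-method (Simel) intervals, with a 0.5 continuity correction
  applied to all four cells for interval (not point) computation when any
  cell is zero.

Predictive values depend on prevalence; :func:`metrics_from_rates` exposes
the Bayes identities directly so that operating points quoted in the
literature can be converted between (sens, spec, prevalence) and
(PPV, NPV, LR+, LR−).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import pandas as pd
from scipy import stats

from .cohort import CohortTable, PatientRecord
from .scores import ScorePanel

__all__ = [
    "ConfusionMatrix",
    "Estimate",
    "DiagnosticMetrics",
    "CiConfig",
    "confusion",
    "metrics_from_counts",
    "metrics_from_rates",
    "metrics_grid",
    "default_rules",
    "default_strata",
]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts of a rule against the culture reference, plus exclusions."""

    tp: int
    fp: int
    fn: int
    tn: int
    n_excluded_missing: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn, self.n_excluded_missing) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / self.n


@dataclass(frozen=True)
class Estimate:
    """Point estimate with an optional 95% confidence interval."""

    value: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: Estimate
    specificity: Estimate
    ppv: Estimate
    npv: Estimate
    lr_pos: Estimate
    lr_neg: Estimate
    prevalence: float


@dataclass(frozen=True)
class CiConfig:
    """Interval-method switches (defaults follow common clinical practice)."""

    proportion: str = "clopper-pearson"   # or "wald"
    predictive: str = "logit"             # or "wald"
    likelihood_ratio: str = "log"


def confusion(predictions: Sequence[Optional[bool]], truths: Sequence[bool]) -> ConfusionMatrix:
    """Tabulate rule predictions against reference truths.

    ``predictions`` may contain None (missing predictor): such records are
    counted only in ``n_excluded_missing``. Truths must all be present.
    """
    if len(predictions) != len(truths):
        raise ValueError(f"length mismatch: {len(predictions)} predictions vs {len(truths)} truths")
    tp = fp = fn = tn = excluded = 0
    for pred, truth in zip(predictions, truths):
        if truth is None:
            raise ValueError("reference truth may not be missing")
        if pred is None:
            excluded += 1
        elif pred and truth:
            tp += 1
        elif pred and not truth:
            fp += 1
        elif not pred and truth:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn, n_excluded_missing=excluded)


def _clopper_pearson(x: int, n: int) -> tuple[float, float]:
    lo = 0.0 if x == 0 else stats.beta.ppf(0.025, x, n - x + 1)
    hi = 1.0 if x == n else stats.beta.ppf(0.975, x + 1, n - x)
    return float(lo), float(hi)


def _wald(x: int, n: int) -> tuple[float, float]:
    p = x / n
    half = _Z95 * math.sqrt(p * (1 - p) / n)
    return max(0.0, p - half), min(1.0, p + half)


def _logit_interval(x: int, n: int) -> tuple[float, float]:
    # standard logit interval; 0.5 correction on empty cells
    a, b = float(x), float(n - x)
    if a == 0 or b == 0:
        a, b = a + 0.5, b + 0.5
    logit = math.log(a / b)
    se = math.sqrt(1 / a + 1 / b)
    lo = 1 / (1 + math.exp(-(logit - _Z95 * se)))
    hi = 1 / (1 + math.exp(-(logit + _Z95 * se)))
    return lo, hi


def _proportion_estimate(x: int, n: int, method: str) -> Estimate:
    p = x / n
    if method == "clopper-pearson":
        lo, hi = _clopper_pearson(x, n)
    elif method == "wald":
        lo, hi = _wald(x, n)
    else:
        raise ValueError(f"unknown proportion CI method {method!r}")
    return Estimate(p, lo, hi)


def _predictive_estimate(x: int, n: int, method: str) -> Estimate:
    p = x / n
    if method == "logit":
        lo, hi = _logit_interval(x, n)
    elif method == "wald":
        lo, hi = _wald(x, n)
    else:
        raise ValueError(f"unknown predictive-value CI method {method!r}")
    return Estimate(p, lo, hi)


def _lr_estimates(cm: ConfusionMatrix) -> tuple[Estimate, Estimate]:
    """LR point estimates from raw counts, log-method intervals (Simel).

    Intervals use a 0.5 continuity correction on all four cells when any cell
    is zero; the point estimate never does. spec = 1 makes LR+ infinite and
    its interval one-sided; sens = 1 does the same for LR−'s lower bound at 0.
    """
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    sens = tp / (tp + fn)
    spec = tn / (fp + tn)
    lr_pos = math.inf if spec == 1.0 else (sens / (1 - spec) if sens > 0 else 0.0)
    lr_neg = 0.0 if sens == 1.0 else ((1 - sens) / spec if spec > 0 else math.inf)

    a, b, c, d = (float(v) for v in (tp, fp, fn, tn))
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    sens_c, spec_c = a / (a + c), d / (b + d)
    se_log_pos = math.sqrt((1 - sens_c) / a + spec_c / b)
    se_log_neg = math.sqrt(sens_c / c + (1 - spec_c) / d)
    centre_pos = math.log(sens_c / (1 - spec_c))
    centre_neg = math.log((1 - sens_c) / spec_c)
    lo_pos = math.exp(centre_pos - _Z95 * se_log_pos)
    hi_pos = math.inf if math.isinf(lr_pos) else math.exp(centre_pos + _Z95 * se_log_pos)
    lo_neg = 0.0 if lr_neg == 0.0 else math.exp(centre_neg - _Z95 * se_log_neg)
    hi_neg = math.exp(centre_neg + _Z95 * se_log_neg)
    return Estimate(lr_pos, lo_pos, hi_pos), Estimate(lr_neg, lo_neg, hi_neg)


def metrics_from_counts(cm: ConfusionMatrix, ci: CiConfig | None = None,
                        stratum: str = "") -> DiagnosticMetrics:
    """Diagnostic metrics with 95% CIs from a confusion matrix."""
    ci = ci or CiConfig()
    label = f" in stratum {stratum!r}" if stratum else ""
    if cm.tp + cm.fn == 0:
        raise ValueError(f"no reference-positive records{label}: sensitivity undefined")
    if cm.fp + cm.tn == 0:
        raise ValueError(f"no reference-negative records{label}: specificity undefined")
    sens = _proportion_estimate(cm.tp, cm.tp + cm.fn, ci.proportion)
    spec = _proportion_estimate(cm.tn, cm.fp + cm.tn, ci.proportion)
    if cm.tp + cm.fp > 0:
        ppv = _predictive_estimate(cm.tp, cm.tp + cm.fp, ci.predictive)
    else:
        ppv = Estimate(math.nan)
    if cm.tn + cm.fn > 0:
        npv = _predictive_estimate(cm.tn, cm.tn + cm.fn, ci.predictive)
    else:
        npv = Estimate(math.nan)
    lr_pos, lr_neg = _lr_estimates(cm)
    return DiagnosticMetrics(sens, spec, ppv, npv, lr_pos, lr_neg, cm.prevalence)


def metrics_from_rates(sens: float, spec: float, prevalence: float) -> DiagnosticMetrics:
    """Point-estimate metrics from (sensitivity, specificity, prevalence).

    Bayes identities::

        PPV = sens*prev / (sens*prev + (1-spec)*(1-prev))
        NPV = spec*(1-prev) / (spec*(1-prev) + (1-sens)*prev)
        LR+ = sens / (1-spec);  LR- = (1-sens) / spec
    """
    for name, v in (("sens", sens), ("spec", spec), ("prevalence", prevalence)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} = {v} outside [0, 1]")
    tp_mass = sens * prevalence
    fp_mass = (1 - spec) * (1 - prevalence)
    fn_mass = (1 - sens) * prevalence
    tn_mass = spec * (1 - prevalence)
    ppv = tp_mass / (tp_mass + fp_mass) if tp_mass + fp_mass > 0 else 0.0
    npv = tn_mass / (tn_mass + fn_mass) if tn_mass + fn_mass > 0 else 1.0
    if prevalence == 0.0:
        ppv, npv = 0.0, 1.0
    lr_pos = math.inf if spec == 1.0 else sens / (1 - spec)
    lr_neg = math.inf if spec == 0.0 else (1 - sens) / spec
    return DiagnosticMetrics(
        Estimate(sens), Estimate(spec), Estimate(ppv), Estimate(npv),
        Estimate(lr_pos), Estimate(lr_neg), prevalence,
    )


Rule = tuple[str, Callable[[ScorePanel], Optional[bool]]]
Stratum = tuple[str, Callable[[PatientRecord, ScorePanel], bool]]


def default_rules() -> list[Rule]:
    """The five operating points evaluated in the analysis."""

    def nlcr_gt(cut):
        return lambda p: None if p.nlcr is None else p.nlcr > cut

    def mss_ge(cut):
        return lambda p: p.mss_points >= cut

    def combined(p):
        return None if p.nlcr is None else (p.nlcr > 12 and p.mss_points >= 3)

    return [
        ("NLCR>10", nlcr_gt(10.0)),
        ("NLCR>12", nlcr_gt(12.0)),
        ("MSS>=2", mss_ge(2)),
        ("MSS>=3", mss_ge(3)),
        ("NLCR>12 & MSS>=3", combined),
    ]


def default_strata() -> list[Stratum]:
    """Whole cohort plus the Sepsis-3 / non-Sepsis-3 subgroups."""
    return [
        ("all", lambda r, p: True),
        ("sepsis3", lambda r, p: p.sepsis3 is True),
        ("non_sepsis3", lambda r, p: p.sepsis3 is False),
    ]


def metrics_grid(cohort: CohortTable, panels: Sequence[ScorePanel],
                 rules: Sequence[Rule] | None = None,
                 strata: Sequence[Stratum] | None = None,
                 ci: CiConfig | None = None) -> pd.DataFrame:
    """One row of diagnostic metrics per rule x stratum (complete-case per rule).

    A stratum with an empty reference class yields an error row carrying the
    diagnostic message instead of metrics.
    """
    if len(cohort) != len(panels):
        raise ValueError("cohort and panels must be aligned")
    rules = list(rules) if rules is not None else default_rules()
    strata = list(strata) if strata is not None else default_strata()
    rows = []
    for s_name, s_filter in strata:
        idx = [i for i, (r, p) in enumerate(zip(cohort, panels)) if s_filter(r, p)]
        truths = [cohort[i].culture_positive for i in idx]
        for r_name, predicate in rules:
            preds = [predicate(panels[i]) for i in idx]
            cm = confusion(preds, truths)
            row = {"stratum": s_name, "rule": r_name, "n_stratum": len(idx),
                   "n_evaluated": cm.n, "n_excluded_missing": cm.n_excluded_missing,
                   "tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn}
            try:
                m = metrics_from_counts(cm, ci, stratum=s_name)
            except ValueError as exc:
                row["error"] = str(exc)
                rows.append(row)
                continue
            row.update({
                "prevalence": m.prevalence,
                "sensitivity": m.sensitivity.value,
                "sens_lo": m.sensitivity.ci_low, "sens_hi": m.sensitivity.ci_high,
                "specificity": m.specificity.value,
                "spec_lo": m.specificity.ci_low, "spec_hi": m.specificity.ci_high,
                "ppv": m.ppv.value, "ppv_lo": m.ppv.ci_low, "ppv_hi": m.ppv.ci_high,
                "npv": m.npv.value, "npv_lo": m.npv.ci_low, "npv_hi": m.npv.ci_high,
                "lr_pos": m.lr_pos.value, "lr_pos_lo": m.lr_pos.ci_low, "lr_pos_hi": m.lr_pos.ci_high,
                "lr_neg": m.lr_neg.value, "lr_neg_lo": m.lr_neg.ci_low, "lr_neg_hi": m.lr_neg.ci_high,
                "error": "",
            })
            rows.append(row)
    return pd.DataFrame(rows)
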