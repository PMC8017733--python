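"""End-to-end analysis: cohort -> scores -> accuracy grid -> ROC -> report.

``run_pipeline`` orchestrates the full analysis over a cohort that is either
read from CSV or simulated, producing an :class:`AnalysisReport` whose every
number is reproducible from the input cohort and configuration alone:

* a baseline-characteristics comparison by culture status (counts,
  median/IQR or mean/SD, test p-values: chi-square for categorical,
  Mann-Whitney or t for continuous);
* the diagnostic-metrics grid (rules x strata) with 95% CIs;
* ROC blocks per stratum: AUC with DeLong CI for MSS, NLCR and their
  logistic combination, pairwise DeLong comparisons, Youden cut-offs;
* the rule-agreement (Venn) partition of true positives with the Gram-stain
  cross-tabulation and Fisher p;
* provenance (seed, config hash, package version).

Report rendering follows common clinical-journal conventions: integer
percentages, one-decimal likelihood ratios, bracketed CIs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .accuracy import CiConfig, default_rules, default_strata, metrics_grid
from .cohort import CohortTable, read_cohort_csv
from .roc import delong_compare, roc_curve, youden_cutoff
from .scores import ScorePanel, score_cohort
from .stattests import (chi_square, gram_crosstab, logistic_fit, mann_whitney,
                        t_test_from_stats)
from .synth import GeneratorConfig, simulate_cohort

__all__ = ["AnalysisReport", "run_pipeline", "render_tables",
           "fmt_pct", "fmt_lr", "fmt_ci_pct"]

logger = logging.getLogger(__name__)

CohortSource = Union[str, Path, CohortTable, GeneratorConfig]


def fmt_pct(p: float) -> str:
    """Proportion -> integer-percent string (0.694 -> '69')."""
    return str(int(round(100 * p)))


def fmt_lr(lr: float) -> str:
    """Likelihood ratio -> one-decimal string; infinity prints 'inf'."""
    if math.isinf(lr):
        return "inf"
    return f"{lr:.1f}"


def fmt_ci_pct(value: float, lo: Optional[float], hi: Optional[float]) -> str:
    if lo is None or hi is None:
        return fmt_pct(value)
    return f"{fmt_pct(value)} ({fmt_pct(lo)}–{fmt_pct(hi)})"


@dataclass
class AnalysisReport:
    cohort_summary: pd.DataFrame
    completeness: pd.DataFrame
    metrics: pd.DataFrame
    roc_blocks: list[dict]
    gram_block: dict
    provenance: dict

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "cohort_summary": self.cohort_summary.to_dict(orient="records"),
            "completeness": self.completeness.to_dict(orient="records"),
            "metrics": self.metrics.to_dict(orient="records"),
            "roc": self.roc_blocks,
            "gram": self.gram_block,
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=indent, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _resolve_cohort(source: CohortSource, seed: Optional[int]) -> tuple[CohortTable, dict]:
    if isinstance(source, CohortTable):
        return source, {"source": source.metadata.get("source", "in-memory")}
    if isinstance(source, GeneratorConfig):
        cohort = simulate_cohort(source, seed=seed)
        cfg_hash = hashlib.sha256(repr(source).encode()).hexdigest()[:16]
        return cohort, {"source": "simulated", "config_sha256": cfg_hash}
    cohort = read_cohort_csv(source)
    return cohort, {"source": str(source)}


def _summary_rows(cohort: CohortTable, panels: Sequence[ScorePanel]) -> pd.DataFrame:
    """Baseline characteristics by culture status with test p-values."""
    pos = [r for r in cohort if r.culture_positive]
    neg = [r for r in cohort if not r.culture_positive]
    rows = []

    def continuous(label, getter, use_t=False):
        xs = [getter(r) for r in pos if getter(r) is not None]
        ys = [getter(r) for r in neg if getter(r) is not None]
        if len(xs) < 2 or len(ys) < 2:
            return
        if use_t:
            x, y = np.array(xs), np.array(ys)
            _, p = t_test_from_stats(x.mean(), x.std(ddof=1), len(x),
                                     y.mean(), y.std(ddof=1), len(y))
            desc_p = f"{np.mean(xs):.1f} (±{np.std(xs, ddof=1):.1f})"
            desc_n = f"{np.mean(ys):.1f} (±{np.std(ys, ddof=1):.1f})"
        else:
            _, p, _ = mann_whitney(xs, ys)
            qx = np.percentile(xs, [50, 25, 75])
            qy = np.percentile(ys, [50, 25, 75])
            desc_p = f"{qx[0]:.1f} ({qx[1]:.1f}–{qx[2]:.1f})"
            desc_n = f"{qy[0]:.1f} ({qy[1]:.1f}–{qy[2]:.1f})"
        rows.append({"characteristic": label, "positive": desc_p,
                     "negative": desc_n, "p": round(p, 4)})

    def categorical(label, flag):
        a = sum(bool(flag(r, p)) for r, p in zip(cohort, panels) if r.culture_positive)
        c = sum(bool(flag(r, p)) for r, p in zip(cohort, panels) if not r.culture_positive)
        table = [[a, len(pos) - a], [c, len(neg) - c]]
        try:
            _, p = chi_square(table)
        except ValueError:
            p = float("nan")
        rows.append({
            "characteristic": label,
            "positive": f"{a} ({100 * a / len(pos):.1f})" if pos else "0",
            "negative": f"{c} ({100 * c / len(neg):.1f})" if neg else "0",
            "p": round(p, 4),
        })

    panel_by_id = {p.event_id: p for p in panels}

    continuous("Age, mean (SD)", lambda r: r.age, use_t=True)
    categorical("Male sex", lambda r, p: r.sex == "male")
    categorical("SIRS criteria fulfilled", lambda r, p: p.sirs_fulfilled)
    categorical("qSOFA >=2 points", lambda r, p: p.qsofa >= 2)
    categorical("Sepsis-3 criteria fulfilled", lambda r, p: p.sepsis3 is True)
    categorical("Shapiro >=2 points", lambda r, p: p.mss_points >= 2)
    continuous("Body temperature C", lambda r: r.temperature)
    continuous("Systolic blood pressure, mmHg", lambda r: r.systolic_bp)
    continuous("Respiratory rate", lambda r: r.respiratory_rate)
    continuous("Pulse rate, beats per minute", lambda r: r.heart_rate)
    continuous("WBC x10^9/L", lambda r: r.wbc)
    continuous("Neutrophil cell count x10^9/L", lambda r: r.neutrophils)
    continuous("Lymphocyte cell count x10^9/L", lambda r: r.lymphocytes)
    continuous("NLCR", lambda r: panel_by_id[r.event_id].nlcr)
    continuous("Serum lactate (mmol/L)", lambda r: r.lactate)
    continuous("Creatinine (umol/L)", lambda r: r.creatinine)
    continuous("Bilirubin (umol/L)", lambda r: r.bilirubin)
    continuous("C-reactive protein (mg/L)", lambda r: r.crp)
    return pd.DataFrame(rows)


def _roc_block(cohort: CohortTable, panels: Sequence[ScorePanel],
               stratum_name: str, keep) -> dict:
    """AUCs, Youden cut-offs and pairwise DeLong tests for one stratum.

    Markers are paired complete-case on NLCR (MSS is always computable), so
    every comparison uses the same patients.
    """
    rows = [(r, p) for r, p in zip(cohort, panels) if keep(r, p) and p.nlcr is not None]
    truths = np.array([r.culture_positive for r, _ in rows])
    if truths.sum() < 2 or (~truths).sum() < 2:
        return {"stratum": stratum_name,
                "error": f"stratum {stratum_name!r} has fewer than 2 positives "
                         "or 2 negatives with evaluable scores"}
    mss = np.array([p.mss_points for _, p in rows], dtype=float)
    nlcr = np.array([p.nlcr for _, p in rows], dtype=float)
    fit = logistic_fit(truths.astype(float), np.column_stack([mss, np.log(nlcr)]))
    combined = fit.linear_predictor

    block: dict = {"stratum": stratum_name, "n": len(rows),
                   "n_pos": int(truths.sum()), "markers": {}, "comparisons": [],
                   "logistic": {"intercept": fit.intercept,
                                "coef_mss": float(fit.coef[0]),
                                "coef_log_nlcr": float(fit.coef[1]),
                                "converged": fit.converged}}
    curves = {}
    for name, scores, orient in (("MSS", mss, ">="), ("NLCR", nlcr, ">"),
                                 ("MSS+NLCR", combined, ">")):
        curve = roc_curve(scores[truths], scores[~truths], orientation=orient)
        cut = youden_cutoff(curve)
        curves[name] = (scores, curve)
        block["markers"][name] = {
            "auc": curve.auc, "auc_se": curve.auc_se,
            "auc_ci95": list(curve.auc_ci95),
            "youden": {"threshold": cut.threshold, "j": cut.youden_j,
                       "sens": cut.sens, "spec": cut.spec,
                       "orientation": cut.orientation},
        }
    for a, b in (("MSS", "NLCR"), ("NLCR", "MSS+NLCR"), ("MSS", "MSS+NLCR")):
        sa, sb = curves[a][0], curves[b][0]
        cmp_ = delong_compare(sa[truths], sa[~truths], sb[truths], sb[~truths])
        block["comparisons"].append({
            "a": a, "b": b, "auc_a": cmp_.auc_a, "auc_b": cmp_.auc_b,
            "diff": cmp_.diff, "z": cmp_.z, "p": cmp_.p,
        })
    return block


def run_pipeline(cohort_source: CohortSource, seed: Optional[int] = None,
                 ci: CiConfig | None = None) -> AnalysisReport:
    """Run the full analysis and return the report.

    ``cohort_source`` is a CSV path, an in-memory cohort, or a generator
    config (simulated with ``seed``). Deterministic given inputs.
    """
    from .cohort import completeness_report

    cohort, prov = _resolve_cohort(cohort_source, seed)
    logger.info("pipeline: cohort loaded, %d events (%d culture-positive)",
                len(cohort), cohort.n_positive)
    panels = score_cohort(cohort)

    grid = metrics_grid(cohort, panels, ci=ci)
    n_err = int((grid.get("error", pd.Series(dtype=str)) != "").sum())
    if n_err:
        logger.warning("pipeline: %d metric rows carry errors", n_err)

    strata = [(name, f) for name, f in default_strata() if name != "non_sepsis3"]
    roc_blocks = [_roc_block(cohort, panels, name, f) for name, f in strata]

    gram = gram_crosstab(cohort, panels)
    gram_block = {"venn": gram.venn, "n_evaluable": gram.n_evaluable,
                  "message": gram.message}
    if gram.gram_table is not None:
        gram_block["gram_table"] = {"only_nlcr": [gram.gram_table.a, gram.gram_table.b],
                                    "only_mss": [gram.gram_table.c, gram.gram_table.d]}
        gram_block["fisher_p"] = gram.fisher_p

    report = AnalysisReport(
        cohort_summary=_summary_rows(cohort, panels),
        completeness=completeness_report(cohort),
        metrics=grid,
        roc_blocks=roc_blocks,
        gram_block=gram_block,
        provenance={"seed": seed, "version": __version__, **prov},
    )
    logger.info("pipeline: report complete (%d metric rows)", len(grid))
    return report


def _metrics_table_formatted(grid: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for _, r in grid.iterrows():
        if r.get("error"):
            rows.append({"stratum": r["stratum"], "rule": r["rule"], "note": r["error"]})
            continue
        rows.append({
            "stratum": r["stratum"], "rule": r["rule"],
            "n": int(r["n_evaluated"]),
            "sensitivity_pct": fmt_ci_pct(r["sensitivity"], r["sens_lo"], r["sens_hi"]),
            "specificity_pct": fmt_ci_pct(r["specificity"], r["spec_lo"], r["spec_hi"]),
            "ppv_pct": fmt_ci_pct(r["ppv"], r["ppv_lo"], r["ppv_hi"]),
            "npv_pct": fmt_ci_pct(r["npv"], r["npv_lo"], r["npv_hi"]),
            "lr_pos": f"{fmt_lr(r['lr_pos'])} ({fmt_lr(r['lr_pos_lo'])}–{fmt_lr(r['lr_pos_hi'])})",
            "lr_neg": f"{fmt_lr(r['lr_neg'])} ({fmt_lr(r['lr_neg_lo'])}–{fmt_lr(r['lr_neg_hi'])})",
            "note": "",
        })
    return pd.DataFrame(rows)


def render_tables(report: AnalysisReport, outdir) -> dict[str, Path]:
    """Write the report as TSV tables plus the full JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["metrics"] = outdir / "metrics_grid.tsv"
    _metrics_table_formatted(report.metrics).to_csv(paths["metrics"], sep="\t", index=False)

    paths["cohort_summary"] = outdir / "cohort_summary.tsv"
    report.cohort_summary.to_csv(paths["cohort_summary"], sep="\t", index=False)

    paths["completeness"] = outdir / "completeness.tsv"
    report.completeness.to_csv(paths["completeness"], sep="\t", index=False)

    roc_rows = []
    for block in report.roc_blocks:
        if "error" in block:
            continue
        for marker, info in block["markers"].items():
            roc_rows.append({
                "stratum": block["stratum"], "marker": marker,
                "auc": f"{info['auc']:.2f}",
                "auc_ci95": f"{info['auc_ci95'][0]:.2f}–{info['auc_ci95'][1]:.2f}",
                "youden_threshold": f"{info['youden']['threshold']:.2f}",
                "sens_pct": fmt_pct(info["youden"]["sens"]),
                "spec_pct": fmt_pct(info["youden"]["spec"]),
            })
    paths["roc"] = outdir / "roc_summary.tsv"
    pd.DataFrame(roc_rows).to_csv(paths["roc"], sep="\t", index=False)

    paths["report"] = outdir / "report.json"
    paths["report"].write_text(report.to_json())
    return paths
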