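"""Model/results interface for the blood-culture prediction analysis.

:class:`BsiStudy` is the model object: it holds a cohort (read from CSV,
built from a DataFrame, or simulated) and the analysis configuration.
``fit()`` scores every record, evaluates the decision rules against the
culture reference and returns a :class:`BsiStudyResults` carrying the
metrics grid, ROC comparisons, Youden cut-offs, the Gram-agreement block
and a ``summary()`` table.

Example
-------
>>> from bsirisk import BsiStudy
>>> res = BsiStudy.simulated(seed=1).fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd

from .accuracy import CiConfig
from .cohort import CohortTable, read_cohort_csv
from .pipeline import (AnalysisReport, _metrics_table_formatted, fmt_pct,
                       render_tables, run_pipeline)
from .synth import GeneratorConfig, simulate_cohort

__all__ = ["BsiStudy", "BsiStudyResults"]


class BsiStudy:
    """Diagnostic-accuracy study of BSI prediction rules on one cohort."""

    def __init__(self, cohort: CohortTable, ci: CiConfig | None = None):
        self.cohort = cohort
        self.ci = ci or CiConfig()

    @classmethod
    def from_csv(cls, path, schema_config: dict | None = None,
                 ci: CiConfig | None = None) -> "BsiStudy":
        return cls(read_cohort_csv(path, schema_config), ci=ci)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, ci: CiConfig | None = None) -> "BsiStudy":
        """Build a study from a DataFrame in the canonical cohort schema."""
        import io

        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        return cls(read_cohort_csv(buf), ci=ci)

    @classmethod
    def simulated(cls, config: GeneratorConfig | None = None,
                  seed: Optional[int] = None, ci: CiConfig | None = None) -> "BsiStudy":
        return cls(simulate_cohort(config, seed=seed), ci=ci)

    def fit(self) -> "BsiStudyResults":
        report = run_pipeline(self.cohort, ci=self.ci)
        return BsiStudyResults(self, report)


class BsiStudyResults:
    """Fitted study: diagnostic metrics, ROC comparisons and agreement."""

    def __init__(self, model: BsiStudy, report: AnalysisReport):
        self.model = model
        self.report = report

    @property
    def metrics_grid(self) -> pd.DataFrame:
        return self.report.metrics

    @property
    def roc_blocks(self) -> list[dict]:
        return self.report.roc_blocks

    @property
    def gram_block(self) -> dict:
        return self.report.gram_block

    def auc(self, marker: str, stratum: str = "all") -> float:
        for block in self.report.roc_blocks:
            if block["stratum"] == stratum and "markers" in block:
                return block["markers"][marker]["auc"]
        raise KeyError(f"no ROC block for stratum {stratum!r}")

    def save(self, outdir) -> dict[str, Path]:
        return render_tables(self.report, outdir)

    def summary(self) -> str:
        """Human-readable report: accuracy grid, AUCs, agreement."""
        lines = []
        n = len(self.model.cohort)
        n_pos = self.model.cohort.n_positive
        lines.append("Blood-stream-infection prediction study")
        lines.append("=" * 72)
        lines.append(f"Events: {n}   culture-positive: {n_pos} ({fmt_pct(n_pos / n)}%)")
        lines.append("")
        lines.append("Diagnostic accuracy (per rule and stratum)")
        lines.append("-" * 72)
        lines.append(_metrics_table_formatted(self.report.metrics).to_string(index=False))
        lines.append("")
        lines.append("ROC analysis")
        lines.append("-" * 72)
        for block in self.report.roc_blocks:
            if "error" in block:
                lines.append(f"{block['stratum']}: {block['error']}")
                continue
            lines.append(f"stratum {block['stratum']} (n={block['n']}, "
                         f"positives={block['n_pos']}):")
            for marker, info in block["markers"].items():
                lo, hi = info["auc_ci95"]
                y = info["youden"]
                lines.append(
                    f"  {marker:9s} AUC {info['auc']:.2f} ({lo:.2f}–{hi:.2f})  "
                    f"Youden cut-off {y['orientation']}{y['threshold']:.2f} "
                    f"sens {fmt_pct(y['sens'])}% spec {fmt_pct(y['spec'])}%")
            for c in block["comparisons"]:
                lines.append(f"  DeLong {c['a']} vs {c['b']}: "
                             f"dAUC {c['diff']:+.3f}, p = {c['p']:.3f}")
        lines.append("")
        lines.append("Rule agreement among culture positives")
        lines.append("-" * 72)
        venn = self.report.gram_block["venn"]
        lines.append(f"both rules: {venn['both']}   only NLCR>12: {venn['only_nlcr']}   "
                     f"only MSS>=3: {venn['only_mss']}   neither: {venn['neither']}")
        if "fisher_p" in self.report.gram_block:
            gt = self.report.gram_block["gram_table"]
            lines.append(f"Gram-negative/positive isolates — only NLCR: "
                         f"{gt['only_nlcr'][0]}/{gt['only_nlcr'][1]}, only MSS: "
                         f"{gt['only_mss'][0]}/{gt['only_mss'][1]} "
                         f"(Fisher p = {self.report.gram_block['fisher_p']:.3f})")
        elif self.report.gram_block.get("message"):
            lines.append(self.report.gram_block["message"])
        return "\n".join(lines)
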