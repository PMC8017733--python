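"""Bedside prediction scores for blood-stream infection.

Implements, per patient record:

* **Modified Shapiro score (MSS)** — the Shapiro blood-culture decision rule
  with the band-cell criterion removed (band percentages are not routinely
  measured in many laboratories). Majors: suspected endocarditis (2 p),
  temperature > 39.4 °C (3 p), indwelling vascular catheter (3 p). Minors
  (1 p each): age > 65 y, temperature 38.3–39.3 °C, chills, systolic BP
  < 90 mmHg, WBC > 18 ×10⁹/L, platelets < 150 ×10⁹/L, creatinine
  > 176.8 µmol/L (2 mg/dL). Maximum total 14.
* **NLCR** — neutrophil-to-lymphocyte count ratio, a stress-response marker.
* **SIRS** (Sepsis-2): temperature > 38 or < 36 °C; heart rate > 90; respiratory
  rate > 20; WBC > 12 or < 4 ×10⁹/L. Fulfilled when >= 2 criteria hold.
* **qSOFA**: respiratory rate >= 22, systolic BP <= 100, altered mentation.
* **Sepsis-3 flag**: acute SOFA increase >= 2 points over baseline.

Missing-data contract: a score is the total over the components that are
evaluable (a missing component contributes 0) and a completeness flag records
whether every component could be evaluated. NLCR and the Sepsis-3 flag are
missing when their inputs are.

The temperature band (39.3, 39.4] °C is unassigned in the original score
table; it is scored here as minor (1 point) for continuity of risk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .cohort import CohortTable, PatientRecord

__all__ = [
    "ScorePanel",
    "MSS_MAX_POINTS",
    "mss_components",
    "compute_mss",
    "mss_rule_advises_culture",
    "compute_nlcr",
    "compute_sirs",
    "compute_qsofa",
    "compute_sepsis3",
    "score_cohort",
]

logger = logging.getLogger(__name__)

#: endocarditis 2 + catheter 3 + temperature major 3 + six remaining minors
MSS_MAX_POINTS = 14

CREATININE_THRESHOLD_UMOLL = 176.8  # 2 mg/dL x 88.4
WBC_THRESHOLD = 18.0                # 18,000 cells/mm^3 = 18 x 10^9/L
PLATELET_THRESHOLD = 150.0          # 150,000 cells/mm^3 = 150 x 10^9/L


@dataclass(frozen=True)
class ScorePanel:
    """Derived per-patient scores, aligned with one :class:`PatientRecord`."""

    event_id: str
    mss_points: int
    mss_complete: bool
    mss_rule: Optional[bool]      # original decision rule: 1 major or >=2 minors
    nlcr: Optional[float]
    sirs_count: int
    sirs_fulfilled: bool
    qsofa: int
    sepsis3: Optional[bool]


def mss_components(record: PatientRecord) -> list[tuple[str, str, int, Optional[bool]]]:
    """Evaluate the nine MSS criteria on a record.

    Returns ``(name, kind, points, satisfied)`` per criterion with
    ``satisfied`` None when the component cannot be evaluated. Temperature
    yields two mutually exclusive entries (major / minor band).
    """
    t = record.temperature
    temp_major = None if t is None else t > 39.4
    # minor band 38.3-39.3 extended through the unassigned gap up to 39.4
    temp_minor = None if t is None else (38.3 <= t <= 39.4)

    def gt(value, threshold):
        return None if value is None else value > threshold

    def lt(value, threshold):
        return None if value is None else value < threshold

    return [
        ("suspected_endocarditis", "major", 2, record.suspected_endocarditis),
        ("temperature_major", "major", 3, temp_major),
        ("indwelling_vascular_catheter", "major", 3, record.indwelling_vascular_catheter),
        ("age_over_65", "minor", 1, gt(record.age, 65)),
        ("temperature_minor", "minor", 1, temp_minor),
        ("chills", "minor", 1, record.chills),
        ("hypotension", "minor", 1, lt(record.systolic_bp, 90)),
        ("wbc_high", "minor", 1, gt(record.wbc, WBC_THRESHOLD)),
        ("platelets_low", "minor", 1, lt(record.platelets, PLATELET_THRESHOLD)),
        ("creatinine_high", "minor", 1, gt(record.creatinine, CREATININE_THRESHOLD_UMOLL)),
    ]


def compute_mss(record: PatientRecord) -> tuple[int, bool]:
    """Modified Shapiro score: (points, complete_flag).

    Missing components contribute 0 points and clear the completeness flag,
    mirroring pragmatic scoring on available data. Temperature contributes at
    most one of the major (3 p) / minor (1 p) entries.
    """
    points = 0
    complete = True
    for _, _, pts, satisfied in mss_components(record):
        if satisfied is None:
            complete = False
        elif satisfied:
            points += pts
    return points, complete


def mss_rule_advises_culture(record: PatientRecord) -> Optional[bool]:
    """Original Shapiro decision rule: one major criterion or >= 2 minors.

    Returns None when no evaluable component fires and at least one component
    is missing (the rule could still go either way).
    """
    comps = mss_components(record)
    majors = sum(1 for _, kind, _, s in comps if kind == "major" and s)
    minors = sum(1 for _, kind, _, s in comps if kind == "minor" and s)
    advised = majors >= 1 or minors >= 2
    if advised:
        return True
    if any(s is None for _, _, _, s in comps):
        return None
    return False


def compute_nlcr(record: PatientRecord) -> Optional[float]:
    """Neutrophil-to-lymphocyte count ratio; None when not computable."""
    n, l = record.neutrophils, record.lymphocytes
    if n is None or l is None or l <= 0:
        return None
    return n / l


def compute_sirs(record: PatientRecord) -> tuple[int, bool]:
    """SIRS criteria count (0-4) and the fulfilled flag (count >= 2)."""
    count = 0
    t = record.temperature
    if t is not None and (t > 38.0 or t < 36.0):
        count += 1
    if record.heart_rate is not None and record.heart_rate > 90:
        count += 1
    if record.respiratory_rate is not None and record.respiratory_rate > 20:
        count += 1
    if record.wbc is not None and (record.wbc > 12.0 or record.wbc < 4.0):
        count += 1
    return count, count >= 2


def compute_qsofa(record: PatientRecord) -> int:
    """qSOFA count 0-3 (RR >= 22, SBP <= 100, altered mentation)."""
    count = 0
    if record.respiratory_rate is not None and record.respiratory_rate >= 22:
        count += 1
    if record.systolic_bp is not None and record.systolic_bp <= 100:
        count += 1
    if record.altered_mentation:
        count += 1
    return count


def compute_sepsis3(record: PatientRecord) -> Optional[bool]:
    """Sepsis-3 organ-dysfunction flag: SOFA rise >= 2 over baseline."""
    if record.sofa_baseline is None or record.sofa_admission is None:
        return None
    return record.sofa_admission - record.sofa_baseline >= 2


def score_cohort(cohort: CohortTable) -> list[ScorePanel]:
    """Score every record, preserving cohort order."""
    panels = []
    for r in cohort:
        points, complete = compute_mss(r)
        nlcr = compute_nlcr(r)
        sirs_count, sirs_ok = compute_sirs(r)
        panels.append(
            ScorePanel(
                event_id=r.event_id,
                mss_points=points,
                mss_complete=complete,
                mss_rule=mss_rule_advises_culture(r),
                nlcr=nlcr,
                sirs_count=sirs_count,
                sirs_fulfilled=sirs_ok,
                qsofa=compute_qsofa(r),
                sepsis3=compute_sepsis3(r),
            )
        )
    if panels:
        logger.info(
            "scored %d records: MSS>=2 %d, MSS>=3 %d, NLCR>12 %d, Sepsis-3 %d",
            len(panels),
            sum(p.mss_points >= 2 for p in panels),
            sum(p.mss_points >= 3 for p in panels),
            sum(p.nlcr is not None and p.nlcr > 12 for p in panels),
            sum(bool(p.sepsis3) for p in panels),
        )
    return panels
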