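"""CP 1: diabetes detection from labs, codes and prescriptions, then type-1
exclusion rules; remaining detected cases are labeled type 2.

Rule summary (all record lookups restricted to a closed two-calendar-year
window ending with the prevalence year):

* diabetes if abnormal glycemic labs on >=2 distinct dates (pooled across
  HbA1c >= 6.5 %, fasting glucose >= 126 mg/dL, random glucose >= 200 mg/dL),
  or qualifying diagnosis codes (ICD-9 250.x; ICD-10 E10.x/E11.x/E14.x) on
  >=2 distinct dates, or >=1 insulin prescription dated outside every
  pregnancy interval, or >=1 prescription from the non-insulin medication
  list;
* among detected cases, type 1 if C-peptide < 0.8 ng/mL, a positive diabetes
  autoantibody, a urine-acetone-test-strip prescription, or a T1D:T2D code
  ratio > 0.5 combined with either a glucagon prescription or the absence of
  any listed non-insulin medication;
* type 2 otherwise.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import pandas as pd

from phenoequiv.datamodel import (
    DateWindow,
    EhrBundle,
    PatientView,
    code_matches_any,
    iter_patient_views,
)

__all__ = [
    "CP1_NONINSULIN_MEDICATIONS",
    "Cp1Criteria",
    "classify_cp1",
    "cp1_window",
    "detect_diabetes_cp1",
    "detect_t1d_cp1",
]

#: the 29 non-insulin antidiabetic ingredients accepted as direct evidence
#: of diabetes (and whose absence feeds the never-prescribed T1D clause)
CP1_NONINSULIN_MEDICATIONS = frozenset(
    {
        "albiglutide", "alogliptin", "chlorpropamide", "dulaglutide",
        "ertugliflozin", "exenatide", "glimepiride", "glipizide", "glyburide",
        "liraglutide", "lixisenatide", "pramlintide", "rosiglitazone",
        "semaglutide", "sitagliptin", "tolazamide", "tolbutamide", "acarbose",
        "canagliflozin", "dapagliflozin", "empagliflozin", "gliclazide",
        "linagliptin", "miglitol", "nateglinide", "pioglitazone",
        "repaglinide", "saxagliptin", "tirzepatide",
    }
)


@dataclass(frozen=True)
class Cp1Criteria:
    """Every threshold, code pattern and medication list used by CP 1."""

    hba1c_threshold: float = 6.5
    fasting_glucose_threshold: float = 126.0
    random_glucose_threshold: float = 200.0
    min_occasions: int = 2
    occasion_window_years: int = 2
    dx_patterns_icd9: tuple[str, ...] = ("250.x",)
    dx_patterns_icd10: tuple[str, ...] = ("E10.x", "E11.x", "E14.x")
    noninsulin_medications: frozenset[str] = CP1_NONINSULIN_MEDICATIONS
    c_peptide_t1d_threshold: float = 0.8
    t1d_ratio_threshold: float = 0.5
    # pooled: any mix of abnormal HbA1c / fasting / random glucose counts
    # toward the 2-occasion requirement; per-criterion counting is the
    # alternative reading of the rule layout
    pooled_lab_occasions: bool = True
    t1d_code_patterns: tuple[str, ...] = field(default=("E10.x", "250.x1", "250.x3"))
    t2d_code_patterns: tuple[str, ...] = field(default=("E11.x", "250.x0", "250.x2"))

    def __post_init__(self) -> None:
        for name in ("hba1c_threshold", "fasting_glucose_threshold",
                     "random_glucose_threshold", "c_peptide_t1d_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        assert len(self.noninsulin_medications) == 29
        assert all(m == m.lower() for m in self.noninsulin_medications)


def cp1_window(prevalence_year: int) -> DateWindow:
    """Two calendar years: [Jan 1 of year-1, Dec 31 of year]."""
    return DateWindow(dt.date(prevalence_year - 1, 1, 1), dt.date(prevalence_year, 12, 31))


def _abnormal(lab, criteria: Cp1Criteria) -> bool:
    if lab.analyte == "hba1c":
        return float(lab.value) >= criteria.hba1c_threshold
    if lab.analyte == "fasting_glucose":
        return float(lab.value) >= criteria.fasting_glucose_threshold
    if lab.analyte == "random_glucose":
        return float(lab.value) >= criteria.random_glucose_threshold
    return False


def detect_diabetes_cp1(
    view: PatientView, window: DateWindow, criteria: Cp1Criteria = Cp1Criteria()
) -> tuple[bool, list[str]]:
    """Return (detected, evidence) for the CP 1 diabetes definition.

    Evidence entries name each satisfied clause with its triggering dates.
    """
    evidence: list[str] = []

    if criteria.pooled_lab_occasions:
        dates = {l.date for l in view.labs if window.contains(l.date) and _abnormal(l, criteria)}
        if len(dates) >= criteria.min_occasions:
            evidence.append(f"abnormal_labs_{criteria.min_occasions}_occasions:"
                            + ",".join(d.isoformat() for d in sorted(dates)))
    else:
        for analyte in ("hba1c", "fasting_glucose", "random_glucose"):
            dates = {
                l.date for l in view.labs
                if l.analyte == analyte and window.contains(l.date) and _abnormal(l, criteria)
            }
            if len(dates) >= criteria.min_occasions:
                evidence.append(f"abnormal_{analyte}_{criteria.min_occasions}_occasions:"
                                + ",".join(d.isoformat() for d in sorted(dates)))

    patterns = criteria.dx_patterns_icd9 + criteria.dx_patterns_icd10
    dx_dates = {
        d.date for d in view.diagnoses
        if window.contains(d.date) and code_matches_any(d.code, patterns)
    }
    if len(dx_dates) >= criteria.min_occasions:
        evidence.append(f"diabetes_codes_{criteria.min_occasions}_occasions:"
                        + ",".join(d.isoformat() for d in sorted(dx_dates)))

    insulin_dates = [
        m.date for m in view.medications
        if m.ingredient == "insulin" and m.event_type == "prescribed"
        and window.contains(m.date) and not view.in_pregnancy(m.date)
    ]
    if insulin_dates:
        evidence.append("insulin_outside_pregnancy:"
                        + ",".join(d.isoformat() for d in sorted(insulin_dates)))

    other = [
        m for m in view.medications
        if m.ingredient in criteria.noninsulin_medications
        and m.event_type == "prescribed" and window.contains(m.date)
    ]
    if other:
        evidence.append("noninsulin_medication:"
                        + ",".join(f"{m.ingredient}@{m.date.isoformat()}" for m in sorted(other)))

    return bool(evidence), evidence


def _t1d_t2d_ratio_exceeds(view: PatientView, window: DateWindow,
                           criteria: Cp1Criteria) -> bool:
    """T1D:T2D code-count ratio > threshold; infinite ratio (zero T2D-type
    codes, >=1 T1D-type) counts as exceeding; zero of both types fails."""
    n_t1 = n_t2 = 0
    for d in view.diagnoses:
        if not window.contains(d.date):
            continue
        if code_matches_any(d.code, criteria.t1d_code_patterns):
            n_t1 += 1
        elif code_matches_any(d.code, criteria.t2d_code_patterns):
            n_t2 += 1
    if n_t1 == 0:
        return False
    if n_t2 == 0:
        return True
    return n_t1 / n_t2 > criteria.t1d_ratio_threshold


def detect_t1d_cp1(
    view: PatientView, window: DateWindow, criteria: Cp1Criteria = Cp1Criteria()
) -> tuple[bool, list[str]]:
    """Type-1 exclusion rules, applied to patients already detected as diabetic."""
    evidence: list[str] = []

    for l in view.labs:
        if not window.contains(l.date):
            continue
        if l.analyte == "c_peptide" and float(l.value) < criteria.c_peptide_t1d_threshold:
            evidence.append(f"c_peptide_below_{criteria.c_peptide_t1d_threshold}:"
                            f"{l.value}@{l.date.isoformat()}")
        elif l.analyte == "diabetes_autoantibody" and l.value == "positive":
            evidence.append(f"autoantibody_positive:{l.date.isoformat()}")

    def _rx(ingredient: str) -> list:
        return [m for m in view.medications
                if m.ingredient == ingredient and m.event_type == "prescribed"
                and window.contains(m.date)]

    if _rx("urine acetone test strips"):
        evidence.append("urine_acetone_test_strips")

    ratio_high = _t1d_t2d_ratio_exceeds(view, window, criteria)
    if ratio_high and _rx("glucagon"):
        evidence.append("ratio_gt_threshold_and_glucagon")
    never_oral = not any(
        m.ingredient in criteria.noninsulin_medications
        and m.event_type == "prescribed" and window.contains(m.date)
        for m in view.medications
    )
    if ratio_high and never_oral:
        evidence.append("ratio_gt_threshold_and_never_oral_hypoglycemics")

    return bool(evidence), evidence


def classify_patient_cp1(
    view: PatientView, window: DateWindow, criteria: Cp1Criteria = Cp1Criteria()
) -> tuple[str, list[str]]:
    """Label one patient: T2D iff diabetes detected and not T1D."""
    detected, evidence = detect_diabetes_cp1(view, window, criteria)
    if not detected:
        return "none", []
    t1d, t1d_evidence = detect_t1d_cp1(view, window, criteria)
    if t1d:
        return "T1D", evidence + t1d_evidence
    return "T2D", evidence


def classify_cp1(
    bundle: EhrBundle, prevalence_year: int, criteria: Cp1Criteria = Cp1Criteria()
) -> pd.DataFrame:
    """Label every patient in the bundle; returns patient_id, label, evidence."""
    window = cp1_window(prevalence_year)
    rows = []
    for view in iter_patient_views(bundle):
        label, evidence = classify_patient_cp1(view, window, criteria)
        rows.append({"patient_id": view.patient_id, "label": label,
                     "evidence": ";".join(evidence)})
    return pd.DataFrame(rows, columns=["patient_id", "label", "evidence"])
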