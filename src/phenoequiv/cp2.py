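"""CP 2: wide-net candidate identification over a three-calendar-year
lookback, diabetes-case confirmation by diagnosis codes only, then type-2
classification from code counts (with the printed three-clause OR rule and
the narrative ratio-only rule as selectable modes).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import NamedTuple

import pandas as pd

from phenoequiv.datamodel import (
    DateWindow,
    EhrBundle,
    PatientView,
    code_matches_any,
    iter_patient_views,
)

__all__ = [
    "CP2_WIDENET_MEDICATIONS",
    "CodeCounts",
    "Cp2Criteria",
    "classify_cp2",
    "classify_t2d_cp2",
    "confirm_dm_cp2",
    "cp2_window",
    "wide_net_cp2",
]

#: the 16 wide-net medication entries (ingredient or drug-class names,
#: matched literally on the normalized ingredient string)
CP2_WIDENET_MEDICATIONS = frozenset(
    {
        "exenatide", "gliclazide", "glimepiride", "glipizide", "glyburide",
        "insulin", "meglitinide", "metformin", "nateglinide", "pioglitazone",
        "pramlintide", "repaglinide", "rosiglitazone", "sitagliptin",
        "sulfonylurea", "thiazolidinediones",
    }
)

T2D_RULE_MODES = ("or_printed", "ratio_only")


class CodeCounts(NamedTuple):
    """In-window diagnosis-code tallies for the type ratio."""

    t1d_codes: int
    dm_codes: int


@dataclass(frozen=True)
class Cp2Criteria:
    hba1c_threshold: float = 6.5
    fasting_glucose_threshold: float = 126.0
    random_glucose_threshold: float = 200.0
    widenet_medications: frozenset[str] = CP2_WIDENET_MEDICATIONS
    # codes-only confirmation step; E09.x is available via include_e09
    dm_dx_patterns: tuple[str, ...] = ("250.x0", "250.x2", "E08.x", "E10.x", "E11.x", "E13.x")
    include_e09: bool = False
    t1d_ratio_threshold: float = 0.5
    t2d_rule_mode: str = "or_printed"
    lookback_years: int = 3
    # ICD-9 type-1 fifth-digit codes join the ratio (numerator and
    # denominator) even though the confirmation pattern list omits them
    t1d_code_patterns: tuple[str, ...] = ("E10.x", "250.x1", "250.x3")

    def __post_init__(self) -> None:
        if self.t2d_rule_mode not in T2D_RULE_MODES:
            raise ValueError(f"unknown t2d_rule_mode {self.t2d_rule_mode!r}")
        assert all(m == m.lower() for m in self.widenet_medications)

    @property
    def effective_dm_patterns(self) -> tuple[str, ...]:
        return self.dm_dx_patterns + (("E09.x",) if self.include_e09 else ())


def cp2_window(prevalence_year: int, criteria: Cp2Criteria = Cp2Criteria()) -> DateWindow:
    """Three calendar years: [Jan 1 of year-2, Dec 31 of year]."""
    return DateWindow(
        dt.date(prevalence_year - criteria.lookback_years + 1, 1, 1),
        dt.date(prevalence_year, 12, 31),
    )


def wide_net_cp2(
    view: PatientView, window: DateWindow, criteria: Cp2Criteria = Cp2Criteria()
) -> bool:
    """Inclusive first pass: one abnormal lab, one diabetes-related code, or
    one diabetes-related medication event (prescribed, dispensed or
    administered) anywhere in the lookback window."""
    for l in view.labs:
        if not window.contains(l.date):
            continue
        if l.analyte == "hba1c" and float(l.value) >= criteria.hba1c_threshold:
            return True
        if l.analyte == "fasting_glucose" and float(l.value) >= criteria.fasting_glucose_threshold:
            return True
        if l.analyte == "random_glucose" and float(l.value) >= criteria.random_glucose_threshold:
            return True
    patterns = criteria.effective_dm_patterns
    for d in view.diagnoses:
        if window.contains(d.date) and code_matches_any(d.code, patterns):
            return True
    for m in view.medications:
        if window.contains(m.date) and m.ingredient in criteria.widenet_medications:
            return True
    return False


def confirm_dm_cp2(
    view: PatientView, window: DateWindow, criteria: Cp2Criteria = Cp2Criteria()
) -> tuple[bool, CodeCounts]:
    """Codes-only confirmation: >=1 in-window code matching the DM pattern
    list. Returns the type-1 and total DM code tallies for the ratio."""
    patterns = criteria.effective_dm_patterns
    n_t1 = n_dm = n_confirm = 0
    for d in view.diagnoses:
        if not window.contains(d.date):
            continue
        is_t1 = code_matches_any(d.code, criteria.t1d_code_patterns)
        is_dm = code_matches_any(d.code, patterns)
        if is_dm:
            n_confirm += 1
        if is_t1 or is_dm:
            n_dm += 1
        if is_t1:
            n_t1 += 1
    return n_confirm >= 1, CodeCounts(t1d_codes=n_t1, dm_codes=n_dm)


def classify_t2d_cp2(
    view: PatientView,
    window: DateWindow,
    counts: CodeCounts,
    criteria: Cp2Criteria = Cp2Criteria(),
    mode: str | None = None,
) -> bool:
    """Type-2 decision for a confirmed DM case.

    ``ratio_only``: T2D iff (T1D codes / DM codes) <= 0.5.
    ``or_printed``: T2D iff the ratio clause holds, OR there is an
    anti-diabetes medication besides insulin or metformin, OR there is no
    glucagon medication event in-window.
    """
    mode = mode or criteria.t2d_rule_mode
    if mode not in T2D_RULE_MODES:
        raise ValueError(f"unknown t2d_rule_mode {mode!r}")
    assert counts.dm_codes >= 1, "classify_t2d_cp2 requires a confirmed DM case"
    ratio_ok = counts.t1d_codes / counts.dm_codes <= criteria.t1d_ratio_threshold
    if mode == "ratio_only":
        return ratio_ok
    other_med = any(
        window.contains(m.date)
        and m.ingredient in criteria.widenet_medications
        and m.ingredient not in ("insulin", "metformin")
        for m in view.medications
    )
    glucagon = any(
        window.contains(m.date) and m.ingredient == "glucagon"
        for m in view.medications
    )
    return ratio_ok or other_med or not glucagon


def classify_patient_cp2(
    view: PatientView,
    window: DateWindow,
    criteria: Cp2Criteria = Cp2Criteria(),
    mode: str | None = None,
) -> tuple[str, list[str]]:
    if not wide_net_cp2(view, window, criteria):
        return "none", []
    confirmed, counts = confirm_dm_cp2(view, window, criteria)
    if not confirmed:
        return "none", ["wide_net_only"]
    evidence = [f"dm_codes:{counts.dm_codes}", f"t1d_codes:{counts.t1d_codes}"]
    if classify_t2d_cp2(view, window, counts, criteria, mode):
        return "T2D", evidence
    return "T1D", evidence


def classify_cp2(
    bundle: EhrBundle,
    prevalence_year: int,
    criteria: Cp2Criteria = Cp2Criteria(),
    mode: str | None = None,
) -> pd.DataFrame:
    """Label every patient in the bundle; returns patient_id, label, evidence."""
    window = cp2_window(prevalence_year, criteria)
    rows = []
    for view in iter_patient_views(bundle):
        label, evidence = classify_patient_cp2(view, window, criteria, mode)
        rows.append({"patient_id": view.patient_id, "label": label,
                     "evidence": ";".join(evidence)})
    return pd.DataFrame(rows, columns=["patient_id", "label", "evidence"])
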