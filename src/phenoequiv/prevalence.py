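"""Eligibility windows, demographic stratification, and numerator/denominator
prevalence tables for each computable phenotype.

Eligibility (both phenotypes restricted to ages 18-44, completed years on
December 31 of the prevalence year):

* CP 1 -- at least one encounter in the two calendar years ending with the
  prevalence year, at a system belonging to the two-system catchment;
* CP 2 -- at least one encounter in the three calendar years ending with the
  prevalence year, at any system (optionally two encounters, the narrative
  variant).
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from phenoequiv.datamodel import DateWindow, EhrBundle

__all__ = [
    "AGE_BANDS",
    "StratumCount",
    "age_group",
    "age_on",
    "eligible_patients",
    "prevalence_table",
    "round_half_up",
]

AGE_BANDS = (("18-24", 18, 24), ("25-34", 25, 34), ("35-44", 35, 44))
AGE_MIN, AGE_MAX = 18, 44

STRATUM_DIMENSIONS = ("age_group", "sex", "race_ethnicity")


@dataclass(frozen=True)
class StratumCount:
    dimension: str
    level: str
    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if not (0 <= self.numerator <= self.denominator) or self.denominator < 1:
            raise ValueError(f"invalid counts n={self.numerator}, N={self.denominator}")

    @property
    def prevalence_pct(self) -> float:
        return 100.0 * self.numerator / self.denominator

    @property
    def prevalence_display(self) -> float:
        return round_half_up(self.prevalence_pct, 1)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (2.25 -> 2.3; ties away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def age_on(birth_date: dt.date, ref: dt.date) -> int:
    """Completed years of age on the reference date."""
    years = ref.year - birth_date.year
    if (ref.month, ref.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def age_group(age: int) -> str | None:
    for name, lo, hi in AGE_BANDS:
        if lo <= age <= hi:
            return name
    return None


def eligible_patients(bundle: EhrBundle, cp: str, prevalence_year: int,
                      min_encounters: int = 1) -> set[str]:
    """Patient ids in the given phenotype's denominator."""
    if cp == "cp1":
        window = DateWindow(dt.date(prevalence_year - 1, 1, 1),
                            dt.date(prevalence_year, 12, 31))
        enc = bundle.encounters
        enc = enc[enc["system_id"].isin(bundle.cp1_systems)] if len(enc) else enc
    elif cp == "cp2":
        window = DateWindow(dt.date(prevalence_year - 2, 1, 1),
                            dt.date(prevalence_year, 12, 31))
        enc = bundle.encounters
    else:
        raise ValueError(f"unknown phenotype {cp!r} (expected 'cp1' or 'cp2')")

    ref = dt.date(prevalence_year, 12, 31)
    ages = bundle.patients["birth_date"].map(lambda b: age_on(b, ref))
    in_age = set(bundle.patients.loc[(ages >= AGE_MIN) & (ages <= AGE_MAX), "patient_id"])

    if not len(enc):
        return set()
    in_window = enc[[window.contains(d) for d in enc["date"]]]
    counts = in_window.groupby("patient_id").size()
    has_encounters = set(counts[counts >= min_encounters].index)
    return in_age & has_encounters


def _strata_frame(patients: pd.DataFrame, prevalence_year: int) -> pd.DataFrame:
    ref = dt.date(prevalence_year, 12, 31)
    out = patients[["patient_id", "sex", "race_ethnicity"]].copy()
    out["age_group"] = patients["birth_date"].map(
        lambda b: age_group(age_on(b, ref)) if pd.notna(b) else None
    )
    return out


def prevalence_table(
    labels: pd.DataFrame,
    eligible: set[str],
    patients: pd.DataFrame,
    prevalence_year: int,
    dimensions: tuple[str, ...] = STRATUM_DIMENSIONS,
) -> pd.DataFrame:
    """One row per stratum level per dimension plus overall.

    Columns: dimension, level, numerator, denominator, prevalence_pct
    (unrounded) and prevalence_display (half-up to one decimal).  Strata with
    an empty denominator are excluded with a warning.  ``labels`` must cover
    the eligible set.
    """
    missing = eligible - set(labels["patient_id"])
    if missing:
        raise ValueError(f"labels missing for {len(missing)} eligible patients")

    t2d = set(labels.loc[labels["label"] == "T2D", "patient_id"]) & eligible
    strata = _strata_frame(patients, prevalence_year)
    strata = strata[strata["patient_id"].isin(eligible)]

    rows: list[StratumCount] = []
    if len(strata) == 0:
        raise ValueError("empty denominator: no eligible patients")
    rows.append(StratumCount("overall", "overall", len(set(strata["patient_id"]) & t2d),
                             len(strata)))
    for dim in dimensions:
        with_value = strata[strata[dim].notna()]
        for level, grp in with_value.groupby(dim, sort=True):
            n = len(set(grp["patient_id"]) & t2d)
            rows.append(StratumCount(dim, str(level), n, len(grp)))
    known_levels = {
        "age_group": [b[0] for b in AGE_BANDS],
        "sex": ["female", "male"],
        "race_ethnicity": ["african_american", "asian", "hispanic", "white", "other"],
    }
    present = {(r.dimension, r.level) for r in rows}
    for dim in dimensions:
        for level in known_levels.get(dim, []):
            if (dim, level) not in present:
                warnings.warn(f"empty denominator for stratum ({dim}, {level}); excluded",
                              stacklevel=2)

    return pd.DataFrame(
        [
            {
                "dimension": r.dimension,
                "level": r.level,
                "numerator": r.numerator,
                "denominator": r.denominator,
                "prevalence_pct": r.prevalence_pct,
                "prevalence_display": r.prevalence_display,
            }
            for r in rows
        ]
    )
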