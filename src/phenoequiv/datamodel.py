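"""Patient-level EHR data model: tables, validation, CSV I/O, ICD code matching.

The unit of input for every downstream stage is an :class:`EhrBundle` holding
six pandas tables (patients, encounters, diagnoses, labs, medications,
pregnancies) plus the set of system ids that constitute CP 1's two-system
catchment.  All dates are ``datetime.date``; all diagnosis codes are stored
normalized (uppercase, dots and whitespace removed).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import pandas as pd

__all__ = [
    "BundleValidationError",
    "DateWindow",
    "DiagnosisRecord",
    "EhrBundle",
    "Encounter",
    "LabResult",
    "MedicationRecord",
    "Patient",
    "PatientView",
    "code_matches",
    "iter_patient_views",
    "load_bundle",
    "normalize_code",
    "validate_bundle",
    "write_bundle",
]

SEX_CATEGORIES = frozenset({"female", "male"})
RACE_CATEGORIES = frozenset({"african_american", "asian", "hispanic", "white", "other"})
ENCOUNTER_SETTINGS = frozenset({"inpatient", "outpatient", "emergency"})
DX_SETTINGS = frozenset({"inpatient", "outpatient"})
CODE_SYSTEMS = frozenset({"ICD9", "ICD10"})
NUMERIC_ANALYTES = frozenset({"hba1c", "fasting_glucose", "random_glucose", "c_peptide"})
QUALITATIVE_ANALYTES = frozenset({"diabetes_autoantibody"})
ANALYTES = NUMERIC_ANALYTES | QUALITATIVE_ANALYTES
MED_EVENT_TYPES = frozenset({"prescribed", "dispensed", "administered"})

#: column contracts for the on-disk CSV tables
TABLE_COLUMNS = {
    "patients": ["patient_id", "birth_date", "sex", "race_ethnicity"],
    "encounters": ["patient_id", "date", "system_id", "setting"],
    "diagnoses": ["patient_id", "date", "code_system", "code", "setting"],
    "labs": ["patient_id", "date", "analyte", "value", "units"],
    "medications": ["patient_id", "date", "ingredient", "event_type"],
    "pregnancies": ["patient_id", "start_date", "end_date"],
}

_CODE_RE = re.compile(r"^[A-Z0-9]+$")


class BundleValidationError(ValueError):
    """A table violates the documented column/row contract."""


class DateWindow(NamedTuple):
    """Closed calendar-date interval [start, end]."""

    start: dt.date
    end: dt.date

    def contains(self, d: dt.date) -> bool:
        return self.start <= d <= self.end


# ---------------------------------------------------------------------------
# record dataclasses (row contracts; convenient for building test bundles)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Patient:
    patient_id: str
    birth_date: dt.date
    sex: str
    race_ethnicity: str
    pregnancy_intervals: tuple[tuple[dt.date, dt.date], ...] = ()


@dataclass(frozen=True)
class Encounter:
    patient_id: str
    date: dt.date
    system_id: str
    setting: str = "outpatient"


@dataclass(frozen=True)
class DiagnosisRecord:
    patient_id: str
    date: dt.date
    code_system: str
    code: str
    setting: str = "outpatient"


@dataclass(frozen=True)
class LabResult:
    patient_id: str
    date: dt.date
    analyte: str
    value: float | str
    units: str = ""


@dataclass(frozen=True)
class MedicationRecord:
    patient_id: str
    date: dt.date
    ingredient: str
    event_type: str = "prescribed"


# ---------------------------------------------------------------------------
# code normalization and pattern matching
# ---------------------------------------------------------------------------


def normalize_code(raw: str) -> str:
    """Normalize an ICD code: strip whitespace and dots, uppercase.

    >>> normalize_code("E11.9")
    'E119'
    >>> normalize_code(" e10.65 ")
    'E1065'
    """
    if not isinstance(raw, str):
        raise ValueError(f"code must be a string, got {type(raw).__name__}")
    code = re.sub(r"\s+", "", raw).replace(".", "").upper()
    if not code:
        raise ValueError("empty diagnosis code")
    if not _CODE_RE.match(code):
        raise ValueError(f"malformed diagnosis code {raw!r}")
    return code


def code_matches(code: str, pattern: str) -> bool:
    """Match a normalized code against a textbox-style ICD pattern.

    Two pattern styles are supported:

    * open-extension patterns ending in ``.x`` -- ``"E11.x"`` matches ``E11``
      and any extension (``E119``, ``E1165``);
    * fixed-length wildcard patterns with ``x`` before literal characters --
      ``"250.x0"`` matches exactly five characters with any fourth character
      and a literal fifth (``25000``, ``25090``; not ``25001`` or ``250``).
    """
    pat = pattern.strip().upper()
    if pat.endswith(".X"):
        prefix = pat[:-2].replace(".", "")
        if not prefix or not _CODE_RE.match(prefix) or "X" in prefix:
            raise ValueError(f"invalid code pattern {pattern!r}")
        return code.startswith(prefix)
    body = pat.replace(".", "")
    if not body or not _CODE_RE.match(body):
        raise ValueError(f"invalid code pattern {pattern!r}")
    if len(code) != len(body):
        return False
    return all(pc == "X" or pc == cc for pc, cc in zip(body, code))


def code_matches_any(code: str, patterns: Iterable[str]) -> bool:
    return any(code_matches(code, p) for p in patterns)


# ---------------------------------------------------------------------------
# bundle
# ---------------------------------------------------------------------------


@dataclass
class EhrBundle:
    """The six patient-level tables plus CP 1 catchment metadata."""

    patients: pd.DataFrame
    encounters: pd.DataFrame
    diagnoses: pd.DataFrame
    labs: pd.DataFrame
    medications: pd.DataFrame
    pregnancies: pd.DataFrame
    cp1_systems: frozenset[str] = field(default_factory=frozenset)

    @classmethod
    def from_records(
        cls,
        patients: Sequence[Patient] = (),
        encounters: Sequence[Encounter] = (),
        diagnoses: Sequence[DiagnosisRecord] = (),
        labs: Sequence[LabResult] = (),
        medications: Sequence[MedicationRecord] = (),
        cp1_systems: Iterable[str] = (),
        validate: bool = True,
    ) -> "EhrBundle":
        """Build a bundle from record dataclasses (codes are normalized here)."""
        pregnancy_rows = []
        patient_rows = []
        for p in patients:
            patient_rows.append(
                {"patient_id": p.patient_id, "birth_date": p.birth_date,
                 "sex": p.sex, "race_ethnicity": p.race_ethnicity}
            )
            for start, end in p.pregnancy_intervals:
                pregnancy_rows.append(
                    {"patient_id": p.patient_id, "start_date": start, "end_date": end}
                )
        dx_rows = [dataclasses.asdict(d) for d in diagnoses]
        for row in dx_rows:
            row["code"] = normalize_code(row["code"])
        bundle = cls(
            patients=_frame(patient_rows, "patients"),
            encounters=_frame([dataclasses.asdict(e) for e in encounters], "encounters"),
            diagnoses=_frame(dx_rows, "diagnoses"),
            labs=_frame([dataclasses.asdict(x) for x in labs], "labs"),
            medications=_frame([dataclasses.asdict(m) for m in medications], "medications"),
            pregnancies=_frame(pregnancy_rows, "pregnancies"),
            cp1_systems=frozenset(cp1_systems),
        )
        if validate:
            validate_bundle(bundle)
        return bundle

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def row_counts(self) -> dict[str, int]:
        return {name: len(self.table(name)) for name in TABLE_COLUMNS}

    def equals(self, other: "EhrBundle") -> bool:
        """Field-for-field equality (row order within each table matters)."""
        if self.cp1_systems != other.cp1_systems:
            return False
        return all(
            self.table(n).reset_index(drop=True).equals(other.table(n).reset_index(drop=True))
            for n in TABLE_COLUMNS
        )


def _frame(rows: list[dict], name: str) -> pd.DataFrame:
    cols = TABLE_COLUMNS[name]
    if not rows:
        return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
    df = pd.DataFrame(rows)[cols]
    if "value" in cols:  # labs hold mixed numeric/qualitative values
        df["value"] = df["value"].astype(object)
    return df


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _check_category(df: pd.DataFrame, table: str, col: str, allowed: frozenset[str]) -> None:
    bad = ~df[col].isin(allowed)
    if bad.any():
        i = int(bad.idxmax())
        raise BundleValidationError(
            f"{table} row {i}: invalid {col} {df[col].iloc[i]!r} (allowed: {sorted(allowed)})"
        )


def _check_fk(df: pd.DataFrame, table: str, known_ids: set[str]) -> None:
    bad = ~df["patient_id"].isin(known_ids)
    if bad.any():
        i = int(bad.idxmax())
        raise BundleValidationError(
            f"{table} row {i}: unknown patient_id {df['patient_id'].iloc[i]!r}"
        )


def validate_bundle(bundle: EhrBundle) -> None:
    """Raise :class:`BundleValidationError` on the first contract violation."""
    pat = bundle.patients
    if pat["patient_id"].duplicated().any():
        dup = pat["patient_id"][pat["patient_id"].duplicated()].iloc[0]
        raise BundleValidationError(f"patients: duplicate patient_id {dup!r}")
    _check_category(pat, "patients", "sex", SEX_CATEGORIES)
    _check_category(pat, "patients", "race_ethnicity", RACE_CATEGORIES)

    known = set(pat["patient_id"])
    for name in ("encounters", "diagnoses", "labs", "medications", "pregnancies"):
        _check_fk(bundle.table(name), name, known)

    _check_category(bundle.encounters, "encounters", "setting", ENCOUNTER_SETTINGS)
    _check_category(bundle.diagnoses, "diagnoses", "setting", DX_SETTINGS)
    _check_category(bundle.diagnoses, "diagnoses", "code_system", CODE_SYSTEMS)
    for i, code in enumerate(bundle.diagnoses["code"]):
        if not isinstance(code, str) or not _CODE_RE.match(code):
            raise BundleValidationError(f"diagnoses row {i}: malformed code {code!r}")

    _check_category(bundle.labs, "labs", "analyte", ANALYTES)
    for i, (analyte, value) in enumerate(zip(bundle.labs["analyte"], bundle.labs["value"])):
        if analyte in QUALITATIVE_ANALYTES:
            if value not in ("positive", "negative"):
                raise BundleValidationError(
                    f"labs row {i}: {analyte} requires a qualitative value, got {value!r}"
                )
        else:
            try:
                v = float(value)
            except (TypeError, ValueError):
                raise BundleValidationError(
                    f"labs row {i}: {analyte} requires a numeric value, got {value!r}"
                ) from None
            if v < 0:
                raise BundleValidationError(f"labs row {i}: negative value {v}")

    _check_category(bundle.medications, "medications", "event_type", MED_EVENT_TYPES)
    for i, ing in enumerate(bundle.medications["ingredient"]):
        if not isinstance(ing, str) or not ing or ing != ing.strip().lower():
            raise BundleValidationError(
                f"medications row {i}: ingredient must be non-empty lowercase, got {ing!r}"
            )

    # pregnancy intervals: start <= end, pairwise non-overlapping per patient
    preg = bundle.pregnancies
    for i, (s, e) in enumerate(zip(preg["start_date"], preg["end_date"])):
        if s > e:
            raise BundleValidationError(f"pregnancies row {i}: start_date after end_date")
    for pid, grp in preg.groupby("patient_id"):
        ivals = sorted(zip(grp["start_date"], grp["end_date"]))
        for (s1, e1), (s2, _) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                raise BundleValidationError(
                    f"pregnancies: overlapping intervals for patient {pid!r}"
                )

    observed = set(bundle.encounters["system_id"])
    extra = set(bundle.cp1_systems) - observed
    if extra:
        raise BundleValidationError(
            f"cp1_systems {sorted(extra)} never appear as encounter system_id"
        )


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

_DATE_COLUMNS = {
    "patients": ["birth_date"],
    "encounters": ["date"],
    "diagnoses": ["date"],
    "labs": ["date"],
    "medications": ["date"],
    "pregnancies": ["start_date", "end_date"],
}

_META_FILE = "bundle_meta.json"


def _parse_dates(df: pd.DataFrame, table: str) -> pd.DataFrame:
    for col in _DATE_COLUMNS[table]:
        parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            i = int(bad.idxmax())
            raise BundleValidationError(
                f"{table} row {i}: malformed date {df[col].iloc[i]!r} in column {col}"
            )
        if parsed.isna().any():
            i = int(parsed.isna().idxmax())
            raise BundleValidationError(f"{table} row {i}: missing date in column {col}")
        df[col] = parsed.dt.date
    return df


def load_bundle(directory: str | Path, validate: bool = True) -> EhrBundle:
    """Load the six CSV tables (plus catchment metadata) from *directory*.

    Raises a descriptive :class:`BundleValidationError` naming the table and
    row on any contract violation (missing file, unknown column, malformed
    date, unresolvable foreign key, bad category value).
    """
    directory = Path(directory)
    tables: dict[str, pd.DataFrame] = {}
    for name, cols in TABLE_COLUMNS.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            raise BundleValidationError(f"missing table file: {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
        if list(df.columns) != cols:
            raise BundleValidationError(
                f"{name}: columns {list(df.columns)} do not match contract {cols}"
            )
        df = _parse_dates(df, name)
        tables[name] = df
    labs = tables["labs"]
    if len(labs):
        numeric = labs["analyte"].isin(NUMERIC_ANALYTES)
        labs["value"] = labs["value"].astype(object)
        labs.loc[numeric, "value"] = [float(v) for v in labs.loc[numeric, "value"]]
        labs["units"] = labs["units"].fillna("")
    if len(tables["diagnoses"]):
        tables["diagnoses"]["code"] = [normalize_code(c) for c in tables["diagnoses"]["code"]]
    meta_path = directory / _META_FILE
    cp1_systems: frozenset[str] = frozenset()
    if meta_path.exists():
        cp1_systems = frozenset(json.loads(meta_path.read_text())["cp1_systems"])
    bundle = EhrBundle(cp1_systems=cp1_systems, **tables)
    if validate:
        validate_bundle(bundle)
    return bundle


def write_bundle(bundle: EhrBundle, directory: str | Path) -> Path:
    """Write the bundle as six CSV tables plus ``bundle_meta.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in TABLE_COLUMNS:
        df = bundle.table(name).copy()
        for col in _DATE_COLUMNS[name]:
            df[col] = [d.isoformat() for d in df[col]]
        df.to_csv(directory / f"{name}.csv", index=False)
    (directory / _META_FILE).write_text(
        json.dumps({"cp1_systems": sorted(bundle.cp1_systems)}, indent=1) + "\n"
    )
    return directory


# ---------------------------------------------------------------------------
# per-patient views (the unit both phenotype modules consume)
# ---------------------------------------------------------------------------


class LabRec(NamedTuple):
    date: dt.date
    analyte: str
    value: float | str


class DxRec(NamedTuple):
    date: dt.date
    code_system: str
    code: str


class MedRec(NamedTuple):
    date: dt.date
    ingredient: str
    event_type: str


@dataclass
class PatientView:
    """All records for one patient, as consumed by the phenotype rules."""

    patient_id: str
    birth_date: dt.date | None = None
    sex: str | None = None
    race_ethnicity: str | None = None
    labs: list[LabRec] = field(default_factory=list)
    diagnoses: list[DxRec] = field(default_factory=list)
    medications: list[MedRec] = field(default_factory=list)
    pregnancies: list[tuple[dt.date, dt.date]] = field(default_factory=list)

    def in_pregnancy(self, d: dt.date) -> bool:
        return any(s <= d <= e for s, e in self.pregnancies)


def iter_patient_views(bundle: EhrBundle) -> Iterator[PatientView]:
    """Yield one :class:`PatientView` per patient, in patients-table order."""
    labs: dict[str, list[LabRec]] = defaultdict(list)
    for r in bundle.labs.itertuples(index=False):
        labs[r.patient_id].append(LabRec(r.date, r.analyte, r.value))
    dxs: dict[str, list[DxRec]] = defaultdict(list)
    for r in bundle.diagnoses.itertuples(index=False):
        dxs[r.patient_id].append(DxRec(r.date, r.code_system, r.code))
    meds: dict[str, list[MedRec]] = defaultdict(list)
    for r in bundle.medications.itertuples(index=False):
        meds[r.patient_id].append(MedRec(r.date, r.ingredient, r.event_type))
    pregs: dict[str, list[tuple[dt.date, dt.date]]] = defaultdict(list)
    for r in bundle.pregnancies.itertuples(index=False):
        pregs[r.patient_id].append((r.start_date, r.end_date))
    for r in bundle.patients.itertuples(index=False):
        pid = r.patient_id
        yield PatientView(
            patient_id=pid,
            birth_date=r.birth_date,
            sex=r.sex,
            race_ethnicity=r.race_ethnicity,
            labs=labs.get(pid, []),
            diagnoses=dxs.get(pid, []),
            medications=meds.get(pid, []),
            pregnancies=pregs.get(pid, []),
        )
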