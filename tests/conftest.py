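import datetime as dt
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from phenoequiv.datamodel import (
    DiagnosisRecord,
    EhrBundle,
    Encounter,
    LabResult,
    MedicationRecord,
    Patient,
)

D = dt.date


@pytest.fixture
def small_bundle() -> EhrBundle:
    """Three patients: a clear T2D, a clear T1D, and an unaffected control."""
    patients = [
        Patient("p1", D(1990, 5, 1), "female", "white"),
        Patient("p2", D(1985, 2, 10), "male", "african_american"),
        Patient("p3", D(2000, 8, 20), "female", "hispanic",
                pregnancy_intervals=((D(2022, 1, 1), D(2022, 9, 30)),)),
    ]
    encounters = [
        Encounter("p1", D(2022, 3, 1), "alpha"),
        Encounter("p2", D(2021, 6, 1), "beta"),
        Encounter("p3", D(2020, 5, 1), "gamma"),
    ]
    diagnoses = [
        DiagnosisRecord("p1", D(2021, 3, 1), "ICD10", "E11.9"),
        DiagnosisRecord("p1", D(2022, 6, 1), "ICD10", "E11.65"),
        DiagnosisRecord("p2", D(2021, 4, 1), "ICD10", "E10.9"),
        DiagnosisRecord("p2", D(2022, 2, 1), "ICD10", "E10.65"),
    ]
    labs = [
        LabResult("p1", D(2021, 3, 1), "hba1c", 7.2, "%"),
        LabResult("p1", D(2022, 6, 1), "hba1c", 7.4, "%"),
        LabResult("p2", D(2022, 2, 1), "c_peptide", 0.5, "ng/mL"),
    ]
    medications = [
        MedicationRecord("p1", D(2022, 6, 1), "glipizide"),
        MedicationRecord("p2", D(2022, 2, 1), "insulin"),
    ]
    return EhrBundle.from_records(
        patients, encounters, diagnoses, labs, medications,
        cp1_systems={"alpha", "beta"},
    )
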