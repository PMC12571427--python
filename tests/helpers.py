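"""Shared builders for patient views and randomized patient records."""

import datetime as dt

from phenoequiv.datamodel import DxRec, LabRec, MedRec, PatientView

D = dt.date

CODE_POOL = [
    "E109", "E1165", "E119", "E149", "E089", "E083", "E139", "E099",
    "25000", "25001", "25002", "25003", "2509", "250", "E669", "Z0100",
]
MED_POOL = [
    "insulin", "glipizide", "metformin", "glucagon", "urine acetone test strips",
    "aspirin", "semaglutide", "sulfonylurea", "tirzepatide", "lisinopril",
]
EVENT_TYPES = ["prescribed", "dispensed", "administered"]
LAB_SPECS = [
    ("hba1c", 5.0, 8.5),
    ("fasting_glucose", 90.0, 180.0),
    ("random_glucose", 120.0, 260.0),
    ("c_peptide", 0.2, 1.6),
]


def view_from_rec(rec, pid="p1"):
    """Build a PatientView from an oracle-style plain record dict."""
    return PatientView(
        patient_id=pid,
        labs=[LabRec(d, a, v) for d, a, v in rec["labs"]],
        diagnoses=[
            DxRec(d, "ICD9" if c[0].isdigit() else "ICD10", c) for d, c in rec["dxs"]
        ],
        medications=[MedRec(d, i, e) for d, i, e in rec["meds"]],
        pregnancies=list(rec.get("pregnancies", [])),
    )


def make_rec(labs=(), dxs=(), meds=(), pregnancies=()):
    return {"labs": list(labs), "dxs": list(dxs), "meds": list(meds),
            "pregnancies": list(pregnancies)}


def random_rec(rng, year=2022):
    """One random patient record exercising codes, labs, meds and windows."""
    base = D(year - 3, 1, 1)
    ndays = 4 * 365

    def rdate():
        return base + dt.timedelta(days=int(rng.integers(0, ndays)))

    labs = []
    for _ in range(rng.integers(0, 4)):
        if rng.random() < 0.12:
            labs.append((rdate(), "diabetes_autoantibody",
                         "positive" if rng.random() < 0.5 else "negative"))
        else:
            analyte, lo, hi = LAB_SPECS[rng.integers(0, len(LAB_SPECS))]
            labs.append((rdate(), analyte, round(float(rng.uniform(lo, hi)), 1)))
    dxs = [(rdate(), CODE_POOL[rng.integers(0, len(CODE_POOL))])
           for _ in range(rng.integers(0, 5))]
    meds = [(rdate(), MED_POOL[rng.integers(0, len(MED_POOL))],
             EVENT_TYPES[rng.integers(0, len(EVENT_TYPES))])
            for _ in range(rng.integers(0, 4))]
    pregnancies = []
    if rng.random() < 0.2:
        start = rdate()
        pregnancies.append((start, start + dt.timedelta(days=int(rng.integers(30, 280)))))
    return make_rec(labs, dxs, meds, pregnancies)
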