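"""Synthetic EHR generator with known truth labels.

Generation is split into three independently seeded phases so that
observability parameters can be varied while the underlying clinical truth
stays fixed (common random numbers):

1. *truth stream* -- demographics, true disease labels, encounters,
   pregnancies and every clinically true event (labs, diagnosis codes,
   medications), drawn from ``seed`` stream 1;
2. *capture stream* -- one uniform per true event, drawn from stream 2; the
   event is recorded iff its uniform falls below the relevant capture
   probability, so lowering a capture probability only ever removes records;
3. *miscoding stream* -- one uniform per true diagnosis code, drawn from
   stream 3; a code flips type (E10<->E11, ICD-9 fifth digit 0<->1, 2<->3)
   iff its uniform falls below ``type_miscode_prob``.

True T2D patients carry two elevated HbA1c results, two T2D-pattern codes
and one non-insulin antidiabetic prescription; true T1D patients carry two
elevated HbA1c results, two T1D-pattern codes, insulin and glucagon
prescriptions, and (half of them) a C-peptide below the T1D threshold.
Everyone else gets one normal HbA1c.  Lab values are drawn uniformly on
ranges strictly separated by the diagnostic thresholds, so at capture
probability 1 and miscoding 0 both phenotypes recover the truth exactly.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from phenoequiv.datamodel import EhrBundle, TABLE_COLUMNS, validate_bundle

__all__ = [
    "SimulationConfig",
    "StratumKey",
    "all_strata",
    "generate_population",
    "load_sim_config",
    "truth_prevalence",
    "write_truth",
]

SEXES = ("female", "male")
AGE_GROUPS = ("18-24", "25-34", "35-44")
RACES = ("african_american", "asian", "hispanic", "white", "other")
AGE_BOUNDS = {"18-24": (18, 24), "25-34": (25, 34), "35-44": (35, 44)}

#: CP 1 catchment systems ("alpha", "beta"); "gamma" is outside it
CATCHMENT_SYSTEMS = ("alpha", "beta")
OUTSIDE_SYSTEM = "gamma"

StratumKey = tuple[str, str, str]  # (sex, age_group, race_ethnicity)


def all_strata() -> list[StratumKey]:
    return [(s, a, r) for s in SEXES for a in AGE_GROUPS for r in RACES]


class ConfigError(ValueError):
    """Invalid simulation configuration (raised before any generation)."""


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 1000
    prevalence_year: int = 2022
    stratum_mix: Mapping[StratumKey, float] | None = None  # None = uniform
    true_t2d_prev: float | Mapping[StratumKey, float] = 0.06
    true_t1d_prev: float | Mapping[StratumKey, float] = 0.005
    encounter_rate: float = 2.0          # expected encounters / patient / year
    lab_capture_prob: float = 1.0
    med_capture_prob: float = 1.0
    dx_capture_prob: float = 1.0
    type_miscode_prob: float = 0.0
    pregnancy_prob: float = 0.1
    catchment_fraction: float = 0.7
    t1d_cpeptide_prob: float = 0.5       # share of T1D patients with a C-peptide test
    seed: int = 20220101

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        if self.encounter_rate < 0:
            raise ConfigError("encounter_rate must be >= 0")
        for name in ("lab_capture_prob", "med_capture_prob", "dx_capture_prob",
                     "type_miscode_prob", "pregnancy_prob", "catchment_fraction",
                     "t1d_cpeptide_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        for name in ("true_t2d_prev", "true_t1d_prev"):
            v = getattr(self, name)
            vals = v.values() if isinstance(v, Mapping) else [v]
            if any(not 0.0 <= x <= 1.0 for x in vals):
                raise ConfigError(f"{name} outside [0, 1]")
        if self.stratum_mix is not None:
            if set(self.stratum_mix) - set(all_strata()):
                raise ConfigError("stratum_mix has unknown stratum keys")
            total = sum(self.stratum_mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"stratum_mix sums to {total}, expected 1")
            if any(p < 0 for p in self.stratum_mix.values()):
                raise ConfigError("stratum_mix has negative proportions")

    def _per_stratum(self, value: float | Mapping[StratumKey, float]) -> np.ndarray:
        strata = all_strata()
        if isinstance(value, Mapping):
            return np.array([value.get(k, 0.0) for k in strata])
        return np.full(len(strata), float(value))


def load_sim_config(path: str | Path) -> SimulationConfig:
    """Read a YAML config mirroring the SimulationConfig field names."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "stratum_mix" in raw and raw["stratum_mix"] is not None:
        raw["stratum_mix"] = {tuple(k.split("|")): v for k, v in raw["stratum_mix"].items()}
    for key in ("true_t2d_prev", "true_t1d_prev"):
        if isinstance(raw.get(key), dict):
            raw[key] = {tuple(k.split("|")): v for k, v in raw[key].items()}
    cfg = SimulationConfig(**raw)
    cfg.validate()
    return cfg


def _dates_from_offsets(base: dt.date, offsets: np.ndarray) -> list[dt.date]:
    b = np.datetime64(base.isoformat())
    return (b + offsets.astype("timedelta64[D]")).astype("datetime64[D]").tolist()


def _distinct_pair(rng: np.random.Generator, ndays: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Two distinct day offsets per row, uniform over ordered pairs."""
    d1 = rng.integers(0, ndays, m)
    d2 = (d1 + 1 + rng.integers(0, ndays - 1, m)) % ndays
    return d1, d2


def generate_population(config: SimulationConfig) -> tuple[EhrBundle, pd.DataFrame]:
    """Generate a validated bundle plus its truth table.

    Deterministic given the config (identical configs yield byte-identical
    written tables).  Returns ``(bundle, truth)`` where truth has columns
    patient_id, true_label, sex, age_group, race_ethnicity.
    """
    config.validate()
    year = config.prevalence_year
    n = config.n_patients

    empty_truth = pd.DataFrame(
        {c: pd.Series(dtype=object)
         for c in ("patient_id", "true_label", "sex", "age_group", "race_ethnicity")}
    )
    if n == 0:
        bundle = EhrBundle(
            **{name: pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
               for name, cols in TABLE_COLUMNS.items()},
            cp1_systems=frozenset(),
        )
        return bundle, empty_truth

    rng_truth = np.random.default_rng([config.seed, 1])
    rng_capture = np.random.default_rng([config.seed, 2])
    rng_miscode = np.random.default_rng([config.seed, 3])

    strata = all_strata()
    mix = (np.full(len(strata), 1.0 / len(strata))
           if config.stratum_mix is None
           else np.array([config.stratum_mix.get(k, 0.0) for k in strata]))

    base3 = dt.date(year - 2, 1, 1)
    base2 = dt.date(year - 1, 1, 1)
    ndays3 = (dt.date(year, 12, 31) - base3).days + 1
    ndays2 = (dt.date(year, 12, 31) - base2).days + 1

    # ---- phase 1: truth stream -------------------------------------------
    s_idx = rng_truth.choice(len(strata), size=n, p=mix)
    sex = np.array([strata[i][0] for i in s_idx])
    ageg = np.array([strata[i][1] for i in s_idx])
    race = np.array([strata[i][2] for i in s_idx])

    lo = np.array([AGE_BOUNDS[a][0] for a in ageg])
    hi = np.array([AGE_BOUNDS[a][1] for a in ageg])
    age = lo + np.floor(rng_truth.random(n) * (hi - lo + 1)).astype(int)
    age = np.minimum(age, hi)
    # completed age on Dec 31 of the prevalence year equals `age` exactly:
    # birth date lies in (Dec 31 of year-age-1, Dec 31 of year-age]
    day_back = rng_truth.integers(0, 365, n)
    birth_dates = [
        dt.date(year - int(a), 12, 31) - dt.timedelta(days=int(db))
        for a, db in zip(age, day_back)
    ]

    p2 = config._per_stratum(config.true_t2d_prev)[s_idx]
    p1 = config._per_stratum(config.true_t1d_prev)[s_idx]
    u_label = rng_truth.random(n)
    label = np.where(u_label < p2, "T2D", np.where(u_label < p2 + p1, "T1D", "none"))

    in_catchment = rng_truth.random(n) < config.catchment_fraction

    n_enc = rng_truth.poisson(config.encounter_rate * 3.0, n)
    total_enc = int(n_enc.sum())
    enc_pid_idx = np.repeat(np.arange(n), n_enc)
    enc_off = rng_truth.integers(0, ndays3, total_enc)
    enc_sys_pick = rng_truth.integers(0, 2, total_enc)
    enc_setting = rng_truth.choice(
        ["outpatient", "inpatient", "emergency"], size=total_enc, p=[0.7, 0.15, 0.15]
    )

    u_preg = rng_truth.random(n)
    preg_end_off = rng_truth.integers(270, ndays2, n) if ndays2 > 270 else np.full(n, 270)

    diabetic = label != "none"
    dia_idx = np.flatnonzero(diabetic)
    m = len(dia_idx)
    lab_d1, lab_d2 = _distinct_pair(rng_truth, ndays2, m)
    lab_vals = rng_truth.uniform(6.6, 11.0, (m, 2))
    dx_d1, dx_d2 = _distinct_pair(rng_truth, ndays2, m)
    dx_icd9 = rng_truth.integers(0, 2, (m, 2))  # 0 -> ICD-10, 1 -> ICD-9
    med_off = rng_truth.integers(0, ndays2, m)

    t1d_mask_local = label[dia_idx] == "T1D"
    m1 = int(t1d_mask_local.sum())
    glucagon_off = rng_truth.integers(0, ndays2, m1)
    u_cpep = rng_truth.random(m1)
    cpep_vals = rng_truth.uniform(0.1, 0.7, m1)
    cpep_off = rng_truth.integers(0, ndays2, m1)

    non_idx = np.flatnonzero(~diabetic)
    m0 = len(non_idx)
    norm_vals = rng_truth.uniform(4.5, 6.0, m0)
    norm_off = rng_truth.integers(0, ndays2, m0)

    # ---- phase 2: capture stream (one uniform per true event) ------------
    u_lab_dia = rng_capture.random((m, 2))
    u_cpep_cap = rng_capture.random(m1)
    u_lab_norm = rng_capture.random(m0)
    u_dx = rng_capture.random((m, 2))
    u_med = rng_capture.random(m)
    u_med_glucagon = rng_capture.random(m1)

    # ---- phase 3: miscoding stream ---------------------------------------
    u_mis = rng_miscode.random((m, 2))

    # ---- assemble tables --------------------------------------------------
    pids = np.array([f"P{i:06d}" for i in range(n)])

    patients = pd.DataFrame(
        {"patient_id": pids, "birth_date": birth_dates, "sex": sex, "race_ethnicity": race}
    )

    enc_sys = np.where(
        in_catchment[enc_pid_idx],
        np.array(CATCHMENT_SYSTEMS)[enc_sys_pick],
        OUTSIDE_SYSTEM,
    )
    encounters = pd.DataFrame(
        {
            "patient_id": pids[enc_pid_idx],
            "date": _dates_from_offsets(base3, enc_off),
            "system_id": enc_sys,
            "setting": enc_setting,
        }
    )

    lab_rows: dict[str, list] = {"patient_id": [], "date": [], "analyte": [],
                                 "value": [], "units": []}

    def _add_labs(pidx, offs, analyte, values, units):
        lab_rows["patient_id"].extend(pids[pidx])
        lab_rows["date"].extend(_dates_from_offsets(base2, np.asarray(offs)))
        lab_rows["analyte"].extend([analyte] * len(pidx))
        lab_rows["value"].extend(values)
        lab_rows["units"].extend([units] * len(pidx))

    for col, (d_off, vals) in enumerate(
        [(lab_d1, lab_vals[:, 0]), (lab_d2, lab_vals[:, 1])]
    ):
        keep = u_lab_dia[:, col] < config.lab_capture_prob
        _add_labs(dia_idx[keep], d_off[keep], "hba1c", np.round(vals[keep], 1), "%")
    keep_cp = (u_cpep < config.t1d_cpeptide_prob) & (u_cpep_cap < config.lab_capture_prob)
    t1d_idx = dia_idx[t1d_mask_local]
    _add_labs(t1d_idx[keep_cp], cpep_off[keep_cp], "c_peptide",
              np.round(cpep_vals[keep_cp], 2), "ng/mL")
    keep_n = u_lab_norm < config.lab_capture_prob
    _add_labs(non_idx[keep_n], norm_off[keep_n], "hba1c", np.round(norm_vals[keep_n], 1), "%")
    labs = pd.DataFrame(lab_rows)
    if len(labs):
        labs["value"] = [float(v) for v in labs["value"]]
        labs["value"] = labs["value"].astype(object)

    # diagnosis codes: type-true codes, miscoded per occurrence
    is_t1_row = t1d_mask_local[:, None].repeat(2, axis=1)
    flip = u_mis < config.type_miscode_prob
    code_t1 = is_t1_row ^ flip
    icd10_code = np.where(code_t1, "E109", "E119")
    icd9_code = np.where(code_t1, "25001", "25000")
    codes = np.where(dx_icd9 == 1, icd9_code, icd10_code)
    systems = np.where(dx_icd9 == 1, "ICD9", "ICD10")
    dx_rows: dict[str, list] = {"patient_id": [], "date": [], "code_system": [],
                                "code": [], "setting": []}
    for col, d_off in [(0, dx_d1), (1, dx_d2)]:
        keep = u_dx[:, col] < config.dx_capture_prob
        dx_rows["patient_id"].extend(pids[dia_idx[keep]])
        dx_rows["date"].extend(_dates_from_offsets(base2, d_off[keep]))
        dx_rows["code_system"].extend(systems[keep, col])
        dx_rows["code"].extend(codes[keep, col])
        dx_rows["setting"].extend(["outpatient"] * int(keep.sum()))
    diagnoses = pd.DataFrame(dx_rows)

    med_rows: dict[str, list] = {"patient_id": [], "date": [], "ingredient": [],
                                 "event_type": []}
    primary_ing = np.where(t1d_mask_local, "insulin", "glipizide")
    keep_med = u_med < config.med_capture_prob
    med_rows["patient_id"].extend(pids[dia_idx[keep_med]])
    med_rows["date"].extend(_dates_from_offsets(base2, med_off[keep_med]))
    med_rows["ingredient"].extend(primary_ing[keep_med])
    med_rows["event_type"].extend(["prescribed"] * int(keep_med.sum()))
    keep_glu = u_med_glucagon < config.med_capture_prob
    med_rows["patient_id"].extend(pids[t1d_idx[keep_glu]])
    med_rows["date"].extend(_dates_from_offsets(base2, glucagon_off[keep_glu]))
    med_rows["ingredient"].extend(["glucagon"] * int(keep_glu.sum()))
    med_rows["event_type"].extend(["prescribed"] * int(keep_glu.sum()))
    medications = pd.DataFrame(med_rows)

    pregnant = (sex == "female") & (u_preg < config.pregnancy_prob)
    preg_idx = np.flatnonzero(pregnant)
    ends = _dates_from_offsets(base2, preg_end_off[preg_idx])
    pregnancies = pd.DataFrame(
        {
            "patient_id": pids[preg_idx],
            "start_date": [e - dt.timedelta(days=269) for e in ends],
            "end_date": ends,
        }
    )

    observed_systems = set(encounters["system_id"]) if len(encounters) else set()
    cp1_systems = frozenset(CATCHMENT_SYSTEMS) & observed_systems

    tables = {
        "patients": patients,
        "encounters": encounters,
        "diagnoses": diagnoses,
        "labs": labs,
        "medications": medications,
        "pregnancies": pregnancies,
    }
    for name, df in tables.items():
        if len(df) == 0:
            tables[name] = pd.DataFrame(
                {c: pd.Series(dtype=object) for c in TABLE_COLUMNS[name]}
            )
            continue
        sort_cols = [c for c in ("patient_id", "date", "start_date") if c in df.columns]
        tables[name] = (
            df.sort_values(sort_cols, kind="stable").reset_index(drop=True)[TABLE_COLUMNS[name]]
        )

    bundle = EhrBundle(cp1_systems=cp1_systems, **tables)
    validate_bundle(bundle)
    truth = pd.DataFrame(
        {"patient_id": pids, "true_label": label, "sex": sex,
         "age_group": ageg, "race_ethnicity": race}
    )
    return bundle, truth


def truth_prevalence(truth: pd.DataFrame, stratum: tuple[str, str] = ("overall", "overall")) -> float:
    """Exact fraction of T2D-true patients within a stratum.

    ``stratum`` is ``(dimension, level)``; ``("overall", "overall")`` covers
    everyone.  Raises on an empty stratum (undefined proportion).
    """
    dim, level = stratum
    if dim == "overall":
        sub = truth
    else:
        if dim not in ("sex", "age_group", "race_ethnicity"):
            raise ValueError(f"unknown stratum dimension {dim!r}")
        sub = truth[truth[dim] == level]
    if len(sub) == 0:
        raise ValueError(f"empty stratum {stratum}: proportion undefined")
    return float((sub["true_label"] == "T2D").mean())


def write_truth(truth: pd.DataFrame, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / "truth.csv"
    truth.to_csv(path, index=False)
    return path
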