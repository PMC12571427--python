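import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from phenoequiv.cp1 import classify_cp1
from phenoequiv.cp2 import classify_cp2, confirm_dm_cp2, cp2_window
from phenoequiv.datamodel import iter_patient_views, load_bundle, validate_bundle, write_bundle
from phenoequiv.prevalence import eligible_patients, prevalence_table
from phenoequiv.simulate import (
    ConfigError,
    SimulationConfig,
    all_strata,
    generate_population,
    load_sim_config,
    truth_prevalence,
    write_truth,
)

YEAR = 2022


def _dir_bytes(directory: Path) -> dict[str, bytes]:
    return {p.name: p.read_bytes() for p in sorted(Path(directory).iterdir())}


class TestConfig:
    def test_invalid_probability(self):
        with pytest.raises(ConfigError):
            SimulationConfig(lab_capture_prob=1.2).validate()

    def test_negative_n(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_patients=-1).validate()

    def test_mix_must_sum_to_one(self):
        mix = {k: 0.0 for k in all_strata()}
        mix[("female", "18-24", "white")] = 0.5
        with pytest.raises(ConfigError):
            SimulationConfig(stratum_mix=mix).validate()

    def test_error_before_generation(self):
        with pytest.raises(ConfigError):
            generate_population(SimulationConfig(catchment_fraction=2.0))

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "sim.yaml"
        path.write_text("n_patients: 25\nseed: 3\ntrue_t2d_prev: 0.1\n")
        cfg = load_sim_config(path)
        assert cfg.n_patients == 25 and cfg.true_t2d_prev == 0.1

    def test_yaml_unknown_key(self, tmp_path):
        path = tmp_path / "sim.yaml"
        path.write_text("n_patients: 25\nbogus: 1\n")
        with pytest.raises(ConfigError, match="bogus"):
            load_sim_config(path)


class TestGenerate:
    def test_empty_population(self):
        bundle, truth = generate_population(SimulationConfig(n_patients=0))
        assert len(bundle.patients) == 0 and len(truth) == 0
        validate_bundle(bundle)

    def test_determinism_byte_identical(self, tmp_path):
        cfg = SimulationConfig(n_patients=300, seed=5, type_miscode_prob=0.1,
                               lab_capture_prob=0.8)
        for run in ("a", "b"):
            bundle, truth = generate_population(cfg)
            write_bundle(bundle, tmp_path / run)
            write_truth(truth, tmp_path / run)
        assert _dir_bytes(tmp_path / "a") == _dir_bytes(tmp_path / "b")

    def test_round_trip_valid(self, tmp_path):
        bundle, _ = generate_population(SimulationConfig(n_patients=200, seed=8,
                                                         type_miscode_prob=0.2))
        write_bundle(bundle, tmp_path / "b")
        loaded = load_bundle(tmp_path / "b")
        assert loaded.equals(bundle)

    def test_truth_covers_exactly_generated_patients(self):
        bundle, truth = generate_population(SimulationConfig(n_patients=150, seed=2))
        assert set(truth["patient_id"]) == set(bundle.patients["patient_id"])

    def test_ages_inside_bands(self):
        from phenoequiv.prevalence import age_group, age_on
        import datetime as dt

        bundle, truth = generate_population(SimulationConfig(n_patients=300, seed=4))
        ref = dt.date(YEAR, 12, 31)
        merged = bundle.patients.merge(truth, on="patient_id")
        for _, row in merged.iterrows():
            assert age_group(age_on(row["birth_date"], ref)) == row["age_group"]

    def test_perfect_capture_recovers_truth_for_diabetics(self):
        cfg = SimulationConfig(n_patients=2000, seed=31, lab_capture_prob=1.0,
                               med_capture_prob=1.0, dx_capture_prob=1.0,
                               type_miscode_prob=0.0, encounter_rate=2.0)
        bundle, truth = generate_population(cfg)
        labels = classify_cp1(bundle, YEAR).set_index("patient_id")["label"]
        tl = truth.set_index("patient_id")["true_label"]
        diabetic = tl[tl != "none"]
        assert (labels[diabetic.index] == diabetic).all()
        # and nobody healthy is swept in
        assert (labels[tl[tl == "none"].index] == "none").all()


class TestTruthPrevalence:
    def test_all_none(self):
        _, truth = generate_population(SimulationConfig(n_patients=50, seed=1,
                                                        true_t2d_prev=0.0,
                                                        true_t1d_prev=0.0))
        assert truth_prevalence(truth) == 0.0

    def test_counting(self):
        truth = pd.DataFrame(
            {"patient_id": [f"p{i}" for i in range(10)],
             "true_label": ["T2D"] * 3 + ["none"] * 7,
             "sex": ["female"] * 10, "age_group": ["18-24"] * 10,
             "race_ethnicity": ["white"] * 10}
        )
        assert truth_prevalence(truth, ("sex", "female")) == pytest.approx(0.3)

    def test_empty_stratum_raises(self):
        _, truth = generate_population(SimulationConfig(n_patients=10, seed=1))
        with pytest.raises(ValueError, match="empty stratum"):
            truth_prevalence(truth, ("sex", "unobserved"))

    def test_binomial_concentration(self):
        p = 0.08
        n = 5000
        _, truth = generate_population(
            SimulationConfig(n_patients=n, seed=17, true_t2d_prev=p)
        )
        tol = 4 * math.sqrt(p * (1 - p) / n)
        assert abs(truth_prevalence(truth) - p) < tol


class TestObservationProcess:
    def _detected_cp1(self, cfg):
        bundle, _ = generate_population(cfg)
        labels = classify_cp1(bundle, YEAR)
        return set(labels.loc[labels["label"] != "none", "patient_id"])

    def _confirmed_cp2(self, cfg):
        bundle, _ = generate_population(cfg)
        window = cp2_window(YEAR)
        return {
            v.patient_id for v in iter_patient_views(bundle)
            if confirm_dm_cp2(v, window)[0]
        }

    def test_capture_monotonicity_common_random_numbers(self):
        base = dict(n_patients=1500, seed=23, true_t2d_prev=0.15, true_t1d_prev=0.02)
        probs = [(1.0, 1.0), (0.6, 0.6), (0.25, 0.25)]
        cp1_sets = [
            self._detected_cp1(SimulationConfig(**base, lab_capture_prob=lab,
                                                dx_capture_prob=dx))
            for lab, dx in probs
        ]
        cp2_sets = [
            self._confirmed_cp2(SimulationConfig(**base, lab_capture_prob=lab,
                                                 dx_capture_prob=dx))
            for lab, dx in probs
        ]
        for series in (cp1_sets, cp2_sets):
            for bigger, smaller in zip(series, series[1:]):
                assert smaller <= bigger

    def test_catchment_fraction_scales_cp1_denominator(self):
        f = 0.5
        bundle, _ = generate_population(
            SimulationConfig(n_patients=6000, seed=12, catchment_fraction=f)
        )
        n1 = len(eligible_patients(bundle, "cp1", YEAR))
        n2 = len(eligible_patients(bundle, "cp2", YEAR))
        assert n2 > 0
        assert abs(n1 / n2 - f) < 4 * math.sqrt(f * (1 - f) / n2) + 0.02

    def test_perfect_observation_matches_truth_prevalence_exactly(self):
        cfg = SimulationConfig(n_patients=4000, seed=44, true_t2d_prev=0.1)
        bundle, truth = generate_population(cfg)
        tl = truth.set_index("patient_id")["true_label"]
        for cp, classify in (("cp1", classify_cp1), ("cp2", classify_cp2)):
            eligible = eligible_patients(bundle, cp, YEAR)
            labels = classify(bundle, YEAR)
            table = prevalence_table(labels, eligible, bundle.patients, YEAR)
            observed = table.loc[table["dimension"] == "overall", "prevalence_pct"].item()
            truth_among_eligible = 100.0 * (tl[list(eligible)] == "T2D").mean()
            assert observed == pytest.approx(truth_among_eligible)
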