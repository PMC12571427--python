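import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import (
    CODE_POOL,
    EVENT_TYPES,
    LAB_SPECS,
    MED_POOL,
    make_rec,
    random_rec,
    view_from_rec,
)
from oracles import oracle_cp1_label
from phenoequiv.cp1 import (
    CP1_NONINSULIN_MEDICATIONS,
    Cp1Criteria,
    classify_cp1,
    classify_patient_cp1,
    cp1_window,
    detect_diabetes_cp1,
    detect_t1d_cp1,
)
from phenoequiv.simulate import SimulationConfig, generate_population

D = dt.date
WINDOW = cp1_window(2022)
YEAR = 2022


def _classify(rec):
    return classify_patient_cp1(view_from_rec(rec), WINDOW)[0]


class TestCriteria:
    def test_medication_list(self):
        crit = Cp1Criteria()
        assert len(crit.noninsulin_medications) == 29
        assert "metformin" not in crit.noninsulin_medications
        assert "glipizide" in crit.noninsulin_medications

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            Cp1Criteria(hba1c_threshold=0.0)


class TestDetectDiabetes:
    def test_two_abnormal_hba1c(self):
        rec = make_rec(labs=[(D(2021, 3, 1), "hba1c", 7.2), (D(2022, 6, 1), "hba1c", 7.4)])
        detected, evidence = detect_diabetes_cp1(view_from_rec(rec), WINDOW)
        assert detected
        assert any(e.startswith("abnormal_labs") for e in evidence)

    def test_single_abnormal_glucose_insufficient(self):
        rec = make_rec(labs=[(D(2022, 6, 1), "random_glucose", 250.0)])
        assert not detect_diabetes_cp1(view_from_rec(rec), WINDOW)[0]

    def test_pooled_occasions_mix_of_criteria(self):
        # one abnormal HbA1c date + one abnormal fasting date qualify together
        rec = make_rec(labs=[(D(2021, 3, 1), "hba1c", 6.5),
                             (D(2022, 6, 1), "fasting_glucose", 126.0)])
        assert detect_diabetes_cp1(view_from_rec(rec), WINDOW)[0]
        crit = Cp1Criteria(pooled_lab_occasions=False)
        assert not detect_diabetes_cp1(view_from_rec(rec), WINDOW, crit)[0]

    def test_same_date_counts_once(self):
        rec = make_rec(labs=[(D(2021, 3, 1), "hba1c", 7.2),
                             (D(2021, 3, 1), "random_glucose", 300.0)])
        assert not detect_diabetes_cp1(view_from_rec(rec), WINDOW)[0]

    def test_insulin_inside_pregnancy_does_not_qualify(self):
        rec = make_rec(meds=[(D(2022, 5, 1), "insulin", "prescribed")],
                       pregnancies=[(D(2022, 1, 1), D(2022, 9, 30))])
        assert not detect_diabetes_cp1(view_from_rec(rec), WINDOW)[0]

    def test_insulin_outside_pregnancy_qualifies(self):
        rec = make_rec(meds=[(D(2021, 5, 1), "insulin", "prescribed")],
                       pregnancies=[(D(2022, 1, 1), D(2022, 9, 30))])
        detected, evidence = detect_diabetes_cp1(view_from_rec(rec), WINDOW)
        assert detected and any("insulin" in e for e in evidence)

    def test_single_noninsulin_medication_qualifies(self):
        rec = make_rec(meds=[(D(2022, 2, 1), "semaglutide", "prescribed")])
        assert detect_diabetes_cp1(view_from_rec(rec), WINDOW)[0]

    def test_two_codes_two_dates(self):
        rec = make_rec(dxs=[(D(2021, 3, 1), "25000"), (D(2022, 6, 1), "E149")])
        assert detect_diabetes_cp1(view_from_rec(rec), WINDOW)[0]

    def test_codes_outside_window_ignored(self):
        rec = make_rec(dxs=[(D(2019, 3, 1), "E119"), (D(2020, 12, 31), "E119")])
        assert not detect_diabetes_cp1(view_from_rec(rec), WINDOW)[0]


class TestDetectT1d:
    def test_low_c_peptide(self):
        rec = make_rec(labs=[(D(2022, 1, 1), "c_peptide", 0.5)])
        assert detect_t1d_cp1(view_from_rec(rec), WINDOW)[0]

    def test_ratio_with_glucagon(self):
        rec = make_rec(
            dxs=[(D(2022, 1, 1), "E109")] * 3 + [(D(2022, 2, 1), "E119")],
            meds=[(D(2022, 3, 1), "glucagon", "prescribed"),
                  (D(2022, 3, 1), "glipizide", "prescribed")],
        )
        assert detect_t1d_cp1(view_from_rec(rec), WINDOW)[0]

    def test_low_ratio_no_marker(self):
        rec = make_rec(dxs=[(D(2022, 1, 1), "E109")] + [(D(2022, 2, 1), "E119")] * 3)
        assert not detect_t1d_cp1(view_from_rec(rec), WINDOW)[0]

    def test_ratio_infinite_when_no_t2d_codes(self):
        # only T1D-type codes, never prescribed oral agents -> T1D
        rec = make_rec(dxs=[(D(2021, 5, 1), "E109"), (D(2022, 5, 1), "E109")])
        assert _classify(rec) == "T1D"

    def test_ratio_needs_some_t1d_codes(self):
        rec = make_rec(dxs=[(D(2021, 5, 1), "E149"), (D(2022, 5, 1), "E149")])
        assert _classify(rec) == "T2D"


class TestClassify:
    def test_diabetes_no_t1d_marker_is_t2d(self):
        rec = make_rec(labs=[(D(2021, 3, 1), "hba1c", 7.2), (D(2022, 6, 1), "hba1c", 7.4)])
        assert _classify(rec) == "T2D"

    def test_no_records_is_none(self):
        assert _classify(make_rec()) == "none"

    def test_labels_exhaustive_and_exclusive(self, small_bundle):
        labels = classify_cp1(small_bundle, YEAR)
        assert set(labels["label"]) <= {"none", "T1D", "T2D"}
        assert len(labels) == len(small_bundle.patients)
        assert labels["patient_id"].is_unique

    def test_small_bundle_labels(self, small_bundle):
        labels = classify_cp1(small_bundle, YEAR).set_index("patient_id")["label"]
        assert labels["p1"] == "T2D"
        assert labels["p2"] == "T1D"
        assert labels["p3"] == "none"

    def test_adding_noninsulin_med_never_untags_t2d(self):
        rec = make_rec(labs=[(D(2021, 3, 1), "hba1c", 7.2), (D(2022, 6, 1), "hba1c", 7.4)])
        assert _classify(rec) == "T2D"
        rec["meds"].append((D(2022, 1, 1), "glipizide", "prescribed"))
        assert _classify(rec) == "T2D"

    def test_removing_t1d_markers_yields_t2d(self):
        rec = make_rec(
            labs=[(D(2021, 3, 1), "hba1c", 7.2), (D(2022, 6, 1), "hba1c", 7.4),
                  (D(2022, 1, 1), "c_peptide", 0.3)],
        )
        assert _classify(rec) == "T1D"
        rec["labs"] = [l for l in rec["labs"] if l[1] != "c_peptide"]
        assert _classify(rec) == "T2D"


class TestOracleEquivalence:
    def test_random_records(self):
        rng = np.random.default_rng(1234)
        for i in range(1000):
            rec = random_rec(rng)
            assert _classify(rec) == oracle_cp1_label(rec, YEAR), rec

    def test_synthetic_bundle(self):
        cfg = SimulationConfig(n_patients=400, seed=99, lab_capture_prob=0.7,
                               med_capture_prob=0.5, dx_capture_prob=0.8,
                               type_miscode_prob=0.15)
        bundle, _ = generate_population(cfg)
        labels = classify_cp1(bundle, YEAR).set_index("patient_id")["label"]
        from phenoequiv.datamodel import iter_patient_views

        for view in iter_patient_views(bundle):
            rec = make_rec(
                labs=[(l.date, l.analyte, l.value) for l in view.labs],
                dxs=[(d.date, d.code) for d in view.diagnoses],
                meds=[(m.date, m.ingredient, m.event_type) for m in view.medications],
                pregnancies=view.pregnancies,
            )
            assert labels[view.patient_id] == oracle_cp1_label(rec, YEAR)


@st.composite
def rec_strategy(draw):
    date = st.dates(D(2019, 6, 1), D(2023, 6, 1))
    labs = draw(st.lists(st.tuples(
        date,
        st.sampled_from([a for a, _, _ in LAB_SPECS]),
        st.one_of(st.floats(0.0, 400.0, allow_nan=False),
                  st.sampled_from([6.5, 126.0, 200.0, 0.8])),
    ), max_size=4))
    ab = draw(st.lists(st.tuples(
        date, st.just("diabetes_autoantibody"), st.sampled_from(["positive", "negative"])
    ), max_size=1))
    dxs = draw(st.lists(st.tuples(date, st.sampled_from(CODE_POOL)), max_size=5))
    meds = draw(st.lists(st.tuples(
        date, st.sampled_from(MED_POOL), st.sampled_from(EVENT_TYPES)), max_size=4))
    pregnancies = []
    if draw(st.booleans()):
        start = draw(date)
        pregnancies.append((start, start + dt.timedelta(days=draw(st.integers(0, 280)))))
    return make_rec(labs + ab, dxs, meds, pregnancies)


@settings(max_examples=300, deadline=None)
@given(rec_strategy())
def test_property_oracle_equivalence(rec):
    assert _classify(rec) == oracle_cp1_label(rec, YEAR)
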