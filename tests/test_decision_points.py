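import pandas as pd
import pytest

from precohort import (
    HBA1C,
    OutcomeSpec,
    assign_treatments,
    compute_guideline_flags,
    dps_to_frame,
    extract_decision_points,
)
from precohort.synthetic import SimConfig, make_toy_patient, simulate_population

BASE = pd.Timestamp("2013-06-01")


def _hba1c(day, value):
    return {
        "table": "measurements",
        "date": BASE + pd.Timedelta(days=day),
        "nhg_code": "817",
        "description": "HbA1c",
        "value": value,
    }


def _rx(day, atc, desc):
    return {
        "table": "prescriptions",
        "date": BASE + pd.Timedelta(days=day),
        "atc_code": atc,
        "description": desc,
    }


def _advice(day):
    return {
        "table": "measurements",
        "date": BASE + pd.Timedelta(days=day),
        "nhg_code": "1401",
        "description": "follow dietary advice",
        "value": 1.0,
    }


class TestWindowRule:
    def test_four_test_fixture_yields_two_hand_enumerated_dps(self, four_test_patient):
        dps = extract_decision_points(four_test_patient, HBA1C)
        assert len(dps) == 2
        first, second = dps
        assert first.index_date == BASE and first.index_value == 8.1
        assert first.outcome_date == BASE + pd.Timedelta(days=120)
        assert first.outcome_label == "controlled"
        assert second.index_date == BASE + pd.Timedelta(days=400)
        assert second.outcome_date == BASE + pd.Timedelta(days=500)
        assert second.outcome_label == "uncontrolled"

    def test_all_values_controlled_yield_no_dps(self):
        tables = make_toy_patient([_hba1c(d, 6.5) for d in (0, 120, 240)])
        assert extract_decision_points(tables, HBA1C) == []

    def test_follow_up_before_90_days_does_not_qualify(self):
        tables = make_toy_patient([_hba1c(0, 8.0), _hba1c(80, 6.5)])
        assert extract_decision_points(tables, HBA1C) == []

    def test_value_exactly_at_threshold_is_controlled_and_no_index(self):
        # 7.0 is not an index (not > 7) and as a follow-up counts controlled
        tables = make_toy_patient([_hba1c(0, 8.0), _hba1c(100, 7.0)])
        dps = extract_decision_points(tables, HBA1C)
        assert len(dps) == 1
        assert dps[0].outcome_label == "controlled"
        tables2 = make_toy_patient([_hba1c(0, 7.0), _hba1c(100, 6.5)])
        assert extract_decision_points(tables2, HBA1C) == []

    def test_index_before_diagnosis_excluded(self):
        tables = make_toy_patient(
            [_hba1c(0, 8.0), _hba1c(100, 6.5)], diagnosis_date="2014-01-01"
        )
        assert extract_decision_points(tables, HBA1C) == []

    def test_same_day_tests_use_maximum_for_index(self):
        tables = make_toy_patient([_hba1c(0, 6.5), _hba1c(0, 8.2), _hba1c(100, 6.0)])
        dps = extract_decision_points(tables, HBA1C)
        assert len(dps) == 1
        assert dps[0].index_value == 8.2

    def test_outcome_test_may_serve_as_next_index(self):
        tables = make_toy_patient([_hba1c(0, 8.0), _hba1c(100, 7.5), _hba1c(200, 6.5)])
        dps = extract_decision_points(tables, HBA1C)
        assert [dp.index_date for dp in dps] == [BASE, BASE + pd.Timedelta(days=100)]

    def test_unknown_outcome_variable_rejected(self, four_test_patient):
        with pytest.raises(ValueError):
            extract_decision_points(
                four_test_patient, OutcomeSpec(variable="ketones", threshold=1.0)
            )


class TestTreatmentAssignment:
    def test_no_events_give_no_treatment_then_no_change(self, four_test_patient):
        active, new = assign_treatments(
            four_test_patient, "P00000", BASE, BASE + pd.Timedelta(days=120)
        )
        assert active == "no treatment"
        assert new == "no change"

    def test_medication_plus_advice_merge_into_combined_label(self):
        tables = make_toy_patient(
            [_rx(-30, "A10BA02", "metformin"), _advice(-10), _hba1c(0, 8.0), _hba1c(100, 6.5)]
        )
        active, new = assign_treatments(tables, "P00000", BASE, BASE + pd.Timedelta(days=100))
        assert active == "healthy lifestyle_metformin"

    def test_added_medication_renders_sorted_combination(self):
        tables = make_toy_patient(
            [
                _rx(-30, "A10BA02", "metformin"),
                _hba1c(0, 8.0),
                _rx(10, "A10BB09", "gliclazide"),
                _rx(60, "A10BA02", "metformin"),
                _hba1c(100, 6.5),
            ]
        )
        active, new = assign_treatments(tables, "P00000", BASE, BASE + pd.Timedelta(days=100))
        assert active == "metformin"
        assert new == "gliclazide_metformin"

    def test_stale_prescription_outside_active_window_ignored(self):
        tables = make_toy_patient([_rx(-300, "A10BA02", "metformin"), _hba1c(0, 8.0)])
        active, _ = assign_treatments(tables, "P00000", BASE, BASE + pd.Timedelta(days=100))
        assert active == "no treatment"

    def test_continued_regimen_is_no_change(self):
        tables = make_toy_patient(
            [
                _rx(-30, "A10BA02", "metformin"),
                _hba1c(0, 8.0),
                _rx(60, "A10BA02", "metformin"),
                _hba1c(100, 6.5),
            ]
        )
        active, new = assign_treatments(tables, "P00000", BASE, BASE + pd.Timedelta(days=100))
        assert active == "metformin"
        assert new == "no change"


class TestGuidelineFlags:
    def test_age_above_70_flag(self):
        tables = make_toy_patient([_hba1c(0, 8.0)], birth_year=1933)  # age 80 in 2013
        flags, _ = compute_guideline_flags(tables, "P00000", BASE)
        assert flags.age_above_70y

    def test_no_episodes_mean_no_impairment_flags(self, four_test_patient):
        flags, has_chronic = compute_guideline_flags(four_test_patient, "P00000", BASE)
        assert not flags.mobility_impaired and not flags.mental_impaired
        assert not has_chronic

    def test_chronic_mobility_episode_active_from_start(self):
        tables = make_toy_patient(
            [
                _hba1c(0, 8.0),
                {
                    "table": "comorbidities",
                    "icpc_code": "L95",
                    "description": "Osteoporosis",
                    "start_date": BASE - pd.Timedelta(days=100),
                    "end_date": None,
                    "duration_class": "chronic",
                },
            ]
        )
        flags, has_chronic = compute_guideline_flags(tables, "P00000", BASE)
        assert flags.mobility_impaired
        assert has_chronic

    def test_ended_temporary_episode_does_not_count(self):
        tables = make_toy_patient(
            [
                _hba1c(0, 8.0),
                {
                    "table": "comorbidities",
                    "icpc_code": "L15",
                    "description": "Knee symptoms or complaints",
                    "start_date": BASE - pd.Timedelta(days=200),
                    "end_date": BASE - pd.Timedelta(days=144),
                    "duration_class": "8 weeks",
                },
            ]
        )
        flags, has_chronic = compute_guideline_flags(tables, "P00000", BASE)
        assert not flags.mobility_impaired
        assert not has_chronic

    def test_mental_episode_sets_mental_flag_only(self):
        tables = make_toy_patient(
            [
                _hba1c(0, 8.0),
                {
                    "table": "comorbidities",
                    "icpc_code": "P76",
                    "description": "Depressive disorder",
                    "start_date": BASE - pd.Timedelta(days=50),
                    "end_date": None,
                    "duration_class": "chronic",
                },
            ]
        )
        flags, _ = compute_guideline_flags(tables, "P00000", BASE)
        assert flags.mental_impaired and not flags.mobility_impaired

    def test_missing_bmi_gives_false_flag(self, four_test_patient):
        flags, _ = compute_guideline_flags(four_test_patient, "P00000", BASE)
        assert not flags.bmi_below_25

    def test_low_bmi_measurement_sets_flag(self):
        tables = make_toy_patient(
            [
                {
                    "table": "measurements",
                    "date": BASE - pd.Timedelta(days=30),
                    "nhg_code": "560",
                    "description": "BMI",
                    "value": 23.0,
                },
                _hba1c(0, 8.0),
            ]
        )
        flags, _ = compute_guideline_flags(tables, "P00000", BASE)
        assert flags.bmi_below_25


class TestPopulationInvariants:
    def test_emitted_dps_satisfy_contract(self, small_population):
        tables, _ = small_population
        frame = dps_to_frame(extract_decision_points(tables, HBA1C))
        reg = tables.registry.set_index("patient_id")
        dx = frame["patient_id"].map(reg["diagnosis_date"])
        assert (frame["index_date"] > dx).all()
        assert (frame["index_value"] > HBA1C.threshold).all()
        gap = (frame["outcome_date"] - frame["index_date"]).dt.days
        assert gap.between(90, 365).all()
        assert set(frame["outcome"]) <= {"controlled", "uncontrolled"}

    def test_dp_count_monotone_in_measurement_rate(self):
        counts = []
        for rate in (1.5, 3.0):
            tables, _ = simulate_population(
                SimConfig(n_patients=150, seed=13, measurement_rate=rate)
            )
            counts.append(len(extract_decision_points(tables, HBA1C)))
        assert counts[0] < counts[1]

    def test_history_counts_on_hand_built_patient(self):
        tables = make_toy_patient(
            [
                _rx(-30, "A10BA02", "metformin"),
                _rx(-200, "A10BA02", "metformin"),  # after diagnosis, before index
                _hba1c(0, 8.0),
                _hba1c(100, 6.5),
            ],
            diagnosis_date="2012-06-01",
        )
        dps = extract_decision_points(tables, HBA1C)
        assert len(dps) == 1
        n_rx, n_meas, n_consult, n_co = dps[0].history_counts
        assert (n_rx, n_meas, n_consult, n_co) == (2, 1, 0, 0)
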