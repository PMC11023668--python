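import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehrpgx import (
    GenerativeParams,
    RxBehavior,
    ScenarioConfig,
    VariantSpec,
    VisitSchedule,
    simulate_ehr,
)
from ehrpgx.cohort import (
    Regimen,
    build_regimen,
    classify_prescriptions,
    control_pairs,
    impute_missing_dose,
    parse_dose,
    qc_cascade,
    regularity,
    select_window_measure,
)

from conftest import measures_frame, rx_frame


@pytest.mark.parametrize(
    "text,expected",
    [
        ("Simvastatin 40mg tablets", 40.0),
        ("Atorvastatin 10 mg", 10.0),
        ("Metformin tablets", None),
        ("Gliclazide 2.5mg", 2.5),
        ("", None),
    ],
)
def test_parse_dose(text, expected):
    assert parse_dose(text) == expected


def test_impute_missing_dose_uses_per_drug_median():
    regs = [
        Regimen("P1", 0, "simvastatin", 20.0),
        Regimen("P2", 0, "simvastatin", 40.0),
        Regimen("P3", 0, "simvastatin", 40.0),
        Regimen("P4", 0, "simvastatin", None),
        Regimen("P5", 0, "atorvastatin", 10.0),
        Regimen("P6", 0, "atorvastatin", 80.0),
        Regimen("P7", 0, "atorvastatin", None),
        Regimen("P8", 0, "rosuvastatin", None),  # no observed dose at all
    ]
    impute_missing_dose(regs)
    assert regs[3].start_dose_mg == 40.0
    assert regs[6].start_dose_mg == 45.0
    assert regs[0].start_dose_mg == 20.0  # untouched
    assert regs[7].start_dose_mg is None  # stays missing, excluded from covariate


def test_classify_prescriptions_tags(code_map):
    rx = rx_frame(
        [
            ("P1", 0, "STA1", "Simvastatin 40mg"),
            ("P1", 10, "CMB1", "Simvastatin + Ezetimibe 40mg"),
            ("P1", 20, "SUL1", "Gliclazide 80mg"),
            ("P1", 30, "ZZZ", "Unknown"),
        ]
    )
    out, rejects = classify_prescriptions(rx, code_map, primary="statin")
    assert rejects["reason"].tolist() == ["unknown_code"]
    by_code = out.set_index("code")
    assert by_code.loc["STA1", "is_primary"] and by_code.loc["STA1", "broad_class"] == "lipid"
    assert by_code.loc["CMB1", "is_combination"]
    assert not by_code.loc["SUL1", "is_same_class_other"]  # different broad class
    out2, _ = classify_prescriptions(rx, code_map, primary="metformin")
    assert out2.set_index("code").loc["SUL1", "is_same_class_other"]


class TestRegimen:
    def test_combination_product_always_violates(self, code_map, lenient):
        rx = rx_frame([("P1", 0, "STA1", "Simvastatin 40mg"), ("P1", 100, "CMB1", "Combo 40mg")])
        ann, _ = classify_prescriptions(rx, code_map, "statin")
        reg = build_regimen(ann, lenient, "statin")
        assert reg.comed_violation == "combination_product"

    def test_allowed_addon_flagged_in_lenient_mode(self, code_map, lenient, stringent):
        lenient.addon_rules = {"metformin": {"gliclazide"}}
        rx = rx_frame(
            [
                ("P1", 1000, "MET1", "Metformin 500mg"),
                ("P1", 800, "SUL1", "Gliclazide 80mg"),
                ("P1", 1300, "SUL1", "Gliclazide 80mg"),
            ]
        )
        ann, _ = classify_prescriptions(rx, code_map, "metformin")
        reg = build_regimen(ann, lenient, "metformin")
        assert reg.comed_violation is None
        assert reg.addon_flags == {"gliclazide": True}
        reg2 = build_regimen(ann, stringent, "metformin")
        assert reg2.comed_violation == "same_class_comedication"

    def test_one_sided_addon_is_a_violation(self, code_map, lenient):
        lenient.addon_rules = {"metformin": {"gliclazide"}}
        rx = rx_frame(
            [("P1", 1000, "MET1", "Metformin 500mg"), ("P1", 1300, "SUL1", "Gliclazide 80mg")]
        )
        ann, _ = classify_prescriptions(rx, code_map, "metformin")
        assert build_regimen(ann, lenient, "metformin").comed_violation == "same_class_comedication"

    def test_switch_events_detected(self, code_map, lenient):
        rx = rx_frame(
            [
                ("P1", 0, "STA1", "Simvastatin 40mg"),
                ("P1", 61, "STA1", "Simvastatin 80mg"),
                ("P1", 122, "STA2", "Atorvastatin 20mg"),
            ]
        )
        ann, _ = classify_prescriptions(rx, code_map, "statin")
        reg = build_regimen(ann, lenient, "statin")
        assert reg.start_date == 0 and reg.start_dose_mg == 40.0
        assert reg.switch_events == [(61, "dose_change"), (122, "type_change")]

    def test_no_primary_prescription_is_not_a_candidate(self, code_map, lenient):
        rx = rx_frame([("P1", 0, "EZE1", "Ezetimibe 10mg")])
        ann, _ = classify_prescriptions(rx, code_map, "statin")
        assert build_regimen(ann, lenient, "statin") is None


class TestRegularity:
    def test_dense_prescriptions_cover_every_window(self):
        assert regularity(list(range(0, 610, 30)), 0, 610) == 1.0

    def test_sparse_prescriptions_enumerated(self):
        # ten 61-day windows over [0, 610); days 0, 200, 400 cover windows 0, 3, 6
        assert regularity([0, 200, 400], 0, 610) == pytest.approx(0.3)

    def test_empty_interval_is_zero(self):
        assert regularity([], 0, 610) == 0.0

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValueError):
            regularity([0], 100, 100)

    @settings(max_examples=50, deadline=None)
    @given(
        dates=st.lists(st.integers(0, 600), max_size=15),
        extra=st.integers(0, 600),
    )
    def test_adding_a_prescription_never_decreases_regularity(self, dates, extra):
        before = regularity(dates, 0, 610)
        after = regularity(dates + [extra], 0, 610)
        assert 0.0 <= before <= after <= 1.0


class TestWindowSelection:
    def setup_method(self):
        self.meas = measures_frame([("P1", -100, 5.0), ("P1", -30, 4.0), ("P1", 3, 3.5)])

    def test_single_takes_closest_to_start(self, stringent):
        value, date, n = select_window_measure(self.meas, 0, stringent, "baseline")
        assert (value, date, n) == (3.5, 3, 2)  # day +3 beats day -30; -100 outside

    def test_average_means_in_window_values(self, stringent):
        stringent.measure_mode = "average"
        value, date, n = select_window_measure(self.meas, 0, stringent, "baseline")
        assert value == pytest.approx((4.0 + 3.5) / 2)
        assert date == pytest.approx((-30 + 3) / 2)
        assert n == 2

    def test_out_of_window_only_gives_missing(self, stringent):
        meas = measures_frame([("P1", -100, 5.0)])
        assert select_window_measure(meas, 0, stringent, "baseline") is None

    def test_baseline_tie_prefers_pretreatment_measure(self, stringent):
        meas = measures_frame([("P1", -5, 5.0), ("P1", 5, 3.0)])
        value, date, _ = select_window_measure(meas, 0, stringent, "baseline")
        assert (value, date) == (5.0, -5)

    def test_post_takes_earliest_in_window(self, lenient):
        meas = measures_frame([("P1", 300, 3.0), ("P1", 500, 2.5)])
        value, date, n = select_window_measure(meas, 0, lenient, "post")
        assert (value, date, n) == (3.0, 300, 2)


def six_person_fixture():
    """Each person engineered to fail exactly one successive QC stage."""
    start = 1000
    refills = [(d, "STA1", "Simvastatin 40mg tablets") for d in range(start, 1801, 61)]

    def person(pid, rx_rows, meas_rows):
        return (
            [(pid, d, c, t) for d, c, t in rx_rows],
            [(pid, d, v) for d, v in meas_rows],
        )

    base_meas = [(100, 4.0), (950, 4.0), (1300, 3.0)]
    persons = {}
    # P1: ezetimibe near start -> comedication
    persons["P1"] = person("P1", refills + [(1100, "EZE1", "Ezetimibe 10mg")], base_meas)
    # P2: no baseline measure -> stage i
    persons["P2"] = person("P2", refills, [(100, 4.0), (1300, 3.0)])
    # P3: no record two years before start -> stage ii
    persons["P3"] = person("P3", refills, [(950, 4.0), (1300, 3.0)])
    # P4: refills stop before the post measure -> stage iii
    early = [(d, "STA1", "Simvastatin 40mg tablets") for d in range(start, 1281, 61)]
    persons["P4"] = person("P4", early, base_meas)
    # P5: statin type switch before the post measure -> stage iv
    switched = [
        (d, ("STA1" if d < 1100 else "STA2"), ("Simvastatin 40mg" if d < 1100 else "Atorvastatin 40mg"))
        for d in range(start, 1801, 61)
    ]
    persons["P5"] = person("P5", switched, base_meas)
    # P6: only two far-apart prescriptions -> stage v (regularity 1/5)
    persons["P6"] = person(
        "P6", [(1000, "STA1", "Simvastatin 40mg"), (1790, "STA1", "Simvastatin 40mg")], base_meas
    )
    rx = rx_frame([r for p in persons.values() for r in p[0]])
    meas = measures_frame([m for p in persons.values() for m in p[1]])
    return meas, rx


class TestQCCascade:
    def test_each_stage_removes_exactly_one_engineered_person(self, code_map, lenient):
        meas, rx = six_person_fixture()
        cohort, audit = qc_cascade(meas, rx, code_map, lenient, "LDL", "statin")
        assert audit.n_input == 6 and audit.n_final == 0
        assert [audit.removed[s] for s in audit.stages] == [1, 1, 1, 1, 1, 1, 0, 0]
        assert audit.first_failing == {
            "P1": "comedication",
            "P2": "i_measures",
            "P3": "ii_prior_record",
            "P4": "iii_later_prescription",
            "P5": "iv_drug_change",
            "P6": "v_regularity",
        }
        assert audit.conserved()

    def test_low_baseline_removed_at_stage_vi(self, code_map, lenient):
        refills = [("P1", d, "STA1", "Simvastatin 40mg") for d in range(1000, 1801, 61)]
        meas = measures_frame([("P1", 100, 4.0), ("P1", 950, 1.5), ("P1", 1300, 1.2)])
        cohort, audit = qc_cascade(meas, rx_frame(refills), code_map, lenient, "LDL", "statin")
        assert audit.removed["vi_min_baseline"] == 1 and audit.n_final == 0

    def test_survivor_row_and_dose_covariate(self, code_map, lenient):
        refills = [("P1", d, "STA1", "Simvastatin 40mg tablets") for d in range(1000, 1801, 61)]
        meas = measures_frame([("P1", 100, 4.0), ("P1", 950, 4.0), ("P1", 1300, 3.0)])
        cohort, audit = qc_cascade(meas, rx_frame(refills), code_map, lenient, "LDL", "statin")
        assert audit.n_final == 1
        row = cohort.iloc[0]
        assert row["baseline_value"] == 4.0 and row["post_value"] == 3.0
        assert row["drug_type"] == "simvastatin" and row["dose_mg"] == 40.0
        assert 183 <= row["time_start_to_post"] < 730
        assert not audit.cohort_size_warning  # min_cohort_size=1, n_final=1
        # with the default threshold a 1-person cohort must warn
        big = qc_cascade(meas, rx_frame(refills), code_map,
                         ScenarioConfig(mode="lenient", measure_mode="single", min_drug_group_size=1),
                         "LDL", "statin")[1]
        assert big.cohort_size_warning


@pytest.fixture(scope="module")
def generated_streams():
    params = GenerativeParams(variants=[VariantSpec("v0", 0.3, beta0=0.3, gammaD=0.2)], betaD=-1.0)
    behavior = RxBehavior(p_same_class_comed=0.1, p_combo=0.05, p_switch=0.1, regularity=0.85)
    return simulate_ehr(600, params, behavior, VisitSchedule(), seed=21)


class TestCascadeProperties:
    def test_audit_conservation_on_randomized_inputs(self, code_map, generated_streams):
        meas, rx, pop, _ = generated_streams
        for mode in ("stringent", "lenient"):
            for mm in ("single", "average"):
                sc = ScenarioConfig(mode=mode, measure_mode=mm, min_drug_group_size=1, min_cohort_size=1)
                cohort, audit = qc_cascade(meas, rx, code_map, sc, "LDL", "statin", pop.persons)
                assert audit.conserved()
                assert audit.n_final == len(cohort)

    def test_stringent_survivors_subset_of_lenient(self, code_map, generated_streams):
        meas, rx, pop, _ = generated_streams
        strict = ScenarioConfig(mode="stringent", measure_mode="single", min_drug_group_size=1, min_cohort_size=1)
        loose = ScenarioConfig(mode="lenient", measure_mode="single", min_drug_group_size=1, min_cohort_size=1)
        s_cohort, _ = qc_cascade(meas, rx, code_map, strict, "LDL", "statin")
        l_cohort, _ = qc_cascade(meas, rx, code_map, loose, "LDL", "statin")
        assert set(s_cohort["person_id"]) <= set(l_cohort["person_id"])

    def test_no_cohort_row_uses_out_of_window_measures(self, code_map, generated_streams):
        meas, rx, pop, _ = generated_streams
        sc = ScenarioConfig(mode="stringent", measure_mode="average", min_drug_group_size=1, min_cohort_size=1)
        cohort, _ = qc_cascade(meas, rx, code_map, sc, "LDL", "statin")
        for _, row in cohort.iterrows():
            start = row["start_date"]
            assert start - sc.baseline_lookback_days <= row["baseline_date"] <= start + 7
            assert start + 183 <= row["post_date"] < start + sc.post_max_days


class TestControlPairs:
    def test_pair_retained_within_band(self):
        pairs = control_pairs(measures_frame([("P1", 0, 4.0), ("P1", 400, 3.9)]), "LDL")
        assert len(pairs) == 1 and pairs.iloc[0]["time_start_to_post"] == 400

    def test_too_close_pair_dropped(self):
        pairs = control_pairs(measures_frame([("P1", 0, 4.0), ("P1", 100, 3.9)]), "LDL")
        assert pairs.empty

    def test_earliest_qualifying_pair_chosen(self):
        pairs = control_pairs(
            measures_frame([("P1", 0, 4.0), ("P1", 100, 3.9), ("P1", 400, 3.8)]), "LDL"
        )
        assert pairs.iloc[0][["baseline_date", "post_date"]].tolist() == [0, 400]
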