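import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gpcomplexity.codesets import CodeSetRegistry, FactorDefinition
from gpcomplexity.reference import toy_registry as _toy_registry
from gpcomplexity.factors import (
    FactorFlags,
    FlagError,
    classify_complexity,
    compute_flags,
    flag_consultation_factors,
    flag_patient_factors,
)

from tests.conftest import consultations_frame, events_frame, prescriptions_frame


@pytest.fixture
def registry(toy_registry):
    return toy_registry


def one_consultation(date="2014-01-01", cid=1, pid=1):
    return consultations_frame([(cid, pid, date, 10.0)])


class TestConsultationFactors:
    def test_no_records_all_false(self, registry):
        flags = flag_consultation_factors(registry, one_consultation())
        assert not flags.any().any()

    def test_code_match_within_consultation(self, registry):
        ev = events_frame([(1, 1, 1, "2014-01-01", "MHC1.")])
        flags = flag_consultation_factors(registry, one_consultation(), ev)
        assert flags.loc[1, "mental_health_consult"]
        assert not flags.loc[1, "dementia_consult"]

    def test_unlinked_event_does_not_fire_consultation_factor(self, registry):
        ev = events_frame([(1, 1, None, "2014-01-01", "MHC1.")])
        flags = flag_consultation_factors(registry, one_consultation(), ev)
        assert not flags.loc[1, "mental_health_consult"]

    def test_multiple_diagnosis_rule_needs_two_chapters(self):
        # rule over all coded events, no code restriction
        reg = CodeSetRegistry(
            [
                FactorDefinition(
                    "multi", "multi", "consultation", "count_rule",
                    count_threshold=2, count_unit="chapter",
                )
            ]
        )
        two_chapters = events_frame(
            [(1, 1, 1, "2014-01-01", "E20.."), (2, 1, 1, "2014-01-01", "H33..")]
        )
        same_chapter = events_frame(
            [(1, 1, 1, "2014-01-01", "E20.."), (2, 1, 1, "2014-01-01", "E35..")]
        )
        assert flag_consultation_factors(reg, one_consultation(), two_chapters).loc[1, "multi"]
        assert not flag_consultation_factors(reg, one_consultation(), same_chapter).loc[1, "multi"]

    def test_excluded_chapters_ignored(self):
        reg = CodeSetRegistry(
            [
                FactorDefinition(
                    "multi", "multi", "consultation", "count_rule",
                    count_threshold=2, count_unit="chapter",
                )
            ]
        )
        ev = events_frame(
            [(1, 1, 1, "2014-01-01", "E20.."), (2, 1, 1, "2014-01-01", "Z00..")]
        )
        flags = flag_consultation_factors(
            reg, one_consultation(), ev, excluded_chapters=("Z",)
        )
        assert not flags.loc[1, "multi"]

    def test_prescribing_rule_unique_substances(self, registry):
        # 3 prescriptions of 2 unique substances -> false
        rx2 = prescriptions_frame(
            [
                (1, 1, 1, "2014-01-01", "SUB01"),
                (2, 1, 1, "2014-01-01", "SUB01"),
                (3, 1, 1, "2014-01-01", "SUB02"),
            ]
        )
        flags = flag_consultation_factors(registry, one_consultation(), None, rx2)
        assert not flags.loc[1, "many_drugs_prescribed"]
        # adding a third unique substance -> true
        rx3 = prescriptions_frame(
            [
                (1, 1, 1, "2014-01-01", "SUB01"),
                (2, 1, 1, "2014-01-01", "SUB01"),
                (3, 1, 1, "2014-01-01", "SUB02"),
                (4, 1, 1, "2014-01-01", "SUB03"),
            ]
        )
        flags = flag_consultation_factors(registry, one_consultation(), None, rx3)
        assert flags.loc[1, "many_drugs_prescribed"]

    def test_preventive_tasks_need_two_distinct_codes(self, registry):
        one_code_twice = events_frame(
            [(1, 1, 1, "2014-01-01", "PRV1."), (2, 1, 1, "2014-01-01", "PRV1.")]
        )
        flags = flag_consultation_factors(registry, one_consultation(), one_code_twice)
        assert not flags.loc[1, "preventive_tasks"]
        two_codes = events_frame(
            [(1, 1, 1, "2014-01-01", "PRV1."), (2, 1, 1, "2014-01-01", "PRV2.")]
        )
        flags = flag_consultation_factors(registry, one_consultation(), two_codes)
        assert flags.loc[1, "preventive_tasks"]

    def test_event_linked_to_other_patient_errors(self, registry):
        ev = events_frame([(1, 99, 1, "2014-01-01", "MHC1.")])
        with pytest.raises(FlagError, match="different patient"):
            flag_consultation_factors(registry, one_consultation(), ev)


class TestFirstConsultAfterDiagnosis:
    def test_same_day_counts_and_tie_breaks_by_id(self, registry):
        cons = consultations_frame(
            [
                (1, 1, "2014-01-05", 10.0),
                (2, 1, "2014-01-10", 10.0),
                (3, 1, "2014-01-10", 10.0),
                (4, 1, "2014-01-20", 10.0),
            ]
        )
        dx = events_frame([(1, 1, None, "2014-01-10", "FCC1.")])
        flags = flag_consultation_factors(registry, cons, dx)
        col = flags["first_consult_cancer"]
        assert col.loc[2] and not col.loc[1] and not col.loc[3] and not col.loc[4]

    def test_first_after_means_no_intervening(self, registry):
        cons = consultations_frame(
            [(1, 1, "2014-01-05", 10.0), (2, 1, "2014-01-20", 10.0)]
        )
        dx = events_frame([(1, 1, None, "2014-01-12", "FCD1.")])
        flags = flag_consultation_factors(registry, cons, dx)
        assert flags.loc[2, "first_consult_diabetes"]
        assert not flags.loc[1, "first_consult_diabetes"]

    def test_diagnosis_after_all_consultations_never_fires(self, registry):
        cons = one_consultation(date="2014-01-01")
        dx = events_frame([(1, 1, None, "2014-06-01", "FCC1.")])
        flags = flag_consultation_factors(registry, cons, dx)
        assert not flags.loc[1, "first_consult_cancer"]


class TestPatientFactors:
    def test_window_boundary_half_open(self, registry):
        cons = one_consultation(date="2014-01-01")
        # exactly 365 days before -> OUTSIDE the (d-365, d] window
        at_boundary = events_frame([(1, 1, None, "2013-01-01", "DVP1.")])
        flags = flag_patient_factors(registry, cons, at_boundary)
        assert not flags.loc[1, "domestic_violence_patient"]
        # 364 days before -> inside
        inside = events_frame([(1, 1, None, "2013-01-02", "DVP1.")])
        flags = flag_patient_factors(registry, cons, inside)
        assert flags.loc[1, "domestic_violence_patient"]
        # on the consultation date -> inside
        same_day = events_frame([(1, 1, None, "2014-01-01", "DVP1.")])
        flags = flag_patient_factors(registry, cons, same_day)
        assert flags.loc[1, "domestic_violence_patient"]

    def test_ever_factor_unbounded(self, registry):
        cons = one_consultation(date="2014-01-01")
        ev = events_frame([(1, 1, None, "2004-01-01", "DMP1.")])
        flags = flag_patient_factors(registry, cons, ev)
        assert flags.loc[1, "dementia_patient"]

    def test_no_lookahead(self, registry):
        cons = one_consultation(date="2014-01-01")
        ev = events_frame([(1, 1, None, "2014-01-02", "DMP1.")])
        flags = flag_patient_factors(registry, cons, ev)
        assert not flags.loc[1, "dementia_patient"]

    def test_consultation_before_all_history_is_false_not_error(self, registry):
        cons = one_consultation(date="2000-01-01")
        ev = events_frame([(1, 1, None, "2014-01-01", "DMP1.")])
        flags = flag_patient_factors(registry, cons, ev)
        assert not flags.loc[1, "dementia_patient"]

    @pytest.mark.parametrize("n_prior,expected", [(13, False), (14, True)])
    def test_frequent_attender_threshold(self, registry, n_prior, expected):
        rows = [(100, 1, "2014-06-01", 10.0)]  # index consultation
        rows += [(i, 1, pd.Timestamp("2014-06-01") - pd.Timedelta(days=7 * (i + 1)), 10.0)
                 for i in range(1, n_prior + 1)]
        cons = consultations_frame(rows)
        flags = flag_patient_factors(registry, cons)
        assert bool(flags.loc[100, "frequent_attender"]) is expected

    def test_frequent_attender_can_include_index(self, registry):
        rows = [(100, 1, "2014-06-01", 10.0)]
        rows += [(i, 1, pd.Timestamp("2014-06-01") - pd.Timedelta(days=7 * (i + 1)), 10.0)
                 for i in range(1, 14)]
        cons = consultations_frame(rows)
        flags = flag_patient_factors(registry, cons, exclude_index_consultation=False)
        assert flags.loc[100, "frequent_attender"]  # 13 prior + index = 14

    @pytest.mark.parametrize("n_subst,expected", [(8, False), (9, True)])
    def test_polypharmacy_unique_substances_in_3_months(self, registry, n_subst, expected):
        cons = one_consultation(date="2014-06-01")
        rx = prescriptions_frame(
            [(i, 1, None, "2014-05-01", f"PLY{i:02d}") for i in range(1, n_subst + 1)]
        )
        flags = flag_patient_factors(registry, cons, None, rx)
        assert bool(flags.loc[1, "polypharmacy"]) is expected

    def test_polypharmacy_window_excludes_old_prescriptions(self, registry):
        cons = one_consultation(date="2014-06-01")
        rx = prescriptions_frame(
            [(i, 1, None, "2013-05-01", f"PLY{i:02d}") for i in range(1, 10)]
        )
        flags = flag_patient_factors(registry, cons, None, rx)
        assert not flags.loc[1, "polypharmacy"]

    @pytest.mark.parametrize("n_groups,expected", [(2, False), (3, True)])
    def test_ltc_counts_condition_groups(self, registry, n_groups, expected):
        cons = one_consultation(date="2014-06-01")
        codes = ["LTA1.", "LTB1.", "LTC1."][:n_groups] + ["LTA1."]  # duplicate group
        ev = events_frame(
            [(i, 1, None, "2010-01-01", c) for i, c in enumerate(codes, 1)]
        )
        flags = flag_patient_factors(registry, cons, ev)
        assert bool(flags.loc[1, "ltc_3plus"]) is expected


class TestClassifyComplexity:
    def test_all_false_not_complex(self, registry):
        cons = one_consultation()
        flags = compute_flags(registry, cons)
        out = classify_complexity(flags, ["mental_health_consult"], cons)
        assert not out["is_complex"].iloc[0]

    def test_retained_set_gates_complexity(self, registry):
        cons = one_consultation()
        ev = events_frame([(1, 1, 1, "2014-01-01", "MHC1.")])
        flags = compute_flags(registry, cons, ev)
        complex_out = classify_complexity(flags, ["mental_health_consult"], cons)
        assert complex_out["is_complex"].iloc[0]
        gated = classify_complexity(flags, ["dementia_consult"], cons)
        assert not gated["is_complex"].iloc[0]

    def test_unknown_retained_factor_errors(self, registry):
        cons = one_consultation()
        flags = compute_flags(registry, cons)
        with pytest.raises(FlagError, match="absent from flags"):
            classify_complexity(flags, ["ghost"], cons)

    def test_factor_flags_counts_true_entries(self):
        ff = FactorFlags(1, {"a": True, "b": False, "c": True})
        assert ff.n_factors_present == 2

    def test_proportion_matches_planted_truth_oracle(self, small_dataset, registry):
        retained = sorted(small_dataset.truth.factor_prevalence)
        flags = compute_flags(
            registry,
            small_dataset.consultations,
            small_dataset.events,
            small_dataset.prescriptions,
        )
        out = classify_complexity(flags, retained, small_dataset.consultations)
        oracle = small_dataset.truth_flags[retained].any(axis=1)
        assert out.set_index("consultation_id")["is_complex"].equals(oracle)

    def test_recovered_flags_equal_planted_truth(self, small_dataset, registry):
        flags = compute_flags(
            registry,
            small_dataset.consultations,
            small_dataset.events,
            small_dataset.prescriptions,
        )
        planted = sorted(small_dataset.truth.factor_prevalence)
        pd.testing.assert_frame_equal(flags[planted], small_dataset.truth_flags[planted])


class TestMonotonicity:
    @given(
        st.lists(
            st.sampled_from(["MHC1.", "DMC1.", "DAC1.", "CPC1.", "EMA1.", "LDC1."]),
            max_size=6,
        ),
        st.sampled_from(["MHC1.", "DMC1.", "DAC1."]),
    )
    @settings(max_examples=40, deadline=None)
    def test_adding_codes_never_reduces_flag_count(self, codes, extra):
        registry = _toy_registry()
        cons = one_consultation()
        base_ev = events_frame(
            [(i, 1, 1, "2014-01-01", c) for i, c in enumerate(codes, 1)]
        )
        more_ev = events_frame(
            [(i, 1, 1, "2014-01-01", c) for i, c in enumerate(codes + [extra], 1)]
        )
        before = compute_flags(registry, cons, base_ev).loc[1]
        after = compute_flags(registry, cons, more_ev).loc[1]
        assert (after | ~before).all()  # before implies after
        assert after.sum() >= before.sum()
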