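"""Case definition, record merging, histories, and identification regions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asdsurv.ascertain import (
    CaseStatus,
    CognitiveAssessment,
    Evaluation,
    SourceRecord,
    SpedEligibility,
    classify_case,
    classify_cognitive,
    diagnosis_history,
    earliest_evaluation_age,
    identification_regions,
    is_asd_indicator_code,
    merge_child_records,
    REGIONS,
)
from asdsurv.errors import ConsistencyError, ValidationError

from conftest import dx_evaluation, education_record, health_record


# -- independent brute-force oracle -----------------------------------------

_ICD9_VALID = {f"299.{d:02d}" for d in range(100)} | {f"299.{d}" for d in range(10)} | {"299"}
_ICD10_VALID = {"F84"} | {f"F84.{d}" for d in range(10) if d != 2} | {
    f"F84.{d}{e}" for d in range(10) for e in range(10) if d != 2
}


def oracle_code(code: str) -> bool:
    return str(code).strip().upper() in _ICD9_VALID | _ICD10_VALID


def oracle_classify(records, resident=True, birth_year=2010) -> bool:
    """Scan every record and indicator independently of the merge path."""
    indicators = set()
    for rec in records:
        if any(oracle_code(code) for code, _ in rec.icd_codes):
            indicators.add("icd")
        if rec.sped_eligibility is not None and rec.sped_eligibility.classification in (
            "autism-primary",
            "autism-eligibility-met",
        ):
            indicators.add("sped")
        if rec.accessible:
            for ev in rec.evaluations:
                qualified_dx = ev.conclusion == "asd-diagnosis" and ev.by_qualified_professional
                if qualified_dx or ev.reported_prior_diagnosis_age_months is not None:
                    indicators.add("dx")
    return bool(indicators) and resident and birth_year == 2010


# -- ICD code matching -------------------------------------------------------

@pytest.mark.parametrize(
    "code, expected",
    [
        ("299.00", True),
        ("299.99", True),
        ("299.0", True),  # short billing dialect, normalized
        ("299", True),
        ("F84", True),
        ("F84.0", True),
        ("F84.9", True),
        ("F84.2", False),  # Rett syndrome exclusion
        ("F84.21", False),  # extension of the exclusion
        ("F83", False),
        ("298.9", False),
        ("300.00", False),
        ("f84.0", True),  # case-insensitive
        (" F84.5 ", True),
        ("", False),
        ("not-a-code", False),
    ],
)
def test_icd_indicator_codes(code, expected):
    assert is_asd_indicator_code(code) is expected


def test_unparseable_code_warns_but_never_raises(caplog):
    with caplog.at_level("WARNING"):
        assert is_asd_indicator_code("garbage!!") is False
    assert any("unparseable" in m for m in caplog.messages)


# -- merging -----------------------------------------------------------------

class TestMerge:
    def test_union_across_sources(self):
        health = health_record(icd_codes=[("F84.0", 40)])
        edu = education_record()
        merged = merge_child_records([health, edu])
        assert merged.icd_codes == [("F84.0", 40)]
        assert len(merged.sped_entries) == 1

    def test_inaccessible_record_transmits_codes_only(self):
        rec = health_record(
            accessible=False,
            icd_codes=[("F84.0", 40)],
            evaluations=[dx_evaluation(age=38)],
            cognitive=[CognitiveAssessment(age_months=60, kind="test-score", iq_score=64)],
        )
        merged = merge_child_records([rec])
        assert merged.icd_codes and not merged.evaluations and not merged.cognitive
        status = classify_case(merged)
        assert status.has_icd and not status.has_dx_statement
        assert status.region == "icd-only"

    def test_empty_list_and_mixed_ids_rejected(self):
        with pytest.raises(ConsistencyError):
            merge_child_records([])
        with pytest.raises(ConsistencyError):
            merge_child_records([health_record(child_id="a"), health_record(child_id="b")])


# -- case classification ------------------------------------------------------

class TestClassifyCase:
    def test_rett_only_child_is_never_a_case(self):
        merged = merge_child_records([health_record(icd_codes=[("F84.2", 50)])])
        status = classify_case(merged)
        assert not status.is_case and status.region == "none"

    def test_sped_only_child_is_a_case(self):
        status = classify_case(merge_child_records([education_record()]))
        assert status.is_case and status.region == "sped-only"

    def test_residency_and_birth_year_preconditions(self):
        merged = merge_child_records(
            [
                health_record(
                    icd_codes=[("F84.0", 40)], evaluations=[dx_evaluation()]
                ),
                education_record(),
            ]
        )
        assert classify_case(merged).region == "all-three"
        assert not classify_case(merged, resident_in_year=False).is_case
        assert not classify_case(merged, birth_year=2011).is_case

    def test_unqualified_statement_does_not_count(self):
        merged = merge_child_records(
            [health_record(evaluations=[dx_evaluation(qualified=False)])]
        )
        assert not classify_case(merged).is_case

    def test_reported_prior_diagnosis_counts_as_statement(self):
        merged = merge_child_records(
            [
                health_record(
                    evaluations=[
                        Evaluation(
                            age_months=50,
                            conclusion="other",
                            reported_prior_diagnosis_age_months=38,
                        )
                    ]
                )
            ]
        )
        status = classify_case(merged)
        assert status.has_dx_statement
        assert status.earliest_dx_age_months == 38

    def test_adding_indicators_never_removes_case_status(self):
        base = [health_record(icd_codes=[("299.00", 44)])]
        assert classify_case(merge_child_records(base)).is_case
        richer = base + [education_record(), health_record(evaluations=[dx_evaluation()])]
        assert classify_case(merge_child_records(richer)).is_case

    @settings(max_examples=150, deadline=None)
    @given(data=st.data())
    def test_agrees_with_brute_force_oracle(self, data):
        """Random small record sets classify identically to a flat scan."""
        codes = st.sampled_from(
            ["F84.0", "F84.2", "299.00", "299", "F83", "junk", "300.9"]
        )
        n_records = data.draw(st.integers(min_value=1, max_value=4))
        records = []
        for _ in range(n_records):
            icd = [
                (data.draw(codes), data.draw(st.integers(12, 107)))
                for _ in range(data.draw(st.integers(0, 2)))
            ]
            evs = []
            for _ in range(data.draw(st.integers(0, 2))):
                age = data.draw(st.integers(12, 107))
                evs.append(
                    Evaluation(
                        age_months=age,
                        conclusion=data.draw(
                            st.sampled_from(
                                ["asd-diagnosis", "asd-suspected", "asd-ruled-out", "other"]
                            )
                        ),
                        by_qualified_professional=data.draw(st.booleans()),
                        reported_prior_diagnosis_age_months=(
                            data.draw(st.integers(12, age)) if data.draw(st.booleans()) else None
                        ),
                    )
                )
            sped = None
            if data.draw(st.booleans()):
                sped = SpedEligibility(
                    classification=data.draw(
                        st.sampled_from(["autism-primary", "autism-eligibility-met", "other"])
                    ),
                    age_months=data.draw(st.integers(12, 107)),
                )
            records.append(
                SourceRecord(
                    child_id="c1",
                    site="s",
                    source_type=data.draw(st.sampled_from(["health", "education"])),
                    accessible=data.draw(st.booleans()),
                    icd_codes=icd,
                    sped_eligibility=sped,
                    evaluations=evs,
                )
            )
        resident = data.draw(st.booleans())
        status = classify_case(merge_child_records(records), resident_in_year=resident)
        assert status.is_case == oracle_classify(records, resident=resident)


# -- diagnosis history / evaluation ages --------------------------------------

class TestDiagnosisHistory:
    def test_ruled_out_before_diagnosis_is_not_more_recent(self):
        merged = merge_child_records(
            [
                health_record(
                    evaluations=[
                        Evaluation(age_months=30, conclusion="asd-ruled-out"),
                        dx_evaluation(age=45),
                    ]
                )
            ]
        )
        _, _, ruled_out, more_recent = diagnosis_history(merged)
        assert ruled_out and not more_recent

    def test_ruled_out_after_diagnosis_is_more_recent(self):
        merged = merge_child_records(
            [
                health_record(
                    evaluations=[
                        dx_evaluation(age=40),
                        Evaluation(age_months=70, conclusion="asd-ruled-out"),
                    ]
                )
            ]
        )
        assert diagnosis_history(merged)[3] is True

    def test_same_month_rule_out_is_not_more_recent(self):
        merged = merge_child_records(
            [
                health_record(
                    evaluations=[
                        dx_evaluation(age=40),
                        Evaluation(age_months=40, conclusion="asd-ruled-out"),
                    ]
                )
            ]
        )
        assert diagnosis_history(merged)[3] is False

    def test_reported_prior_age_defines_earliest_diagnosis(self):
        merged = merge_child_records(
            [health_record(evaluations=[dx_evaluation(age=50, prior=38)])]
        )
        assert diagnosis_history(merged)[0] == 38

    def test_sped_eligibility_age_anchors_more_recent_comparison(self):
        merged = merge_child_records(
            [
                education_record(age=80),
                health_record(evaluations=[Evaluation(age_months=60, conclusion="asd-ruled-out")]),
            ]
        )
        assert diagnosis_history(merged)[3] is False


class TestEarliestEvaluation:
    def test_minimum_and_inclusive_boundary(self):
        merged = merge_child_records(
            [
                health_record(
                    evaluations=[
                        Evaluation(age_months=48, conclusion="other"),
                        Evaluation(age_months=36, conclusion="asd-suspected"),
                    ]
                )
            ]
        )
        age = earliest_evaluation_age(merged)
        assert age == 36
        assert age <= 36  # by-36-months flag boundary is inclusive

    def test_no_evaluations_returns_none(self):
        merged = merge_child_records([health_record(icd_codes=[("F84.0", 40)])])
        assert earliest_evaluation_age(merged) is None

    def test_single_late_evaluation(self):
        merged = merge_child_records(
            [health_record(evaluations=[Evaluation(age_months=37, conclusion="other")])]
        )
        assert earliest_evaluation_age(merged) == 37


class TestCognitive:
    def test_most_recent_entry_wins(self):
        merged = merge_child_records(
            [
                health_record(
                    cognitive=[
                        CognitiveAssessment(age_months=60, kind="test-score", iq_score=65),
                        CognitiveAssessment(age_months=80, kind="test-score", iq_score=90),
                    ]
                )
            ]
        )
        assert classify_cognitive(merged) == ">85"

    @pytest.mark.parametrize("score, band", [(70, "<=70"), (71, "71-85"), (85, "71-85"), (86, ">85")])
    def test_band_boundaries(self, score, band):
        merged = merge_child_records(
            [health_record(cognitive=[CognitiveAssessment(age_months=70, kind="test-score", iq_score=score)])]
        )
        assert classify_cognitive(merged) == band

    def test_examiner_statement_alone_suffices(self):
        merged = merge_child_records(
            [
                health_record(
                    cognitive=[
                        CognitiveAssessment(
                            age_months=66, kind="examiner-statement", stated_band="71-85"
                        )
                    ]
                )
            ]
        )
        assert classify_cognitive(merged) == "71-85"

    def test_equal_age_tie_prefers_test_score(self):
        merged = merge_child_records(
            [
                health_record(
                    cognitive=[
                        CognitiveAssessment(
                            age_months=66, kind="examiner-statement", stated_band=">85"
                        ),
                        CognitiveAssessment(age_months=66, kind="test-score", iq_score=64),
                    ]
                )
            ]
        )
        assert classify_cognitive(merged) == "<=70"

    def test_no_cognitive_data_returns_none(self):
        assert classify_cognitive(merge_child_records([health_record()])) is None


# -- identification regions ----------------------------------------------------

def _status(dx, sped, icd):
    region = {
        (True, False, False): "dx-only",
        (False, True, False): "sped-only",
        (False, False, True): "icd-only",
        (True, True, False): "dx+sped",
        (True, False, True): "dx+icd",
        (False, True, True): "sped+icd",
        (True, True, True): "all-three",
    }[(dx, sped, icd)]
    return CaseStatus(
        child_id="x",
        has_dx_statement=dx,
        has_sped=sped,
        has_icd=icd,
        is_case=True,
        region=region,
        earliest_dx_age_months=None,
        earliest_eval_age_months=None,
        suspected_ever=False,
        ruled_out_ever=False,
        ruled_out_more_recent=False,
        cognitive_band=None,
    )


class TestIdentificationRegions:
    def test_all_three_counts_toward_multi_type(self):
        summary = identification_regions([_status(True, True, True)])
        assert summary.counts["all-three"] == 1
        assert summary.pct_two_or_more == 100.0

    def test_icd_only_region(self):
        summary = identification_regions([_status(False, False, True)])
        assert summary.counts["icd-only"] == 1
        assert summary.pct_icd_only == 100.0

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.booleans(), st.booleans(), st.booleans()), min_size=1, max_size=40))
    def test_partition_identity(self, flag_sets):
        statuses = [_status(*flags) for flags in flag_sets if any(flags)]
        if not statuses:
            return
        summary = identification_regions(statuses)
        assert sum(summary.counts.values()) == len(statuses)
        assert summary.pct_any_dx + summary.pct_sped_no_dx + summary.pct_icd_only == pytest.approx(100.0)

    def test_non_case_rejected(self):
        bad = _status(True, False, False)
        bad.is_case = False
        with pytest.raises(ValidationError):
            identification_regions([bad])
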