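"""Case detection, onset timing, R-value patterns and severity grading."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from dilipipe import (
    Cohort,
    FoldSet,
    LabVisit,
    MissingBaselineError,
    PatientRecord,
    adjudicate_cohort,
    adjudicate_patient,
    classify_pattern,
    compute_r,
    fold_elevations,
    grade_severity,
    meets_case_definition,
    published_uln,
)
from dilipipe.adjudicate import (
    ALP_RULE,
    ALT_RULE,
    BASELINE_ELEVATED,
    BASELINE_NORMAL,
    BASELINE_RELATIVE_SCALE,
    CHOLESTATIC,
    HEPATOCELLULAR,
    HY_RULE,
    MIXED,
    ULN_SCALE,
)
from dilipipe.simulate import SimConfig, generate_cohort

ULN = published_uln()


def folds(alt=None, alp=None, tbil=None):
    return FoldSet(alt_fold=alt, alp_fold=alp, tbil_fold=tbil,
                   alt_branch=BASELINE_NORMAL, alp_branch=BASELINE_NORMAL)


def male_patient(panels, baseline=(20.0, 100.0), flags=(), pid="P1"):
    """panels: {week: (alt, alp, tbil)}; baseline: (alt, alp) at week 0."""
    visits = [LabVisit(pid, 0.0, alt=baseline[0], ast=25.0, alp=baseline[1], tbil=0.5, dbil=0.1)]
    for week, (alt, alp, tbil) in sorted(panels.items()):
        visits.append(LabVisit(pid, float(week), alt=alt, ast=None, alp=alp, tbil=tbil, dbil=None))
    return PatientRecord(patient_id=pid, arm="Arm4", sex="male",
                         haart_regimen="none", clinical_flags=frozenset(flags),
                         visits=visits)


class TestFoldElevations:
    def test_baseline_normal_uses_uln(self):
        p = male_patient({1: (165.0, 128.0, 1.0)})
        f = fold_elevations(p.visits[1], p.baseline(), ULN, "male")
        assert f.alt_fold == pytest.approx(5.0)  # 165 / 33
        assert f.alt_branch == BASELINE_NORMAL

    def test_baseline_elevated_uses_baseline(self):
        p = male_patient({1: (260.0, 128.0, 1.0)}, baseline=(50.0, 100.0))
        f = fold_elevations(p.visits[1], p.baseline(), ULN, "male")
        assert f.alt_fold == pytest.approx(260.0 / 50.0)  # 5.2 vs baseline
        assert f.alt_branch == BASELINE_ELEVATED
        assert f.alp_branch == BASELINE_NORMAL  # branches chosen per analyte

    def test_tbil_fold_always_vs_uln(self):
        p = male_patient({1: (20.0, 100.0, 2.0)})
        f = fold_elevations(p.visits[1], p.baseline(), ULN, "male")
        assert f.tbil_fold == pytest.approx(2.0)


class TestCaseDefinition:
    @pytest.mark.parametrize(
        "alt,alp,tbil,expect",
        [
            (5.0, 1.0, 1.0, (True, ALT_RULE)),    # inclusive ALT boundary
            (1.0, 2.0, 1.0, (True, ALP_RULE)),    # inclusive ALP boundary
            (3.0, 1.5, 2.0, (True, HY_RULE)),     # combination rule
            (4.9, 1.9, 1.9, (False, None)),       # just below all three
            (5.0, 2.0, 2.0, (True, ALT_RULE)),    # fixed rule order
            (None, 2.5, None, (True, ALP_RULE)),  # missing ALT ignored
            (None, None, 3.0, (False, None)),     # bilirubin alone never qualifies
        ],
    )
    def test_rule_table(self, alt, alp, tbil, expect):
        assert meets_case_definition(folds(alt, alp, tbil)) == expect

    def test_exhaustive_grid_below_thresholds(self):
        # no (alt, alp, tbil) strictly below (5, 2, 2) with alt < 3 qualifies
        for alt, alp, tbil in itertools.product((0.5, 2.9, 4.9), (0.5, 1.9), (0.5, 1.9)):
            hit, _ = meets_case_definition(folds(alt, alp, tbil))
            assert hit == (alt >= 3 and tbil >= 2)


class TestRValue:
    def test_hepatocellular_example(self):
        v = LabVisit("P", 1.0, alt=165.0, alp=128.0)
        assert compute_r(v, ULN, "male") == pytest.approx(5.0)
        assert classify_pattern(5.0) == HEPATOCELLULAR

    def test_equal_folds_are_cholestatic(self):
        v = LabVisit("P", 1.0, alt=66.0, alp=256.0)
        assert compute_r(v, ULN, "male") == pytest.approx(1.0)

    def test_mixed_example(self):
        v = LabVisit("P", 1.0, alt=198.0, alp=256.0)
        assert compute_r(v, ULN, "male") == pytest.approx(3.0)  # 6 / 2
        assert classify_pattern(3.0) == MIXED

    @pytest.mark.parametrize(
        "r,pattern",
        [(0.0, CHOLESTATIC), (2.0, CHOLESTATIC), (2.0000001, MIXED),
         (3.7, MIXED), (4.9999, MIXED), (5.0, HEPATOCELLULAR), (1e6, HEPATOCELLULAR)],
    )
    def test_boundaries(self, r, pattern):
        assert classify_pattern(r) == pattern

    @given(st.floats(min_value=0, max_value=1e9, allow_nan=False))
    def test_partition_totality(self, r):
        """Every non-negative R falls in exactly one pattern class."""
        claims = [r <= 2, 2 < r < 5, r >= 5]
        assert sum(claims) == 1
        assert classify_pattern(r) == [CHOLESTATIC, MIXED, HEPATOCELLULAR][claims.index(True)]


class TestGradeSeverity:
    @pytest.mark.parametrize(
        "alt,alp,scale,expect",
        [
            (1.0, 2.1, ULN_SCALE, 1),        # below 2.5x band
            (2.6, 1.0, ULN_SCALE, 2),
            (5.0, 1.0, ULN_SCALE, 3),
            (10.0, 1.0, ULN_SCALE, 4),
            (3.6, 1.0, BASELINE_RELATIVE_SCALE, 3),  # compressed bands
            (5.0, 1.0, BASELINE_RELATIVE_SCALE, 4),
            (None, 2.1, ULN_SCALE, 1),       # ALP alone drives the band
        ],
    )
    def test_band_grades(self, alt, alp, scale, expect):
        assert grade_severity(folds(alt, alp, 1.0), frozenset(), scale) == expect

    def test_bilirubin_escalates_to_two(self):
        assert grade_severity(folds(1.0, 2.1, 2.0), frozenset(), ULN_SCALE) == 2

    def test_bilirubin_plus_inr_escalates_to_three(self):
        assert grade_severity(folds(1.0, 2.1, 2.0), {"inr_ge_1_5"}, ULN_SCALE) == 3

    def test_death_or_transplant_is_grade_four(self):
        for scale in (ULN_SCALE, BASELINE_RELATIVE_SCALE):
            g = grade_severity(folds(1.0, 2.1, 1.0), {"death_or_transplant_due_to_dili"}, scale)
            assert g == 4

    def test_flag_without_bilirubin_does_not_escalate(self):
        assert grade_severity(folds(1.0, 2.1, 1.0), {"ascites"}, ULN_SCALE) == 1

    def test_band_never_below_one(self):
        assert grade_severity(folds(0.5, 2.0, 1.0), frozenset(), ULN_SCALE) == 1

    def test_grade_invariant_to_flag_iteration_order(self):
        flag_list = ["inr_ge_1_5", "ascites", "encephalopathy"]
        grades = {
            grade_severity(folds(1.0, 2.1, 2.5), perm, ULN_SCALE)
            for perm in itertools.permutations(flag_list)
        }
        assert grades == {3}


class TestAdjudicatePatient:
    def test_all_normal_is_noncase(self):
        p = male_patient({1: (30.0, 110.0, 0.6), 4: (35.0, 120.0, 0.8)})
        call = adjudicate_patient(p, ULN)
        assert not call.is_case and call.onset_week is None
        assert call.censor_week == 4.0  # min(last followup, cutoff)

    def test_first_crossing_sets_onset(self):
        p = male_patient({1: (30.0, 110.0, 0.6), 2: (170.0, 110.0, 0.6), 4: (170.0, 110.0, 0.6)})
        call = adjudicate_patient(p, ULN)
        assert call.is_case and call.onset_week == 2.0

    def test_pattern_and_grade_at_qualifying_visit(self):
        p = male_patient({2: (170.0, 110.0, 0.6)})
        call = adjudicate_patient(p, ULN)
        assert call.pattern == HEPATOCELLULAR
        assert call.grade == 3  # 170/33 = 5.15x in the 5-10x band
        assert call.grading_scale == ULN_SCALE

    def test_baseline_elevated_patient_uses_relative_scale(self):
        p = male_patient({2: (260.0, 110.0, 0.6)}, baseline=(50.0, 100.0))
        call = adjudicate_patient(p, ULN)
        assert call.is_case and call.grading_scale == BASELINE_RELATIVE_SCALE
        assert call.grade == 4  # 5.2x baseline on the compressed scale

    def test_visits_beyond_censor_week_ignored(self):
        p = male_patient({48: (170.0, 110.0, 0.6)})
        assert not adjudicate_patient(p, ULN, censor_week=24.0).is_case
        assert adjudicate_patient(p, ULN, censor_week=48.0).is_case

    def test_missing_alp_at_qualifying_visit_is_unclassifiable(self):
        p = male_patient({2: (170.0, None, 0.6)})
        call = adjudicate_patient(p, ULN)
        assert call.is_case and call.pattern == "unclassifiable" and call.r_value is None
        assert call.grade == 3

    def test_missing_baseline_propagates(self):
        p = male_patient({2: (170.0, 110.0, 0.6)})
        p.visits = p.visits[1:]
        with pytest.raises(MissingBaselineError):
            adjudicate_patient(p, ULN)

    def test_onset_minimality(self):
        """No visit strictly earlier than onset satisfies the case definition."""
        p = male_patient({1: (80.0, 110.0, 0.6), 2: (100.0, 200.0, 0.6), 4: (170.0, 300.0, 2.5)})
        call = adjudicate_patient(p, ULN)
        assert call.onset_week == 4.0
        base = p.baseline()
        for v in p.visits:
            if 0 < v.week < call.onset_week:
                hit, _ = meets_case_definition(fold_elevations(v, base, ULN, p.sex))
                assert not hit

    def test_monotone_under_uniform_enzyme_scaling(self):
        """Scaling all post-baseline ALT/ALP by growing lambda >= 1 never
        un-makes a case, never delays onset, and never lowers the grade
        (onset pinned by a single post-baseline visit)."""
        cases, grades = [], []
        for lam in (1.0, 1.3, 1.8, 2.5, 5.0, 10.0):
            p = male_patient({2: (100.0 * lam, 150.0 * lam, 0.6)})
            call = adjudicate_patient(p, ULN)
            cases.append(call.is_case)
            grades.append(call.grade or 0)
        assert cases == sorted(cases)
        assert grades == sorted(grades)

    def test_scaling_can_only_advance_onset(self):
        p1 = male_patient({2: (100.0, 200.0, 0.6), 4: (170.0, 110.0, 0.6)})
        before = adjudicate_patient(p1, ULN)
        for v in p1.visits:
            if v.week > 0:
                v.alt, v.alp = v.alt * 1.5, v.alp * 1.5
        after = adjudicate_patient(p1, ULN)
        assert before.is_case and after.is_case
        assert after.onset_week <= before.onset_week


# ---------------------------------------------------------------------------
# brute-force oracle: test every (visit, rule) pair exhaustively
# ---------------------------------------------------------------------------


def brute_force_call(patient, uln, censor_week=24.0):
    base = next(v for v in patient.visits if v.week == 0)
    uln_alt = uln.alt_female if patient.sex == "female" else uln.alt_male
    alt_ref = base.alt if (base.alt is not None and base.alt > uln_alt) else uln_alt
    alp_ref = base.alp if (base.alp is not None and base.alp > uln.alp) else uln.alp
    hits = []
    for v in patient.visits:
        if not 0 < v.week <= censor_week:
            continue
        if v.alt is not None and v.alt / alt_ref >= 5:
            hits.append((v.week, "alt_rule"))
        elif v.alp is not None and v.alp / alp_ref >= 2:
            hits.append((v.week, "alp_rule"))
        elif (v.alt is not None and v.tbil is not None
              and v.alt / alt_ref >= 3 and v.tbil / uln.tbil >= 2):
            hits.append((v.week, "hy_combination_rule"))
    if not hits:
        return (False, None, None)
    week, rule = min(hits)
    return (True, week, rule)


def test_adjudication_matches_brute_force_on_small_cohorts(uln):
    """Exhaustive (visit, rule) re-implementation agrees on generated cohorts."""
    for seed in range(3):
        cfg = SimConfig(seed=seed, n_per_arm=(12, 13, 12, 13),
                        event_prob_per_arm=(0.5, 0.5, 0.5, 0.5))
        cohort, _ = generate_cohort(cfg)
        calls = {c.patient_id: c for c in adjudicate_cohort(cohort, uln).calls}
        for p in cohort:
            is_case, onset, rule = brute_force_call(p, uln)
            call = calls[p.patient_id]
            assert call.is_case == is_case
            assert call.onset_week == onset
            assert call.qualifying_criterion == rule


class TestAdjudicateCohort:
    def test_single_noncase(self, uln):
        cohort = Cohort(patients=[male_patient({1: (30.0, 110.0, 0.6)})])
        result = adjudicate_cohort(cohort, uln)
        assert len(result.calls) == 1 and result.n_cases == 0

    def test_one_case_per_pattern(self, uln):
        patients = [
            male_patient({1: (170.0, 110.0, 0.6)}, pid="HEP"),   # R = 5.99
            male_patient({1: (100.0, 300.0, 0.6)}, pid="CHO"),   # R = 1.29
            male_patient({1: (300.0, 300.0, 0.6)}, pid="MIX"),   # R = 3.88
            male_patient({1: (30.0, 110.0, 0.6)}, pid="NON"),
        ]
        calls = {c.patient_id: c for c in adjudicate_cohort(Cohort(patients=patients), uln).calls}
        assert calls["HEP"].pattern == HEPATOCELLULAR
        assert calls["CHO"].pattern == CHOLESTATIC
        assert calls["MIX"].pattern == MIXED
        assert not calls["NON"].is_case

    def test_per_patient_errors_collected_not_fatal(self, uln):
        good = male_patient({1: (30.0, 110.0, 0.6)}, pid="OK")
        bad = male_patient({2: (170.0, 110.0, 0.6)}, pid="NOBASE")
        bad.visits = bad.visits[1:]
        result = adjudicate_cohort(Cohort(patients=[good, bad]), uln)
        assert [c.patient_id for c in result.calls] == ["OK"]
        assert "NOBASE" in result.errors
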