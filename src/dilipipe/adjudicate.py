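"""Per-patient DILI adjudication: case detection, onset, pattern, grade.

The case definition follows the international DILI expert working group
consensus, with a two-branch reference choice per analyte:

* baseline-normal branch — the analyte's pre-treatment value is at or
  below its ULN, and on-treatment elevations are read as multiples of the
  ULN;
* baseline-elevated branch — the pre-treatment value already exceeds the
  ULN, and elevations are read as multiples of the patient's own baseline
  (avoids labelling chronic elevation as treatment-emergent injury).

A visit qualifies when ALT reaches 5x its reference, ALP reaches 2x its
reference, or ALT reaches 3x together with total bilirubin at 2x its ULN
(the Hy's-law-like combination).  Injury pattern at the qualifying visit
comes from the R-value, R = (ALT/ULN_ALT) / (ALP/ULN_ALP): R <= 2
cholestatic, 2 < R < 5 mixed, R >= 5 hepatocellular.  Severity is graded
1-4 on the ULN scale (baseline-normal patients) or on a compressed
baseline-relative scale (baseline-elevated patients), with clinical
escalation for hyperbilirubinaemia, coagulopathy/decompensation flags,
and death or transplantation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .cohort import Cohort, LabVisit, MissingBaselineError, PatientRecord
from .reference import ULNSet

BASELINE_NORMAL = "baseline_normal"
BASELINE_ELEVATED = "baseline_elevated"

ALT_RULE = "alt_rule"
ALP_RULE = "alp_rule"
HY_RULE = "hy_combination_rule"

CHOLESTATIC = "cholestatic"
MIXED = "mixed"
HEPATOCELLULAR = "hepatocellular"
UNCLASSIFIABLE = "unclassifiable"
PATTERNS = (CHOLESTATIC, MIXED, HEPATOCELLULAR)

ULN_SCALE = "uln_scale"
BASELINE_RELATIVE_SCALE = "baseline_relative_scale"

#: Flags that escalate a hyperbilirubinaemic case to at least grade 3.
_GRADE3_FLAGS = frozenset(
    {"inr_ge_1_5", "ascites", "encephalopathy", "other_organ_failure"}
)
_GRADE4_FLAG = "death_or_transplant_due_to_dili"

#: Default analysis cutoff: completion of anti-TB therapy.
DEFAULT_CENSOR_WEEK = 24.0


@dataclass(frozen=True)
class FoldSet:
    """Per-analyte fold elevations at one visit.

    ``alt_fold``/``alp_fold`` are multiples of that analyte's reference
    (ULN or the patient's baseline, per branch); ``tbil_fold`` is always a
    multiple of the total-bilirubin ULN.  ``None`` marks a missing analyte.
    """

    alt_fold: Optional[float]
    alp_fold: Optional[float]
    tbil_fold: Optional[float]
    alt_branch: Optional[str]
    alp_branch: Optional[str]


@dataclass
class DILICall:
    """Adjudication outcome for one patient."""

    patient_id: str
    is_case: bool
    censor_week: float
    onset_week: Optional[float] = None
    qualifying_criterion: Optional[str] = None
    alt_branch: Optional[str] = None
    alp_branch: Optional[str] = None
    r_value: Optional[float] = None
    pattern: Optional[str] = None
    grade: Optional[int] = None
    grading_scale: Optional[str] = None


def _branch_and_reference(
    baseline_value: Optional[float], uln_value: float
) -> tuple[str, float]:
    if baseline_value is not None and baseline_value > uln_value:
        return BASELINE_ELEVATED, baseline_value
    return BASELINE_NORMAL, uln_value


def fold_elevations(
    visit: LabVisit, baseline: LabVisit, uln: ULNSet, sex: str
) -> FoldSet:
    """Fold elevations of ALT/ALP vs their branch reference and TBIL vs ULN."""
    alt_branch, alt_ref = _branch_and_reference(baseline.alt, uln.alt(sex))
    alp_branch, alp_ref = _branch_and_reference(baseline.alp, uln.alp)
    if not alt_ref > 0 or not alp_ref > 0 or not uln.tbil > 0:
        raise ValueError("nonpositive reference value")
    return FoldSet(
        alt_fold=None if visit.alt is None else visit.alt / alt_ref,
        alp_fold=None if visit.alp is None else visit.alp / alp_ref,
        tbil_fold=None if visit.tbil is None else visit.tbil / uln.tbil,
        alt_branch=None if visit.alt is None else alt_branch,
        alp_branch=None if visit.alp is None else alp_branch,
    )


def meets_case_definition(folds: FoldSet) -> tuple[bool, Optional[str]]:
    """Test the three case rules in fixed order (ALT, ALP, combination).

    Thresholds are inclusive: ALT >= 5x, ALP >= 2x, or ALT >= 3x with
    total bilirubin >= 2x ULN.
    """
    alt, alp, tb = folds.alt_fold, folds.alp_fold, folds.tbil_fold
    if alt is not None and alt >= 5:
        return True, ALT_RULE
    if alp is not None and alp >= 2:
        return True, ALP_RULE
    if alt is not None and alt >= 3 and tb is not None and tb >= 2:
        return True, HY_RULE
    return False, None


def compute_r(visit: LabVisit, uln: ULNSet, sex: str) -> float:
    """R-value: ULN-normalised ALT over ULN-normalised ALP.

    Always uses ULN normalisation, including for baseline-elevated
    patients — R describes the biochemical signature of the injury, not
    its treatment-emergence.
    """
    if visit.alt is None or visit.alp is None:
        raise ValueError("R-value requires ALT and ALP at the visit")
    return (visit.alt / uln.alt(sex)) / (visit.alp / uln.alp)


def classify_pattern(r: float) -> str:
    """Partition R into cholestatic (R<=2), mixed (2<R<5), hepatocellular (R>=5)."""
    if r < 0:
        raise ValueError("R-value must be >= 0")
    if r <= 2:
        return CHOLESTATIC
    if r >= 5:
        return HEPATOCELLULAR
    return MIXED


# Severity bands as contiguous half-open intervals on the driving fold.
# ULN scale: [_,2.5) -> 1, [2.5,5) -> 2, [5,10) -> 3, [10,inf) -> 4.
# Baseline-relative scale: [_,2.5) -> 1, [2.5,3.5) -> 2, [3.5,5) -> 3, [5,inf) -> 4.
_BANDS = {
    ULN_SCALE: ((2.5, 1), (5.0, 2), (10.0, 3), (float("inf"), 4)),
    BASELINE_RELATIVE_SCALE: ((2.5, 1), (3.5, 2), (5.0, 3), (float("inf"), 4)),
}


def grade_severity(
    folds: FoldSet,
    clinical_flags: Iterable[str],
    grading_scale: str,
) -> int:
    """Severity grade 1-4 for a patient already meeting the case definition.

    The band grade is driven by the larger of the ALT and ALP folds (each
    vs its branch reference); a case whose driving fold sits below the
    grade-1 floor (possible when the ALP rule fired the case) is clamped
    to grade 1.  Clinical escalation: TBIL >= 2x ULN forces at least
    grade 2; with any of INR >= 1.5, ascites, encephalopathy or other
    organ failure, at least grade 3; death or transplantation due to the
    injury is grade 4 outright.
    """
    if grading_scale not in _BANDS:
        raise ValueError(f"unknown grading scale {grading_scale!r}")
    flags = frozenset(clinical_flags)
    present = [f for f in (folds.alt_fold, folds.alp_fold) if f is not None]
    driving = max(present) if present else 0.0
    band = 4
    for upper, g in _BANDS[grading_scale]:
        if driving < upper:
            band = g
            break

    escalation = 1
    tb = folds.tbil_fold
    if tb is not None and tb >= 2:
        escalation = 3 if flags & _GRADE3_FLAGS else 2
    if _GRADE4_FLAG in flags:
        escalation = 4
    return max(band, escalation)


def adjudicate_patient(
    patient: PatientRecord,
    uln: ULNSet,
    censor_week: float = DEFAULT_CENSOR_WEEK,
) -> DILICall:
    """Scan post-baseline visits in week order; the first qualifying visit
    fixes onset, pattern and grade.

    Visits missing both ALT and ALP contribute nothing.  If ALT or ALP is
    absent at the qualifying visit the case keeps its grade (from the
    available fold) but the pattern is marked unclassifiable.
    """
    base = patient.baseline()  # raises MissingBaselineError if absent
    followup = patient.last_followup_week
    if followup is None:
        followup = max((v.week for v in patient.visits), default=0.0)
    at_risk_end = min(followup, censor_week)

    scale = ULN_SCALE
    if (base.alt is not None and base.alt > uln.alt(patient.sex)) or (
        base.alp is not None and base.alp > uln.alp
    ):
        scale = BASELINE_RELATIVE_SCALE

    for visit in sorted(patient.visits, key=lambda v: v.week):
        if visit.week <= 0 or visit.week > censor_week:
            continue
        if visit.alt is None and visit.alp is None:
            continue
        folds = fold_elevations(visit, base, uln, patient.sex)
        hit, criterion = meets_case_definition(folds)
        if not hit:
            continue
        if visit.alt is not None and visit.alp is not None:
            r = compute_r(visit, uln, patient.sex)
            pattern = classify_pattern(r)
        else:
            r, pattern = None, UNCLASSIFIABLE
        grade = grade_severity(folds, patient.clinical_flags, scale)
        return DILICall(
            patient_id=patient.patient_id,
            is_case=True,
            censor_week=at_risk_end,
            onset_week=visit.week,
            qualifying_criterion=criterion,
            alt_branch=folds.alt_branch,
            alp_branch=folds.alp_branch,
            r_value=r,
            pattern=pattern,
            grade=grade,
            grading_scale=scale,
        )
    return DILICall(
        patient_id=patient.patient_id, is_case=False, censor_week=at_risk_end
    )


@dataclass
class AdjudicationResult:
    """Batch outcome: one call per adjudicable patient, plus failures."""

    calls: list[DILICall]
    errors: dict[str, str]

    @property
    def n_cases(self) -> int:
        return sum(c.is_case for c in self.calls)


def adjudicate_cohort(
    cohort: Cohort,
    uln: ULNSet,
    censor_week: float = DEFAULT_CENSOR_WEEK,
) -> AdjudicationResult:
    """Adjudicate every patient; per-patient errors are collected, not fatal."""
    calls: list[DILICall] = []
    errors: dict[str, str] = {}
    for patient in cohort:
        try:
            calls.append(adjudicate_patient(patient, uln, censor_week=censor_week))
        except MissingBaselineError as exc:
            errors[patient.patient_id] = str(exc)
    return AdjudicationResult(calls=calls, errors=errors)


def calls_to_rows(calls: Sequence[DILICall]) -> list[dict]:
    """Flatten calls for tabular output (CSV / DataFrame)."""
    return [
        {
            "patient_id": c.patient_id,
            "is_case": c.is_case,
            "onset_week": c.onset_week,
            "qualifying_criterion": c.qualifying_criterion,
            "r_value": c.r_value,
            "pattern": c.pattern,
            "grade": c.grade,
            "grading_scale": c.grading_scale,
            "censor_week": c.censor_week,
        }
        for c in calls
    ]
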