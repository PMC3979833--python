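"""Reported count structure of the Ethiopian four-arm cohort.

The synthetic generator's defaults emulate a published prospective
four-arm cohort (HIV on HAART / TB-HIV on HAART + anti-TB / TB-HIV on
anti-TB / TB on anti-TB).  This module carries that cohort's reported
marginal counts — arm sizes, cases per arm, and the pattern and grade
breakdowns — so incidence tables and odds ratios can be recomputed from
the counts themselves, e.g. to check a reimplementation or to benchmark
a synthetic cohort against the real one.
"""

from __future__ import annotations

from .adjudicate import CHOLESTATIC, DILICall, HEPATOCELLULAR, MIXED
from .cohort import ARMS, Cohort, PatientRecord

#: Patients enrolled per arm.
ARM_SIZES = (273, 495, 83, 209)

#: Adjudicated DILI cases per arm.
CASES_PER_ARM = (24, 120, 9, 6)

#: Injury-pattern counts per arm (rows sum to the arm's cases).
PATTERN_COUNTS = {
    CHOLESTATIC: (17, 70, 6, 4),
    HEPATOCELLULAR: (3, 18, 2, 1),
    MIXED: (4, 32, 1, 1),
}

#: Severity-grade counts per arm (rows sum to the arm's cases).
GRADE_COUNTS = {
    1: (17, 65, 2, 1),
    2: (5, 35, 7, 5),
    3: (2, 16, 0, 0),
    4: (0, 4, 0, 0),
}


def reported_cohort_calls() -> tuple[Cohort, list[DILICall]]:
    """Rebuild a cohort skeleton and per-patient calls from the reported
    marginal counts.

    Only arm membership, case status, pattern and grade are populated
    (the joint pattern x grade assignment within an arm is arbitrary:
    the reported tables are marginals, and the incidence/odds-ratio
    operations only consume marginals).
    """
    patients: list[PatientRecord] = []
    calls: list[DILICall] = []
    for arm_idx, arm in enumerate(ARMS):
        n, n_cases = ARM_SIZES[arm_idx], CASES_PER_ARM[arm_idx]
        patterns = [
            p for p, row in PATTERN_COUNTS.items() for _ in range(row[arm_idx])
        ]
        grades = [g for g, row in GRADE_COUNTS.items() for _ in range(row[arm_idx])]
        assert len(patterns) == len(grades) == n_cases
        for k in range(n):
            pid = f"{arm}-{k:04d}"
            patients.append(
                PatientRecord(
                    patient_id=pid,
                    arm=arm,
                    sex="female",
                    haart_regimen="D4T/3TC/EFV" if arm in ("Arm1", "Arm2") else "none",
                )
            )
            if k < n_cases:
                calls.append(
                    DILICall(
                        patient_id=pid,
                        is_case=True,
                        censor_week=24.0,
                        onset_week=1.0,
                        pattern=patterns[k],
                        grade=grades[k],
                    )
                )
            else:
                calls.append(DILICall(patient_id=pid, is_case=False, censor_week=24.0))
    return Cohort(patients=patients), calls
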