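"""Domain model and CSV round-trip for longitudinal liver-panel cohorts.

A cohort is a collection of patients, each carrying an arm assignment,
baseline covariates, clinical flags, and an ordered series of liver-panel
visits (ALT, AST, ALP, total and direct bilirubin) on the scheduled
monitoring grid 0, 1, 2, 4, 8, 12, 24 and 48 weeks after treatment start.

Storage is a two-file long format mirroring the repeated-measures
structure: ``patients.csv`` (one row per patient) and ``visits.csv`` (one
row per panel).  Missing analytes are empty cells; numeric text is written
with full ``repr`` precision so that write → read is an exact identity.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

ARMS = ("Arm1", "Arm2", "Arm3", "Arm4")
SEXES = ("female", "male")
HAART_REGIMENS = ("D4T/3TC/EFV", "AZT/3TC/EFV", "TDF/3TC/EFV", "none")

#: Clinical flags recorded on the patient, used by severity escalation.
CLINICAL_FLAGS = frozenset(
    {
        "inr_ge_1_5",
        "ascites",
        "encephalopathy",
        "other_organ_failure",
        "cirrhosis",
        "death_or_transplant_due_to_dili",
    }
)

#: Scheduled liver-panel weeks (monitoring at baseline then on therapy).
SCHEDULED_WEEKS = (0.0, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0, 48.0)

PATIENT_COLUMNS = (
    "patient_id",
    "arm",
    "sex",
    "age",
    "bmi",
    "karnofsky",
    "hbsag",
    "hcv_ab",
    "cd4",
    "log_viral_load",
    "hemoglobin",
    "wbc",
    "neutrophil",
    "platelet",
    "albumin",
    "creatinine",
    "urea",
    "haart_regimen",
    "clinical_flags",
    "last_followup_week",
)
VISIT_COLUMNS = ("patient_id", "week", "alt", "ast", "alp", "tbil", "dbil")

ANALYTES = ("alt", "ast", "alp", "tbil", "dbil")


class CohortError(Exception):
    """Base class for cohort-layer failures."""


class SchemaError(CohortError):
    """A CSV file does not carry the documented columns."""


class CohortValidationError(CohortError):
    """One or more rows violate a cohort invariant.

    ``problems`` lists every violation found, not only the first.
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        preview = "\n  ".join(self.problems[:25])
        more = "" if len(self.problems) <= 25 else f"\n  ... {len(self.problems) - 25} more"
        super().__init__(f"{len(self.problems)} validation problem(s):\n  {preview}{more}")


class MissingBaselineError(CohortError):
    """Patient has no week-0 liver panel."""


@dataclass
class LabVisit:
    """One liver-panel measurement at a scheduled week for one patient.

    Enzyme activities (ALT, AST, ALP) are U/L; bilirubins (total, direct)
    mg/dL.  ``None`` marks a missing analyte.
    """

    patient_id: str
    week: float
    alt: Optional[float] = None
    ast: Optional[float] = None
    alp: Optional[float] = None
    tbil: Optional[float] = None
    dbil: Optional[float] = None

    def problems(self) -> list[str]:
        out = []
        tag = f"visit ({self.patient_id}, week {self.week})"
        if self.week < 0:
            out.append(f"{tag}: week must be >= 0")
        for name in ANALYTES:
            v = getattr(self, name)
            if v is not None and not v > 0:
                out.append(f"{tag}: {name} must be > 0 when present, got {v}")
        if self.dbil is not None and self.tbil is not None and self.dbil > self.tbil:
            out.append(f"{tag}: direct bilirubin {self.dbil} exceeds total {self.tbil}")
        return out


@dataclass
class PatientRecord:
    """Arm assignment, sex, baseline covariates, flags and visit series."""

    patient_id: str
    arm: str
    sex: str
    age: Optional[float] = None
    bmi: Optional[float] = None
    karnofsky: Optional[float] = None
    hbsag: bool = False
    hcv_ab: bool = False
    cd4: Optional[float] = None
    log_viral_load: Optional[float] = None
    hemoglobin: Optional[float] = None
    wbc: Optional[float] = None
    neutrophil: Optional[float] = None
    platelet: Optional[float] = None
    albumin: Optional[float] = None
    creatinine: Optional[float] = None
    urea: Optional[float] = None
    haart_regimen: str = "none"
    clinical_flags: frozenset[str] = field(default_factory=frozenset)
    visits: list[LabVisit] = field(default_factory=list)
    last_followup_week: Optional[float] = None

    def __post_init__(self) -> None:
        self.clinical_flags = frozenset(self.clinical_flags)
        if self.last_followup_week is None and self.visits:
            self.last_followup_week = max(v.week for v in self.visits)

    # -- accessors -------------------------------------------------------

    def baseline(self) -> LabVisit:
        """Return the week-0 panel; raise :class:`MissingBaselineError` if absent."""
        for v in self.visits:
            if v.week == 0:
                return v
        raise MissingBaselineError(f"patient {self.patient_id} has no week-0 panel")

    def has_baseline(self) -> bool:
        return any(v.week == 0 for v in self.visits)

    # -- validation ------------------------------------------------------

    def problems(self, require_baseline: bool = False) -> list[str]:
        out = []
        pid = self.patient_id
        if self.arm not in ARMS:
            out.append(f"patient {pid}: unknown arm {self.arm!r}")
        if self.sex not in SEXES:
            out.append(f"patient {pid}: unknown sex {self.sex!r}")
        if self.haart_regimen not in HAART_REGIMENS:
            out.append(f"patient {pid}: unknown haart_regimen {self.haart_regimen!r}")
        if self.arm in ("Arm3", "Arm4") and self.haart_regimen != "none":
            out.append(f"patient {pid}: arm {self.arm} must have haart_regimen 'none'")
        if self.arm in ("Arm1", "Arm2") and self.haart_regimen == "none":
            out.append(f"patient {pid}: arm {self.arm} requires a HAART regimen")
        if self.arm == "Arm4" and (self.cd4 is not None or self.log_viral_load is not None):
            out.append(f"patient {pid}: CD4/viral load present for HIV-negative arm Arm4")
        unknown = self.clinical_flags - CLINICAL_FLAGS
        if unknown:
            out.append(f"patient {pid}: unknown clinical flags {sorted(unknown)}")
        weeks = [v.week for v in self.visits]
        if any(b <= a for a, b in zip(weeks, weeks[1:])):
            out.append(f"patient {pid}: visit weeks not strictly increasing: {weeks}")
        n_baseline = sum(1 for w in weeks if w == 0)
        if n_baseline > 1:
            out.append(f"patient {pid}: {n_baseline} week-0 panels (expected one)")
        if require_baseline and n_baseline == 0:
            out.append(f"patient {pid}: no week-0 baseline panel")
        if self.last_followup_week is not None and weeks:
            if self.last_followup_week < max(weeks):
                out.append(
                    f"patient {pid}: last_followup_week {self.last_followup_week} "
                    f"precedes last visit week {max(weeks)}"
                )
        for v in self.visits:
            if v.patient_id != pid:
                out.append(f"patient {pid}: visit carries foreign id {v.patient_id!r}")
            out.extend(v.problems())
        return out


@dataclass
class Cohort:
    """A validated collection of patients."""

    patients: list[PatientRecord]
    provenance: str = ""
    config_digest: str = ""

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.patients)

    def __len__(self) -> int:
        return len(self.patients)

    def by_id(self) -> dict[str, PatientRecord]:
        return {p.patient_id: p for p in self.patients}

    def problems(self, require_baseline: bool = False) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        for p in self.patients:
            if p.patient_id in seen:
                out.append(f"duplicate patient_id {p.patient_id!r}")
            seen.add(p.patient_id)
            out.extend(p.problems(require_baseline=require_baseline))
        return out

    def validate(self, require_baseline: bool = False) -> "Cohort":
        probs = self.problems(require_baseline=require_baseline)
        if probs:
            raise CohortValidationError(probs)
        return self


def baseline_panel(patient: PatientRecord) -> LabVisit:
    """The pre-treatment (week-0) liver panel of ``patient``."""
    return patient.baseline()


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, bool):
        return "true" if x else "false"
    if isinstance(x, float):
        return repr(x)
    return str(x)


def _parse_float(text: str, where: str, problems: list[str]) -> Optional[float]:
    text = text.strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        problems.append(f"{where}: unparseable numeric {text!r}")
        return None


def _parse_bool(text: str, where: str, problems: list[str]) -> bool:
    t = text.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no", ""):
        return False
    problems.append(f"{where}: unparseable boolean {text!r}")
    return False


def _check_header(found: Sequence[str], expected: Sequence[str], path) -> None:
    missing = [c for c in expected if c not in found]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_cohort(
    patient_table_path, visit_table_path, require_baseline: bool = False
) -> Cohort:
    """Read and validate a cohort from the two-file CSV layout.

    Raises :class:`SchemaError` on missing columns and
    :class:`CohortValidationError` with *all* row-level diagnostics (bad
    numerics, duplicate visits, orphan visits, invariant violations).
    """
    problems: list[str] = []
    patients: dict[str, PatientRecord] = {}

    with open(patient_table_path, newline="") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames or (), PATIENT_COLUMNS, patient_table_path)
        for i, row in enumerate(reader, start=2):
            where = f"{Path(patient_table_path).name} row {i}"
            pid = row["patient_id"].strip()
            flags = frozenset(
                t.strip() for t in row["clinical_flags"].split(";") if t.strip()
            )
            rec = PatientRecord(
                patient_id=pid,
                arm=row["arm"].strip(),
                sex=row["sex"].strip(),
                age=_parse_float(row["age"], where + " (age)", problems),
                bmi=_parse_float(row["bmi"], where + " (bmi)", problems),
                karnofsky=_parse_float(row["karnofsky"], where + " (karnofsky)", problems),
                hbsag=_parse_bool(row["hbsag"], where + " (hbsag)", problems),
                hcv_ab=_parse_bool(row["hcv_ab"], where + " (hcv_ab)", problems),
                cd4=_parse_float(row["cd4"], where + " (cd4)", problems),
                log_viral_load=_parse_float(
                    row["log_viral_load"], where + " (log_viral_load)", problems
                ),
                hemoglobin=_parse_float(row["hemoglobin"], where + " (hemoglobin)", problems),
                wbc=_parse_float(row["wbc"], where + " (wbc)", problems),
                neutrophil=_parse_float(row["neutrophil"], where + " (neutrophil)", problems),
                platelet=_parse_float(row["platelet"], where + " (platelet)", problems),
                albumin=_parse_float(row["albumin"], where + " (albumin)", problems),
                creatinine=_parse_float(row["creatinine"], where + " (creatinine)", problems),
                urea=_parse_float(row["urea"], where + " (urea)", problems),
                haart_regimen=row["haart_regimen"].strip() or "none",
                clinical_flags=flags,
                last_followup_week=_parse_float(
                    row["last_followup_week"], where + " (last_followup_week)", problems
                ),
            )
            if pid in patients:
                problems.append(f"{where}: duplicate patient_id {pid!r}")
            else:
                patients[pid] = rec

    seen_visits: set[tuple[str, float]] = set()
    with open(visit_table_path, newline="") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames or (), VISIT_COLUMNS, visit_table_path)
        for i, row in enumerate(reader, start=2):
            where = f"{Path(visit_table_path).name} row {i}"
            pid = row["patient_id"].strip()
            week = _parse_float(row["week"], where + " (week)", problems)
            if week is None:
                problems.append(f"{where}: visit has no week")
                continue
            visit = LabVisit(
                patient_id=pid,
                week=week,
                alt=_parse_float(row["alt"], where + " (alt)", problems),
                ast=_parse_float(row["ast"], where + " (ast)", problems),
                alp=_parse_float(row["alp"], where + " (alp)", problems),
                tbil=_parse_float(row["tbil"], where + " (tbil)", problems),
                dbil=_parse_float(row["dbil"], where + " (dbil)", problems),
            )
            if pid not in patients:
                problems.append(f"{where}: visit references unknown patient {pid!r}")
                continue
            key = (pid, week)
            if key in seen_visits:
                problems.append(f"{where}: duplicate visit for {pid!r} at week {week}")
                continue
            seen_visits.add(key)
            patients[pid].visits.append(visit)

    for rec in patients.values():
        rec.visits.sort(key=lambda v: v.week)
        if rec.last_followup_week is None and rec.visits:
            rec.last_followup_week = max(v.week for v in rec.visits)

    cohort = Cohort(patients=list(patients.values()))
    problems.extend(cohort.problems(require_baseline=require_baseline))
    if problems:
        raise CohortValidationError(problems)
    return cohort


def write_cohort(cohort: Cohort, patient_table_path, visit_table_path) -> None:
    """Write the cohort so that :func:`read_cohort` reproduces it exactly."""
    with open(patient_table_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(PATIENT_COLUMNS)
        for p in cohort.patients:
            w.writerow(
                [
                    p.patient_id,
                    p.arm,
                    p.sex,
                    _fmt(p.age),
                    _fmt(p.bmi),
                    _fmt(p.karnofsky),
                    _fmt(p.hbsag),
                    _fmt(p.hcv_ab),
                    _fmt(p.cd4),
                    _fmt(p.log_viral_load),
                    _fmt(p.hemoglobin),
                    _fmt(p.wbc),
                    _fmt(p.neutrophil),
                    _fmt(p.platelet),
                    _fmt(p.albumin),
                    _fmt(p.creatinine),
                    _fmt(p.urea),
                    p.haart_regimen,
                    ";".join(sorted(p.clinical_flags)),
                    _fmt(p.last_followup_week),
                ]
            )
    with open(visit_table_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(VISIT_COLUMNS)
        for p in cohort.patients:
            for v in p.visits:
                w.writerow(
                    [
                        v.patient_id,
                        _fmt(v.week),
                        _fmt(v.alt),
                        _fmt(v.ast),
                        _fmt(v.alp),
                        _fmt(v.tbil),
                        _fmt(v.dbil),
                    ]
                )
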