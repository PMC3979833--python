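"""Constraint-built synthetic four-arm cohorts with planted ground truth.

The generator emulates a prospective observational cohort of 1,060
treatment-naive patients in four disease/treatment arms (HIV on
efavirenz-based HAART; TB-HIV on concomitant anti-TB + HAART; TB-HIV on
anti-TB alone; TB on anti-TB alone), with liver panels on the scheduled
monitoring grid and per-arm injury incidences, onset-week medians,
pattern mixtures and baseline covariate distributions matching the study
conditions the pipeline targets.

Liver-panel trajectories are *constraint-built*, not free-form: for each
planted case the generator solves for ALT/ALP/TBIL fold multiples that
provably satisfy the assigned case rule, R-value pattern class and
severity band at the onset visit — with a safety margin to every decision
boundary — and provably fail all case rules at every earlier visit.
Adjudication therefore recovers the planted truth exactly, which is what
makes the downstream tests sharp rather than statistical.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .adjudicate import (
    ALP_RULE,
    ALT_RULE,
    CHOLESTATIC,
    HEPATOCELLULAR,
    HY_RULE,
    MIXED,
    PATTERNS,
)
from .cohort import ARMS, Cohort, LabVisit, PatientRecord, SCHEDULED_WEEKS
from .reference import ULNSet, published_uln

#: Post-baseline weeks at which an onset can be planted (analysis grid).
ONSET_GRID = (1.0, 2.0, 4.0, 8.0, 12.0, 24.0)

GRADES = (1, 2, 3, 4)


class SimulationConfigError(Exception):
    """The requested simulation is infeasible or inconsistent."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

# Baseline covariate families: (family, per-arm (median, q25, q75), clip).
# Location/scale are matched to the target median and interquartile range;
# 'lognormal' families match them on the log scale.  ``None`` for an arm
# means the covariate is not recorded there.
DEFAULT_BASELINE_PARAMS: dict[str, dict] = {
    "age": {"family": "normal", "per_arm": [(34, 28, 40), (35, 30, 42), (33, 27, 41), (28, 23, 40)], "clip": (18, 90)},
    "bmi": {"family": "normal", "per_arm": [(19.5, 17.8, 21.9), (18.7, 16.8, 20.3), (18.6, 17.4, 20.6), (19.3, 17.5, 21.5)], "clip": (13, 35)},
    "karnofsky": {"family": "normal", "per_arm": [(100, 90, 100), (90, 80, 100), (100, 90, 100), None], "clip": (40, 100)},
    "hemoglobin": {"family": "normal", "per_arm": [(12.8, 11, 14), (11, 10, 13), (12, 11, 14), (13, 12, 14)], "clip": (5, 18)},
    "wbc": {"family": "lognormal", "per_arm": [(4, 4, 6), (6, 4, 7.7), (6, 5, 8), (7, 6, 9)], "clip": (1, 30)},
    "neutrophil": {"family": "normal", "per_arm": [(56, 47, 65), (69, 60, 77), (59, 49, 68), (68, 60, 75)], "clip": (5, 98)},
    "platelet": {"family": "normal", "per_arm": [(240, 171, 302), (296, 223, 376), (247, 165, 343), (387, 292, 494)], "clip": (20, 900)},
    "albumin": {"family": "normal", "per_arm": [(3.8, 3.4, 4.2)] * 4, "clip": (1.5, 5.5)},
    "creatinine": {"family": "normal", "per_arm": [(1.0, 0.85, 1.15)] * 4, "clip": (0.4, 3.0)},
    "urea": {"family": "lognormal", "per_arm": [(24, 19, 30), (25, 20, 32), (26, 20, 35), (25, 21, 31)], "clip": (5, 150)},
    "cd4": {"family": "lognormal", "per_arm": [(104, 56, 155), (79, 45, 129), (279, 223, 349), None], "clip": (1, 1500)},
    "log_viral_load": {"family": "normal", "per_arm": [(5.21, 4.61, 5.67), (5.09, 4.55, 5.53), None, None], "clip": (2, 7)},
    "ast": {"family": "lognormal", "per_arm": [(33, 27, 44), (43, 30, 74), (40, 31, 62), (30, 24, 41)], "clip": (5, 400)},
    "alt": {"family": "lognormal", "per_arm": [(28, 21, 39), (29, 20, 42), (28, 24, 39), (27, 21, 39)], "clip": (5, 400)},
    "alp": {"family": "lognormal", "per_arm": [(109, 88, 129), (121, 91, 174), (126, 110, 165), (111, 98, 138)], "clip": (20, 800)},
    "tbil": {"family": "lognormal", "per_arm": [(0.5, 0.35, 0.7)] * 4, "clip": (0.05, 0.95)},
    "dbil": {"family": "lognormal", "per_arm": [(0.12, 0.08, 0.18)] * 4, "clip": (0.01, 0.28)},
}

# Per-arm pattern mixtures over (cholestatic, hepatocellular, mixed),
# as case-count fractions in the target study conditions.
DEFAULT_PATTERN_MIX = (
    {CHOLESTATIC: 17 / 24, HEPATOCELLULAR: 3 / 24, MIXED: 4 / 24},
    {CHOLESTATIC: 70 / 120, HEPATOCELLULAR: 18 / 120, MIXED: 32 / 120},
    {CHOLESTATIC: 6 / 9, HEPATOCELLULAR: 2 / 9, MIXED: 1 / 9},
    {CHOLESTATIC: 4 / 6, HEPATOCELLULAR: 1 / 6, MIXED: 1 / 6},
)

DEFAULT_GRADE_MIX = {1: 0.535, 2: 0.327, 3: 0.113, 4: 0.025}

DEFAULT_HAART_MIX = (
    {"D4T/3TC/EFV": 0.553, "TDF/3TC/EFV": 0.044, "AZT/3TC/EFV": 0.403},
    {"D4T/3TC/EFV": 0.331, "TDF/3TC/EFV": 0.381, "AZT/3TC/EFV": 0.288},
    None,
    None,
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the four-arm cohort the pipeline targets: arm
    sizes 273/495/83/209, injury probabilities 8.8/24.2/10.8/2.9%,
    onset-week medians 4/1/2/6, per-arm pattern mixtures, the pooled
    severity-grade mixture, and baseline covariate medians/IQRs.
    """

    seed: int = 0
    n_per_arm: tuple[int, int, int, int] = (273, 495, 83, 209)
    event_prob_per_arm: tuple[float, float, float, float] = (0.088, 0.242, 0.108, 0.029)
    onset_median_weeks_per_arm: tuple[float, float, float, float] = (4.0, 1.0, 2.0, 6.0)
    pattern_mix_per_arm: tuple[dict, dict, dict, dict] = DEFAULT_PATTERN_MIX
    grade_mix: dict = field(default_factory=lambda: dict(DEFAULT_GRADE_MIX))
    baseline_covariate_params: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_BASELINE_PARAMS.items()}
    )
    female_prop_per_arm: tuple[float, float, float, float] = (0.733, 0.491, 0.470, 0.478)
    hbsag_prev_per_arm: tuple[float, float, float, float] = (0.055, 0.085, 0.049, 0.019)
    hcv_prev_per_arm: tuple[float, float, float, float] = (0.022, 0.018, 0.061, 0.019)
    haart_mix_per_arm: tuple = DEFAULT_HAART_MIX
    covariate_effects: Optional[dict[str, float]] = None
    uln: ULNSet = field(default_factory=published_uln)
    dropout_prob: float = 64 / 1060

    def validate(self) -> "SimConfig":
        if any(n <= 0 for n in self.n_per_arm):
            raise SimulationConfigError("n_per_arm entries must be > 0")
        for name in ("event_prob_per_arm", "hbsag_prev_per_arm", "hcv_prev_per_arm", "female_prop_per_arm"):
            if any(not 0 <= p <= 1 for p in getattr(self, name)):
                raise SimulationConfigError(f"{name} entries must lie in [0, 1]")
        if not 0 <= self.dropout_prob <= 1:
            raise SimulationConfigError("dropout_prob must lie in [0, 1]")
        for mix in (*self.pattern_mix_per_arm, self.grade_mix):
            if any(w < 0 for w in mix.values()):
                raise SimulationConfigError("mixture weights must be >= 0")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise SimulationConfigError(f"mixture weights must sum to 1, got {sum(mix.values())}")
        return self

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_per_arm": list(self.n_per_arm),
            "event_prob_per_arm": list(self.event_prob_per_arm),
            "onset_median_weeks_per_arm": list(self.onset_median_weeks_per_arm),
            "pattern_mix_per_arm": [dict(m) for m in self.pattern_mix_per_arm],
            "grade_mix": {str(k): v for k, v in self.grade_mix.items()},
            "covariate_effects": self.covariate_effects,
            "uln": self.uln.to_dict(),
            "dropout_prob": self.dropout_prob,
        }

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        """Build a config from a (possibly partial) plain-dict override."""
        cfg = cls()
        d = dict(d)
        if "uln" in d:
            d["uln"] = ULNSet.from_dict(d["uln"])
        if "grade_mix" in d:
            d["grade_mix"] = {int(k): float(v) for k, v in d["grade_mix"].items()}
        if "pattern_mix_per_arm" in d:
            d["pattern_mix_per_arm"] = tuple(dict(m) for m in d["pattern_mix_per_arm"])
        for key, value in d.items():
            if not hasattr(cfg, key):
                raise SimulationConfigError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), tuple) and not isinstance(value, tuple):
                value = tuple(value)
            setattr(cfg, key, value)
        return cfg.validate()


# ---------------------------------------------------------------------------
# onset-week calibration: truncated geometric over the visit grid
# ---------------------------------------------------------------------------


def _truncated_geometric_cdf(q: float, i: int, m: int) -> float:
    return (1 - (1 - q) ** i) / (1 - (1 - q) ** m)


def calibrate_onset_q(median_week: float, grid: Sequence[float] = ONSET_GRID) -> float:
    """Success parameter of a truncated geometric over grid positions whose
    median matches ``median_week``.

    For a target on the grid, q is chosen so 0.5 sits centred between the
    CDF at the target and at the previous grid week.  For a target
    strictly between grid weeks (possible when the reported median is the
    midpoint of two visit weeks), q is chosen so the CDF at the lower
    bracketing week equals 0.5, the closest any distribution supported on
    the visit grid can come.
    """
    grid = list(grid)
    m = len(grid)
    if median_week in grid:
        i = grid.index(median_week) + 1
        if i == 1:
            return brentq(lambda q: _truncated_geometric_cdf(q, 1, m) - 0.75, 1e-9, 1 - 1e-9)
        f = lambda q: _truncated_geometric_cdf(q, i - 1, m) + _truncated_geometric_cdf(q, i, m) - 1.0
    else:
        i = sum(1 for w in grid if w < median_week)
        if not 0 < i < m:
            raise SimulationConfigError(
                f"onset median {median_week} outside the visit grid {grid}"
            )
        f = lambda q: _truncated_geometric_cdf(q, i, m) - 0.5
    lo, hi = 1e-9, 1 - 1e-9
    if f(lo) >= 0:  # already at/above target in the uniform limit
        return lo
    return brentq(f, lo, hi)


def _onset_pmf(q: float, m: int) -> np.ndarray:
    w = np.array([(1 - q) ** k * q for k in range(m)])
    return w / w.sum()


# ---------------------------------------------------------------------------
# fold-constraint solving for planted cases
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CaseFolds:
    """Solved fold multiples (vs ULN) for a planted case's onset visit."""

    alt_fold: float
    alp_fold: float
    tbil_fold: float
    criterion: str


class InfeasibleCellError(SimulationConfigError):
    """The requested (pattern, grade) cell admits no fold solution."""


#: (pattern, grade) cells with no solution under the ULN grading scale:
#: the grade-1 band forces the ALP-rule geometry (ALP fold in [2, 2.5),
#: ALT fold < 2.5), which pins R below 1.25 — cholestatic territory.
INFEASIBLE_CELLS = frozenset({(HEPATOCELLULAR, 1), (MIXED, 1)})


def solve_case_folds(pattern: str, grade: int, rng: np.random.Generator) -> CaseFolds:
    """Sample ALT/ALP/TBIL folds satisfying the case rule, pattern class and
    severity band for the given cell, with margin to every boundary.

    All folds are vs the ULN (planted cases are built on the
    baseline-normal branch).  Raises :class:`InfeasibleCellError` for the
    two geometrically impossible cells.
    """
    if pattern not in PATTERNS or grade not in GRADES:
        raise SimulationConfigError(f"unknown cell ({pattern!r}, {grade!r})")
    if (pattern, grade) in INFEASIBLE_CELLS:
        raise InfeasibleCellError(
            f"cell ({pattern}, grade {grade}) is infeasible: the grade-1 band "
            "forces ALP-rule geometry with R < 1.25"
        )
    U = rng.uniform
    tb_low = U(0.3, 1.7)  # safely below the 2x ULN escalation threshold
    if grade == 1:  # necessarily cholestatic
        return CaseFolds(U(0.3, 2.2), U(2.05, 2.45), tb_low, ALP_RULE)
    if pattern == CHOLESTATIC:
        lo, hi = {2: (2.55, 4.85), 3: (5.15, 9.7), 4: (10.3, 14.0)}[grade]
        f_alp = U(lo, hi)
        # ALT capped below the 3x combination threshold so the ALP rule
        # is the one that fires; R stays <= 2.8/2.55 < 2 regardless
        f_alt = U(0.3, min(0.95 * f_alp, 2.8))
        return CaseFolds(f_alt, f_alp, tb_low, ALP_RULE)
    if pattern == MIXED:
        if grade == 2:
            f_alp = U(2.05, 2.2)
            f_alt = U(2.12 * f_alp, 4.85)  # R in (2.12, 2.37), band 2
            return CaseFolds(f_alt, f_alp, tb_low, ALP_RULE)
        lo, hi = {3: (5.15, 9.7), 4: (10.3, 15.0)}[grade]
        f_alt = U(lo, hi)
        return CaseFolds(f_alt, f_alt / U(2.2, 4.6), tb_low, ALT_RULE)
    # hepatocellular
    if grade == 2:
        # band must stay below 5x, so the case qualifies via the
        # ALT + bilirubin combination; TBIL >= 2 escalates to exactly 2.
        f_alt = U(3.1, 4.85)
        return CaseFolds(f_alt, U(0.3, f_alt / 5.3), U(2.1, 3.2), HY_RULE)
    lo, hi = {3: (5.15, 9.7), 4: (10.3, 15.0)}[grade]
    f_alt = U(lo, hi)
    return CaseFolds(f_alt, U(0.3, f_alt / 5.3), tb_low, ALT_RULE)


def _joint_cell_weights(pattern_mix: dict, grade_mix: dict) -> dict[tuple[str, int], float]:
    """Product mixture over (pattern, grade) conditioned on feasible cells."""
    weights = {}
    infeasible_mass = 0.0
    for p, wp in pattern_mix.items():
        for g, wg in grade_mix.items():
            w = wp * wg
            if w <= 0:
                continue
            if (p, g) in INFEASIBLE_CELLS:
                infeasible_mass += w
            else:
                weights[(p, int(g))] = w
    total = sum(weights.values())
    if total <= 0:
        bad = sorted({(p, g) for p in pattern_mix for g in grade_mix if pattern_mix[p] * grade_mix[g] > 0})
        raise SimulationConfigError(
            f"all joint (pattern, grade) mass falls on infeasible cells {bad}"
        )
    return {cell: w / total for cell, w in weights.items()}


# ---------------------------------------------------------------------------
# covariate draws
# ---------------------------------------------------------------------------


def _family_params(spec: dict, arm_idx: int) -> Optional[tuple[str, float, float, tuple]]:
    triple = spec["per_arm"][arm_idx]
    if triple is None:
        return None
    med, q25, q75 = triple
    if spec["family"] == "lognormal":
        mu = math.log(med)
        sigma = max(math.log(q75 / q25) / 1.349, 1e-6)
    else:
        mu = float(med)
        sigma = max((q75 - q25) / 1.349, 1e-6)
    return spec["family"], mu, sigma, spec["clip"]


def _draw_covariate(spec: dict, arm_idx: int, rng: np.random.Generator) -> Optional[float]:
    params = _family_params(spec, arm_idx)
    if params is None:
        return None
    family, mu, sigma, clip = params
    if family == "lognormal":
        x = math.exp(rng.normal(mu, sigma))
    else:
        x = rng.normal(mu, sigma)
    return float(min(max(x, clip[0]), clip[1]))


def standardized_covariate(config: SimConfig, name: str, arm_idx: int, value: float) -> float:
    """Z-score of a baseline covariate under its generating family.

    Used by the logistic event model (``covariate_effects``) and by
    parameter-recovery tests, so the planted coefficient and the fitted
    covariate live on the same scale.
    """
    params = _family_params(config.baseline_covariate_params[name], arm_idx)
    if params is None:
        raise SimulationConfigError(f"covariate {name!r} not recorded in arm {arm_idx + 1}")
    family, mu, sigma, _ = params
    x = math.log(value) if family == "lognormal" else value
    return (x - mu) / sigma


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

# Safety caps for non-qualifying panels, as fold multiples of each
# analyte's reference: >= 7% below every case-rule threshold.
_SAFE_ALT_CAP = 2.6  # combination rule needs 3x
_SAFE_ALP_CAP = 1.8  # ALP rule needs 2x
_SAFE_TBIL_CAP = 1.8  # combination rule needs 2x ULN


def _subthreshold_panel(
    rng: np.random.Generator,
    base: dict[str, float],
    alt_ref: float,
    alp_ref: float,
    uln: ULNSet,
) -> dict[str, float]:
    """Panel wandering around baseline, provably failing every case rule."""
    alt = min(base["alt"] * math.exp(rng.normal(0, 0.2)), _SAFE_ALT_CAP * alt_ref)
    alp = min(base["alp"] * math.exp(rng.normal(0, 0.15)), _SAFE_ALP_CAP * alp_ref)
    ast = min(base["ast"] * math.exp(rng.normal(0, 0.2)), 390.0)
    tbil = min(base["tbil"] * math.exp(rng.normal(0, 0.2)), _SAFE_TBIL_CAP * uln.tbil)
    dbil = tbil * rng.uniform(0.15, 0.5)
    return {"alt": alt, "ast": ast, "alp": alp, "tbil": tbil, "dbil": dbil}


def _onset_panel(
    rng: np.random.Generator, folds: CaseFolds, sex: str, uln: ULNSet
) -> dict[str, float]:
    alt = folds.alt_fold * uln.alt(sex)
    alp = folds.alp_fold * uln.alp
    tbil = folds.tbil_fold * uln.tbil
    return {
        "alt": alt,
        "ast": alt * rng.uniform(0.8, 1.4),
        "alp": alp,
        "tbil": tbil,
        "dbil": tbil * rng.uniform(0.2, 0.5),
    }


def generate_cohort(config: SimConfig) -> tuple[Cohort, pd.DataFrame]:
    """Generate a cohort plus its per-patient truth table.

    Truth columns: ``patient_id``, ``arm``, ``event`` (observable planted
    case status), ``onset_week``, ``pattern``, ``grade``, ``criterion``,
    ``truncated`` (a planted case lost to dropout before its onset and
    therefore, by design, not detectable), ``dropout_week``.

    Deterministic: the same config (including its seed) yields a
    bit-identical cohort.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    uln = config.uln
    effects = config.covariate_effects or {}

    onset_q = [
        calibrate_onset_q(m, ONSET_GRID) for m in config.onset_median_weeks_per_arm
    ]
    onset_pmf = [_onset_pmf(q, len(ONSET_GRID)) for q in onset_q]
    joint_cells = [
        _joint_cell_weights(config.pattern_mix_per_arm[i], config.grade_mix)
        for i in range(4)
    ]

    patients: list[PatientRecord] = []
    truth_rows: list[dict] = []

    for arm_idx, arm in enumerate(ARMS):
        cells = sorted(joint_cells[arm_idx])
        cell_w = np.array([joint_cells[arm_idx][c] for c in cells])
        haart_mix = config.haart_mix_per_arm[arm_idx]
        regimens = sorted(haart_mix) if haart_mix else None
        regimen_w = (
            np.array([haart_mix[r] for r in regimens]) / sum(haart_mix.values())
            if haart_mix
            else None
        )
        for k in range(config.n_per_arm[arm_idx]):
            pid = f"A{arm_idx + 1}-{k + 1:05d}"
            sex = "female" if rng.random() < config.female_prop_per_arm[arm_idx] else "male"
            cov = {
                name: _draw_covariate(spec, arm_idx, rng)
                for name, spec in config.baseline_covariate_params.items()
            }
            if cov["dbil"] is not None and cov["tbil"] is not None:
                cov["dbil"] = min(cov["dbil"], 0.8 * cov["tbil"])
            hbsag = rng.random() < config.hbsag_prev_per_arm[arm_idx]
            hcv = rng.random() < config.hcv_prev_per_arm[arm_idx]
            regimen = (
                regimens[rng.choice(len(regimens), p=regimen_w)] if regimens else "none"
            )

            p_event = config.event_prob_per_arm[arm_idx]
            if effects and 0 < p_event < 1:
                eta = logit(p_event) + sum(
                    beta * standardized_covariate(config, name, arm_idx, cov[name])
                    for name, beta in effects.items()
                )
                p_event = float(np.clip(expit(eta), 1e-9, 1 - 1e-9))
            event = rng.random() < p_event

            dropout_week = None
            if rng.random() < config.dropout_prob:
                dropout_week = float(ONSET_GRID[rng.choice(len(ONSET_GRID))])

            onset_week = None
            pattern = grade = criterion = None
            truncated = False
            folds = None
            if event:
                onset_week = float(
                    ONSET_GRID[rng.choice(len(ONSET_GRID), p=onset_pmf[arm_idx])]
                )
                if dropout_week is not None and dropout_week < onset_week:
                    # planted case unobservable under dropout: designed non-detection
                    event, truncated, onset_week = False, True, None
                else:
                    pattern, grade = cells[rng.choice(len(cells), p=cell_w)]
                    folds = solve_case_folds(pattern, grade, rng)
                    criterion = folds.criterion
                    # baseline-normal branch so that case folds and the
                    # R-value share the ULN reference
                    cov["alt"] = min(cov["alt"], 0.92 * uln.alt(sex))
                    cov["alp"] = min(cov["alp"], 0.92 * uln.alp)

            base_panel = {name: cov[name] for name in ("alt", "ast", "alp", "tbil", "dbil")}
            alt_ref = uln.alt(sex) if base_panel["alt"] <= uln.alt(sex) else base_panel["alt"]
            alp_ref = uln.alp if base_panel["alp"] <= uln.alp else base_panel["alp"]

            last_week = dropout_week if dropout_week is not None else SCHEDULED_WEEKS[-1]
            visits = [LabVisit(patient_id=pid, week=0.0, **base_panel)]
            onset_values: Optional[dict] = None
            for week in SCHEDULED_WEEKS[1:]:
                if week > last_week:
                    break
                if event and week == onset_week:
                    panel = _onset_panel(rng, folds, sex, uln)
                    onset_values = panel
                elif event and onset_values is not None:
                    # geometric recovery toward baseline after onset
                    panel = {
                        name: base_panel[name]
                        + (onset_values[name] - base_panel[name]) * 0.5 ** max(week - onset_week, 1)
                        for name in base_panel
                    }
                    panel["dbil"] = min(panel["dbil"], panel["tbil"])
                else:
                    panel = _subthreshold_panel(rng, base_panel, alt_ref, alp_ref, uln)
                visits.append(LabVisit(patient_id=pid, week=float(week), **panel))

            patients.append(
                PatientRecord(
                    patient_id=pid,
                    arm=arm,
                    sex=sex,
                    age=cov["age"],
                    bmi=cov["bmi"],
                    karnofsky=cov["karnofsky"],
                    hbsag=hbsag,
                    hcv_ab=hcv,
                    cd4=cov["cd4"] if arm != "Arm4" else None,
                    log_viral_load=cov["log_viral_load"] if arm_idx < 2 else None,
                    hemoglobin=cov["hemoglobin"],
                    wbc=cov["wbc"],
                    neutrophil=cov["neutrophil"],
                    platelet=cov["platelet"],
                    albumin=cov["albumin"],
                    creatinine=cov["creatinine"],
                    urea=cov["urea"],
                    haart_regimen=regimen,
                    clinical_flags=frozenset(),
                    visits=visits,
                    last_followup_week=float(last_week),
                )
            )
            truth_rows.append(
                {
                    "patient_id": pid,
                    "arm": arm,
                    "event": bool(event),
                    "onset_week": onset_week,
                    "pattern": pattern,
                    "grade": grade,
                    "criterion": criterion,
                    "truncated": truncated,
                    "dropout_week": dropout_week,
                }
            )

    cohort = Cohort(
        patients=patients,
        provenance=f"synthetic four-arm cohort, seed={config.seed}",
        config_digest=config.digest(),
    )
    truth = pd.DataFrame(truth_rows)
    return cohort, truth


# ---------------------------------------------------------------------------
# truth report
# ---------------------------------------------------------------------------


@dataclass
class TruthReport:
    """Agreement of adjudication against the generator's planted truth."""

    n: int
    sensitivity: float
    specificity: float
    onset_agreement: float
    pattern_agreement: float
    grade_agreement: float
    n_truncated_cases: int
    pattern_confusion: pd.DataFrame
    grade_confusion: pd.DataFrame

    @property
    def exact(self) -> bool:
        return (
            self.sensitivity == 1.0
            and self.specificity == 1.0
            and self.onset_agreement == 1.0
            and self.pattern_agreement == 1.0
            and self.grade_agreement == 1.0
        )


def truth_report(truth: pd.DataFrame, calls: Sequence) -> TruthReport:
    """Confusion summary of adjudicated calls against planted truth.

    Truncated planted cases (dropout before onset) are recorded as
    designed non-detections in the truth table and therefore count toward
    specificity, not sensitivity.
    """
    call_df = pd.DataFrame(
        {
            "patient_id": [c.patient_id for c in calls],
            "called": [c.is_case for c in calls],
            "called_onset": [c.onset_week for c in calls],
            "called_pattern": [c.pattern for c in calls],
            "called_grade": [c.grade for c in calls],
        }
    )
    if set(call_df["patient_id"]) != set(truth["patient_id"]):
        raise ValueError("truth table and calls cover different patients")
    m = truth.merge(call_df, on="patient_id", validate="one_to_one")

    pos = m[m["event"]]
    neg = m[~m["event"]]
    sens = float((pos["called"]).mean()) if len(pos) else 1.0
    spec = float((~neg["called"]).mean()) if len(neg) else 1.0
    detected = m[m["event"] & m["called"]]
    onset_agree = (
        float((detected["onset_week"] == detected["called_onset"]).mean())
        if len(detected)
        else 1.0
    )
    pattern_agree = (
        float((detected["pattern"] == detected["called_pattern"]).mean())
        if len(detected)
        else 1.0
    )
    grade_agree = (
        float((detected["grade"] == detected["called_grade"]).mean())
        if len(detected)
        else 1.0
    )
    pattern_conf = pd.crosstab(detected["pattern"], detected["called_pattern"])
    grade_conf = pd.crosstab(detected["grade"], detected["called_grade"])
    return TruthReport(
        n=len(m),
        sensitivity=sens,
        specificity=spec,
        onset_agreement=onset_agree,
        pattern_agreement=pattern_agree,
        grade_agreement=grade_agree,
        n_truncated_cases=int(truth["truncated"].sum()),
        pattern_confusion=pattern_conf,
        grade_confusion=grade_conf,
    )
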