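"""Cohort-level statistics for adjudicated DILI calls.

Covers the descriptive and inferential layer of the pipeline: per-arm
incidence with pattern and grade breakdowns, pairwise odds ratios with
Woolf (log-normal) confidence intervals and Haldane-Anscombe correction,
Bonferroni-adjusted proportion tests, Kaplan-Meier / Nelson-Aalen
estimation of the time to injury onset, and a univariate-screen ->
backward-elimination Cox proportional-hazards workflow with the Efron
approximation for the heavily tied onset weeks of an interval visit
schedule.  Cox, KM and NA fitting is delegated to lifelines; the
orchestration, contingency arithmetic and reporting live here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter, NelsonAalenFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats as sps

from .adjudicate import DILICall, PATTERNS
from .cohort import ARMS, Cohort

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class UndefinedOddsRatioError(Exception):
    """No cases in either group: the odds ratio carries no information."""


# ---------------------------------------------------------------------------
# contingency tables and odds ratios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: (exposed cases a, exposed non-cases b, reference cases c,
    reference non-cases d)."""

    a: int
    b: int
    c: int
    d: int
    exposed_label: str = "exposed"
    reference_label: str = "reference"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be >= 0")


@dataclass(frozen=True)
class ORResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    method: str  # 'woolf' | 'woolf_haldane'
    p_value: float
    test: str  # 'chi_square' | 'fisher_exact'
    exposed_label: str = "exposed"
    reference_label: str = "reference"


def odds_ratio(table: ContingencyTable, alpha: float = 0.05) -> ORResult:
    """OR = ad/bc with a Woolf log-normal confidence interval.

    Any zero cell triggers the Haldane-Anscombe correction (add 0.5 to
    every cell).  The two-sided p-value uses Pearson's chi-square, or
    Fisher's exact test when any expected cell count is below 5.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a == 0 and c == 0:
        raise UndefinedOddsRatioError(
            f"no cases in either group ({table.exposed_label} vs {table.reference_label})"
        )
    method = "woolf"
    fa, fb, fc, fd = float(a), float(b), float(c), float(d)
    if min(a, b, c, d) == 0:
        fa, fb, fc, fd = fa + 0.5, fb + 0.5, fc + 0.5, fd + 0.5
        method = "woolf_haldane"
    oddsr = (fa * fd) / (fb * fc)
    se = math.sqrt(1 / fa + 1 / fb + 1 / fc + 1 / fd)
    z = sps.norm.ppf(1 - alpha / 2)
    ci_low = math.exp(math.log(oddsr) - z * se)
    ci_high = math.exp(math.log(oddsr) + z * se)

    obs = np.array([[a, b], [c, d]], dtype=float)
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    if expected.min() < 5:
        _, p = sps.fisher_exact([[a, b], [c, d]])
        test = "fisher_exact"
    else:
        _, p, _, _ = sps.chi2_contingency(obs, correction=False)
        test = "chi_square"
    return ORResult(
        odds_ratio=oddsr,
        ci_low=ci_low,
        ci_high=ci_high,
        method=method,
        p_value=float(p),
        test=test,
        exposed_label=table.exposed_label,
        reference_label=table.reference_label,
    )


def arm_contingency(
    calls: Sequence[DILICall], cohort: Cohort, exposed_arm: str, reference_arm: str
) -> ContingencyTable:
    """Build the 2x2 case/non-case table for two arms from adjudicated calls."""
    arm_of = {p.patient_id: p.arm for p in cohort}
    counts = {exposed_arm: [0, 0], reference_arm: [0, 0]}
    for call in calls:
        arm = arm_of.get(call.patient_id)
        if arm in counts:
            counts[arm][0 if call.is_case else 1] += 1
    (a, b), (c, d) = counts[exposed_arm], counts[reference_arm]
    return ContingencyTable(a, b, c, d, exposed_label=exposed_arm, reference_label=reference_arm)


@dataclass(frozen=True)
class PropTestResult:
    exposed_label: str
    reference_label: str
    p_raw: float
    p_adjusted: float
    significant: bool
    test: str


def pairwise_proportion_tests(
    tables: Sequence[ContingencyTable], alpha: float = 0.05
) -> list[PropTestResult]:
    """Raw chi-square/Fisher p per table with Bonferroni adjustment over k tables."""
    k = len(tables)
    if k < 1:
        raise ValueError("need at least one comparison")
    out = []
    for t in tables:
        res = odds_ratio(t)
        p_adj = min(1.0, k * res.p_value)
        out.append(
            PropTestResult(
                exposed_label=t.exposed_label,
                reference_label=t.reference_label,
                p_raw=res.p_value,
                p_adjusted=p_adj,
                significant=p_adj < alpha,
                test=res.test,
            )
        )
    return out


# ---------------------------------------------------------------------------
# incidence, pattern and grade tables
# ---------------------------------------------------------------------------


def _pct(num: int, den: int) -> float:
    return round(100.0 * num / den, 1) if den else 0.0


@dataclass
class IncidenceTables:
    """Per-arm incidence plus pattern x arm and grade x arm breakdowns.

    ``incidence`` rows are arms plus a Total row; ``pattern_by_arm`` and
    ``grade_by_arm`` carry counts per arm with Total counts and the share
    (percent of all classified cases, one decimal).  Cases with an
    unclassifiable pattern are excluded from the pattern table and
    counted in ``n_pattern_unclassifiable``.
    """

    incidence: pd.DataFrame
    pattern_by_arm: pd.DataFrame
    grade_by_arm: pd.DataFrame
    n_pattern_unclassifiable: int = 0


def incidence_table(calls: Sequence[DILICall], cohort: Cohort) -> IncidenceTables:
    arm_of = {p.patient_id: p.arm for p in cohort}
    arms = [a for a in ARMS if any(arm_of.get(c.patient_id) == a for c in calls)]
    n = {a: 0 for a in arms}
    cases = {a: 0 for a in arms}
    pattern_counts = {p: {a: 0 for a in arms} for p in PATTERNS}
    grade_counts = {g: {a: 0 for a in arms} for g in (1, 2, 3, 4)}
    unclassifiable = 0

    for call in calls:
        arm = arm_of.get(call.patient_id)
        if arm is None:
            continue
        n[arm] += 1
        if not call.is_case:
            continue
        cases[arm] += 1
        if call.pattern in pattern_counts:
            pattern_counts[call.pattern][arm] += 1
        else:
            unclassifiable += 1
        if call.grade in grade_counts:
            grade_counts[call.grade][arm] += 1

    total_n = sum(n.values())
    total_cases = sum(cases.values())
    inc_rows = [
        {"arm": a, "n": n[a], "cases": cases[a], "percent": _pct(cases[a], n[a])}
        for a in arms
    ]
    inc_rows.append(
        {"arm": "Total", "n": total_n, "cases": total_cases, "percent": _pct(total_cases, total_n)}
    )
    incidence = pd.DataFrame(inc_rows).set_index("arm")

    classified = total_cases - unclassifiable

    def _breakdown(counts: dict) -> pd.DataFrame:
        rows = []
        for key, per_arm in counts.items():
            tot = sum(per_arm.values())
            row = {"level": key, **per_arm, "total": tot, "share_percent": _pct(tot, classified if counts is pattern_counts else total_cases)}
            rows.append(row)
        return pd.DataFrame(rows).set_index("level")

    pattern_df = _breakdown(pattern_counts)
    grade_df = _breakdown(grade_counts)
    return IncidenceTables(
        incidence=incidence,
        pattern_by_arm=pattern_df,
        grade_by_arm=grade_df,
        n_pattern_unclassifiable=unclassifiable,
    )


# ---------------------------------------------------------------------------
# survival dataset, KM / Nelson-Aalen, Cox workflow
# ---------------------------------------------------------------------------

#: Covariates extractable from a PatientRecord by name.
_PATIENT_COVARIATES = (
    "age",
    "bmi",
    "karnofsky",
    "cd4",
    "log_viral_load",
    "hemoglobin",
    "wbc",
    "neutrophil",
    "platelet",
    "albumin",
    "creatinine",
    "urea",
)
_BASELINE_ANALYTES = ("alt", "ast", "alp", "tbil", "dbil")


def build_survival_dataset(
    cohort: Cohort,
    calls: Sequence[DILICall],
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-patient time-to-event frame: ``duration`` (weeks), ``event``, covariates.

    Duration is the onset week for cases, the censoring week otherwise
    (last follow-up or the analysis cutoff, whichever is earlier).
    Covariate names: patient attributes (``age`` ... ``urea``),
    ``sex_male``, ``hbsag``, ``hcv_ab``, ``baseline_<analyte>`` for week-0
    panel values, and ``arm`` which expands to indicator columns
    ``arm_Arm1``..``arm_Arm3`` with Arm4 as reference.
    """
    by_id = cohort.by_id()
    rows = []
    for call in calls:
        p = by_id[call.patient_id]
        duration = call.onset_week if call.is_case else call.censor_week
        if duration is None or duration <= 0:
            raise ValueError(
                f"patient {call.patient_id}: nonpositive time at risk {duration!r}"
            )
        row: dict = {
            "patient_id": call.patient_id,
            "duration": float(duration),
            "event": int(call.is_case),
            "arm": p.arm,
        }
        base = p.baseline() if p.has_baseline() else None
        for name in covariates:
            if name == "arm":
                for arm in ("Arm1", "Arm2", "Arm3"):
                    row[f"arm_{arm}"] = int(p.arm == arm)
            elif name == "sex_male":
                row[name] = int(p.sex == "male")
            elif name in ("hbsag", "hcv_ab"):
                row[name] = int(getattr(p, name))
            elif name.startswith("baseline_"):
                analyte = name.removeprefix("baseline_")
                if analyte not in _BASELINE_ANALYTES:
                    raise KeyError(f"unknown baseline analyte {analyte!r}")
                row[name] = None if base is None else getattr(base, analyte)
            elif name in _PATIENT_COVARIATES:
                row[name] = getattr(p, name)
            else:
                raise KeyError(f"unknown covariate {name!r}")
        rows.append(row)
    return pd.DataFrame(rows)


def expand_covariates(covariates: Sequence[str]) -> list[str]:
    """Column names produced by :func:`build_survival_dataset` for ``covariates``."""
    cols: list[str] = []
    for name in covariates:
        if name == "arm":
            cols.extend(["arm_Arm1", "arm_Arm2", "arm_Arm3"])
        else:
            cols.append(name)
    return cols


def cumulative_hazard(
    dataset: pd.DataFrame, group_by_arm: bool = True
) -> dict[str, pd.DataFrame]:
    """Nelson-Aalen cumulative hazard and Kaplan-Meier survival step functions.

    Returns one frame per group (arms, or 'all') with columns ``week``,
    ``cumulative_hazard`` (H(t) = sum of d_i/n_i over event weeks <= t)
    and ``km_survival``.
    """
    if dataset.empty:
        raise ValueError("empty survival dataset")
    groups = (
        [(arm, df) for arm, df in dataset.groupby("arm", sort=True)]
        if group_by_arm and "arm" in dataset
        else [("all", dataset)]
    )
    out: dict[str, pd.DataFrame] = {}
    for label, df in groups:
        naf = NelsonAalenFitter(nelson_aalen_smoothing=False)
        naf.fit(df["duration"], event_observed=df["event"])
        kmf = KaplanMeierFitter()
        kmf.fit(df["duration"], event_observed=df["event"])
        na = naf.cumulative_hazard_.iloc[:, 0]
        km = kmf.survival_function_.iloc[:, 0]
        merged = pd.DataFrame(
            {
                "week": na.index.to_numpy(dtype=float),
                "cumulative_hazard": na.to_numpy(dtype=float),
                "km_survival": km.reindex(na.index).to_numpy(dtype=float),
            }
        ).reset_index(drop=True)
        out[str(label)] = merged
    return out


@dataclass
class CoxResult:
    """One covariate's fit summary from a Cox proportional-hazards model."""

    variable: str
    hazard_ratio: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_value: Optional[float]
    model_stage: str  # 'univariate' | 'multivariate'
    retained: bool
    ties_method: str = "efron"
    note: str = ""


def _fit_cox(df: pd.DataFrame, variables: Sequence[str]) -> CoxPHFitter:
    cph = CoxPHFitter()
    cols = ["duration", "event", *variables]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df[cols].dropna(), duration_col="duration", event_col="event")
    return cph


def _extract(cph: CoxPHFitter, var: str, stage: str, retained: bool) -> CoxResult:
    s = cph.summary.loc[var]
    return CoxResult(
        variable=var,
        hazard_ratio=float(s["exp(coef)"]),
        ci_low=float(s["exp(coef) lower 95%"]),
        ci_high=float(s["exp(coef) upper 95%"]),
        p_value=float(s["p"]),
        model_stage=stage,
        retained=retained,
    )


def univariate_screen(
    dataset: pd.DataFrame,
    variables: Sequence[str],
    entry_p: float = 0.1,
) -> list[CoxResult]:
    """One single-covariate Cox fit per variable (Efron ties).

    Variables with p below ``entry_p`` are flagged ``retained`` for the
    multivariate stage.  Constant covariates carry no information and are
    excluded; non-converging fits are excluded with a note.
    """
    results = []
    for var in variables:
        col = dataset[var].dropna()
        if col.nunique() <= 1:
            results.append(
                CoxResult(var, None, None, None, None, "univariate", False, note="constant covariate, excluded")
            )
            continue
        try:
            cph = _fit_cox(dataset, [var])
        except (ConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
            results.append(
                CoxResult(var, None, None, None, None, "univariate", False, note=f"did not converge: {exc}")
            )
            continue
        res = _extract(cph, var, "univariate", retained=False)
        res.retained = res.p_value < entry_p
        results.append(res)
    return results


def _drop_collinear(dataset: pd.DataFrame, variables: Sequence[str]) -> tuple[list[str], list[str]]:
    """Greedy rank check in declaration order; later-declared collinear
    variables are dropped deterministically."""
    kept: list[str] = []
    dropped: list[str] = []
    sub = dataset[list(variables)].dropna()
    for var in variables:
        cols = kept + [var]
        mat = sub[cols].to_numpy(dtype=float)
        mat = np.column_stack([np.ones(len(mat)), mat])
        if np.linalg.matrix_rank(mat) == len(cols) + 1:
            kept.append(var)
        else:
            dropped.append(var)
    return kept, dropped


def multivariate_backward(
    dataset: pd.DataFrame,
    entered: Sequence[str],
    removal_p: float = 0.05,
) -> list[CoxResult]:
    """Backward elimination from the entered set (Efron ties throughout).

    Repeatedly removes the variable with the largest p >= ``removal_p``
    and refits, until every retained variable is below the threshold or a
    single variable remains.  Removed variables appear in the result with
    ``retained=False`` and their p at removal.  Collinear covariates are
    dropped up front (later-declared loses).
    """
    entered = list(entered)
    if not entered:
        raise ValueError("no variables entered the multivariate stage")
    current, collinear = _drop_collinear(dataset, entered)
    removed: list[CoxResult] = [
        CoxResult(v, None, None, None, None, "multivariate", False, note="collinear, dropped")
        for v in collinear
    ]
    while True:
        cph = _fit_cox(dataset, current)
        pvals = {v: float(cph.summary.loc[v, "p"]) for v in current}
        worst = max(pvals, key=lambda v: pvals[v])
        if pvals[worst] >= removal_p and len(current) > 1:
            removed.append(
                CoxResult(
                    worst,
                    None,
                    None,
                    None,
                    pvals[worst],
                    "multivariate",
                    False,
                    note="removed by backward elimination",
                )
            )
            current.remove(worst)
            continue
        break
    final = [_extract(cph, v, "multivariate", retained=True) for v in current]
    return final + removed


def cox_results_frame(results: Sequence[CoxResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variable": r.variable,
                "hazard_ratio": r.hazard_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
                "model_stage": r.model_stage,
                "retained": r.retained,
                "ties_method": r.ties_method,
                "note": r.note,
            }
            for r in results
        ]
    )
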