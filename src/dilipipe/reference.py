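"""Population-specific upper limits of normal (ULN) for liver analytes.

Commercial assay reference ranges travel poorly across populations, so
the pipeline derives its ULNs from the cohort's own pre-treatment panels:
each analyte's limit is the mean of the baseline values after discarding
the extreme 5% of observations (trimmed mean).  ALT is sex-stratified;
AST, ALP and the bilirubins are pooled.  A set of limits published for an
Ethiopian adult treatment cohort ships as the packaged default for use
when raw baselines are unavailable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .cohort import Cohort


class DerivationError(Exception):
    """Too few baseline panels in a stratum to derive a limit."""


@dataclass(frozen=True)
class ULNSet:
    """Per-analyte upper limits of normal (ALT sex-stratified).

    Units: enzymes U/L, bilirubins mg/dL.
    """

    alt_female: float
    alt_male: float
    ast: float
    alp: float
    tbil: float
    dbil: float
    method: str = "published"  # 'published' | 'derived'
    trim_fraction: float = 0.05

    def __post_init__(self) -> None:
        for name in ("alt_female", "alt_male", "ast", "alp", "tbil", "dbil"):
            if not getattr(self, name) > 0:
                raise ValueError(f"ULN {name} must be > 0")
        if not (0 <= self.trim_fraction < 0.5):
            raise ValueError("trim_fraction must lie in [0, 0.5)")

    def alt(self, sex: str) -> float:
        """ALT limit for the given sex ('female' or 'male')."""
        if sex == "female":
            return self.alt_female
        if sex == "male":
            return self.alt_male
        raise ValueError(f"unknown sex {sex!r}")

    def to_dict(self) -> dict:
        return {
            "alt_female": self.alt_female,
            "alt_male": self.alt_male,
            "ast": self.ast,
            "alp": self.alp,
            "tbil": self.tbil,
            "dbil": self.dbil,
            "method": self.method,
            "trim_fraction": self.trim_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ULNSet":
        return cls(**d)


def published_uln() -> ULNSet:
    """ULNs published for an Ethiopian adult TB/HIV treatment cohort.

    ALT 33 U/L (men) / 29 U/L (women); AST 41 U/L; ALP 128 U/L; total
    bilirubin 1.0 mg/dL; direct bilirubin 0.3 mg/dL.
    """
    return ULNSet(
        alt_female=29.0,
        alt_male=33.0,
        ast=41.0,
        alp=128.0,
        tbil=1.0,
        dbil=0.3,
        method="published",
        trim_fraction=0.05,
    )


def trimmed_mean(
    values: Iterable[float], trim_fraction: float, one_sided: bool = False
) -> float:
    """Mean after discarding the extreme ``trim_fraction`` of observations.

    Two-sided (default): ``floor(n * trim_fraction / 2)`` values removed
    from each tail.  One-sided: ``floor(n * trim_fraction)`` removed from
    the top only.  Ties are broken by value order (stable sort), so the
    result is invariant to input ordering.
    """
    xs = sorted(values)
    n = len(xs)
    if n == 0:
        raise ValueError("trimmed_mean of empty sample")
    if one_sided:
        hi = math.floor(n * trim_fraction)
        kept = xs[: n - hi] if hi else xs
    else:
        k = math.floor(n * trim_fraction / 2.0)
        kept = xs[k : n - k] if k else xs
    return sum(kept) / len(kept)


_MIN_STRATUM = 20


def derive_uln(
    cohort: Cohort,
    trim_fraction: float = 0.05,
    one_sided: bool = False,
) -> ULNSet:
    """Derive ULNs from the cohort's week-0 panels by extreme-value trimming.

    ALT is stratified by sex; AST, ALP, total and direct bilirubin are
    pooled.  Each stratum needs at least 20 baseline observations.
    """
    strata: dict[str, list[float]] = {
        "alt_female": [],
        "alt_male": [],
        "ast": [],
        "alp": [],
        "tbil": [],
        "dbil": [],
    }
    for p in cohort:
        if not p.has_baseline():
            continue
        b = p.baseline()
        if b.alt is not None:
            strata["alt_female" if p.sex == "female" else "alt_male"].append(b.alt)
        for name in ("ast", "alp", "tbil", "dbil"):
            v = getattr(b, name)
            if v is not None:
                strata[name].append(v)

    limits: dict[str, float] = {}
    for name, vals in strata.items():
        if len(vals) < _MIN_STRATUM:
            raise DerivationError(
                f"stratum {name!r} has only {len(vals)} baseline values "
                f"(need >= {_MIN_STRATUM})"
            )
        limits[name] = trimmed_mean(vals, trim_fraction, one_sided=one_sided)

    return ULNSet(method="derived", trim_fraction=trim_fraction, **limits)
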