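"""Life expectancy, healthy and unhealthy life years from projections.

Two health-expectancy readings of the projection aggregates:

* **Sullivan (cross-sectional)**: period death probabilities at year t come
  from the year-on-year survival of each cohort, q(a) = 1 - N(a+1, t+1) /
  N(a, t); combined with the year-t disability prevalence pi(a) in a period
  life table with mid-interval deaths (L = l - d/2).  The survival ratio is
  only a cohort identity while the receiving cell is a closed one-year
  class, so the last closed age (94) takes its death flow D/N instead, and
  the open 95+ class closes with a constant hazard, e95 = 1/m95 where
  m95 = D95 / (N95 - D95/2) from the aggregates, with pi(95) applied to
  that remaining expectation.
* **Cohort**: follows the baseline cohort aged A down its diagonal of the
  aggregates; whatever lies beyond the simulation horizon is continued
  deterministically with the final projected year's age-specific rates
  (the horizon cannot observe extinction), and the same open-class closure.

ULY is the pi-weighted sum of person-years, HLY = LE - ULY, so
HLY + ULY = LE holds identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import AGES, OPEN_AGE, SEXES, ValidationError
from .engine import ProjectionAggregates

__all__ = [
    "ExpectancyResult",
    "sullivan_expectancies",
    "cohort_expectancies",
    "difference_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpectancyResult:
    scenario: str
    label: str  # calendar year as str, or "cohort-<baseline year>"
    age: int
    sex: str
    LE: float
    HLY: float
    ULY: float

    def __post_init__(self) -> None:
        if not (self.LE >= 0 and self.HLY >= 0 and self.ULY >= 0):
            raise ValidationError("expectancies must be non-negative")
        if abs(self.HLY + self.ULY - self.LE) > 1e-9:
            raise ValidationError("HLY + ULY must equal LE")


def _life_table(q: np.ndarray, pi: np.ndarray, e_open: float) -> tuple[float, float]:
    """LE and ULY from start-age-relative q, pi (last entry = open class).

    q has one entry per closed age plus none for the open class; pi has one
    entry per age including the open class; e_open is the open-class
    remaining expectation per survivor.
    """
    l = 1.0
    LE = 0.0
    ULY = 0.0
    for i, qa in enumerate(q):
        d = l * qa
        L = l - d / 2.0
        LE += L
        ULY += L * pi[i]
        l -= d
    L_open = l * e_open
    LE += L_open
    ULY += L_open * pi[-1]
    return LE, ULY


def _open_class_expectation(N95: float, D95: float) -> float:
    """Constant-hazard closure: e95 = 1/m95 with m95 = D95 / (N95 - D95/2)."""
    L95 = N95 - D95 / 2.0
    if D95 <= 0:
        raise ValidationError("open age class has no deaths; cannot close life table")
    return L95 / D95


def sullivan_expectancies(agg: ProjectionAggregates, year: int, start_age: int,
                          sex: str, scenario: str = "") -> ExpectancyResult:
    """Cross-sectional LE/HLY/ULY at ``start_age`` in calendar ``year``."""
    t = agg.year_index(year)
    if t + 1 >= len(agg.years):
        raise ValidationError(
            f"Sullivan at {year} needs year {year + 1} in the projection")
    N = agg.N(sex)
    for a in range(start_age, OPEN_AGE + 1):
        if N[t, a] <= 0:
            raise ValidationError(f"empty cell (year={year}, age={a}, sex={sex})")
    ages = np.arange(start_age, OPEN_AGE - 1)
    q = 1.0 - N[t + 1, ages + 1] / N[t, ages]
    # age 94 feeds the open class at t+1, so its survival ratio is not a
    # cohort identity; use the death flow instead
    q = np.append(q, agg.D[sex][t, OPEN_AGE - 1] / N[t, OPEN_AGE - 1])
    pi = agg.disabled[sex][t, start_age:] / N[t, start_age:]
    e95 = _open_class_expectation(N[t, OPEN_AGE], agg.D[sex][t, OPEN_AGE])
    LE, ULY = _life_table(q, pi, e95)
    return ExpectancyResult(scenario=scenario, label=str(year), age=start_age,
                            sex=sex, LE=LE, HLY=LE - ULY, ULY=ULY)


def cohort_expectancies(agg: ProjectionAggregates, baseline_age: int, sex: str,
                        scenario: str = "") -> ExpectancyResult:
    """Cohort LE/HLY/ULY for the baseline cohort aged ``baseline_age``.

    Observed cohort rates run down the aggregate diagonal (age = A + t);
    beyond the horizon the last projected year's rates continue the cohort to
    extinction, with the truncation share (survivors at the switch) logged.
    """
    T = len(agg.years)
    N = agg.N(sex)
    D = agg.D[sex]
    dis = agg.disabled[sex]
    if N[0, baseline_age] <= 0:
        raise ValidationError(
            f"empty baseline cohort (age={baseline_age}, sex={sex})")
    l = 1.0
    LE = 0.0
    ULY = 0.0
    l_switch = None
    for a in range(baseline_age, OPEN_AGE):
        t = min(a - baseline_age, T - 1)
        if N[t, a] <= 0:
            if l <= 0:  # cohort extinct before the open class
                break
            raise ValidationError(f"empty cell (t={t}, age={a}, sex={sex})")
        qa = D[t, a] / N[t, a]
        pia = dis[t, a] / N[t, a]
        d = l * qa
        L = l - d / 2.0
        LE += L
        ULY += L * pia
        l -= d
        if a - baseline_age == T - 2:
            l_switch = l
    if l > 0:
        t95 = min(OPEN_AGE - baseline_age, T - 1)
        e95 = _open_class_expectation(N[t95, OPEN_AGE], D[t95, OPEN_AGE])
        L_open = l * e95
        LE += L_open
        ULY += L_open * dis[t95, OPEN_AGE] / N[t95, OPEN_AGE]
    if l_switch is not None and baseline_age + (T - 1) < OPEN_AGE:
        logger.info(
            "cohort aged %d truncated at the horizon with survival share %.4f; "
            "continued with final-year rates", baseline_age, l_switch)
    return ExpectancyResult(scenario=scenario,
                            label=f"cohort-{agg.baseline_year}",
                            age=baseline_age, sex=sex,
                            LE=LE, HLY=LE - ULY, ULY=ULY)


def difference_table(results: list[ExpectancyResult],
                     reference: list[ExpectancyResult]) -> pd.DataFrame:
    """Scenario-minus-reference differences, rounded to 2 decimals.

    Reference rows keep their levels (differences 0.00); every other row
    reports its levels plus LE/HLY/ULY differences against the reference row
    with the same (label, age, sex) key.  Missing keys raise.
    """
    ref = {(r.label, r.age, r.sex): r for r in reference}
    rows = []
    for r in results:
        key = (r.label, r.age, r.sex)
        if key not in ref:
            raise ValidationError(f"no reference result for key {key}")
        b = ref[key]
        rows.append({
            "scenario": r.scenario, "label": r.label, "age": r.age, "sex": r.sex,
            "LE": round(r.LE, 2), "HLY": round(r.HLY, 2), "ULY": round(r.ULY, 2),
            "LE_diff": round(r.LE - b.LE, 2),
            "HLY_diff": round(r.HLY - b.HLY, 2),
            "ULY_diff": round(r.ULY - b.ULY, 2),
        })
    return pd.DataFrame(rows)
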