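"""Synthetic survey microdata and demographic schedules.

The analysis needs four kinds of input: cross-sectional survey microdata (age,
sex, smoking status in {never, current, former}, activity limitation (GALI) in
{none, not_severe, severe}), baseline population counts and all-cause
mortality by age and sex, and a projected newborn series.  This module
generates all of them from a single deterministic parameter set
(:class:`TruthParams`) so that estimation and projection can be validated
against a known ground truth.

Generating model
----------------
* Smoking: the probability of ever having smoked is logistic in age with a
  quadratic predictor on the rescaled age ``x = age/10``, non-decreasing over
  15..95 (a cross-section in which the never-smoker share rose with age would
  admit no non-negative net starting flow, since never-smoker status can only
  be left); current smokers are a declining logistic share of ever-smokers,
  so current smoking peaks in mid-adulthood and former smoking accumulates
  with age.  Ages below 15 are never-smokers.
* Disability: each record is disabled with probability
  ``logistic(beta0(age, sex) + log OR_state)`` where ``beta0`` is the
  never-smoker log-odds, linear in age, and the odds ratios exceed 1 for
  current and former smokers.  Disabled records split 70/30 into
  not-severely / severely limited; only the dichotomy matters downstream.
* Mortality: Gompertz one-year death probabilities
  ``q(a) = 1 - exp(-level * exp(slope * a))`` per sex.
* Demography: the baseline population is cohort-consistent with the mortality
  schedule and a newborn series declining geometrically, so the baseline age
  pyramid is exactly what the projected newborn/mortality history implies.

All generators are pure functions of ``(truth, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data_io import (
    AGES,
    OPEN_AGE,
    SEXES,
    SMOKING_STATES,
    NewbornSeries,
    PrevalenceTable,
    RateTable,
    StateRatioTable,
    ValidationError,
)

__all__ = [
    "GALI_LEVELS",
    "SurveyRecord",
    "TruthParams",
    "default_truth",
    "smoking_prevalence",
    "disability_prevalence",
    "generate_survey",
    "generate_demography",
    "low_smoking_prevalence",
]

GALI_LEVELS = ("none", "not_severe", "severe")

MIN_ADULT_AGE = 15


@dataclass(frozen=True)
class SurveyRecord:
    """One survey respondent (the row contract of the microdata table)."""

    age: int
    sex: str
    smoking: str
    gali: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.smoking not in SMOKING_STATES:
            raise ValidationError(f"unknown smoking state {self.smoking!r}")
        if self.gali not in GALI_LEVELS:
            raise ValidationError(f"unknown GALI level {self.gali!r}")
        if not self.weight > 0:
            raise ValidationError("weight must be positive")


@dataclass(frozen=True)
class TruthParams:
    """Generating parameters behind every synthetic input.

    smoking_coef[sex]["ever"] are (b0, b1, b2): logit P(ever smoked) = b0 +
    b1*x + b2*x**2 with x = age/10 on ages 15+ (kept non-decreasing on the
    grid); smoking_coef[sex]["current_share"] are (c0, c1): logit of the
    current share among ever-smokers, c0 + c1*x.  disability_logodds[sex]
    are (c0, c1): never-smoker disability log-odds c0 + c1*age.
    """

    smoking_coef: Mapping[str, Mapping[str, tuple[float, ...]]]
    disability_logodds: Mapping[str, tuple[float, float]]
    or_disability: StateRatioTable
    rr_mortality: StateRatioTable
    gompertz: Mapping[str, tuple[float, float]]  # (level, slope) per sex
    newborn_base: Mapping[str, float]
    newborn_decline: float = 0.002
    severity_split: float = 0.70  # share of disabled who are not_severe


def default_truth() -> TruthParams:
    """Deterministic default parameter set.

    Current-smoker prevalence peaks near 25-28% in mid-adulthood and is lower
    for women; former-smoker prevalence rises through adulthood; disability
    prevalence increases with age; odds ratios of disability and relative
    risks of death exceed 1 for current and former smokers.  Gompertz
    parameters give a male period life expectancy at birth between 75 and 82
    years under the deterministic life table.
    """
    return TruthParams(
        smoking_coef={
            "male": {
                "ever": (-2.2, 0.55, -0.0275),
                "current_share": (2.2, -0.45),
            },
            "female": {
                "ever": (-2.6, 0.50, -0.025),
                "current_share": (2.0, -0.42),
            },
        },
        disability_logodds={
            "male": (-5.4, 0.060),
            "female": (-5.2, 0.062),
        },
        or_disability=StateRatioTable(
            current={"male": 1.8, "female": 2.0},
            former={"male": 1.3, "female": 1.4},
        ),
        rr_mortality=StateRatioTable(
            current={"male": 2.1, "female": 1.9},
            former={"male": 1.35, "female": 1.3},
        ),
        gompertz={
            "male": (3.2e-5, 0.097),
            "female": (1.4e-5, 0.104),
        },
        newborn_base={"male": 61500.0, "female": 58500.0},
    )


def _logistic(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


def _poly_logistic(coef: tuple[float, ...], ages: np.ndarray) -> np.ndarray:
    x = np.asarray(ages, dtype=float) / 10.0
    eta = np.zeros_like(x)
    for k, b in enumerate(coef):
        eta += b * x ** k
    return _logistic(eta)


def smoking_prevalence(truth: TruthParams) -> PrevalenceTable:
    """Generating smoking-state prevalence on the full grid.

    Ages below 15 are all never-smokers; from 15 on, current = ever-smoked
    curve times the current share, former the remainder of ever, never the
    rest.  The ever curve must be non-decreasing on the grid so that the
    implied net starting flow is non-negative at every age.
    """
    probs = {}
    for sex in SEXES:
        p = np.zeros((len(AGES), 3))
        p[:, 0] = 1.0
        adult = AGES >= MIN_ADULT_AGE
        ever = _poly_logistic(truth.smoking_coef[sex]["ever"], AGES[adult])
        if np.any(np.diff(ever) < 0):
            raise ValidationError("truth ever-smoked curve must be non-decreasing")
        share = _poly_logistic(truth.smoking_coef[sex]["current_share"], AGES[adult])
        cur = ever * share
        fmr = ever * (1.0 - share)
        p[adult, 0], p[adult, 1], p[adult, 2] = 1.0 - ever, cur, fmr
        probs[sex] = p
    return PrevalenceTable(probs)


def _disability_by_state(truth: TruthParams, sex: str) -> np.ndarray:
    """State-specific disability probabilities d_k(a) implied by the truth,
    zero below age 15.  Shape (96, 3) in state order never/current/former."""
    c0, c1 = truth.disability_logodds[sex]
    beta0 = c0 + c1 * AGES.astype(float)
    log_or = np.log(truth.or_disability.ratios(sex))
    d = _logistic(beta0[:, None] + log_or[None, :])
    d[AGES < MIN_ADULT_AGE, :] = 0.0
    return d


def disability_prevalence(truth: TruthParams) -> RateTable:
    """Overall disability prevalence pi(a,s) implied by the truth: the
    smoking-prevalence-weighted mixture of state-specific probabilities."""
    prev = smoking_prevalence(truth)
    values = {}
    for sex in SEXES:
        d = _disability_by_state(truth, sex)
        values[sex] = (prev.probs[sex] * d).sum(axis=1)
    return RateTable(values, kind="probability")


def mortality_schedule(truth: TruthParams) -> RateTable:
    """Gompertz one-year death probabilities q(a,s), capped at 1."""
    values = {}
    for sex in SEXES:
        level, slope = truth.gompertz[sex]
        q = 1.0 - np.exp(-level * np.exp(slope * AGES.astype(float)))
        values[sex] = np.minimum(q, 1.0)
    return RateTable(values, kind="probability")


def generate_demography(truth: TruthParams, baseline_year: int,
                        horizon_years: int = 30
                        ) -> tuple[RateTable, RateTable, NewbornSeries]:
    """Baseline population counts, mortality schedule and newborn projection.

    The newborn series covers ``baseline_year .. baseline_year + horizon + 2``
    (two spare years so a projection can carry the extra calendar year that
    period life tables at the final year need).  Population counts are
    cohort-consistent: the cohort aged ``a`` at baseline is the newborn count
    ``a`` years before baseline (extrapolating the same geometric trend
    backwards) times cumulative survival to age ``a``.
    """
    mortality = mortality_schedule(truth)
    years = tuple(range(baseline_year, baseline_year + horizon_years + 3))
    g = 1.0 - truth.newborn_decline
    counts = {
        sex: truth.newborn_base[sex] * g ** np.arange(len(years), dtype=float)
        for sex in SEXES
    }
    newborns = NewbornSeries(years=years, counts=counts)
    pop = {}
    for sex in SEXES:
        q = mortality.values[sex]
        # survival l(a): probability of reaching age a from birth
        l = np.concatenate([[1.0], np.cumprod(1.0 - q[:-1])])
        birth_cohorts = truth.newborn_base[sex] * g ** (-AGES.astype(float))
        counts = birth_cohorts * l
        # the open 95+ class holds its accumulated stationary count:
        # inflow l(95) balanced against the class death probability q(95)
        counts[OPEN_AGE] = counts[OPEN_AGE] / q[OPEN_AGE]
        pop[sex] = counts
    return RateTable(pop, kind="rate"), mortality, newborns


def generate_survey(truth: TruthParams, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` survey records (ages 15+) as a DataFrame.

    Columns: age, sex, smoking, gali, weight (all weights 1).  Ages and sexes
    are drawn proportionally to the synthetic population aged 15+, smoking
    from the truth prevalence curves, and GALI from the state-specific
    disability odds; disabled records split 70/30 into not_severe / severe.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    population, _, _ = generate_demography(truth, baseline_year=2018)
    prev = smoking_prevalence(truth)

    cells = [(sex, int(age)) for sex in SEXES for age in AGES if age >= MIN_ADULT_AGE]
    weights = np.array([population.values[sex][age] for sex, age in cells])
    idx = rng.choice(len(cells), size=n, p=weights / weights.sum())
    sexes = np.array([cells[i][0] for i in idx])
    ages = np.array([cells[i][1] for i in idx])

    smoking = np.empty(n, dtype=object)
    gali = np.empty(n, dtype=object)
    u_state = rng.random(n)
    u_dis = rng.random(n)
    u_sev = rng.random(n)
    for sex in SEXES:
        mask = sexes == sex
        cum = np.cumsum(prev.probs[sex], axis=1)[ages[mask]]
        state_idx = (u_state[mask, None] > cum).sum(axis=1)
        state_idx = np.minimum(state_idx, 2)
        smoking[mask] = np.asarray(SMOKING_STATES, dtype=object)[state_idx]
        d = _disability_by_state(truth, sex)[ages[mask], state_idx]
        disabled = u_dis[mask] < d
        g = np.where(disabled,
                     np.where(u_sev[mask] < truth.severity_split,
                              "not_severe", "severe"),
                     "none")
        gali[mask] = g
    return pd.DataFrame({
        "age": ages.astype(int),
        "sex": sexes,
        "smoking": smoking,
        "gali": gali,
        "weight": np.ones(n),
    })


def low_smoking_prevalence(truth: TruthParams) -> PrevalenceTable:
    """An alternative low-smoking prevalence table.

    Emulates a country at the low end of the European smoking distribution:
    at every age 15+, current-smoker prevalence is 45% of the default truth's
    (hence strictly below it), with the removed mass split between former
    (5/11) and never (6/11) smokers.  Ages below 15 are unchanged (all never).
    """
    base = smoking_prevalence(truth)
    probs = {}
    for sex in SEXES:
        p = base.probs[sex].copy()
        adult = AGES >= MIN_ADULT_AGE
        removed = 0.55 * p[adult, 1]
        p[adult, 1] -= removed
        p[adult, 2] += removed * (5.0 / 11.0)
        p[adult, 0] += removed * (6.0 / 11.0)
        probs[sex] = p
    return PrevalenceTable(probs)
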