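"""Prevalence smoothing and disability models from survey microdata.

Smoking-state prevalence is smoothed over age with fractional-polynomial (FP)
logistic regressions: for each sex, three binary outcomes (current vs rest,
former vs rest, never vs rest) are fitted independently and the three fitted
curves are then renormalized per age so the state probabilities sum to 100%.
Disability (the GALI dichotomy: limited, severely or not, vs not limited) gets
an FP-logistic age curve per sex, and odds ratios of disability for current
and former smokers (reference: never) come from a logistic regression on
smoking status adjusting for age and age squared, per sex.

The FP candidate set is the conventional one: powers of the rescaled age
``x = age/10`` drawn from {-2, -1, -0.5, 0, 0.5, 1, 2, 3} (0 meaning log x),
with one- and two-term models.  Selection follows the usual FP
function-selection procedure: the lowest-deviance model within each degree
(ties: lexicographically smaller power set), with the two-term winner kept
only when it improves on the one-term winner by more than the 2-df
chi-square critical value at the 5% level — otherwise an extra power term
always buys a spurious chance improvement and the generating model would
never be selected.

Record weights, when not all 1, enter the fits as frequency weights; no
complex-survey variance estimation is attempted (point estimates only flow
downstream).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_io import (
    AGES,
    SEXES,
    SMOKING_STATES,
    PrevalenceTable,
    RateTable,
    StateRatioTable,
    ValidationError,
)
from .synthetic_data import MIN_ADULT_AGE

__all__ = [
    "FP_POWERS",
    "FPModel",
    "DisabilityInputs",
    "fit_fp_logistic",
    "estimate_smoking_prevalence",
    "estimate_disability_model",
]

FP_POWERS: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

_MIN_RECORDS = 50
_SEP_EPS = 1e-8
_CHI2_2DF_95 = 5.991464547107979  # chi2.ppf(0.95, df=2)


class SeparationError(ValidationError):
    """Logistic fit is degenerate (fitted probabilities all 0/1); a larger
    sample is needed."""


def _fp_design(ages: np.ndarray, powers: tuple[float, ...]) -> np.ndarray:
    """Design matrix (with intercept) of FP terms of x = age/10."""
    x = np.asarray(ages, dtype=float) / 10.0
    cols = [np.ones_like(x)]
    for p in powers:
        cols.append(np.log(x) if p == 0.0 else x ** p)
    return np.column_stack(cols)


@dataclass(frozen=True)
class FPModel:
    """A fitted fractional-polynomial logistic curve for one outcome and sex."""

    outcome: str
    sex: str
    powers: tuple[float, ...]
    coef: np.ndarray  # intercept first, then one coefficient per power term
    deviance: float

    def predict(self, ages: np.ndarray) -> np.ndarray:
        """Fitted probabilities at the given ages (must be > 0)."""
        eta = _fp_design(np.asarray(ages), self.powers) @ self.coef
        return 1.0 / (1.0 + np.exp(-eta))


def _outcome_indicator(records: pd.DataFrame, outcome: str) -> np.ndarray:
    if outcome in SMOKING_STATES:
        return (records["smoking"] == outcome).to_numpy()
    if outcome == "disabled":
        return (records["gali"] != "none").to_numpy()
    raise ValidationError(
        f"unknown outcome {outcome!r}; expected one of {SMOKING_STATES} or 'disabled'")


def _aggregate_binomial(ages: np.ndarray, y: np.ndarray, w: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Collapse records to per-age (successes, failures) weight totals."""
    df = pd.DataFrame({"age": ages, "s": np.where(y, w, 0.0), "f": np.where(y, 0.0, w)})
    g = df.groupby("age", sort=True).sum()
    return g.index.to_numpy(dtype=float), g[["s", "f"]].to_numpy()


def fit_fp_logistic(records: pd.DataFrame, outcome: str, sex: str) -> FPModel:
    """Select and fit the best FP logistic curve of an outcome on age.

    Searches all one- and two-power models over :data:`FP_POWERS`, fits each
    by maximum likelihood, and picks the winner by the FP function-selection
    procedure (best of each degree, two-term kept only on a significant
    deviance improvement; ties go to the lexicographically smaller powers).
    """
    sub = records[records["sex"] == sex]
    if len(sub) < _MIN_RECORDS:
        raise ValidationError(
            f"need >= {_MIN_RECORDS} records for sex={sex!r}, got {len(sub)}")
    y = _outcome_indicator(sub, outcome)
    if y.all() or (~y).all():
        raise ValidationError(
            f"outcome {outcome!r} is constant for sex={sex!r}; both classes required")
    w = sub["weight"].to_numpy(dtype=float) if "weight" in sub else np.ones(len(sub))
    ages, counts = _aggregate_binomial(sub["age"].to_numpy(dtype=float), y, w)

    candidates = [(p,) for p in FP_POWERS]
    candidates += list(itertools.combinations(FP_POWERS, 2))

    fits: list[tuple[float, int, tuple[float, ...], np.ndarray]] = []
    for powers in candidates:
        X = _fp_design(ages, powers)
        try:
            res = sm.GLM(counts, X, family=sm.families.Binomial()).fit()
        except Exception:  # singular / non-converged candidate: skip
            continue
        if not np.all(np.isfinite(res.params)):
            continue
        fits.append((float(res.deviance), len(powers), tuple(powers),
                     np.asarray(res.params)))
    if not fits:
        raise SeparationError(
            f"no FP logistic candidate converged for outcome={outcome!r}, "
            f"sex={sex!r}; a larger sample may help")
    def _best(degree: int):
        pool = [f for f in fits if f[1] == degree]
        if not pool:
            return None
        dev_min = min(f[0] for f in pool)
        # deviance ties within numerical noise: lexicographic power order
        return min((f for f in pool if f[0] <= dev_min + 1e-7),
                   key=lambda f: f[2])

    best1, best2 = _best(1), _best(2)
    chosen = best1 or best2
    if best1 and best2 and best1[0] - best2[0] > _CHI2_2DF_95:
        chosen = best2
    dev, _, powers, coef = chosen
    model = FPModel(outcome=outcome, sex=sex, powers=powers, coef=coef,
                    deviance=dev)
    mu = model.predict(ages)
    if np.all((mu < _SEP_EPS) | (mu > 1 - _SEP_EPS)):
        raise SeparationError(
            f"separation in FP logistic fit for outcome={outcome!r}, sex={sex!r}; "
            "fitted probabilities are all 0/1 — a larger sample is needed")
    return model


def estimate_smoking_prevalence(records: pd.DataFrame) -> PrevalenceTable:
    """Smoothed, internally normalized smoking-state prevalence.

    Per sex, fits three binary FP-logistic curves (current, former, never,
    each vs the rest), predicts them on the age grid and divides by their sum
    per age so the three estimates sum to 100%.  Ages below 15 are set to
    all-never.
    """
    probs = {}
    adult_ages = AGES[AGES >= MIN_ADULT_AGE]
    for sex in SEXES:
        raw = np.column_stack([
            fit_fp_logistic(records, state, sex).predict(adult_ages)
            for state in SMOKING_STATES
        ])
        raw /= raw.sum(axis=1, keepdims=True)
        p = np.zeros((len(AGES), 3))
        p[:, 0] = 1.0
        p[AGES >= MIN_ADULT_AGE] = raw
        probs[sex] = p
    return PrevalenceTable(probs)


@dataclass(frozen=True)
class DisabilityInputs:
    """Overall disability prevalence pi(a,s) plus odds ratios of disability by
    smoking state (never = 1 by construction)."""

    pi: RateTable
    odds_ratios: StateRatioTable


def _fit_or_model(sub: pd.DataFrame, sex: str) -> tuple[float, float]:
    """Odds ratios (current, former) of disability vs never, adjusting for
    age and age squared, from a logistic regression within one sex."""
    for state in SMOKING_STATES:
        if not (sub["smoking"] == state).any():
            raise ValidationError(
                f"smoking category {state!r} absent for sex={sex!r}; "
                "cannot estimate its odds ratio")
    y = (sub["gali"] != "none").to_numpy()
    w = sub["weight"].to_numpy(dtype=float) if "weight" in sub else np.ones(len(sub))
    # collapse to (age, smoking) binomial cells
    df = pd.DataFrame({
        "age": sub["age"].to_numpy(dtype=float),
        "smoking": sub["smoking"].to_numpy(),
        "s": np.where(y, w, 0.0),
        "f": np.where(y, 0.0, w),
    })
    g = df.groupby(["age", "smoking"], sort=True).sum().reset_index()
    age = g["age"].to_numpy()
    X = np.column_stack([
        np.ones(len(g)),
        (g["smoking"] == "current").to_numpy(float),
        (g["smoking"] == "former").to_numpy(float),
        age,
        age ** 2,
    ])
    res = sm.GLM(g[["s", "f"]].to_numpy(), X, family=sm.families.Binomial()).fit()
    if not np.all(np.isfinite(res.params)):
        raise SeparationError(f"disability OR model did not converge for sex={sex!r}")
    return float(np.exp(res.params[1])), float(np.exp(res.params[2]))


def estimate_disability_model(records: pd.DataFrame) -> DisabilityInputs:
    """Overall disability prevalence curve and smoking odds ratios per sex.

    The prevalence curve is an FP-logistic fit of the GALI dichotomy on age
    (zero below age 15); the odds ratios come from a logistic regression of
    disability on smoking status with age + age^2 adjustment.
    """
    pi_values = {}
    or_current: dict[str, float] = {}
    or_former: dict[str, float] = {}
    for sex in SEXES:
        curve = fit_fp_logistic(records, "disabled", sex)
        pi = np.zeros(len(AGES))
        adult = AGES >= MIN_ADULT_AGE
        pi[adult] = curve.predict(AGES[adult])
        pi_values[sex] = pi
        sub = records[records["sex"] == sex]
        if len(sub) < _MIN_RECORDS:
            raise ValidationError(f"need >= {_MIN_RECORDS} records for sex={sex!r}")
        or_current[sex], or_former[sex] = _fit_or_model(sub, sex)
    return DisabilityInputs(
        pi=RateTable(pi_values, kind="probability"),
        odds_ratios=StateRatioTable(current=or_current, former=or_former),
    )
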