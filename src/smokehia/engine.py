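"""Population projection: partial microsimulation and deterministic recursion.

Both engines project the baseline population 30 years (configurable) forward
under a scenario-transformed prevalence and transition schedule, with
state-specific mortality held at its reference derivation.

The microsimulation is *partial*: individual smoking histories are stochastic
(one uniform draw per person-year decides start/quit/restart), but survival
is carried as a deterministic fractional alive-weight multiplied by
(1 - q_state) each year — no random death events — which removes most Monte
Carlo variance from the mortality side.  The transition kernel is the exact
stochastic counterpart of the net-flow balance: start acts on never-smokers
first, and the net quit flow then acts on the post-start current pool, so a
never-smoker can pass through current to former within one year; a net
restart flow acts on the start-of-year former pool only.  The deterministic
engine propagates the exact expectation of the same bookkeeping via a matrix
recursion on state counts and serves as the microsimulation's oracle and
fast path.

Within a year, the survival update comes first and the transition second;
ages then advance, with the 95+ class absorbing.  Newborn cohorts enter each
year at age 0 as never-smokers, weighted by the newborn series.  One extra
calendar year beyond the configured horizon is projected internally so that
period (Sullivan) life tables at the final reported year have the year+1
survival they need.

``common_random_runs`` simulates a list of scenarios with the same
individuals and the same per-person-year uniform draws, so scenario
differences are not dominated by Monte Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

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
    RunConfig,
    ValidationError,
)
from .rates import DisabilityModel, StateMortality, TransitionSchedule
from .scenarios import ScenarioSpec, apply_scenario

__all__ = [
    "BaselineInputs",
    "ProjectionAggregates",
    "simulate",
    "run_deterministic",
    "common_random_runs",
    "deterministic_runs",
]

N_AGES = len(AGES)


@dataclass(frozen=True)
class BaselineInputs:
    """Everything a projection needs, already on the common grid."""

    prev: PrevalenceTable
    ts: TransitionSchedule
    sm: StateMortality
    dis: DisabilityModel
    population: RateTable
    newborns: NewbornSeries


class ProjectionAggregates:
    """Weighted person-counts by calendar year x age x sex x smoking state.

    Arrays are indexed [t, age(, state)] with t = 0 at the baseline year.
    ``N`` is the total count at the start of the year, ``D`` the death flow
    within the year, ``disabled`` the expected disabled count
    (sum over states of state count times d_state).
    """

    def __init__(self, baseline_year: int, n_years: int,
                 n_baseline_individuals: int | None = None) -> None:
        self.baseline_year = baseline_year
        self.years = np.arange(baseline_year, baseline_year + n_years)
        self.Nk: dict[str, np.ndarray] = {
            sex: np.zeros((n_years, N_AGES, 3)) for sex in SEXES}
        # N is accumulated directly (not derived from Nk) so that it does not
        # inherit floating-point summation-order differences from the state
        # split; Nk sums back to N within 1e-9 relative
        self._N: dict[str, np.ndarray] = {
            sex: np.zeros((n_years, N_AGES)) for sex in SEXES}
        self.D: dict[str, np.ndarray] = {
            sex: np.zeros((n_years, N_AGES)) for sex in SEXES}
        self.disabled: dict[str, np.ndarray] = {
            sex: np.zeros((n_years, N_AGES)) for sex in SEXES}
        self.n_baseline_individuals = n_baseline_individuals

    def N(self, sex: str) -> np.ndarray:
        return self._N[sex]

    def sync_totals(self) -> None:
        """Recompute the total-count array from the state split (for
        aggregates assembled by hand rather than by an engine)."""
        for sex in SEXES:
            self._N[sex][:] = self.Nk[sex].sum(axis=2)

    def year_index(self, year: int) -> int:
        if not (self.years[0] <= year <= self.years[-1]):
            raise ValidationError(
                f"year {year} outside projection {self.years[0]}..{self.years[-1]}")
        return int(year - self.years[0])

    def prevalence(self, sex: str) -> np.ndarray:
        """State shares per [t, age]; NaN where the cell is empty."""
        N = self.N(sex)
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.Nk[sex] / N[:, :, None]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sex in SEXES:
            N = self.N(sex)
            for t, year in enumerate(self.years):
                for a in range(N_AGES):
                    rows.append({
                        "year": int(year), "age": int(AGES[a]), "sex": sex,
                        "N": N[t, a],
                        "N_never": self.Nk[sex][t, a, 0],
                        "N_current": self.Nk[sex][t, a, 1],
                        "N_former": self.Nk[sex][t, a, 2],
                        "deaths": self.D[sex][t, a],
                        "disabled_person_years": self.disabled[sex][t, a],
                    })
        return pd.DataFrame(rows)


def _n_time_points(cfg: RunConfig) -> int:
    # one extra internal year for period life tables at the final horizon year
    return cfg.horizon_years + 2


def _check_newborn_cover(newborns: NewbornSeries, cfg: RunConfig) -> None:
    last_needed = cfg.baseline_year + cfg.horizon_years + 1
    if last_needed > newborns.years[-1]:
        raise ValidationError(
            f"projection needs newborns through {last_needed} but the series "
            f"ends in {newborns.years[-1]}")


def run_deterministic(prev: PrevalenceTable, ts: TransitionSchedule,
                      sm: StateMortality, dis: DisabilityModel,
                      population: RateTable, newborns: NewbornSeries,
                      cfg: RunConfig) -> ProjectionAggregates:
    """Exact expectation of the projection via a state-count recursion."""
    _check_newborn_cover(newborns, cfg)
    T = _n_time_points(cfg)
    agg = ProjectionAggregates(cfg.baseline_year, T)
    for sex in SEXES:
        q = sm.q[sex]
        d = dis.d[sex]
        start = ts.start[sex]
        quit_p = ts.quit(sex)
        restart_p = ts.restart(sex)
        Nk = agg.Nk[sex]
        Nk[0] = population.values[sex][:, None] * prev.probs[sex]
        for t in range(T - 1):
            n = Nk[t] * (1.0 - q)
            moved = start * n[:, 0]
            never = n[:, 0] - moved
            current = n[:, 1] + moved
            former = n[:, 2]
            qf = quit_p * current
            rf = restart_p * former
            trans = np.column_stack([never, current - qf + rf, former + qf - rf])
            Nk[t + 1, 1:, :] = trans[:-1]
            Nk[t + 1, OPEN_AGE, :] += trans[OPEN_AGE]
            Nk[t + 1, 0, 0] += newborns.count(int(agg.years[t + 1]), sex)
        agg._N[sex][:] = Nk.sum(axis=2)
        agg.D[sex][:] = (Nk * q[None, :, :]).sum(axis=2)
        agg.disabled[sex][:] = (Nk * d[None, :, :]).sum(axis=2)
    return agg


# ---------------------------------------------------------------------------
# microsimulation


@dataclass(frozen=True)
class _Draws:
    """Frozen per-sex random inputs shared across scenarios.

    ``u_init`` decides the baseline smoking state of each initial individual;
    ``u_trans[i, t]`` decides individual i's transition in year t.
    """

    u_init: dict[str, np.ndarray]
    u_trans: dict[str, np.ndarray]
    n_per_class: int
    n_years: int


def _make_draws(cfg: RunConfig) -> _Draws:
    T = _n_time_points(cfg)
    n = cfg.n_per_class
    n_total = N_AGES * n + (T - 1) * n
    ss = np.random.SeedSequence(cfg.seed)
    u_init, u_trans = {}, {}
    for sex, child in zip(SEXES, ss.spawn(len(SEXES))):
        rng = np.random.default_rng(child)
        u_init[sex] = rng.random(N_AGES * n)
        u_trans[sex] = rng.random((n_total, T - 1))
    return _Draws(u_init=u_init, u_trans=u_trans, n_per_class=n, n_years=T)


def _simulate_with_draws(prev: PrevalenceTable, ts: TransitionSchedule,
                         sm: StateMortality, dis: DisabilityModel,
                         population: RateTable, newborns: NewbornSeries,
                         cfg: RunConfig, draws: _Draws) -> ProjectionAggregates:
    _check_newborn_cover(newborns, cfg)
    T = draws.n_years
    n = draws.n_per_class
    agg = ProjectionAggregates(cfg.baseline_year, T,
                               n_baseline_individuals=2 * N_AGES * n)
    for sex in SEXES:
        q = sm.q[sex]
        d = dis.d[sex]
        start_p = ts.start[sex]
        quit_p = ts.quit(sex)
        restart_p = ts.restart(sex)

        n_initial = N_AGES * n
        n_total = n_initial + (T - 1) * n
        ages = np.zeros(n_total, dtype=np.int64)
        ages[:n_initial] = np.repeat(AGES, n)
        state = np.zeros(n_total, dtype=np.int64)
        cum = np.cumsum(prev.probs[sex], axis=1)
        state[:n_initial] = np.minimum(
            (draws.u_init[sex][:, None] > cum[ages[:n_initial]]).sum(axis=1), 2)
        wpop = np.zeros(n_total)
        wpop[:n_initial] = population.values[sex][ages[:n_initial]] / n
        active_from = np.zeros(n_total, dtype=np.int64)
        for b in range(1, T):
            lo = n_initial + (b - 1) * n
            active_from[lo:lo + n] = b
            wpop[lo:lo + n] = newborns.count(cfg.baseline_year + b, sex) / n
        alive = np.ones(n_total)

        U = draws.u_trans[sex]
        for t in range(T):
            act = active_from <= t
            a = ages[act]
            st = state[act]
            w = wpop[act] * alive[act]
            idx = a * 3 + st
            agg.Nk[sex][t] += np.bincount(idx, weights=w,
                                          minlength=3 * N_AGES).reshape(N_AGES, 3)
            agg._N[sex][t] += np.bincount(a, weights=w, minlength=N_AGES)
            qv = q[a, st]
            agg.D[sex][t] += np.bincount(a, weights=w * qv, minlength=N_AGES)
            agg.disabled[sex][t] += np.bincount(a, weights=w * d[a, st],
                                                minlength=N_AGES)
            if t == T - 1:
                break
            alive[act] *= 1.0 - qv
            u = U[act, t]
            si, qi, ri = start_p[a], quit_p[a], restart_p[a]
            new_st = st.copy()
            # never-smokers who start are exposed to the same year's net quit
            # flow (the balance equations apply quit to the post-start pool),
            # so never -> former is a possible two-hop within one year
            nv = st == 0
            new_st[nv & (u < si * (1.0 - qi))] = 1
            new_st[nv & (u >= si * (1.0 - qi)) & (u < si)] = 2
            new_st[(st == 1) & (u < qi)] = 2
            # net restart applies to the start-of-year former pool only
            new_st[(st == 2) & (u < ri)] = 1
            state[act] = new_st
            ages[act] = np.minimum(a + 1, OPEN_AGE)
    return agg


def simulate(prev: PrevalenceTable, ts: TransitionSchedule, sm: StateMortality,
             dis: DisabilityModel, population: RateTable,
             newborns: NewbornSeries, cfg: RunConfig) -> ProjectionAggregates:
    """Partial microsimulation of one (already scenario-transformed) setting.

    Creates ``cfg.n_per_class`` individuals per one-year age class 0-95 per
    sex (so 480,000 at the default 2500), each representing
    cell population / n_per_class persons, and projects them with stochastic
    smoking paths and deterministic alive-weights.  Seeded by ``cfg.seed``.
    """
    return _simulate_with_draws(prev, ts, sm, dis, population, newborns, cfg,
                                _make_draws(cfg))


def common_random_runs(specs: Sequence[ScenarioSpec], inputs: BaselineInputs,
                       cfg: RunConfig) -> dict[str, ProjectionAggregates]:
    """Microsimulate each scenario with identical individuals and draws."""
    if not specs:
        raise ValidationError("at least one scenario is required")
    draws = _make_draws(cfg)
    out = {}
    for spec in specs:
        prev_s, ts_s = apply_scenario(spec, inputs.prev, inputs.ts, inputs.sm)
        out[spec.name] = _simulate_with_draws(
            prev_s, ts_s, inputs.sm, inputs.dis, inputs.population,
            inputs.newborns, cfg, draws)
    return out


def deterministic_runs(specs: Sequence[ScenarioSpec], inputs: BaselineInputs,
                       cfg: RunConfig) -> dict[str, ProjectionAggregates]:
    """Deterministic projection of each scenario."""
    if not specs:
        raise ValidationError("at least one scenario is required")
    out = {}
    for spec in specs:
        prev_s, ts_s = apply_scenario(spec, inputs.prev, inputs.ts, inputs.sm)
        out[spec.name] = run_deterministic(
            prev_s, ts_s, inputs.sm, inputs.dis, inputs.population,
            inputs.newborns, cfg)
    return out
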