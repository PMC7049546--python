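"""Tobacco-control scenarios as declarative transforms of the baseline.

A scenario is a pair of optional transforms: one applied once to the baseline
smoking prevalence at simulation start, one applied to the net transition
schedule used in every projection year.  The registry covers the
business-as-usual reference and eight alternatives:

========================  =====================================================
name                      definition
========================  =====================================================
reference                 business as usual (identity transforms)
smoking_free              population consists of never smokers only
zero_restart              (re)start chances equal 0%
all_quit                  quit chances equal 100%
zero_restart_all_quit     both of the above
low_prevalence            swap in a supplied low-smoking prevalence table and
                          re-derive net transitions so it is stationary
no_init_under_18          zero smoking prevalence below age 18 (and no
                          initiation below 18; rates at 18+ untouched)
quit_x1_3                 quit chances multiplied by 1.3 (capped at 1)
quit_x2                   quit chances multiplied by 2.0 (capped at 1)
========================  =====================================================

Quit-chance scenarios act every projection year, not as one-off shocks.
Transition transforms always recompute from the untransformed baseline
schedule, so applying a scenario twice equals applying it once.  Scenarios
change population composition only; state-specific mortality hazards are
derived once from the reference inputs and held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .data_io import AGES, SEXES, PrevalenceTable, ValidationError
from .rates import StateMortality, TransitionSchedule, derive_net_transitions

__all__ = [
    "ScenarioSpec",
    "SCENARIO_ORDER",
    "scenario_names",
    "make_scenario",
    "apply_scenario",
]

PrevTransform = Callable[[PrevalenceTable], PrevalenceTable]
TransTransform = Callable[[TransitionSchedule], TransitionSchedule]


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    description: str
    prevalence_transform: PrevTransform | None = None
    transition_transform: TransTransform | None = None
    rederive_transitions: bool = False


def _all_never(prev: PrevalenceTable) -> PrevalenceTable:
    probs = {}
    for sex in SEXES:
        p = np.zeros_like(prev.probs[sex])
        p[:, 0] = 1.0
        probs[sex] = p
    return PrevalenceTable(probs)


def _never_below(age_limit: int) -> PrevTransform:
    def transform(prev: PrevalenceTable) -> PrevalenceTable:
        probs = {}
        for sex in SEXES:
            p = prev.probs[sex].copy()
            young = AGES < age_limit
            p[young] = 0.0
            p[young, 0] = 1.0
            probs[sex] = p
        return PrevalenceTable(probs)
    return transform


def _edit_transitions(edit) -> TransTransform:
    """Lift a per-sex (start, net_cf) -> (start, net_cf) edit into a transform
    anchored at the baseline schedule (idempotent by construction)."""
    def transform(ts: TransitionSchedule) -> TransitionSchedule:
        base = ts.root()
        start, net_cf = {}, {}
        for sex in SEXES:
            start[sex], net_cf[sex] = edit(base.start[sex].copy(),
                                           base.net_cf[sex].copy())
        return TransitionSchedule(start, net_cf, baseline=base)
    return transform


def _no_start(start, net_cf):
    return np.zeros_like(start), net_cf


def _zero_restart(start, net_cf):
    return np.zeros_like(start), np.maximum(net_cf, 0.0)


def _all_quit(start, net_cf):
    # quit chance 100% wherever the net flow is not a restart; restarts kept
    return start, np.where(net_cf >= 0, 1.0, net_cf)


def _zero_restart_all_quit(start, net_cf):
    return np.zeros_like(start), np.ones_like(net_cf)


def _no_start_below(age_limit: int):
    def edit(start, net_cf):
        start[AGES < age_limit] = 0.0
        return start, net_cf
    return edit


def _quit_times(factor: float):
    def edit(start, net_cf):
        return start, np.where(net_cf > 0, np.minimum(factor * net_cf, 1.0), net_cf)
    return edit


def make_scenario(name: str, params: dict | None = None) -> ScenarioSpec:
    """Build a :class:`ScenarioSpec` from the registry.

    ``low_prevalence`` requires ``params={"prevalence_table": PrevalenceTable}``
    (the alternative table whose transitions are re-derived); no other
    scenario takes parameters.
    """
    params = params or {}
    if name == "reference":
        return ScenarioSpec(name, "business-as-usual")
    if name == "smoking_free":
        return ScenarioSpec(
            name, "population consists of never smokers only",
            prevalence_transform=_all_never,
            transition_transform=_edit_transitions(_no_start))
    if name == "zero_restart":
        return ScenarioSpec(
            name, "(re)start chances equal 0%",
            transition_transform=_edit_transitions(_zero_restart))
    if name == "all_quit":
        return ScenarioSpec(
            name, "quit chances equal 100%",
            transition_transform=_edit_transitions(_all_quit))
    if name == "zero_restart_all_quit":
        return ScenarioSpec(
            name, "(re)start chances 0% and quit chances 100%",
            transition_transform=_edit_transitions(_zero_restart_all_quit))
    if name == "low_prevalence":
        table = params.get("prevalence_table")
        if table is None:
            raise ValidationError(
                "low_prevalence requires params={'prevalence_table': ...}")
        return ScenarioSpec(
            name, "alternative low-smoking prevalence, transitions re-derived",
            prevalence_transform=lambda _prev: table,
            rederive_transitions=True)
    if name == "no_init_under_18":
        return ScenarioSpec(
            name, "zero smoking prevalence below age 18",
            prevalence_transform=_never_below(18),
            transition_transform=_edit_transitions(_no_start_below(18)))
    if name == "quit_x1_3":
        return ScenarioSpec(
            name, "quit chances multiplied by 1.3",
            transition_transform=_edit_transitions(_quit_times(1.3)))
    if name == "quit_x2":
        return ScenarioSpec(
            name, "quit chances multiplied by 2.0",
            transition_transform=_edit_transitions(_quit_times(2.0)))
    raise ValidationError(
        f"unknown scenario {name!r}; valid names: {sorted(scenario_names())}")


SCENARIO_ORDER: tuple[str, ...] = (
    "reference",
    "smoking_free",
    "zero_restart",
    "all_quit",
    "zero_restart_all_quit",
    "low_prevalence",
    "no_init_under_18",
    "quit_x1_3",
    "quit_x2",
)


def scenario_names() -> tuple[str, ...]:
    return SCENARIO_ORDER


def apply_scenario(spec: ScenarioSpec, prev: PrevalenceTable,
                   ts: TransitionSchedule,
                   sm: StateMortality | None = None
                   ) -> tuple[PrevalenceTable, TransitionSchedule]:
    """Apply a scenario to the baseline prevalence and transition schedule.

    The prevalence transform acts once (at baseline); the transition
    transform yields the schedule used in every projection year.  Scenarios
    that re-derive transitions (``low_prevalence``) need the baseline
    state-specific mortality ``sm``.
    """
    prev_out = spec.prevalence_transform(prev) if spec.prevalence_transform else prev
    if spec.rederive_transitions:
        if sm is None:
            raise ValidationError(
                f"scenario {spec.name!r} re-derives transitions and needs "
                "state-specific mortality")
        ts_out = derive_net_transitions(prev_out, sm)
    elif spec.transition_transform:
        ts_out = spec.transition_transform(ts)
    else:
        ts_out = ts
    return prev_out, ts_out
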