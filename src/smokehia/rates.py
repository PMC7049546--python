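"""State-specific mortality, stationary net transitions, disability linkage.

Three derivations turn the estimated inputs into projection machinery:

1. ``partition_mortality`` splits baseline all-cause death probabilities
   q(a,s) into never/current/former-specific probabilities using relative
   risks, so that the prevalence-weighted mixture returns the baseline:
   q_never = q / (p_n + p_c RR_c + p_f RR_f), q_k = RR_k q_never.

2. ``derive_net_transitions`` finds the net start (never -> current) and a
   single signed current <-> former flow per age step that keep the
   age-specific smoking prevalence stationary over calendar time: survivors
   of age a, redistributed by these flows, must land exactly on the age a+1
   prevalence.  With three states and two free prevalence constraints this is
   exactly identified once the flows are attributed to "start" (never can
   only lose members) and one net quit/restart flow.

3. ``solve_disability`` finds, per cell, the baseline disability log-odds
   beta0 such that the prevalence-weighted mixture of state-specific
   disability probabilities logistic(beta0 + log OR_k) reproduces the overall
   disability prevalence pi(a,s); a prevalence-odds attribution of disability
   to smoking states.

Within a year, mortality acts first and transitions second, both as annual
probabilities; survivor shares are the constraint target.  Out-of-range flow
solutions (possible at the oldest ages for real smoothed curves) are clipped
into [0, 1] with a logged warning.  The open 95+ class gets the transition
that makes its own prevalence a fixed point under age-95 mortality, so that
stationarity holds on the whole grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .data_io import (
    AGES,
    OPEN_AGE,
    SEXES,
    PrevalenceTable,
    RateTable,
    StateRatioTable,
    ValidationError,
)

__all__ = [
    "RelativeRiskSet",
    "StateMortality",
    "TransitionSchedule",
    "DisabilityModel",
    "partition_mortality",
    "derive_net_transitions",
    "project_prevalence_one_step",
    "solve_disability",
]

logger = logging.getLogger(__name__)

_CLIP_EPS = 1e-12


class RelativeRiskSet(StateRatioTable):
    """Relative risks of all-cause death by smoking state (never = 1)."""


class StateMortality:
    """One-year death probabilities per smoking state on the grid.

    ``q[sex]`` has shape (96, 3) in state order never/current/former.  Where
    no capping occurred, the prevalence-weighted mixture equals the baseline
    all-cause probability.
    """

    def __init__(self, q: Mapping[str, np.ndarray]) -> None:
        self.q: dict[str, np.ndarray] = {}
        for sex in SEXES:
            v = np.asarray(q[sex], dtype=float)
            if v.shape != (len(AGES), 3):
                raise ValidationError(f"state mortality for {sex!r} must be (96, 3)")
            if np.any((v < 0) | (v > 1) | ~np.isfinite(v)):
                raise ValidationError(f"state mortality for {sex!r} outside [0, 1]")
            self.q[sex] = v.copy()


class TransitionSchedule:
    """Net annual transition probabilities per age and sex.

    ``start[sex][a]`` is the never -> current probability over [a, a+1);
    ``net_cf[sex][a]`` is the signed current <-> former flow: positive values
    are a quit probability applied to current smokers, negative values a
    restart probability applied to former smokers.

    ``baseline`` points at the untransformed schedule this one was derived
    from (None for a schedule straight out of :func:`derive_net_transitions`);
    scenario transforms always recompute from the baseline, which makes them
    idempotent.
    """

    def __init__(self, start: Mapping[str, np.ndarray],
                 net_cf: Mapping[str, np.ndarray],
                 baseline: "TransitionSchedule | None" = None) -> None:
        self.start: dict[str, np.ndarray] = {}
        self.net_cf: dict[str, np.ndarray] = {}
        for sex in SEXES:
            s = np.asarray(start[sex], dtype=float)
            n = np.asarray(net_cf[sex], dtype=float)
            if s.shape != (len(AGES),) or n.shape != (len(AGES),):
                raise ValidationError(f"transition arrays for {sex!r} must be (96,)")
            if np.any((s < 0) | (s > 1) | ~np.isfinite(s)):
                raise ValidationError(f"start probabilities for {sex!r} outside [0, 1]")
            if np.any((np.abs(n) > 1) | ~np.isfinite(n)):
                raise ValidationError(
                    f"quit/restart probabilities for {sex!r} outside [0, 1]")
            self.start[sex] = s.copy()
            self.net_cf[sex] = n.copy()
        self.baseline = baseline

    def root(self) -> "TransitionSchedule":
        """The untransformed schedule this one descends from."""
        return self if self.baseline is None else self.baseline

    def quit(self, sex: str) -> np.ndarray:
        return np.clip(self.net_cf[sex], 0.0, 1.0)

    def restart(self, sex: str) -> np.ndarray:
        return np.clip(-self.net_cf[sex], 0.0, 1.0)


class DisabilityModel:
    """State-specific disability probabilities and the baseline log-odds.

    ``d[sex]`` has shape (96, 3); ``beta0[sex]`` (96,) holds the solved
    never-smoker log-odds (-inf / +inf where the overall prevalence is
    exactly 0 / 1).
    """

    def __init__(self, d: Mapping[str, np.ndarray],
                 beta0: Mapping[str, np.ndarray]) -> None:
        self.d: dict[str, np.ndarray] = {}
        self.beta0: dict[str, np.ndarray] = {}
        for sex in SEXES:
            v = np.asarray(d[sex], dtype=float)
            if v.shape != (len(AGES), 3):
                raise ValidationError(f"disability probabilities for {sex!r} must be (96, 3)")
            if np.any((v < 0) | (v > 1) | ~np.isfinite(v)):
                raise ValidationError(f"disability probabilities for {sex!r} outside [0, 1]")
            self.d[sex] = v.copy()
            self.beta0[sex] = np.asarray(beta0[sex], dtype=float).copy()


def partition_mortality(q: RateTable, prev: PrevalenceTable,
                        rr: StateRatioTable) -> StateMortality:
    """Split baseline all-cause mortality into state-specific probabilities.

    q_never = q / (p_never + p_current RR_current + p_former RR_former) and
    q_k = RR_k q_never, each capped at 1 (capping is warned, and breaks the
    mixture identity at the affected cells only).
    """
    out = {}
    for sex in SEXES:
        ratios = rr.ratios(sex)
        p = prev.probs[sex]
        denom = p @ ratios
        if np.any(denom <= 0):
            raise RuntimeError("mortality partition denominator <= 0")  # unreachable
        q_never = q.values[sex] / denom
        qs = q_never[:, None] * ratios[None, :]
        capped = qs > 1.0
        if np.any(capped):
            cells = [int(AGES[i]) for i in np.unique(np.where(capped)[0])]
            logger.warning("state mortality capped at 1 for sex=%s, ages %s",
                           sex, cells)
            qs = np.minimum(qs, 1.0)
        out[sex] = qs
    return StateMortality(out)


def _solve_cell(p_from: np.ndarray, p_to: np.ndarray, q_cell: np.ndarray
                ) -> tuple[float, float, bool]:
    """Net (start, net_cf) moving survivors of p_from under q_cell onto p_to.

    Returns (start, net_cf, clipped).  Survivor counts n_k = p_k (1 - q_k)
    are redistributed by start first (applied to never survivors), then by
    one net quit/restart flow; the resulting shares must equal p_to.
    """
    n = p_from * (1.0 - q_cell)
    S = n.sum()
    if S <= 0:
        return 0.0, 0.0, False
    clipped = False
    target = p_to * S
    if n[0] > 0:
        start = 1.0 - target[0] / n[0]
    else:
        start = 0.0
        clipped = clipped or target[0] > _CLIP_EPS * S
    if start < 0 or start > 1:
        clipped = clipped or (start < -_CLIP_EPS or start > 1 + _CLIP_EPS)
        start = min(max(start, 0.0), 1.0)
    c1 = n[1] + start * n[0]
    if target[1] <= c1:  # net flow out of current: quit
        quit_p = 1.0 - target[1] / c1 if c1 > 0 else 0.0
        if quit_p > 1 or quit_p < 0:
            clipped = clipped or (quit_p > 1 + _CLIP_EPS or quit_p < -_CLIP_EPS)
            quit_p = min(max(quit_p, 0.0), 1.0)
        net_cf = quit_p
    else:  # net flow into current: restart
        restart_p = (target[1] - c1) / n[2] if n[2] > 0 else 0.0
        if restart_p > 1 or restart_p < 0:
            clipped = clipped or (restart_p > 1 + _CLIP_EPS or restart_p < -_CLIP_EPS)
            restart_p = min(max(restart_p, 0.0), 1.0)
        net_cf = -restart_p
    return float(start), float(net_cf), clipped


def derive_net_transitions(prev: PrevalenceTable, sm: StateMortality
                           ) -> TransitionSchedule:
    """Net transitions that keep the age-specific prevalence stationary.

    For each sex and age a < 95, solves the one-step balance taking survivors
    of the age-a prevalence onto the age-(a+1) prevalence.  The open 95+
    class gets the flow making its own prevalence a fixed point under age-95
    mortality.  Solutions outside [0, 1] are clipped with a warning naming
    the cells.
    """
    start = {}
    net_cf = {}
    for sex in SEXES:
        p = prev.probs[sex]
        q = sm.q[sex]
        s_arr = np.zeros(len(AGES))
        n_arr = np.zeros(len(AGES))
        clipped_cells = []
        for a in range(OPEN_AGE):
            s_arr[a], n_arr[a], clipped = _solve_cell(p[a], p[a + 1], q[a])
            if clipped:
                clipped_cells.append(int(AGES[a]))
        # open class: self-map fixed point so the 95+ prevalence is stationary
        s_arr[OPEN_AGE], n_arr[OPEN_AGE], clipped = _solve_cell(
            p[OPEN_AGE], p[OPEN_AGE], q[OPEN_AGE])
        if clipped:
            clipped_cells.append(int(AGES[OPEN_AGE]))
        if clipped_cells:
            logger.warning("net transitions clipped to [0, 1] for sex=%s, ages %s",
                           sex, clipped_cells)
        start[sex] = s_arr
        net_cf[sex] = n_arr
    return TransitionSchedule(start, net_cf)


def project_prevalence_one_step(p: np.ndarray, q_cell: np.ndarray,
                                start: float, net_cf: float) -> np.ndarray:
    """Forward operator: mortality, then transitions, renormalized.

    ``p`` is the (never, current, former) prevalence at age a, ``q_cell`` the
    state-specific death probabilities at age a, ``start``/``net_cf`` the
    transitions over [a, a+1); returns the prevalence at age a+1.
    """
    n = np.asarray(p, dtype=float) * (1.0 - np.asarray(q_cell, dtype=float))
    moved = start * n[0]
    never = n[0] - moved
    current = n[1] + moved
    former = n[2]
    if net_cf >= 0:
        flow = net_cf * current
        current -= flow
        former += flow
    else:
        flow = -net_cf * former
        former -= flow
        current += flow
    out = np.array([never, current, former])
    total = out.sum()
    if total <= 0:
        raise ValidationError("no survivors to renormalize")
    return out / total


def solve_disability(prev: PrevalenceTable, pi: RateTable,
                     or_set: StateRatioTable) -> DisabilityModel:
    """Solve the baseline disability log-odds per cell by bisection.

    Finds beta0 in [-50, 50] with sum_k p_k logistic(beta0 + log OR_k) = pi
    (the left side is strictly increasing in beta0, so bisection converges);
    d_k = logistic(beta0 + log OR_k).  pi exactly 0 or 1 maps to all d_k = 0
    or 1 with beta0 = -inf / +inf.
    """
    d_out = {}
    b_out = {}
    for sex in SEXES:
        p = prev.probs[sex]
        target = pi.values[sex]
        log_or = np.log(or_set.ratios(sex))

        lo = np.full(len(AGES), -50.0)
        hi = np.full(len(AGES), 50.0)
        interior = (target > 0) & (target < 1)

        def mix(beta0: np.ndarray) -> np.ndarray:
            d = 1.0 / (1.0 + np.exp(-(beta0[:, None] + log_or[None, :])))
            return (p * d).sum(axis=1)

        if np.any(interior & (mix(lo) > target)) or np.any(interior & (mix(hi) < target)):
            raise ValidationError("no root in bracket for disability log-odds")
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            high = mix(mid) > target
            hi = np.where(high, mid, hi)
            lo = np.where(high, lo, mid)
        beta0 = 0.5 * (lo + hi)
        d = 1.0 / (1.0 + np.exp(-(beta0[:, None] + log_or[None, :])))
        beta0 = np.where(interior, beta0, np.where(target <= 0, -np.inf, np.inf))
        d = np.where(interior[:, None], d, np.where(target[:, None] <= 0, 0.0, 1.0))
        d_out[sex] = d
        b_out[sex] = beta0
    return DisabilityModel(d_out, b_out)
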