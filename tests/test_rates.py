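"""Mortality partition, net transitions and the disability solver, checked
against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq, fsolve

from smokehia import rates
from smokehia.data_io import AGES, SEXES, PrevalenceTable, RateTable, StateRatioTable
from smokehia.rates import (
    _solve_cell,
    derive_net_transitions,
    partition_mortality,
    project_prevalence_one_step,
    solve_disability,
)


def _const_prev(row):
    p = np.tile(row, (96, 1))
    return PrevalenceTable({s: p for s in SEXES})


def _const_rate(v):
    return RateTable({s: np.full(96, v) for s in SEXES}, kind="probability")


def _ratios(cur, fmr):
    return StateRatioTable(current={s: cur for s in SEXES},
                           former={s: fmr for s in SEXES})


def forward_cell(p, q, start, net_cf):
    """Independent forward operator written out longhand for oracle use."""
    survivors = [p[0] * (1 - q[0]), p[1] * (1 - q[1]), p[2] * (1 - q[2])]
    moved = start * survivors[0]
    never = survivors[0] - moved
    current = survivors[1] + moved
    former = survivors[2]
    if net_cf >= 0:
        current, former = current * (1 - net_cf), former + current * net_cf
    else:
        current, former = current - net_cf * former, former * (1 + net_cf)
    total = never + current + former
    return np.array([never, current, former]) / total


class TestPartitionMortality:
    def test_null_relative_risks_leave_mortality_unchanged(self):
        sm = partition_mortality(_const_rate(0.01), _const_prev([0.5, 0.3, 0.2]),
                                 _ratios(1.0, 1.0))
        for s in SEXES:
            assert np.allclose(sm.q[s], 0.01, atol=1e-15)

    def test_degenerate_prevalence_gives_baseline_to_never(self):
        sm = partition_mortality(_const_rate(0.02), _const_prev([1.0, 0.0, 0.0]),
                                 _ratios(3.0, 2.0))
        for s in SEXES:
            assert np.allclose(sm.q[s][:, 0], 0.02, atol=1e-15)

    def test_worked_example_and_mixture_identity(self):
        sm = partition_mortality(_const_rate(0.01), _const_prev([0.5, 0.3, 0.2]),
                                 _ratios(2.0, 1.5))
        q = sm.q["male"][40]
        assert np.allclose(q, [0.0071429, 0.0142857, 0.0107143], atol=5e-8)
        # direct summation of the mixture
        assert abs(np.dot([0.5, 0.3, 0.2], q) - 0.01) < 1e-12

    def test_mixture_identity_on_defaults(self, baseline, demography):
        _, mortality, _ = demography
        for s in SEXES:
            mix = (baseline.prev.probs[s] * baseline.sm.q[s]).sum(axis=1)
            assert np.abs(mix - mortality.values[s]).max() < 1e-12


class TestNetTransitions:
    def test_constant_prevalence_null_rr_gives_zero_flows(self):
        prev = _const_prev([0.5, 0.3, 0.2])
        sm = partition_mortality(_const_rate(0.01), prev, _ratios(1.0, 1.0))
        ts = derive_net_transitions(prev, sm)
        for s in SEXES:
            assert np.abs(ts.start[s]).max() < 1e-12
            assert np.abs(ts.net_cf[s]).max() < 1e-12

    def test_single_flow_case(self):
        """p_never falls 1.0 -> 0.9 under equal mortality: start = 0.1."""
        p = np.tile([1.0, 0.0, 0.0], (96, 1))
        p[1:] = [0.9, 0.1, 0.0]
        prev = PrevalenceTable({s: p for s in SEXES})
        sm = partition_mortality(_const_rate(0.01), prev, _ratios(1.0, 1.0))
        ts = derive_net_transitions(prev, sm)
        assert abs(ts.start["male"][0] - 0.1) < 1e-12

    def test_worked_example_round_trips(self):
        p_from = np.array([0.5, 0.3, 0.2])
        p_to = np.array([0.48, 0.28, 0.24])
        q = np.array([0.0071429, 0.0142857, 0.0107143])
        start, net_cf, clipped = _solve_cell(p_from, p_to, q)
        assert not clipped
        out = project_prevalence_one_step(p_from, q, start, net_cf)
        assert np.abs(out - p_to).max() < 1e-10

    def test_brute_force_oracle_on_random_cells(self):
        """derive's per-cell solution agrees with a two-variable numerical
        root-finder on 1000 random interior cells, to 1e-8."""
        rng = np.random.default_rng(123)
        n_checked = 0
        while n_checked < 1000:
            p_from = rng.dirichlet([5, 3, 2])
            q_never = rng.uniform(0.0, 0.3)
            q = q_never * np.array([1.0, 2.0, 1.5])
            true_start = rng.uniform(0.0, 0.6)
            true_net = rng.uniform(-0.3, 0.6)
            p_to = forward_cell(p_from, q, true_start, true_net)
            start, net_cf, clipped = _solve_cell(p_from, p_to, q)
            assert not clipped

            def residual(z):
                out = forward_cell(p_from, q, z[0], z[1])
                return [out[0] - p_to[0], out[1] - p_to[1]]

            sol = fsolve(residual, [0.1, 0.0], full_output=False, xtol=1e-13)
            assert abs(start - sol[0]) < 1e-8
            assert abs(net_cf - sol[1]) < 1e-8
            assert abs(start - true_start) < 1e-8
            assert abs(net_cf - true_net) < 1e-8
            n_checked += 1

    def test_stationarity_round_trip_on_defaults(self, baseline):
        """Derived transitions reproduce the baseline prevalence age-by-age,
        including the open-class fixed point."""
        for s in SEXES:
            p = baseline.prev.probs[s]
            q = baseline.sm.q[s]
            for a in range(95):
                out = project_prevalence_one_step(
                    p[a], q[a], baseline.ts.start[s][a], baseline.ts.net_cf[s][a])
                assert np.abs(out - p[a + 1]).max() < 1e-10
            out95 = project_prevalence_one_step(
                p[95], q[95], baseline.ts.start[s][95], baseline.ts.net_cf[s][95])
            assert np.abs(out95 - p[95]).max() < 1e-10

    @settings(derandomize=True, max_examples=200)
    @given(
        p_raw=st.tuples(*([st.floats(0.05, 1.0)] * 3)),
        q_never=st.floats(0.0, 0.4),
        start=st.floats(0.0, 0.9),
        net_cf=st.floats(-0.9, 0.9),
    )
    def test_forward_then_solve_recovers_flows(self, p_raw, q_never, start,
                                               net_cf):
        """Inverse property: any valid (start, net_cf) pushed forward and
        solved back is recovered."""
        p_from = np.array(p_raw) / sum(p_raw)
        q = q_never * np.array([1.0, 2.0, 1.5])
        p_to = forward_cell(p_from, q, start, net_cf)
        got_start, got_net, clipped = _solve_cell(p_from, p_to, q)
        assert not clipped
        assert abs(got_start - start) < 1e-8
        assert abs(got_net - net_cf) < 1e-8


class TestProjectOneStep:
    def test_identity_under_zero_flows_equal_mortality(self):
        p = np.array([0.5, 0.3, 0.2])
        out = project_prevalence_one_step(p, np.full(3, 0.1), 0.0, 0.0)
        assert np.abs(out - p).max() < 1e-15

    def test_full_start_moves_everyone(self):
        out = project_prevalence_one_step(np.array([1.0, 0.0, 0.0]),
                                          np.zeros(3), 1.0, 0.0)
        assert np.allclose(out, [0.0, 1.0, 0.0])

    def test_output_sums_to_one(self):
        out = project_prevalence_one_step(np.array([0.2, 0.5, 0.3]),
                                          np.array([0.1, 0.3, 0.2]), 0.4, -0.2)
        assert abs(out.sum() - 1.0) < 1e-14


class TestSolveDisability:
    def test_homogeneous_odds_gives_pi_everywhere(self):
        prev = _const_prev([0.5, 0.3, 0.2])
        pi = _const_rate(0.2)
        model = solve_disability(prev, pi, _ratios(1.0, 1.0))
        for s in SEXES:
            assert np.abs(model.d[s] - 0.2).max() < 1e-10

    def test_degenerate_prevalence(self):
        prev = _const_prev([1.0, 0.0, 0.0])
        model = solve_disability(prev, _const_rate(0.15), _ratios(4.0, 2.0))
        assert np.abs(model.d["male"][:, 0] - 0.15).max() < 1e-10

    def test_forward_construct_then_invert(self):
        """pi built from beta0 = log 0.1 with OR (1, 2, 1.5) and p
        (0.5, 0.3, 0.2) is 0.121541...; solving back recovers d_never =
        1/11 and beta0 to 1e-10."""
        beta0 = np.log(0.1)
        ors = np.array([1.0, 2.0, 1.5])
        p = np.array([0.5, 0.3, 0.2])
        d_true = 1 / (1 + np.exp(-(beta0 + np.log(ors))))
        pi_val = float(p @ d_true)
        assert abs(pi_val - 0.121541) < 1e-6  # printed 6-dp precision
        model = solve_disability(_const_prev(p), _const_rate(pi_val),
                                 _ratios(2.0, 1.5))
        assert abs(model.d["male"][40, 0] - 0.090909090909) < 1e-10
        assert abs(model.beta0["male"][40] - beta0) < 1e-10

    def test_extreme_prevalence_maps_to_extreme_d(self):
        prev = _const_prev([0.5, 0.3, 0.2])
        zero = solve_disability(prev, _const_rate(0.0), _ratios(2.0, 1.5))
        one = solve_disability(prev, _const_rate(1.0), _ratios(2.0, 1.5))
        assert np.all(zero.d["male"] == 0.0) and np.all(one.d["male"] == 1.0)
        assert np.isneginf(zero.beta0["male"]).all()
        assert np.isposinf(one.beta0["male"]).all()

    def test_brute_force_oracle_on_random_cells(self):
        """Vectorized bisection agrees with scipy brentq on 1000 random
        cells to 1e-10 in d_never."""
        rng = np.random.default_rng(77)
        p_all = rng.dirichlet([4, 2, 2], size=1000)
        pi_all = rng.uniform(0.01, 0.9, size=1000)
        or_c, or_f = 2.3, 1.4
        # pack the 1000 cells into consecutive 96-cell tables
        for lo in range(0, 1000, 96):
            chunk_p = p_all[lo:lo + 96]
            chunk_pi = pi_all[lo:lo + 96]
            m = len(chunk_p)
            p_mat = np.vstack([chunk_p, np.tile([1, 0, 0], (96 - m, 1))])
            pi_vec = np.concatenate([chunk_pi, np.full(96 - m, 0.5)])
            model = solve_disability(
                PrevalenceTable({s: p_mat for s in SEXES}),
                RateTable({s: pi_vec for s in SEXES}, kind="probability"),
                _ratios(or_c, or_f))
            for i in range(m):
                log_or = np.log([1.0, or_c, or_f])

                def g(b0):
                    return float(chunk_p[i] @ (1 / (1 + np.exp(-(b0 + log_or)))) \
                                 - chunk_pi[i])

                b0_ref = brentq(g, -50, 50, xtol=1e-13)
                d_ref = 1 / (1 + np.exp(-b0_ref))
                assert abs(model.d["male"][i, 0] - d_ref) < 1e-10

    def test_beta0_strictly_increasing_in_pi(self):
        prev = _const_prev([0.5, 0.3, 0.2])
        pi_vals = np.linspace(0.01, 0.95, 96)
        pi = RateTable({s: pi_vals for s in SEXES}, kind="probability")
        model = solve_disability(prev, pi, _ratios(2.0, 1.5))
        assert np.all(np.diff(model.beta0["male"]) > 0)

    def test_mixture_conservation_on_defaults(self, baseline, true_pi):
        for s in SEXES:
            mix = (baseline.prev.probs[s] * baseline.dis.d[s]).sum(axis=1)
            assert np.abs(mix - true_pi.values[s]).max() < 1e-10
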