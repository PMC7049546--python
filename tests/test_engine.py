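"""Projection engines: accounting identities, convergence, common draws."""

import numpy as np
import pytest

from smokehia import scenarios as sc, synthetic_data as sd
from smokehia.data_io import (
    AGES,
    SEXES,
    NewbornSeries,
    PrevalenceTable,
    RateTable,
    RunConfig,
    ValidationError,
)
from smokehia.engine import (
    BaselineInputs,
    common_random_runs,
    run_deterministic,
    simulate,
)
from smokehia.rates import DisabilityModel, StateMortality, TransitionSchedule
from smokehia.summary import sullivan_expectancies


def _uniform_inputs(q=0.0, d=0.0, pop=1000.0, prev_row=(0.6, 0.3, 0.1),
                    baseline_year=2018, n_years=40):
    """Minimal hand-built inputs: constant q and d, zero transitions."""
    prev = PrevalenceTable({s: np.tile(prev_row, (96, 1)) for s in SEXES})
    sm = StateMortality({s: np.full((96, 3), q) for s in SEXES})
    ts = TransitionSchedule({s: np.zeros(96) for s in SEXES},
                            {s: np.zeros(96) for s in SEXES})
    dis = DisabilityModel({s: np.full((96, 3), d) for s in SEXES},
                          {s: np.zeros(96) for s in SEXES})
    population = RateTable({s: np.full(96, pop) for s in SEXES}, kind="rate")
    years = tuple(range(baseline_year, baseline_year + n_years))
    newborns = NewbornSeries(years,
                             {s: np.full(len(years), pop) for s in SEXES})
    return BaselineInputs(prev, ts, sm, dis, population, newborns)


class TestDeterministic:
    def test_conservation_without_mortality_or_transitions(self):
        inp = _uniform_inputs(q=0.0)
        cfg = RunConfig(horizon_years=5, n_per_class=1, seed=0)
        agg = run_deterministic(inp.prev, inp.ts, inp.sm, inp.dis,
                                inp.population, inp.newborns, cfg)
        for s in SEXES:
            # each year's composition equals baseline shifted by age
            for t in range(1, 6):
                assert np.allclose(agg.Nk[s][t, t:95],
                                   agg.Nk[s][0, :95 - t], atol=1e-9)

    def test_cohort_accounting_identity(self, baseline, small_cfg):
        agg = run_deterministic(baseline.prev, baseline.ts, baseline.sm,
                                baseline.dis, baseline.population,
                                baseline.newborns, small_cfg)
        for s in SEXES:
            N = agg.N(s)
            lhs = N[1:, 1:95]
            rhs = N[:-1, :94] - agg.D[s][:-1, :94]
            assert np.abs(lhs - rhs).max() < 1e-9 * N.max()

    def test_reference_prevalence_stationary(self, baseline, small_cfg):
        agg = run_deterministic(baseline.prev, baseline.ts, baseline.sm,
                                baseline.dis, baseline.population,
                                baseline.newborns, small_cfg)
        for s in SEXES:
            shares = agg.prevalence(s)
            assert np.nanmax(np.abs(shares - shares[0][None])) < 1e-8

    def test_horizon_beyond_newborns_rejected(self, baseline):
        cfg = RunConfig(horizon_years=40, n_per_class=1, seed=0)
        with pytest.raises(ValidationError, match="newborn"):
            run_deterministic(baseline.prev, baseline.ts, baseline.sm,
                              baseline.dis, baseline.population,
                              baseline.newborns, cfg)

    def test_constant_mortality_cohort_life_expectancy_closed_form(self):
        """With q = 0.5, no transitions and mid-interval deaths, cohort LE at
        age 0 is the geometric series sum_(k>=0) (1-q)^k (1 - q/2) = 1.5,
        exactly (the open-class closure continues the same geometry)."""
        from smokehia.summary import cohort_expectancies
        inp = _uniform_inputs(q=0.5, n_years=40)
        cfg = RunConfig(horizon_years=35, n_per_class=1, seed=0)
        agg = run_deterministic(inp.prev, inp.ts, inp.sm, inp.dis,
                                inp.population, inp.newborns, cfg)
        res = cohort_expectancies(agg, 0, "male")
        assert abs(res.LE - 1.5) < 1e-12


class TestMicrosim:
    def test_baseline_individual_count_matches_design(self, baseline):
        """2500 simulants per one-year age class 0-95 per sex: 480,000."""
        cfg = RunConfig(horizon_years=1, n_per_class=2500, seed=0)
        agg = simulate(baseline.prev, baseline.ts, baseline.sm, baseline.dis,
                       baseline.population, baseline.newborns, cfg)
        assert agg.n_baseline_individuals == 480_000

    def test_same_seed_reproduces_aggregates(self, baseline, small_cfg):
        a = simulate(baseline.prev, baseline.ts, baseline.sm, baseline.dis,
                     baseline.population, baseline.newborns, small_cfg)
        b = simulate(baseline.prev, baseline.ts, baseline.sm, baseline.dis,
                     baseline.population, baseline.newborns, small_cfg)
        for s in SEXES:
            assert np.array_equal(a.Nk[s], b.Nk[s])
            assert np.array_equal(a.D[s], b.D[s])

    def test_cohort_accounting_identity(self, baseline, small_cfg):
        agg = simulate(baseline.prev, baseline.ts, baseline.sm, baseline.dis,
                       baseline.population, baseline.newborns, small_cfg)
        for s in SEXES:
            N = agg.N(s)
            lhs = N[1:, 1:95]
            rhs = N[:-1, :94] - agg.D[s][:-1, :94]
            assert np.abs(lhs - rhs).max() < 1e-9 * N.max()

    def test_error_scales_with_inverse_root_n(self, baseline):
        """RMS prevalence error vs the deterministic recursion shrinks like
        n^(-1/2) over n in {100, 400, 1600} (factor ~4 from end to end)."""
        cfg0 = RunConfig(horizon_years=10, n_per_class=1, seed=0)
        det = run_deterministic(baseline.prev, baseline.ts, baseline.sm,
                                baseline.dis, baseline.population,
                                baseline.newborns, cfg0)
        ref = {s: det.prevalence(s) for s in SEXES}
        errs = []
        for n in (100, 400, 1600):
            per_seed = []
            for seed in (1, 2, 3):
                cfg = RunConfig(horizon_years=10, n_per_class=n, seed=seed)
                mic = simulate(baseline.prev, baseline.ts, baseline.sm,
                               baseline.dis, baseline.population,
                               baseline.newborns, cfg)
                diffs = []
                for s in SEXES:
                    d = mic.prevalence(s)[:, 15:80] - ref[s][:, 15:80]
                    diffs.append(d.ravel())
                per_seed.append(np.sqrt(np.mean(np.concatenate(diffs) ** 2)))
            errs.append(np.mean(per_seed))
        assert errs[0] > errs[1] > errs[2]
        assert 2.0 < errs[0] / errs[2] < 8.0


class TestCommonRandomRuns:
    def test_reference_vs_reference_is_exactly_zero(self, baseline, small_cfg):
        specs = [sc.make_scenario("reference"), sc.make_scenario("reference")]
        specs[1] = type(specs[1])(name="reference_b",
                                  description=specs[1].description)
        runs = common_random_runs(specs, baseline, small_cfg)
        a, b = runs["reference"], runs["reference_b"]
        for s in SEXES:
            assert np.array_equal(a.Nk[s], b.Nk[s])
            assert np.array_equal(a.disabled[s], b.disabled[s])

    def test_empty_scenario_list_rejected(self, baseline, small_cfg):
        with pytest.raises(ValidationError):
            common_random_runs([], baseline, small_cfg)

    def test_common_draws_reduce_difference_variance(self, baseline):
        """Across 20 replicate seeds, the variance of the all_quit-minus-
        reference LE difference is no larger with common draws than with
        independent draws."""
        specs = [sc.make_scenario("reference"), sc.make_scenario("all_quit")]
        common_diffs, indep_diffs = [], []
        for seed in range(20):
            cfg = RunConfig(horizon_years=11, n_per_class=60, seed=seed)
            runs = common_random_runs(specs, baseline, cfg)
            le = {k: sullivan_expectancies(v, 2028, 15, "male").LE
                  for k, v in runs.items()}
            common_diffs.append(le["all_quit"] - le["reference"])

            cfg_b = RunConfig(horizon_years=11, n_per_class=60, seed=seed + 1000)
            runs_a = common_random_runs([specs[0]], baseline, cfg)
            runs_b = common_random_runs([specs[1]], baseline, cfg_b)
            indep_diffs.append(
                sullivan_expectancies(runs_b["all_quit"], 2028, 15, "male").LE
                - sullivan_expectancies(runs_a["reference"], 2028, 15, "male").LE)
        assert np.var(common_diffs) <= np.var(indep_diffs)
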