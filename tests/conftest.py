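"""Shared fixtures: the synthetic truth and the derived baseline machinery.

Expensive objects (the large recovery survey, the derived baseline inputs)
are session-scoped; tests must not mutate them.
"""

from __future__ import annotations

import numpy as np
import pytest

from smokehia import rates, synthetic_data as sd
from smokehia.data_io import RunConfig
from smokehia.engine import BaselineInputs


@pytest.fixture(scope="session")
def truth():
    return sd.default_truth()


@pytest.fixture(scope="session")
def true_prevalence(truth):
    return sd.smoking_prevalence(truth)


@pytest.fixture(scope="session")
def true_pi(truth):
    return sd.disability_prevalence(truth)


@pytest.fixture(scope="session")
def demography(truth):
    return sd.generate_demography(truth, baseline_year=2018, horizon_years=30)


@pytest.fixture(scope="session")
def baseline(truth, true_prevalence, true_pi, demography) -> BaselineInputs:
    """Baseline projection inputs derived from the generating truth curves."""
    population, mortality, newborns = demography
    sm = rates.partition_mortality(mortality, true_prevalence, truth.rr_mortality)
    ts = rates.derive_net_transitions(true_prevalence, sm)
    dis = rates.solve_disability(true_prevalence, true_pi, truth.or_disability)
    return BaselineInputs(prev=true_prevalence, ts=ts, sm=sm, dis=dis,
                          population=population, newborns=newborns)


@pytest.fixture(scope="session")
def big_survey(truth):
    """200k survey records for parameter-recovery checks."""
    return sd.generate_survey(truth, 200_000, seed=11)


@pytest.fixture
def small_cfg() -> RunConfig:
    """A light configuration for engine tests (short horizon, few simulants)."""
    return RunConfig(baseline_year=2018, horizon_years=12, n_per_class=150, seed=42)
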