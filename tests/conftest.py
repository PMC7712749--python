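"""Shared fixtures: nominal specs and the four reference forward runs.

The two-year forward simulations are expensive, so they are computed once
per session and shared by the dynamics and acceptance tests.
"""

import numpy as np
import pytest

from mepweb import (FoodWebSpec, PondModel, ScenarioSpec, load_scenario,
                    optimal_traits, zero_growth_traits)


@pytest.fixture(scope="session")
def nominal():
    return ScenarioSpec().validate()


@pytest.fixture(scope="session")
def circadian_web():
    return FoodWebSpec(strategy="circadian").validate()


def _forward(strategy, traits=None):
    scen, web = load_scenario("nominal", strategy)
    tv = traits if traits is not None else optimal_traits(strategy, web)
    return PondModel(scen, web, tv).simulate()


@pytest.fixture(scope="session")
def circadian_run():
    """Two-year nominal run at the published circadian trait optimum."""
    return _forward("circadian")


@pytest.fixture(scope="session")
def passive_run():
    return _forward("passive")


@pytest.fixture(scope="session")
def balanced_run():
    return _forward("balanced")


@pytest.fixture(scope="session")
def zero_growth_run():
    """Abiotic baseline: all growth efficiencies zero."""
    scen, web = load_scenario("nominal", "passive")
    return PondModel(scen, web, zero_growth_traits(web)).simulate()


@pytest.fixture(scope="session")
def mj(circadian_run):
    def _mj(run):
        return run.sigma[-1] / 1e6
    return _mj
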