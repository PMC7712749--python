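"""Photon energetics, transformed free energies and the two drives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mepweb import (entropy_rate, photon_free_energy, photon_molar_energy,
                    thermo_drive_ft)
from mepweb.thermo import ThermoTable

FEED = {"H2CO3": 2000.0, "O2": 225.0, "NH3": 5.0,
        "CL": 10.0, "CD": 100.0, "ND": 7.0}


def test_photon_energy_planck_scaling():
    u440 = photon_molar_energy(440.0)
    assert u440 == pytest.approx(271.9, abs=0.1)          # J/mmol
    assert photon_molar_energy(880.0) == pytest.approx(u440 / 2)
    assert photon_molar_energy(1e9) < 1e-3
    with pytest.raises(ValueError):
        photon_molar_energy(0.0)


def test_photon_free_energy_below_energy():
    u = photon_molar_energy(440.0)
    g = photon_free_energy(u, 293.0)
    assert 0 < g < u
    assert g == pytest.approx(u * (1 - 293.0 / 5778.0))


def test_thermo_drive_limits_and_midpoint():
    # deeply exergonic -> full drive
    assert thermo_drive_ft(-1e5, 1, 293.0) == pytest.approx(1.0)
    # drG/ne exactly offsetting the membrane potential -> 0.5
    from mepweb.constants import FARADAY
    assert thermo_drive_ft(-FARADAY * 0.1, 1, 293.0) == pytest.approx(0.5)
    # at equilibrium the membrane term keeps a small but positive drive
    assert thermo_drive_ft(0.0, 1, 293.0) == pytest.approx(0.0187, abs=2e-4)
    with pytest.raises(ValueError):
        thermo_drive_ft(0.0, 0, 293.0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.floats(-2000, 2000), st.integers(1, 8))
def test_thermo_drive_bounded_and_monotone(drg, ne):
    ft = thermo_drive_ft(drg, ne, 293.0)
    assert 0.0 <= ft <= 1.0
    assert thermo_drive_ft(drg - 10.0, ne, 293.0) >= ft
    if drg < -20.0:
        # spreading the same free energy over more electrons weakens the
        # per-electron drive
        assert thermo_drive_ft(drg, ne + 1, 293.0) <= ft


def test_entropy_rate_sign_and_arithmetic():
    assert entropy_rate(0.0, -100.0, 293.0) == 0.0
    assert entropy_rate(1.0, 0.0, 293.0) == 0.0
    assert entropy_rate(1.0, -478.7, 293.0) == pytest.approx(1.634, abs=1e-3)


def test_organic_oxidation_free_energy_scale():
    """Aerobic combustion of unit-carbon carbohydrate at pond feed
    conditions releases 440-480 J/mmol-C -- the value pinned by the
    scenario's chemical free-energy inputs."""
    tt = ThermoTable()
    g = tt.oxidation_free_energy("CL", FEED)
    assert -480.0 < g < -440.0
    # detrital carbon is at lower concentration, so slightly more exergonic
    assert tt.oxidation_free_energy("CD", FEED) < g


def test_chemical_entropy_bound_nominal():
    tt = ThermoTable()
    sigma = tt.chemical_entropy_bound(FEED, 0.2, 730.0)
    assert sigma / 1e6 == pytest.approx(0.025, rel=0.03)


def test_photons_per_co2_quotient_direction():
    tt = ThermoTable()
    g_gamma = photon_free_energy(photon_molar_energy(440.0), 293.0)
    n1 = tt.photons_per_co2(2000.0, 225.0, g_gamma)
    assert 1.0 < n1 < 3.0      # near two photons per CO2 at reversibility
    # product (O2) accumulation makes fixation steeper
    assert tt.photons_per_co2(2000.0, 450.0, g_gamma) > n1
    # consuming DIC also steepens the gradient
    assert tt.photons_per_co2(1000.0, 225.0, g_gamma) > n1
    # halving the photon free energy doubles the requirement
    assert tt.photons_per_co2(2000.0, 225.0, g_gamma / 2) == pytest.approx(2 * n1)


def test_epsilon_one_reactions_are_at_equilibrium():
    """drG of any growth reaction collapses to 0 as eps -> 1 (free energy
    fully conserved), the constructive heart of the efficiency coupling."""
    from mepweb import FoodWebSpec, ScenarioSpec, TraitVector
    from mepweb.dynamics import PondModel
    web = FoodWebSpec(strategy="passive")
    tv = TraitVector(eps_p=[0.9999], t_on=[0], t_off=[1], omega_amp=[0.5],
                     eps_b=[0.9999], omega_b=[[0.4, 0.3, 0.3]],
                     eps_c=[0.9999], omega_c=[[0.3, 0.3, 0.3]])
    m = PondModel(ScenarioSpec(), web, tv)
    state = m.initial_state()
    state[m.i_cp] = 0.0     # no stores: predation has no combustion term
    _, drg, _, _ = m._rates_and_entropy(0.5, state[:m.n_conc])
    for j, kind in enumerate(m.kind):
        if kind in ("growth", "graze"):
            assert abs(drg[j]) < 0.1, f"reaction {j} not at equilibrium"


def test_decomposition_free_energy_is_pure_mixing():
    """CD -> CL has drG = RT ln([CL]/[CD]): zero at equal concentrations."""
    tt = ThermoTable()
    g_eq = tt.delta_r_g({"CD": -1.0, "CL": 1.0}, {"CD": 50.0, "CL": 50.0})
    assert g_eq == pytest.approx(0.0, abs=1e-9)
    g_down = tt.delta_r_g({"CD": -1.0, "CL": 1.0}, {"CD": 100.0, "CL": 1.0})
    assert g_down == pytest.approx(tt.rt * math.log(1.0 / 100.0))


def test_thermo_table_export_is_documented():
    frame = ThermoTable().to_frame()
    assert {"species", "dfG_prime", "note"} <= set(frame.columns)
    assert {"S", "CH2O", "H2CO3", "O2", "NH3"} <= set(frame.species)
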