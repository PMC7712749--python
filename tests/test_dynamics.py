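"""Mass balances, entropy accounting and trajectory-level invariants."""

import numpy as np
import pytest

from mepweb import (FoodWebSpec, PondModel, ScenarioSpec, TraitVector,
                    zero_growth_traits)
from mepweb.dynamics import gas_exchange


def model(strategy="circadian", eps_c=0.3, **scen_kw):
    scen = ScenarioSpec(**scen_kw)
    web = FoodWebSpec(strategy=strategy)
    tv = TraitVector(eps_p=[0.3788], t_on=[0.2389], t_off=[0.7799],
                     omega_amp=[1.0 if strategy == "circadian" else 0.8],
                     eps_b=[0.1628], omega_b=[[0.4349, 0.2869, 0.2782]],
                     eps_c=[eps_c], omega_c=[[0.6547, 0.5809, 0.0963]])
    return PondModel(scen, web, tv)


def test_gas_exchange_is_linear_in_deficit():
    assert gas_exchange(225.0, 225.0, 1.0, 1.0) == 0.0
    assert gas_exchange(250.0, 225.0, 1.0, 1.0) == -25.0    # outgassing
    assert gas_exchange(200.0, 225.0, 2.0, 0.5) == 100.0
    with pytest.raises(ValueError):
        gas_exchange(1.0, 1.0, 1.0, 0.0)


def test_dark_abiotic_pond_washes_to_feed():
    """With no organisms and no light every constituent relaxes to the
    feed: the chemostat operator alone."""
    scen = ScenarioSpec(i0_max=0.0, horizon=80.0)
    for sp in ("SP", "CP", "SB", "SC"):
        scen.feed[sp] = 0.0
    web = FoodWebSpec(strategy="passive")
    m = PondModel(scen, web, zero_growth_traits(web))
    y0 = m.initial_state()
    y0[:6] = [500.0, 100.0, 1.0, 50.0, 10.0, 1.0]    # start off-feed
    m.initial_state = lambda: y0
    tr = m.simulate(horizon=80.0)   # ~16 residence times
    np.testing.assert_allclose(tr.concentrations[-1, :6], m.c_in[:6],
                               rtol=1e-4, atol=1e-3)
    assert tr.ledger.sigma_t == 0.0


def test_rhs_conserves_nitrogen_and_carbon():
    """Reaction terms move N and C among pools without creating either;
    only dilution and gas exchange cross the boundary.  Checked at random
    states, which exercises predation with state-dependent prey stores."""
    m = model(eps_c=0.4)
    gamma = m.web.gamma
    nvec = np.zeros(m.n_conc)
    cvec = np.zeros(m.n_conc)
    for k, name in enumerate(m.species):
        if name in ("NH3", "ND"):
            nvec[k] = 1.0
        if name.startswith(("SP", "SB", "SC")):
            nvec[k] = gamma
            cvec[k] = 1.0
        if name in ("H2CO3", "CL", "CD") or name.startswith("CP"):
            cvec[k] = 1.0
    rng = np.random.default_rng(3)
    for trial in range(25):
        y = np.concatenate([np.abs(rng.normal(30, 30, m.n_conc)), np.zeros(5)])
        t = rng.uniform(0, 365)
        dy = m.rhs(t, y)[:m.n_conc]
        transport = m.scenario.dilution * (m.c_in - y[:m.n_conc])
        gas = np.zeros(m.n_conc)
        gas[0] = gas_exchange(y[0], m.web.dic_saturation,
                              m.web.gas_velocity, m.scenario.depth)
        gas[1] = gas_exchange(y[1], m.web.o2_saturation,
                              m.web.gas_velocity, m.scenario.depth)
        react = dy - transport - gas
        assert abs(nvec @ react) < 1e-8 * max(1.0, np.abs(react).max())
        assert abs(cvec @ react) < 1e-8 * max(1.0, np.abs(react).max())


def test_fast_rhs_matches_reference():
    rng = np.random.default_rng(11)
    for strategy in ("circadian", "passive", "balanced"):
        m = model(strategy)
        for _ in range(10):
            y = np.abs(rng.normal(40, 40, m.n_conc + 5))
            t = rng.uniform(0, 400)
            a, b = m.rhs_reference(t, y), m.rhs_fast(t, y)
            np.testing.assert_allclose(a, b, rtol=1e-12, atol=1e-12)


def test_entropy_accumulators_monotone_and_additive(circadian_run):
    sig = circadian_run.sigma
    # non-decreasing up to interpolation error, relative to the total scale
    assert np.all(np.diff(sig, axis=0) > -1e-6 * (1.0 + sig[-1].max()))
    total = sig.sum(axis=1)
    np.testing.assert_allclose(
        total, sig[:, 0] + sig[:, 1] + sig[:, 2], rtol=0, atol=1e-9)


def test_states_stay_non_negative(circadian_run, balanced_run):
    for run in (circadian_run, balanced_run):
        assert run.concentrations.min() > -1e-6


def test_energy_audit_closes(circadian_run):
    assert abs(circadian_run.energy_audit()["relative_gap"]) < 1e-3


def test_reaction_entropy_rates_non_negative(circadian_run):
    """-r drG >= 0 for every reaction everywhere along the trajectory:
    one-way kinetics never destroy entropy."""
    m = circadian_run.model
    for t, y in zip(circadian_run.t[::200], circadian_run.y[::200]):
        rates, drg, _, _ = m._rates_and_entropy(float(t), y[:m.n_conc])
        assert np.all(-rates * drg >= -1e-9)


def test_circadian_full_window_reproduces_passive():
    """tOn=0, tOff=1 makes the clock a constant allocation: trajectories
    coincide with the passive strategy to solver tolerance."""
    base = dict(eps_b=[0.16], omega_b=[[0.4, 0.3, 0.3]],
                eps_c=[0.2], omega_c=[[0.5, 0.3, 0.2]])
    scen = ScenarioSpec(horizon=30.0)
    tv_c = TraitVector(eps_p=[0.35], t_on=[0.0], t_off=[1.0],
                       omega_amp=[0.8], **base)
    web_c = FoodWebSpec(strategy="circadian")
    web_p = FoodWebSpec(strategy="passive")
    tr_c = PondModel(scen, web_c, tv_c).simulate(rtol=1e-8, atol=1e-10)
    tr_p = PondModel(scen, web_p, tv_c).simulate(rtol=1e-8, atol=1e-10)
    k = min(len(tr_c.t), len(tr_p.t)) - 1
    np.testing.assert_allclose(tr_c.y[k], tr_p.y[k], rtol=1e-5, atol=1e-5)


def test_balanced_growth_holds_cn_ratio(balanced_run):
    cn = balanced_run.phyto_cn()
    assert np.all(np.abs(cn - 14.0) < 0.2)


def test_storage_strategies_run_carbon_rich(circadian_run, passive_run):
    """Under N limitation the storage strategies push phytoplankton C:N
    far above the balanced value."""
    for run in (circadian_run, passive_run):
        k = np.searchsorted(run.t, 540.0)     # mid-summer, year 2
        assert run.phyto_cn()[k] > 50.0


def test_trajectory_writers(circadian_run):
    frame = circadian_run.to_frame()
    assert set(frame.columns) == {"t", "variable", "value"}
    ds = circadian_run.to_dataset()
    assert ds["sigma_R"].attrs["units"] == "J K-1"
    assert "sigma_T" in circadian_run.ledger_json()
    rates = circadian_run.rates(every=400)
    assert rates.shape[1] == circadian_run.model.n_rxn
    assert (rates >= -1e-12).all().all()


def test_integration_failure_surfaces_diagnostics():
    m = model()
    m.rhs_fast = lambda t, y: np.full(m.n_conc + 5, np.nan)
    with pytest.raises((RuntimeError, FloatingPointError, ValueError)):
        m.simulate(horizon=1.0)
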