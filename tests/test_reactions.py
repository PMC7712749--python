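"""Stoichiometric integrity of the generated reaction network."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mepweb import FoodWebSpec, TraitVector, build_reaction_set
from mepweb.reactions import (build_bacteria_reactions,
                              build_consumer_reactions,
                              build_phyto_reactions, element_residual)

WEB = FoodWebSpec(strategy="circadian")


def random_traits(web, seed=0):
    rng = np.random.default_rng(seed)
    nP, nB, nC = web.n_phyto, web.n_bact, web.n_cons
    return TraitVector(
        eps_p=rng.uniform(0.05, 0.95, nP), t_on=np.zeros(nP),
        t_off=np.ones(nP), omega_amp=rng.uniform(0, 1, nP),
        eps_b=rng.uniform(0.05, 0.95, nB),
        omega_b=rng.dirichlet(np.ones(3), nB) if nB else np.zeros((0, 3)),
        eps_c=rng.uniform(0.05, 0.95, nC),
        omega_c=rng.uniform(0, 1, (nC, nP + nB + nC)))


@pytest.mark.parametrize("nP,nB,nC", [(0, 0, 1), (1, 1, 1), (2, 1, 3),
                                      (3, 3, 3), (1, 0, 2)])
def test_reaction_count_formula(nP, nB, nC):
    web = FoodWebSpec(n_phyto=nP, n_bact=nB, n_cons=nC, strategy="circadian")
    rxns = build_reaction_set(web, random_traits(web))
    assert len(rxns) == 2 * nP + 3 * nB + (nP + nB + nC) * nC


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.floats(0.0, 0.9999), st.integers(0, 10_000))
def test_element_balance_for_any_efficiency(eps, seed):
    """Every generated reaction conserves C, H, O, N, P to 1e-9 by brute
    atom summation, for efficiencies across the whole trait range."""
    for rxn in (build_phyto_reactions(1, eps, WEB)
                + build_bacteria_reactions(1, eps, WEB)
                + build_consumer_reactions(1, eps, ["SP1", "SB1", "SC1"], WEB)):
        res = element_residual(rxn, WEB)
        assert np.abs(res).max() < 1e-9, rxn.name


def test_epsilon_one_phyto_biosynthesis_releases_no_co2():
    r1, r2 = build_phyto_reactions(1, 0.9999999, WEB)
    assert abs(r2.stoich.get("H2CO3", 0.0)) < 1e-6
    assert r2.stoich["SP1"] == pytest.approx(1.0, abs=1e-6)


def test_epsilon_zero_phyto_store_fully_combusted():
    _, r2 = build_phyto_reactions(1, 0.0, WEB)
    assert r2.stoich["H2CO3"] == pytest.approx(1.0)     # all C to CO2
    assert "SP1" not in r2.stoich                       # no biomass made
    assert r2.stoich["O2"] == pytest.approx(-1.0)       # CH2O combustion


def test_phyto_pair_carbon_closure():
    for eps in (0.1, 0.5, 0.9):
        r1, r2 = build_phyto_reactions(1, eps, WEB)
        c_fixed = -r1.stoich["H2CO3"]
        assert c_fixed == pytest.approx(r1.stoich["CP1"])
        c_in = -sum(nu for sp, nu in r2.stoich.items()
                    if sp in ("CP1",) and nu < 0)
        c_out = r2.stoich.get("SP1", 0.0) + r2.stoich.get("H2CO3", 0.0)
        assert c_in == pytest.approx(c_out)


def test_bacteria_decomposition_reactions_are_isomerizations():
    grow, dec_c, dec_n = build_bacteria_reactions(1, 0.1628, WEB)
    assert dec_c.stoich == {"CD": -1.0, "CL": 1.0}
    assert dec_n.stoich == {"ND": -1.0, "NH3": 1.0}
    # growth consumes N in proportion to biomass made
    assert grow.stoich["NH3"] == pytest.approx(-0.1628 * WEB.gamma)


def test_consumer_nitrogen_partition():
    """Prey N ends up in new biomass, ammonia and detrital N, conserving N
    exactly; the non-assimilated split follows the sloppy-feeding fraction."""
    eps = 0.4
    rxns = build_consumer_reactions(1, eps, ["SP1", "SB1", "SC1"], WEB)
    assert len(rxns) == 3
    for rxn in rxns:
        n_in = WEB.gamma
        n_bio = WEB.gamma * rxn.stoich.get("SC1", 0.0)
        if rxn.prey == "SC1":
            n_bio = WEB.gamma * (rxn.stoich["SC1"] + 1.0)
        n_out = n_bio + rxn.stoich.get("NH3", 0.0) + rxn.stoich.get("ND", 0.0)
        assert n_out == pytest.approx(n_in)
        assert rxn.stoich.get("NH3", 0.0) == pytest.approx(
            rxn.stoich.get("ND", 0.0))    # 50/50 sloppy split


def test_cannibalism_reaction_exists_and_balances():
    rxns = build_consumer_reactions(1, 0.3, ["SP1", "SB1", "SC1"], WEB)
    cann = [r for r in rxns if r.prey == "SC1"][0]
    assert cann.stoich["SC1"] == pytest.approx(0.3 - 1.0)
    assert np.abs(element_residual(cann, WEB)).max() < 1e-9


def test_epsilon_zero_consumer_full_remineralization():
    rxns = build_consumer_reactions(1, 0.0, ["SP1"], WEB)
    assert "SC1" not in rxns[0].stoich
    # all prey carbon leaves as CO2 + CD
    c_out = rxns[0].stoich["H2CO3"] + rxns[0].stoich["CD"]
    assert c_out == pytest.approx(1.0)


def test_consumer_needs_prey():
    with pytest.raises(ValueError):
        build_consumer_reactions(1, 0.5, [], WEB)


def test_stoichiometry_table_dump():
    rxns = build_reaction_set(WEB, random_traits(WEB))
    frame = rxns.to_frame()
    assert list(frame.columns) == ["reaction", "species", "coefficient"]
    assert set(r.name for r in rxns.reactions) == set(frame.reaction)
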