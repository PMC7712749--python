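"""Named scenarios, shipped trait presets, and the random-trait null model.

The scenario library covers the configurations the model was characterized
on: the nominal pond (nominal feed at D = 0.2 1/d), the same pond at
high dilution (1.5 and 2.0 1/d), larger food webs (2P2B2C, 3P3B3C), and a
"chem-vs-light" variant where solar input is cut 10x and labile-carbon
feed raised 1200x so chemical and electromagnetic free-energy inputs are
nearly equal.

The shipped trait presets are the published 1P1B1C optima for the three
temporal strategies; they anchor the package's regression suite.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .config import (FoodWebSpec, ScenarioSpec, TraitVector, build_scenario,
                     validate_traits)
from .dynamics import PondModel, Trajectory
from .optimize import TraitCodec, lhs_starts

SCENARIOS: dict[str, dict] = {
    "nominal": {},
    "nominal-2p2b2c": {"foodweb": {"n_phyto": 2, "n_bact": 2, "n_cons": 2}},
    "nominal-3p3b3c": {"foodweb": {"n_phyto": 3, "n_bact": 3, "n_cons": 3}},
    "high-dilution": {"environment": {"dilution": 1.5}},
    "high-dilution-2.0": {"environment": {"dilution": 2.0}},
    "chem-vs-light": {"environment": {"i0_max": 40_600.0},
                      "feed": {"CL": 12_000.0}},
}


def scenario_names() -> list[str]:
    return sorted(SCENARIOS)


def load_scenario(name: str, strategy: str = "circadian"
                  ) -> tuple[ScenarioSpec, FoodWebSpec]:
    """A named scenario from the library, validated."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; known: {scenario_names()}")
    cfg = {k: dict(v) for k, v in SCENARIOS[name].items()}
    cfg["strategy"] = strategy
    return build_scenario(cfg)


def optimal_traits(strategy: str, web: FoodWebSpec | None = None) -> TraitVector:
    """Published optimal 1P1B1C trait values for a temporal strategy."""
    if strategy not in ("balanced", "passive", "circadian"):
        raise KeyError(f"no shipped preset for strategy {strategy!r}")
    web = web or FoodWebSpec(strategy=strategy)
    if (web.n_phyto, web.n_bact, web.n_cons) != (1, 1, 1):
        raise ValueError("shipped presets are for the 1P1B1C web")
    path = resources.files("mepweb.data") / f"optimal_traits_1p1b1c_{strategy}.csv"
    with resources.as_file(path) as p:
        frame = pd.read_csv(p)
    return validate_traits(TraitVector.from_frame(frame, web), web)


def zero_growth_traits(web: FoodWebSpec) -> TraitVector:
    """The abiotic baseline: every efficiency 0, no photosynthetic
    allocation, so only feed biomass absorbs light and no reaction runs."""
    nP, nB, nC = web.n_phyto, web.n_bact, web.n_cons
    return TraitVector(
        eps_p=np.zeros(nP), t_on=np.zeros(nP), t_off=np.ones(nP),
        omega_amp=np.zeros(nP),
        eps_b=np.zeros(nB), omega_b=np.full((nB, 3), 1.0 / 3.0),
        eps_c=np.zeros(nC), omega_c=np.full((nC, web.n_prey), 0.5))


def random_trait_ensemble(scenario: ScenarioSpec, web: FoodWebSpec,
                          n: int = 90, seed=None, horizon=None,
                          rtol: float = 1e-5, atol: float = 1e-6,
                          keep_trajectories: bool = False):
    """Latin-hypercube random traits, each simulated: the null model that
    MEP-optimized traits are judged against.

    Returns (traits, sigma_t) where sigma_t is in J/K with NaN for failed
    runs (failures are recorded, not fatal).
    """
    codec = TraitCodec(web)
    lo = np.array([b[0] for b in codec.bounds])
    hi = np.array([b[1] for b in codec.bounds])
    traits, sigmas, trajs = [], [], []
    for u in lhs_starts(n, codec.dim, seed):
        tv = codec.decode(lo + (hi - lo) * u)
        traits.append(tv)
        try:
            tr = PondModel(scenario, web, tv).simulate(
                horizon=horizon, rtol=rtol, atol=atol, dt_out=2.0)
            sigmas.append(tr.ledger.sigma_t)
            if keep_trajectories:
                trajs.append(tr)
        except Exception:
            sigmas.append(np.nan)
            if keep_trajectories:
                trajs.append(None)
    out = (traits, np.array(sigmas))
    return out + (trajs,) if keep_trajectories else out


def run_preset(strategy: str, scenario_name: str = "nominal",
               **sim_kw) -> Trajectory:
    """Forward-run a shipped preset on a library scenario."""
    scen, web = load_scenario(scenario_name, strategy)
    tv = optimal_traits(strategy, web)
    return PondModel(scen, web, tv).simulate(**sim_kw)
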