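"""Domain types, scenario assembly and trait validation.

The model world is a well-mixed cylindrical pond of depth ``zeta_d`` and
surface area ``A`` run as a chemostat at dilution rate ``D`` and lit from
above with diel/seasonal solar radiation.  A scenario couples that
environment with a food web of ``nP`` phytoplankton, ``nB`` bacterial and
``nC`` consumer ecotypes whose free trait values (thermodynamic
efficiencies eps, catalyst allocations Omega, and the circadian clock
parameters tOn/tOff/OmegaAmp) are either supplied for a forward run or set
by the entropy-maximizing optimizer.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

STRATEGIES = ("balanced", "passive", "circadian", "sinusoid")

#: dissolved constituents, in state-vector order
DISSOLVED = ("H2CO3", "O2", "NH3", "CL", "CD", "ND")


def trait_count(n_phyto: int, n_bact: int, n_cons: int) -> int:
    """Number of free trait variables of an (nP, nB, nC) food web.

    Each phytoplankton carries (eps, tOn, tOff, OmegaAmp); each bacterium
    (eps, Omega1..3) with the allocation triplet confined to the simplex
    (hence 3 free entries); each consumer carries eps plus one prey
    allocation per prey, and every ecotype is potential prey:

        nT = 4 nP + 3 nB + (1 + nP + nB + nC) nC
    """
    for n in (n_phyto, n_bact, n_cons):
        if n < 0 or int(n) != n:
            raise ValueError("ecotype counts must be non-negative integers")
    return 4 * n_phyto + 3 * n_bact + (1 + n_phyto + n_bact + n_cons) * n_cons


@dataclass
class ScenarioSpec:
    """Environment, transport and feed of the pond chemostat.

    Feed concentrations are mmol m^-3; ``i0_max`` is the maximum surface
    solar photon flux at 0 deg latitude (mmol-gamma m^-2 d^-1).
    """

    temperature: float = 293.0          # K
    ph: float = 8.1
    ionic_strength: float = 0.72        # mol L^-1
    latitude: float = 42.0              # degrees
    depth: float = 1.0                  # m
    area: float = 1.0                   # m^2
    dilution: float = 0.2               # d^-1
    i0_max: float = 406_000.0           # mmol-gamma m^-2 d^-1
    horizon: float = 730.0              # d
    feed: dict = field(default_factory=lambda: {
        "H2CO3": 2000.0, "O2": 225.0, "NH3": 5.0,
        "CL": 10.0, "CD": 100.0, "ND": 7.0,
        "SP": 0.1, "CP": 0.1, "SB": 0.1, "SC": 0.1,
    })
    optimizer_options: dict = field(default_factory=dict)

    @property
    def volume(self) -> float:
        return self.area * self.depth

    @property
    def flow(self) -> float:
        return self.dilution * self.volume

    def validate(self) -> "ScenarioSpec":
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.depth <= 0 or self.area <= 0:
            raise ValueError("pond geometry must be positive")
        if self.dilution < 0:
            raise ValueError("dilution rate must be non-negative")
        if abs(self.latitude) > 90:
            raise ValueError("latitude out of range")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        missing = [k for k in (*DISSOLVED, "SP", "CP", "SB", "SC")
                   if k not in self.feed]
        if missing:
            raise ValueError(f"feed missing species: {missing}")
        bad = {k: v for k, v in self.feed.items() if v < 0}
        if bad:
            raise ValueError(f"negative feed concentrations: {bad}")
        return self


@dataclass
class FoodWebSpec:
    """Food-web size, biomass composition and fixed kinetic constants.

    Biomass ("biological structure", a catalyst rather than an organism)
    has a single elemental composition CH_a O_b N_g P_d shared by every
    ecotype.  nu_star/kappa_star parameterize the oligotroph-copiotroph
    family of adaptive Monod curves through eps; nu_d_star is the slower
    maximal rate of detritus decomposition.
    """

    n_phyto: int = 1
    n_bact: int = 1
    n_cons: int = 1
    strategy: str = "circadian"
    alpha: float = 1.8                  # H per C in biomass
    beta: float = 0.5                   # O per C
    gamma: float = 0.15                 # N per C (Redfield-like C:N ~ 6.7)
    delta: float = 0.01                 # P per C
    nu_star: float = 350.0              # d^-1
    kappa_star: float = 5000.0          # mmol m^-3
    nu_d_star: float = 175.0            # d^-1
    delta_psi: float = 0.1              # V
    detrital_fraction: float = 0.5      # sloppy-feeding split to detritus
    gas_velocity: float = 1.0           # m d^-1 (piston velocity, O2 & CO2)
    o2_saturation: float = 225.0        # mmol m^-3
    dic_saturation: float = 2000.0      # mmol m^-3
    # 440 nm absorption coefficients; defaults frozen in constants.py
    k_w: float | None = None
    k_chl: float | None = None
    k_p: float | None = None
    k_wp: float | None = None
    wavelength_nm: float = 440.0

    def __post_init__(self):
        from . import constants as C
        if self.k_w is None:
            self.k_w = C.K_W
        if self.k_chl is None:
            self.k_chl = C.K_CHL
        if self.k_p is None:
            self.k_p = C.K_P
        if self.k_wp is None:
            self.k_wp = C.K_WP

    @property
    def n_prey(self) -> int:
        return self.n_phyto + self.n_bact + self.n_cons

    @property
    def trait_count(self) -> int:
        return trait_count(self.n_phyto, self.n_bact, self.n_cons)

    @property
    def storage_ratio(self) -> float:
        """CP:SP ratio rho* enforced under balanced growth (C:N fixed at 14)."""
        rho = 14.0 * self.gamma - 1.0
        if rho <= 0:
            raise ValueError("balanced growth needs gamma > 1/14")
        return rho

    def validate(self) -> "FoodWebSpec":
        if min(self.n_phyto, self.n_bact, self.n_cons) < 0:
            raise ValueError("ecotype counts must be non-negative")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        for name in ("alpha", "beta", "gamma", "delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"composition exponent {name} must be > 0")
        if not 0.0 <= self.detrital_fraction <= 1.0:
            raise ValueError("detrital_fraction must be in [0, 1]")
        for name in ("nu_star", "kappa_star", "nu_d_star"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        return self


@dataclass
class TraitVector:
    """All free variables the optimizer controls.

    Shapes: phytoplankton arrays are (nP,), ``omega_b`` is (nB, 3) on the
    simplex, ``omega_c`` is (nC, nP+nB+nC) with entries individually in
    [0, 1] and *not* simplex-constrained (prey-concentration re-weighting
    makes the overall scale irrelevant).
    """

    eps_p: np.ndarray
    t_on: np.ndarray
    t_off: np.ndarray
    omega_amp: np.ndarray
    eps_b: np.ndarray
    omega_b: np.ndarray
    eps_c: np.ndarray
    omega_c: np.ndarray
    freq_p: np.ndarray | None = None    # sinusoid strategy only (d^-1)
    phase_p: np.ndarray | None = None   # sinusoid strategy only (d)

    def __post_init__(self):
        for name in ("eps_p", "t_on", "t_off", "omega_amp", "eps_b",
                     "omega_b", "eps_c", "omega_c"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
        nB, nC = len(self.eps_b), len(self.eps_c)
        self.omega_b = (self.omega_b.reshape(nB, 3) if nB
                        else np.zeros((0, 3)))
        self.omega_c = (self.omega_c.reshape(nC, self.omega_c.size // nC)
                        if nC else np.zeros((0, 0)))

    @property
    def n_free(self) -> int:
        return trait_count(len(self.eps_p), len(self.eps_b), len(self.eps_c))

    def copy(self) -> "TraitVector":
        return TraitVector(*(np.array(getattr(self, f)) for f in
                             ("eps_p", "t_on", "t_off", "omega_amp",
                              "eps_b", "omega_b", "eps_c", "omega_c")),
                           freq_p=None if self.freq_p is None else np.array(self.freq_p),
                           phase_p=None if self.phase_p is None else np.array(self.phase_p))

    # ---- serialization ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Tidy (group, ecotype, trait, value) table."""
        rows = []
        for i, (e, a, b, w) in enumerate(zip(self.eps_p, self.t_on,
                                             self.t_off, self.omega_amp), 1):
            rows += [("P", i, "eps", e), ("P", i, "t_on", a),
                     ("P", i, "t_off", b), ("P", i, "omega_amp", w)]
        for i, (e, om) in enumerate(zip(self.eps_b, self.omega_b), 1):
            rows.append(("B", i, "eps", e))
            rows += [("B", i, f"omega_{j+1}", om[j]) for j in range(3)]
        nP, nB = len(self.eps_p), len(self.eps_b)
        prey = [f"P{j+1}" for j in range(nP)] + [f"B{j+1}" for j in range(nB)] \
            + [f"C{j+1}" for j in range(len(self.eps_c))]
        for i, (e, om) in enumerate(zip(self.eps_c, self.omega_c), 1):
            rows.append(("C", i, "eps", e))
            rows += [("C", i, f"omega_{p}", om[j]) for j, p in enumerate(prey)]
        return pd.DataFrame(rows, columns=["group", "ecotype", "trait", "value"])

    def to_json(self) -> str:
        return json.dumps(
            {r.trait + f"_{r.group}{r.ecotype}": r.value
             for r in self.to_frame().itertuples()}, indent=1, sort_keys=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, web: FoodWebSpec) -> "TraitVector":
        get = {(g, int(i), t): v for g, i, t, v in
               frame[["group", "ecotype", "trait", "value"]].itertuples(index=False)}
        nP, nB, nC = web.n_phyto, web.n_bact, web.n_cons
        prey = [f"P{j+1}" for j in range(nP)] + [f"B{j+1}" for j in range(nB)] \
            + [f"C{j+1}" for j in range(nC)]
        return cls(
            eps_p=[get[("P", i + 1, "eps")] for i in range(nP)],
            t_on=[get.get(("P", i + 1, "t_on"), 0.0) for i in range(nP)],
            t_off=[get.get(("P", i + 1, "t_off"), 1.0) for i in range(nP)],
            omega_amp=[get[("P", i + 1, "omega_amp")] for i in range(nP)],
            eps_b=[get[("B", i + 1, "eps")] for i in range(nB)],
            omega_b=[[get[("B", i + 1, f"omega_{j+1}")] for j in range(3)]
                     for i in range(nB)],
            eps_c=[get[("C", i + 1, "eps")] for i in range(nC)],
            omega_c=[[get[("C", i + 1, f"omega_{p}")] for p in prey]
                     for i in range(nC)],
        )


def validate_traits(traits: TraitVector, web: FoodWebSpec,
                    simplex_tol: float = 1e-3) -> TraitVector:
    """Check bounds and shapes; renormalize near-simplex bacterial Omega.

    eps may be 0 (a no-growth ecotype, used by the abiotic baseline) but
    must be < 1; the bacterial allocation triplet must sum to 1 within
    ``simplex_tol`` (loose enough to admit 4-decimal rounded tables) and is renormalized exactly onto the simplex.
    """
    tv = traits.copy()
    shapes = {"eps_p": web.n_phyto, "t_on": web.n_phyto, "t_off": web.n_phyto,
              "omega_amp": web.n_phyto, "eps_b": web.n_bact, "eps_c": web.n_cons}
    for name, n in shapes.items():
        if len(getattr(tv, name)) != n:
            raise ValueError(f"{name} has wrong length for this food web")
    if tv.omega_b.shape != (web.n_bact, 3):
        raise ValueError("omega_b must be (nB, 3)")
    if web.n_cons and tv.omega_c.shape != (web.n_cons, web.n_prey):
        raise ValueError("omega_c must be (nC, nP+nB+nC)")
    for name in ("eps_p", "eps_b", "eps_c"):
        e = getattr(tv, name)
        if np.any(e < 0) or np.any(e >= 1):
            raise ValueError(f"{name} out of [0, 1)")
    for name in ("t_on", "t_off", "omega_amp"):
        v = getattr(tv, name)
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError(f"{name} out of [0, 1]")
    if np.any(tv.omega_b < 0):
        raise ValueError("omega_b entries must be non-negative")
    sums = tv.omega_b.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > simplex_tol):
        raise ValueError("bacterial omega triplet must sum to 1")
    tv.omega_b = tv.omega_b / sums[:, None]
    if np.any(tv.omega_c < 0) or np.any(tv.omega_c > 1):
        raise ValueError("omega_c entries must be in [0, 1]")
    if tv.freq_p is not None and np.any(np.asarray(tv.freq_p) <= 0):
        raise ValueError("sinusoid frequency must be positive")
    return tv


# --------------------------------------------------------------------------
# Scenario assembly

def _as_mapping(config) -> dict:
    if isinstance(config, dict):
        return config
    if hasattr(config, "read"):
        config = config.read()
    text = str(config)
    if "\n" not in text and text.endswith((".yaml", ".yml", ".json")):
        with open(text) as fh:
            text = fh.read()
    data = yaml.safe_load(io.StringIO(text))
    if not isinstance(data, dict):
        raise ValueError("scenario config must be a mapping")
    return data


def build_scenario(config) -> tuple[ScenarioSpec, FoodWebSpec]:
    """Assemble validated specs from a YAML string/path or nested dict.

    Recognized sections: ``environment``, ``feed``, ``foodweb``,
    ``strategy``, ``optimizer``.  Omitted fields take the nominal-scenario
    defaults (nominal feed, D = 0.2 1/d, 1 m deep 1 m^2 pond at 42 deg,
    730 d horizon).
    """
    data = _as_mapping(config)
    if not data:
        raise ValueError("empty scenario config")
    unknown = set(data) - {"environment", "feed", "foodweb", "strategy", "optimizer"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")

    scen = ScenarioSpec()
    env = dict(data.get("environment", {}))
    if "flow" in env:
        env["dilution"] = env.pop("flow") / (
            env.get("area", scen.area) * env.get("depth", scen.depth))
    for key, value in env.items():
        if not hasattr(scen, key):
            raise ValueError(f"unknown environment field {key!r}")
        setattr(scen, key, float(value))
    feed = dict(data.get("feed", {}))
    for key, value in feed.items():
        if key not in scen.feed:
            raise ValueError(f"unknown feed species {key!r}")
        scen.feed[key] = float(value)
    scen.optimizer_options = dict(data.get("optimizer", {}))

    web = FoodWebSpec()
    for key, value in dict(data.get("foodweb", {})).items():
        if not hasattr(web, key):
            raise ValueError(f"unknown foodweb field {key!r}")
        setattr(web, key, type(getattr(web, key))(value) if getattr(web, key) is not None else value)
    if "strategy" in data:
        web.strategy = str(data["strategy"])
    return scen.validate(), web.validate()


def scenario_to_dict(scen: ScenarioSpec, web: FoodWebSpec) -> dict:
    """Inverse of :func:`build_scenario` (round-trips exactly)."""
    return {
        "environment": {k: getattr(scen, k) for k in
                        ("temperature", "ph", "ionic_strength", "latitude",
                         "depth", "area", "dilution", "i0_max", "horizon")},
        "feed": dict(scen.feed),
        "strategy": web.strategy,
        "foodweb": {k: getattr(web, k) for k in
                    ("n_phyto", "n_bact", "n_cons", "alpha", "beta", "gamma",
                     "delta", "nu_star", "kappa_star", "nu_d_star",
                     "delta_psi", "detrital_fraction", "gas_velocity",
                     "o2_saturation", "dic_saturation",
                     "k_w", "k_chl", "k_p", "k_wp", "wavelength_nm")},
        "optimizer": dict(scen.optimizer_options),
    }
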