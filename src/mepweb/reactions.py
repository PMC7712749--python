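"""Stoichiometry of the ecotype reaction network.

For an (nP, nB, nC) web there are 2 nP + 3 nB + (nP+nB+nC) nC reactions:
each phytoplankton runs photon-driven carbon fixation (R1P) and
biosynthesis from its store (R2P); each bacterium runs aerobic growth on
labile carbon (R1B) plus decomposition of detrital carbon (R2B) and
nitrogen (R3B); each consumer runs one predation reaction per prey
(every ecotype, itself included).

All reactions are coupled between a catabolic and an anabolic sub-reaction
by the thermodynamic efficiency eps: the fraction eps of the catabolic free
energy is conserved in new biomass, the remainder dissipated.  Oxygen and
water coefficients are solved from elemental balance, so every generated
reaction conserves C, H, O, N and P exactly for any eps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import FoodWebSpec, TraitVector

#: element composition (C, H, O, N, P) keyed by thermodynamic base species
BASE_COMPOSITION = {
    "H2CO3": (1, 2, 3, 0, 0),
    "O2": (0, 0, 2, 0, 0),
    "NH3": (0, 3, 0, 1, 0),
    "CH2O": (1, 2, 1, 0, 0),     # CL, CD, CP
    "ND": (0, 3, 0, 1, 0),
    "H3PO4": (0, 3, 4, 0, 1),
    "PD": (0, 3, 4, 0, 1),
    "H2O": (0, 2, 1, 0, 0),
}


def _base_name(name: str) -> str:
    """Strip the ecotype number from SP{i}/CP{i}/SB{i}/SC{i} names."""
    if name[:2] in ("SP", "SB", "SC", "CP") and name[2:].isdigit():
        return name[:2]
    return name


def species_composition(name: str, web: FoodWebSpec) -> tuple:
    base = _base_name(name)
    if base in ("SP", "SB", "SC", "S"):
        return (1, web.alpha, web.beta, web.gamma, web.delta)
    if base in ("CL", "CD", "CP"):
        return BASE_COMPOSITION["CH2O"]
    return BASE_COMPOSITION[base]


def thermo_base(name: str) -> str:
    """Map a state/virtual species name to its thermodynamic table entry."""
    base = _base_name(name)
    if base in ("SP", "SB", "SC"):
        return "S"
    if base == "CP":
        return "CP"
    return base


@dataclass
class Reaction:
    """One reaction of the network.

    ``stoich`` holds signed coefficients per unit reaction extent over
    state plus virtual (H2O, H3PO4, PD) species.  For predation on
    phytoplankton, ``stoich_rho`` is the additional combustion of the
    prey's internal carbon store per unit of the (state-dependent) ratio
    rho = [CP]/[SP].  ``catabolic`` lists (weight-kind, stoichiometry)
    pairs whose quotient-corrected free energies, scaled by the weights,
    compose drG; ``lambda_mask`` lists the substrates entering the kinetic
    drive F_K.
    """
    name: str
    kind: str                    # photo | growth | decomp | graze
    catalyst: str                # catalyst species name, e.g. "SP1"
    omega_slot: int              # which allocation variable of the catalyst
    eps: float
    stoich: dict = field(default_factory=dict)
    stoich_rho: dict = field(default_factory=dict)
    lambda_mask: tuple = ()
    nu_max: float | None = None  # None for the photon-driven reaction
    catabolic: list = field(default_factory=list)
    n_e0: float = 0.0            # electrons per extent, (1-eps) part
    n_e_rho: float = 0.0         # electrons per extent per unit rho
    prey: str | None = None      # prey species (graze only)
    prey_cp: str | None = None   # prey carbon store (graze on phyto)


def _balance(stoich: dict, web: FoodWebSpec) -> dict:
    """Solve the O2 and H2O coefficients from O and H conservation and
    verify C, N, P close to 1e-12."""
    s = dict(stoich)
    s.pop("O2", None), s.pop("H2O", None)
    tot = np.zeros(5)
    for name, nu in s.items():
        tot += nu * np.asarray(species_composition(name, web), float)
    c, h, o, n, p = tot
    if abs(c) > 1e-9 or abs(n) > 1e-9 or abs(p) > 1e-9:
        raise ValueError(f"unbalanced composition (C={c}, N={n}, P={p})")
    b_h2o = -h / 2.0                       # 2 H per water
    b_o2 = -(o + b_h2o) / 2.0              # 2 O per O2
    s["H2O"] = b_h2o
    s["O2"] = b_o2
    return {k: v for k, v in s.items() if abs(v) > 1e-14}


def element_residual(rxn: Reaction, web: FoodWebSpec) -> np.ndarray:
    """(C, H, O, N, P) imbalance of the base and rho stoichiometries."""
    res = []
    for stoich in (rxn.stoich, rxn.stoich_rho):
        tot = np.zeros(5)
        for name, nu in stoich.items():
            tot += nu * np.asarray(species_composition(name, web), float)
        res.append(tot)
    return np.concatenate(res)


def build_phyto_reactions(i: int, eps: float, web: FoodWebSpec) -> list[Reaction]:
    """CO2 fixation into the carbon store, and store-fueled biosynthesis."""
    if not 0.0 <= eps < 1.0 + 1e-12:
        raise ValueError("eps out of range")
    sp, cp = f"SP{i}", f"CP{i}"
    r1 = Reaction(
        name=f"R1,P{i}", kind="photo", catalyst=sp, omega_slot=0, eps=eps,
        stoich={"H2CO3": -eps, cp: eps, "O2": eps},
        lambda_mask=("H2CO3",),
        # catabolic record for reporting; drG handled via the fixation
        # free energy and photon count at run time
        catabolic=[("photo", {"H2CO3": -1.0, cp: 1.0, "O2": 1.0})],
    )
    r2 = Reaction(
        name=f"R2,P{i}", kind="growth", catalyst=sp, omega_slot=1, eps=eps,
        stoich=_balance({cp: -1.0, "NH3": -eps * web.gamma,
                         "H3PO4": -eps * web.delta, sp: eps,
                         "H2CO3": 1.0 - eps}, web),
        lambda_mask=(),
        nu_max=web.nu_star,
        catabolic=[("one_minus_eps",
                    _balance({cp: -1.0, "H2CO3": 1.0}, web))],
        n_e0=4.0,
    )
    return [r1, r2]


def build_bacteria_reactions(i: int, eps: float, web: FoodWebSpec) -> list[Reaction]:
    """Aerobic growth on labile C plus the two decomposition reactions."""
    if not 0.0 <= eps < 1.0 + 1e-12:
        raise ValueError("eps out of range")
    sb = f"SB{i}"
    grow = Reaction(
        name=f"R1,B{i}", kind="growth", catalyst=sb, omega_slot=0, eps=eps,
        stoich=_balance({"CL": -1.0, "NH3": -eps * web.gamma,
                         "H3PO4": -eps * web.delta, sb: eps,
                         "H2CO3": 1.0 - eps}, web),
        lambda_mask=("CL",),
        nu_max=web.nu_star,
        catabolic=[("one_minus_eps",
                    _balance({"CL": -1.0, "H2CO3": 1.0}, web))],
        n_e0=4.0,
    )
    dec_c = Reaction(
        name=f"R2,B{i}", kind="decomp", catalyst=sb, omega_slot=1, eps=eps,
        stoich={"CD": -1.0, "CL": 1.0},
        lambda_mask=("CD",),
        nu_max=web.nu_d_star,
        catabolic=[("unit", {"CD": -1.0, "CL": 1.0})],
        n_e0=1.0,
    )
    dec_n = Reaction(
        name=f"R3,B{i}", kind="decomp", catalyst=sb, omega_slot=2, eps=eps,
        stoich={"ND": -1.0, "NH3": 1.0},
        lambda_mask=("ND",),
        nu_max=web.nu_d_star,
        catabolic=[("unit", {"ND": -1.0, "NH3": 1.0})],
        n_e0=1.0,
    )
    return [grow, dec_c, dec_n]


def build_consumer_reactions(i: int, eps: float, prey: list[str],
                             web: FoodWebSpec) -> list[Reaction]:
    """One predation reaction per prey ecotype (cannibalism included).

    Per unit prey biomass consumed: the fraction eps is assimilated as
    consumer biomass (identical composition), and of the remainder a
    fraction ``detrital_fraction`` is returned as detrital C/N/P ("sloppy
    feeding") while the rest is combusted/remineralized to H2CO3, NH3 and
    phosphate.  Internal carbon stores of phytoplankton prey are combusted
    entirely, contributing free energy but no biomass.
    """
    if not 0.0 <= eps < 1.0 + 1e-12:
        raise ValueError("eps out of range")
    if not prey:
        raise ValueError("consumer needs at least one prey")
    sc = f"SC{i}"
    f_d = web.detrital_fraction
    out = []
    for chi in prey:
        rem = 1.0 - eps
        raw = {
            "CD": rem * f_d,
            "H2CO3": rem * (1.0 - f_d),
            "NH3": web.gamma * rem * (1.0 - f_d),
            "ND": web.gamma * rem * f_d,
            "H3PO4": web.delta * rem * (1.0 - f_d),
            "PD": web.delta * rem * f_d,
        }
        # accumulate so cannibalism (chi == sc) nets to eps - 1
        raw[chi] = raw.get(chi, 0.0) - 1.0
        raw[sc] = raw.get(sc, 0.0) + eps
        stoich = _balance(raw, web)
        comb = _balance({"S": -1.0, "H2CO3": 1.0, "NH3": web.gamma,
                         "H3PO4": web.delta}, web)
        conv = _balance({"S": -1.0, "CD": 1.0, "ND": web.gamma,
                         "PD": web.delta}, web)
        rxn = Reaction(
            name=f"R{chi},C{i}", kind="graze", catalyst=sc, omega_slot=0,
            eps=eps,
            stoich=stoich,
            lambda_mask=(chi,),
            nu_max=web.nu_star,
            catabolic=[("one_minus_eps_comb", comb),
                       ("one_minus_eps_conv", conv)],
            n_e0=4.0 * (-comb["O2"]) * (1.0 - f_d) + 4.0 * max(-conv.get("O2", 0.0), 0.0) * f_d,
            prey=chi,
        )
        if chi.startswith("SP"):
            rxn.prey_cp = "CP" + chi[2:]
            rxn.stoich_rho = {rxn.prey_cp: -1.0, "O2": -1.0, "H2CO3": 1.0}
            rxn.n_e_rho = 4.0
        out.append(rxn)
    return out


@dataclass
class ReactionSet:
    reactions: list[Reaction]
    web: FoodWebSpec

    def __len__(self):
        return len(self.reactions)

    def to_frame(self) -> pd.DataFrame:
        """Human-readable stoichiometry table (reaction, species, coef)."""
        rows = []
        for r in self.reactions:
            for sp, nu in sorted(r.stoich.items()):
                rows.append((r.name, sp, nu))
            for sp, nu in sorted(r.stoich_rho.items()):
                rows.append((r.name, f"{sp} (per rho)", nu))
        return pd.DataFrame(rows, columns=["reaction", "species", "coefficient"])


def build_reaction_set(web: FoodWebSpec, traits: TraitVector) -> ReactionSet:
    """All reactions of the food web at the trait values given."""
    rxns: list[Reaction] = []
    for i in range(web.n_phyto):
        rxns += build_phyto_reactions(i + 1, float(traits.eps_p[i]), web)
    for i in range(web.n_bact):
        rxns += build_bacteria_reactions(i + 1, float(traits.eps_b[i]), web)
    prey = ([f"SP{j+1}" for j in range(web.n_phyto)]
            + [f"SB{j+1}" for j in range(web.n_bact)]
            + [f"SC{j+1}" for j in range(web.n_cons)])
    for i in range(web.n_cons):
        rxns += build_consumer_reactions(i + 1, float(traits.eps_c[i]), prey, web)
    expected = 2 * web.n_phyto + 3 * web.n_bact + web.n_prey * web.n_cons
    assert len(rxns) == expected
    return ReactionSet(rxns, web)
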