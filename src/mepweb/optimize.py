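"""Entropy-maximizing trait search.

Trait vectors are encoded into a bounded box: efficiencies in
[1e-4, 0.9999], clock and allocation variables in [0, 1], and each
bacterial allocation triplet through two stick-breaking coordinates so the
simplex constraint is built into the geometry.  The objective -- total
entropy produced over the simulation horizon -- is maximized by independent
local searches (derivative-free quadratic trust-region models, COBYQA)
started from a seeded Latin hypercube, the same multi-start protocol used
for the published optima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .config import FoodWebSpec, ScenarioSpec, TraitVector, validate_traits
from .dynamics import PondModel

EPS_LO, EPS_HI = 1e-4, 0.9999


class TraitCodec:
    """Bijective map between TraitVector and a bounded search vector.

    For the passive and balanced strategies tOn/tOff are frozen at (0, 1)
    and dropped from the vector; the sinusoid strategy swaps the clock
    window for (frequency, phase).
    """

    def __init__(self, web: FoodWebSpec):
        self.web = web
        names: list[str] = []
        for i in range(1, web.n_phyto + 1):
            names.append(f"eps_P{i}")
            if web.strategy in ("circadian",):
                names += [f"t_on_P{i}", f"t_off_P{i}"]
            elif web.strategy == "sinusoid":
                names += [f"freq_P{i}", f"phase_P{i}"]
            names.append(f"amp_P{i}")
        for i in range(1, web.n_bact + 1):
            names += [f"eps_B{i}", f"stick1_B{i}", f"stick2_B{i}"]
        prey = ([f"P{j+1}" for j in range(web.n_phyto)]
                + [f"B{j+1}" for j in range(web.n_bact)]
                + [f"C{j+1}" for j in range(web.n_cons)])
        for i in range(1, web.n_cons + 1):
            names.append(f"eps_C{i}")
            names += [f"om_{p}_C{i}" for p in prey]
        self.names = names

    @property
    def dim(self) -> int:
        return len(self.names)

    @property
    def bounds(self) -> list[tuple[float, float]]:
        out = []
        for n in self.names:
            if n.startswith("eps"):
                out.append((EPS_LO, EPS_HI))
            elif n.startswith("freq"):
                out.append((0.1, 4.0))
            else:
                out.append((0.0, 1.0))
        return out

    # -- simplex via stick breaking ------------------------------------
    @staticmethod
    def _sticks_to_simplex(s1: float, s2: float) -> np.ndarray:
        w1 = s1
        w2 = (1.0 - w1) * s2
        return np.array([w1, w2, 1.0 - w1 - w2])

    @staticmethod
    def _simplex_to_sticks(w: np.ndarray) -> tuple[float, float]:
        w = np.asarray(w, float) / np.sum(w)
        s1 = w[0]
        s2 = w[1] / (1.0 - w[0]) if w[0] < 1.0 else 0.0
        return float(s1), float(s2)

    def encode(self, tv: TraitVector) -> np.ndarray:
        web = self.web
        x = []
        for i in range(web.n_phyto):
            x.append(tv.eps_p[i])
            if web.strategy == "circadian":
                x += [tv.t_on[i], tv.t_off[i]]
            elif web.strategy == "sinusoid":
                x += [1.0 if tv.freq_p is None else tv.freq_p[i],
                      0.0 if tv.phase_p is None else tv.phase_p[i]]
            x.append(tv.omega_amp[i])
        for i in range(web.n_bact):
            s1, s2 = self._simplex_to_sticks(tv.omega_b[i])
            x += [tv.eps_b[i], s1, s2]
        for i in range(web.n_cons):
            x.append(tv.eps_c[i])
            x += list(tv.omega_c[i])
        v = np.array(x, float)
        if len(v) != self.dim:
            raise ValueError("trait vector does not match this codec")
        return v

    def decode(self, x: np.ndarray) -> TraitVector:
        web = self.web
        x = np.asarray(x, float)
        if x.shape != (self.dim,):
            raise ValueError("wrong search-vector length")
        k = 0
        eps_p, t_on, t_off, amp = [], [], [], []
        freq, phase = [], []
        for _ in range(web.n_phyto):
            eps_p.append(x[k]); k += 1
            if web.strategy == "circadian":
                t_on.append(x[k]); t_off.append(x[k + 1]); k += 2
            elif web.strategy == "sinusoid":
                freq.append(x[k]); phase.append(x[k + 1]); k += 2
                t_on.append(0.0); t_off.append(1.0)
            else:
                t_on.append(0.0); t_off.append(1.0)
            amp.append(x[k]); k += 1
        eps_b, om_b = [], []
        for _ in range(web.n_bact):
            eps_b.append(x[k])
            om_b.append(self._sticks_to_simplex(x[k + 1], x[k + 2]))
            k += 3
        eps_c, om_c = [], []
        for _ in range(web.n_cons):
            eps_c.append(x[k]); k += 1
            om_c.append(x[k:k + web.n_prey]); k += web.n_prey
        tv = TraitVector(eps_p, t_on, t_off, amp, eps_b, np.array(om_b),
                         eps_c, np.array(om_c) if web.n_cons else np.zeros((0, web.n_prey)),
                         freq_p=np.array(freq) if freq else None,
                         phase_p=np.array(phase) if phase else None)
        return validate_traits(tv, self.web)


def lhs_starts(n: int, dim: int, seed) -> np.ndarray:
    """n Latin-hypercube points in the unit box: each margin is stratified
    into n equal bins holding exactly one sample."""
    if n < 1:
        raise ValueError("need at least one start")
    return qmc.LatinHypercube(d=dim, seed=seed).random(n)


def local_maximize(objective, x0, bounds, budget: int = 300,
                   radius_floor: float = 1e-4):
    """Bound-constrained derivative-free ascent from x0.

    Quadratic interpolation models in a shrinking trust region; stops at
    the radius floor or the evaluation budget.  Objective failures at trial
    points are treated as -inf so the region contracts away from them.
    Returns (x_best, f_best, n_evals); f_best >= f(x0).
    """
    best = {"x": np.array(x0, float), "f": -np.inf, "n": 0}

    def neg(x):
        best["n"] += 1
        try:
            f = float(objective(np.asarray(x)))
        except Exception:
            return 1e30
        if f > best["f"]:
            best["f"], best["x"] = f, np.array(x)
        return -f

    f0 = -neg(x0)
    try:
        minimize(neg, x0, method="cobyqa", bounds=bounds,
                 options={"maxfev": max(budget, 2), "final_tr_radius": radius_floor})
    except Exception:
        pass    # keep the best point seen so far
    if best["f"] < f0:      # pragma: no cover - monotone by construction
        best["f"], best["x"] = f0, np.array(x0, float)
    return best["x"], best["f"], best["n"]


@dataclass
class OptimizationResult:
    best_traits: TraitVector
    best_sigma_t: float                 # J/K over the horizon
    restarts: list = field(default_factory=list)
    seed: int | None = None
    budget: int = 0

    def restart_table(self):
        import pandas as pd
        return pd.DataFrame(self.restarts,
                            columns=["restart", "sigma_t_start", "sigma_t_final",
                                     "n_evals"])


def make_objective(scenario: ScenarioSpec, web: FoodWebSpec,
                   codec: TraitCodec | None = None, horizon=None,
                   rtol: float = 1e-6, atol: float = 1e-8):
    """sigma_T (J/K) of a forward run as a function of the search vector."""
    codec = codec or TraitCodec(web)

    def objective(x):
        tv = codec.decode(x)
        tr = PondModel(scenario, web, tv).simulate(horizon=horizon,
                                                   rtol=rtol, atol=atol,
                                                   dt_out=1.0)
        return tr.ledger.sigma_t

    return objective


def optimize_traits(scenario: ScenarioSpec, web: FoodWebSpec,
                    restarts: int = 90, seed: int | None = None,
                    budget: int | None = None, horizon=None,
                    rtol: float = 1e-6, atol: float = 1e-8,
                    warm_starts: list[TraitVector] | None = None,
                    callback=None) -> OptimizationResult:
    """Multi-start MEP trait optimization.

    ``restarts`` independent local searches begin from a seeded Latin
    hypercube (plus optional warm starts, e.g. the optimum of a nested
    strategy); the searches are independent, so the result does not depend
    on execution order.  Simulation failures abort only their own restart.
    """
    codec = TraitCodec(web)
    dim = codec.dim
    budget = int(budget if budget is not None else 300 * dim)
    objective = make_objective(scenario, web, codec, horizon, rtol, atol)
    lo = np.array([b[0] for b in codec.bounds])
    hi = np.array([b[1] for b in codec.bounds])
    starts = [lo + (hi - lo) * u for u in lhs_starts(restarts, dim, seed)]
    for tv in (warm_starts or []):
        starts.append(codec.encode(validate_traits(tv, web)))

    records, best_x, best_f = [], None, -np.inf
    for k, x0 in enumerate(starts):
        try:
            f0 = objective(x0)
        except Exception:
            records.append((k, np.nan, np.nan, 1))
            continue
        x, f, n = local_maximize(objective, x0, codec.bounds, budget)
        records.append((k, f0, f, n))
        if f > best_f:
            best_x, best_f = x, f
        if callback is not None:
            callback(k, f)
    if best_x is None:
        raise RuntimeError("every restart failed")
    return OptimizationResult(codec.decode(best_x), best_f, records,
                              seed=seed, budget=budget)
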