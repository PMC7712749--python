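"""Rate laws and the phytoplankton temporal strategies.

All chemotrophic reactions follow the adaptive Monod law

    r = nu* eps^2 Omega [S] F_K F_T,

whose maximal rate (nu* eps^2) and half-saturation (kappa* eps^4) are both
parameterized by the thermodynamic efficiency eps, spanning the
oligotroph-to-copiotroph continuum: a low-eps ecotype is slow but
high-affinity, a high-eps ecotype fast but easily substrate-limited.
The photon-driven fixation reaction instead runs at the photon capture
rate divided by the quantum requirement n1P, times the same two drives.

The temporal strategies act through the allocation Omega1(t) of
phytoplankton biomass to fixation versus biosynthesis: constant under
balanced growth and passive storage, a diel square wave (tOn, tOff,
OmegaAmp) under the circadian clock, or a sinusoid variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import constants as C


@dataclass
class ScheduleSpec:
    strategy: str
    t_on: float = 0.0
    t_off: float = 1.0
    amplitude: float = 1.0
    freq: float = 1.0        # d^-1, sinusoid only
    phase: float = 0.0       # d, sinusoid only


def omega_schedule(t: float, s: ScheduleSpec) -> float:
    """Allocation to the fixation reaction, Omega1(t); Omega2 = 1 - Omega1.

    Circadian: OmegaAmp inside the diel window [tOn, tOff] (wrapping when
    tOn > tOff), 0 outside — off-window biomass is fully redirected to
    biosynthesis.  Passive/balanced: constant OmegaAmp, so (tOn, tOff) =
    (0, 1) circadian reproduces passive storage exactly.
    """
    if s.strategy in ("balanced", "passive"):
        return s.amplitude
    if s.strategy == "sinusoid":
        return s.amplitude * 0.5 * (
            1.0 + math.sin(2.0 * math.pi * s.freq * (t - s.phase)))
    td = t % 1.0
    if s.t_on <= s.t_off:
        on = s.t_on <= td <= s.t_off
    else:
        on = td >= s.t_on or td <= s.t_off
    return s.amplitude if on else 0.0


def schedule_switches(s: ScheduleSpec) -> tuple[float, ...]:
    """Discontinuity times (fraction of day) of the square wave."""
    if s.strategy != "circadian":
        return ()
    pts = {s.t_on % 1.0, s.t_off % 1.0} - {0.0}
    return tuple(sorted(pts))


def kinetic_drive_fk(conc, eps: float, kappa_star: float) -> float:
    """F_K = prod c/(c + kappa* eps^4) over the masked substrates, in [0,1].

    An empty mask gives 1 (empty product); eps = 0 gives full drive, the
    infinite-affinity end of the family.
    """
    k = kappa_star * eps ** 4
    fk = 1.0
    for c in np.atleast_1d(np.asarray(conc, float)):
        c = max(c, 0.0)
        fk *= c / (c + k) if (c + k) > 0 else 0.0
    return fk


def monod_rate(nu_star: float, eps: float, omega: float, s_cat: float,
               fk: float, ft: float) -> float:
    """Adaptive Monod rate (mmol m^-3 d^-1)."""
    return nu_star * eps * eps * omega * max(s_cat, 0.0) * fk * ft


def photo_rate(delta_i: float, n1p: float, fk: float, ft: float) -> float:
    """Photon-driven fixation rate r1P = (DeltaI / n1P) F_K F_T."""
    if n1p <= 0:
        raise ValueError("n1p must be positive")
    return max(delta_i, 0.0) / n1p * fk * ft


def prey_weighting(omega_row, prey_conc) -> np.ndarray:
    """Concentration re-weighted prey allocation omega.

    omega_j = Omega_j c_j / sum_k Omega_k c_k; all zero when no prey is
    present, and summing to 1 otherwise.
    """
    om = np.asarray(omega_row, float)
    c = np.maximum(np.asarray(prey_conc, float), 0.0)
    if om.shape != c.shape or om.size == 0:
        raise ValueError("need one allocation entry per prey")
    w = om * c
    tot = w.sum()
    if tot <= 0:
        return np.zeros_like(w)
    return w / tot


def balanced_coupling(r1_kin: float, r2_kin: float, eps: float,
                      rho_star: float, transport_bias: float = 0.0
                      ) -> tuple[float, float]:
    """Couple fixation and biosynthesis so [CP]/[SP] stays at rho*.

    Holding the ratio requires eps r1 - r2 = rho* eps r2 + bias, where the
    bias accounts for transport in/out of the two pools (zero in a closed
    system).  Whichever kinetic rate is limiting is honored and the other
    scaled down; at night (r1_kin = 0) growth stops entirely.
    """
    if rho_star <= 0:
        raise ValueError("rho_star must be positive")
    if eps <= 0:
        return 0.0, 0.0
    r2 = min(r2_kin, max(0.0, eps * r1_kin - transport_bias)
             / (1.0 + rho_star * eps))
    r1 = (r2 * (1.0 + rho_star * eps) + transport_bias) / eps
    return min(max(r1, 0.0), r1_kin), r2
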