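"""Solar forcing and the partition of absorbed photons in the water column.

Surface irradiance follows a clear-sky geometric model: solar declination
(23.45 deg obliquity) plus hour angle give the cosine of the solar zenith
angle; the direct beam is attenuated by a broadband atmospheric
transmittance raised to the relative air mass 1/cos(theta_z).  Within the
pond, 440 nm light decays exponentially (Beer-Lambert) with additive
contributions from water, chlorophyll-bearing photosynthetic machinery,
non-photosynthetic biomass particles, and phytoplankton carbon stores; the
absorbed flux is split among those classes in proportion to their share of
the total attenuation coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import constants as C


def solar_declination(t_days) -> np.ndarray:
    """Declination (radians) at simulation time t (d); t = 0 is Jan 1."""
    return np.deg2rad(C.EARTH_OBLIQUITY_DEG) * np.sin(
        2.0 * np.pi * (np.asarray(t_days, float) - C.VERNAL_EQUINOX_DOY)
        / C.DAYS_PER_YEAR)


def cos_zenith(t_days, latitude_deg: float) -> np.ndarray:
    """cos(solar zenith angle); negative values mean the sun is down.

    The hour angle places local solar noon at fractional time of day 0.5.
    """
    if abs(latitude_deg) > 90:
        raise ValueError("latitude out of range")
    t = np.asarray(t_days, float)
    phi = math.radians(latitude_deg)
    dec = solar_declination(t)
    hour = 2.0 * np.pi * ((t % 1.0) - 0.5)
    return np.sin(phi) * np.sin(dec) + np.cos(phi) * np.cos(dec) * np.cos(hour)


def surface_irradiance(t_days, latitude_deg: float, i0_max: float,
                       tau_atm: float = C.TAU_ATM) -> np.ndarray:
    """Surface photon flux I0(t) = I0M cos(theta_z) tau^(1/cos(theta_z))
    (mmol-gamma m^-2 d^-1).

    ``i0_max`` plays the role of the solar constant expressed in 440 nm
    photons; the clear-sky transmittance on the slant path (relative air
    mass 1/cos theta_z) makes I0 vanish smoothly at dawn and dusk and
    exactly at night.
    """
    if i0_max < 0:
        raise ValueError("i0_max must be non-negative")
    mu = cos_zenith(t_days, latitude_deg)
    mu = np.maximum(mu, 0.0)
    with np.errstate(divide="ignore", over="ignore"):
        atm = np.where(mu > 0, tau_atm ** (1.0 / np.maximum(mu, 1e-12)), 0.0)
    return i0_max * mu * atm


def solar_entropy_bound(latitude_deg: float, i0_max: float,
                        horizon: float = 730.0, temperature: float = 293.0,
                        wavelength_nm: float = 440.0, area: float = 1.0,
                        n_per_day: int = 480) -> float:
    """Entropy (J/K) from dissipating the whole solar input as heat at the
    pond temperature -- the electromagnetic upper bound of a scenario."""
    from .thermo import photon_molar_energy
    t = (np.arange(int(horizon * n_per_day)) + 0.5) / n_per_day
    photons = float(np.mean(surface_irradiance(t, latitude_deg, i0_max))) * horizon
    return photons * photon_molar_energy(wavelength_nm) * area / temperature


@dataclass
class AbsorptionPartition:
    """Volumetric photon capture (mmol-gamma m^-3 d^-1) per absorber class."""
    water: float
    particles: float            # kp * (SB + SC + (1-Omega1) SP) and kwp * CP
    machinery: np.ndarray       # per phytoplankton ecotype, kChl * Omega1 * SP
    transmitted: float          # flux leaving the bottom, mmol-gamma m^-2 d^-1
    i_mean: float               # depth-averaged flux, mmol-gamma m^-2 d^-1
    k_total: float              # m^-1


def attenuation_coefficient(s_phyto, c_phyto, s_bact, s_cons, omega1, web):
    """Total and per-class 440 nm attenuation (m^-1).

    k = kw + kChl sum(Omega1 SP) + kwp sum(CP) + kp (sum SB + sum SC
        + sum (1-Omega1) SP)

    Returns (k_total, k_water, k_machinery_per_ecotype, k_particles).
    """
    s_phyto = np.maximum(np.atleast_1d(np.asarray(s_phyto, float)), 0.0)
    c_phyto = np.maximum(np.atleast_1d(np.asarray(c_phyto, float)), 0.0)
    omega1 = np.atleast_1d(np.asarray(omega1, float))
    k_mach = web.k_chl * omega1 * s_phyto
    k_part = (web.k_p * (float(np.sum(np.maximum(s_bact, 0.0)))
                         + float(np.sum(np.maximum(s_cons, 0.0)))
                         + float(np.sum((1.0 - omega1) * s_phyto)))
              + web.k_wp * float(np.sum(c_phyto)))
    k_total = web.k_w + float(np.sum(k_mach)) + k_part
    if k_total < 0:
        raise ValueError("negative attenuation coefficient")
    return k_total, web.k_w, k_mach, k_part


def photon_capture(i0: float, k_total: float, k_water: float, k_mach,
                   k_part: float, depth: float) -> AbsorptionPartition:
    """Beer-Lambert partition of the incident flux over one mixed layer.

    Total volumetric absorption is I0 (1 - exp(-k zeta)) / zeta, split
    among classes in proportion to their attenuation share; equivalently
    every class absorbs k_class * I_mean where I_mean is the depth-averaged
    flux, so machinery capture matches the optically-thin chlorophyll
    capture law exactly.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    kz = k_total * depth
    if kz < 1e-12:
        i_mean = i0
        transmitted = i0
    else:
        i_mean = i0 * (1.0 - math.exp(-kz)) / kz
        transmitted = i0 * math.exp(-kz)
    return AbsorptionPartition(
        water=k_water * i_mean,
        particles=k_part * i_mean,
        machinery=np.asarray(k_mach, float) * i_mean,
        transmitted=transmitted,
        i_mean=i_mean,
        k_total=k_total,
    )


def irradiance_series(latitude_deg: float, i0_max: float, horizon: float,
                      n_per_day: int = 96):
    """(t, I0) samples for inspection/export."""
    t = np.arange(int(horizon * n_per_day)) / n_per_day
    return t, surface_irradiance(t, latitude_deg, i0_max)
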