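"""Physical constants and frozen model coefficients.

Units follow the model convention: concentrations in mmol m^-3, time in
days, energies in J mmol^-1 (numerically equal to kJ mol^-1), entropy in
J K^-1.
"""

# Fundamental constants
AVOGADRO = 6.02214076e23          # mol^-1
PLANCK = 6.62607015e-34           # J s
LIGHT_SPEED = 2.99792458e8        # m s^-1
FARADAY = 96.48533212             # J mmol^-1 V^-1  (= 96485 C/mol)
R_GAS = 8.31446261815e-3          # J mmol^-1 K^-1  (= 8.314 J/mol/K)

# Extended Debye-Hueckel parameters used in the ionic-strength correction of
# transformed formation energies (Alberty-style, 298 K values).
DEBYE_HUCKEL_A = 2.91482          # kJ mol^-1 kg^1/2 mol^-1/2  (= RT*alpha*ln10 at 298 K)
DEBYE_HUCKEL_B = 1.6              # kg^1/2 mol^-1/2

# Radiative temperature of the solar photosphere, used in the Carnot-like
# photon free-energy convention g = u*(1 - T/T_SUN).
T_SUN = 5778.0                    # K

# Solar geometry
EARTH_OBLIQUITY_DEG = 23.45
DAYS_PER_YEAR = 365.0
# Day-of-year of the vernal equinox used to phase the declination cycle.
VERNAL_EQUINOX_DOY = 81.0

# Broadband clear-sky atmospheric transmittance on the direct beam,
# attenuated along the relative air mass 1/cos(zenith): the surface flux is
# I0M * cos(theta_z) * tau^(1/cos(theta_z)), with I0M the solar constant
# expressed as 440 nm photons.  Calibrated once so that the two-year
# integral of surface irradiance at 42 deg latitude, converted to heat at
# 293 K, reproduces the 27.1 MJ/K solar dissipation bound of the nominal
# scenario; frozen thereafter.
TAU_ATM = 0.6089

# Light-absorption coefficients at 440 nm (reconstructed; see docs/methods.md).
# kw: clear water; kChl: photosynthetic machinery per mmol biomass C;
# kp: non-photosynthetic biomass particles; kwp: phytoplankton internal
# carbon store.  kw and kp are calibrated against the zero-growth run
# (0.3077 MJ/K) and the balanced-run water share; kChl and kwp against the
# circadian forward run; all frozen.
K_W = 0.0109                     # m^-1
K_CHL = 0.0029                    # m^2 mmol-C^-1
K_P = 0.0038                      # m^2 mmol-C^-1
K_WP = 0.00042                    # m^2 mmol-C^-1

# Concentration floor inside logarithms and kinetic drives (mmol m^-3).
CONC_FLOOR = 1e-10

# Half-saturation (mmol m^-3) of the availability guard applied to
# consumed reactants outside the kinetic-drive mask (e.g. the phytoplankton
# carbon store fueling biosynthesis, or oxygen).  Small enough to be inert
# at realistic concentrations; it only shuts a rate off smoothly as its
# substrate empties, keeping trajectories non-negative.
KAPPA_GUARD = 0.1

# Virtual concentration (mmol m^-3) for species that participate in
# thermodynamic bookkeeping only (H3PO4, detrital P).
VIRTUAL_CONC = 1.0

# mmol m^-3 -> mol L^-1 (activity scale in reaction quotients)
MMOL_M3_TO_M = 1e-6
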