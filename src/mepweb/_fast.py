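"""Numba-compiled right-hand side.

Loop-free-of-Python port of PondModel's reference RHS; compiled lazily on
first use and verified against the reference implementation in the test
suite.  Everything is passed as flat arrays/scalars so the kernel has no
object-mode fallbacks.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except Exception:      # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]

OBLIQ = 0.40927970959267024          # 23.45 deg in radians
TWO_PI = 2.0 * math.pi


@njit(cache=False, fastmath=False)
def rhs_core(t, y, out,
             # scenario / environment
             lat_rad, i0m, tau, dilution, depth, temperature, rt,
             u_gamma, g_gamma, f_dpsi, c_in,
             # optics & gas
             k_w, k_chl, k_p, k_wp, gas_v, o2_sat, dic_sat,
             # model structure
             strategy_code, rho_star, bias, conc_floor, kappa_guard, volume,
             t_on, t_off, amp, freq, phase,
             i_sp, i_cp, i_sb, i_sc, i_prey,
             S0, kind_code, cat_idx, eps, nu, kappa, ne_const, ne_rho,
             G0, GV, Lam, Guard, extent_scale,
             prey_idx, prey_cp_idx, phyto_of_rxn, cons_of_rxn,
             omega_static, omega_c,
             photo_rows, growth_p_rows,
             gfix0, goxcp0):
    n_conc = c_in.shape[0]
    n_rxn = eps.shape[0]
    nP = i_sp.shape[0]
    nC = omega_c.shape[0]
    n_prey = i_prey.shape[0]

    # ---- solar forcing ------------------------------------------------
    dec = OBLIQ * math.sin(TWO_PI * (t - 81.0) / 365.0)
    td = t - math.floor(t)
    mu = (math.sin(lat_rad) * math.sin(dec)
          + math.cos(lat_rad) * math.cos(dec) * math.cos(TWO_PI * (td - 0.5)))
    i0 = i0m * mu * tau ** (1.0 / mu) if mu > 0.0 else 0.0

    # ---- clipped concentrations and activities ------------------------
    cc = np.empty(n_conc)
    for k in range(n_conc):
        cc[k] = y[k] if y[k] > 0.0 else 0.0
    ln6 = np.empty(6)
    for k in range(6):
        c = cc[k] if cc[k] > conc_floor else conc_floor
        ln6[k] = math.log(c * 1e-6)

    # ---- schedules ----------------------------------------------------
    om1 = np.empty(nP)
    for i in range(nP):
        if strategy_code <= 1:          # balanced / passive
            om1[i] = amp[i]
        elif strategy_code == 3:        # sinusoid
            om1[i] = amp[i] * 0.5 * (1.0 + math.sin(
                TWO_PI * freq[i] * (t - phase[i])))
        else:                           # circadian square wave
            if t_on[i] <= t_off[i]:
                on = (td >= t_on[i]) and (td <= t_off[i])
            else:
                on = (td >= t_on[i]) or (td <= t_off[i])
            om1[i] = amp[i] if on else 0.0

    # ---- light attenuation and capture --------------------------------
    k_mach = np.empty(nP)
    k_bio = 0.0
    for i in range(nP):
        k_mach[i] = k_chl * om1[i] * cc[i_sp[i]]
        k_bio += k_mach[i] + k_p * (1.0 - om1[i]) * cc[i_sp[i]] + k_wp * cc[i_cp[i]]
    for i in range(i_sb.shape[0]):
        k_bio += k_p * cc[i_sb[i]]
    for i in range(i_sc.shape[0]):
        k_bio += k_p * cc[i_sc[i]]
    k_tot = k_w + k_bio
    kz = k_tot * depth
    if kz < 1e-12:
        i_mean = i0
    else:
        i_mean = i0 * (1.0 - math.exp(-kz)) / kz
    cap_w = k_w * i_mean
    cap_p = (k_bio - k_mach.sum()) * i_mean

    # ---- thermodynamics ----------------------------------------------
    gfix = gfix0 + rt * (ln6[1] - ln6[0])
    if gfix < 1e-6:
        gfix = 1e-6
    n1 = gfix / g_gamma
    goxcp = goxcp0 + rt * (ln6[0] - ln6[1])

    # ---- prey weighting -----------------------------------------------
    om_cons = np.zeros((nC, n_prey))
    for i in range(nC):
        tot = 0.0
        for j in range(n_prey):
            om_cons[i, j] = omega_c[i, j] * cc[i_prey[j]]
            tot += om_cons[i, j]
        if tot > 0.0:
            for j in range(n_prey):
                om_cons[i, j] /= tot
        else:
            for j in range(n_prey):
                om_cons[i, j] = 0.0

    # ---- per-reaction rates -------------------------------------------
    rates = np.empty(n_rxn)
    drg = np.empty(n_rxn)
    for j in range(n_rxn):
        # free energy
        g = G0[j]
        for k in range(6):
            g += GV[j, k] * ln6[k]
        ne = ne_const[j]
        rho = 0.0
        if prey_cp_idx[j] >= 0:
            spc = cc[prey_idx[j]]
            if spc > conc_floor:
                rho = cc[prey_cp_idx[j]] / spc
            g += rho * goxcp
            ne += rho * ne_rho[j]
        if kind_code[j] == 0:           # photon-driven fixation
            g = -(1.0 - eps[j]) * gfix
            ne = n1
        drg[j] = g
        # thermodynamic drive (one-way)
        if g >= 0.0:
            ft = 0.0
        else:
            x = (g / (ne if ne > 1e-12 else 1e-12) + f_dpsi) / rt
            if x > 60.0:
                ft = 0.0
            elif x < -60.0:
                ft = 1.0
            else:
                ft = 1.0 / (1.0 + math.exp(x))
        # kinetic drive and availability guard
        fk = 1.0
        for k in range(n_conc):
            if Lam[j, k]:
                denom = cc[k] + kappa[j]
                fk *= cc[k] / denom if denom > 0.0 else 0.0
            elif Guard[j, k]:
                fk *= cc[k] / (cc[k] + kappa_guard)
        # allocation
        if kind_code[j] == 0:
            om = om1[phyto_of_rxn[j]]
        elif kind_code[j] == 1 and phyto_of_rxn[j] >= 0:
            om = 1.0 - om1[phyto_of_rxn[j]]
        elif kind_code[j] == 3:
            ci = cons_of_rxn[j]
            pj = 0
            for q in range(n_prey):
                if i_prey[q] == prey_idx[j]:
                    pj = q
                    break
            om = om_cons[ci, pj]
        else:
            om = omega_static[j]
        if kind_code[j] == 0:
            cap = k_mach[phyto_of_rxn[j]] * i_mean
            rates[j] = cap / n1 * fk * ft
        else:
            rates[j] = (nu[j] * eps[j] * eps[j] * om * cc[cat_idx[j]]
                        * fk * ft) * extent_scale[j]

    # ---- balanced-growth coupling -------------------------------------
    if strategy_code == 0:
        for i in range(nP):
            j1 = photo_rows[i]
            j2 = growth_p_rows[i]
            e = eps[j2]
            if e <= 0.0:
                rates[j1] = 0.0
                rates[j2] = 0.0
            else:
                r2 = (e * rates[j1] - bias) / (1.0 + rho_star * e)
                if r2 < 0.0:
                    r2 = 0.0
                if r2 > rates[j2]:
                    r2 = rates[j2]
                r1 = (r2 * (1.0 + rho_star * e) + bias) / e
                if r1 > rates[j1]:
                    r1 = rates[j1]
                if r1 < 0.0:
                    r1 = 0.0
                rates[j1] = r1
                rates[j2] = r2

    # ---- mass balances ------------------------------------------------
    for k in range(n_conc):
        acc = dilution * (c_in[k] - y[k])
        for j in range(n_rxn):
            acc += S0[k, j] * rates[j]
        out[k] = acc
    for j in range(n_rxn):
        if prey_cp_idx[j] >= 0 and rates[j] > 0.0:
            spc = cc[prey_idx[j]]
            rho = cc[prey_cp_idx[j]] / spc if spc > conc_floor else 0.0
            flux = rates[j] * rho
            out[prey_cp_idx[j]] -= flux
            out[1] -= flux
            out[0] += flux
    vk = gas_v / depth
    out[1] += vk * (o2_sat - y[1])
    out[0] += vk * (dic_sat - y[0])

    # ---- entropy accumulators -----------------------------------------
    ds_r = 0.0
    used = 0.0
    mach = 0.0
    for j in range(n_rxn):
        ds_r -= rates[j] * drg[j]
        if kind_code[j] == 0:
            used += rates[j] * n1
    for i in range(nP):
        mach += k_mach[i] * i_mean
    out[n_conc] = ds_r * volume / temperature
    out[n_conc + 1] = u_gamma * cap_w * volume / temperature
    out[n_conc + 2] = (u_gamma * (cap_p + mach) - g_gamma * used) * volume / temperature
    out[n_conc + 3] = u_gamma * (cap_w + cap_p + mach) * volume
    out[n_conc + 4] = g_gamma * used * volume
    return out
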