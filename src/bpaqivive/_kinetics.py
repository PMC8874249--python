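"""Numba-compiled kernel of the whole-body delay-differential kinetic model.

The model is flow-limited (venous equilibration): the concentration leaving a
tissue is tissue concentration divided by its tissue:blood partition
coefficient.  Two transport lags make the system a DDE: a fixed 4 h biliary
transit between hepatic uptake and reappearance in the small intestine, and a
sampled lymphatic lag between the lymph pool and venous blood.  Both are
resolved by the method of steps: the integrator stores the full state history
on its own uniform grid and delayed terms are linear interpolations of that
history.  Every lag is much larger than the integration step, so delayed
lookups never touch the current step and the scheme stays explicit in the
delays.

Every state obeys a production/decay form  y' = inflow - D(t, y) * y,  where
D collects the state's own linear outflow constants (and the effective
first-order rate of the Michaelis-Menten sinks).  Hepatic conjugation of BPA
is extremely fast over parts of parameter space (effective rate constants of
1e3-1e5 per hour), which makes the system stiff.  The integrator is therefore
a conservative exponential midpoint scheme:

1. a predictor exponential half-step gives the midpoint state, at which the
   decay rates ``D_i`` and the routing fractions of each state's outflow are
   frozen for the step;
2. each donor's outflow mass over the step has the closed form
   ``O_i = y_i (1 - E_i) + Pbar_i (h - (1 - E_i)/D_i)`` with
   ``E_i = exp(-D_i h)`` and ``Pbar_i`` its (constant) inflow rate;
3. a few fixed-point sweeps make every receiver's inflow equal the routed
   donor outflows (plus exact external inputs: the zero-order ingestion and
   the two delayed arrival fluxes), after which states are updated with the
   exact constant-coefficient solution.

The update is unconditionally stable in D, positivity preserving, second
order in h, and conserves mass by construction (delayed arrivals debit their
transit pool with exactly the mass credited downstream).

State vector (47 entries, amounts in ug): shared states 0-7 are the stomach
lumen (hepatic-route, lymphatic-route, unabsorbed), gut lumen (same three
routes), the lymph pool and the lymph-to-blood transit pool; then one
13-state block per analyte (BPA, BPAG, BPAS): recirculated gut lumen, gut
tissue, stomach tissue, liver, kidney, fat, slowly perfused, rapidly
perfused, blood unbound, blood bound, bile transit, cumulative urine,
cumulative faeces.
"""

import numpy as np
from numba import njit

NSTATE = 47
BASE = 8
BLK = 13
# per-analyte block offsets
GUT_RECIRC, GUT, STO, LIV, KID, FAT, SPD, RPD, BLD_U, BLD_B, BILE, URINE, FAECES = range(13)
# shared states
ST_HEP, ST_LYM, ST_UN, GI_HEP, GI_LYM, GI_UN, LYMPH, LYMPH_TR = range(8)

BILE_LAG = 4.0
_SWEEPS = 4

# up[] layout
_BELLYPERM, _GIPERM, _BELLYPERMLYM, _GIPERMLYM, _KEMAX, _KEMIN, _DRINKTIME, \
    _K1LYMPH, _LYMPHLAG, _FRACHEP, _FRACLYM = range(11)


@njit(cache=True)
def _lagged(Y, tq, h, nmax, idx):
    """Linear interpolation of state ``idx`` at time ``tq`` from history Y."""
    if tq <= 0.0:
        return 0.0
    x = tq / h
    i0 = int(x)
    if i0 >= nmax:
        return Y[nmax, idx]
    fr = x - i0
    return Y[i0, idx] * (1.0 - fr) + Y[i0 + 1, idx] * fr


@njit(cache=True)
def _decay_rates(t, y, q, vol, part, mm, el, up, dose, D):
    """Diagonal decay coefficient of every state at (t, y)."""
    te = t - dose[1]
    if te < 0.0:
        te = 0.0
    ke = up[_KEMIN] + (up[_KEMAX] - up[_KEMIN]) * np.exp(-te / up[_DRINKTIME])

    D[ST_HEP] = ke + up[_BELLYPERM]
    D[ST_LYM] = ke + up[_BELLYPERMLYM]
    D[ST_UN] = ke
    D[GI_HEP] = up[_GIPERM]
    D[GI_LYM] = up[_GIPERMLYM]
    D[GI_UN] = el[0, 1]
    D[LYMPH] = up[_K1LYMPH]
    D[LYMPH_TR] = 0.0

    b0 = BASE
    c_li = y[b0 + LIV] / vol[0] / part[0, 0] * 1e-3   # free liver conc, mg/L
    c_gu = y[b0 + GUT] / vol[2] / part[0, 3] * 1e-3
    k_liv_g = mm[0] / (mm[1] + c_li) / (vol[0] * part[0, 0] * 1e3)
    k_liv_s = mm[2] / (mm[3] + c_li) / (vol[0] * part[0, 0] * 1e3)
    k_gut_g = mm[4] / (mm[5] + c_gu) / (vol[2] * part[0, 3] * 1e3)
    k_gut_s = mm[6] / (mm[7] + c_gu) / (vol[2] * part[0, 3] * 1e3)

    q_liv_out = q[0] + q[1] + q[2]
    for a in range(3):
        b = BASE + BLK * a
        D[b + GUT_RECIRC] = up[_GIPERM] + el[a, 1]
        D[b + GUT] = q[2] / (vol[2] * part[a, 3])
        D[b + STO] = q[1] / (vol[3] * part[a, 4])
        D[b + LIV] = q_liv_out / (vol[0] * part[a, 0]) + el[a, 0]
        D[b + KID] = q[3] / (vol[1] * part[a, 1]) + el[a, 2]
        D[b + FAT] = q[4] / (vol[4] * part[a, 2])
        D[b + SPD] = q[5] / (vol[5] * part[a, 6])
        D[b + RPD] = q[6] / (vol[6] * part[a, 5])
        D[b + BLD_U] = q[7] / vol[7]
        D[b + BLD_B] = el[a, 3]
        D[b + BILE] = 0.0
        D[b + URINE] = 0.0
        D[b + FAECES] = 0.0
        if a == 0:
            D[b + GUT] += k_gut_g + k_gut_s
            D[b + LIV] += k_liv_g + k_liv_s
    return ke, k_liv_g, k_liv_s, k_gut_g, k_gut_s


@njit(cache=True)
def _push(O, I, ke, kmet, q, vol, part, el, fb, up, mwr, D):
    """Route every donor's outflow mass O into its receivers' inflow I."""
    k_liv_g, k_liv_s, k_gut_g, k_gut_s = kmet
    for i in range(NSTATE):
        I[i] = 0.0
    # stomach/gut lumen and lymph
    I[GI_HEP] += O[ST_HEP] * ke / D[ST_HEP]
    I[BASE + LIV] += O[ST_HEP] * up[_BELLYPERM] / D[ST_HEP]
    I[GI_LYM] += O[ST_LYM] * ke / D[ST_LYM]
    I[LYMPH] += O[ST_LYM] * up[_BELLYPERMLYM] / D[ST_LYM]
    I[GI_UN] += O[ST_UN]
    I[BASE + GUT] += O[GI_HEP]
    I[LYMPH] += O[GI_LYM]
    I[BASE + FAECES] += O[GI_UN]
    I[LYMPH_TR] += O[LYMPH]

    q_liv_out = q[0] + q[1] + q[2]
    for a in range(3):
        b = BASE + BLK * a
        d = D[b + GUT_RECIRC]
        I[b + GUT] += O[b + GUT_RECIRC] * up[_GIPERM] / d
        I[b + FAECES] += O[b + GUT_RECIRC] * el[a, 1] / d

        # gut tissue -> liver (perfusion) and, for BPA, -> conjugates
        d = D[b + GUT]
        if a == 0:
            w_flow = (d - k_gut_g - k_gut_s) / d
            I[b + LIV] += O[b + GUT] * w_flow
            I[BASE + BLK + GUT] += O[b + GUT] * (k_gut_g / d) * mwr[0]
            I[BASE + 2 * BLK + GUT] += O[b + GUT] * (k_gut_s / d) * mwr[1]
        else:
            I[b + LIV] += O[b + GUT]

        I[b + LIV] += O[b + STO]   # stomach tissue drains into the liver

        # liver -> venous blood, bile, and (BPA) conjugates
        d = D[b + LIV]
        w_bile = el[a, 0] / d
        if a == 0:
            w_flow = (d - el[a, 0] - k_liv_g - k_liv_s) / d
            I[BASE + BLK + LIV] += O[b + LIV] * (k_liv_g / d) * mwr[0]
            I[BASE + 2 * BLK + LIV] += O[b + LIV] * (k_liv_s / d) * mwr[1]
        else:
            w_flow = (d - el[a, 0]) / d
        bin_a = O[b + LIV] * w_flow
        I[b + BILE] += O[b + LIV] * w_bile

        # kidney: perfusion return + urinary loss
        d = D[b + KID]
        I[b + URINE] += O[b + KID] * el[a, 2] / d
        bin_a += O[b + KID] * (d - el[a, 2]) / d

        bin_a += O[b + FAT] + O[b + SPD] + O[b + RPD]

        # venous inflow splits into bound/unbound blood pools
        I[b + BLD_B] += fb[a] * bin_a
        I[b + BLD_U] += (1.0 - fb[a]) * bin_a
        I[b + BLD_U] += O[b + BLD_B]

        # arterial distribution of the unbound pool
        ob = O[b + BLD_U] / q[7]
        I[b + LIV] += ob * q[0]
        I[b + STO] += ob * q[1]
        I[b + GUT] += ob * q[2]
        I[b + KID] += ob * q[3]
        I[b + FAT] += ob * q[4]
        I[b + SPD] += ob * q[5]
        I[b + RPD] += ob * q[6]


@njit(cache=True)
def integrate(n_steps, h, q, vol, part, mm, el, fb, up, mwr, dose):
    """Conservative exponential midpoint scheme; returns (n_steps+1, 47) history."""
    Y = np.zeros((n_steps + 1, NSTATE))
    lag_l = up[_LYMPHLAG]
    D = np.zeros(NSTATE)
    E = np.zeros(NSTATE)
    bcoef = np.zeros(NSTATE)
    O = np.zeros(NSTATE)
    I = np.zeros(NSTATE)
    ext = np.zeros(NSTATE)
    Pbar = np.zeros(NSTATE)
    ymid = np.zeros(NSTATE)
    kmet = np.zeros(4)

    for n in range(n_steps):
        t = n * h
        y = Y[n]

        # ---- predictor: exponential Euler half-step to the midpoint -------
        ke, klg, kls, kgg, kgs = _decay_rates(t, y, q, vol, part, mm, el, up, dose, D)
        kmet[0], kmet[1], kmet[2], kmet[3] = klg, kls, kgg, kgs
        for i in range(NSTATE):
            O[i] = y[i] * D[i]          # instantaneous outflow rate
        _push(O, I, ke, kmet, q, vol, part, el, fb, up, mwr, D)
        # external inputs at t (rates)
        if dose[0] > 0.0 and dose[1] <= t < dose[1] + dose[2]:
            I[ST_HEP] += dose[0] * up[_FRACHEP]
            I[ST_LYM] += dose[0] * up[_FRACLYM]
            I[ST_UN] += dose[0] * (1.0 - up[_FRACHEP] - up[_FRACLYM])
        arr_lym = up[_K1LYMPH] * _lagged(Y, t - lag_l, h, n, LYMPH)
        I[LYMPH_TR] -= arr_lym
        I[BASE + BLD_U] += (1.0 - fb[0]) * arr_lym
        I[BASE + BLD_B] += fb[0] * arr_lym
        for a in range(3):
            b = BASE + BLK * a
            arr = el[a, 0] * _lagged(Y, t - BILE_LAG, h, n, b + LIV)
            I[b + BILE] -= arr
            I[b + GUT_RECIRC] += arr
        hh = 0.5 * h
        for i in range(NSTATE):
            d = D[i]
            if d > 1e-12:
                e = np.exp(-d * hh)
                ymid[i] = y[i] * e + (I[i] / d) * (1.0 - e)
            else:
                ymid[i] = y[i] + hh * I[i]
            if ymid[i] < 0.0:
                ymid[i] = 0.0

        # ---- corrector: frozen midpoint coefficients, conservative fluxes -
        tm = t + 0.5 * h
        ke, klg, kls, kgg, kgs = _decay_rates(tm, ymid, q, vol, part, mm, el, up, dose, D)
        kmet[0], kmet[1], kmet[2], kmet[3] = klg, kls, kgg, kgs
        for i in range(NSTATE):
            d = D[i]
            if d > 1e-12:
                e = np.exp(-d * h)
                E[i] = e
                bcoef[i] = h - (1.0 - e) / d
            else:
                E[i] = 1.0
                bcoef[i] = 0.0

        # exact external masses over [t, t+h]
        for i in range(NSTATE):
            ext[i] = 0.0
        if dose[0] > 0.0:
            lo = t if t > dose[1] else dose[1]
            hi = t + h if t + h < dose[1] + dose[2] else dose[1] + dose[2]
            if hi > lo:
                m = dose[0] * (hi - lo)
                ext[ST_HEP] += m * up[_FRACHEP]
                ext[ST_LYM] += m * up[_FRACLYM]
                ext[ST_UN] += m * (1.0 - up[_FRACHEP] - up[_FRACLYM])
        arr_lym = up[_K1LYMPH] * _lagged(Y, tm - lag_l, h, n, LYMPH) * h
        ext[LYMPH_TR] -= arr_lym
        ext[BASE + BLD_U] += (1.0 - fb[0]) * arr_lym
        ext[BASE + BLD_B] += fb[0] * arr_lym
        for a in range(3):
            b = BASE + BLK * a
            arr = el[a, 0] * _lagged(Y, tm - BILE_LAG, h, n, b + LIV) * h
            ext[b + BILE] -= arr
            ext[b + GUT_RECIRC] += arr

        # fixed-point sweeps on the per-step mass balance
        for i in range(NSTATE):
            Pbar[i] = ymid[i] * D[i]    # initial guess: midpoint throughput
        for _ in range(_SWEEPS):
            for i in range(NSTATE):
                O[i] = y[i] * (1.0 - E[i]) + Pbar[i] * bcoef[i]
            _push(O, I, ke, kmet, q, vol, part, el, fb, up, mwr, D)
            for i in range(NSTATE):
                Pbar[i] = (I[i] + ext[i]) / h

        for i in range(NSTATE):
            d = D[i]
            if d > 1e-12:
                Y[n + 1, i] = y[i] * E[i] + (Pbar[i] / d) * (1.0 - E[i])
            else:
                Y[n + 1, i] = y[i] + Pbar[i] * h
    return Y
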