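"""Independently written re-encoding of the 2006 human ventricular myocyte
model, used as the cross-check oracle for the package implementation.

This transcription was written separately from ``iksvar.tt06``: plain-numpy
right-hand side, different state ordering and naming, integrated with
scipy's adaptive stiff LSODA solver instead of fixed-step Rush-Larsen.  It
is a synthetic stand-in for an external reference encoding of the model
(no deposited encoding is bundled); agreement between the two routes
checks both the equation transcription and the solver numerics.
"""

from __future__ import annotations

from math import exp, log, sqrt

import numpy as np
from scipy.integrate import solve_ivp

# state ordering of THIS encoding (differs from the package on purpose):
# [Vm, Nai, Ki, Cai, CaSS, CaSR, Rprime,
#  m, h, j, xr1, xr2, xs, r, s, d, f, f2, fCass]

RGAS, TEMP, FARADAY = 8314.472, 310.0, 96485.3415
VRT = RGAS * TEMP / FARADAY
CM, VOL_C, VOL_SR, VOL_SS = 0.185, 0.016404, 0.001094, 0.00005468
KOUT, NAOUT, CAOUT, P_KNA = 5.4, 140.0, 2.0, 0.03


def epi_conductances(gks_scale: float = 1.0, xs_shift: float = 0.0) -> dict:
    return dict(
        g_na=14.838, g_k1=5.405, g_kr=0.153, g_ks=0.392 * gks_scale,
        g_cal=3.98e-5, g_bna=0.00029, g_bca=0.000592, g_to=0.294,
        g_pca=0.1238, g_pk=0.0146, p_nak=2.724, k_naca=1000.0,
        xs_shift=xs_shift,
    )


def y0() -> np.ndarray:
    return np.array([
        -85.23, 8.604, 136.89, 0.000126, 0.00036, 3.64, 0.9073,
        0.00172, 0.7444, 0.7045, 0.00621, 0.4712, 0.0095,
        2.42e-8, 0.999998, 3.373e-5, 0.7888, 0.9755, 0.9953,
    ])


def rhs(t, y, g, i_stim_of_t):
    (vm, nai, ki, cai, cass, casr, rpr,
     m, h, j, xr1, xr2, xs, rr, s, d, f, f2, fcass) = y
    istim = i_stim_of_t(t)

    e_k = VRT * log(KOUT / ki)
    e_na = VRT * log(NAOUT / nai)
    e_ca = 0.5 * VRT * log(CAOUT / cai)
    e_ks = VRT * log((KOUT + P_KNA * NAOUT) / (ki + P_KNA * nai))

    ina = g["g_na"] * m**3 * h * j * (vm - e_na)
    ibna = g["g_bna"] * (vm - e_na)
    vshift = vm - 15.0
    expo = exp(2.0 * vshift / VRT)
    ical = (g["g_cal"] * d * f * f2 * fcass * 4.0 * vshift * FARADAY / VRT
            * (0.25 * cass * expo - CAOUT) / (expo - 1.0))
    ibca = g["g_bca"] * (vm - e_ca)
    ito = g["g_to"] * rr * s * (vm - e_k)
    ikr = g["g_kr"] * sqrt(KOUT / 5.4) * xr1 * xr2 * (vm - e_k)
    iks = g["g_ks"] * xs**2 * (vm - e_ks)
    ak1 = 0.1 / (1.0 + exp(0.06 * (vm - e_k - 200.0)))
    bk1 = ((3.0 * exp(0.0002 * (vm - e_k + 100.0)) + exp(0.1 * (vm - e_k - 10.0)))
           / (1.0 + exp(-0.5 * (vm - e_k))))
    ik1 = g["g_k1"] * sqrt(KOUT / 5.4) * ak1 / (ak1 + bk1) * (vm - e_k)
    inaca = (g["k_naca"]
             * (exp(0.35 * vm / VRT) * nai**3 * CAOUT
                - exp(-0.65 * vm / VRT) * NAOUT**3 * cai * 2.5)
             / ((87.5**3 + NAOUT**3) * (1.38 + CAOUT)
                * (1.0 + 0.1 * exp(-0.65 * vm / VRT))))
    inak = (g["p_nak"] * KOUT / (KOUT + 1.0) * nai / (nai + 40.0)
            / (1.0 + 0.1245 * exp(-0.1 * vm / VRT) + 0.0353 * exp(-vm / VRT)))
    ipca = g["g_pca"] * cai / (0.0005 + cai)
    ipk = g["g_pk"] * (vm - e_k) / (1.0 + exp((25.0 - vm) / 5.98))

    itot = ina + ik1 + ito + ikr + iks + ical + inaca + inak + ipca + ipk + ibna + ibca

    # gating
    minf = 1.0 / (1.0 + exp((-56.86 - vm) / 9.03)) ** 2
    taum = (1.0 / (1.0 + exp((-60.0 - vm) / 5.0))) * (
        0.1 / (1.0 + exp((vm + 35.0) / 5.0)) + 0.1 / (1.0 + exp((vm - 50.0) / 200.0)))
    hinf = 1.0 / (1.0 + exp((vm + 71.55) / 7.43)) ** 2
    if vm >= -40.0:
        ah, bh = 0.0, 0.77 / (0.13 * (1.0 + exp(-(vm + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.6 * exp(0.057 * vm) / (1.0 + exp(-0.1 * (vm + 32.0)))
    else:
        ah = 0.057 * exp(-(vm + 80.0) / 6.8)
        bh = 2.7 * exp(0.079 * vm) + 3.1e5 * exp(0.3485 * vm)
        aj = ((-2.5428e4 * exp(0.2444 * vm) - 6.948e-6 * exp(-0.04391 * vm))
              * (vm + 37.78) / (1.0 + exp(0.311 * (vm + 79.23))))
        bj = 0.02424 * exp(-0.01052 * vm) / (1.0 + exp(-0.1378 * (vm + 40.14)))
    tauh = 1.0 / (ah + bh)
    jinf = hinf
    tauj = 1.0 / (aj + bj)

    xr1inf = 1.0 / (1.0 + exp((-26.0 - vm) / 7.0))
    tauxr1 = (450.0 / (1.0 + exp((-45.0 - vm) / 10.0))) * (
        6.0 / (1.0 + exp((vm + 30.0) / 11.5)))
    xr2inf = 1.0 / (1.0 + exp((vm + 88.0) / 24.0))
    tauxr2 = (3.0 / (1.0 + exp((-60.0 - vm) / 20.0))) * (
        1.12 / (1.0 + exp((vm - 60.0) / 20.0)))

    xsinf = 1.0 / (1.0 + exp((-5.0 - (vm - g["xs_shift"])) / 14.0))
    tauxs = (1400.0 / sqrt(1.0 + exp((5.0 - vm) / 6.0))) * (
        1.0 / (1.0 + exp((vm - 35.0) / 15.0))) + 80.0

    rinf = 1.0 / (1.0 + exp((20.0 - vm) / 6.0))
    taur = 9.5 * exp(-((vm + 40.0) ** 2) / 1800.0) + 0.8
    sinf = 1.0 / (1.0 + exp((vm + 20.0) / 5.0))  # epicardial
    taus = (85.0 * exp(-((vm + 45.0) ** 2) / 320.0)
            + 5.0 / (1.0 + exp((vm - 20.0) / 5.0)) + 3.0)

    dinf = 1.0 / (1.0 + exp((-8.0 - vm) / 7.5))
    taud = ((1.4 / (1.0 + exp((-35.0 - vm) / 13.0)) + 0.25)
            * (1.4 / (1.0 + exp((vm + 5.0) / 5.0)))
            + 1.0 / (1.0 + exp((50.0 - vm) / 20.0)))
    finf = 1.0 / (1.0 + exp((vm + 20.0) / 7.0))
    tauf = (1102.5 * exp(-((vm + 27.0) ** 2) / 225.0)
            + 200.0 / (1.0 + exp((13.0 - vm) / 10.0))
            + 180.0 / (1.0 + exp((vm + 30.0) / 10.0)) + 20.0)
    f2inf = 0.67 / (1.0 + exp((vm + 35.0) / 7.0)) + 0.33
    tauf2 = (562.0 * exp(-((vm + 27.0) ** 2) / 240.0)
             + 31.0 / (1.0 + exp((25.0 - vm) / 10.0))
             + 80.0 / (1.0 + exp((vm + 30.0) / 10.0)))
    fcassinf = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
    taufcass = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0

    # calcium handling
    kcasr = 2.5 - 1.5 / (1.0 + (1.5 / casr) ** 2)
    k1 = 0.15 / kcasr
    k2 = 0.045 * kcasr
    o_gate = k1 * cass**2 * rpr / (0.06 + k1 * cass**2)
    irel = 0.102 * o_gate * (casr - cass)
    ileak = 0.00036 * (casr - cai)
    iup = 0.006375 / (1.0 + (0.00025 / cai) ** 2)
    ixfer = 0.0038 * (cass - cai)
    drpr = -k2 * cass * rpr + 0.005 * (1.0 - rpr)

    capv = CM / (VOL_C * FARADAY)
    bc = 1.0 / (1.0 + 0.2 * 0.001 / (cai + 0.001) ** 2)
    bsr = 1.0 / (1.0 + 10.0 * 0.3 / (casr + 0.3) ** 2)
    bss = 1.0 / (1.0 + 0.4 * 0.00025 / (cass + 0.00025) ** 2)
    dcai = bc * ((ileak - iup) * VOL_SR / VOL_C + ixfer
                 - (ibca + ipca - 2.0 * inaca) * capv / 2.0)
    dcasr = bsr * (iup - irel - ileak)
    dcass = bss * (-ical * capv * VOL_C / (2.0 * VOL_SS)
                   + irel * VOL_SR / VOL_SS - ixfer * VOL_C / VOL_SS)
    dnai = -(ina + ibna + 3.0 * inak + 3.0 * inaca) * capv
    dki = -(ik1 + ito + ikr + iks + ipk + istim - 2.0 * inak) * capv

    return [
        -(itot + istim),
        dnai, dki, dcai, dcass, dcasr, drpr,
        (minf - m) / taum, (hinf - h) / tauh, (jinf - j) / tauj,
        (xr1inf - xr1) / tauxr1, (xr2inf - xr2) / tauxr2, (xsinf - xs) / tauxs,
        (rinf - rr) / taur, (sinf - s) / taus,
        (dinf - d) / taud, (finf - f) / tauf, (f2inf - f2) / tauf2,
        (fcassinf - fcass) / taufcass,
    ]


def simulate_beats(
    n_beats: int,
    cycle_ms: float = 500.0,
    gks_scale: float = 1.0,
    xs_shift: float = 0.0,
    stim_amp: float = 52.0,
    stim_dur: float = 1.0,
    sample_ms: float = 0.1,
):
    """LSODA integration; returns (t, Vm) of the final beat."""
    g = epi_conductances(gks_scale, xs_shift)
    y = y0()
    t_out = v_out = None
    for beat in range(n_beats):
        segments = [(0.0, stim_dur, -stim_amp), (stim_dur, cycle_ms, 0.0)]
        ts, vs = [], []
        for t0, t1, amp in segments:
            tev = np.arange(t0, t1, sample_ms)
            sol = solve_ivp(
                rhs, (t0, t1), y, args=(g, lambda t, a=amp: a),
                method="LSODA", rtol=1e-6, atol=1e-8, max_step=1.0,
                t_eval=tev, dense_output=False,
            )
            if not sol.success:
                raise RuntimeError(f"LSODA failure on beat {beat + 1}: {sol.message}")
            ts.append(sol.t)
            vs.append(sol.y[0])
            y = sol.y[:, -1].copy()
            # re-solve endpoint exactly at t1 for clean hand-off
            tail = solve_ivp(rhs, (sol.t[-1], t1), y, args=(g, lambda t, a=amp: a),
                             method="LSODA", rtol=1e-6, atol=1e-8, max_step=1.0)
            y = tail.y[:, -1].copy()
        t_out = np.concatenate(ts)
        v_out = np.concatenate(vs)
    return t_out, v_out
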