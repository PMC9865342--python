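"""ten Tusscher–Panfilov (2006) human ventricular myocyte model.

Numba-compiled core used by both the single-cell and the cable stage.  The
state vector is ``[V, m, h, j, d, f, f2, fCass, r, s, xs, xr1, xr2, Rbar,
Cai, CaSR, Cass, Nai, Ki]`` with V in mV, concentrations in mM, time in ms
and membrane currents in pA/pF.  Gates are advanced with the Rush–Larsen
exponential update, concentrations with forward Euler; the Ca-release
recovery variable Rbar, linear in itself, also uses the exact exponential
update.  Cell types (ENDO, M, EPI) differ in the transient-outward
conductance/kinetics and the IKs conductance, as in the source model.

The IKs perturbation contract: the activation-gate steady state ``xs_inf``
can be shifted along the voltage axis by ``xs_shift`` (positive =
depolarizing shift; time constants untouched) and the maximum conductance
``G_Ks`` scaled by a nonnegative factor.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "CELL_ENDO",
    "CELL_EPI",
    "CELL_M",
    "N_STATES",
    "INITIAL_STATE",
    "build_params",
    "cell_step",
    "run_beat",
    "run_cable_beat",
]

CELL_ENDO, CELL_EPI, CELL_M = 0, 1, 2
N_STATES = 19

# physical constants
_R = 8314.472  # mJ/(mol K)
_T = 310.0  # K
_F = 96485.3415  # C/mol
_RTF = _R * _T / _F
_CM = 0.185  # uF
_VC = 0.016404  # nL
_VSR = 0.001094
_VSS = 0.00005468
_CAPV = _CM / (_VC * _F)
_KO = 5.4
_NAO = 140.0
_CAO = 2.0
_PKNA = 0.03

# published initial state (V, m, h, j, d, f, f2, fCass, r, s, xs, xr1, xr2,
# Rbar, Cai, CaSR, Cass, Nai, Ki); all cell types are paced from this state.
INITIAL_STATE = np.array(
    [
        -85.23, 0.00172, 0.7444, 0.7045, 3.373e-5, 0.7888, 0.9755, 0.9953,
        2.42e-8, 0.999998, 0.0095, 0.00621, 0.4712, 0.9073, 0.000126, 3.64,
        0.00036, 8.604, 136.89,
    ]
)

# parameter-vector layout
_P_GNA, _P_GK1, _P_GKR, _P_GKS, _P_GCAL, _P_GBNA, _P_GBCA, _P_GTO, _P_GPCA, \
    _P_GPK, _P_PNAK, _P_KNACA, _P_XSSHIFT, _P_CELLTYPE = range(14)


def build_params(
    cell_type: int,
    gks_scale: float = 1.0,
    xs_shift_mV: float = 0.0,
) -> np.ndarray:
    """Parameter vector for one cell type with an optional IKs perturbation."""
    if cell_type not in (CELL_ENDO, CELL_EPI, CELL_M):
        raise ValueError(f"unknown cell type {cell_type}")
    if gks_scale < 0:
        raise ValueError("gks_scale must be nonnegative")
    g_ks = 0.098 if cell_type == CELL_M else 0.392
    g_to = 0.073 if cell_type == CELL_ENDO else 0.294
    return np.array(
        [
            14.838,  # G_Na
            5.405,  # G_K1
            0.153,  # G_Kr
            g_ks * gks_scale,
            0.0000398,  # G_CaL
            0.00029,  # G_bNa
            0.000592,  # G_bCa
            g_to,
            0.1238,  # G_pCa
            0.0146,  # G_pK
            2.724,  # P_NaK
            1000.0,  # k_NaCa
            xs_shift_mV,
            float(cell_type),
        ]
    )


@njit(cache=True)
def cell_step(s, p, dt, i_stim):
    """Advance gates/concentrations of one cell by dt; return (I_ion, I_Ks).

    Membrane potential s[0] is *not* updated here: the caller adds
    ``dt * (-(I_ion + i_stim) + diffusion)`` so the same reaction step
    serves single cells and cable nodes.
    """
    V = s[0]
    m, h, j = s[1], s[2], s[3]
    d, f, f2, fcass = s[4], s[5], s[6], s[7]
    r, ss = s[8], s[9]
    xs, xr1, xr2 = s[10], s[11], s[12]
    rbar = s[13]
    cai, casr, cass = s[14], s[15], s[16]
    nai, ki = s[17], s[18]

    ek = _RTF * np.log(_KO / ki)
    ena = _RTF * np.log(_NAO / nai)
    eks = _RTF * np.log((_KO + _PKNA * _NAO) / (ki + _PKNA * nai))
    eca = 0.5 * _RTF * np.log(_CAO / cai)

    # fast Na+
    i_na = p[_P_GNA] * m * m * m * h * j * (V - ena)
    # L-type Ca2+
    z = 2.0 * (V - 15.0) / _RTF
    if np.abs(z) < 1e-7:
        z = 1e-7
    ez = np.exp(z)
    i_cal = (
        p[_P_GCAL] * d * f * f2 * fcass * 4.0 * (V - 15.0) * _F / _RTF
        * (0.25 * cass * ez - _CAO) / (ez - 1.0)
    )
    # transient outward
    i_to = p[_P_GTO] * r * ss * (V - ek)
    # delayed rectifiers
    i_ks = p[_P_GKS] * xs * xs * (V - eks)
    i_kr = p[_P_GKR] * np.sqrt(_KO / 5.4) * xr1 * xr2 * (V - ek)
    # inward rectifier
    a_k1 = 0.1 / (1.0 + np.exp(0.06 * (V - ek - 200.0)))
    b_k1 = (
        3.0 * np.exp(0.0002 * (V - ek + 100.0)) + np.exp(0.1 * (V - ek - 10.0))
    ) / (1.0 + np.exp(-0.5 * (V - ek)))
    i_k1 = p[_P_GK1] * np.sqrt(_KO / 5.4) * a_k1 / (a_k1 + b_k1) * (V - ek)
    # Na+/K+ pump
    i_nak = (
        p[_P_PNAK] * _KO / (_KO + 1.0) * nai / (nai + 40.0)
        / (1.0 + 0.1245 * np.exp(-0.1 * V / _RTF) + 0.0353 * np.exp(-V / _RTF))
    )
    # Na+/Ca2+ exchanger
    i_naca = (
        p[_P_KNACA]
        * (
            np.exp(0.35 * V / _RTF) * nai**3 * _CAO
            - np.exp(-0.65 * V / _RTF) * _NAO**3 * cai * 2.5
        )
        / (
            (87.5**3 + _NAO**3) * (1.38 + _CAO)
            * (1.0 + 0.1 * np.exp(-0.65 * V / _RTF))
        )
    )
    # sarcolemmal Ca2+ pump, plateau K+, backgrounds
    i_pca = p[_P_GPCA] * cai / (cai + 0.0005)
    i_pk = p[_P_GPK] * (V - ek) / (1.0 + np.exp((25.0 - V) / 5.98))
    i_bna = p[_P_GBNA] * (V - ena)
    i_bca = p[_P_GBCA] * (V - eca)

    i_ion = (
        i_na + i_cal + i_to + i_ks + i_kr + i_k1 + i_nak + i_naca
        + i_pca + i_pk + i_bna + i_bca
    )

    # ---- gate kinetics (Rush-Larsen) ----
    m_inf = 1.0 / (1.0 + np.exp((-56.86 - V) / 9.03)) ** 2
    a_m = 1.0 / (1.0 + np.exp((-60.0 - V) / 5.0))
    b_m = 0.1 / (1.0 + np.exp((V + 35.0) / 5.0)) + 0.1 / (
        1.0 + np.exp((V - 50.0) / 200.0)
    )
    tau_m = a_m * b_m

    h_inf = 1.0 / (1.0 + np.exp((V + 71.55) / 7.43)) ** 2
    if V < -40.0:
        a_h = 0.057 * np.exp(-(V + 80.0) / 6.8)
        b_h = 2.7 * np.exp(0.079 * V) + 310000.0 * np.exp(0.3485 * V)
    else:
        a_h = 0.0
        b_h = 0.77 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
    tau_h = 1.0 / (a_h + b_h)

    j_inf = h_inf
    if V < -40.0:
        a_j = (
            (-25428.0 * np.exp(0.2444 * V) - 6.948e-6 * np.exp(-0.04391 * V))
            * (V + 37.78)
            / (1.0 + np.exp(0.311 * (V + 79.23)))
        )
        b_j = 0.02424 * np.exp(-0.01052 * V) / (
            1.0 + np.exp(-0.1378 * (V + 40.14))
        )
    else:
        a_j = 0.0
        b_j = 0.6 * np.exp(0.057 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    tau_j = 1.0 / (a_j + b_j)

    d_inf = 1.0 / (1.0 + np.exp((-8.0 - V) / 7.5))
    a_d = 1.4 / (1.0 + np.exp((-35.0 - V) / 13.0)) + 0.25
    b_d = 1.4 / (1.0 + np.exp((V + 5.0) / 5.0))
    g_d = 1.0 / (1.0 + np.exp((50.0 - V) / 20.0))
    tau_d = a_d * b_d + g_d

    f_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 7.0))
    tau_f = (
        1102.5 * np.exp(-((V + 27.0) ** 2) / 225.0)
        + 200.0 / (1.0 + np.exp((13.0 - V) / 10.0))
        + 180.0 / (1.0 + np.exp((V + 30.0) / 10.0))
        + 20.0
    )

    f2_inf = 0.67 / (1.0 + np.exp((V + 35.0) / 7.0)) + 0.33
    tau_f2 = (
        562.0 * np.exp(-((V + 27.0) ** 2) / 240.0)
        + 31.0 / (1.0 + np.exp((25.0 - V) / 10.0))
        + 80.0 / (1.0 + np.exp((V + 30.0) / 10.0))
    )

    fcass_inf = 0.6 / (1.0 + (cass / 0.05) ** 2) + 0.4
    tau_fcass = 80.0 / (1.0 + (cass / 0.05) ** 2) + 2.0

    r_inf = 1.0 / (1.0 + np.exp((20.0 - V) / 6.0))
    tau_r = 9.5 * np.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8

    if p[_P_CELLTYPE] == 0.0:  # ENDO
        s_inf = 1.0 / (1.0 + np.exp((V + 28.0) / 5.0))
        tau_s = 1000.0 * np.exp(-((V + 67.0) ** 2) / 1000.0) + 8.0
    else:  # EPI and M
        s_inf = 1.0 / (1.0 + np.exp((V + 20.0) / 5.0))
        tau_s = (
            85.0 * np.exp(-((V + 45.0) ** 2) / 320.0)
            + 5.0 / (1.0 + np.exp((V - 20.0) / 5.0))
            + 3.0
        )

    # IKs activation; steady state shifted by the variant perturbation
    vx = V - p[_P_XSSHIFT]
    xs_inf = 1.0 / (1.0 + np.exp((-5.0 - vx) / 14.0))
    a_xs = 1400.0 / np.sqrt(1.0 + np.exp((5.0 - V) / 6.0))
    b_xs = 1.0 / (1.0 + np.exp((V - 35.0) / 15.0))
    tau_xs = a_xs * b_xs + 80.0

    xr1_inf = 1.0 / (1.0 + np.exp((-26.0 - V) / 7.0))
    a_xr1 = 450.0 / (1.0 + np.exp((-45.0 - V) / 10.0))
    b_xr1 = 6.0 / (1.0 + np.exp((V + 30.0) / 11.5))
    tau_xr1 = a_xr1 * b_xr1

    xr2_inf = 1.0 / (1.0 + np.exp((V + 88.0) / 24.0))
    a_xr2 = 3.0 / (1.0 + np.exp((-60.0 - V) / 20.0))
    b_xr2 = 1.12 / (1.0 + np.exp((V - 60.0) / 20.0))
    tau_xr2 = a_xr2 * b_xr2

    s[1] = m_inf + (m - m_inf) * np.exp(-dt / tau_m)
    s[2] = h_inf + (h - h_inf) * np.exp(-dt / tau_h)
    s[3] = j_inf + (j - j_inf) * np.exp(-dt / tau_j)
    s[4] = d_inf + (d - d_inf) * np.exp(-dt / tau_d)
    s[5] = f_inf + (f - f_inf) * np.exp(-dt / tau_f)
    s[6] = f2_inf + (f2 - f2_inf) * np.exp(-dt / tau_f2)
    s[7] = fcass_inf + (fcass - fcass_inf) * np.exp(-dt / tau_fcass)
    s[8] = r_inf + (r - r_inf) * np.exp(-dt / tau_r)
    s[9] = s_inf + (ss - s_inf) * np.exp(-dt / tau_s)
    s[10] = xs_inf + (xs - xs_inf) * np.exp(-dt / tau_xs)
    s[11] = xr1_inf + (xr1 - xr1_inf) * np.exp(-dt / tau_xr1)
    s[12] = xr2_inf + (xr2 - xr2_inf) * np.exp(-dt / tau_xr2)

    # ---- Ca2+ subsystem ----
    kcasr = 2.5 - 1.5 / (1.0 + (1.5 / casr) ** 2)
    k1 = 0.15 / kcasr
    k2 = 0.045 * kcasr
    o_rel = k1 * cass * cass * rbar / (0.06 + k1 * cass * cass)
    i_rel = 0.102 * o_rel * (casr - cass)
    i_leak = 0.00036 * (casr - cai)
    i_up = 0.006375 / (1.0 + (0.00025 / cai) ** 2)
    i_xfer = 0.0038 * (cass - cai)

    # Rbar is linear in itself: exact exponential update
    rb_rate = k2 * cass + 0.005
    rb_inf = 0.005 / rb_rate
    s[13] = rb_inf + (rbar - rb_inf) * np.exp(-dt * rb_rate)

    buf_c = 1.0 / (1.0 + 0.2 * 0.001 / (cai + 0.001) ** 2)
    dcai = buf_c * (
        (i_leak - i_up) * _VSR / _VC
        + i_xfer
        - (i_bca + i_pca - 2.0 * i_naca) * _CAPV / 2.0
    )
    buf_sr = 1.0 / (1.0 + 10.0 * 0.3 / (casr + 0.3) ** 2)
    dcasr = buf_sr * (i_up - i_rel - i_leak)
    buf_ss = 1.0 / (1.0 + 0.4 * 0.00025 / (cass + 0.00025) ** 2)
    dcass = buf_ss * (
        -i_cal * _CAPV * _VC / (2.0 * _VSS)
        + i_rel * _VSR / _VSS
        - i_xfer * _VC / _VSS
    )
    s[14] = cai + dt * dcai
    s[15] = casr + dt * dcasr
    s[16] = cass + dt * dcass
    s[17] = nai + dt * (-(i_na + i_bna + 3.0 * i_nak + 3.0 * i_naca) * _CAPV)
    s[18] = ki + dt * (
        -(i_k1 + i_to + i_kr + i_ks + i_pk + i_stim - 2.0 * i_nak) * _CAPV
    )

    return i_ion, i_ks


@njit(cache=True)
def run_beat(s, p, dt, cycle_ms, stim_amp, stim_dur, record_every):
    """Integrate one paced beat, mutating state ``s``.

    The stimulus (``stim_amp`` pA/pF, depolarizing, applied as a negative
    inward current) starts at t=0 and lasts ``stim_dur`` ms.  Returns
    (t, V, IKs) sampled every ``record_every`` steps.
    """
    n_steps = int(round(cycle_ms / dt))
    n_rec = n_steps // record_every + 1
    t_out = np.empty(n_rec)
    v_out = np.empty(n_rec)
    iks_out = np.empty(n_rec)
    k = 0
    for i in range(n_steps):
        t = i * dt
        i_stim = -stim_amp if t < stim_dur else 0.0
        if i % record_every == 0:
            t_out[k] = t
            v_out[k] = s[0]
            k += 1
        i_ion, i_ks = cell_step(s, p, dt, i_stim)
        if i % record_every == 0:
            iks_out[k - 1] = i_ks
        s[0] = s[0] + dt * (-(i_ion + i_stim))
    return t_out[:k], v_out[:k], iks_out[:k]


@njit(cache=True)
def run_cable_beat(S, P, dt, cycle_ms, diff_coeff, dx, stim_amp, stim_dur,
                   n_stim_nodes, record_every):
    """One paced beat of a 1D monodomain cable with no-flux boundaries.

    ``S`` is the (n_nodes, 19) state matrix (mutated in place), ``P`` the
    (n_nodes, 14) per-node parameter matrix.  The stimulus is applied to the
    first ``n_stim_nodes`` nodes.  Returns (t, Vm[x, t_recorded]).
    """
    n = S.shape[0]
    n_steps = int(round(cycle_ms / dt))
    n_rec = n_steps // record_every + 1
    t_out = np.empty(n_rec)
    v_out = np.empty((n, n_rec))
    i_ion = np.empty(n)
    r = diff_coeff / (dx * dx)
    k = 0
    for step in range(n_steps):
        t = step * dt
        if step % record_every == 0:
            t_out[k] = t
            for ix in range(n):
                v_out[ix, k] = S[ix, 0]
            k += 1
        stim_on = t < stim_dur
        for ix in range(n):
            i_stim = -stim_amp if (stim_on and ix < n_stim_nodes) else 0.0
            ion, _ = cell_step(S[ix], P[ix], dt, i_stim)
            i_ion[ix] = ion + i_stim
        # diffusion (no-flux boundaries) + reaction update of V, on a
        # snapshot of V so the Laplacian uses consistent values
        v_old = S[:, 0].copy()
        for ix in range(n):
            vl = v_old[ix - 1] if ix > 0 else v_old[ix + 1]
            vr = v_old[ix + 1] if ix < n - 1 else v_old[ix - 1]
            lap = r * (vl - 2.0 * v_old[ix] + vr)
            S[ix, 0] = v_old[ix] + dt * (-i_ion[ix] + lap)
        for ix in range(n):
            if np.abs(S[ix, 0]) > 200.0:
                # signal numerical blow-up to the caller
                t_out[0] = -1.0
                return t_out[:1], v_out[:, :1]
    return t_out[:k], v_out[:, :k]
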