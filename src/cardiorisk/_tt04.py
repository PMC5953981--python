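"""Numerical kernel for the ten Tusscher 2004 (tT04) human ventricular myocyte.

State layout per cell (17 variables)::

    0  V      membrane potential, mV
    1  m, 2 h, 3 j        fast Na+ gates
    4  d, 5 f, 6 fCa      L-type Ca2+ gates
    7  r, 8 s             transient-outward gates
    9  xs                 slow delayed-rectifier gate
    10 xr1, 11 xr2        rapid delayed-rectifier gates
    12 g                  Ca release inactivation gate
    13 Cai   mM, 14 CaSR  mM, 15 Nai  mM, 16 Ki  mM

The integrator is forward Euler (the model's original scheme) with an
optional Rush-Larsen exponential update for the Hodgkin-Huxley gates.
Cells are coupled, when more than one is present, by a monodomain cable
term with zero-flux boundaries.  All kernels are numba-compiled; a single
cell is simply a fiber of length one with zero diffusion.

Constants are the canonical published tT04 set.  The endo/mid/epi variants
differ in G_to, G_Ks and the s-gate kinetics.  Cell-type codes: 0 endo,
1 mid (M), 2 epi.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

N_STATES = 17

# physical constants
R_GAS = 8314.472  # mJ/(mol*K)
TEMP = 310.0  # K
FARADAY = 96485.3415  # C/mol
RTONF = R_GAS * TEMP / FARADAY  # ~26.714 mV

# reference morphometry of the published model (used for proportional
# rescaling by virtual-individual covariates)
CM_REF = 0.185
VC_REF = 0.016404
VSR_REF = 0.001094
CAPACITANCE_REF_PF = 185.0
CELL_VOLUME_REF_UM3 = 16404.0
SR_VOLUME_REF_UM3 = 1094.0

# maximal conductances (nS/pF) and transporter constants
G_NA = 14.838
G_K1 = 5.405
G_KR = 0.096
G_CAL = 0.000175
G_PK = 0.0146
G_PCA = 0.825
G_BNA = 0.00029
G_BCA = 0.000592
P_NAK = 1.362
K_MK = 1.0
K_MNA = 40.0
K_NACA = 1000.0
GAMMA_NACA = 0.35
K_MCA = 1.38
K_MNAI = 87.5
K_SAT = 0.1
ALPHA_NACA = 2.5
P_KNA = 0.03
K_PCA = 0.0005
# SR calcium handling
A_REL = 0.016464
B_REL = 0.25
C_REL = 0.008232
V_LEAK = 8e-5
VMAX_UP = 0.000425
K_UP = 0.00025
BUF_C = 0.15
K_BUF_C = 0.001
BUF_SR = 10.0
K_BUF_SR = 0.3

# cell-type dependent conductances, indexed by code (endo, mid, epi)
G_TO_BY_TYPE = np.array([0.073, 0.294, 0.294])
G_KS_BY_TYPE = np.array([0.245, 0.062, 0.245])

#: published tT04 initial state (quiescent, near resting)
INITIAL_STATE = np.array(
    [
        -86.2,  # V
        0.0,  # m
        0.75,  # h
        0.75,  # j
        0.0,  # d
        1.0,  # f
        1.0,  # fCa
        0.0,  # r
        1.0,  # s
        0.0,  # xs
        0.0,  # xr1
        1.0,  # xr2
        1.0,  # g
        0.0002,  # Cai
        0.2,  # CaSR
        11.6,  # Nai
        138.3,  # Ki
    ]
)


def initial_states(n_cells: int) -> np.ndarray:
    """Fresh (n_cells, N_STATES) state array at the published initial point."""
    return np.tile(INITIAL_STATE, (n_cells, 1))


@njit(cache=True)
def _ionic_step(s, i, cell_type, dt, istim, scale_kr, scale_ks, scale_na,
                scale_cal, ko, nao, cao, cap_over_vcf, vc_over_vsr, use_rl):
    """Advance the ionic state of cell ``i`` by one step; return dV/dt (ionic)."""
    v = s[i, 0]
    m = s[i, 1]
    h = s[i, 2]
    jj = s[i, 3]
    d = s[i, 4]
    f = s[i, 5]
    fca = s[i, 6]
    r = s[i, 7]
    ss = s[i, 8]
    xs = s[i, 9]
    xr1 = s[i, 10]
    xr2 = s[i, 11]
    g = s[i, 12]
    cai = s[i, 13]
    casr = s[i, 14]
    nai = s[i, 15]
    ki = s[i, 16]

    # reversal potentials
    ena = RTONF * math.log(nao / nai)
    ek = RTONF * math.log(ko / ki)
    eks = RTONF * math.log((ko + P_KNA * nao) / (ki + P_KNA * nai))
    eca = 0.5 * RTONF * math.log(cao / cai)

    # fast sodium current
    ina = scale_na * G_NA * m * m * m * h * jj * (v - ena)

    # L-type calcium current (GHK-type driving term)
    vv = v
    if -1e-6 < vv < 1e-6:
        vv = 1e-6
    efrac = math.exp(2.0 * vv / RTONF)
    ical = (
        scale_cal
        * G_CAL
        * d
        * f
        * fca
        * 4.0
        * vv
        * (FARADAY / RTONF)
        * (cai * efrac - 0.341 * cao)
        / (efrac - 1.0)
    )

    # transient outward
    ito = G_TO_BY_TYPE[cell_type] * r * ss * (v - ek)

    # delayed rectifiers
    ikr = scale_kr * G_KR * math.sqrt(ko / 5.4) * xr1 * xr2 * (v - ek)
    iks = scale_ks * G_KS_BY_TYPE[cell_type] * xs * xs * (v - eks)

    # inward rectifier
    ak1 = 0.1 / (1.0 + math.exp(0.06 * (v - ek - 200.0)))
    bk1 = (
        3.0 * math.exp(0.0002 * (v - ek + 100.0)) + math.exp(0.1 * (v - ek - 10.0))
    ) / (1.0 + math.exp(-0.5 * (v - ek)))
    ik1 = G_K1 * math.sqrt(ko / 5.4) * (ak1 / (ak1 + bk1)) * (v - ek)

    # Na/Ca exchanger and Na/K pump
    inaca = (
        K_NACA
        * (
            math.exp(GAMMA_NACA * v / RTONF) * nai * nai * nai * cao
            - math.exp((GAMMA_NACA - 1.0) * v / RTONF)
            * nao
            * nao
            * nao
            * cai
            * ALPHA_NACA
        )
        / (
            (K_MNAI * K_MNAI * K_MNAI + nao * nao * nao)
            * (K_MCA + cao)
            * (1.0 + K_SAT * math.exp((GAMMA_NACA - 1.0) * v / RTONF))
        )
    )
    inak = (
        P_NAK
        * ko
        * nai
        / (
            (ko + K_MK)
            * (nai + K_MNA)
            * (1.0 + 0.1245 * math.exp(-0.1 * v / RTONF) + 0.0353 * math.exp(-v / RTONF))
        )
    )

    # background and plateau currents
    ipca = G_PCA * cai / (K_PCA + cai)
    ipk = G_PK * (v - ek) / (1.0 + math.exp((25.0 - v) / 5.98))
    ibna = G_BNA * (v - ena)
    ibca = G_BCA * (v - eca)

    itot = ina + ical + ito + ikr + iks + ik1 + inaca + inak + ipca + ipk + ibna + ibca

    # --- gate kinetics ---------------------------------------------------
    # m
    minf = 1.0 / ((1.0 + math.exp((-56.86 - v) / 9.03)) ** 2)
    am = 1.0 / (1.0 + math.exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + math.exp((v + 35.0) / 5.0)) + 0.1 / (
        1.0 + math.exp((v - 50.0) / 200.0)
    )
    taum = am * bm
    # h
    hinf = 1.0 / ((1.0 + math.exp((v + 71.55) / 7.43)) ** 2)
    if v < -40.0:
        ah = 0.057 * math.exp(-(v + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.3485 * v)
    else:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
    tauh = 1.0 / (ah + bh)
    # j
    jinf = hinf
    if v < -40.0:
        aj = (
            (-2.5428e4 * math.exp(0.2444 * v) - 6.948e-6 * math.exp(-0.04391 * v))
            * (v + 37.78)
            / (1.0 + math.exp(0.311 * (v + 79.23)))
        )
        bj = 0.02424 * math.exp(-0.01052 * v) / (
            1.0 + math.exp(-0.1378 * (v + 40.14))
        )
    else:
        aj = 0.0
        bj = 0.6 * math.exp(0.057 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    tauj = 1.0 / (aj + bj)
    # d
    dinf = 1.0 / (1.0 + math.exp((-5.0 - v) / 7.5))
    ad = 1.4 / (1.0 + math.exp((-35.0 - v) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + math.exp((v + 5.0) / 5.0))
    gd = 1.0 / (1.0 + math.exp((50.0 - v) / 20.0))
    taud = ad * bd + gd
    # f
    finf = 1.0 / (1.0 + math.exp((v + 20.0) / 7.0))
    tauf = (
        1125.0 * math.exp(-((v + 27.0) ** 2) / 240.0)
        + 80.0
        + 165.0 / (1.0 + math.exp((25.0 - v) / 10.0))
    )
    # fCa (Ca-dependent, clamped from updating upward during depolarization)
    afca = 1.0 / (1.0 + (cai / 0.000325) ** 8)
    bfca = 0.1 / (1.0 + math.exp((cai - 0.0005) / 0.0001))
    gfca = 0.2 / (1.0 + math.exp((cai - 0.00075) / 0.0008))
    fcainf = (afca + bfca + gfca + 0.23) / 1.46
    tau_fca = 2.0
    # r and s
    rinf = 1.0 / (1.0 + math.exp((20.0 - v) / 6.0))
    taur = 9.5 * math.exp(-((v + 40.0) ** 2) / 1800.0) + 0.8
    if cell_type == 0:  # endo
        sinf = 1.0 / (1.0 + math.exp((v + 28.0) / 5.0))
        taus = 1000.0 * math.exp(-((v + 67.0) ** 2) / 1000.0) + 8.0
    else:  # mid, epi
        sinf = 1.0 / (1.0 + math.exp((v + 20.0) / 5.0))
        taus = (
            85.0 * math.exp(-((v + 45.0) ** 2) / 320.0)
            + 5.0 / (1.0 + math.exp((v - 20.0) / 5.0))
            + 3.0
        )
    # xs
    xsinf = 1.0 / (1.0 + math.exp((-5.0 - v) / 14.0))
    axs = 1100.0 / math.sqrt(1.0 + math.exp((-10.0 - v) / 6.0))
    bxs = 1.0 / (1.0 + math.exp((v - 60.0) / 20.0))
    tauxs = axs * bxs
    # xr1, xr2
    xr1inf = 1.0 / (1.0 + math.exp((-26.0 - v) / 7.0))
    axr1 = 450.0 / (1.0 + math.exp((-45.0 - v) / 10.0))
    bxr1 = 6.0 / (1.0 + math.exp((v + 30.0) / 11.5))
    tauxr1 = axr1 * bxr1
    xr2inf = 1.0 / (1.0 + math.exp((v + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + math.exp((-60.0 - v) / 20.0))
    bxr2 = 1.12 / (1.0 + math.exp((v - 60.0) / 20.0))
    tauxr2 = axr2 * bxr2
    # g (SR release inactivation)
    if cai < 0.00035:
        ginf = 1.0 / (1.0 + (cai / 0.00035) ** 6)
    else:
        ginf = 1.0 / (1.0 + (cai / 0.00035) ** 16)
    tau_g = 2.0

    if use_rl:
        s[i, 1] = minf + (m - minf) * math.exp(-dt / taum)
        s[i, 2] = hinf + (h - hinf) * math.exp(-dt / tauh)
        s[i, 3] = jinf + (jj - jinf) * math.exp(-dt / tauj)
        s[i, 4] = dinf + (d - dinf) * math.exp(-dt / taud)
        s[i, 5] = finf + (f - finf) * math.exp(-dt / tauf)
        s[i, 7] = rinf + (r - rinf) * math.exp(-dt / taur)
        s[i, 8] = sinf + (ss - sinf) * math.exp(-dt / taus)
        s[i, 9] = xsinf + (xs - xsinf) * math.exp(-dt / tauxs)
        s[i, 10] = xr1inf + (xr1 - xr1inf) * math.exp(-dt / tauxr1)
        s[i, 11] = xr2inf + (xr2 - xr2inf) * math.exp(-dt / tauxr2)
    else:
        s[i, 1] = m + dt * (minf - m) / taum
        s[i, 2] = h + dt * (hinf - h) / tauh
        s[i, 3] = jj + dt * (jinf - jj) / tauj
        s[i, 4] = d + dt * (dinf - d) / taud
        s[i, 5] = f + dt * (finf - f) / tauf
        s[i, 7] = r + dt * (rinf - r) / taur
        s[i, 8] = ss + dt * (sinf - ss) / taus
        s[i, 9] = xs + dt * (xsinf - xs) / tauxs
        s[i, 10] = xr1 + dt * (xr1inf - xr1) / tauxr1
        s[i, 11] = xr2 + dt * (xr2inf - xr2) / tauxr2
    # clamp gates into [0, 1] (forward Euler can overshoot marginally)
    for k in range(1, 12):
        if s[i, k] < 0.0:
            s[i, k] = 0.0
        elif s[i, k] > 1.0:
            s[i, k] = 1.0
    # fCa and g only relax while the cell is repolarized
    if not (fcainf > fca and v > -60.0):
        fca_new = fca + dt * (fcainf - fca) / tau_fca
        s[i, 6] = min(max(fca_new, 0.0), 1.0)
    if not (ginf > g and v > -60.0):
        g_new = g + dt * (ginf - g) / tau_g
        s[i, 12] = min(max(g_new, 0.0), 1.0)

    # --- intracellular concentrations ------------------------------------
    irel = (A_REL * casr * casr / (B_REL * B_REL + casr * casr) + C_REL) * d * s[i, 12]
    ileak = V_LEAK * (casr - cai)
    iup = VMAX_UP / (1.0 + (K_UP / cai) ** 2)

    bufc_factor = 1.0 / (1.0 + BUF_C * K_BUF_C / ((cai + K_BUF_C) ** 2))
    bufsr_factor = 1.0 / (1.0 + BUF_SR * K_BUF_SR / ((casr + K_BUF_SR) ** 2))

    dcai = bufc_factor * (
        ileak - iup + irel - (ical + ibca + ipca - 2.0 * inaca) * cap_over_vcf * 0.5
    )
    dcasr = bufsr_factor * vc_over_vsr * (iup - irel - ileak)
    dnai = -(ina + ibna + 3.0 * inak + 3.0 * inaca) * cap_over_vcf
    dki = -(ik1 + ito + ikr + iks - 2.0 * inak + ipk + istim) * cap_over_vcf

    s[i, 13] = cai + dt * dcai
    s[i, 14] = casr + dt * dcasr
    s[i, 15] = nai + dt * dnai
    s[i, 16] = ki + dt * dki

    return -(itot + istim)


@njit(cache=True)
def run_fiber(states, cell_types, dt, n_steps, cycle_steps, stim_steps,
              stim_amp, n_stim_cells, d_over_dx2, scale_kr, scale_ks,
              scale_na, scale_cal, ko, nao, cao, cap_over_vcf, vc_over_vsr,
              use_rl, record_start, record_stride, v_out, ca_out):
    """Advance a fiber (or single cell) ``n_steps`` with periodic pacing.

    Records V and Cai every ``record_stride`` steps starting at
    ``record_start`` (values sampled before the step update, i.e. at time
    step*dt).  Returns -1 on success, or the failing step index on numerical
    blow-up (|V| > 200 mV or non-finite state).
    """
    n_cells = states.shape[0]
    lap = np.zeros(n_cells)
    rec = 0
    n_rec = v_out.shape[1]
    for step in range(n_steps):
        if step >= record_start and (step - record_start) % record_stride == 0 and rec < n_rec:
            for i in range(n_cells):
                v_out[i, rec] = states[i, 0]
                ca_out[i, rec] = states[i, 13]
            rec += 1
        # cable coupling from the pre-step voltage field, zero-flux ends
        if n_cells > 1 and d_over_dx2 > 0.0:
            lap[0] = d_over_dx2 * 2.0 * (states[1, 0] - states[0, 0])
            lap[n_cells - 1] = d_over_dx2 * 2.0 * (
                states[n_cells - 2, 0] - states[n_cells - 1, 0]
            )
            for i in range(1, n_cells - 1):
                lap[i] = d_over_dx2 * (
                    states[i - 1, 0] - 2.0 * states[i, 0] + states[i + 1, 0]
                )
        phase = step % cycle_steps
        stim_on = phase < stim_steps
        for i in range(n_cells):
            istim = stim_amp if (stim_on and i < n_stim_cells) else 0.0
            dv = _ionic_step(
                states, i, cell_types[i], dt, istim, scale_kr, scale_ks,
                scale_na, scale_cal, ko, nao, cao, cap_over_vcf, vc_over_vsr,
                use_rl,
            )
            states[i, 0] = states[i, 0] + dt * dv + dt * lap[i]
        for i in range(n_cells):
            v = states[i, 0]
            if not math.isfinite(v) or abs(v) > 200.0 or not math.isfinite(states[i, 13]):
                return step
    return -1
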