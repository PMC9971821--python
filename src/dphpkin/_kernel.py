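"""Numba-compiled ODE right-hand side and integrator for the PBPK model.

The model is a linear (time-inhomogeneous through two smoothed lag switches)
compartment system, integrated with an adaptive Cash-Karp RK4(5) pair and
cubic-Hermite interpolation onto the requested output grid.  A hand-rolled
integrator is used because the calibration and uncertainty-analysis loops
need tens of thousands of simulations; the whole solve stays inside compiled
code at well under a millisecond per run.

Parameter-vector and state-vector layouts are defined here and shared with
:mod:`dphpkin.pbpk`.
"""

import numpy as np
from numba import njit

# --- parameter vector layout -------------------------------------------------
P_V_LI = 0      # liver volume, L
P_V_FA = 1      # adipose volume, L
P_V_KI = 2      # kidney volume, L
P_V_RPD = 3     # rapidly perfused volume, L
P_V_SPD = 4     # slowly perfused volume, L
P_V_BLD = 5     # blood volume, L
P_Q_HEPART = 6  # hepatic artery flow, L/h
P_Q_KI = 7
P_Q_FA = 8
P_Q_GU = 9
P_Q_ST = 10
P_Q_SPD = 11
P_Q_RPD = 12
P_FU_D = 13     # unbound fraction DPHP
P_FU_M = 14     # unbound fraction MPHP
P_PFA_D = 15    # tissue:blood partition coefficients, DPHP
P_PKI_D = 16
P_PLI_D = 17
P_PRPD_D = 18
P_PSPD_D = 19
P_PFA_M = 20    # tissue:blood partition coefficients, MPHP
P_PKI_M = 21
P_PLI_M = 22
P_PRPD_M = 23
P_PSPD_M = 24
P_CL_D = 25     # hepatic intrinsic clearance DPHP, L/h
P_CL_M = 26     # hepatic intrinsic clearance MPHP, L/h
P_K_GUT = 27    # gut DPHP->MPHP metabolism rate, 1/h
P_BELLYPERM = 28
P_K_ST_GUT = 29
P_GIPERM1 = 30
P_GIPERM2 = 31
P_K_TRANSIT = 32
P_GUTLAG = 33
P_K1_LYMPH = 34
P_LYMPHLAG = 35
P_K1_DPHP_LIVER = 36
P_K_BILE = 37       # 1 / bile_delay, 1/h
P_K_ABS_MPHP = 38
P_ESCAPE_GU = 39
P_ESCAPE_LI = 40
P_FRAC_MOH = 41
P_FRAC_CX = 42
P_K1_MPHP = 43
P_K1_MOH = 44
P_K1_CX = 45
P_R_MD = 46         # MW_MPHP / MW_DPHP
P_R_OM = 47         # MW_OH / MW_MPHP
P_R_CM = 48         # MW_cx / MW_MPHP
P_HS_WIDTH = 49     # lag-switch smoothing width, h
NP = 50

# --- state vector layout (amounts, mg) --------------------------------------
S_ST = 0        # DPHP stomach lumen
S_GUT1 = 1      # DPHP gut section 1 lumen
S_GUT2 = 2      # DPHP gut section 2 lumen
S_LYMPH = 3     # DPHP lymph depot
S_BILE = 4      # DPHP bile transit
S_LI = 5        # DPHP liver
S_FA = 6        # DPHP adipose
S_KI = 7        # DPHP kidney
S_RPD = 8       # DPHP rapidly perfused
S_SPD = 9       # DPHP slowly perfused
S_BLD = 10      # DPHP blood
S_GUTM = 11     # MPHP gut lumen
S_LIM = 12      # MPHP liver
S_FAM = 13      # MPHP adipose
S_KIM = 14      # MPHP kidney
S_RPDM = 15     # MPHP rapidly perfused
S_SPDM = 16     # MPHP slowly perfused
S_BLDM = 17     # MPHP blood
S_URINEM = 18   # cumulative urinary MPHP
S_OH = 19       # OH-MPHP central pool
S_URINEOH = 20  # cumulative urinary OH-MPHP
S_CX = 21       # cx-MPHP central pool
S_URINECX = 22  # cumulative urinary cx-MPHP
S_FAECES = 23   # cumulative faecal DPHP (unabsorbed dose)
S_OTHER = 24    # other-metabolite sink (MPHP mass units)
NSTATE = 25

STATE_NAMES = (
    "A_st_DPHP", "A_gut1_DPHP", "A_gut2_DPHP", "A_lymph_DPHP", "A_bile_DPHP",
    "A_li_DPHP", "A_fa_DPHP", "A_ki_DPHP", "A_rpd_DPHP", "A_spd_DPHP",
    "A_bld_DPHP", "A_gut_MPHP", "A_li_MPHP", "A_fa_MPHP", "A_ki_MPHP",
    "A_rpd_MPHP", "A_spd_MPHP", "A_bld_MPHP", "A_urine_MPHP", "A_OH",
    "A_urine_OH", "A_cx", "A_urine_cx", "A_faeces_DPHP", "A_other_metab",
)


@njit(cache=True)
def _switch(t, lag, width):
    """Smoothed Heaviside H(t - lag); width 0 falls back to a hard switch."""
    if width <= 0.0:
        return 1.0 if t >= lag else 0.0
    z = (t - lag) / width
    if z > 35.0:
        return 1.0
    if z < -35.0:
        return 0.0
    return 1.0 / (1.0 + np.exp(-z))


@njit(cache=True)
def rhs(t, y, p, dy):
    """Time-derivative of the state vector (mg/h)."""
    q_portal = p[P_Q_GU] + p[P_Q_ST]
    q_litot = p[P_Q_HEPART] + q_portal
    q_sum = q_litot + p[P_Q_FA] + p[P_Q_KI] + p[P_Q_RPD] + p[P_Q_SPD]

    cart_d = y[S_BLD] / p[P_V_BLD]
    cu_d = p[P_FU_D] * cart_d
    cart_m = y[S_BLDM] / p[P_V_BLD]
    cu_m = p[P_FU_M] * cart_m

    g_gut = _switch(t, p[P_GUTLAG], p[P_HS_WIDTH])
    g_lym = _switch(t, p[P_LYMPHLAG], p[P_HS_WIDTH])

    # --- DPHP: lumen, lymph, bile ---
    dy[S_ST] = -(p[P_BELLYPERM] + p[P_K_ST_GUT]) * y[S_ST]
    k_gut = p[P_K_GUT]
    transit = p[P_K_TRANSIT] * g_gut * y[S_GUT1]
    dy[S_GUT1] = p[P_K_ST_GUT] * y[S_ST] - (p[P_GIPERM1] + k_gut) * y[S_GUT1] - transit
    bile_out = p[P_K_BILE] * y[S_BILE]
    dy[S_GUT2] = transit + bile_out - p[P_GIPERM2] * y[S_GUT2]
    lymph_out = p[P_K1_LYMPH] * g_lym * y[S_LYMPH]
    dy[S_LYMPH] = -lymph_out
    bile_in = p[P_K1_DPHP_LIVER] * y[S_LI]
    dy[S_BILE] = bile_in - bile_out

    # --- DPHP: liver and flow-limited tissues ---
    cv_li = y[S_LI] / p[P_V_LI] / p[P_PLI_D]
    met_d = p[P_CL_D] * cv_li                      # hepatic DPHP -> MPHP (mg DPHP/h)
    dy[S_LI] = (
        q_litot * cu_d
        + p[P_GIPERM1] * y[S_GUT1]
        + p[P_GIPERM2] * y[S_GUT2]
        - q_litot * cv_li
        - met_d
        - bile_in
    )
    cv_fa = y[S_FA] / p[P_V_FA] / p[P_PFA_D]
    dy[S_FA] = p[P_Q_FA] * (cu_d - cv_fa)
    cv_ki = y[S_KI] / p[P_V_KI] / p[P_PKI_D]
    dy[S_KI] = p[P_Q_KI] * (cu_d - cv_ki)
    cv_rpd = y[S_RPD] / p[P_V_RPD] / p[P_PRPD_D]
    dy[S_RPD] = p[P_Q_RPD] * (cu_d - cv_rpd)
    cv_spd = y[S_SPD] / p[P_V_SPD] / p[P_PSPD_D]
    dy[S_SPD] = p[P_Q_SPD] * (cu_d - cv_spd)
    dy[S_BLD] = (
        q_litot * cv_li
        + p[P_Q_FA] * cv_fa
        + p[P_Q_KI] * cv_ki
        + p[P_Q_RPD] * cv_rpd
        + p[P_Q_SPD] * cv_spd
        - q_sum * cu_d
        + p[P_BELLYPERM] * y[S_ST]
        + lymph_out
    )

    # --- MPHP sub-model ---
    form_gut = k_gut * y[S_GUT1] * p[P_R_MD]       # gut-formed MPHP, mg MPHP/h
    abs_m = p[P_K_ABS_MPHP] * y[S_GUTM]
    dy[S_GUTM] = form_gut - abs_m
    form_li = met_d * p[P_R_MD]                    # liver-formed MPHP, mg MPHP/h
    cv_lim = y[S_LIM] / p[P_V_LI] / p[P_PLI_M]
    met_m = p[P_CL_M] * cv_lim                     # hepatic MPHP metabolism, mg MPHP/h
    dy[S_LIM] = (
        (1.0 - p[P_ESCAPE_LI]) * form_li
        + (1.0 - p[P_ESCAPE_GU]) * abs_m
        + q_litot * cu_m
        - q_litot * cv_lim
        - met_m
    )
    cv_fam = y[S_FAM] / p[P_V_FA] / p[P_PFA_M]
    dy[S_FAM] = p[P_Q_FA] * (cu_m - cv_fam)
    urine_m = p[P_K1_MPHP] * y[S_KIM]
    cv_kim = y[S_KIM] / p[P_V_KI] / p[P_PKI_M]
    dy[S_KIM] = p[P_Q_KI] * (cu_m - cv_kim) - urine_m
    cv_rpdm = y[S_RPDM] / p[P_V_RPD] / p[P_PRPD_M]
    dy[S_RPDM] = p[P_Q_RPD] * (cu_m - cv_rpdm)
    cv_spdm = y[S_SPDM] / p[P_V_SPD] / p[P_PSPD_M]
    dy[S_SPDM] = p[P_Q_SPD] * (cu_m - cv_spdm)
    dy[S_BLDM] = (
        p[P_ESCAPE_LI] * form_li
        + p[P_ESCAPE_GU] * abs_m
        + q_litot * cv_lim
        + p[P_Q_FA] * cv_fam
        + p[P_Q_KI] * cv_kim
        + p[P_Q_RPD] * cv_rpdm
        + p[P_Q_SPD] * cv_spdm
        - q_sum * cu_m
    )
    dy[S_URINEM] = urine_m

    # --- secondary metabolites: central pools, first-order urinary loss ---
    dy[S_OH] = p[P_FRAC_MOH] * met_m * p[P_R_OM] - p[P_K1_MOH] * y[S_OH]
    dy[S_URINEOH] = p[P_K1_MOH] * y[S_OH]
    dy[S_CX] = p[P_FRAC_CX] * met_m * p[P_R_CM] - p[P_K1_CX] * y[S_CX]
    dy[S_URINECX] = p[P_K1_CX] * y[S_CX]

    dy[S_FAECES] = 0.0
    dy[S_OTHER] = (1.0 - p[P_FRAC_MOH] - p[P_FRAC_CX]) * met_m


# Cash-Karp RK4(5) tableau
_CK_C = np.array([0.0, 0.2, 0.3, 0.6, 1.0, 0.875])
_CK_B5 = np.array([37.0 / 378.0, 0.0, 250.0 / 621.0, 125.0 / 594.0, 0.0, 512.0 / 1771.0])
_CK_B4 = np.array(
    [2825.0 / 27648.0, 0.0, 18575.0 / 48384.0, 13525.0 / 55296.0, 277.0 / 14336.0, 0.25]
)
_CK_A = np.array([
    [0.0, 0.0, 0.0, 0.0, 0.0],
    [0.2, 0.0, 0.0, 0.0, 0.0],
    [3.0 / 40.0, 9.0 / 40.0, 0.0, 0.0, 0.0],
    [0.3, -0.9, 1.2, 0.0, 0.0],
    [-11.0 / 54.0, 2.5, -70.0 / 27.0, 35.0 / 27.0, 0.0],
    [1631.0 / 55296.0, 175.0 / 512.0, 575.0 / 13824.0, 44275.0 / 110592.0, 253.0 / 4096.0],
])


@njit(cache=True)
def integrate(p, y0, t_grid, rtol, atol, max_steps=2_000_000):
    """Integrate the model over ``t_grid`` (strictly increasing, t_grid[0] = t0).

    Returns ``(Y, status, t_fail)`` where ``Y[i]`` is the state at
    ``t_grid[i]``; status 0 is success, 1 step-size collapse / step budget,
    2 non-finite state.  Output at interior grid times uses cubic-Hermite
    interpolation over the bracketing accepted step.
    """
    n_out = t_grid.shape[0]
    Y = np.zeros((n_out, NSTATE))
    t = t_grid[0]
    t_end = t_grid[n_out - 1]
    y = y0.copy()
    Y[0] = y
    i_out = 1

    f = np.zeros(NSTATE)
    rhs(t, y, p, f)
    k = np.zeros((6, NSTATE))
    ytmp = np.zeros(NSTATE)
    y5 = np.zeros(NSTATE)
    err = np.zeros(NSTATE)
    f_new = np.zeros(NSTATE)

    h = 1e-4
    if h > t_end - t:
        h = (t_end - t) * 0.5
    hmin = 1e-12

    steps = 0
    while t < t_end and i_out < n_out:
        steps += 1
        if steps > max_steps or h < hmin:
            return Y, 1, t
        if t + h > t_end:
            h = t_end - t

        # Cash-Karp stages
        for s in range(6):
            for j in range(NSTATE):
                acc = 0.0
                for m in range(s):
                    acc += _CK_A[s, m] * k[m, j]
                ytmp[j] = y[j] + h * acc
            if s == 0:
                for j in range(NSTATE):
                    k[0, j] = f[j]
            else:
                rhs(t + _CK_C[s] * h, ytmp, p, k[s])

        errnorm = 0.0
        for j in range(NSTATE):
            a5 = 0.0
            e = 0.0
            for s in range(6):
                a5 += _CK_B5[s] * k[s, j]
                e += (_CK_B5[s] - _CK_B4[s]) * k[s, j]
            y5[j] = y[j] + h * a5
            err[j] = h * e
            sc = atol + rtol * max(abs(y[j]), abs(y5[j]))
            r = abs(err[j]) / sc
            if r > errnorm:
                errnorm = r

        if not np.isfinite(errnorm):
            return Y, 2, t

        if errnorm <= 1.0:
            # accept
            t_new = t + h
            rhs(t_new, y5, p, f_new)
            # interpolate any requested outputs inside (t, t_new]
            while i_out < n_out and t_grid[i_out] <= t_new + 1e-12:
                tq = t_grid[i_out]
                if tq >= t_new:
                    Y[i_out] = y5
                else:
                    th = (tq - t) / h
                    h00 = (1.0 + 2.0 * th) * (1.0 - th) ** 2
                    h10 = th * (1.0 - th) ** 2
                    h01 = th * th * (3.0 - 2.0 * th)
                    h11 = th * th * (th - 1.0)
                    for j in range(NSTATE):
                        Y[i_out, j] = (
                            h00 * y[j]
                            + h10 * h * f[j]
                            + h01 * y5[j]
                            + h11 * h * f_new[j]
                        )
                i_out += 1
            t = t_new
            for j in range(NSTATE):
                y[j] = y5[j]
                f[j] = f_new[j]
            fac = 0.9 * errnorm ** -0.2 if errnorm > 1e-10 else 5.0
            if fac > 5.0:
                fac = 5.0
            h *= fac
        else:
            fac = 0.9 * errnorm ** -0.2
            if fac < 0.1:
                fac = 0.1
            h *= fac

    return Y, 0, t
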