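"""Compiled trajectory kernels.

The 6MP absorption/metabolism cascade (gut -> plasma -> 6-TGN) is linear with
constant coefficients, so between events it is advanced by its exact
closed-form (Bateman) solution.  Only the five myelosuppression states are
integrated numerically, with a classical RK4 whose steps are aligned to dose
and output times (the forcing 6-TGN level is smooth inside every step).  All
fast rates live in the exactly-solved cascade, so the numerical subsystem is
non-stiff (rates below ~2.4/day).
"""

import numpy as np
from numba import njit

__all__ = ["simulate_states", "simulate_anc_sens"]

_EPS_RATE = 1e-9


@njit(cache=True)
def _phi(u, v, h):
    # (exp(-v h) - exp(-u h)) / (u - v), continuous limit at u == v
    if abs(u - v) < _EPS_RATE * (abs(u) + abs(v) + 1.0):
        return h * np.exp(-u * h)
    return (np.exp(-v * h) - np.exp(-u * h)) / (u - v)


@njit(cache=True)
def _pk_step(x1, x2, x3, a, b, c, d, h):
    """Advance the linear cascade x1' = -a x1; x2' = a x1 - b x2;
    x3' = c x2 - d x3 exactly over a step h."""
    # nudge near-degenerate rate pairs; error is O(eps * h)
    if abs(a - b) < _EPS_RATE * (a + b + 1.0):
        b = b * (1.0 + 1e-8) + 1e-12
    if abs(b - d) < _EPS_RATE * (b + d + 1.0):
        d = d * (1.0 + 1e-8) + 1e-12
    if abs(a - d) < _EPS_RATE * (a + d + 1.0):
        d = d * (1.0 + 1e-8) + 1e-12
    ea = np.exp(-a * h)
    eb = np.exp(-b * h)
    ed = np.exp(-d * h)
    y1 = x1 * ea
    y2 = x2 * eb + x1 * a * _phi(a, b, h)
    bate = (ea / ((b - a) * (d - a))
            + eb / ((a - b) * (d - b))
            + ed / ((a - d) * (b - d)))
    y3 = x3 * ed + x2 * c * _phi(b, d, h) + x1 * a * c * bate
    return y1, y2, y3


@njit(cache=True)
def _pd_rhs(p0, p1, p2, p3, p4, x3, base, ktr, gamma, slope, kma):
    e_drug = slope * x3
    fb = (base / p4) ** gamma
    dp0 = ktr * p0 * (1.0 - e_drug) * fb - ktr * p0
    dp1 = ktr * (p0 - p1)
    dp2 = ktr * (p1 - p2)
    dp3 = ktr * (p2 - p3)
    dp4 = ktr * p3 - kma * p4
    return dp0, dp1, dp2, dp3, dp4


@njit(cache=True)
def simulate_states(out_t, dose_t, dose_a, x0, t0,
                    base, ktr, gamma, slope,
                    bioav, ka, k20, cmet, cl, kma, h):
    """Simulate the 8-state system from ``x0`` at ``t0``.

    Doses are impulses of ``bioav * amount`` into the gut compartment.
    Returns an (n_out, 8) state matrix; filled with NaN from the point where
    the circulating compartment becomes non-positive (integration failure).
    """
    nout = out_t.shape[0]
    nd = dose_t.shape[0]
    out = np.full((nout, 8), np.nan)

    x1 = x0[0]
    x2 = x0[1]
    x3 = x0[2]
    p0 = x0[3]
    p1 = x0[4]
    p2 = x0[5]
    p3 = x0[6]
    p4 = x0[7]

    t = t0
    i_o = 0
    i_d = 0
    big = 1.0e300
    while i_o < nout or i_d < nd:
        t_obs = out_t[i_o] if i_o < nout else big
        t_dose = dose_t[i_d] if i_d < nd else big
        te = t_obs if t_obs < t_dose else t_dose
        if te > t:
            nstep = int(np.ceil((te - t) / h))
            if nstep < 1:
                nstep = 1
            hs = (te - t) / nstep
            for _ in range(nstep):
                if p4 <= 0.0:
                    return out
                x1h, x2h, x3h = _pk_step(x1, x2, x3, ka, k20, cmet, cl, 0.5 * hs)
                x1f, x2f, x3f = _pk_step(x1h, x2h, x3h, ka, k20, cmet, cl, 0.5 * hs)
                a0, a1, a2, a3, a4 = _pd_rhs(p0, p1, p2, p3, p4, x3,
                                             base, ktr, gamma, slope, kma)
                q4 = p4 + 0.5 * hs * a4
                if q4 <= 0.0:
                    return out
                b0, b1, b2, b3, b4 = _pd_rhs(p0 + 0.5 * hs * a0, p1 + 0.5 * hs * a1,
                                             p2 + 0.5 * hs * a2, p3 + 0.5 * hs * a3,
                                             q4, x3h,
                                             base, ktr, gamma, slope, kma)
                q4 = p4 + 0.5 * hs * b4
                if q4 <= 0.0:
                    return out
                c0, c1, c2, c3, c4 = _pd_rhs(p0 + 0.5 * hs * b0, p1 + 0.5 * hs * b1,
                                             p2 + 0.5 * hs * b2, p3 + 0.5 * hs * b3,
                                             q4, x3h,
                                             base, ktr, gamma, slope, kma)
                q4 = p4 + hs * c4
                if q4 <= 0.0:
                    return out
                d0, d1, d2, d3, d4 = _pd_rhs(p0 + hs * c0, p1 + hs * c1,
                                             p2 + hs * c2, p3 + hs * c3,
                                             q4, x3f,
                                             base, ktr, gamma, slope, kma)
                p0 += hs / 6.0 * (a0 + 2.0 * b0 + 2.0 * c0 + d0)
                p1 += hs / 6.0 * (a1 + 2.0 * b1 + 2.0 * c1 + d1)
                p2 += hs / 6.0 * (a2 + 2.0 * b2 + 2.0 * c2 + d2)
                p3 += hs / 6.0 * (a3 + 2.0 * b3 + 2.0 * c3 + d3)
                p4 += hs / 6.0 * (a4 + 2.0 * b4 + 2.0 * c4 + d4)
                x1, x2, x3 = x1f, x2f, x3f
            t = te
            if p4 <= 0.0:
                return out
        while i_o < nout and out_t[i_o] <= t:
            out[i_o, 0] = x1
            out[i_o, 1] = x2
            out[i_o, 2] = x3
            out[i_o, 3] = p0
            out[i_o, 4] = p1
            out[i_o, 5] = p2
            out[i_o, 6] = p3
            out[i_o, 7] = p4
            i_o += 1
        while i_d < nd and dose_t[i_d] <= t:
            x1 += bioav * dose_a[i_d]
            i_d += 1
    return out


@njit(cache=True)
def _aug_deriv(p, S, x3, base, ktr, gamma, slope, kma, dp, dS):
    """Derivative of the PD state p (5,) and its parameter sensitivities
    S (5, 4; columns d/dBase, d/dk_tr, d/dgamma, d/dslope) at forcing x3."""
    e_drug = slope * x3
    ratio = base / p[4]
    fb = ratio ** gamma
    w = ktr * p[0] * (1.0 - e_drug) * fb   # proliferation inflow
    dp[0] = w - ktr * p[0]
    dp[1] = ktr * (p[0] - p[1])
    dp[2] = ktr * (p[1] - p[2])
    dp[3] = ktr * (p[2] - p[3])
    dp[4] = ktr * p[3] - kma * p[4]
    # state-Jacobian entries of row 0 (rows 1-4 are the linear chain)
    a00 = ktr * ((1.0 - e_drug) * fb - 1.0)
    a04 = -w * gamma / p[4]
    # explicit parameter partials of row 0
    p0b = w * gamma / base
    p0k = p[0] * ((1.0 - e_drug) * fb - 1.0)
    p0g = w * np.log(ratio)
    p0s = -ktr * p[0] * x3 * fb
    for j in range(4):
        s0 = S[0, j]
        s1 = S[1, j]
        s2 = S[2, j]
        s3 = S[3, j]
        s4 = S[4, j]
        dS[0, j] = a00 * s0 + a04 * s4
        dS[1, j] = ktr * (s0 - s1)
        dS[2, j] = ktr * (s1 - s2)
        dS[3, j] = ktr * (s2 - s3)
        dS[4, j] = ktr * s3 - kma * s4
    dS[0, 0] += p0b
    dS[0, 1] += p0k
    dS[0, 2] += p0g
    dS[0, 3] += p0s
    # k_tr also enters rows 1-4 explicitly
    dS[1, 1] += p[0] - p[1]
    dS[2, 1] += p[1] - p[2]
    dS[3, 1] += p[2] - p[3]
    dS[4, 1] += p[3]


@njit(cache=True)
def simulate_anc_sens(obs_t, dose_t, dose_a,
                      base, ktr, gamma, slope,
                      bioav, ka, k20, cmet, cl, kma, h):
    """ANC and its exact parameter sensitivities at the observation times.

    Starts from the drug-free steady state (whose parameter dependence is
    included).  Integrates the PD state together with its forward
    sensitivities using the same RK4 stages, so the returned gradient is the
    machine-accurate derivative of the discretized trajectory.  Returns
    ``(anc (n,), sens (n, 4))``; NaN-filled rows flag integration failure.
    """
    nout = obs_t.shape[0]
    nd = dose_t.shape[0]
    anc = np.full(nout, np.nan)
    sens = np.full((nout, 4), np.nan)

    x1 = 0.0
    x2 = 0.0
    x3 = 0.0
    p = np.empty(5)
    pool = base * kma / ktr
    for i in range(4):
        p[i] = pool
    p[4] = base
    S = np.zeros((5, 4))
    for i in range(4):
        S[i, 0] = kma / ktr            # d pool / d Base
        S[i, 1] = -base * kma / (ktr * ktr)  # d pool / d k_tr
    S[4, 0] = 1.0

    dp1 = np.empty(5); dS1 = np.empty((5, 4))
    dp2 = np.empty(5); dS2 = np.empty((5, 4))
    dp3 = np.empty(5); dS3 = np.empty((5, 4))
    dp4 = np.empty(5); dS4 = np.empty((5, 4))
    pt = np.empty(5); St = np.empty((5, 4))

    t = 0.0
    i_o = 0
    i_d = 0
    big = 1.0e300
    while i_o < nout or i_d < nd:
        t_obs = obs_t[i_o] if i_o < nout else big
        t_dose = dose_t[i_d] if i_d < nd else big
        te = t_obs if t_obs < t_dose else t_dose
        if te > t:
            nstep = int(np.ceil((te - t) / h))
            if nstep < 1:
                nstep = 1
            hs = (te - t) / nstep
            for _ in range(nstep):
                if p[4] <= 0.0:
                    return anc, sens
                x1h, x2h, x3h = _pk_step(x1, x2, x3, ka, k20, cmet, cl, 0.5 * hs)
                x1f, x2f, x3f = _pk_step(x1h, x2h, x3h, ka, k20, cmet, cl, 0.5 * hs)
                _aug_deriv(p, S, x3, base, ktr, gamma, slope, kma, dp1, dS1)
                ok = True
                for i in range(5):
                    pt[i] = p[i] + 0.5 * hs * dp1[i]
                    for j in range(4):
                        St[i, j] = S[i, j] + 0.5 * hs * dS1[i, j]
                if pt[4] <= 0.0:
                    return anc, sens
                _aug_deriv(pt, St, x3h, base, ktr, gamma, slope, kma, dp2, dS2)
                for i in range(5):
                    pt[i] = p[i] + 0.5 * hs * dp2[i]
                    for j in range(4):
                        St[i, j] = S[i, j] + 0.5 * hs * dS2[i, j]
                if pt[4] <= 0.0:
                    return anc, sens
                _aug_deriv(pt, St, x3h, base, ktr, gamma, slope, kma, dp3, dS3)
                for i in range(5):
                    pt[i] = p[i] + hs * dp3[i]
                    for j in range(4):
                        St[i, j] = S[i, j] + hs * dS3[i, j]
                if pt[4] <= 0.0:
                    return anc, sens
                _aug_deriv(pt, St, x3f, base, ktr, gamma, slope, kma, dp4, dS4)
                for i in range(5):
                    p[i] += hs / 6.0 * (dp1[i] + 2.0 * dp2[i] + 2.0 * dp3[i] + dp4[i])
                    for j in range(4):
                        S[i, j] += hs / 6.0 * (dS1[i, j] + 2.0 * dS2[i, j]
                                               + 2.0 * dS3[i, j] + dS4[i, j])
                x1, x2, x3 = x1f, x2f, x3f
            t = te
            if p[4] <= 0.0:
                return anc, sens
        while i_o < nout and obs_t[i_o] <= t:
            anc[i_o] = p[4]
            for j in range(4):
                sens[i_o, j] = S[4, j]
            i_o += 1
        while i_d < nd and dose_t[i_d] <= t:
            x1 += bioav * dose_a[i_d]
            i_d += 1
    return anc, sens
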