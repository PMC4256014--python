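"""Numba-compiled inner loops for the tissue simulation.

The reaction substep mirrors :func:`retinawave.kinetics.reaction_rhs`
term-for-term (a consistency test enforces agreement with the numpy
reference); diffusion of the ACh field uses a locally one-dimensional
Crank-Nicolson scheme with zero-flux boundaries, sweep order alternating
per step to cancel directional bias at second order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# parameter vector layout used by the kernels
PVEC_KEYS = (
    "C", "E_K", "E_Ca", "E_leak", "E_ACh",
    "g_leak", "g_K", "g_Ca", "g_ACh", "g_noise",
    "m_half", "m_slope", "r_half", "r_slope", "rate_scale",
    "release_rate", "release_half", "release_steepness", "clearance_time",
    "half_saturation", "hill_coefficient",
    "tau_R", "tau_S", "kappa", "D", "s_half", "s_steepness", "release_exponent",
    "E_noise",
)


def pack_params(p) -> np.ndarray:
    E, g, gp, ap, st = (p.reversal_potentials, p.max_conductances,
                        p.gating_params, p.ach_params, p.sahp_times)
    return np.array([
        p.membrane_capacitance, E.E_K, E.E_Ca, E.E_leak, E.E_ACh,
        g.g_leak, g.g_K, g.g_Ca, g.g_ACh, g.g_noise,
        gp.m_half, gp.m_slope, gp.r_half, gp.r_slope, gp.rate_scale,
        ap.release_rate, ap.release_half, ap.release_steepness, ap.clearance_time,
        ap.half_saturation, ap.hill_coefficient,
        st.tau_R, st.tau_S, p.sahp_strength, p.diffusion_coefficient,
        gp.s_half, gp.s_steepness, ap.release_exponent, p.noise.reversal,
    ])


@njit(cache=True, fastmath=True)
def _rhs_scalar(v, r, s, a, pv, i_ext, noise_open):
    """Reaction right-hand side.

    Identical algebra to kinetics.reaction_rhs; sigmoids are evaluated in
    their logistic form  0.5*(1+tanh(x)) == 1/(1+exp(-2x))  and the Hill
    term avoids float pow for the common integer exponents.
    """
    (C, E_K, E_Ca, E_leak, E_ACh, g_leak, g_K, g_Ca, g_ACh, g_noise,
     m_half, m_slope, r_half, r_slope, rate_scale,
     release_rate, release_half, release_steepness, clearance_time,
     half_saturation, hill_n, tau_R, tau_S, kappa, D,
     s_half, s_steepness, release_exponent, E_noise) = pv
    zm = -2.0 * (v - m_half) / m_slope
    if zm > 500.0:
        zm = 500.0
    m_inf = 1.0 / (1.0 + np.exp(zm))
    zr = -2.0 * (v - r_half) / r_slope
    if zr > 500.0:
        zr = 500.0
    r_inf = 1.0 / (1.0 + np.exp(zr))
    arg = (v - r_half) / (2.0 * r_slope)
    if arg > 300.0:
        arg = 300.0
    elif arg < -300.0:
        arg = -300.0
    ea = np.exp(arg)
    tau_r = 2.0 / (rate_scale * (ea + 1.0 / ea))
    if hill_n == 2.0:
        an = a * a
        kn = half_saturation * half_saturation
    else:
        an = a ** hill_n
        kn = half_saturation ** hill_n
    g_a = g_ACh * an / (kn + an)
    z = -release_steepness * (v - release_half)
    if z > 500.0:
        z = 500.0
    elif z < -500.0:
        z = -500.0
    sig_rel = 1.0 / (1.0 + np.exp(z))
    if release_exponent == 2.0:
        rel = release_rate * sig_rel * sig_rel
    else:
        rel = release_rate * sig_rel ** release_exponent
    zs = -s_steepness * (v - s_half)
    if zs > 500.0:
        zs = 500.0
    elif zs < -500.0:
        zs = -500.0
    s_inf = 1.0 / (1.0 + np.exp(zs))
    i_n = g_noise * (E_noise - v) if noise_open else 0.0
    dv = (-g_leak * (v - E_leak) - g_Ca * m_inf * (v - E_Ca)
          - g_K * r * (v - E_K) - g_a * (v - E_ACh) + i_n + i_ext) / C
    dr = (r_inf + kappa * s - r) / tau_r
    ds = s_inf * (1.0 - s) / tau_R - s / tau_S
    da = rel - a / clearance_time
    return dv, dr, ds, da


@njit(cache=True)
def _any_nonfinite(V):
    n0, n1 = V.shape
    for i in range(n0):
        for j in range(n1):
            if not np.isfinite(V[i, j]):
                return True
    return False


@njit(cache=True, fastmath=True)
def heun_reaction_2d(V, R, S, A, chi, stim, pv, dt):
    """One explicit two-stage (Heun) reaction step, cell-wise, in place."""
    n0, n1 = V.shape
    for i in range(n0):
        for j in range(n1):
            v = V[i, j]; r = R[i, j]; s = S[i, j]; a = A[i, j]
            op = chi[i, j]
            dv1, dr1, ds1, da1 = _rhs_scalar(v, r, s, a, pv, stim[i, j], op)
            v1 = v + dt * dv1
            r1 = r + dt * dr1
            s1 = s + dt * ds1
            a1 = a + dt * da1
            if a1 < 0.0:
                a1 = 0.0
            dv2, dr2, ds2, da2 = _rhs_scalar(v1, r1, s1, a1, pv, stim[i, j], op)
            V[i, j] = v + 0.5 * dt * (dv1 + dv2)
            R[i, j] = r + 0.5 * dt * (dr1 + dr2)
            S[i, j] = s + 0.5 * dt * (ds1 + ds2)
            na = a + 0.5 * dt * (da1 + da2)
            A[i, j] = na if na > 0.0 else 0.0
    return 0


@njit(cache=True)
def lod_cn_2d(A, lam, order):
    """LOD Crank-Nicolson diffusion step on A (in place), zero-flux boundaries.

    lam = D*dt/dx^2; ``order`` 0 sweeps x then y, 1 sweeps y then x.
    """
    n = A.shape[0]
    a = np.empty(n); b = np.empty(n); c = np.empty(n); cp = np.empty(n)
    for k in range(n):
        a[k] = -0.5 * lam
        b[k] = 1.0 + lam
        c[k] = -0.5 * lam
    b[0] = 1.0 + 0.5 * lam
    b[n - 1] = 1.0 + 0.5 * lam
    a[0] = 0.0
    c[n - 1] = 0.0
    Y = np.empty((n, n))
    for sweep in range(2):
        axis = (sweep + order) % 2
        if axis == 0:
            for jj in range(n):
                Y[0, jj] = A[0, jj] + 0.5 * lam * (A[1, jj] - A[0, jj])
                Y[n - 1, jj] = A[n - 1, jj] + 0.5 * lam * (A[n - 2, jj] - A[n - 1, jj])
            for ii in range(1, n - 1):
                for jj in range(n):
                    Y[ii, jj] = A[ii, jj] + 0.5 * lam * (
                        A[ii + 1, jj] - 2.0 * A[ii, jj] + A[ii - 1, jj])
            for jj in range(n):
                cp[0] = c[0] / b[0]
                Y[0, jj] = Y[0, jj] / b[0]
                for ii in range(1, n):
                    denom = b[ii] - a[ii] * cp[ii - 1]
                    cp[ii] = c[ii] / denom
                    Y[ii, jj] = (Y[ii, jj] - a[ii] * Y[ii - 1, jj]) / denom
                for ii in range(n - 2, -1, -1):
                    Y[ii, jj] -= cp[ii] * Y[ii + 1, jj]
        else:
            for ii in range(n):
                Y[ii, 0] = A[ii, 0] + 0.5 * lam * (A[ii, 1] - A[ii, 0])
                Y[ii, n - 1] = A[ii, n - 1] + 0.5 * lam * (A[ii, n - 2] - A[ii, n - 1])
                for jj in range(1, n - 1):
                    Y[ii, jj] = A[ii, jj] + 0.5 * lam * (
                        A[ii, jj + 1] - 2.0 * A[ii, jj] + A[ii, jj - 1])
            for ii in range(n):
                cp[0] = c[0] / b[0]
                Y[ii, 0] = Y[ii, 0] / b[0]
                for jj in range(1, n):
                    denom = b[jj] - a[jj] * cp[jj - 1]
                    cp[jj] = c[jj] / denom
                    Y[ii, jj] = (Y[ii, jj] - a[jj] * Y[ii, jj - 1]) / denom
                for jj in range(n - 2, -1, -1):
                    Y[ii, jj] -= cp[jj] * Y[ii, jj + 1]
        for ii in range(n):
            for jj in range(n):
                A[ii, jj] = Y[ii, jj]
    return A


@njit(cache=True)
def lod_cn_1d(A, lam):
    """Crank-Nicolson diffusion step on a 1-D field, zero-flux boundaries."""
    n = A.shape[0]
    a = np.empty(n); b = np.empty(n); c = np.empty(n); cp = np.empty(n)
    for k in range(n):
        a[k] = -0.5 * lam
        b[k] = 1.0 + lam
        c[k] = -0.5 * lam
    b[0] = 1.0 + 0.5 * lam
    b[n - 1] = 1.0 + 0.5 * lam
    a[0] = 0.0
    c[n - 1] = 0.0
    y = np.empty(n)
    y[0] = A[0] + 0.5 * lam * (A[1] - A[0])
    y[n - 1] = A[n - 1] + 0.5 * lam * (A[n - 2] - A[n - 1])
    for i in range(1, n - 1):
        y[i] = A[i] + 0.5 * lam * (A[i + 1] - 2.0 * A[i] + A[i - 1])
    cp[0] = c[0] / b[0]
    y[0] = y[0] / b[0]
    for i in range(1, n):
        denom = b[i] - a[i] * cp[i - 1]
        cp[i] = c[i] / denom
        y[i] = (y[i] - a[i] * y[i - 1]) / denom
    for i in range(n - 2, -1, -1):
        y[i] -= cp[i] * y[i + 1]
    for i in range(n):
        A[i] = y[i]
    return A


@njit(cache=True)
def run_block_2d(V, R, S, A, chi, stim, pv, dt, nsteps, lam, step0):
    """Advance ``nsteps`` full (reaction + diffusion) steps; returns error flag.

    A 1 x n field is treated as a one-dimensional strip (single tridiagonal
    solve along the long axis); square fields use the LOD splitting.
    """
    one_d = A.shape[0] == 1
    for k in range(nsteps):
        heun_reaction_2d(V, R, S, A, chi, stim, pv, dt)
        if lam > 0.0:
            if one_d:
                lod_cn_1d(A[0], lam)
            else:
                lod_cn_2d(A, lam, (step0 + k) % 2)
    if _any_nonfinite(V):
        return nsteps
    return 0


@njit(cache=True)
def run_single_cell_loop(y0, pv, dt, nsteps, opens, noise_every, stim_series,
                         record_every):
    """0-D integration with the Bernoulli noise channel and event detection.

    ``opens`` is a pre-drawn boolean array with one entry per noise update.
    ``stim_series`` gives the injected current (pA) per step (length nsteps,
    may be a length-1 array meaning constant).  Records every
    ``record_every`` steps; returns (trace, n_events, event_times).
    """
    v, r, s, a = y0[0], y0[1], y0[2], y0[3]
    nrec = nsteps // record_every + 1
    out = np.empty((nrec, 4))
    out[0, 0] = v; out[0, 1] = r; out[0, 2] = s; out[0, 3] = a
    krec = 1
    ev = np.empty(100000)
    nev = 0
    vprev = v
    open_now = False
    for k in range(nsteps):
        if k % noise_every == 0:
            open_now = opens[k // noise_every]
        i_ext = stim_series[k] if stim_series.shape[0] > 1 else stim_series[0]
        dv1, dr1, ds1, da1 = _rhs_scalar(v, r, s, a, pv, i_ext, open_now)
        v1 = v + dt * dv1; r1 = r + dt * dr1; s1 = s + dt * ds1; a1 = a + dt * da1
        if a1 < 0.0:
            a1 = 0.0
        dv2, dr2, ds2, da2 = _rhs_scalar(v1, r1, s1, a1, pv, i_ext, open_now)
        v = v + 0.5 * dt * (dv1 + dv2)
        r = r + 0.5 * dt * (dr1 + dr2)
        s = s + 0.5 * dt * (ds1 + ds2)
        a = a + 0.5 * dt * (da1 + da2)
        if a < 0.0:
            a = 0.0
        if vprev <= -50.0 and v > -50.0 and nev < ev.shape[0]:
            ev[nev] = (k + 1) * dt
            nev += 1
        vprev = v
        if (k + 1) % record_every == 0 and krec < nrec:
            out[krec, 0] = v; out[krec, 1] = r; out[krec, 2] = s; out[krec, 3] = a
            krec += 1
    return out[:krec], nev, ev[:nev]
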