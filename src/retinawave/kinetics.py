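"""Single-cell reaction kinetics: gating functions, right-hand sides, rest state.

All functions are vectorised over the state fields, so the same code serves
the 0-D (single cell), 1-D (front) and 2-D (tissue) integrations.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .params import ModelParams, nondimensionalize

__all__ = [
    "gating_functions",
    "ach_conductance",
    "ach_release_rate",
    "sahp_activation",
    "reaction_rhs",
    "find_rest_state",
    "rest_state_stability",
]


def _check_finite(x, name: str) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite {name}")


def gating_functions(v, p: ModelParams):
    """Morris-Lecar auxiliary functions at voltage ``v`` (mV).

    Returns ``(m_inf, r_inf, tau_r)`` where ``m_inf`` is the instantaneous
    calcium activation, ``r_inf`` the steady state of the potassium gate and
    ``tau_r`` its voltage-dependent time constant in seconds (canonical
    1/cosh form, fastest far from the half-activation voltage).
    """
    _check_finite(v, "voltage")
    gp = p.gating_params
    v = np.asarray(v, dtype=float)
    m_inf = 0.5 * (1.0 + np.tanh((v - gp.m_half) / gp.m_slope))
    r_inf = 0.5 * (1.0 + np.tanh((v - gp.r_half) / gp.r_slope))
    arg = np.clip((v - gp.r_half) / (2.0 * gp.r_slope), -300.0, 300.0)
    tau_r = 1.0 / (gp.rate_scale * np.cosh(arg))
    return m_inf, r_inf, tau_r


def ach_conductance(a, p: ModelParams):
    """Hill-saturating nicotinic conductance (nS) at ACh concentration ``a`` (nM)."""
    a = np.asarray(a, dtype=float)
    _check_finite(a, "ACh concentration")
    if np.any(a < 0):
        raise ValueError("ACh concentration must be >= 0")
    ap = p.ach_params
    an = a ** ap.hill_coefficient
    return p.max_conductances.g_ACh * an / (ap.half_saturation ** ap.hill_coefficient + an)


def ach_release_rate(v, p: ModelParams):
    """Voltage-dependent ACh release rate (nM/s).

    A cooperative (squared-logistic) gate: release requires the coincident
    opening of the calcium machinery, so the rate rises as the square of a
    logistic with midpoint at the release threshold near -55 mV.
    """
    _check_finite(v, "voltage")
    ap = p.ach_params
    v = np.asarray(v, dtype=float)
    z = np.clip(-ap.release_steepness * (v - ap.release_half), -500.0, 500.0)
    return ap.release_rate * (1.0 / (1.0 + np.exp(z))) ** ap.release_exponent


def sahp_activation(v, p: ModelParams):
    """Steady-state sAHP drive in [0, 1] (logistic in v).

    The slow after-hyperpolarisation is built by calcium entering during a
    burst, so its drive turns on at burst voltages, somewhat above the ACh
    release threshold.
    """
    _check_finite(v, "voltage")
    gp = p.gating_params
    v = np.asarray(v, dtype=float)
    z = np.clip(-gp.s_steepness * (v - gp.s_half), -500.0, 500.0)
    return 1.0 / (1.0 + np.exp(z))


def reaction_rhs(x, p: ModelParams, i_ext=0.0, noise_open=False):
    """Local time derivatives of ``(v, r, s, a)``; diffusion excluded.

    ``x`` is a length-4 sequence of (possibly array-valued) fields.
    ``i_ext`` is an injected current in pA (nS x mV).  ``noise_open``
    selects the excitatory noise conductance contribution.
    """
    v, r, s, a = (np.asarray(c, dtype=float) for c in x)
    for name, c in (("r", r), ("s", s)):
        _check_finite(c, name)
    if np.any(r < -1e-9) or np.any(s < -1e-9):
        raise ValueError("invalid state: r and s must be non-negative")
    E, g = p.reversal_potentials, p.max_conductances
    m_inf, r_inf, tau_r = gating_functions(v, p)
    g_a = ach_conductance(a, p)
    i_noise = np.where(noise_open, g.g_noise * (p.noise.reversal - v), 0.0)
    dv = (
        -g.g_leak * (v - E.E_leak)
        - g.g_Ca * m_inf * (v - E.E_Ca)
        - g.g_K * r * (v - E.E_K)
        - g_a * (v - E.E_ACh)
        + i_noise
        + i_ext
    ) / p.membrane_capacitance
    dr = (r_inf + p.sahp_strength * s - r) / tau_r
    s_inf = sahp_activation(v, p)
    dsdt = s_inf * (1.0 - s) / p.sahp_times.tau_R - s / p.sahp_times.tau_S
    da = ach_release_rate(v, p) - a / p.ach_params.clearance_time
    return np.array([dv, dr, dsdt, da])


def _rest_residual(v, p: ModelParams):
    """Voltage equation residual with r, s, a at their v-conditional steady states."""
    _, r_inf, _ = gating_functions(v, p)
    s_inf = sahp_activation(v, p)
    st = p.sahp_times
    s_eq = (s_inf / st.tau_R) / (s_inf / st.tau_R + 1.0 / st.tau_S)
    r_eq = r_inf + p.sahp_strength * s_eq
    a_eq = ach_release_rate(v, p) * p.ach_params.clearance_time
    x = np.array([v, r_eq, s_eq, a_eq])
    return reaction_rhs(x, p)[0], x


def find_rest_state(p: ModelParams, v_lo: float = -95.0, v_hi: float = -50.0):
    """Hyperpolarised fixed point of the local kinetics.

    Solves the one-dimensional reduced residual (the three gating fields are
    slaved to v at a fixed point) by bracketing and bisection, then verifies
    the full four-dimensional residual.
    """
    f = lambda v: _rest_residual(v, p)[0]
    vs = np.linspace(v_lo, v_hi, 200)
    fs = np.array([f(v) for v in vs])
    sign_change = np.where(np.sign(fs[:-1]) * np.sign(fs[1:]) < 0)[0]
    if len(sign_change) == 0:
        raise RuntimeError("no rest state found in bracket; parameters may not "
                           "support a hyperpolarised fixed point")
    i = sign_change[0]
    v0 = brentq(f, vs[i], vs[i + 1], xtol=1e-12)
    _, x0 = _rest_residual(v0, p)
    resid = reaction_rhs(x0, p)
    if np.max(np.abs(resid)) > 1e-6:
        raise RuntimeError(f"rest state residual too large: {resid}")
    return x0


def _jacobian(x, p: ModelParams, h: float = 1e-6):
    x = np.asarray(x, dtype=float)
    J = np.empty((4, 4))
    f0 = reaction_rhs(x, p)
    for j in range(4):
        dx = np.zeros(4)
        dx[j] = h * max(1.0, abs(x[j]))
        J[:, j] = (reaction_rhs(x + dx, p) - reaction_rhs(x - dx, p)) / (2 * dx[j])
    return J


def rest_state_stability(p: ModelParams, x0=None):
    """Eigenvalues of the linearisation at the rest state; stable iff Re < 0."""
    if x0 is None:
        x0 = find_rest_state(p)
    eig = np.linalg.eigvals(_jacobian(x0, p))
    return eig, bool(np.all(eig.real < 0))
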