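"""Singular-perturbation front analysis.

The sAHP level ``s`` evolves far more slowly than the membrane, gate and
ACh fields, so the propagation problem is analysed in the *fast subsystem*:
the three fast fields (v, r, a) with ``s`` frozen as a parameter.  A planar
front then connects the rest and excited spatially-uniform fixed points,
and its signed speed c(s) decides whether activity invades (c > 0) or
recedes (c < 0).  c(s) is computed two independent ways: by relaxation of
the 1-D initial-value problem, and by solving the moving-frame boundary
value problem for the heteroclinic profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_bvp
from scipy.optimize import brentq

from .kinetics import (ach_conductance, ach_release_rate, find_rest_state,
                       gating_functions, sahp_activation)
from .params import ModelParams, nondimensionalize
from .simulator import run_front_1d, run_simulation, SimConfig

__all__ = [
    "FrontSolution",
    "fast_rhs",
    "fast_fixed_points",
    "front_speed_relaxation",
    "front_profile_bvp",
    "speed_vs_refractory",
    "excitability_threshold_curve",
    "excitability_by_simulation",
    "absolute_refractory_period",
]


def fast_rhs(v, r, a, s, p: ModelParams):
    """Kinetics of the fast (v, r, a) subsystem at frozen sAHP level s."""
    E, g = p.reversal_potentials, p.max_conductances
    m_inf, r_inf, tau_r = gating_functions(v, p)
    g_a = ach_conductance(np.maximum(a, 0.0), p)
    dv = (-g.g_leak * (v - E.E_leak) - g.g_Ca * m_inf * (v - E.E_Ca)
          - g.g_K * r * (v - E.E_K) - g_a * (v - E.E_ACh)) / p.membrane_capacitance
    dr = (r_inf + p.sahp_strength * s - r) / tau_r
    da = ach_release_rate(v, p) - a / p.ach_params.clearance_time
    return dv, dr, da


def _fast_v_residual(v, s, p):
    """Voltage nullcline residual with r and a slaved to v."""
    _, r_inf, _ = gating_functions(v, p)
    r = r_inf + p.sahp_strength * s
    a = ach_release_rate(v, p) * p.ach_params.clearance_time
    dv, _, _ = fast_rhs(v, r, a, s, p)
    return dv


def _fast_jacobian(x, s, p, h=1e-6):
    J = np.empty((3, 3))
    f0 = np.array(fast_rhs(*x, s, p))
    for j in range(3):
        dx = np.zeros(3)
        dx[j] = h * max(1.0, abs(x[j]))
        fp = np.array(fast_rhs(*(x + dx), s, p))
        fm = np.array(fast_rhs(*(x - dx), s, p))
        J[:, j] = (fp - fm) / (2 * dx[j])
    return J


def fast_fixed_points(s: float, p: ModelParams, v_range=(-95.0, 45.0),
                      nscan: int = 600):
    """Spatially uniform fixed points of the fast subsystem at frozen s.

    Returns a list of dicts with the state, eigenvalues and a stability tag,
    ordered by voltage (rest first, excited last; a saddle between when the
    subsystem is bistable).
    """
    vs = np.linspace(*v_range, nscan)
    res = np.array([_fast_v_residual(v, s, p) for v in vs])
    roots = []
    for i in np.where(np.sign(res[:-1]) * np.sign(res[1:]) < 0)[0]:
        v0 = brentq(lambda v: _fast_v_residual(v, s, p), vs[i], vs[i + 1],
                    xtol=1e-12)
        _, r_inf, _ = gating_functions(v0, p)
        x = np.array([v0, float(r_inf + p.sahp_strength * s),
                      float(ach_release_rate(v0, p) * p.ach_params.clearance_time)])
        eig = np.linalg.eigvals(_fast_jacobian(x, s, p))
        roots.append({
            "state": x,
            "eigenvalues": eig,
            "stable": bool(np.all(eig.real < 0)),
        })
    return roots


def front_speed_relaxation(s: float, p: ModelParams, n: int = 512,
                           length: float = 8.0, duration: float = 50.0,
                           dt: float = 1e-3):
    """Signed front speed c(s) (mm/s) from a 1-D fast-subsystem relaxation run.

    Positive speed means the excited region invades the rest state.
    Receding fronts are detected by tracking the retreat of the excited
    region; if the excited region collapses entirely the speed is measured
    from its shrink rate while it lasts.
    """
    fps = fast_fixed_points(s, p)
    stable = [f for f in fps if f["stable"]]
    if len(stable) < 2:
        return {"speed": np.nan, "status": "no-front", "fixed_points": fps}
    out = run_front_1d(p, frozen_s=s, n=n, length=length, duration=duration,
                       dt=dt)
    if np.isnan(out["speed"]):
        # receding: fit the shrinking excited-region edge while it exists
        t, pos = out["times"], out["positions"]
        ok = ~np.isnan(pos)
        if ok.sum() >= 5:
            tt, pp = t[ok], pos[ok]
            use = tt > 0.1 * tt[-1]
            if use.sum() >= 3:
                speed = float(np.polyfit(tt[use], pp[use], 1)[0])
                return {"speed": min(speed, 0.0), "status": "receding",
                        "fixed_points": fps, "run": out}
        return {"speed": np.nan, "status": "receding", "fixed_points": fps,
                "run": out}
    return {"speed": out["speed"], "status": out["status"],
            "fixed_points": fps, "run": out}


@dataclass
class FrontSolution:
    xi: np.ndarray  # moving-frame coordinate, mm
    v: np.ndarray
    r: np.ndarray
    a: np.ndarray
    da: np.ndarray  # spatial derivative of a
    speed: float  # mm/s
    frozen_s: float
    rest: np.ndarray
    excited: np.ndarray
    residual: float


def front_profile_bvp(s: float, p: ModelParams, c_init: float,
                      relaxation: dict | None = None, profile_init=None,
                      length: float = 1.0, npts: int = 600,
                      tol: float = 1e-6, max_iter: int = 60,
                      _retry=None) -> FrontSolution:
    """Moving-frame refinement of the traveling front by damped Newton.

    In the frame xi = x - c t the stationary profile satisfies
        c v' = -F_v,   c r' = -F_r,   D a'' + c a' + F_a = 0,
    a heteroclinic orbit from the excited fixed point (xi -> -inf) to the
    rest fixed point (xi -> +inf).  The equations are discretised with a
    one-sided (upwind) first derivative for v and r and central differences
    for a on a uniform grid; the unknowns are the three profiles plus the
    speed c, closed by a phase condition pinning the voltage midpoint at the
    grid centre.  A damped Newton iteration with a sparse banded Jacobian
    solves the system, seeded by a relaxation run.
    """
    from scipy import sparse
    from scipy.sparse.linalg import spsolve

    fps = fast_fixed_points(s, p)
    stable = [f for f in fps if f["stable"]]
    if len(stable) < 2:
        raise RuntimeError("fast subsystem not bistable at this s")
    rest = stable[0]["state"]
    excited = stable[-1]["state"]
    D = p.diffusion_coefficient
    if _retry is None:
        # progressively finer grids / damped speed guesses if Newton stalls
        last = None
        for (fac_n, fac_c) in ((1.0, 1.0), (2.0, 1.0), (2.0, 0.9), (1.5, 1.1)):
            try:
                return front_profile_bvp(
                    s, p, c_init * fac_c, relaxation=relaxation,
                    profile_init=profile_init, length=length,
                    npts=int(npts * fac_n), tol=tol, max_iter=max_iter,
                    _retry=False)
            except RuntimeError as exc:
                last = exc
        raise last
    n = npts
    xi = np.linspace(-length / 2, length / 2, n)
    h = xi[1] - xi[0]
    mid_level = 0.5 * (rest[0] + excited[0])
    i_mid = n // 2

    # initial guess
    if profile_init is not None:
        v0, r0, a0 = profile_init(xi)
    elif relaxation is not None and "profile" in relaxation.get("run", {}):
        prof = relaxation["run"]["profile"]
        x, vv = prof["x"], prof["v"]
        cross = np.where((vv[:-1] > mid_level) & (vv[1:] <= mid_level))[0]
        x0 = x[cross[0]] if len(cross) else x[len(x) // 2]
        xs = x - x0
        v0 = np.interp(xi, xs, prof["v"], left=excited[0], right=rest[0])
        r0 = np.interp(xi, xs, prof["r"], left=excited[1], right=rest[1])
        a0 = np.interp(xi, xs, prof["a"], left=excited[2], right=rest[2])
    else:
        sig = 1.0 / (1.0 + np.exp(xi / (0.03 * length)))
        v0 = rest[0] + (excited[0] - rest[0]) * sig
        r0 = rest[1] + (excited[1] - rest[1]) * sig
        a0 = rest[2] + (excited[2] - rest[2]) * sig

    scale = np.concatenate([np.full(n, 100.0), np.full(n, 1.0),
                            np.full(n, max(p.ach_params.half_saturation, 1.0)),
                            [1.0]])

    def residual(u):
        v, r, a, c = u[:n], u[n:2 * n], u[2 * n:3 * n], u[3 * n]
        dv, dr, da = fast_rhs(v, np.maximum(r, 0.0), np.maximum(a, 0.0), s, p)
        res_v = np.empty(n); res_r = np.empty(n); res_a = np.empty(n)
        # upwind first derivative (information flows from the rest side)
        res_v[:-1] = c * (v[1:] - v[:-1]) / h + dv[:-1]
        res_r[:-1] = c * (r[1:] - r[:-1]) / h + dr[:-1]
        res_v[-1] = v[-1] - rest[0]
        res_r[-1] = r[-1] - rest[1]
        res_a[1:-1] = (D * (a[2:] - 2 * a[1:-1] + a[:-2]) / h ** 2
                       + c * (a[2:] - a[:-2]) / (2 * h) + da[1:-1])
        res_a[0] = a[1] - a[0]
        res_a[-1] = a[-1] - a[-2]
        phase = v[i_mid] - mid_level
        return np.concatenate([res_v, res_r, res_a, [phase]])

    def jacobian(u):
        f0 = residual(u)
        cols, data, rows = [], [], []
        N = 3 * n + 1
        # grouped finite differences: unknowns at grid distance > 2 are
        # independent, so 3 groups per field (+1 for c) cover the Jacobian
        J = sparse.lil_matrix((N, N))
        for block in range(3):
            for offset in range(3):
                du = np.zeros(N)
                idx = np.arange(offset, n, 3) + block * n
                step = 1e-6 * scale[idx]
                du[idx] = step
                f1 = residual(u + du)
                diff = (f1 - f0)
                for k, i_col in enumerate(idx):
                    # rows affected: within +/-2 grid points in every field
                    gi = i_col - block * n
                    for fb in range(3):
                        for g in range(max(0, gi - 1), min(n, gi + 2)):
                            r_row = fb * n + g
                            if diff[r_row] != 0.0:
                                J[r_row, i_col] = diff[r_row] / step[k]
                    if diff[N - 1] != 0.0:
                        J[N - 1, i_col] = diff[N - 1] / step[k]
        du = np.zeros(N); du[N - 1] = 1e-8
        f1 = residual(u + du)
        J[:, N - 1] = ((f1 - f0) / 1e-8)[:, None]
        return J.tocsr(), f0

    wt = np.concatenate([np.full(n, 1e3), np.full(n, 10.0),
                         np.full(n, 1e4), [1.0]])
    u = np.concatenate([v0, r0, a0, [c_init]])
    norm_prev = np.inf
    for it in range(max_iter):
        J, f0 = jacobian(u)
        norm0 = np.max(np.abs(f0 / wt))
        if norm0 < tol:
            break
        if norm0 < 1e-5 and norm0 > 0.5 * norm_prev:
            break  # finite-difference Jacobian precision floor
        norm_prev = norm0
        try:
            step = spsolve(J, -f0)
        except Exception as exc:
            raise RuntimeError(f"Newton linear solve failed: {exc}")
        lam = 1.0
        for _ in range(16):
            f1 = residual(u + lam * step)
            if np.linalg.norm(f1 / wt) < np.linalg.norm(f0 / wt):
                break
            lam *= 0.5
        else:
            raise RuntimeError(
                f"Newton damping failed at iteration {it}; residual {norm0:.3g}")
        u = u + lam * step
    else:
        if norm0 > 1e-4:
            raise RuntimeError(f"Newton did not converge; residual {norm0:.3g}")
    v, r, a, c = u[:n], u[n:2 * n], u[2 * n:3 * n], float(u[3 * n])
    f_final = residual(u)
    resid = float(np.max(np.abs(f_final / np.concatenate(
        [np.full(n, 1e3), np.full(n, 10.0), np.full(n, 1e4), [1.0]]))))
    return FrontSolution(xi=xi, v=v, r=r, a=a,
                         da=np.gradient(a, xi), speed=c, frozen_s=s,
                         rest=rest, excited=excited, residual=resid)


def speed_vs_refractory(p: ModelParams, s_grid, refine_root: bool = True,
                        **relax_kw):
    """c(s) over a grid of frozen sAHP levels, plus the root s* of c(s*)=0.

    The root is bracketed on the grid and refined by bisection on the
    relaxation speed.
    """
    speeds = []
    for s in s_grid:
        out = front_speed_relaxation(s, p, **relax_kw)
        speeds.append(out["speed"])
    speeds = np.asarray(speeds)
    s_grid = np.asarray(s_grid, dtype=float)
    s_star = np.nan
    # propagation stops either where c crosses zero or where the bistable
    # structure disappears entirely; both count as blocked for the bracketing
    eff = np.where(np.isfinite(speeds), speeds, -1.0)
    sign_change = np.where((eff[:-1] > 0) & (eff[1:] <= 0))[0]
    if len(sign_change):
        lo, hi = s_grid[sign_change[0]], s_grid[sign_change[0] + 1]
        if refine_root:
            for _ in range(8):
                mid = 0.5 * (lo + hi)
                cm = front_speed_relaxation(mid, p, **relax_kw)["speed"]
                if np.isfinite(cm) and cm > 0:
                    lo = mid
                else:
                    hi = mid
        s_star = 0.5 * (lo + hi)
    return {"s": s_grid, "c": speeds, "s_star": float(s_star)}


def excitability_threshold_curve(p: ModelParams, g_K_values,
                                 g_ACh_bounds=(1.0, 80.0), tol_c: float = 5e-3,
                                 **relax_kw):
    """Excitability threshold in the (g_K, g_ACh) conductance plane.

    For each potassium conductance, bisect on the ACh conductance for the
    transition between propagating and receding fronts at s = 0.  Points
    above the returned curve are excitable.
    """
    out = []
    for gk in g_K_values:
        q = p.replace()
        q.max_conductances.g_K = float(gk)

        def cspeed(ga):
            q.max_conductances.g_ACh = float(ga)
            c = front_speed_relaxation(0.0, q, **relax_kw)["speed"]
            return -1.0 if not np.isfinite(c) else c

        lo, hi = g_ACh_bounds
        clo, chi = cspeed(lo), cspeed(hi)
        if clo > 0:
            out.append((gk, lo, "below-range"))
            continue
        if chi < 0:
            out.append((gk, np.nan, "open"))
            continue
        for _ in range(20):
            mid = 0.5 * (lo + hi)
            cm = cspeed(mid)
            if abs(cm) < tol_c and abs(hi - lo) < 0.05 * mid:
                break
            if cm > 0:
                hi = mid
            else:
                lo = mid
        out.append((gk, 0.5 * (lo + hi), "ok"))
    return out


def excitability_by_simulation(p: ModelParams, horizon: float = 25.0,
                               init: str = "strip", grid_n: int = 64,
                               excited_threshold: float = -40.0,
                               timescale: float = 1.0,
                               dimensionality: int = 2) -> bool:
    """Noise-free propagation test: excite one side, watch the far side.

    ``timescale`` multiplies the slow sAHP time constants (larger values
    approach the singular fast/slow limit).  Returns True iff activity above
    the excited threshold reaches the far 10% of the domain within the
    horizon (the default horizon covers the domain at ~0.1 mm/s).
    """
    q = p.replace()
    q.noise.open_probability_rate = 0.0
    q.sahp_times.tau_R = p.sahp_times.tau_R * timescale
    q.sahp_times.tau_S = p.sahp_times.tau_S * timescale
    cfg = SimConfig(duration=horizon, warmup=0.0, grid_n=grid_n,
                    snapshot_interval=0.05, seed=0, init=init,
                    dimensionality=dimensionality)
    snap = run_simulation(cfg, q)
    far = snap.v[:, :, -grid_n // 10:]
    return bool((far > excited_threshold).any())


def absolute_refractory_period(p: ModelParams, s_star: float | None = None,
                               s_grid=None, stim_amp: float = 400.0,
                               stim_dur: float = 1.0, horizon: float = 200.0):
    """Time after a burst during which the cell cannot support a wave.

    The cell is driven through a standard burst; the period is the time from
    burst end until its sAHP level first falls below the propagation
    threshold s* (where c(s*) = 0).  Returns (period_s, s_star).
    """
    from .simulator import run_single_cell, StimulusProtocol

    if s_star is None:
        if s_grid is None:
            s_grid = np.linspace(0.0, 0.35, 8)
        s_star = speed_vs_refractory(p, s_grid)["s_star"]
    if not np.isfinite(s_star):
        raise RuntimeError("no propagation threshold s* found")
    proto = StimulusProtocol([(1.0, stim_dur, stim_amp, None)])
    times, trace, _ = run_single_cell(p, protocol=proto,
                                      duration=horizon, noise=False)
    s = trace[:, 2]
    t_end = 1.0 + stim_dur
    after = times >= t_end
    if s[after].max() < s_star:
        import warnings
        warnings.warn("sAHP never exceeds s*; refractory period is zero")
        return 0.0, float(s_star)
    peak_idx = np.argmax(s)
    below = np.where(after & (np.arange(len(s)) > peak_idx) & (s < s_star))[0]
    if len(below) == 0:
        return float("inf"), float(s_star)
    return float(times[below[0]] - t_end), float(s_star)
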