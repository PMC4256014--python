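"""Tissue and single-cell integration of the stochastic reaction-diffusion model.

Time stepping follows an operator-splitting scheme: the local reaction terms
advance with an explicit two-stage Runge-Kutta (Heun) step and the ACh
diffusion advances with a locally one-dimensional Crank-Nicolson step,
both at a fixed 1 ms step by default.  The stochastic excitatory channel is
redrawn every 10 ms as an independent Bernoulli variable per cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import solve_banded

from . import _kernels
from .io import SnapshotSeries, params_hash
from .kinetics import find_rest_state
from .params import ModelParams

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "StimulusProtocol",
    "NumericalBlowup",
    "step_reaction",
    "step_diffusion",
    "update_noise",
    "run_simulation",
    "run_single_cell",
    "run_front_1d",
    "calibrate_noise_rate",
]


class NumericalBlowup(RuntimeError):
    def __init__(self, t):
        super().__init__(f"non-finite field at t = {t:.4f} s")
        self.time = t


@dataclass
class SimConfig:
    """Configuration of a tissue simulation."""

    duration: float = 500.0  # s, recorded time after warmup
    warmup: float = 500.0  # s, discarded
    dt: float = 1e-3  # s
    noise_update_interval: float = 0.01  # s
    snapshot_interval: float = 0.01  # s
    grid_n: int = 64
    domain_length: float = 2.0  # mm
    seed: int = 0
    dimensionality: int = 2  # 2-D sheet or 1-D strip
    record_fields: bool = False  # store all four fields, every fields_stride-th
    fields_stride: int = 10      # snapshot (0.1 s cadence by default)
    record_noise_mask: bool = False
    init: str = "rest"  # 'rest' | 'strip' | 'point'
    init_width: int = 4  # cells, for strip/point initial data

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        for name in ("snapshot_interval", "noise_update_interval"):
            ratio = getattr(self, name) / self.dt
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(f"{name} must be an integer multiple of dt")
        if self.dimensionality not in (1, 2):
            raise ValueError("dimensionality must be 1 or 2")

    @property
    def dx(self) -> float:
        return self.domain_length / self.grid_n


@dataclass
class StimulusProtocol:
    """Sequence of current injections: (start s, duration s, amplitude pA, cells).

    ``cells`` is ``None`` (all cells), an index pair, or a boolean mask.
    Episodes targeting a common cell must not overlap in time.
    """

    episodes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for (t0, dur, amp, _cells) in self.episodes:
            if dur <= 0:
                raise ValueError("stimulus durations must be > 0")
        spans = sorted((t0, t0 + dur) for t0, dur, _a, _c in self.episodes)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                # overlap is only an error if the episodes share cells; the
                # conservative check rejects all overlaps for None targets
                targets = [c for _t, _d, _a, c in self.episodes]
                if any(c is None for c in targets):
                    raise ValueError("overlapping stimulus episodes")

    def current_at(self, t: float, shape) -> np.ndarray:
        stim = np.zeros(shape)
        for (t0, dur, amp, cells) in self.episodes:
            if t0 <= t < t0 + dur:
                if cells is None:
                    stim += amp
                elif isinstance(cells, np.ndarray) and cells.dtype == bool:
                    stim[cells] += amp
                else:
                    stim[tuple(cells)] += amp
        return stim


# ----------------------------------------------------------------- reference ops

def step_reaction(fields, p: ModelParams, dt: float, stim=None, noise_mask=None):
    """Reference (numpy) Heun step of the reaction terms; no spatial coupling.

    ``fields`` is a tuple ``(v, r, s, a)`` of equally-shaped arrays; returns
    the stepped tuple.  The numba production kernel must agree with this to
    rounding error.
    """
    from .kinetics import reaction_rhs

    v, r, s, a = (np.array(f, dtype=float) for f in fields)
    stim = np.zeros_like(v) if stim is None else stim
    noise = np.zeros_like(v, dtype=bool) if noise_mask is None else noise_mask
    x = np.array([v, r, s, a])
    k1 = reaction_rhs(x, p, i_ext=stim, noise_open=noise)
    x1 = x + dt * k1
    x1[3] = np.maximum(x1[3], 0.0)
    k2 = reaction_rhs(x1, p, i_ext=stim, noise_open=noise)
    out = x + 0.5 * dt * (k1 + k2)
    out[3] = np.maximum(out[3], 0.0)
    if not np.all(np.isfinite(out)):
        raise NumericalBlowup(0.0)
    return tuple(out)


def _cn_matrix(n: int, lam: float):
    ab = np.zeros((3, n))
    ab[0, 1:] = -0.5 * lam
    ab[1, :] = 1.0 + lam
    ab[1, 0] = ab[1, -1] = 1.0 + 0.5 * lam
    ab[2, :-1] = -0.5 * lam
    return ab


def step_diffusion(a_field: np.ndarray, D: float, dt: float, dx: float,
                   order: int = 0) -> np.ndarray:
    """Reference Crank-Nicolson diffusion step with zero-flux boundaries.

    2-D fields use the locally one-dimensional splitting (x then y for
    ``order`` 0, swapped for 1); 1-D fields use a single solve.  Mass is
    conserved to rounding error.
    """
    if dt <= 0 or dx <= 0:
        raise ValueError("dt and dx must be positive")
    a = np.array(a_field, dtype=float)
    lam = D * dt / dx**2
    if lam == 0:
        return a
    n = a.shape[0]
    ab = _cn_matrix(n, lam)

    def sweep(x, axis):
        x = np.moveaxis(x, axis, 0)
        rhs = np.empty_like(x)
        rhs[1:-1] = x[1:-1] + 0.5 * lam * (x[2:] - 2 * x[1:-1] + x[:-2])
        rhs[0] = x[0] + 0.5 * lam * (x[1] - x[0])
        rhs[-1] = x[-1] + 0.5 * lam * (x[-2] - x[-1])
        sol = solve_banded((1, 1), ab, rhs.reshape(n, -1)).reshape(x.shape)
        return np.moveaxis(sol, 0, axis)

    if a.ndim == 1:
        return sweep(a, 0)
    axes = (0, 1) if order % 2 == 0 else (1, 0)
    for ax in axes:
        a = sweep(a, ax)
    return a


def update_noise(mask: np.ndarray, p: ModelParams, rng: np.random.Generator):
    """Redraw the Bernoulli channel mask for one noise interval."""
    prob = p.noise.open_probability_rate * p.noise.update_interval
    if not (0.0 <= prob <= 1.0):
        raise ValueError(f"opening probability {prob} outside [0, 1]")
    return rng.random(mask.shape) < prob


# ----------------------------------------------------------------- full runs

def _initial_fields(cfg: SimConfig, p: ModelParams):
    x0 = find_rest_state(p)
    shape = (cfg.grid_n, cfg.grid_n) if cfg.dimensionality == 2 else (1, cfg.grid_n)
    V = np.full(shape, x0[0])
    R = np.full(shape, x0[1])
    S = np.full(shape, x0[2])
    A = np.full(shape, x0[3])
    if cfg.init == "strip":
        V[:, : cfg.init_width] = 0.0
        A[:, : cfg.init_width] = 1000.0
    elif cfg.init == "point":
        c = cfg.grid_n // 2
        w = cfg.init_width
        if cfg.dimensionality == 2:
            V[c - w:c + w, 0:2 * w] = 0.0
            A[c - w:c + w, 0:2 * w] = 1000.0
        else:
            V[:, :2 * w] = 0.0
            A[:, :2 * w] = 1000.0
    elif cfg.init != "rest":
        raise ValueError(f"unknown init {cfg.init!r}")
    return V, R, S, A


def run_simulation(cfg: SimConfig, p: ModelParams,
                   protocol: StimulusProtocol | None = None) -> SnapshotSeries:
    """Integrate the tissue model and return the recorded snapshot series.

    The warmup period is integrated and discarded; snapshots are collected at
    ``cfg.snapshot_interval``.  Identical (cfg, params, seed) produce a
    bit-identical series.
    """
    rng = np.random.default_rng(cfg.seed)
    pv = _kernels.pack_params(p)
    V, R, S, A = _initial_fields(cfg, p)
    n_noise = int(round(cfg.noise_update_interval / cfg.dt))
    n_snap = int(round(cfg.snapshot_interval / cfg.dt))
    # block = one noise interval; snapshots must align with block boundaries
    if n_snap % n_noise and n_noise % n_snap:
        raise ValueError("snapshot_interval must divide or contain noise interval")
    lam = p.diffusion_coefficient * cfg.dt / cfg.dx**2
    prob = p.noise.open_probability_rate * p.noise.update_interval
    if not (0.0 <= prob <= 1.0):
        raise ValueError("noise opening probability outside [0, 1]")
    total_steps = int(round((cfg.warmup + cfg.duration) / cfg.dt))
    warm_steps = int(round(cfg.warmup / cfg.dt))
    chi = np.zeros(V.shape, dtype=bool)
    stim0 = np.zeros(V.shape)
    times, vs, rs, ss, as_, masks = [], [], [], [], [], []
    step = 0
    isnap = 0
    while step < total_steps:
        if step % n_noise == 0:
            chi = update_noise(chi, p, rng)
        if protocol is not None:
            stim = protocol.current_at(step * cfg.dt, V.shape)
        else:
            stim = stim0
        nblock = min(n_noise - (step % n_noise), n_snap - (step % n_snap),
                     total_steps - step)
        err = _kernels.run_block_2d(V, R, S, A, chi, stim, pv, cfg.dt, nblock,
                                    lam, step)
        if err:
            raise NumericalBlowup((step + err) * cfg.dt)
        step += nblock
        if step % n_snap == 0 and step > warm_steps:
            t = step * cfg.dt
            if cfg.record_fields and isnap % cfg.fields_stride != 0:
                isnap += 1
            else:
                times.append(t)
                vs.append(V.astype(np.float32))
                if cfg.record_fields:
                    rs.append(R.astype(np.float32))
                    ss.append(S.astype(np.float32))
                    as_.append(A.astype(np.float32))
                if cfg.record_noise_mask:
                    masks.append(chi.copy())
                isnap += 1
    meta = {
        "config": {k: (v if not isinstance(v, np.ndarray) else None)
                   for k, v in vars(cfg).items()},
        "params_hash": params_hash(p),
        "params": p.to_dict(),
        "seed": cfg.seed,
    }
    return SnapshotSeries(
        times=np.array(times),
        v=np.stack(vs),
        r=np.stack(rs) if rs else None,
        s=np.stack(ss) if ss else None,
        a=np.stack(as_) if as_ else None,
        noise_mask=np.stack(masks) if masks else None,
        domain_length=cfg.domain_length,
        meta=meta,
    )


def run_single_cell(p: ModelParams, protocol: StimulusProtocol | None = None,
                    duration: float = 100.0, noise: bool = False,
                    seed: int = 0, dt: float = 1e-3, record_every: int = 10,
                    init=None):
    """0-D integration (no diffusion); returns (times, states, event_times).

    Events are upward crossings of -50 mV, the detection threshold used for
    spontaneous depolarisations.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    pv = _kernels.pack_params(p)
    y0 = np.asarray(init if init is not None else find_rest_state(p), dtype=float)
    nsteps = int(round(duration / dt))
    n_noise = int(round(p.noise.update_interval / dt))
    nupd = nsteps // n_noise + 1
    prob = p.noise.open_probability_rate * p.noise.update_interval if noise else 0.0
    opens = rng.random(nupd) < prob
    if protocol is None:
        stim_series = np.zeros(1)
    else:
        tgrid = np.arange(nsteps) * dt
        stim_series = np.zeros(nsteps)
        for (t0, dur, amp, _cells) in protocol.episodes:
            stim_series[(tgrid >= t0) & (tgrid < t0 + dur)] += amp
    trace, nev, evt = _kernels.run_single_cell_loop(
        y0, pv, dt, nsteps, opens, n_noise, stim_series, record_every)
    times = np.arange(len(trace)) * dt * record_every
    return times, trace, np.asarray(evt)


def calibrate_noise_rate(p: ModelParams, target_interval: float = 900.0,
                         trial: float = 3000.0, seeds=(0, 1, 2, 3),
                         rates=None):
    """Pick the Bernoulli rate whose mean inter-event interval is closest to
    ``target_interval`` (s) in single-cell simulation."""
    rates = rates if rates is not None else [0.15, 0.2, 0.3, 0.45, 0.6]
    best, best_err = p.noise.open_probability_rate, np.inf
    for rate in rates:
        q = p.replace(noise={"open_probability_rate": rate,
                             "update_interval": p.noise.update_interval})
        events = 0
        for s in seeds:
            _, _, evt = run_single_cell(q, duration=trial, noise=True, seed=s)
            events += len(evt)
        if events == 0:
            continue
        interval = trial * len(seeds) / events
        err = abs(np.log(interval / target_interval))
        if err < best_err:
            best, best_err = rate, err
    return best


def run_front_1d(p: ModelParams, frozen_s: float | None = None,
                 n: int = 512, length: float = 8.0, duration: float = 40.0,
                 dt: float = 1e-3, level: float | None = None):
    """Propagate a planar front in 1-D and measure its asymptotic speed.

    With ``frozen_s`` set, the slow sAHP field is clamped at that value
    (the fast-subsystem configuration); otherwise s evolves freely.
    Returns a dict with ``speed`` (mm/s, signed; positive = excited region
    grows), ``status`` ('propagating' | 'receding'), and the final profile.
    """
    from .kinetics import find_rest_state

    x0 = find_rest_state(p)
    dx = length / n
    V = np.full(n, x0[0]); R = np.full(n, x0[1])
    S = np.full(n, frozen_s if frozen_s is not None else x0[2])
    A = np.full(n, x0[3])
    # sigmoid initial front between excited (left) and rest (right)
    xx = np.arange(n) * dx
    wfrac = 0.08 * length
    sig = 1.0 / (1.0 + np.exp((xx - 0.15 * length) / (0.02 * length)))
    V = x0[0] + (0.0 - x0[0]) * sig
    A = x0[3] + (1000.0 - x0[3]) * sig
    pv = _kernels.pack_params(p)
    lam = p.diffusion_coefficient * dt / dx**2
    if level is None:
        level = 0.5 * (x0[0] + 0.0)  # midpoint between rest and excited v
    chi = np.zeros((1, n), dtype=bool)
    stim = np.zeros((1, n))
    nsteps = int(round(duration / dt))
    times, pos = [], []
    Vv = V[None, :].copy(); Rr = R[None, :].copy()
    Ss = S[None, :].copy(); Aa = A[None, :].copy()
    freeze = frozen_s is not None
    sample = max(1, int(round(0.25 / dt)))
    mid_profile = None
    for k in range(nsteps):
        err = _kernels.heun_reaction_2d(Vv, Rr, Ss, Aa, chi, stim, pv, dt)
        if err:
            raise NumericalBlowup(k * dt)
        if freeze:
            Ss[:] = frozen_s
        if lam > 0:
            _kernels.lod_cn_1d(Aa[0], lam)
        if k % sample == 0:
            above = np.where(Vv[0] > level)[0]
            times.append(k * dt)
            pos.append(above[-1] * dx if len(above) else np.nan)
            # keep a copy of the profile while the front is well inside the
            # domain (the final state may have hit the boundary)
            if mid_profile is None and len(above) \
                    and 0.5 * length < above[-1] * dx < 0.75 * length:
                mid_profile = {"x": xx.copy(), "v": Vv[0].copy(),
                               "r": Rr[0].copy(), "s": Ss[0].copy(),
                               "a": Aa[0].copy()}
    times = np.asarray(times); pos = np.asarray(pos)
    # measurement window: after transients, before the front nears the far wall
    hit = np.where(pos >= length - 6 * dx)[0]
    t_hi = times[hit[0]] if len(hit) else times[-1]
    ok = (~np.isnan(pos)) & (times > 0.35 * t_hi) & (times < t_hi) \
         & (pos > 6 * dx)
    profile = mid_profile if mid_profile is not None else {
        "x": xx, "v": Vv[0], "r": Rr[0], "s": Ss[0], "a": Aa[0]}
    if ok.sum() < 5:
        return {"speed": np.nan, "status": "receding", "profile": profile,
                "times": times, "positions": pos}
    speed = float(np.polyfit(times[ok], pos[ok], 1)[0])
    status = "propagating" if speed > 0 else "receding"
    return {"speed": speed, "status": status, "profile": profile,
            "times": times, "positions": pos}
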