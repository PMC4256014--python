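"""Numerics of the operator-split integrator and the stochastic channel."""
import numpy as np
import pytest
from scipy.integrate import solve_ivp

import retinawave as rw
from retinawave import _kernels
from retinawave.kinetics import reaction_rhs
from retinawave.simulator import (SimConfig, StimulusProtocol, run_simulation,
                                  run_single_cell, step_diffusion,
                                  step_reaction, update_noise)


def test_uniform_grid_stays_uniform(params, rest):
    n = 8
    fields = tuple(np.full((n, n), x) for x in rest)
    out = step_reaction(fields, params, 1e-3)
    for f in out:
        assert np.ptp(f) == 0.0


def test_numba_kernel_matches_numpy_reference(params, rest):
    rng = np.random.default_rng(0)
    n = 6
    V = rest[0] + rng.normal(0, 10, (n, n))
    R = np.clip(rest[1] + rng.normal(0, 0.05, (n, n)), 0, 1)
    S = np.abs(rng.normal(0, 0.02, (n, n)))
    A = np.abs(rng.normal(100, 50, (n, n)))
    chi = rng.random((n, n)) < 0.5
    stim = rng.normal(0, 50, (n, n))
    ref = step_reaction((V, R, S, A), params, 1e-3, stim=stim, noise_mask=chi)
    Vk, Rk, Sk, Ak = V.copy(), R.copy(), S.copy(), A.copy()
    _kernels.heun_reaction_2d(Vk, Rk, Sk, Ak, chi, stim,
                              _kernels.pack_params(params), 1e-3)
    for got, want in zip((Vk, Rk, Sk, Ak), ref):
        np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-12)


def test_reaction_step_is_second_order(params, rest):
    """Richardson: halving dt shrinks the one-step error ~4x (Heun is 2nd order)."""
    x = np.array(rest) + np.array([20.0, 0.05, 0.01, 200.0])
    fields = tuple(np.array([[xi]]) for xi in x)

    def integrate(dt, nsteps):
        f = fields
        for _ in range(nsteps):
            f = step_reaction(f, params, dt)
        return np.array([c[0, 0] for c in f])

    ref = solve_ivp(lambda t, y: reaction_rhs(y, params).astype(float),
                    (0, 4e-3), x, rtol=1e-12, atol=1e-14).y[:, -1]
    err1 = np.abs(integrate(4e-3, 1) - ref)
    err2 = np.abs(integrate(2e-3, 2) - ref)
    ratio = err1[0] / err2[0]
    assert 2.5 < ratio < 6.0


def test_diffusion_constant_field_invariant():
    a = np.full((16, 16), 3.7)
    out = step_diffusion(a, D=0.01, dt=1e-3, dx=0.03)
    np.testing.assert_allclose(out, a, rtol=1e-14)


def test_diffusion_conserves_mass():
    rng = np.random.default_rng(1)
    a = rng.random((32, 32)) * 100
    total = a.sum()
    for k in range(50):
        a = step_diffusion(a, D=0.01, dt=1e-3, dx=0.03125, order=k)
    assert abs(a.sum() - total) / total < 1e-10


def test_diffusion_matches_heat_kernel():
    """Gaussian bump spreading on an effectively unbounded domain."""
    n, L, D = 128, 8.0, 0.01
    dx = L / n
    x = (np.arange(n) + 0.5) * dx - L / 2
    X, Y = np.meshgrid(x, x, indexing="ij")
    s0 = 0.05  # initial variance mm^2
    a = np.exp(-(X**2 + Y**2) / (2 * s0))
    t, dt = 0.5, 1e-3
    for k in range(int(t / dt)):
        a = step_diffusion(a, D, dt, dx, order=k)
    s1 = s0 + 2 * D * t
    exact = (s0 / s1) * np.exp(-(X**2 + Y**2) / (2 * s1))
    l2 = np.sqrt(((a - exact) ** 2).sum() / (exact ** 2).sum())
    assert l2 < 0.01


def test_diffusion_1d_variant():
    a = np.zeros(64)
    a[30:34] = 1.0
    total = a.sum()
    out = a.copy()
    for _ in range(100):
        out = step_diffusion(out, 0.01, 1e-3, 0.03125)
    assert abs(out.sum() - total) < 1e-10 * total
    assert out.max() < a.max()


def test_noise_rate_zero_never_opens(params):
    q = params.replace()
    q.noise.open_probability_rate = 0.0
    rng = np.random.default_rng(0)
    mask = np.zeros((16, 16), bool)
    for _ in range(100):
        mask = update_noise(mask, q, rng)
        assert not mask.any()


def test_noise_empirical_frequency(params):
    rng = np.random.default_rng(42)
    prob = params.noise.open_probability_rate * params.noise.update_interval
    n_draw = 10**6
    mask = np.zeros((100, 100), bool)
    opens = 0
    for _ in range(100):
        mask = update_noise(mask, params, rng)
        opens += mask.sum()
    sd = np.sqrt(n_draw * prob * (1 - prob))
    assert abs(opens - n_draw * prob) < 3 * sd


def test_noise_interopening_times_geometric(params):
    """Single-cell openings are a Bernoulli process: exponential waiting times."""
    rng = np.random.default_rng(7)
    prob = params.noise.open_probability_rate * params.noise.update_interval
    draws = rng.random(400000) < prob
    idx = np.where(draws)[0]
    waits = np.diff(idx) * params.noise.update_interval
    expected = 1.0 / params.noise.open_probability_rate
    assert abs(waits.mean() - expected) / expected < 0.05


def test_run_simulation_deterministic(params):
    cfg = SimConfig(duration=2.0, warmup=0.5, grid_n=16, seed=11)
    a = run_simulation(cfg, params)
    b = run_simulation(cfg, params)
    np.testing.assert_array_equal(a.v, b.v)
    assert a.meta["params_hash"] == b.meta["params_hash"]


def test_run_simulation_seed_changes_noise(params):
    cfg1 = SimConfig(duration=3.0, warmup=0.0, grid_n=16, seed=1)
    cfg2 = SimConfig(duration=3.0, warmup=0.0, grid_n=16, seed=2)
    a = run_simulation(cfg1, params)
    b = run_simulation(cfg2, params)
    assert not np.array_equal(a.v, b.v)
    assert a.meta["params_hash"] == b.meta["params_hash"]


def test_decoupled_limit_matches_ode_solver(params, rest):
    """D = 0, noise off: every cell follows the single-cell ODE."""
    q = params.replace(diffusion_coefficient=0.0)
    q.noise.open_probability_rate = 0.0
    x0 = np.array(rest) + np.array([25.0, 0.0, 0.0, 300.0])  # excited start
    cfg = SimConfig(duration=100.0, warmup=0.0, grid_n=4, seed=0,
                    snapshot_interval=1.0, record_fields=False)
    # run via the grid integrator
    from retinawave.simulator import _initial_fields
    import retinawave._kernels as K
    V, R, S, A = (np.full((4, 4), v) for v in x0)
    pv = K.pack_params(q)
    chi = np.zeros((4, 4), bool)
    stim = np.zeros((4, 4))
    K.run_block_2d(V, R, S, A, chi, stim, pv, 1e-3, 100000, 0.0, 0)
    ref = solve_ivp(lambda t, y: reaction_rhs(y, q).astype(float), (0, 100.0),
                    x0, rtol=1e-10, atol=1e-12).y[:, -1]
    got = np.array([V[0, 0], R[0, 0], S[0, 0], A[0, 0]])
    scale = np.array([100.0, 1.0, 1.0, 1000.0])
    assert np.max(np.abs(got - ref) / scale) < 1e-6


def test_splitting_step_halving_consistency(params, rest):
    """Full-step vs two half-steps differ at O(dt^2) on smooth data."""
    n = 16
    rng = np.random.default_rng(3)
    base = [np.full((n, n), x) for x in rest]
    base[0] += rng.normal(0, 5, (n, n))
    base[3] += np.abs(rng.normal(200, 50, (n, n)))

    def advance(dt, nsteps, fields):
        V, R, S, A = (f.copy() for f in fields)
        pv = _kernels.pack_params(params)
        chi = np.zeros((n, n), bool)
        stim = np.zeros((n, n))
        lam = params.diffusion_coefficient * dt / (2.0 / n) ** 2
        _kernels.run_block_2d(V, R, S, A, chi, stim, pv, dt, nsteps, lam, 0)
        return V

    v1 = advance(2e-3, 1, base)
    v2 = advance(1e-3, 2, base)
    v4 = advance(0.5e-3, 4, base)
    d12 = np.abs(v1 - v2).max()
    d24 = np.abs(v2 - v4).max()
    assert d24 < d12  # refinement converges
    assert d12 / max(d24, 1e-15) > 2.0


def test_single_cell_flat_without_noise(params, rest):
    t, trace, events = run_single_cell(params, duration=20.0, noise=False)
    assert np.ptp(trace[:, 0]) < 1e-3
    assert len(events) == 0


def test_single_cell_stimulus_burst_and_refractoriness(params):
    """A suprathreshold injection bursts; a second one 10 s later is damped
    while the sAHP is elevated, and larger injections prolong the sAHP."""
    proto = StimulusProtocol([(1.0, 1.5, 400.0, None), (12.0, 1.5, 400.0, None)])
    t, trace, _ = run_single_cell(params, protocol=proto, duration=40.0,
                                  noise=False)
    v, s = trace[:, 0], trace[:, 2]
    seg1 = (t >= 1.0) & (t < 8.0)
    seg2 = (t >= 12.0) & (t < 19.0)
    assert v[seg1].max() > -20.0  # full burst
    assert v[seg2].max() < v[seg1].max() - 5.0  # damped response
    assert s[(t > 11.5) & (t < 12.0)].max() > 0.02  # still refractory
    # post-burst hyperpolarisation below rest
    rest_v = trace[0, 0]
    assert v[(t > 4.0) & (t < 10.0)].min() < rest_v - 2.0
    # larger injection -> larger sAHP build-up
    proto_big = StimulusProtocol([(1.0, 1.5, 800.0, None)])
    _, tr2, _ = run_single_cell(params, protocol=proto_big, duration=20.0,
                                noise=False)
    assert tr2[:, 2].max() >= s.max() * 0.9


def test_point_stimulus_front_is_radially_symmetric(params):
    """Zero noise: a centred excited spot grows into a circular front."""
    q = params.replace()
    q.noise.open_probability_rate = 0.0
    cfg = SimConfig(duration=3.0, warmup=0.0, grid_n=64, seed=0,
                    snapshot_interval=0.5)
    from retinawave.kinetics import find_rest_state
    from retinawave import _kernels as K
    x0 = find_rest_state(q)
    n = 64
    V = np.full((n, n), x0[0]); R = np.full((n, n), x0[1])
    S = np.full((n, n), x0[2]); A = np.full((n, n), x0[3])
    c = n // 2
    V[c - 2:c + 2, c - 2:c + 2] = 0.0
    A[c - 2:c + 2, c - 2:c + 2] = 1000.0
    pv = K.pack_params(q)
    chi = np.zeros((n, n), bool); stim = np.zeros((n, n))
    dx = 2.0 / n
    lam = q.diffusion_coefficient * 1e-3 / dx**2
    K.run_block_2d(V, R, S, A, chi, stim, pv, 1e-3, 3000, lam, 0)
    act = V > -50.0
    if act.sum() > 20:  # front formed: check radius isotropy
        ii, jj = np.nonzero(act)
        r = np.hypot(ii - (c - 0.5), jj - (c - 0.5))
        theta = np.arctan2(ii - (c - 0.5), jj - (c - 0.5))
        bins = np.digitize(theta, np.linspace(-np.pi, np.pi, 9))
        radii = [r[bins == b].max() for b in range(1, 9) if (bins == b).any()]
        assert np.ptp(radii) <= 1.5  # less than ~1 cell anisotropy


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(duration=-1.0)
    with pytest.raises(ValueError):
        SimConfig(duration=1.0, snapshot_interval=0.0015)  # not multiple of dt
    with pytest.raises(ValueError):
        StimulusProtocol([(0.0, -1.0, 10.0, None)])
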