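"""Fast-subsystem fixed points, traveling-front speeds and excitability."""
import numpy as np
import pytest

import retinawave as rw
from retinawave.fronts import (absolute_refractory_period, fast_fixed_points,
                               front_profile_bvp, front_speed_relaxation,
                               speed_vs_refractory)


@pytest.fixture(scope="module")
def params():
    return rw.ModelParams()


def test_bistable_structure_at_rest(params):
    fps = fast_fixed_points(0.0, params)
    stable = [f for f in fps if f["stable"]]
    assert len(stable) >= 2  # rest and excited states coexist
    assert len(fps) >= 3  # with a saddle between
    vs = sorted(f["state"][0] for f in stable)
    assert vs[0] < -60.0 and vs[-1] > -40.0


def test_monostable_at_high_refractoriness(params):
    fps = fast_fixed_points(2.0, params)
    stable = [f for f in fps if f["stable"]]
    assert len(stable) == 1
    assert stable[0]["state"][0] < -60.0  # only rest persists


def test_fixed_points_scale_consistently(params):
    """Dimensioned fixed points map onto scaled coordinates exactly."""
    from retinawave.params import nondimensionalize
    dp = nondimensionalize(params)
    for f in fast_fixed_points(0.0, params):
        v_scaled = f["state"][0] / dp.v_scale
        assert -2.0 < v_scaled < 1.0


def test_positive_speed_at_rest_and_receding_when_refractory(params):
    out0 = front_speed_relaxation(0.0, params)
    assert out0["status"] == "propagating" and out0["speed"] > 0
    out_hi = front_speed_relaxation(0.6, params)
    assert not (out_hi["speed"] > 0)


def test_receding_without_ach_coupling(params):
    q = params.replace()
    q.max_conductances.g_ACh = 0.0
    out = front_speed_relaxation(0.0, q)
    assert out["status"] in ("receding", "no-front")


def test_grid_refinement_changes_speed_little(params):
    c1 = front_speed_relaxation(0.0, params, n=384, length=8.0)["speed"]
    c2 = front_speed_relaxation(0.0, params, n=768, length=8.0)["speed"]
    assert abs(c2 - c1) / c1 < 0.03


def test_sqrt_diffusion_scaling(params):
    """Reaction-diffusion fronts scale as sqrt(D): 4x D doubles the speed."""
    c1 = front_speed_relaxation(0.0, params)["speed"]
    q = params.replace(diffusion_coefficient=4 * params.diffusion_coefficient)
    c2 = front_speed_relaxation(0.0, q, length=16.0, n=1024)["speed"]
    assert c2 / c1 == pytest.approx(2.0, rel=0.03)


def test_speed_curve_monotone_and_root(params):
    s_grid = np.linspace(0.0, 0.5, 6)
    out = speed_vs_refractory(params, s_grid)
    c = out["c"]
    finite = np.isfinite(c)
    assert np.all(np.diff(c[finite]) < 1e-3)  # monotone decreasing
    assert np.isfinite(out["s_star"])
    assert 0.0 < out["s_star"] < 0.5


def test_reduced_coupling_lowers_speed_curve(params):
    """25% less ACh conductance lowers c(s) pointwise and shrinks s*."""
    q = params.replace()
    q.max_conductances.g_ACh = 0.75 * params.max_conductances.g_ACh
    s_grid = np.array([0.0, 0.1, 0.2])
    base = speed_vs_refractory(params, s_grid, refine_root=False)["c"]
    less = speed_vs_refractory(q, s_grid, refine_root=False)["c"]
    for b, l in zip(base, less):
        if np.isfinite(b) and np.isfinite(l):
            assert l < b
    s0 = speed_vs_refractory(params, np.linspace(0, 0.5, 6))["s_star"]
    s1 = speed_vs_refractory(q, np.linspace(0, 0.5, 6))["s_star"]
    assert s1 < s0


def test_bvp_agrees_with_relaxation(params):
    """Moving-frame Newton solve and relaxation give the same speed within 5%."""
    checked = 0
    for s in (0.04, 0.06, 0.08):
        rel = front_speed_relaxation(s, params, n=1024)
        if not rel["speed"] > 0:
            continue
        sol = front_profile_bvp(s, params, c_init=rel["speed"], relaxation=rel)
        assert sol.speed == pytest.approx(rel["speed"], rel=0.05)
        assert sol.residual < 1e-4
        # profile endpoints match the fixed points
        assert sol.v[0] == pytest.approx(sol.excited[0], abs=1.0)
        assert sol.v[-1] == pytest.approx(sol.rest[0], abs=1.0)
        checked += 1
    assert checked >= 2


def test_bvp_translation_invariance(params):
    """A translated initial profile converges to the same front speed."""
    rel = front_speed_relaxation(0.05, params, n=1024)
    sol1 = front_profile_bvp(0.05, params, c_init=rel["speed"], relaxation=rel)

    def shifted(xi):
        shift = 10 * (sol1.xi[1] - sol1.xi[0])
        return (np.interp(xi + shift, sol1.xi, sol1.v),
                np.interp(xi + shift, sol1.xi, sol1.r),
                np.interp(xi + shift, sol1.xi, sol1.a))

    sol2 = front_profile_bvp(0.05, params, c_init=rel["speed"] * 1.05,
                             profile_init=shifted)
    assert sol2.speed == pytest.approx(sol1.speed, rel=1e-2)


def test_absolute_refractory_period_scales_with_tau_s(params):
    periods = []
    s_star = speed_vs_refractory(params, np.linspace(0, 0.5, 6))["s_star"]
    for tau in (30.0, 60.0, 90.0):
        q = params.replace()
        q.sahp_times.tau_S = tau
        period, _ = absolute_refractory_period(q, s_star=s_star,
                                               horizon=60.0 + 3 * tau)
        periods.append(period)
    assert periods[0] < periods[1] < periods[2]
    # exponential decay: period approximately proportional to tau_S
    assert periods[2] / periods[0] == pytest.approx(3.0, rel=0.35)
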