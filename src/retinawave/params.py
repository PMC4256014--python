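"""Biophysical parameters of the starburst-amacrine-cell (SAC) wave model.

The model describes a sheet of SACs as an excitable reaction-diffusion medium
with four fields: membrane potential ``v`` (mV), a Morris-Lecar potassium
gate / fast refractory fraction ``r``, a slow after-hyperpolarisation (sAHP)
activation ``s``, and the extracellular acetylcholine concentration ``a`` (nM).
Only ``a`` diffuses; it provides the lateral excitatory coupling.

Unit conventions used throughout: mV, nS, nF, nM, s, mm.  With these units
conductance x voltage is in pA and pA / nF integrates voltage in mV/s, so no
hidden conversion factors appear in the right-hand sides.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ModelParams",
    "DimensionlessParams",
    "StateVector",
    "load_params",
    "save_params",
    "nondimensionalize",
]


@dataclass
class ReversalPotentials:
    """Ionic reversal potentials in mV."""

    E_K: float = -90.0
    E_Ca: float = 50.0
    E_leak: float = -70.0
    E_ACh: float = 50.0


@dataclass
class MaxConductances:
    """Maximal conductances in nS."""

    g_leak: float = 2.0
    g_K: float = 30.0
    g_Ca: float = 10.0
    g_ACh: float = 40.0
    g_noise: float = 3.0


@dataclass
class GatingParams:
    """Morris-Lecar gating constants (mV) and the gate rate scale.

    ``m`` is the instantaneous calcium activation, ``r`` the potassium
    gate.  ``rate_scale`` is 1/tau of the r-gate at its half-activation
    voltage; the voltage dependence of the gate speed follows the canonical
    cosh form with width ``2 * r_slope``.
    """

    m_half: float = -40.0
    m_slope: float = 15.0
    r_half: float = -20.0
    r_slope: float = 40.0
    rate_scale: float = 5.0  # s^-1  (gate time constant 0.2 s at r_half)
    s_half: float = -40.0  # mV, half-activation of the sAHP drive
    s_steepness: float = 0.2  # mV^-1, logistic steepness of the sAHP drive


@dataclass
class AChParams:
    """Acetylcholine release, clearance and receptor binding."""

    release_rate: float = 5000.0  # nM/s at full release
    release_half: float = -40.0  # mV, logistic midpoint of the release gate
    release_steepness: float = 0.2  # mV^-1, logistic steepness
    release_exponent: float = 2.0  # cooperativity of release (sigmoid power)
    clearance_time: float = 2.0  # s
    half_saturation: float = 800.0  # nM, receptor Hill K
    hill_coefficient: float = 2.0


@dataclass
class SAHPTimes:
    """Slow AHP cascade time constants in seconds."""

    tau_R: float = 5.0  # activation (rise during a burst)
    tau_S: float = 60.0  # decay back to rest


@dataclass
class NoiseParams:
    """Stochastic excitatory channel: Bernoulli openings of g_noise."""

    open_probability_rate: float = 2.6  # s^-1
    update_interval: float = 0.01  # s
    reversal: float = 0.0  # mV, driving potential of the noise conductance


@dataclass
class DomainParams:
    length: float = 2.0  # mm
    grid_n: int = 64


@dataclass
class ModelParams:
    """Full dimensioned parameter set of the SAC wave model."""

    membrane_capacitance: float = 0.16  # nF
    reversal_potentials: ReversalPotentials = field(default_factory=ReversalPotentials)
    max_conductances: MaxConductances = field(default_factory=MaxConductances)
    sahp_strength: float = 12.0  # dimensionless coupling of s into the r-gate target
    gating_params: GatingParams = field(default_factory=GatingParams)
    ach_params: AChParams = field(default_factory=AChParams)
    sahp_times: SAHPTimes = field(default_factory=SAHPTimes)
    diffusion_coefficient: float = 0.001  # mm^2/s
    noise: NoiseParams = field(default_factory=NoiseParams)
    domain: DomainParams = field(default_factory=DomainParams)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        g = self.max_conductances
        for name in ("g_leak", "g_K", "g_Ca", "g_ACh", "g_noise"):
            if getattr(g, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")
        for name in ("tau_R", "tau_S"):
            if getattr(self.sahp_times, name) <= 0:
                raise ValueError(f"time constant {name} must be > 0")
        if self.ach_params.clearance_time <= 0:
            raise ValueError("clearance_time must be > 0")
        if self.diffusion_coefficient < 0:
            raise ValueError("diffusion coefficient must be >= 0")
        if self.ach_params.hill_coefficient < 1:
            raise ValueError("hill_coefficient must be >= 1")
        E = self.reversal_potentials
        if not (E.E_K < E.E_leak < E.E_ACh):
            raise ValueError("expected E_K < E_leak < E_ACh")
        if self.membrane_capacitance <= 0:
            raise ValueError("membrane capacitance must be > 0")
        if self.noise.update_interval <= 0:
            raise ValueError("noise update interval must be > 0")
        if self.domain.grid_n < 2 or self.domain.length <= 0:
            raise ValueError("invalid domain")

    # -- convenience --------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        kwargs = dict(d)
        for key, sub in (
            ("reversal_potentials", ReversalPotentials),
            ("max_conductances", MaxConductances),
            ("gating_params", GatingParams),
            ("ach_params", AChParams),
            ("sahp_times", SAHPTimes),
            ("noise", NoiseParams),
            ("domain", DomainParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    def replace(self, **kwargs) -> "ModelParams":
        return ModelParams.from_dict({**self.to_dict(), **kwargs})


# A state is a plain length-4 vector (v, r, s, a); fields may also be N x N.
StateVector = np.ndarray


_REGISTRY_HEADER = """\
# Parameter registry of the SAC retinal-wave model (dimensioned units).
#
# Units: mV (voltages), nS (conductances), nF (capacitance), nM (ACh
# concentration), s (times), mm (lengths), mm^2/s (diffusion).
#
# Field notes:
#   gating_params.m_half/m_slope     tanh half-activation / width of the
#                                    instantaneous Ca gate m_inf
#   gating_params.r_half/r_slope     same for the K gate r_inf; the gate time
#                                    constant is (1/rate_scale)/cosh((v-r_half)/(2*r_slope))
#   ach_params.release_*             squared-logistic voltage dependence of ACh
#                                    release (cooperative); onset near -55 mV
#   sahp_strength                    additive coupling of s into the r-gate target
#   sahp_times.tau_R / tau_S         sAHP activation / decay time constants
#   noise.open_probability_rate      Bernoulli channel opening rate
"""


def save_params(p: ModelParams, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_REGISTRY_HEADER)
        yaml.safe_dump(p.to_dict(), fh, sort_keys=False)


def load_params(path: str | Path | None = None) -> ModelParams:
    """Load a parameter registry file; with no path, return defaults."""
    if path is None:
        return ModelParams()
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ValueError(f"registry file {path} does not contain a mapping")
    return ModelParams.from_dict(d)


@dataclass
class DimensionlessParams:
    """Scaled parameters of the analysis system.

    Voltages are scaled by ``v_scale`` (= E_Ca, 50 mV), conductances by
    ``g_scale`` (= g_K, 30 nS), time by the membrane scale
    ``t_scale = C / g_K`` and space by ``x_scale = sqrt(D * t_scale)``.
    ACh concentration keeps its nM magnitude (scale 1 nM).
    """

    # scales
    v_scale: float
    g_scale: float
    t_scale: float
    x_scale: float
    a_scale: float
    # scaled reversals
    e_K: float
    e_Ca: float
    e_leak: float
    e_ACh: float
    # conductance ratios
    g_leak: float
    g_Ca: float
    g_ACh: float
    g_noise: float
    # gating constants (scaled by v_scale)
    v_m: float
    s_m: float
    v_r: float
    s_r: float
    v_rel: float
    k_rel: float  # steepness, in 1/v_scale units
    # kinetics
    beta: float  # scaled release rate
    k_d: float  # Hill half-saturation in a_scale units
    hill_n: float
    gamma_a: float  # t_scale / clearance_time
    phi_r: float  # t_scale * rate_scale (gate)
    eps_act: float  # t_scale / tau_R  (sAHP activation)
    eps_decay: float  # t_scale / tau_S (sAHP decay)
    kappa: float
    lam_noise: float  # noise rate * t_scale
    degenerate_space: bool = False

    @property
    def epsilon(self) -> float:
        """Fast/slow timescale ratio of the singular-perturbation analysis."""
        return self.eps_decay


def nondimensionalize(p: ModelParams) -> DimensionlessParams:
    """Compute the dimensionless parameter set from a dimensioned one."""
    E, g = p.reversal_potentials, p.max_conductances
    if g.g_K <= 0:
        raise ValueError("g_K must be positive to set the conductance scale")
    v_scale = E.E_Ca
    if v_scale <= 0:
        raise ValueError("E_Ca must be positive to set the voltage scale")
    g_scale = g.g_K
    t_scale = p.membrane_capacitance / g_scale
    degenerate = p.diffusion_coefficient == 0
    x_scale = math.sqrt(p.diffusion_coefficient * t_scale)
    gp, ap = p.gating_params, p.ach_params
    return DimensionlessParams(
        v_scale=v_scale,
        g_scale=g_scale,
        t_scale=t_scale,
        x_scale=x_scale,
        a_scale=1.0,
        e_K=E.E_K / v_scale,
        e_Ca=E.E_Ca / v_scale,
        e_leak=E.E_leak / v_scale,
        e_ACh=E.E_ACh / v_scale,
        g_leak=g.g_leak / g_scale,
        g_Ca=g.g_Ca / g_scale,
        g_ACh=g.g_ACh / g_scale,
        g_noise=g.g_noise / g_scale,
        v_m=gp.m_half / v_scale,
        s_m=gp.m_slope / v_scale,
        v_r=gp.r_half / v_scale,
        s_r=gp.r_slope / v_scale,
        v_rel=ap.release_half / v_scale,
        k_rel=ap.release_steepness * v_scale,
        beta=ap.release_rate * t_scale,
        k_d=ap.half_saturation,
        hill_n=ap.hill_coefficient,
        gamma_a=t_scale / ap.clearance_time,
        phi_r=t_scale * gp.rate_scale,
        eps_act=t_scale / p.sahp_times.tau_R,
        eps_decay=t_scale / p.sahp_times.tau_S,
        kappa=p.sahp_strength,
        lam_noise=p.noise.open_probability_rate * t_scale,
        degenerate_space=degenerate,
    )
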