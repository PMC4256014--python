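"""Synthetic ground-truth inputs for the analysis pipeline.

Expanding/colliding disk-wave movies with programmed radial speed, and
power-law / exponential size samples for the avalanche-statistics fitters.
Fixtures emit the same snapshot container as the simulator, so every
analysis entry point can be exercised without a tissue run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import SnapshotSeries

__all__ = ["FixtureWaveSpec", "make_disk_wave", "sample_powerlaw",
           "sample_exponential", "white_noise_series"]

REST_V = -75.0
ACTIVE_V = -20.0


@dataclass
class FixtureWaveSpec:
    """Programmed expanding disk wave(s).

    Each source ``(x0, y0, t_on)`` (mm, mm, s) expands radially at ``speed``
    (mm/s); a cell stays active for ``burst_duration`` seconds after the
    front reaches it.
    """

    sources: list = field(default_factory=lambda: [(1.0, 1.0, 0.5)])
    speed: float = 0.1  # mm/s
    burst_duration: float = 0.5  # s
    duration: float = 8.0  # s
    grid_n: int = 64
    domain_length: float = 2.0  # mm
    snapshot_interval: float = 0.01  # s
    max_radius: float | None = None  # mm; default: quarter of the domain

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("speed must be > 0")
        if self.burst_duration < 0 or self.duration < 0:
            raise ValueError("negative duration")
        L = self.domain_length
        for (x0, y0, _t) in self.sources:
            if not (0 <= x0 <= L and 0 <= y0 <= L):
                raise ValueError("source outside the domain")


def make_disk_wave(spec: FixtureWaveSpec) -> SnapshotSeries:
    """Render the programmed wave movie as a voltage snapshot series."""
    n = spec.grid_n
    dx = spec.domain_length / n
    nt = int(round(spec.duration / spec.snapshot_interval))
    times = (np.arange(nt) + 1) * spec.snapshot_interval
    if nt == 0:
        return SnapshotSeries(times=np.empty(0), v=np.empty((0, n, n)),
                              domain_length=spec.domain_length,
                              meta={"fixture": "disk_wave"})
    xc = (np.arange(n) + 0.5) * dx
    X, Y = np.meshgrid(xc, xc, indexing="ij")
    rmax = spec.max_radius if spec.max_radius is not None else spec.domain_length / 4
    v = np.full((nt, n, n), REST_V, dtype=np.float32)
    for (x0, y0, t_on) in spec.sources:
        rr = np.hypot(X - x0, Y - y0)
        # front reaches radius rr at t_on + rr/speed; active until + burst
        t_arrive = t_on + rr / spec.speed
        for k, t in enumerate(times):
            act = (t >= t_arrive) & (t < t_arrive + spec.burst_duration) & (rr <= rmax)
            v[k][act] = ACTIVE_V
    return SnapshotSeries(times=times, v=v, domain_length=spec.domain_length,
                          meta={"fixture": "disk_wave",
                                "speed": spec.speed,
                                "burst_duration": spec.burst_duration,
                                "sources": [list(s) for s in spec.sources]})


def sample_powerlaw(exponent: float, xmin: float, n: int, seed: int = 0) -> np.ndarray:
    """Inverse-CDF draws from a Pareto density  p(x) ~ x^-exponent, x >= xmin."""
    if exponent <= 1:
        raise ValueError("exponent must be > 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    return xmin * (1.0 - u) ** (-1.0 / (exponent - 1.0))


def sample_exponential(scale: float, xmin: float, n: int, seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return xmin + rng.exponential(scale, size=n)


def white_noise_series(grid_n: int = 32, nt: int = 400, seed: int = 0,
                       domain_length: float = 2.0,
                       snapshot_interval: float = 0.1) -> SnapshotSeries:
    """Spatially independent Gaussian voltage noise (null for correlations)."""
    rng = np.random.default_rng(seed)
    v = (REST_V + 5.0 * rng.standard_normal((nt, grid_n, grid_n))).astype(np.float32)
    times = (np.arange(nt) + 1) * snapshot_interval
    return SnapshotSeries(times=times, v=v, domain_length=domain_length,
                          meta={"fixture": "white_noise"})
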