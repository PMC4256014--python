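"""Drossel-Schwabl forest-fire model (DS-FFM) and the retina -> (p, f) mapping.

The lattice analogy: a recovered SAC is an occupied site (tree), a bursting
SAC a burning one, a refractory SAC an empty one.  Spontaneous depolarisation
is lightning (probability f per occupied site and step), recovery from the
sAHP is regrowth (probability p per empty site and step), and wave spread is
fire spreading to 4-neighbours.  Self-organised critical avalanche statistics
are expected in a double separation of scales: many regrowth events per
lightning strike, yet a characteristic fire small compared with the lattice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["FFMConfig", "AvalancheRecord", "ffm_run", "map_to_ffm",
           "soc_region", "compare_avalanche_stats"]

EMPTY, TREE, BURNING = 0, 1, 2


@dataclass
class FFMConfig:
    lattice: int = 128
    p: float = 0.05  # regrowth probability per empty site and step
    f: float = 0.00025  # lightning probability per occupied site and step
    steps: int = 20000
    seed: int = 0
    burn_in: int = 2000
    spread: str = "step"  # 'step': one neighbour ring per step; 'instant':
    #                        whole cluster burns in a single step (classic DS-FFM)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 and 0.0 <= self.f <= 1.0):
            raise ValueError("p and f must be probabilities")
        if self.lattice < 16:
            raise ValueError("lattice side must be >= 16")


@dataclass
class AvalancheRecord:
    sizes: np.ndarray  # sites burned per fire
    lifetimes: np.ndarray  # steps per fire
    tree_density: np.ndarray  # per recorded step after burn-in
    config: FFMConfig


@njit(cache=True)
def _ffm_step_spread(grid, rnd_grow, rnd_light, p, f, fire_id, fire_sizes,
                     fire_life, fire_open):
    """One synchronous DS-FFM update with per-step neighbour spread.

    grid values: 0 empty, 1 tree, >=2 burning with (value-2) = fire index.
    Returns number of new fires started this step.
    """
    n = grid.shape[0]
    new_fires = 0
    # 2) burning trees ignite occupied neighbours; 3) burning -> empty
    burning_next = np.zeros((n, n), np.int64)
    for i in range(n):
        for j in range(n):
            g = grid[i, j]
            if g >= 2:
                fid = g - 2
                if i > 0 and grid[i - 1, j] == 1 and burning_next[i - 1, j] == 0:
                    burning_next[i - 1, j] = g
                if i < n - 1 and grid[i + 1, j] == 1 and burning_next[i + 1, j] == 0:
                    burning_next[i + 1, j] = g
                if j > 0 and grid[i, j - 1] == 1 and burning_next[i, j - 1] == 0:
                    burning_next[i, j - 1] = g
                if j < n - 1 and grid[i, j + 1] == 1 and burning_next[i, j + 1] == 0:
                    burning_next[i, j + 1] = g
    for i in range(n):
        for j in range(n):
            if grid[i, j] >= 2:
                grid[i, j] = 0  # burned out
    for i in range(n):
        for j in range(n):
            b = burning_next[i, j]
            if b >= 2 and grid[i, j] == 1:
                grid[i, j] = b
                fid = b - 2
                fire_sizes[fid] += 1
                fire_open[fid] = True
    # 1) lightning; 4) regrowth (synchronous, on the post-spread state)
    k = 0
    for i in range(n):
        for j in range(n):
            if grid[i, j] == 1:
                if rnd_light[k] < f:
                    # start a new fire
                    fid = -1
                    for q in range(fire_sizes.shape[0]):
                        if fire_life[q] == -1:
                            fid = q
                            break
                    if fid >= 0:
                        grid[i, j] = fid + 2
                        fire_sizes[fid] = 1
                        fire_life[fid] = 0
                        fire_open[fid] = True
                        new_fires += 1
            elif grid[i, j] == 0:
                if rnd_grow[k] < p:
                    grid[i, j] = 1
            k += 1
    return new_fires


@njit(cache=True)
def _burn_cluster(grid, i0, j0):
    """Instantaneous cluster burn (classic DS-FFM); returns cluster size."""
    n = grid.shape[0]
    stack_i = np.empty(n * n, np.int64)
    stack_j = np.empty(n * n, np.int64)
    top = 0
    stack_i[top] = i0; stack_j[top] = j0
    top += 1
    grid[i0, j0] = 0
    size = 0
    while top > 0:
        top -= 1
        i = stack_i[top]; j = stack_j[top]
        size += 1
        if i > 0 and grid[i - 1, j] == 1:
            grid[i - 1, j] = 0; stack_i[top] = i - 1; stack_j[top] = j; top += 1
        if i < n - 1 and grid[i + 1, j] == 1:
            grid[i + 1, j] = 0; stack_i[top] = i + 1; stack_j[top] = j; top += 1
        if j > 0 and grid[i, j - 1] == 1:
            grid[i, j - 1] = 0; stack_i[top] = i; stack_j[top] = j - 1; top += 1
        if j < n - 1 and grid[i, j + 1] == 1:
            grid[i, j + 1] = 0; stack_i[top] = i; stack_j[top] = j + 1; top += 1
    return size


def ffm_run(cfg: FFMConfig) -> AvalancheRecord:
    """Run the forest-fire lattice; record every fire's size and lifetime."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.lattice
    grid = (rng.random((n, n)) < 0.4).astype(np.int64)  # initial tree density
    sizes_out, lives_out, density = [], [], []
    if cfg.spread == "instant":
        for step in range(cfg.steps):
            # regrowth
            grow = rng.random((n, n)) < cfg.p
            grid[(grid == 0) & grow] = 1
            # lightning strikes, burn clusters instantly
            strikes = np.argwhere((grid == 1) & (rng.random((n, n)) < cfg.f))
            for (i, j) in strikes:
                if grid[i, j] == 1:
                    size = _burn_cluster(grid, i, j)
                    if step >= cfg.burn_in:
                        sizes_out.append(size)
                        lives_out.append(1)
            if step >= cfg.burn_in:
                density.append((grid == 1).mean())
        return AvalancheRecord(np.array(sizes_out), np.array(lives_out),
                               np.array(density), cfg)
    # per-step spread variant
    max_fires = 4096
    fire_sizes = np.zeros(max_fires, np.int64)
    fire_life = np.full(max_fires, -1, np.int64)
    fire_open = np.zeros(max_fires, np.bool_)
    fire_start = np.zeros(max_fires, np.int64)
    for step in range(cfg.steps):
        rnd_grow = rng.random(n * n)
        rnd_light = rng.random(n * n)
        fire_open[:] = False
        _ffm_step_spread(grid, rnd_grow, rnd_light, cfg.p, cfg.f,
                         0, fire_sizes, fire_life, fire_open)
        # bookkeeping: lifetimes advance for fires still present on the grid
        present = np.zeros(max_fires, np.bool_)
        ids = np.unique(grid[grid >= 2]) - 2
        present[ids] = True
        for q in range(max_fires):
            if fire_life[q] >= 0:
                if present[q]:
                    fire_life[q] += 1
                else:
                    if step >= cfg.burn_in:
                        sizes_out.append(int(fire_sizes[q]))
                        lives_out.append(int(fire_life[q]))
                    fire_sizes[q] = 0
                    fire_life[q] = -1
        if step >= cfg.burn_in:
            density.append((grid == 1).mean())
    return AvalancheRecord(np.array(sizes_out), np.array(lives_out),
                           np.array(density), cfg)


def map_to_ffm(wave_speed: float, spont_rate: float, burst_duration: float,
               refractory_period: float, domain_length: float,
               cell_spacing: float) -> dict:
    """Rescale retina parameters to DS-FFM probabilities.

    Time unit: one burst duration (after one unit an active point is
    refractory).  Lattice unit: the elementary excited area, with linear
    size (wave speed x burst duration) - the patch recruited by one
    spontaneous firing in one time unit.  Then

        p = burst_duration / refractory_period
        f = spont_rate * burst_duration * n_cells_per_lattice_point
    """
    if min(wave_speed, spont_rate, burst_duration, refractory_period,
           domain_length, cell_spacing) <= 0:
        raise ValueError("all mapping inputs must be positive")
    if refractory_period <= burst_duration:
        raise ValueError("degenerate mapping: refractory period must exceed "
                         "the burst duration")
    ell = wave_speed * burst_duration  # mm, lattice spacing
    cells_per_point = max(1.0, (ell / cell_spacing) ** 2)
    p = burst_duration / refractory_period
    f = spont_rate * burst_duration * cells_per_point
    lattice = max(1, int(round(domain_length / ell)))
    return {"p": float(p), "f": float(f), "lattice": lattice,
            "lattice_scale_mm": float(ell),
            "cells_per_point": float(cells_per_point)}


def soc_region(p: float, f: float, lattice: int,
               separation: float = 100.0, fire_frac: float = 0.25) -> bool:
    """Double separation of scales for self-organised criticality.

    Requires (i) many regrowth events per lightning strike, p/f >>1, and
    (ii) a characteristic fire scale small compared with the lattice: the
    mean cluster burned per strike contains ~ p/f sites, whose linear extent
    must stay below a fraction of the lattice side.
    """
    if not (0.0 <= p <= 1.0 and 0.0 <= f <= 1.0):
        raise ValueError("p and f must be probabilities")
    if f == 0 or p == 0:
        return False
    ratio = p / f
    if ratio < separation:
        return False
    char_scale = np.sqrt(ratio)  # linear size of the characteristic fire
    return bool(char_scale < fire_frac * lattice)


def compare_avalanche_stats(wave_sizes, ffm_sizes, fit_range=None) -> dict:
    """Matched log-binned power-law fits of wave and fire size distributions."""
    from .waves import fit_powerlaw

    wave_sizes = np.asarray(wave_sizes, dtype=float)
    ffm_sizes = np.asarray(ffm_sizes, dtype=float)
    if len(wave_sizes) < 100 or len(ffm_sizes) < 100:
        return {"underpowered": True,
                "n_wave": len(wave_sizes), "n_ffm": len(ffm_sizes)}
    fw = fit_powerlaw(wave_sizes, fit_range=fit_range)
    ff = fit_powerlaw(ffm_sizes, fit_range=fit_range)
    return {
        "underpowered": False,
        "wave_fit": fw,
        "ffm_fit": ff,
        "slope_gap": abs(fw["slope"] - ff["slope"]),
        "wave_subcritical": fw["curvature_flag"],
        "ffm_subcritical": ff["curvature_flag"],
    }
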