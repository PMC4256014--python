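"""Wave detection and statistics on snapshot series.

Pipeline: threshold the voltage field (default -60 mV, 5-cell boundary
margin excluded), label spatiotemporal connected components (4-neighbour
within a snapshot, overlap-or-4-neighbour between consecutive snapshots),
then derive per-wave size/duration/speed, per-cell inter-wave intervals,
distance-resolved correlations, and power-law fits of the size distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import SnapshotSeries

__all__ = [
    "ActivityMask",
    "WaveEvent",
    "threshold_activity",
    "label_waves",
    "wave_speed",
    "interwave_intervals",
    "correlation_vs_distance",
    "fit_powerlaw",
    "wave_table",
    "summarize_waves",
]

DEFAULT_THRESHOLD = -60.0  # mV
ACH_RELEASE_THRESHOLD = -55.0  # mV, the lower 'general excitation' threshold


@dataclass
class ActivityMask:
    mask: np.ndarray  # (T, n, n) bool
    times: np.ndarray
    threshold: float
    margin: int
    dx: float  # mm

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0


@dataclass
class WaveEvent:
    id: int
    cells: np.ndarray  # (k, 3) int array of (t_index, i, j) members
    t0: float
    t1: float
    size_cells: int
    size_mm2: float
    duration: float
    initiation_points: list  # list of (i, j) cluster centroids
    collision: bool
    mean_speed: float | None = None
    max_front_speed: float | None = None
    front_path: np.ndarray | None = None
    excluded_reason: str | None = None


def threshold_activity(snap: SnapshotSeries, threshold: float = DEFAULT_THRESHOLD,
                       margin: int = 5) -> ActivityMask:
    """Boolean activity mask: v above threshold, boundary margin removed."""
    n = snap.grid_n
    if margin >= n // 2:
        raise ValueError("margin must be smaller than half the grid")
    v = snap.v
    mask = v > threshold
    if v.ndim == 3:
        if margin:
            mask[:, :margin, :] = False
            mask[:, -margin:, :] = False
            mask[:, :, :margin] = False
            mask[:, :, -margin:] = False
    else:
        if margin:
            mask[:, :margin] = False
            mask[:, -margin:] = False
    return ActivityMask(mask=mask, times=snap.times, threshold=threshold,
                        margin=margin, dx=snap.dx)


_STRUCT3 = np.zeros((3, 3, 3), bool)
_STRUCT3[0] = _STRUCT3[1] = _STRUCT3[2] = [[0, 1, 0], [1, 1, 1], [0, 1, 0]]
_STRUCT8 = np.zeros((3, 3, 3), bool)
_STRUCT8[0] = _STRUCT8[1] = _STRUCT8[2] = [[1, 1, 1], [1, 1, 1], [1, 1, 1]]


def _initiation_clusters(first_frames: np.ndarray):
    """Cluster a 2-D boolean onset map with 8-adjacency; return centroids."""
    lab, k = ndimage.label(first_frames, structure=np.ones((3, 3), bool))
    cents = ndimage.center_of_mass(first_frames, lab, range(1, k + 1))
    return [tuple(c) for c in cents]


def label_waves(am: ActivityMask, neighborhood: int = 4) -> list[WaveEvent]:
    """Spatiotemporal connected components of the activity mask.

    Components connect through the in-plane 4-neighbourhood (8 optional) and
    through identity/4-neighbourhood links between consecutive snapshots.
    Long recordings are split at fully inactive snapshots, which no wave can
    span, keeping the labelling memory footprint small.
    """
    struct = _STRUCT3 if neighborhood == 4 else _STRUCT8
    mask, times = am.mask, am.times
    active_any = mask.reshape(len(mask), -1).any(axis=1)
    waves: list[WaveEvent] = []
    wid = 0
    # segment boundaries at quiet frames
    idx = np.where(active_any)[0]
    if len(idx) == 0:
        return waves
    splits = np.where(np.diff(idx) > 1)[0]
    seg_starts = np.concatenate([[idx[0]], idx[splits + 1]])
    seg_ends = np.concatenate([idx[splits], [idx[-1]]])
    dt = am.dt
    for a, b in zip(seg_starts, seg_ends):
        sub = mask[a:b + 1]
        lab, k = ndimage.label(sub, structure=struct)
        if k == 0:
            continue
        objs = ndimage.find_objects(lab)
        for ci, sl in enumerate(objs):
            comp = lab[sl] == ci + 1
            tt, ii, jj = np.nonzero(comp)
            t_index = tt + a + sl[0].start
            cells = np.column_stack([t_index,
                                     ii + sl[1].start,
                                     jj + sl[2].start])
            t0 = times[t_index.min()]
            t1 = times[t_index.max()]
            uniq = np.unique(cells[:, 1:], axis=0)
            # onset cells: active with no spatiotemporal predecessor
            comp_full = np.zeros_like(sub[sl[0]], shape=comp.shape) | comp
            prev = np.zeros_like(comp)
            prev[1:] = comp[:-1]
            prev_dil = prev | np.roll(prev, 1, 1) | np.roll(prev, -1, 1) \
                | np.roll(prev, 1, 2) | np.roll(prev, -1, 2)
            onset = comp & ~prev_dil
            onset[0] = comp[0]
            onset_map = onset.any(axis=0)
            inits = _initiation_clusters(onset_map)
            # guard against flicker: cluster count from first-activation times
            first_t = np.where(comp.any(axis=0),
                               np.argmax(comp, axis=0), -1)
            collision = len(inits) > 1
            waves.append(WaveEvent(
                id=wid,
                cells=cells,
                t0=float(t0), t1=float(t1),
                size_cells=len(uniq),
                size_mm2=len(uniq) * am.dx ** 2,
                duration=float(t1 - t0) + dt,
                initiation_points=[(c[0] + sl[1].start, c[1] + sl[2].start)
                                   for c in inits],
                collision=collision,
            ))
            wid += 1
    return waves


def wave_speed(w: WaveEvent, am: ActivityMask, step: float = 0.5,
               min_cells: int = 50, min_duration: float = 1.0) -> WaveEvent:
    """Backward-traced front speed (Fig-S1 style algorithm).

    From the most distal active point at the wave's final snapshot, step
    backward in ``step``-second hops, each time moving to the nearest active
    member point at that earlier time; the polyline length over the wave
    duration gives the mean speed, the fastest hop the maximum front speed.
    Collisions and small/short waves are excluded (reason recorded).
    """
    if w.collision:
        w.excluded_reason = "collision"
        return w
    if w.size_cells < min_cells:
        w.excluded_reason = "too_small"
        return w
    if w.duration < min_duration:
        w.excluded_reason = "too_short"
        return w
    times = am.times
    dt = am.dt
    cells = w.cells
    t_indices = cells[:, 0]
    init = np.array(w.initiation_points[0])
    tmax = t_indices.max()
    last = cells[t_indices == tmax][:, 1:]
    d2 = ((last - init) ** 2).sum(axis=1)
    current = last[np.argmax(d2)].astype(float)
    hop = max(1, int(round(step / dt)))
    path = [(times[tmax], current.copy())]
    k = tmax - hop
    tmin = t_indices.min()
    while k >= tmin:
        pts = cells[t_indices == k][:, 1:]
        if len(pts) == 0:
            # nearest non-empty earlier snapshot within one hop
            kk = k
            while kk > tmin and len(cells[t_indices == kk][:, 1:]) == 0:
                kk -= 1
            pts = cells[t_indices == kk][:, 1:]
            k = kk
            if len(pts) == 0:
                break
        d2 = ((pts - current) ** 2).sum(axis=1)
        current = pts[np.argmin(d2)].astype(float)
        path.append((times[k], current.copy()))
        k -= hop
    if len(path) < 2:
        w.excluded_reason = "trace_failed"
        return w
    pts = np.array([p for _t, p in path])
    ts = np.array([t for t, _p in path])
    # collapse sub-grid zigzag: keep nodes at least ~2 cells apart
    keep = [0]
    for i in range(1, len(pts)):
        if np.hypot(*(pts[i] - pts[keep[-1]])) >= 2.0 or i == len(pts) - 1:
            keep.append(i)
    pts, ts = pts[keep], ts[keep]
    w.front_path = pts
    # mean speed: recession rate of the front toward the initiation point
    # (a linear fit is robust to lattice quantisation of the traced path)
    dist = np.hypot(*(pts - init).T) * am.dx
    if len(ts) >= 3 and np.ptp(ts) > 0:
        w.mean_speed = float(abs(np.polyfit(ts, dist, 1)[0]))
    else:
        disp = np.hypot(*(pts[-1] - pts[0])) * am.dx
        w.mean_speed = float(disp / w.duration)
    seg = np.hypot(*np.diff(pts, axis=0).T) * am.dx
    seg_dt = -np.diff(ts)
    good = seg_dt > 0
    w.max_front_speed = float((seg[good] / seg_dt[good]).max()) if good.any() else 0.0
    return w


def interwave_intervals(am: ActivityMask, min_iwi: float = 2.0):
    """Per-cell intervals between successive activity onsets.

    Onsets closer than ``min_iwi`` to the previous accepted onset are merged
    into it.  Returns the pooled interval array and the per-cell count.
    """
    mask, times = am.mask, am.times
    T = len(times)
    onsets = mask[1:] & ~mask[:-1]
    iwis = []
    n = mask.shape[1]
    m = am.margin
    for i in range(m, n - m):
        for j in range(m, mask.shape[2] - m):
            tk = np.where(onsets[:, i, j])[0]
            if mask[0, i, j]:
                tk = np.concatenate([[-1], tk])
            if len(tk) < 2:
                continue
            tt = times[tk + 1] if tk[0] >= 0 else np.concatenate(
                [[times[0]], times[tk[1:] + 1]])
            accepted = [tt[0]]
            for t in tt[1:]:
                if t - accepted[-1] >= min_iwi:
                    accepted.append(t)
            if len(accepted) > 1:
                iwis.extend(np.diff(accepted))
    return np.asarray(iwis)


@dataclass
class CorrelationCurve:
    distances: np.ndarray  # mm
    coefficients: np.ndarray
    smooth_distances: np.ndarray
    smooth_mean: np.ndarray
    dispersion: np.ndarray  # +/- 1 SD band


def correlation_vs_distance(snap: SnapshotSeries, variable: str = "v",
                            reference=None, span: float = 0.3,
                            arrays: dict | None = None) -> CorrelationCurve:
    """Pearson correlation of every cell against a reference (center) cell.

    ``arrays`` may supply auxiliary field stacks (r, s, a) recorded at a
    coarser cadence.  Smoothing uses statsmodels' lowess (local linear
    regression); the dispersion band is +/- 1 SD of the coefficients in the
    lowess window.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    if arrays is not None and variable in arrays:
        x = np.asarray(arrays[variable], dtype=float)
    elif variable == "v":
        x = np.asarray(snap.v, dtype=float)
    elif variable in ("r", "s", "a") and getattr(snap, variable) is not None:
        x = np.asarray(getattr(snap, variable), dtype=float)
    else:
        raise ValueError(f"field {variable!r} not available in this series")
    T, n, _ = x.shape
    if T < 100:
        raise ValueError("need at least 100 snapshots for correlations")
    if reference is None:
        reference = (n // 2, n // 2)
    ref = x[:, reference[0], reference[1]]
    xm = x - x.mean(axis=0)
    rm = ref - ref.mean()
    denom = np.sqrt((xm ** 2).sum(axis=0) * (rm ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (xm * rm[:, None, None]).sum(axis=0) / denom
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    dist = np.hypot(ii - reference[0], jj - reference[1]) * snap.dx
    good = np.isfinite(corr)
    d, c = dist[good].ravel(), corr[good].ravel()
    order = np.argsort(d)
    d, c = d[order], c[order]
    sm = lowess(c, d, frac=span, return_sorted=True)
    # dispersion: rolling SD over the same span
    w = max(5, int(span * len(c)))
    sd = pd.Series(c).rolling(w, center=True, min_periods=5).std().to_numpy()
    return CorrelationCurve(distances=d, coefficients=c,
                            smooth_distances=sm[:, 0], smooth_mean=sm[:, 1],
                            dispersion=sd)


def fit_powerlaw(sizes, fit_range=None, nbins: int = 20, min_count: int = 50):
    """Log-binned least-squares power-law fit of a size distribution.

    Returns a dict with the log-log ``slope`` (density exponent, negative),
    ``intercept``, an ML exponent cross-check (continuous Hill estimator),
    and a curvature diagnostic: the quadratic coefficient of a second-order
    log-log fit, flagged when it indicates faster-than-power-law decay.
    """
    sizes = np.asarray(sizes, dtype=float)
    sizes = sizes[sizes > 0]
    if len(sizes) < min_count:
        raise ValueError(f"need at least {min_count} events, got {len(sizes)}")
    if sizes.min() == sizes.max():
        raise ValueError("degenerate size distribution")
    lo, hi = (sizes.min(), sizes.max()) if fit_range is None else fit_range
    edges = np.logspace(np.log10(lo), np.log10(hi * (1 + 1e-9)), nbins + 1)
    hist, _ = np.histogram(sizes, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    dens = hist / widths / len(sizes)
    good = hist > 0
    if good.sum() < 3:
        raise ValueError("too few occupied bins for a fit")
    lx, ly = np.log10(centers[good]), np.log10(dens[good])
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    quad = np.polyfit(lx, ly, 2)[0] if good.sum() >= 4 else 0.0
    xmin = lo
    tail = sizes[sizes >= xmin]
    ml_alpha = 1.0 + len(tail) / np.log(tail / xmin).sum()
    curved = bool(quad < -0.25)
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "ml_exponent": float(ml_alpha),
        "quadratic": float(quad),
        "curvature_flag": curved,
        "n": int(len(sizes)),
        "bin_centers": centers[good],
        "bin_density": dens[good],
        "rms_residual": float(np.sqrt((resid ** 2).mean())),
    }


def wave_table(waves: list[WaveEvent]) -> pd.DataFrame:
    rows = []
    for w in waves:
        rows.append(dict(
            id=w.id, t0=w.t0, t1=w.t1, size_cells=w.size_cells,
            size_mm2=w.size_mm2, duration_s=w.duration,
            mean_speed=w.mean_speed, max_speed=w.max_front_speed,
            collision=w.collision, n_initiation=len(w.initiation_points),
            excluded_reason=w.excluded_reason,
        ))
    return pd.DataFrame(rows)


def summarize_waves(snap: SnapshotSeries, threshold: float = DEFAULT_THRESHOLD,
                    margin: int = 5, speed_step: float = 0.5,
                    min_iwi: float = 2.0) -> dict:
    """Full Fig-2B style summary of a snapshot series."""
    am = threshold_activity(snap, threshold, margin)
    waves = label_waves(am)
    for w in waves:
        wave_speed(w, am, step=speed_step)
    speeds = [w.mean_speed for w in waves if w.mean_speed is not None]
    sizes = [w.size_mm2 for w in waves]
    durs = [w.duration for w in waves]
    iwis = interwave_intervals(am, min_iwi=min_iwi)
    # global initiation interval: distinct non-collision initiation events/time
    n_events = sum(max(1, len(w.initiation_points)) for w in waves)
    span = float(am.times[-1] - am.times[0]) if len(am.times) > 1 else np.nan
    return {
        "n_waves": len(waves),
        "mean_size_mm2": float(np.mean(sizes)) if sizes else np.nan,
        "sd_size_mm2": float(np.std(sizes)) if sizes else np.nan,
        "mean_duration_s": float(np.mean(durs)) if durs else np.nan,
        "sd_duration_s": float(np.std(durs)) if durs else np.nan,
        "mean_speed_mm_s": float(np.mean(speeds)) if speeds else np.nan,
        "sd_speed_mm_s": float(np.std(speeds)) if speeds else np.nan,
        "n_speed_waves": len(speeds),
        "mean_iwi_s": float(np.mean(iwis)) if len(iwis) else np.nan,
        "sd_iwi_s": float(np.std(iwis)) if len(iwis) else np.nan,
        "n_iwi": int(len(iwis)),
        "global_initiation_interval_s": span / n_events if n_events else np.nan,
        "waves": waves,
    }
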