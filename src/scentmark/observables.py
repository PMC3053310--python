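"""Territory geometry and dynamical observables.

A *territory* at time ``t`` is the set of sites where an animal's own
scent is still active.  This module extracts territories from scent
snapshots and computes the observables that characterize the two-time-
scale dynamics of the model: the (fast, diffusive) animal mean square
displacement, the (slow, subdiffusive) territory-boundary MSD, the
utilization distribution, and power-law fits ``MSD = K * t**alpha``.

Boundary bookkeeping in 1D
--------------------------
With two animals on a ring the two scent arcs meet at two interfaces,
each either a doubly-scented overlap or an unscented gap.  The boundary
*coordinate* is the circular midpoint of that interface interval.  The
two interfaces are labelled by orientation (left flank owned by animal
0 vs animal 1), which makes the per-boundary time series well defined
without any matching step; displacements are unwrapped by minimal-image
continuation between consecutive snapshots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import SimConfig
from .lattice import (
    boundary_of_mask,
    circular_mean,
    min_image,
    site_coords,
)
from .sim import EnsembleArchive, SimResult

__all__ = [
    "TerritorySnapshot",
    "MSDSeries",
    "UtilizationGrid",
    "active_mask",
    "extract_territory",
    "pair_boundaries_1d",
    "boundary_track_1d",
    "animal_msd",
    "boundary_msd",
    "utilization_distribution",
    "fit_power_law",
]


# ----------------------------------------------------------------------
# territory extraction
# ----------------------------------------------------------------------
@dataclass
class TerritorySnapshot:
    """Instantaneous territory of one animal."""

    animal: int
    time: float
    sites: np.ndarray  # flat indices with own active scent
    boundary: np.ndarray  # flat indices of the rim
    centroid: tuple[float, float]  # periodic circular-mean coordinates
    rho: float  # mean centroid-to-boundary distance
    bounds_1d: tuple[float, float] | None = None  # (left, right), 1D only
    empty: bool = False


def active_mask(last_visit: np.ndarray, time: float, tas: float) -> np.ndarray:
    """Active-scent indicator per site: age strictly below ``tas``."""
    return (time - last_visit) < tas


def extract_territory(
    last_visit: np.ndarray,
    time: float,
    config: SimConfig,
    animal: int,
) -> TerritorySnapshot:
    """Territory of ``animal`` from a scent snapshot ``last_visit`` (N, S).

    Site set = own active scent; boundary = member sites with at least
    one von-Neumann neighbour outside; centroid = per-axis circular
    mean; ``rho`` = mean minimal-image distance centroid -> boundary.
    An animal whose scent has fully expired yields a flagged empty
    snapshot.
    """
    L, dims = config.L, config.dims
    mask = active_mask(last_visit[animal], time, config.tas)
    sites = np.flatnonzero(mask)
    if sites.size == 0:
        return TerritorySnapshot(
            animal, time, sites, sites, (math.nan, math.nan), math.nan, None, True
        )
    bnd = boundary_of_mask(mask, L, dims)
    x, y = site_coords(sites, L, dims)
    cx = circular_mean(x, L)
    cy = circular_mean(y, L) if dims == 2 else 0.0
    bx, by = site_coords(bnd, L, dims)
    dx = min_image(bx - cx, L)
    dy = min_image(by - cy, L) if dims == 2 else np.zeros_like(dx)
    rho = float(np.mean(np.hypot(dx, dy))) if bnd.size else 0.0
    bounds = None
    if dims == 1:
        bounds = _arc_bounds_1d(last_visit, time, config, animal)
    return TerritorySnapshot(animal, time, sites, bnd, (cx, cy), rho, bounds)


def _runs_circular(code: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal circular runs of equal values: list of (start, length, value)."""
    L = code.size
    if np.all(code == code[0]):
        return [(0, L, int(code[0]))]
    # rotate so a run boundary sits at index 0
    brk = int(np.flatnonzero(code != np.roll(code, 1))[0])
    c = np.roll(code, -brk)
    change = np.flatnonzero(c != np.roll(c, 1))
    runs = []
    for i, s in enumerate(change):
        e = change[i + 1] if i + 1 < change.size else L
        runs.append((int((s + brk) % L), int(e - s), int(c[s])))
    return runs


def pair_boundaries_1d(
    last_visit: np.ndarray, time: float, config: SimConfig
) -> tuple[float, float]:
    """The two interface coordinates of a two-animal 1D system.

    Returns ``(b_left, b_right)`` where ``b_right`` is the interface
    whose counter-clockwise flank belongs to animal 0 (the clockwise
    end of territory 0) and ``b_left`` the other one.  Coordinates are
    circular midpoints of the overlap/gap interval; ``(nan, nan)`` if
    the interface structure is not the clean two-interface one (e.g.
    during the initial transient or after full scent expiry).
    """
    L = config.L
    a0 = active_mask(last_visit[0], time, config.tas)
    a1 = active_mask(last_visit[1], time, config.tas)
    code = a0.astype(np.int64) + 2 * a1.astype(np.int64)
    runs = _runs_circular(code)
    exclusive = [r for r in runs if r[2] in (1, 2)]
    if len(exclusive) != 2 or exclusive[0][2] == exclusive[1][2]:
        return (math.nan, math.nan)
    b_right = b_left = math.nan
    n = len(runs)
    for i, (s, ln, v) in enumerate(runs):
        if v in (1, 2):
            continue
        prev_v = runs[(i - 1) % n][2]
        next_v = runs[(i + 1) % n][2]
        if {prev_v, next_v} != {1, 2}:
            return (math.nan, math.nan)  # pocket inside one territory
        mid = (s + (ln - 1) / 2.0) % L
        if prev_v == 1:
            b_right = mid
        else:
            b_left = mid
    # direct abutment (no gap/overlap run) between the two arcs
    for i, (s, ln, v) in enumerate(runs):
        nxt = runs[(i + 1) % n]
        if v == 1 and nxt[2] == 2:
            b_right = ((s + ln - 1) + 0.5) % L
        elif v == 2 and nxt[2] == 1:
            b_left = ((s + ln - 1) + 0.5) % L
    if math.isnan(b_right) or math.isnan(b_left):
        return (math.nan, math.nan)
    return (b_left, b_right)


def _arc_bounds_1d(last_visit, time, config, animal) -> tuple[float, float] | None:
    """(left, right) delimiting the animal's contiguous 1D arc.

    For the two-animal system the interface-midpoint rule is used; for
    other counts the outermost sites of the own active arc are returned.
    """
    L = config.L
    if config.N == 2:
        bl, br = pair_boundaries_1d(last_visit, time, config)
        if math.isnan(bl):
            return None
        if animal == 1:
            bl, br = br, bl
        return (bl, br)
    mask = active_mask(last_visit[animal], time, config.tas)
    runs = _runs_circular(mask.astype(np.int64))
    own = [r for r in runs if r[2] == 1]
    if not own:
        return None
    s, ln, _ = max(own, key=lambda r: r[1])
    return (float(s), float((s + ln - 1) % L))


# ----------------------------------------------------------------------
# MSD machinery
# ----------------------------------------------------------------------
@dataclass
class MSDSeries:
    """Ensemble-averaged mean square displacement vs time."""

    times: np.ndarray
    values: np.ndarray
    n_replicates: int
    subject: str  # "animal" | "boundary"
    K: float | None = None
    alpha: float | None = None
    fit_window: tuple[float, float] | None = None
    n_excluded: int = 0  # degenerate snapshots dropped from the average
    meta: dict = field(default_factory=dict)

    def restrict(self, t_min: float, t_max: float) -> "MSDSeries":
        m = (self.times >= t_min) & (self.times <= t_max)
        return MSDSeries(
            self.times[m], self.values[m], self.n_replicates, self.subject,
            n_excluded=self.n_excluded, meta=dict(self.meta),
        )


def animal_msd(
    archive: EnsembleArchive | list[SimResult],
    times: np.ndarray | None = None,
    t0: float | None = None,
) -> MSDSeries:
    """Ensemble MSD of the animals from unwrapped trajectories.

    Displacements are taken from each replicate's own baseline and
    averaged over replicates and animals.  ``times`` selects a subset of
    the recorded times (default: all); ``t0`` moves the baseline to the
    first recorded time at or after it (reported times are then elapsed
    ``t - t0``), which measures the settled-regime motion.
    """
    reps = list(archive)
    if not reps:
        raise ValueError("empty archive")
    ref_times = reps[0].times
    if times is None:
        idx = np.arange(ref_times.size)
        times = ref_times.astype(float)
    else:
        times = np.asarray(times, dtype=float)
        pos_lookup = {int(t): i for i, t in enumerate(ref_times)}
        try:
            idx = np.array([pos_lookup[int(t)] for t in times])
        except KeyError as e:
            raise ValueError(f"time {e} not recorded") from None
    base = 0
    offset = 0.0
    if t0 is not None:
        sel = np.flatnonzero(times >= t0)
        if sel.size == 0:
            raise ValueError(f"no recorded times at or after t0={t0}")
        idx, times = idx[sel], times[sel]
        offset = float(times[0])
        base = 0
    acc = np.zeros(idx.size)
    n = 0
    for res in reps:
        u = res.upos[idx].astype(float)
        d = u - u[base]
        acc += (d**2).sum(axis=2).mean(axis=1)
        n += 1
    return MSDSeries(times=times - offset, values=acc / n,
                     n_replicates=n, subject="animal",
                     meta={"t0": offset})


def boundary_track_1d(res: SimResult) -> np.ndarray:
    """Unwrapped (n_snap, 2) boundary coordinates of a two-animal 1D run.

    NaN rows mark snapshots whose interface structure was degenerate;
    unwrapping continues across them from the last valid value.
    """
    cfg = res.config
    if cfg.dims != 1 or cfg.N != 2:
        raise ValueError("boundary_track_1d needs a two-animal 1D run")
    L = cfg.L
    out = np.full((res.snap_times.size, 2), np.nan)
    last = None
    for k, t in enumerate(res.snap_times):
        bl, br = pair_boundaries_1d(res.snaps[k], float(t), cfg)
        if math.isnan(bl):
            continue
        cur = np.array([bl, br])
        if last is None:
            out[k] = cur
            last = (cur, cur)
        else:
            prev_u, prev_w = last
            u = prev_u + min_image(cur - prev_w, L)
            out[k] = u
            last = (u, cur)
    return out


def boundary_msd(
    archive: EnsembleArchive | list[SimResult],
    direction_deg: float = 45.0,
    t0: float | None = None,
) -> MSDSeries:
    """Ensemble MSD of the territory boundaries.

    1D (two animals): MSD of a boundary point, averaged over the two
    labelled interfaces and over replicates.  2D: centroid MSD plus the
    variance of the territory radius measured along a fixed reference
    direction (north-east by default), averaged over animals.
    Degenerate snapshots are excluded from the average and counted in
    ``n_excluded``.

    ``t0`` sets the displacement baseline: snapshots before ``t0`` are
    dropped and the reported times are elapsed times ``t - t0``.  Use a
    baseline past the formation transient to measure the settled
    (asymptotic-regime) boundary motion; the default baselines each
    replicate at its first valid snapshot.
    """
    reps = list(archive)
    if not reps:
        raise ValueError("empty archive")
    cfg = reps[0].config
    snap_times = reps[0].snap_times
    keep = np.arange(snap_times.size)
    offset = 0.0
    if t0 is not None:
        keep = np.flatnonzero(snap_times >= t0)
        if keep.size == 0:
            raise ValueError(f"no snapshots at or after t0={t0}")
        offset = float(snap_times[keep[0]])
    times_out = snap_times[keep].astype(float) - offset
    if cfg.dims == 1:
        acc = np.zeros(keep.size)
        cnt = np.zeros(keep.size, dtype=np.int64)
        excluded = 0
        for res in reps:
            track = boundary_track_1d(res)[keep]
            valid0 = np.flatnonzero(~np.isnan(track[:, 0]))
            if valid0.size == 0 or (t0 is not None and valid0[0] != 0):
                excluded += keep.size
                continue
            d = track - track[valid0[0]]
            ok = ~np.isnan(d[:, 0])
            excluded += int((~ok).sum())
            acc[ok] += (d[ok] ** 2).mean(axis=1)
            cnt[ok] += 1
        vals = np.divide(acc, cnt, out=np.full_like(acc, np.nan), where=cnt > 0)
        series = MSDSeries(times_out, vals, len(reps),
                           "boundary", n_excluded=excluded,
                           meta={"t0": offset})
        return series
    return _boundary_msd_2d(reps, snap_times, keep, direction_deg, times_out)


def _boundary_msd_2d(reps, snap_times, keep, direction_deg, times_out) -> MSDSeries:
    cfg = reps[0].config
    L = cfg.L
    theta = math.radians(direction_deg)
    n_t = keep.size
    # per replicate/animal: unwrapped centroid track + directional radius
    cen_sq = np.zeros(n_t)
    cen_cnt = np.zeros(n_t, dtype=np.int64)
    rho_vals: list[list[float]] = [[] for _ in range(n_t)]
    excluded = 0
    for res in reps:
        for a in range(cfg.N):
            track = np.full((n_t, 2), np.nan)
            rho_dir = np.full(n_t, np.nan)
            last = None
            for k, ksnap in enumerate(keep):
                t = snap_times[ksnap]
                terr = extract_territory(res.snaps[ksnap], float(t), cfg, a)
                if terr.empty or terr.boundary.size == 0:
                    excluded += 1
                    continue
                c = np.array(terr.centroid)
                if last is None:
                    track[k] = c
                    last = (c, c)
                else:
                    prev_u, prev_w = last
                    u = prev_u + min_image(c - prev_w, L)
                    track[k] = u
                    last = (u, c)
                bx, by = site_coords(terr.boundary, L, 2)
                dx = min_image(bx - terr.centroid[0], L)
                dy = min_image(by - terr.centroid[1], L)
                ang = np.arctan2(dy, dx)
                j = int(np.argmin(np.abs(np.angle(np.exp(1j * (ang - theta))))))
                rho_dir[k] = float(np.hypot(dx[j], dy[j]))
            valid = np.flatnonzero(~np.isnan(track[:, 0]))
            if valid.size == 0:
                continue
            d = track - track[valid[0]]
            ok = ~np.isnan(d[:, 0])
            cen_sq[ok] += (d[ok] ** 2).sum(axis=1)
            cen_cnt[ok] += 1
            for k in range(n_t):
                if not math.isnan(rho_dir[k]):
                    rho_vals[k].append(rho_dir[k])
    cen_msd = np.divide(cen_sq, cen_cnt, out=np.full_like(cen_sq, np.nan),
                        where=cen_cnt > 0)
    rho_var = np.array(
        [np.var(v) if len(v) > 1 else 0.0 for v in rho_vals]
    )
    return MSDSeries(
        times_out, cen_msd + rho_var, len(reps), "boundary",
        n_excluded=excluded, meta={"direction_deg": direction_deg},
    )


# ----------------------------------------------------------------------
# utilization distribution
# ----------------------------------------------------------------------
@dataclass
class UtilizationGrid:
    """Per-animal relative site-occupancy frequency over a window."""

    T_obs: float
    grids: np.ndarray  # (N, L) or (N, L, L), each summing to 1

    @property
    def N(self) -> int:
        return self.grids.shape[0]


def utilization_distribution(
    archive: EnsembleArchive | SimResult,
    T_obs: float,
) -> UtilizationGrid:
    """Relative frequency of recorded (wrapped) locations up to ``T_obs``."""
    reps = [archive] if isinstance(archive, SimResult) else list(archive)
    cfg = reps[0].config
    L, dims, N = cfg.L, cfg.dims, cfg.N
    if T_obs > reps[0].times[-1]:
        raise ValueError(
            f"T_obs={T_obs} exceeds recorded span {reps[0].times[-1]}"
        )
    shape = (N, L) if dims == 1 else (N, L, L)
    counts = np.zeros(shape, dtype=np.int64)
    for res in reps:
        m = res.times <= T_obs
        for a in range(N):
            if dims == 1:
                np.add.at(counts[a], res.pos[m, a, 0], 1)
            else:
                np.add.at(counts[a], (res.pos[m, a, 0], res.pos[m, a, 1]), 1)
    tot = counts.reshape(N, -1).sum(axis=1).astype(float)
    grids = counts / tot.reshape((N,) + (1,) * (dims))
    return UtilizationGrid(T_obs=T_obs, grids=grids)


# ----------------------------------------------------------------------
# power-law fits
# ----------------------------------------------------------------------
def fit_power_law(
    series: MSDSeries,
    window: tuple[float, float] | None = None,
    constrain_alpha: float | None = None,
) -> tuple[float, float]:
    """Least-squares fit of ``MSD = K * t**alpha`` in log-log space.

    ``constrain_alpha`` fixes the exponent (e.g. 1/2 for the 1D boundary
    law) and estimates only the amplitude ``K`` (geometric-mean
    residual).  Requires at least 5 positive points in the window.  The
    fitted values are stored on the series and returned as ``(K, alpha)``.
    """
    t = np.asarray(series.times, dtype=float)
    v = np.asarray(series.values, dtype=float)
    m = (t > 0) & (v > 0) & ~np.isnan(v)
    if window is not None:
        m &= (t >= window[0]) & (t <= window[1])
    if m.sum() < 5:
        raise ValueError(f"need >= 5 positive points in window, have {int(m.sum())}")
    lt, lv = np.log(t[m]), np.log(v[m])
    if constrain_alpha is None:
        alpha, logK = np.polyfit(lt, lv, 1)
    else:
        alpha = float(constrain_alpha)
        logK = float(np.mean(lv - alpha * lt))
    K = float(np.exp(logK))
    series.K, series.alpha = K, float(alpha)
    series.fit_window = (float(t[m].min()), float(t[m].max()))
    return K, float(alpha)
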