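"""Stochastic simulator of scent-depositing, scent-avoiding random walkers.

Model
-----
``N`` animals walk on a periodic lattice (ring in 1D, torus in 2D) in
discrete time.  Every site an animal occupies is stamped with that
animal's scent and the stamp stays *active* for ``tas`` time-steps
(strictly: a mark deposited at ``t0`` is active at ``t`` iff
``t - t0 < tas``).  An animal standing on a site carrying a neighbour's
active scent retreats: only the von-Neumann neighbours free of active
foreign scent are admissible; with no active foreign scent underfoot all
neighbours are admissible.  A trapped animal (no admissible move) stays
put.  Animals are updated once per time-step in a fresh random order, so
two movers never have to resolve a simultaneous conflict.

Two movement variants exist: ``plain`` (uniform choice among admissible
moves) and ``correlated_retreat`` (directional persistence for a few
steps after retreating from foreign scent, halving in strength each
step).  Optionally a *snooping* animal re-scents a contiguous fraction
``snoop_p`` of its territory perimeter whenever it reaches one of its
own boundary sites.

The fast path compiles the inner loop with numba; a pure-Python stepper
(`step_all`) implements the identical update rule and random-number
consumption and is used both as the reference oracle in the tests and as
the fallback engine whenever snooping is enabled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import ConfigError, SimConfig
from .lattice import (
    boundary_of_mask,
    circular_mean,
    neighbor_sites,
    order_boundary_sites,
    site_coords,
    site_index,
)

__all__ = [
    "SimState",
    "SimResult",
    "EnsembleArchive",
    "init_state",
    "active_foreign_owners",
    "admissible_moves",
    "step_all",
    "snoop_perimeter",
    "run",
    "run_ensemble",
    "log_times",
]

_DIRS = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]], dtype=np.int64)
_CHUNK_STEPS = 16_384
_STORAGE_LIMIT_BYTES = 2_000_000_000


# ----------------------------------------------------------------------
# state
# ----------------------------------------------------------------------
@dataclass
class SimState:
    """Mutable state of one running simulation.

    ``pos`` holds wrapped lattice coordinates, ``upos`` the unwrapped
    cumulative displacement (so mean square displacements are free of
    periodic-seam artefacts), ``last_visit[i, s]`` the time animal ``i``
    most recently occupied flat site ``s`` (``-inf`` = never).
    """

    config: SimConfig
    time: int
    pos: np.ndarray  # (N, 2) int64
    upos: np.ndarray  # (N, 2) int64
    heading: np.ndarray  # (N, 2) int64
    nsince: np.ndarray  # (N,) int64
    last_visit: np.ndarray  # (N, S) float64
    rng: np.random.Generator = field(repr=False, default=None)

    @property
    def N(self) -> int:
        return self.config.N

    def copy(self) -> "SimState":
        import copy as _copy

        return SimState(
            config=self.config,
            time=self.time,
            pos=self.pos.copy(),
            upos=self.upos.copy(),
            heading=self.heading.copy(),
            nsince=self.nsince.copy(),
            last_visit=self.last_visit.copy(),
            rng=_copy.deepcopy(self.rng),
        )


def init_state(config: SimConfig, seed: int | None = None) -> SimState:
    """Initial state: animals spread out, no scent except underfoot.

    Placement rule (``placement="grid"``): animals occupy a regular
    sublattice — in 1D animal ``k`` sits at ``floor(k * L / N)`` (two
    animals are diametrically opposed), in 2D on a ``g x g`` grid with
    ``g = ceil(sqrt(N))``.  ``placement="random"`` draws ``N`` distinct
    uniform sites from the seeded generator.  Each animal's starting
    site is stamped with its own scent at ``t = 0``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    N, L, dims = config.N, config.L, config.dims
    pos = np.zeros((N, 2), dtype=np.int64)
    if config.placement == "grid":
        if dims == 1:
            pos[:, 0] = (np.arange(N) * L) // N
        else:
            g = math.ceil(math.sqrt(N))
            k = np.arange(N)
            pos[:, 0] = ((k % g) * L) // g
            pos[:, 1] = ((k // g) * L) // g
    else:
        flat = rng.choice(config.n_sites, size=N, replace=False)
        x, y = site_coords(flat, L, dims)
        pos[:, 0] = x
        pos[:, 1] = y
    if len({(int(x), int(y)) for x, y in pos}) != N:
        raise ConfigError("initial placement produced coinciding animals")
    last_visit = np.full((N, config.n_sites), -np.inf, dtype=np.float64)
    s = site_index(pos[:, 0], pos[:, 1], L, dims)
    last_visit[np.arange(N), s] = 0.0
    return SimState(
        config=config,
        time=0,
        pos=pos,
        upos=pos.copy(),
        heading=np.zeros((N, 2), dtype=np.int64),
        nsince=np.zeros(N, dtype=np.int64),
        last_visit=last_visit,
        rng=rng,
    )


# ----------------------------------------------------------------------
# single-step operations (reference implementation)
# ----------------------------------------------------------------------
def active_foreign_owners(
    state: SimState, site: tuple[int, int] | int, animal: int, tas: float | None = None
) -> set[int]:
    """Animals ``j != animal`` whose scent is active at ``site`` now.

    Activity is strict: a mark of age exactly ``tas`` has just expired.
    """
    cfg = state.config
    if tas is None:
        tas = cfg.tas
    if isinstance(site, tuple):
        s = int(site_index(np.int64(site[0]), np.int64(site[1]), cfg.L, cfg.dims))
    else:
        s = int(site)
    age = state.time - state.last_visit[:, s]
    active = age < tas
    active[animal] = False
    return set(np.flatnonzero(active).tolist())


def admissible_moves(
    state: SimState, animal: int, tas: float | None = None
) -> list[tuple[int, int]]:
    """Destinations animal ``animal`` may move to this step.

    If the animal's own site carries active foreign scent it is
    retreating and only scent-free neighbours qualify; otherwise every
    von-Neumann neighbour does.  The empty list (animal encircled by
    active foreign scent) is a legal return and means "stay put".
    """
    cfg = state.config
    x, y = int(state.pos[animal, 0]), int(state.pos[animal, 1])
    nbrs = neighbor_sites(x, y, cfg.L, cfg.dims)
    if not active_foreign_owners(state, (x, y), animal, tas):
        return nbrs
    return [
        nb for nb in nbrs if not active_foreign_owners(state, nb, animal, tas)
    ]


def _choose_direction(
    state: SimState,
    animal: int,
    adm_dirs: list[int],
    encounter: bool,
    u_move: float,
    u_corr: float,
) -> int:
    """Index into ``adm_dirs``; mirrors the compiled kernel exactly."""
    cfg = state.config
    n_new = int(state.nsince[animal])  # already updated for this step
    hx, hy = int(state.heading[animal, 0]), int(state.heading[animal, 1])
    if (
        cfg.variant == "correlated_retreat"
        and n_new >= 1
        and (hx != 0 or hy != 0)
    ):
        decay = 2.0 ** (-float(min(n_new - 1, 1024)))
        if cfg.dims == 1:
            q = cfg.q0 * decay
            hd = next(
                (a for a, d in enumerate(adm_dirs) if _DIRS[d, 0] == hx), -1
            )
            if hd >= 0 and u_corr < q:
                return hd
        else:
            lam = cfg.lam0 * decay
            w = [
                math.exp(-lam * (1 - (_DIRS[d, 0] * hx + _DIRS[d, 1] * hy)))
                for d in adm_dirs
            ]
            u = u_corr * sum(w)
            c = 0.0
            for a, wa in enumerate(w):
                c += wa
                if u < c:
                    return a
            return len(adm_dirs) - 1
    return min(int(u_move * len(adm_dirs)), len(adm_dirs) - 1)


def step_all(state: SimState, config: SimConfig | None = None) -> SimState:
    """Advance every animal once (randomized sequential order), in place.

    The update order is the argsort of one uniform per animal; a second
    and third uniform feed the move choice — the identical consumption
    pattern the compiled kernel uses, so both engines produce the same
    trajectory from the same seed.
    """
    cfg = state.config if config is None else config
    N, L, dims = cfg.N, cfg.L, cfg.dims
    R = state.rng.random((3, N))
    order = np.argsort(R[0])
    state.time += 1
    t = state.time
    for i in order:
        i = int(i)
        x, y = int(state.pos[i, 0]), int(state.pos[i, 1])
        encounter = bool(active_foreign_owners(state, (x, y), i, cfg.tas))
        nbrs = neighbor_sites(x, y, L, dims)
        if encounter:
            adm_dirs = [
                d
                for d, nb in enumerate(nbrs)
                if not active_foreign_owners(state, nb, i, cfg.tas)
            ]
        else:
            adm_dirs = list(range(len(nbrs)))
        state.nsince[i] = 0 if encounter else state.nsince[i] + 1
        if adm_dirs:
            a = _choose_direction(state, i, adm_dirs, encounter, R[1, i], R[2, i])
            d = adm_dirs[a]
            dx, dy = int(_DIRS[d, 0]), int(_DIRS[d, 1])
            x, y = (x + dx) % L, (y + dy) % L
            state.pos[i, 0], state.pos[i, 1] = x, y
            state.upos[i, 0] += dx
            state.upos[i, 1] += dy
            state.heading[i, 0], state.heading[i, 1] = dx, dy
        s = int(site_index(np.int64(x), np.int64(y), L, dims))
        state.last_visit[i, s] = t
        if cfg.snoop_p > 0.0:
            _maybe_snoop(state, i, cfg.snoop_p)
    return state


def _own_active_mask(state: SimState, animal: int) -> np.ndarray:
    age = state.time - state.last_visit[animal]
    return age < state.config.tas if not state.config.scent_never_expires else np.isfinite(
        state.last_visit[animal]
    )


def _maybe_snoop(state: SimState, animal: int, snoop_p: float) -> None:
    """Trigger a perimeter snoop if the animal just reached its boundary."""
    cfg = state.config
    mask = _own_active_mask(state, animal)
    bnd = boundary_of_mask(mask, cfg.L, cfg.dims)
    s = int(
        site_index(state.pos[animal, 0], state.pos[animal, 1], cfg.L, cfg.dims)
    )
    if s in set(bnd.tolist()):
        snoop_perimeter(state, animal, snoop_p, arrival_site=s)


def snoop_perimeter(
    state: SimState,
    animal: int,
    snoop_p: float,
    arrival_site: int | None = None,
) -> SimState:
    """Refresh a contiguous fraction of the animal's territory perimeter.

    Starting from the arrival site and proceeding around the boundary
    loop in a randomly chosen direction, ``ceil(snoop_p * B)`` of the
    ``B`` boundary sites get their scent time-stamp set to now.  The
    animal itself does not move.  ``snoop_p = 0`` is a no-op.
    """
    if not 0.0 <= snoop_p <= 1.0:
        raise ValueError("snoop_p must lie in [0, 1]")
    if snoop_p == 0.0:
        return state
    cfg = state.config
    mask = _own_active_mask(state, animal)
    bnd = boundary_of_mask(mask, cfg.L, cfg.dims)
    if bnd.size == 0:
        return state
    x, y = site_coords(bnd, cfg.L, cfg.dims)
    cx = circular_mean(x, cfg.L)
    cy = circular_mean(y, cfg.L) if cfg.dims == 2 else 0.0
    ring = order_boundary_sites(bnd, cfg.L, cfg.dims, (cx, cy))
    if arrival_site is None:
        arrival_site = int(
            site_index(state.pos[animal, 0], state.pos[animal, 1], cfg.L, cfg.dims)
        )
    hits = np.flatnonzero(ring == arrival_site)
    start = int(hits[0]) if hits.size else 0
    count = math.ceil(snoop_p * ring.size)
    direction = 1 if state.rng.random() < 0.5 else -1
    idx = (start + direction * np.arange(count)) % ring.size
    state.last_visit[animal, ring[idx]] = state.time
    return state


# ----------------------------------------------------------------------
# full runs
# ----------------------------------------------------------------------
@dataclass
class SimResult:
    """Recorded output of one simulation run."""

    config: SimConfig
    seed: int
    times: np.ndarray  # (n_rec,) recorded position times
    pos: np.ndarray  # (n_rec, N, dims) wrapped
    upos: np.ndarray  # (n_rec, N, dims) unwrapped
    snap_times: np.ndarray  # (n_snap,)
    snaps: np.ndarray  # (n_snap, N, S) last-visit stamps
    engine: str = "numba"

    @property
    def N(self) -> int:
        return self.config.N

    def displacement(self) -> np.ndarray:
        """Unwrapped displacement from each animal's own start, (n_rec, N, dims)."""
        return self.upos - self.upos[0]

    def to_frame(self):
        """Long-format trajectory table (t, animal, x, y)."""
        import pandas as pd

        n_rec, N, dims = self.pos.shape
        return pd.DataFrame(
            {
                "t": np.repeat(self.times, N),
                "animal": np.tile(np.arange(N), n_rec),
                "x": self.pos[:, :, 0].ravel(),
                "y": self.pos[:, :, 1].ravel() if dims == 2 else 0,
            }
        )


def log_times(T_max: int, n: int = 64, t_min: int = 1) -> np.ndarray:
    """~log-spaced integer times in ``[t_min, T_max]`` (unique, ascending)."""
    if T_max < t_min:
        return np.array([], dtype=np.int64)
    t = np.unique(
        np.round(
            np.geomspace(t_min, T_max, num=n)
        ).astype(np.int64)
    )
    return t[(t >= t_min) & (t <= T_max)]


def run(
    config: SimConfig,
    seed: int | None = None,
    rec_stride: int = 1,
    snap_times: np.ndarray | None = None,
    engine: str = "auto",
) -> SimResult:
    """Simulate ``config.T_max`` steps and record trajectories/snapshots.

    ``rec_stride`` thins the recorded positions; ``snap_times`` lists the
    times at which full scent snapshots are kept (default: every
    ``config.record_every`` steps).  ``engine`` is ``"numba"`` (fast
    path), ``"python"`` (reference stepper) or ``"auto"`` (numba unless
    snooping is on, which only the Python stepper implements).
    """
    seed = config.seed if seed is None else seed
    if snap_times is None:
        snap_times = np.arange(
            config.record_every, config.T_max + 1, config.record_every, dtype=np.int64
        )
    snap_times = np.asarray(snap_times, dtype=np.int64)
    if snap_times.size and (snap_times.min() < 1 or snap_times.max() > config.T_max):
        raise ValueError("snapshot times must lie in [1, T_max]")
    n_rec = config.T_max // rec_stride + 1
    est = (
        2 * n_rec * config.N * 2 * 8
        + snap_times.size * config.N * config.n_sites * 8
    )
    if est > _STORAGE_LIMIT_BYTES:
        raise MemoryError(
            f"recording plan needs ~{est/1e9:.1f} GB; thin rec_stride or snapshots"
        )
    if engine == "auto":
        engine = "python" if config.snoop_p > 0 else "numba"
    if engine == "python" or config.snoop_p > 0:
        return _run_python(config, seed, rec_stride, snap_times)
    return _run_numba(config, seed, rec_stride, snap_times)


def _alloc_outputs(config: SimConfig, rec_stride: int, snap_times: np.ndarray):
    n_rec = config.T_max // rec_stride + 1
    pos_out = np.zeros((n_rec, config.N, 2), dtype=np.int64)
    upos_out = np.zeros((n_rec, config.N, 2), dtype=np.int64)
    snaps = np.zeros((snap_times.size, config.N, config.n_sites), dtype=np.float64)
    return pos_out, upos_out, snaps


def _finish(config, seed, rec_stride, pos_out, upos_out, snap_times, snaps, engine):
    n_rec = pos_out.shape[0]
    times = np.arange(n_rec, dtype=np.int64) * rec_stride
    dims = config.dims
    return SimResult(
        config=config,
        seed=seed,
        times=times,
        pos=pos_out[:, :, :dims],
        upos=upos_out[:, :, :dims],
        snap_times=snap_times,
        snaps=snaps,
        engine=engine,
    )


def _run_numba(config, seed, rec_stride, snap_times) -> SimResult:
    from ._kernels import step_chunk

    state = init_state(config, seed)
    pos_out, upos_out, snaps = _alloc_outputs(config, rec_stride, snap_times)
    pos_out[0] = state.pos
    upos_out[0] = state.upos
    snap_ptr = 0
    t = 0
    while t < config.T_max:
        chunk = min(_CHUNK_STEPS, config.T_max - t)
        R = state.rng.random((chunk, 3, config.N))
        snap_ptr = step_chunk(
            state.pos,
            state.upos,
            state.heading,
            state.nsince,
            state.last_visit,
            np.int64(t),
            np.int64(chunk),
            np.int64(config.L),
            np.int64(config.dims),
            np.float64(config.tas),
            config.variant == "correlated_retreat",
            np.float64(config.q0),
            np.float64(config.lam0),
            R,
            np.int64(rec_stride),
            pos_out,
            upos_out,
            snap_times,
            snaps,
            np.int64(snap_ptr),
        )
        t += chunk
    state.time = config.T_max
    return _finish(config, seed, rec_stride, pos_out, upos_out, snap_times, snaps, "numba")


def _run_python(config, seed, rec_stride, snap_times) -> SimResult:
    state = init_state(config, seed)
    pos_out, upos_out, snaps = _alloc_outputs(config, rec_stride, snap_times)
    pos_out[0] = state.pos
    upos_out[0] = state.upos
    snap_ptr = 0
    for _ in range(config.T_max):
        step_all(state)
        t = state.time
        if t % rec_stride == 0:
            pos_out[t // rec_stride] = state.pos
            upos_out[t // rec_stride] = state.upos
        if snap_ptr < snap_times.size and t == snap_times[snap_ptr]:
            snaps[snap_ptr] = state.last_visit
            snap_ptr += 1
    return _finish(config, seed, rec_stride, pos_out, upos_out, snap_times, snaps, "python")


# ----------------------------------------------------------------------
# ensembles
# ----------------------------------------------------------------------
@dataclass
class EnsembleArchive:
    """Replicated runs of one configuration (replicate ``r`` uses ``seed + r``)."""

    config: SimConfig
    replicates: list[SimResult]

    def __len__(self) -> int:
        return len(self.replicates)

    def __iter__(self):
        return iter(self.replicates)

    def to_frame(self):
        import pandas as pd

        frames = []
        for r, res in enumerate(self.replicates):
            f = res.to_frame()
            f.insert(0, "replicate", r)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def save(self, out_dir: str) -> None:
        """Write config + compressed columnar trajectory tables."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        self.config.to_yaml(os.path.join(out_dir, "config.yaml"))
        self.to_frame().to_csv(
            os.path.join(out_dir, "trajectories.csv.gz"), index=False
        )


def run_ensemble(
    config: SimConfig,
    replicates: int,
    rec_stride: int = 1,
    snap_times: np.ndarray | None = None,
    engine: str = "auto",
) -> EnsembleArchive:
    """Run ``replicates`` independent realizations (seeds ``seed + r``)."""
    if replicates < 1:
        raise ValueError("need at least one replicate")
    results = [
        run(config, seed=config.seed + r, rec_stride=rec_stride,
            snap_times=snap_times, engine=engine)
        for r in range(replicates)
    ]
    return EnsembleArchive(config=config, replicates=results)
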