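"""Simulator core: movement/interaction rules, bookkeeping, invariants."""

import math

import numpy as np
import pytest

from scentmark.config import SimConfig
from scentmark.lattice import site_index
from scentmark.sim import (
    active_foreign_owners,
    admissible_moves,
    init_state,
    log_times,
    run,
    run_ensemble,
    snoop_perimeter,
    step_all,
)


def _stamp(state, animal, sites, t):
    cfg = state.config
    for x, y in sites:
        s = int(site_index(np.int64(x), np.int64(y), cfg.L, cfg.dims))
        state.last_visit[animal, s] = t


# ----------------------------------------------------------------------
# initial conditions
# ----------------------------------------------------------------------
def test_init_grid_placement_2d_distinct_with_own_stamps():
    cfg = SimConfig(dims=2, L=100, N=25, tas=1000.0)
    st = init_state(cfg)
    occupied = {(int(x), int(y)) for x, y in st.pos}
    assert len(occupied) == 25
    assert st.time == 0
    s = site_index(st.pos[:, 0], st.pos[:, 1], cfg.L, cfg.dims)
    assert np.all(st.last_visit[np.arange(25), s] == 0.0)
    # exactly one stamp per animal at t=0
    assert np.isfinite(st.last_visit).sum() == 25


def test_init_two_animals_1d_diametric():
    cfg = SimConfig(dims=1, L=100, N=2)
    st = init_state(cfg)
    xs = sorted(int(x) for x in st.pos[:, 0])
    assert xs == [0, 50]


def test_init_random_placement_distinct_and_seeded():
    cfg = SimConfig(dims=2, L=10, N=30, placement="random", seed=4)
    a, b = init_state(cfg), init_state(cfg)
    assert np.array_equal(a.pos, b.pos)
    assert len({(int(x), int(y)) for x, y in a.pos}) == 30


def test_saturated_lattice_leaves_no_scent_free_destination():
    cfg = SimConfig(dims=1, L=6, N=6, tas=math.inf)
    st = init_state(cfg)
    assert len({int(x) for x in st.pos[:, 0]}) == 6
    st.time = 1
    for i in range(6):
        x = int(st.pos[i, 0])
        for nb in [((x + 1) % 6, 0), ((x - 1) % 6, 0)]:
            assert active_foreign_owners(st, nb, i) != set()
        # the animal's own site is clean, so the move rule is still free
        assert len(admissible_moves(st, i)) == 2


# ----------------------------------------------------------------------
# scent activity and admissible moves
# ----------------------------------------------------------------------
def test_scent_expiry_is_strict():
    cfg = SimConfig(dims=1, L=20, N=2, tas=5.0)
    st = init_state(cfg)
    st.time = 10
    _stamp(st, 1, [(3, 0)], t=5)  # age exactly tas -> expired
    assert active_foreign_owners(st, (3, 0), 0) == set()
    _stamp(st, 1, [(4, 0)], t=6)  # age 4 < 5 -> active
    assert active_foreign_owners(st, (4, 0), 0) == {1}


def test_never_visited_site_has_no_owners_even_with_infinite_tas():
    cfg = SimConfig(dims=2, L=7, N=2, tas=math.inf)
    st = init_state(cfg)
    st.time = 100
    assert active_foreign_owners(st, (5, 1), 0) == set()
    assert active_foreign_owners(st, (2, 4), 0) == set()


def test_retreat_restricts_moves_to_unscented_neighbours():
    # blue stands on a red-scented site; red scent also at (3,2), (4,1)
    cfg = SimConfig(dims=2, L=7, N=2, tas=10.0)
    st = init_state(cfg)
    st.time = 1
    st.pos[1] = (4, 2)
    _stamp(st, 0, [(4, 2), (3, 2), (4, 1)], t=0)
    assert set(admissible_moves(st, 1)) == {(5, 2), (4, 3)}


def test_clean_site_allows_all_four_directions():
    cfg = SimConfig(dims=2, L=7, N=2, tas=10.0)
    st = init_state(cfg)
    st.pos[0] = (2, 2)
    assert len(admissible_moves(st, 0)) == 4


def test_encircled_animal_has_no_moves_and_stays():
    cfg = SimConfig(dims=2, L=7, N=2, tas=100.0)
    st = init_state(cfg)
    st.pos[1] = (3, 3)
    _stamp(st, 0, [(3, 3), (2, 3), (4, 3), (3, 2), (3, 4)], t=0)
    st.time = 1
    assert admissible_moves(st, 1) == []
    before = st.pos[1].copy()
    step_all(st)
    assert np.array_equal(st.pos[1], before)
    # trapped animal re-stamps its own site at the new time
    s = int(site_index(np.int64(3), np.int64(3), 7, 2))
    assert st.last_visit[1, s] == st.time


# ----------------------------------------------------------------------
# stepping engines
# ----------------------------------------------------------------------
@pytest.mark.parametrize(
    "cfg",
    [
        SimConfig(dims=1, L=32, N=3, tas=50.0, T_max=300, seed=7),
        SimConfig(dims=2, L=20, N=5, tas=30.0, T_max=200, seed=3),
        SimConfig(dims=2, L=16, N=4, tas=40.0, T_max=200, seed=1,
                  variant="correlated_retreat"),
        SimConfig(dims=1, L=24, N=2, tas=math.inf, T_max=200, seed=9),
    ],
)
def test_compiled_kernel_matches_reference_stepper(cfg):
    snaps = np.array([cfg.T_max // 2, cfg.T_max], dtype=np.int64)
    a = run(cfg, engine="numba", snap_times=snaps)
    b = run(cfg, engine="python", snap_times=snaps)
    assert np.array_equal(a.pos, b.pos)
    assert np.array_equal(a.upos, b.upos)
    assert np.array_equal(a.snaps, b.snaps)


def test_identical_seed_gives_identical_trajectories():
    cfg = SimConfig(dims=2, L=30, N=6, tas=100.0, T_max=500, seed=11)
    a = run(cfg, snap_times=np.array([], dtype=np.int64))
    b = run(cfg, snap_times=np.array([], dtype=np.int64))
    assert np.array_equal(a.pos, b.pos)


def test_correlated_variant_changes_the_trajectory():
    base = dict(dims=1, L=40, N=2, tas=200.0, T_max=400, seed=5)
    a = run(SimConfig(**base), snap_times=np.array([], dtype=np.int64))
    b = run(SimConfig(variant="correlated_retreat", **base),
            snap_times=np.array([], dtype=np.int64))
    assert not np.array_equal(a.pos, b.pos)


# ----------------------------------------------------------------------
# bookkeeping oracles (trajectory replay)
# ----------------------------------------------------------------------
def _replay_last_visit(res):
    """Recompute the scent field by replaying the recorded trajectory."""
    cfg = res.config
    lv = np.full((cfg.N, cfg.n_sites), -np.inf)
    hist = np.full((res.times.size, cfg.N), -1, dtype=np.int64)
    for k, t in enumerate(res.times):
        s = site_index(res.pos[k, :, 0], res.pos[k, :, 1] if cfg.dims == 2
                       else np.zeros(cfg.N, dtype=np.int64), cfg.L, cfg.dims)
        lv[np.arange(cfg.N), s] = t
        hist[k] = s
    return lv, hist


@pytest.mark.parametrize("dims,L,N,tas", [(1, 32, 3, 40.0), (2, 12, 4, 25.0)])
def test_scent_field_equals_trajectory_replay(dims, L, N, tas):
    cfg = SimConfig(dims=dims, L=L, N=N, tas=tas, T_max=800, seed=13)
    res = run(cfg, rec_stride=1, snap_times=np.array([cfg.T_max]))
    lv, _ = _replay_last_visit(res)
    assert np.array_equal(lv, res.snaps[0])


@pytest.mark.parametrize("dims,L,N,tas", [(1, 32, 3, 40.0), (2, 12, 4, 25.0)])
def test_retreating_animal_never_moves_onto_active_foreign_scent(dims, L, N, tas):
    cfg = SimConfig(dims=dims, L=L, N=N, tas=tas, T_max=800, seed=21)
    res = run(cfg, rec_stride=1, snap_times=np.array([], dtype=np.int64))
    _, hist = _replay_last_visit(res)
    # running stamp table built strictly from steps < t
    lv = np.full((N, cfg.n_sites), -np.inf)
    lv[np.arange(N), hist[0]] = 0
    for t in range(1, res.times.size):
        for i in range(N):
            s_prev, s_new = hist[t - 1, i], hist[t, i]
            others = [j for j in range(N) if j != i]
            on_foreign = any(t - lv[j, s_prev] < tas for j in others)
            if on_foreign and s_new != s_prev:
                assert not any(t - lv[j, s_new] < tas for j in others), (
                    f"step {t}: animal {i} retreated onto active foreign scent"
                )
        lv[np.arange(N), hist[t]] = t


def test_timestamps_non_decreasing_and_agents_conserved():
    cfg = SimConfig(dims=1, L=40, N=4, tas=60.0, T_max=500, seed=2)
    snaps = np.array([100, 300, 500], dtype=np.int64)
    res = run(cfg, snap_times=snaps)
    assert res.pos.shape[1] == 4
    for k in range(1, snaps.size):
        prev, cur = res.snaps[k - 1], res.snaps[k]
        m = np.isfinite(prev)
        assert np.all(cur[m] >= prev[m])


# ----------------------------------------------------------------------
# non-interacting limit
# ----------------------------------------------------------------------
@pytest.mark.parametrize("setup", ["single", "tas_zero"])
def test_free_walker_msd_matches_closed_form(setup):
    """Without interactions the MSD is exactly t (one site^2 per step)."""
    if setup == "single":
        cfg = SimConfig(dims=1, L=64, N=1, tas=100.0, T_max=256, seed=1)
    else:
        cfg = SimConfig(dims=1, L=64, N=2, tas=0.0, T_max=256, seed=1)
    arch = run_ensemble(cfg, 1500, rec_stride=16,
                        snap_times=np.array([], dtype=np.int64))
    from scentmark.observables import animal_msd

    am = animal_msd(arch)
    t = am.times[1:]
    rel = am.values[1:] / t
    tol = 4.0 * math.sqrt(2.0 / (1500 * cfg.N))
    assert np.all(np.abs(rel - 1.0) < tol)


def test_permanent_scent_freezes_the_partition():
    cfg = SimConfig(dims=1, L=50, N=2, tas=math.inf, T_max=6000, seed=0)
    res = run(cfg, snap_times=np.array([3000, 4500, 6000], dtype=np.int64))
    covered = np.isfinite(res.snaps[-1]).any(axis=0)
    assert covered.all()
    from scentmark.observables import pair_boundaries_1d

    b1 = pair_boundaries_1d(res.snaps[1], 4500.0, cfg)
    b2 = pair_boundaries_1d(res.snaps[2], 6000.0, cfg)
    assert b1 == pytest.approx(b2, abs=1.0)


# ----------------------------------------------------------------------
# snooping
# ----------------------------------------------------------------------
def _block_state(size=4):
    """Hand-built 2D state whose territory is a size x size block."""
    cfg = SimConfig(dims=2, L=12, N=2, tas=100.0, snoop_p=0.5)
    st = init_state(cfg)
    st.last_visit[:] = -np.inf  # discard the placement stamps
    st.time = 1
    _stamp(st, 0, [(x, y) for x in range(4, 4 + size) for y in range(4, 4 + size)], t=0)
    st.pos[0] = (4, 4)  # a corner of the block: a boundary site
    return cfg, st


def test_snoop_zero_is_a_no_op():
    _, st = _block_state()
    before = st.last_visit.copy()
    snoop_perimeter(st, 0, 0.0)
    assert np.array_equal(st.last_visit, before)


def test_snoop_full_perimeter_refreshes_every_boundary_site():
    from scentmark.lattice import boundary_of_mask

    cfg, st = _block_state()
    mask = (st.time - st.last_visit[0]) < cfg.tas
    bnd = boundary_of_mask(mask, cfg.L, cfg.dims)
    snoop_perimeter(st, 0, 1.0)
    assert np.all(st.last_visit[0, bnd] == st.time)


def test_snoop_half_of_a_12_site_boundary_refreshes_6_contiguous():
    from scentmark.lattice import boundary_of_mask, order_boundary_sites

    cfg, st = _block_state(size=4)  # 4x4 block: 12 boundary sites
    mask = (st.time - st.last_visit[0]) < cfg.tas
    bnd = boundary_of_mask(mask, cfg.L, cfg.dims)
    assert bnd.size == 12
    snoop_perimeter(st, 0, 0.5)
    refreshed = bnd[st.last_visit[0, bnd] == st.time]
    assert refreshed.size == 6
    ring = order_boundary_sites(bnd, cfg.L, cfg.dims, (5.5, 5.5))
    hits = np.isin(ring, refreshed)
    # contiguity on the ring: exactly one False->True transition
    assert int(np.sum(hits & ~np.roll(hits, 1))) == 1


# ----------------------------------------------------------------------
# ensembles
# ----------------------------------------------------------------------
def test_single_replicate_ensemble_equals_plain_run():
    cfg = SimConfig(dims=1, L=30, N=2, tas=40.0, T_max=100, seed=8)
    arch = run_ensemble(cfg, 1, snap_times=np.array([], dtype=np.int64))
    solo = run(cfg, seed=cfg.seed, snap_times=np.array([], dtype=np.int64))
    assert np.array_equal(arch.replicates[0].pos, solo.pos)


def test_replicates_use_distinct_offset_seeds():
    cfg = SimConfig(dims=1, L=30, N=2, tas=40.0, T_max=100, seed=8)
    arch = run_ensemble(cfg, 3, snap_times=np.array([], dtype=np.int64))
    assert not np.array_equal(arch.replicates[0].pos, arch.replicates[1].pos)
    assert arch.replicates[1].seed == cfg.seed + 1


def test_absurd_recording_plan_is_refused():
    cfg = SimConfig(dims=2, L=100, N=10, tas=10.0, T_max=10**8)
    with pytest.raises(MemoryError):
        run(cfg, rec_stride=1)


def test_archive_round_trip(tmp_path):
    cfg = SimConfig(dims=2, L=10, N=3, tas=20.0, T_max=50, seed=5)
    arch = run_ensemble(cfg, 2, snap_times=np.array([], dtype=np.int64))
    arch.save(str(tmp_path))
    assert (tmp_path / "config.yaml").exists()
    import pandas as pd

    tab = pd.read_csv(tmp_path / "trajectories.csv.gz")
    assert set(tab.columns) == {"replicate", "t", "animal", "x", "y"}
    assert tab["replicate"].nunique() == 2
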