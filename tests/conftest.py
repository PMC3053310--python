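"""Shared fixtures.

The expensive session fixtures (ensemble archives, the calibrated
universal curve) are computed once and shared across the observable,
home-range, inference and acceptance tests so the whole suite stays
desk-scale.
"""

from __future__ import annotations

import numpy as np
import pytest

from scentmark.config import SimConfig
from scentmark.sim import log_times, run_ensemble


@pytest.fixture(scope="session")
def pair_archive():
    """Two-animal 1D ensemble deep into the subdiffusive regime.

    L=32, tas = 0.26 T_R, 300 replicates, 2**18 steps: the boundary MSD
    has a clean sqrt(t) window in [2e4, 2.6e5].  Positions are thinned
    (the boundary observables only need the scent snapshots).
    """
    cfg = SimConfig(dims=1, L=32, N=2, tas=256.0, T_max=2**18, seed=3)
    snaps = log_times(cfg.T_max, n=36, t_min=64)
    return run_ensemble(cfg, 300, rec_stride=1024, snap_times=snaps)


@pytest.fixture(scope="session")
def pair_archive_early():
    """Same model, short and finely recorded: the early diffusive regime."""
    cfg = SimConfig(dims=1, L=32, N=2, tas=256.0, T_max=64, seed=3)
    return run_ensemble(cfg, 400, rec_stride=1,
                        snap_times=np.array([], dtype=np.int64))


@pytest.fixture(scope="session")
def universal_curve():
    """Boundary-amplitude calibration used by the inference tests."""
    from scentmark.inference import calibrate_universal_curve

    return calibrate_universal_curve(replicates=200, seed=5)


@pytest.fixture(scope="session")
def exclusivity_result():
    """Two-animal exclusivity cross-over over a small Z ladder."""
    from scentmark.homerange import exclusivity_scan

    cfg = SimConfig(dims=1, L=32, N=2, tas=100.0, T_max=2**16, seed=9)
    return exclusivity_scan(np.array([0.15, 0.4, 0.9]), T_obs=2048,
                            base_config=cfg, replicates=120)


@pytest.fixture(scope="session")
def frozen_sizes_l100():
    """Frozen territory sizes at L=100 (permanent scent), 300 replicates."""
    from scentmark.fpt import frozen_territory_sizes

    return frozen_territory_sizes(100, replicates=300, seed=3)
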