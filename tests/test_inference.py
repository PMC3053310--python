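"""Telemetry-to-active-scent-time chain: projection, calibration, inversion."""

import math

import numpy as np
import pytest

from scentmark.config import SimConfig
from scentmark.fpt import boundary_return_time
from scentmark.inference import (
    DEFAULT_WINDOW_FACTOR,
    TelemetrySummary,
    UniversalCurve,
    active_observation_hours,
    calibrate_time_step,
    calibrate_universal_curve,
    cut_ring_pair,
    estimate_diffusion_constant,
    infer_tas,
    infer_tas_1d,
    mean_exclusive_area,
    project_fixes_1d,
)
from scentmark.sim import run
from scentmark.telemetry import load_fox_table


# ----------------------------------------------------------------------
# projection
# ----------------------------------------------------------------------
def test_projection_hand_geometry():
    # centroids exactly (0,0) and (10,0): the axis is x, origin at (5,0),
    # so the fix (3,4) projects to 3 - 5 = -2
    fa = np.array([[3.0, 4.0], [-3.0, -4.0]])
    fb = np.array([[10.0, 0.0], [10.0, 0.0]])
    pa, pb = project_fixes_1d(fa, fb)
    assert pa[0] == pytest.approx(-2.0)
    assert pb == pytest.approx([5.0, 5.0])


def test_projection_preserves_collinear_distances():
    fa = np.array([[0.0, 0.0], [2.0, 0.0], [4.0, 0.0]])
    fb = np.array([[10.0, 0.0], [12.0, 0.0]])
    pa, pb = project_fixes_1d(fa, fb)
    assert np.diff(pa) == pytest.approx([2.0, 2.0])


def test_projection_antisymmetric_under_label_swap():
    rng = np.random.default_rng(1)
    fa = rng.normal([0, 0], 2, (30, 2))
    fb = rng.normal([12, 5], 2, (30, 2))
    pa, pb = project_fixes_1d(fa, fb)
    pa2, pb2 = project_fixes_1d(fb, fa)
    assert pa == pytest.approx(-pb2)
    assert pb == pytest.approx(-pa2)


def test_projection_requires_distinct_centroids():
    same = np.array([[1.0, 1.0], [1.0, 1.0]])
    with pytest.raises(ValueError, match="coincide"):
        project_fixes_1d(same, same)


# ----------------------------------------------------------------------
# diffusion constant and time-step calibration
# ----------------------------------------------------------------------
def _brownian_fixes(D_m2_min, n_excursions, rng, cadence_s=300.0, dims=2):
    """Stationary spells interleaved with Brownian excursions."""
    D = D_m2_min / 60.0  # m^2/s
    rows, times = [], []
    t = 0.0
    pos = np.zeros(dims)
    for _ in range(n_excursions):
        for _ in range(3):  # stationary spell
            rows.append(pos.copy())
            times.append(t)
            t += cadence_s
        for _ in range(6):  # moving: 25 min of displacements + onset fix
            pos = pos + rng.normal(0, math.sqrt(2 * D * cadence_s), dims)
            rows.append(pos.copy())
            times.append(t)
            t += cadence_s
    return np.array(rows), np.array(times)


def test_diffusion_constant_recovered_within_ten_percent():
    rng = np.random.default_rng(3)
    fixes, times = _brownian_fixes(40.0, 200, rng)
    D = estimate_diffusion_constant(fixes, times, onset_threshold_m=25.0)
    assert D * 60.0 == pytest.approx(40.0, rel=0.10)


def test_stationary_fixes_give_zero_diffusion():
    fixes = np.zeros((50, 2))
    times = np.arange(50) * 300.0
    assert estimate_diffusion_constant(fixes, times, onset_threshold_m=10.0) == 0.0


def test_doubling_coordinates_quadruples_diffusion():
    rng = np.random.default_rng(5)
    fixes, times = _brownian_fixes(40.0, 150, rng)
    D1 = estimate_diffusion_constant(fixes, times, onset_threshold_m=25.0)
    D2 = estimate_diffusion_constant(2 * fixes, times, onset_threshold_m=50.0)
    assert D2 == pytest.approx(4 * D1, rel=1e-9)


def test_time_step_unit_walk_and_scaling():
    assert calibrate_time_step(0.5, 1.0, dims=1) == pytest.approx(1.0)
    assert calibrate_time_step(2.0, 4.0, 2) == pytest.approx(
        4 * calibrate_time_step(2.0, 2.0, 2)
    )
    with pytest.raises(ValueError):
        calibrate_time_step(0.0, 1.0, 1)


def test_time_step_round_trips_through_a_simulated_walk():
    """A lattice walk run at the calibrated dt reproduces the input D."""
    D, a = 0.125, 5.0  # m^2/s, m
    dt = calibrate_time_step(D, a, dims=1)
    cfg = SimConfig(dims=1, L=128, N=1, tas=0.0, T_max=400, seed=2)
    from scentmark.observables import animal_msd
    from scentmark.sim import run_ensemble

    arch = run_ensemble(cfg, 800, rec_stride=20,
                        snap_times=np.array([], dtype=np.int64))
    am = animal_msd(arch)
    # sites^2 per step -> m^2 per s
    slope = np.polyfit(am.times[1:] * dt, am.values[1:] * a * a, 1)[0]
    assert slope / 2.0 == pytest.approx(D, rel=0.05)


# ----------------------------------------------------------------------
# unit conversions and densities
# ----------------------------------------------------------------------
@pytest.mark.parametrize("days,hours,expected", [(90, 8, 720.0), (0, 8, 0.0),
                                                 (10, 12, 120.0)])
def test_active_observation_hours(days, hours, expected):
    assert active_observation_hours(days, hours) == expected


def test_active_observation_steps_via_dt():
    hours, steps = active_observation_hours(90, 8, dt_s=7.2)
    assert hours == 720.0
    assert steps == pytest.approx(720 * 3600 / 7.2)


def test_mean_exclusive_area_from_packaged_densities():
    tab = load_fox_table()
    densities = sorted(tab["density_per_ha"].unique())
    assert densities == [0.0257, 0.0324, 0.0442]
    assert mean_exclusive_area(densities) == pytest.approx(29.3, abs=0.05)


@pytest.mark.parametrize("dens,expected", [([1, 1, 1], 1.0), ([0.02, 0.05], 28.571)])
def test_mean_exclusive_area_arithmetic(dens, expected):
    assert mean_exclusive_area(dens) == pytest.approx(expected, abs=1e-3)


def test_mean_exclusive_area_rejects_bad_input():
    with pytest.raises(ValueError):
        mean_exclusive_area([])
    with pytest.raises(ValueError):
        mean_exclusive_area([0.1, -0.1])


# ----------------------------------------------------------------------
# universal curve
# ----------------------------------------------------------------------
def test_calibration_refuses_undersampling():
    with pytest.raises(ValueError, match="under-sample"):
        calibrate_universal_curve(replicates=1)


def test_curve_amplitude_monotone_and_collapsed(universal_curve):
    c = universal_curve
    assert np.all(np.diff(c._kt_nodes) < 0)  # slower boundaries, longer scent
    res = c.collapse_residuals()
    assert math.sqrt(float(np.mean(res**2))) < 0.15  # rms collapse residual
    # interpolation/inversion are mutual inverses inside the hull
    for Z in (0.25, 0.5, 0.7):
        assert c.invert(c.ktilde_of(Z)) == pytest.approx(Z, rel=1e-9)


def test_curve_refuses_extrapolation(universal_curve):
    lo, hi = universal_curve.z_range
    with pytest.raises(ValueError, match="outside"):
        universal_curve.ktilde_of(hi * 2)
    kmin, kmax = universal_curve.ktilde_range
    with pytest.raises(ValueError, match="outside"):
        universal_curve.invert(kmax * 10)


def test_curve_round_trips_through_json(tmp_path, universal_curve):
    p = tmp_path / "curve.json"
    universal_curve.save(str(p))
    back = UniversalCurve.load(str(p))
    assert np.array_equal(back.Z, universal_curve.Z)
    assert np.array_equal(back.K, universal_curve.K)
    assert back.provenance["replicates"] == universal_curve.provenance["replicates"]


def test_equal_Z_points_collapse_within_combined_error(universal_curve):
    """Two (tas, L) pairs at the same Z give the same collapsed amplitude."""
    c = universal_curve
    for z in np.unique(c.Z):
        kt = c.Ktilde[c.Z == z]
        assert kt.max() / kt.min() < 1.6


# ----------------------------------------------------------------------
# the 1D estimator
# ----------------------------------------------------------------------
def _synthetic_summary(Z_true, seed, L=64, cadence=8, a_m=10.0):
    TR = boundary_return_time(L)
    burn, T_obs = 32 * L * L, 2 * L * L
    cfg = SimConfig(dims=1, L=L, N=2, tas=float(Z_true * TR),
                    T_max=burn + T_obs, seed=seed)
    res = run(cfg, rec_stride=cadence, snap_times=np.array([], dtype=np.int64))
    m = res.times >= burn
    steps = res.times[m].astype(float)
    xa, xb = cut_ring_pair(res.pos[m, 0, 0].astype(float),
                           res.pos[m, 1, 0].astype(float), L)
    return TelemetrySummary(
        proj_a_m=xa * a_m, proj_b_m=xb * a_m, steps_a=steps, steps_b=steps,
        a_m=a_m, dt_s=60.0, ell_m=(L / 2) * a_m,
    )


def test_estimator_monotone_larger_overlap_means_shorter_scent(universal_curve):
    """A wider observed overlap (faster boundary) implies smaller tas."""
    rng = np.random.default_rng(0)
    ests = []
    for half_overlap in (40.0, 90.0):
        xa = rng.uniform(0, 300 + half_overlap, 600)
        xb = rng.uniform(300 - half_overlap, 640, 600)
        steps = np.arange(600) * 14.0
        s = TelemetrySummary(proj_a_m=xa, proj_b_m=xb, steps_a=steps,
                             steps_b=steps, a_m=10.0, dt_s=60.0, ell_m=320.0)
        ests.append(infer_tas_1d(s, universal_curve))
    assert ests[1].tas_steps < ests[0].tas_steps


def test_zero_overlap_reports_lower_bound_flag(universal_curve):
    rng = np.random.default_rng(1)
    xa = rng.uniform(0, 250, 500)
    xb = rng.uniform(390, 640, 500)
    steps = np.arange(500) * 16.0
    s = TelemetrySummary(proj_a_m=xa, proj_b_m=xb, steps_a=steps, steps_b=steps,
                         a_m=10.0, dt_s=60.0, ell_m=320.0)
    est = infer_tas_1d(s, universal_curve)
    assert est.flag == "lower_bound"
    assert est.tas_steps > 0


def test_infer_tas_dispatch_validates_backend(universal_curve):
    s = _synthetic_summary(0.4, seed=0)
    with pytest.raises(TypeError):
        infer_tas(s, "1d", backend={"not": "a curve"})
    est = infer_tas(s, "1d", universal_curve)
    assert est.mode == "1d"
    assert est.tas_days == pytest.approx(
        est.tas_steps * 60.0 / (3600 * 8), rel=1e-12
    )


def test_estimate_units_round_trip(universal_curve):
    """Scaling metres and seconds consistently leaves steps invariant."""
    s1 = _synthetic_summary(0.4, seed=3)
    est1 = infer_tas_1d(s1, universal_curve)
    s2 = TelemetrySummary(
        proj_a_m=s1.proj_a_m * 3.0, proj_b_m=s1.proj_b_m * 3.0,
        steps_a=s1.steps_a, steps_b=s1.steps_b,
        a_m=s1.a_m * 3.0, dt_s=s1.dt_s, ell_m=s1.ell_m * 3.0,
    )
    est2 = infer_tas_1d(s2, universal_curve)
    assert est2.tas_steps == pytest.approx(est1.tas_steps, rel=1e-9)
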