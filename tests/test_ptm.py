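"""Particle tracking: release schedule, interpolation, advection, settlement."""

import numpy as np
import pytest

from seascape import (
    FlowGridSpec,
    PTMConfig,
    ReleaseSchedule,
    SiteTable,
    Status,
    UniformResidual,
    advect,
    build_release_schedule,
    gen_flow,
    interp_velocity,
    run_ptm,
    settle,
)
from seascape._utils import haversine_km
from seascape.ptm import SECONDS_PER_DAY, TrajectoryBundle


# ---------------------------------------------------------------------------
# Release schedule
# ---------------------------------------------------------------------------


def test_default_schedule_releases_12000_per_site(one_site):
    """750 particles/day over 16 days at 12:00 -> 12,000 per site."""
    particles = build_release_schedule(one_site, 0.0, ReleaseSchedule())
    assert len(particles) == 12_000
    # all at 12:00 on the first 16 days
    hours = (particles.release_time_s % SECONDS_PER_DAY) / 3600.0
    assert np.all(hours == 12.0)
    days = particles.release_time_s // SECONDS_PER_DAY
    assert set(days) == set(range(16))


def test_single_particle_schedule(one_site):
    p = build_release_schedule(one_site, 0.0, ReleaseSchedule(cohort_size=1, n_release_days=1))
    assert len(p) == 1
    assert p.release_time_s[0] == 12 * 3600.0


def test_seven_sites_release_84000_distinct_ids():
    sites = SiteTable.from_records(
        [{"site_id": f"S{i}", "lon": -6 + 0.2 * i, "lat": 52.5 + 0.1 * i} for i in range(7)]
    )
    p = build_release_schedule(sites, 0.0, ReleaseSchedule())
    assert len(p) == 84_000
    assert len(np.unique(p.particle_id)) == 84_000


def test_site_outside_grid_is_named_in_error(small_grid_spec):
    grid = small_grid_spec.build()
    sites = SiteTable.from_records(
        [{"site_id": "inside", "lon": -5.5, "lat": 53.0}, {"site_id": "ocean", "lon": 10.0, "lat": 0.0}]
    )
    with pytest.raises(ValueError, match="ocean"):
        build_release_schedule(sites, 0.0, ReleaseSchedule(), field_grid=grid)


def test_schedule_validation():
    with pytest.raises(ValueError):
        ReleaseSchedule(cohort_size=0)
    with pytest.raises(ValueError):
        ReleaseSchedule(n_release_days=0)


# ---------------------------------------------------------------------------
# Velocity interpolation
# ---------------------------------------------------------------------------


def test_interpolation_identity_at_grid_nodes(uniform_east_flow):
    f = uniform_east_flow
    # perturb one node so the identity is informative
    f.u[1, 3, 4] = 0.25
    lon = f.grid.lon_axis[4]
    lat = f.grid.lat_axis[3]
    t = f.grid.time_axis[1]
    u, v, land = interp_velocity(f, lon, lat, t)
    assert u[0] == pytest.approx(0.25, abs=1e-14)
    assert v[0] == pytest.approx(0.0, abs=1e-14)
    assert not land[0]


def test_bilinear_midpoint_between_nodes(small_grid_spec):
    f = gen_flow(small_grid_spec, tidal_amplitude_ms=0.0, residual=None)
    f.u[:, :, :] = 0.0
    f.u[:, :, 5] = 0.0
    f.u[:, :, 6] = 0.2
    lon_mid = 0.5 * (f.grid.lon_axis[5] + f.grid.lon_axis[6])
    u, _, _ = interp_velocity(f, lon_mid, f.grid.lat_axis[2], f.grid.time_axis[0])
    assert u[0] == pytest.approx(0.1, abs=1e-12)


def test_linear_in_time_midpoint(small_grid_spec):
    f = gen_flow(small_grid_spec, tidal_amplitude_ms=0.0, residual=None)
    f.u[0] = 0.0
    f.u[1] = 0.2
    t_mid = 0.5 * (f.grid.time_axis[0] + f.grid.time_axis[1])
    u, _, _ = interp_velocity(f, f.grid.lon_axis[2], f.grid.lat_axis[2], t_mid)
    assert u[0] == pytest.approx(0.1, abs=1e-12)


def test_land_locked_position_returns_zero_and_flag():
    mask = np.ones((4, 4), dtype=bool)  # all land
    spec = FlowGridSpec(n_lon=4, n_lat=4, duration_days=1.0, land_mask=mask)
    f = gen_flow(spec, tidal_amplitude_ms=0.0, residual=UniformResidual(0.1, 0.0))
    u, v, land = interp_velocity(f, f.grid.lon_axis.mean(), f.grid.lat_axis.mean(), 0.0)
    assert u[0] == 0.0 and v[0] == 0.0 and land[0]


# ---------------------------------------------------------------------------
# Advection oracles
# ---------------------------------------------------------------------------


def _one_particle(one_site):
    return build_release_schedule(
        one_site, 0.0, ReleaseSchedule(cohort_size=1, n_release_days=1, release_hour=0.0)
    )


def test_zero_flow_keeps_particles_stationary(one_site, small_grid_spec):
    f = gen_flow(small_grid_spec, tidal_amplitude_ms=0.0, residual=None)
    traj = advect(_one_particle(one_site), f, PTMConfig(pld_days=2.0, settlement_window_days=(0, 2)))
    assert np.allclose(traj.lons, one_site.lon[0])
    assert np.allclose(traj.lats, one_site.lat[0])


@pytest.mark.parametrize("integrator", ["euler", "rk4"])
def test_uniform_flow_displacement_closed_form(one_site, uniform_east_flow, integrator):
    """0.1 m/s eastward for one day -> 8.64 km within 0.1%."""
    cfg = PTMConfig(pld_days=1.0, settlement_window_days=(0, 1), integrator=integrator)
    traj = advect(_one_particle(one_site), uniform_east_flow, cfg)
    d = haversine_km(one_site.lon[0], one_site.lat[0], traj.lons[0, -1], traj.lats[0, -1])
    assert d == pytest.approx(8.64, rel=1e-3)


def test_pure_tide_returns_to_start_after_integer_periods(one_site):
    """Sinusoidal tide over integer periods: net displacement <= one step length."""
    spec = FlowGridSpec(
        lon_min=-6.5, lon_max=-4.5, lat_min=52.2, lat_max=53.8,
        n_lon=20, n_lat=20, duration_days=2.0, time_step_h=0.25,
    )
    f = gen_flow(spec, tidal_amplitude_ms=1.0, tidal_period_h=12.0, residual=None)
    cfg = PTMConfig(pld_days=1.0, settlement_window_days=(0, 1))  # exactly 2 periods
    traj = advect(_one_particle(one_site), f, cfg)
    d_km = haversine_km(one_site.lon[0], one_site.lat[0], traj.lons[0, -1], traj.lats[0, -1])
    step_length_km = 1.0 * cfg.dt_s / 1000.0
    assert d_km <= step_length_km


def test_halving_dt_changes_positions_less_than_settlement_radius(one_site):
    spec = FlowGridSpec(
        lon_min=-6.5, lon_max=-4.5, lat_min=52.2, lat_max=53.8,
        n_lon=20, n_lat=20, duration_days=2.0, time_step_h=0.5,
    )
    f = gen_flow(spec, tidal_amplitude_ms=0.5, tidal_period_h=12.42, residual=UniformResidual(0.03, 0.01))
    finals = []
    for dt in (720.0, 360.0):
        cfg = PTMConfig(dt_s=dt, pld_days=1.5, settlement_window_days=(0, 1.5))
        traj = advect(_one_particle(one_site), f, cfg)
        finals.append((traj.lons[0, -1], traj.lats[0, -1]))
    d = haversine_km(finals[0][0], finals[0][1], finals[1][0], finals[1][1])
    assert d < 10.0


def test_euler_and_rk4_agree_on_smooth_field(one_site, uniform_east_flow):
    finals = {}
    for integ in ("euler", "rk4"):
        cfg = PTMConfig(pld_days=1.0, settlement_window_days=(0, 1), integrator=integ)
        traj = advect(_one_particle(one_site), uniform_east_flow, cfg)
        finals[integ] = (traj.lons[0, -1], traj.lats[0, -1])
    d = haversine_km(*finals["euler"], *finals["rk4"])
    assert d < 0.05  # km, O(dt) agreement on a uniform field


def test_boundary_exit_truncates_and_flags(one_site):
    spec = FlowGridSpec(
        lon_min=-5.6, lon_max=-5.3, lat_min=52.8, lat_max=53.2,
        n_lon=8, n_lat=8, duration_days=2.0,
    )
    f = gen_flow(spec, tidal_amplitude_ms=0.0, residual=UniformResidual(0.5, 0.0))
    # window opens only after the particle has left the small grid
    cfg = PTMConfig(pld_days=1.0, settlement_window_days=(0.5, 1.0))
    traj = advect(_one_particle(one_site), f, cfg)
    assert traj.exited[0]
    assert not traj.valid[0, -1]
    final = settle(traj, one_site, cfg)
    assert final.status[0] == Status.EXPIRED_BOUNDARY


def test_haversine_one_degree_longitude_at_equator():
    assert haversine_km(0.0, 0.0, 1.0, 0.0) == pytest.approx(111.19, abs=0.1)


# ---------------------------------------------------------------------------
# Settlement
# ---------------------------------------------------------------------------


def _manual_bundle(age_days, lons, lats):
    """Single-particle trajectory with hand-placed positions."""
    age = np.asarray(age_days, dtype=float) * SECONDS_PER_DAY
    lons = np.asarray(lons, dtype=float)[None, :]
    lats = np.asarray(lats, dtype=float)[None, :]
    return TrajectoryBundle(
        age_axis_s=age,
        release_time_s=np.array([0.0]),
        particle_id=np.array([0]),
        origin_site_id=np.array(["A"], dtype=object),
        lons=lons,
        lats=lats,
        valid=np.ones_like(lons, dtype=bool),
        exited=np.array([False]),
    )


def _km_east(lon0, lat, km):
    return lon0 + km / (111.194 * np.cos(np.radians(lat)))


def test_particle_at_site_settles_at_first_window_sample(one_site):
    bundle = _manual_bundle([29, 30, 31], [one_site.lon[0]] * 3, [one_site.lat[0]] * 3)
    final = settle(bundle, one_site, PTMConfig())
    assert final.status[0] == Status.SETTLED
    assert final.settled_site_id[0] == "A"
    assert final.settle_time_s[0] == 30 * SECONDS_PER_DAY


def test_contact_before_window_does_not_settle(one_site):
    """Within 10 km only at day 20 -> the day 30-40 window never fires."""
    lon0, lat0 = one_site.lon[0], one_site.lat[0]
    bundle = _manual_bundle(
        [20, 30, 40], [lon0, _km_east(lon0, lat0, 50), _km_east(lon0, lat0, 50)], [lat0] * 3
    )
    final = settle(bundle, one_site, PTMConfig())
    assert final.status[0] == Status.EXPIRED


def test_first_contact_wins_over_closer_later_site():
    """9.9 km from A at day 31, then 1 km from B at day 35 -> settles at A."""
    lat = 53.0
    lon_a, lon_b = -5.5, -5.0
    sites = SiteTable.from_records(
        [{"site_id": "A", "lon": lon_a, "lat": lat}, {"site_id": "B", "lon": lon_b, "lat": lat}]
    )
    bundle = _manual_bundle(
        [31, 35],
        [_km_east(lon_a, lat, 9.9), _km_east(lon_b, lat, 1.0)],
        [lat, lat],
    )
    final = settle(bundle, sites, PTMConfig())
    assert final.settled_site_id[0] == "A"
    assert final.settle_time_s[0] == 31 * SECONDS_PER_DAY


def test_tie_breaks_nearest_then_lexicographic():
    lat = 53.0
    sites = SiteTable.from_records(
        [
            {"site_id": "B", "lon": -5.0, "lat": lat},
            {"site_id": "A", "lon": -5.1, "lat": lat},  # equidistant midpoint below
            {"site_id": "C", "lon": -5.04, "lat": lat},  # nearer than either
        ]
    )
    mid = -5.05
    bundle = _manual_bundle([31], [mid], [lat])
    final = settle(bundle, sites, PTMConfig())
    assert final.settled_site_id[0] == "C"  # nearest wins
    two = SiteTable.from_records(
        [{"site_id": "B", "lon": -5.0, "lat": lat}, {"site_id": "A", "lon": -5.1, "lat": lat}]
    )
    bundle = _manual_bundle([31], [mid], [lat])
    final = settle(bundle, two, PTMConfig())
    assert final.settled_site_id[0] == "A"  # exact tie -> lexicographic


def test_empty_window_warns_and_expires_all(one_site):
    bundle = _manual_bundle([0, 1], [one_site.lon[0]] * 2, [one_site.lat[0]] * 2)
    with pytest.warns(UserWarning, match="window"):
        final = settle(bundle, one_site, PTMConfig())
    assert final.status[0] == Status.EXPIRED


def test_particle_count_conservation(one_site, small_grid_spec):
    f = gen_flow(small_grid_spec, tidal_amplitude_ms=0.2, residual=UniformResidual(0.05, 0.0))
    cfg = PTMConfig(dt_s=1800, pld_days=2.0, settlement_window_days=(1.0, 2.0))
    final, _ = run_ptm(f, one_site, 0.0, ReleaseSchedule(cohort_size=30, n_release_days=2, release_hour=0.0), cfg)
    released = len(final)
    settled = int((final.status == Status.SETTLED).sum())
    expired = int((final.status == Status.EXPIRED).sum())
    boundary = int((final.status == Status.EXPIRED_BOUNDARY).sum())
    assert released == 60
    assert settled + expired + boundary == released


def test_uniform_current_carries_all_particles_from_A_to_B():
    """|AB| = speed x 35 days along the current: A's cohort all settles at B."""
    speed = 0.03  # m/s -> 90.7 km over 35 days
    lat = 53.0
    dist_km = speed * 35 * SECONDS_PER_DAY / 1000.0
    lon_b = _km_east(-6.8, lat, dist_km)
    sites = SiteTable.from_records(
        [{"site_id": "A", "lon": -6.8, "lat": lat}, {"site_id": "B", "lon": lon_b, "lat": lat}]
    )
    spec = FlowGridSpec(
        lon_min=-7.2, lon_max=-4.0, lat_min=52.5, lat_max=53.5,
        n_lon=30, n_lat=10, duration_days=41.0, time_step_h=4.0,
    )
    f = gen_flow(spec, tidal_amplitude_ms=0.0, residual=UniformResidual(speed, 0.0))
    cfg = PTMConfig(dt_s=3600.0, output_interval_s=3600.0)
    final, _ = run_ptm(f, sites, 0.0, ReleaseSchedule(cohort_size=5, n_release_days=1, release_hour=0.0), cfg)
    from_a = final.origin_site_id == "A"
    assert np.all(final.status[from_a] == Status.SETTLED)
    assert set(final.settled_site_id[from_a]) == {"B"}


def test_config_validation():
    with pytest.raises(ValueError):
        PTMConfig(dt_s=7200.0, output_interval_s=3600.0)
    with pytest.raises(ValueError):
        PTMConfig(settlement_window_days=(30.0, 50.0), pld_days=40.0)
    with pytest.raises(ValueError):
        PTMConfig(land_policy="bounce")
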