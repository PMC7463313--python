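"""Lagrangian particle tracking for larval dispersal.

Release schedules, advection of neutrally buoyant particles through a gridded
velocity field, and settlement detection.  The default release schedule puts
cohorts of 750 particles per site into the water each day at 12:00 over the
first 16 days of a month (12,000 per site, spanning a spring-neap tidal
cycle); particles drift for a 40-day pelagic larval duration and settle at the
first trajectory sample aged 30-40 days that comes within 10 km
(great-circle) of a settlement site.

Particles are stored as arrays (one entry per particle) so that advection is
vectorised; trajectories are sampled on a common age axis, which makes the
settlement-window scan a slice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

from ._utils import M_PER_DEG, haversine_km, rng_for
from .flowfield import FlowField
from .sites import SiteTable

SECONDS_PER_DAY = 86_400.0


class Status(IntEnum):
    ACTIVE = 0
    SETTLED = 1
    EXPIRED = 2           # tracked for the full PLD without settling
    EXPIRED_BOUNDARY = 3  # left the grid before the window closed


@dataclass
class ReleaseSchedule:
    """Daily release specification for one spawning month."""

    cohort_size: int = 750
    n_release_days: int = 16
    release_hour: float = 12.0

    def __post_init__(self) -> None:
        if self.cohort_size <= 0:
            raise ValueError("cohort_size must be > 0")
        if self.n_release_days < 1:
            raise ValueError("n_release_days must be >= 1")

    @property
    def total_per_site(self) -> int:
        return self.cohort_size * self.n_release_days


@dataclass
class PTMConfig:
    """Numerical and biological parameters of the tracking model."""

    dt_s: float = 360.0
    output_interval_s: float = 3600.0
    pld_days: float = 40.0
    settlement_window_days: tuple[float, float] = (30.0, 40.0)
    settlement_radius_km: float = 10.0
    land_policy: str = "slide"  # halt | reflect | slide
    integrator: str = "rk4"     # euler | rk4
    diffusion_m2_s: float = 0.0  # horizontal random walk, off by default

    def __post_init__(self) -> None:
        if self.dt_s > self.output_interval_s:
            raise ValueError("dt must be <= output_interval")
        w0, w1 = self.settlement_window_days
        if not (0.0 <= w0 <= w1 <= self.pld_days):
            raise ValueError("settlement window must lie within [0, pld_days]")
        if self.land_policy not in ("halt", "reflect", "slide"):
            raise ValueError(f"unknown land_policy {self.land_policy!r}")
        if self.integrator not in ("euler", "rk4"):
            raise ValueError(f"unknown integrator {self.integrator!r}")


@dataclass
class ParticleEnsemble:
    """Array-of-structs particle state; one entry per particle."""

    particle_id: np.ndarray
    origin_site_id: np.ndarray  # dtype=object (site ids)
    release_time_s: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    status: np.ndarray
    settled_site_id: np.ndarray  # object, None when unsettled
    settle_time_s: np.ndarray    # NaN when unsettled

    def __len__(self) -> int:
        return self.particle_id.size

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "particle_id": self.particle_id,
                "origin_site_id": self.origin_site_id,
                "release_time_s": self.release_time_s,
                "lon": self.lon,
                "lat": self.lat,
                "status": [Status(s).name.lower() for s in self.status],
                "settled_site_id": self.settled_site_id,
                "settle_time_s": self.settle_time_s,
            }
        )


@dataclass
class TrajectoryBundle:
    """Positions of every particle sampled on a common age axis.

    ``lons``/``lats`` have shape (n_particles, n_samples); ``valid`` marks
    samples recorded before a particle left the grid (positions afterwards are
    frozen at the exit point and flagged invalid).
    """

    age_axis_s: np.ndarray
    release_time_s: np.ndarray
    particle_id: np.ndarray
    origin_site_id: np.ndarray
    lons: np.ndarray
    lats: np.ndarray
    valid: np.ndarray
    exited: np.ndarray  # per particle: left the grid at some point

    def __len__(self) -> int:
        return self.particle_id.size

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format (particle_id, t, lon, lat) table of valid samples."""
        n, m = self.lons.shape
        t_abs = self.release_time_s[:, None] + self.age_axis_s[None, :]
        mask = self.valid
        return pd.DataFrame(
            {
                "particle_id": np.repeat(self.particle_id, m)[mask.ravel()],
                "t": t_abs.ravel()[mask.ravel()],
                "lon": self.lons.ravel()[mask.ravel()],
                "lat": self.lats.ravel()[mask.ravel()],
            }
        )


# ---------------------------------------------------------------------------
# Release schedule
# ---------------------------------------------------------------------------


def build_release_schedule(
    sites: SiteTable,
    month_start_s: float = 0.0,
    schedule: ReleaseSchedule | None = None,
    field_grid=None,
) -> ParticleEnsemble:
    """Initial particle states for one spawning month.

    For each site, ``cohort_size`` particles are created at ``release_hour``
    on each of the first ``n_release_days`` days of the month, positioned at
    the site coordinates.  Particle ids are globally unique.
    """
    schedule = schedule or ReleaseSchedule()
    if field_grid is not None:
        inside = field_grid.contains(sites.lon, sites.lat)
        if not np.all(inside):
            bad = [sid for sid, ok in zip(sites.site_ids, inside) if not ok]
            raise ValueError(f"sites outside flow-field grid: {bad}")

    n_per_site = schedule.total_per_site
    n_total = n_per_site * len(sites)
    release_of_day = month_start_s + schedule.release_hour * 3600.0

    origin = np.empty(n_total, dtype=object)
    lon = np.empty(n_total)
    lat = np.empty(n_total)
    release = np.empty(n_total)
    k = 0
    for sid, slon, slat in zip(sites.site_ids, sites.lon, sites.lat):
        for day in range(schedule.n_release_days):
            sl = slice(k, k + schedule.cohort_size)
            origin[sl] = sid
            lon[sl] = slon
            lat[sl] = slat
            release[sl] = release_of_day + day * SECONDS_PER_DAY
            k += schedule.cohort_size
    return ParticleEnsemble(
        particle_id=np.arange(n_total),
        origin_site_id=origin,
        release_time_s=release,
        lon=lon,
        lat=lat,
        status=np.full(n_total, Status.ACTIVE, dtype=np.int8),
        settled_site_id=np.full(n_total, None, dtype=object),
        settle_time_s=np.full(n_total, np.nan),
    )


# ---------------------------------------------------------------------------
# Velocity interpolation
# ---------------------------------------------------------------------------


def interp_velocity(field: FlowField, lon, lat, t):
    """Bilinear-in-space, linear-in-time velocity lookup.

    Returns ``(u, v, on_land)``; ``on_land`` is True where all four
    surrounding cells are masked (velocity is then (0, 0)).  Inputs broadcast;
    times must lie within the field's time axis.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    t = np.broadcast_to(np.atleast_1d(np.asarray(t, dtype=float)), lon.shape)
    g = field.grid

    ti = np.clip(np.searchsorted(g.time_axis, t, side="right") - 1, 0, g.time_axis.size - 2)
    xi = np.clip(np.searchsorted(g.lon_axis, lon, side="right") - 1, 0, g.lon_axis.size - 2)
    yi = np.clip(np.searchsorted(g.lat_axis, lat, side="right") - 1, 0, g.lat_axis.size - 2)

    wt = (t - g.time_axis[ti]) / (g.time_axis[ti + 1] - g.time_axis[ti])
    wx = (lon - g.lon_axis[xi]) / (g.lon_axis[xi + 1] - g.lon_axis[xi])
    wy = (lat - g.lat_axis[yi]) / (g.lat_axis[yi + 1] - g.lat_axis[yi])
    wt = np.clip(wt, 0.0, 1.0)
    wx = np.clip(wx, 0.0, 1.0)
    wy = np.clip(wy, 0.0, 1.0)

    def bilin(arr3d, k):
        a00 = arr3d[k, yi, xi]
        a01 = arr3d[k, yi, xi + 1]
        a10 = arr3d[k, yi + 1, xi]
        a11 = arr3d[k, yi + 1, xi + 1]
        return (
            a00 * (1 - wx) * (1 - wy)
            + a01 * wx * (1 - wy)
            + a10 * (1 - wx) * wy
            + a11 * wx * wy
        )

    u = bilin(field.u, ti) * (1 - wt) + bilin(field.u, ti + 1) * wt
    v = bilin(field.v, ti) * (1 - wt) + bilin(field.v, ti + 1) * wt

    lm = g.land_mask
    on_land = lm[yi, xi] & lm[yi, xi + 1] & lm[yi + 1, xi] & lm[yi + 1, xi + 1]
    u = np.where(on_land, 0.0, u)
    v = np.where(on_land, 0.0, v)
    return u, v, on_land


def _is_land_cell(grid, lon, lat):
    xi = np.clip(np.searchsorted(grid.lon_axis, lon, side="right") - 1, 0, grid.lon_axis.size - 2)
    yi = np.clip(np.searchsorted(grid.lat_axis, lat, side="right") - 1, 0, grid.lat_axis.size - 2)
    lm = grid.land_mask
    return lm[yi, xi] & lm[yi, xi + 1] & lm[yi + 1, xi] & lm[yi + 1, xi + 1]


# ---------------------------------------------------------------------------
# Advection
# ---------------------------------------------------------------------------


def advect(
    particles: ParticleEnsemble,
    field: FlowField,
    config: PTMConfig | None = None,
    seed: int | None = None,
) -> TrajectoryBundle:
    """Integrate particle trajectories through the flow field.

    Each particle is stepped with the configured integrator at ``dt_s`` from
    its own release time for ``pld_days``; positions are recorded every
    ``output_interval_s`` of particle age.  Positions are updated in degrees
    using local metres-per-degree factors.  A particle that leaves the grid is
    frozen at its exit point and flagged.
    """
    config = config or PTMConfig()
    g = field.grid
    t_end_needed = float(np.max(particles.release_time_s)) + config.pld_days * SECONDS_PER_DAY
    if particles.release_time_s.min() < g.time_axis[0] - 1e-9 or t_end_needed > g.time_axis[-1] + 1e-9:
        raise ValueError(
            "flow field does not cover the tracking interval "
            f"[{particles.release_time_s.min():.0f}, {t_end_needed:.0f}] s"
        )

    n = len(particles)
    dt = config.dt_s
    steps_per_output = int(round(config.output_interval_s / dt))
    n_outputs = int(round(config.pld_days * SECONDS_PER_DAY / config.output_interval_s))
    age_axis = np.arange(n_outputs + 1) * config.output_interval_s

    lon = particles.lon.astype(float).copy()
    lat = particles.lat.astype(float).copy()
    alive = np.ones(n, dtype=bool)  # still inside the grid
    exited = np.zeros(n, dtype=bool)

    lons = np.empty((n, n_outputs + 1))
    lats = np.empty((n, n_outputs + 1))
    valid = np.zeros((n, n_outputs + 1), dtype=bool)
    lons[:, 0] = lon
    lats[:, 0] = lat
    valid[:, 0] = True

    rng = rng_for(seed, "ptm-diffusion") if config.diffusion_m2_s > 0 else None

    def deg_rates(u, v, lat_now):
        dlat = v / M_PER_DEG
        dlon = u / (M_PER_DEG * np.cos(np.radians(lat_now)))
        return dlon, dlat

    age = 0.0
    out_idx = 0
    for step in range(n_outputs * steps_per_output):
        t_abs = particles.release_time_s + age
        idx = np.nonzero(alive)[0]
        if idx.size:
            lo, la, ta = lon[idx], lat[idx], t_abs[idx]
            if config.integrator == "euler":
                u, v, _ = interp_velocity(field, lo, la, ta)
                dlon, dlat = deg_rates(u, v, la)
                new_lon = lo + dlon * dt
                new_lat = la + dlat * dt
            else:  # rk4
                u1, v1, _ = interp_velocity(field, lo, la, ta)
                k1x, k1y = deg_rates(u1, v1, la)
                u2, v2, _ = interp_velocity(field, lo + 0.5 * dt * k1x, la + 0.5 * dt * k1y, ta + 0.5 * dt)
                k2x, k2y = deg_rates(u2, v2, la + 0.5 * dt * k1y)
                u3, v3, _ = interp_velocity(field, lo + 0.5 * dt * k2x, la + 0.5 * dt * k2y, ta + 0.5 * dt)
                k3x, k3y = deg_rates(u3, v3, la + 0.5 * dt * k2y)
                u4, v4, _ = interp_velocity(field, lo + dt * k3x, la + dt * k3y, ta + dt)
                k4x, k4y = deg_rates(u4, v4, la + dt * k3y)
                new_lon = lo + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
                new_lat = la + dt / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y)

            if rng is not None:
                sigma_m = np.sqrt(2.0 * config.diffusion_m2_s * dt)
                new_lon = new_lon + rng.normal(0.0, sigma_m, idx.size) / (M_PER_DEG * np.cos(np.radians(la)))
                new_lat = new_lat + rng.normal(0.0, sigma_m, idx.size) / M_PER_DEG

            # land handling
            if g.land_mask.any():
                on_land = _is_land_cell(g, new_lon, new_lat)
                if on_land.any():
                    if config.land_policy == "halt":
                        new_lon = np.where(on_land, lo, new_lon)
                        new_lat = np.where(on_land, la, new_lat)
                    elif config.land_policy == "slide":
                        # zero the offending component: try lon-only, then lat-only
                        try_lon = _is_land_cell(g, new_lon, la)
                        cand_lon = np.where(try_lon, lo, new_lon)
                        cand_lat = np.where(try_lon, new_lat, la)
                        still = _is_land_cell(g, cand_lon, cand_lat)
                        cand_lon = np.where(still, lo, cand_lon)
                        cand_lat = np.where(still, la, cand_lat)
                        new_lon = np.where(on_land, cand_lon, new_lon)
                        new_lat = np.where(on_land, cand_lat, new_lat)
                    else:  # reflect
                        new_lon = np.where(on_land, 2 * lo - new_lon, new_lon)
                        new_lat = np.where(on_land, 2 * la - new_lat, new_lat)

            # grid-boundary exit: freeze at last inside position
            inside = g.contains(new_lon, new_lat)
            lon[idx] = np.where(inside, new_lon, lo)
            lat[idx] = np.where(inside, new_lat, la)
            left = idx[~inside]
            alive[left] = False
            exited[left] = True

        age += dt
        if (step + 1) % steps_per_output == 0:
            out_idx += 1
            lons[:, out_idx] = lon
            lats[:, out_idx] = lat
            valid[:, out_idx] = alive

    return TrajectoryBundle(
        age_axis_s=age_axis,
        release_time_s=particles.release_time_s.copy(),
        particle_id=particles.particle_id.copy(),
        origin_site_id=particles.origin_site_id.copy(),
        lons=lons,
        lats=lats,
        valid=valid,
        exited=exited,
    )


# ---------------------------------------------------------------------------
# Settlement
# ---------------------------------------------------------------------------


def settle(
    trajectories: TrajectoryBundle,
    sites: SiteTable,
    config: PTMConfig | None = None,
) -> ParticleEnsemble:
    """Apply the settlement rule to sampled trajectories.

    Trajectory samples whose particle age falls inside the settlement window
    are scanned in time order; the first sample within the settlement radius
    of any site settles the particle there (nearest site wins when several are
    in range; remaining ties break lexicographically on site id) and the scan
    stops.  Particles that never come in range expire; particles that left the
    grid before settling are counted as unsettled (boundary).
    """
    config = config or PTMConfig()
    w0, w1 = (d * SECONDS_PER_DAY for d in config.settlement_window_days)
    in_window = (trajectories.age_axis_s >= w0 - 1e-9) & (trajectories.age_axis_s <= w1 + 1e-9)
    window_idx = np.nonzero(in_window)[0]
    n = len(trajectories)

    status = np.full(n, Status.EXPIRED, dtype=np.int8)
    settled_site = np.full(n, None, dtype=object)
    settle_time = np.full(n, np.nan)

    if window_idx.size == 0:
        warnings.warn("settlement window contains no trajectory samples; all particles expire")
    else:
        site_ids = np.asarray(sites.site_ids, dtype=object)
        # lexicographic tie-break: pre-sort sites by id, stable argmin then favours
        # the lexicographically earlier id at exactly equal distance
        order = np.argsort(site_ids.astype(str))
        s_lon = sites.lon[order]
        s_lat = sites.lat[order]
        s_rad = sites.radius_km[order]
        s_ids = site_ids[order]

        unsettled = np.ones(n, dtype=bool)
        for j in window_idx:
            active = unsettled & trajectories.valid[:, j]
            idx = np.nonzero(active)[0]
            if idx.size == 0:
                continue
            d = haversine_km(
                trajectories.lons[idx, j][:, None],
                trajectories.lats[idx, j][:, None],
                s_lon[None, :],
                s_lat[None, :],
            )
            in_range = d <= s_rad[None, :]
            any_hit = in_range.any(axis=1)
            if not any_hit.any():
                continue
            hit = idx[any_hit]
            d_hit = np.where(in_range[any_hit], d[any_hit], np.inf)
            best = np.argmin(d_hit, axis=1)  # first (lexicographically earliest) at ties
            status[hit] = Status.SETTLED
            settled_site[hit] = s_ids[best]
            settle_time[hit] = trajectories.release_time_s[hit] + trajectories.age_axis_s[j]
            unsettled[hit] = False

    boundary = (status != Status.SETTLED) & trajectories.exited
    status[boundary] = Status.EXPIRED_BOUNDARY

    final_lon = trajectories.lons[:, -1].copy()
    final_lat = trajectories.lats[:, -1].copy()
    return ParticleEnsemble(
        particle_id=trajectories.particle_id.copy(),
        origin_site_id=trajectories.origin_site_id.copy(),
        release_time_s=trajectories.release_time_s.copy(),
        lon=final_lon,
        lat=final_lat,
        status=status,
        settled_site_id=settled_site,
        settle_time_s=settle_time,
    )


def run_ptm(
    field: FlowField,
    sites: SiteTable,
    month_start_s: float = 0.0,
    schedule: ReleaseSchedule | None = None,
    config: PTMConfig | None = None,
    seed: int | None = None,
) -> tuple[ParticleEnsemble, TrajectoryBundle]:
    """Release, advect and settle one month's cohorts; returns (final, trajectories)."""
    config = config or PTMConfig()
    particles = build_release_schedule(sites, month_start_s, schedule, field_grid=field.grid)
    traj = advect(particles, field, config, seed=seed)
    final = settle(traj, sites, config)
    return final, traj
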