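"""Gridded 2-D velocity fields and the synthetic flow generator.

The generator emulates the shelf-sea circulation regime that drives larval
dispersal in tidally energetic seas: strong but oscillatory tidal currents
(which advect particles tens of kilometres yet produce little net transport)
superimposed on weak (< 0.1 m/s) persistent residual circulation — a uniform
drift, a gyre, or a density-front jet.  Fields are depth-averaged: with no
observational constraint on larval vertical behaviour a 2-D field preserves
every property the downstream analysis exercises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from ._utils import M_PER_DEG, rng_for

MAX_SPEED_MS = 5.0  # sanity bound on |u|, |v|


@dataclass
class FlowGrid:
    """Regular lon/lat/time grid. Axes strictly increasing; time uniform step."""

    lon_axis: np.ndarray
    lat_axis: np.ndarray
    time_axis: np.ndarray  # seconds since simulation start
    land_mask: np.ndarray | None = None  # (lat, lon), True = land

    def __post_init__(self) -> None:
        self.lon_axis = np.asarray(self.lon_axis, dtype=float)
        self.lat_axis = np.asarray(self.lat_axis, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        for name, ax in (("lon", self.lon_axis), ("lat", self.lat_axis), ("time", self.time_axis)):
            if ax.size < 2:
                raise ValueError(f"{name} axis needs at least 2 points")
            if not np.all(np.diff(ax) > 0):
                raise ValueError(f"{name} axis must be strictly increasing")
        if self.land_mask is None:
            self.land_mask = np.zeros((self.lat_axis.size, self.lon_axis.size), dtype=bool)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        if self.land_mask.shape != (self.lat_axis.size, self.lon_axis.size):
            raise ValueError("land_mask shape must be (n_lat, n_lon)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.time_axis.size, self.lat_axis.size, self.lon_axis.size)

    def contains(self, lon, lat) -> np.ndarray:
        return (
            (np.asarray(lon) >= self.lon_axis[0])
            & (np.asarray(lon) <= self.lon_axis[-1])
            & (np.asarray(lat) >= self.lat_axis[0])
            & (np.asarray(lat) <= self.lat_axis[-1])
        )


@dataclass
class FlowField:
    """Velocities u (eastward) and v (northward), m/s, shaped (time, lat, lon)."""

    grid: FlowGrid
    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.grid.shape or self.v.shape != self.grid.shape:
            raise ValueError(f"u/v must have shape {self.grid.shape}")
        sea = ~self.grid.land_mask
        for name, comp in (("u", self.u), ("v", self.v)):
            vals = comp[:, sea]
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"{name} not finite on sea cells")
            if np.nanmax(np.abs(vals), initial=0.0) > MAX_SPEED_MS:
                raise ValueError(f"|{name}| exceeds sanity bound {MAX_SPEED_MS} m/s")

    # -- NetCDF round trip (classic format via the scipy engine) ---------------
    def to_dataset(self) -> xr.Dataset:
        coords = {"time": self.grid.time_axis, "lat": self.grid.lat_axis, "lon": self.grid.lon_axis}
        ds = xr.Dataset(
            {
                "u": (("time", "lat", "lon"), self.u, {"units": "m s-1", "long_name": "eastward velocity"}),
                "v": (("time", "lat", "lon"), self.v, {"units": "m s-1", "long_name": "northward velocity"}),
                "land_mask": (("lat", "lon"), self.grid.land_mask.astype(np.int8)),
            },
            coords=coords,
        )
        # plain seconds-from-start axis; "s" avoids CF datetime decoding
        ds["time"].attrs["units"] = "s"
        ds["lon"].attrs["units"] = "degrees_east"
        ds["lat"].attrs["units"] = "degrees_north"
        return ds

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path) -> "FlowField":
        with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
            grid = FlowGrid(
                lon_axis=ds["lon"].values,
                lat_axis=ds["lat"].values,
                time_axis=ds["time"].values,
                land_mask=ds["land_mask"].values.astype(bool),
            )
            return cls(grid=grid, u=ds["u"].values.copy(), v=ds["v"].values.copy())


# ---------------------------------------------------------------------------
# Residual-circulation components
# ---------------------------------------------------------------------------


@dataclass
class UniformResidual:
    """Spatially constant drift (m/s)."""

    u0: float = 0.0
    v0: float = 0.0

    def evaluate(self, lon2d: np.ndarray, lat2d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return np.full_like(lon2d, self.u0), np.full_like(lat2d, self.v0)


@dataclass
class GyreResidual:
    """Anticlockwise (strength > 0) gyre: tangential speed peaks at ``radius_km``
    from the centre and decays as a Gaussian ring."""

    center_lon: float
    center_lat: float
    strength_ms: float = 0.05
    radius_km: float = 30.0

    def evaluate(self, lon2d, lat2d):
        coslat = np.cos(np.radians(self.center_lat))
        dx_km = (lon2d - self.center_lon) * M_PER_DEG * coslat / 1000.0
        dy_km = (lat2d - self.center_lat) * M_PER_DEG / 1000.0
        r = np.hypot(dx_km, dy_km)
        with np.errstate(invalid="ignore", divide="ignore"):
            speed = self.strength_ms * (r / self.radius_km) * np.exp(0.5 * (1 - (r / self.radius_km) ** 2))
            u = np.where(r > 0, -speed * dy_km / np.maximum(r, 1e-12), 0.0)
            v = np.where(r > 0, speed * dx_km / np.maximum(r, 1e-12), 0.0)
        return u, v


@dataclass
class FrontResidual:
    """Zonal jet along a density front at constant latitude: eastward speed
    ``speed_ms`` at ``front_lat``, Gaussian decay with half-width ``width_km``."""

    front_lat: float
    speed_ms: float = 0.05
    width_km: float = 20.0

    def evaluate(self, lon2d, lat2d):
        dy_km = (lat2d - self.front_lat) * M_PER_DEG / 1000.0
        u = self.speed_ms * np.exp(-0.5 * (dy_km / self.width_km) ** 2)
        return u, np.zeros_like(lat2d)


Residual = UniformResidual | GyreResidual | FrontResidual


@dataclass
class FlowGridSpec:
    """Parameters for a regular synthetic grid."""

    lon_min: float = -6.2
    lon_max: float = -3.3
    lat_min: float = 52.3
    lat_max: float = 53.7
    n_lon: int = 40
    n_lat: int = 20
    duration_days: float = 75.0
    time_step_h: float = 1.0
    land_mask: np.ndarray | None = None

    def build(self) -> FlowGrid:
        if self.n_lon < 2 or self.n_lat < 2:
            raise ValueError("grid too small: need at least 2 points per axis")
        return FlowGrid(
            lon_axis=np.linspace(self.lon_min, self.lon_max, self.n_lon),
            lat_axis=np.linspace(self.lat_min, self.lat_max, self.n_lat),
            time_axis=np.arange(0.0, self.duration_days * 86_400.0 + 1e-9, self.time_step_h * 3600.0),
            land_mask=self.land_mask,
        )


def gen_flow(
    grid_spec: FlowGridSpec | FlowGrid,
    tidal_amplitude_ms: float = 0.5,
    tidal_period_h: float = 12.42,
    tidal_direction_deg: float = 90.0,
    residual: Residual | None = None,
    random_phase: bool = False,
    seed: int | None = None,
) -> FlowField:
    """Synthesise a tidal + residual velocity field.

    u(t, y, x) = A sin(2*pi*t/T + phi) * e_tide + residual(x, y)

    ``tidal_direction_deg`` is the compass-style axis of the rectilinear tidal
    oscillation (90 = east-west). The default amplitude (0.5 m/s) and the M2
    period (12.42 h) are typical of tidally energetic shelf seas; residual
    components default to the weak (< 0.1 m/s) persistent-flow regime.
    ``seed`` only randomises the tidal phase when ``random_phase`` is set, so
    fields are deterministic by construction.
    """
    if tidal_amplitude_ms < 0:
        raise ValueError("tidal amplitude must be >= 0")
    if tidal_period_h <= 0:
        raise ValueError("tidal period must be > 0")
    grid = grid_spec.build() if isinstance(grid_spec, FlowGridSpec) else grid_spec
    if grid.lon_axis.size < 2 or grid.lat_axis.size < 2:
        raise ValueError("grid too small: need at least 2 points per axis")

    lon2d, lat2d = np.meshgrid(grid.lon_axis, grid.lat_axis)
    if residual is None:
        res_u = np.zeros_like(lon2d)
        res_v = np.zeros_like(lon2d)
    else:
        res_u, res_v = residual.evaluate(lon2d, lat2d)

    phase = 0.0
    if random_phase:
        phase = float(rng_for(seed, "tidal-phase").uniform(0.0, 2.0 * np.pi))

    theta = np.radians(tidal_direction_deg)
    ex, ey = np.sin(theta), np.cos(theta)  # compass convention: 90 deg -> east
    omega = 2.0 * np.pi / (tidal_period_h * 3600.0)
    tide = tidal_amplitude_ms * np.sin(omega * grid.time_axis + phase)

    u = tide[:, None, None] * ex + res_u[None, :, :]
    v = tide[:, None, None] * ey + res_v[None, :, :]
    land = grid.land_mask
    u = np.where(land[None, :, :], 0.0, u)
    v = np.where(land[None, :, :], 0.0, v)
    return FlowField(grid=grid, u=u, v=v)
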