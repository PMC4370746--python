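"""Backward-in-time stochastic Lagrangian transport of particle clouds.

A cloud of passive, neutrally buoyant particles is seeded at a larva's
capture point and integrated backward to its hatch day with a
second-order (Heun) advection scheme, Smagorinsky horizontal diffusion
and a vertical random walk.  The product is a per-day occupancy grid:
the fraction of the cloud in each cell, read as a probability
distribution over the larva's location on that day.

The random-walk part of the motion is time-symmetric, so diffusion is
applied identically in backward time; only the advective displacement is
reversed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nataltrack.flowfield import FlowField, interpolate

SECONDS_PER_DAY = 86_400


class SeedingError(ValueError):
    """Capture point unusable for seeding (e.g. on land)."""


class CoverageError(ValueError):
    """Flow-field time span does not cover the requested integration."""


@dataclass
class CaptureRecord:
    """One larva or juvenile: where/when captured, age and size."""

    id: str
    capture_lon: float
    capture_lat: float
    capture_time: np.datetime64
    age_days: int
    total_length_mm: float
    capture_region: str = ""
    life_stage: str = "larva"

    def __post_init__(self):
        self.capture_time = np.datetime64(self.capture_time, "ns")
        if self.age_days < 0:
            raise ValueError("age_days must be >= 0")


@dataclass
class TransportConfig:
    """Numerical parameters of the transport scheme.

    ``smagorinsky_coefficient`` (C_s) scales the deformation-dependent
    horizontal diffusivity K_H = C_s · Δx · Δy · |deformation|; setting
    ``horizontal_diffusivity`` instead imposes a constant K_H (useful
    for diffusion-only studies where the deformation vanishes).
    ``vertical_diffusivity`` (K_v, m²/s) drives the vertical random
    walk.  ``boundary_policy`` is "reflect" (mass-conserving) or
    "freeze" (particles leaving the domain stop and are counted as
    out-of-domain mass).
    """

    dt: float = 600.0
    smagorinsky_coefficient: float = 0.005
    horizontal_diffusivity: float | None = None
    vertical_diffusivity: float = 0.0005
    boundary_policy: str = "reflect"
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.smagorinsky_coefficient < 0 or self.vertical_diffusivity < 0:
            raise ValueError("diffusivities must be non-negative")
        if self.boundary_policy not in ("reflect", "freeze"):
            raise ValueError("boundary_policy must be 'reflect' or 'freeze'")
        if SECONDS_PER_DAY % int(self.dt):
            raise ValueError("dt must divide one day (86400 s)")


@dataclass
class ParticleCloud:
    """Particle positions (metres) plus active flags and the RNG."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    active: np.ndarray
    rng: np.random.Generator

    @property
    def n(self) -> int:
        return self.x.size


@dataclass
class OccupancyGrid:
    """Per-day cell probabilities from a backtracked cloud.

    ``grids[d]`` is the (y, x) occupancy for backtracked day d (day 0 is
    capture day, day ``age_days`` the hatch day).  Under the reflect
    policy each day sums to 1; under freeze the deficit is the mass that
    left the domain (exposed via :meth:`out_mass`).
    """

    record_id: str
    grids: np.ndarray               # (days+1, ny, nx)
    y_axis: np.ndarray
    x_axis: np.ndarray
    origin_lon: float
    origin_lat: float
    mean_temperature: np.ndarray | None = None   # (days+1,) or None

    @property
    def n_days(self) -> int:
        return self.grids.shape[0] - 1

    @property
    def hatch_day_grid(self) -> np.ndarray:
        return self.grids[-1]

    def out_mass(self, day: int) -> float:
        return float(1.0 - self.grids[day].sum())


def seed_cloud(record: CaptureRecord, field: FlowField, n: int = 5000,
               radius_m: float = 5.0, depth_m: float = 1.0,
               seed: int | np.random.Generator = 0) -> ParticleCloud:
    """Seed n particles uniformly on a disc at the capture location.

    The cloud (default 5000 particles over a 5 m radius) represents the
    positional uncertainty of the captured larva.
    """
    if n <= 0:
        raise ValueError("n_particles must be positive")
    cx, cy = field.lonlat_to_xy(record.capture_lon, record.capture_lat)
    if field.is_land(cx, cy):
        raise SeedingError(
            f"capture point of {record.id} falls on a land cell")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    # uniform on a disc: r = R·sqrt(U)
    r = radius_m * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2 * np.pi
    x = cx + r * np.cos(theta)
    y = cy + r * np.sin(theta)
    z = np.full(n, float(depth_m))
    return ParticleCloud(x=x, y=y, z=z,
                         active=np.ones(n, dtype=bool), rng=rng)


# ---------------------------------------------------------------------------
# one transport step
# ---------------------------------------------------------------------------

def _smagorinsky_kh(field: FlowField, x, y, z, t, cs):
    """K_H = C_s·Δx·Δy·√((∂u/∂x)²+(∂v/∂y)²+½(∂u/∂y+∂v/∂x)²) per particle.

    Gradients are centred differences of the time/level-nearest velocity
    slice, gathered at each particle's cell.
    """
    if cs == 0.0:
        return np.zeros_like(np.asarray(x, dtype=float))
    ts = field.seconds_since_start(t)
    tsec = field._t_sec
    it = int(np.clip(round(ts / (tsec[1] - tsec[0])) if tsec.size > 1 else 0,
                     0, tsec.size - 1))
    iz = int(np.clip(
        np.searchsorted(field.z_levels, np.median(z)), 0,
        field.z_levels.size - 1))
    u2 = field.u[it, iz]
    v2 = field.v[it, iz]
    dudy, dudx = np.gradient(u2, field.dy, field.dx)
    dvdy, dvdx = np.gradient(v2, field.dy, field.dx)
    deform = np.sqrt(dudx ** 2 + dvdy ** 2 + 0.5 * (dudy + dvdx) ** 2)
    ix = FlowField._cell_index(np.asarray(x), field.x_axis, field.dx)
    iy = FlowField._cell_index(np.asarray(y), field.y_axis, field.dy)
    return cs * field.dx * field.dy * deform[iy, ix]


def _reflect(pos, lo, hi):
    """Specular reflection of positions into [lo, hi] (vectorised)."""
    span = hi - lo
    if span <= 0:
        return np.clip(pos, lo, hi)
    p = np.mod(pos - lo, 2 * span)
    p = np.where(p > span, 2 * span - p, p)
    return lo + p


def _advect_step(cloud: ParticleCloud, field: FlowField, t, config,
                 direction: int):
    """Heun advection + random-walk diffusion over one dt.

    ``direction`` is +1 (forward) or −1 (backward); diffusion is applied
    identically either way (random walks are time-symmetric).
    """
    dt = config.dt
    act = cloud.active.copy()
    if not np.any(act):
        return
    x, y, z = cloud.x[act], cloud.y[act], cloud.z[act]
    t_end = t + direction * np.timedelta64(int(dt), "s")

    u1, v1, w1, _ = interpolate(field, x, y, z, t, strict=False)
    xs = x + direction * u1 * dt
    ys = y + direction * v1 * dt
    zs = z + direction * w1 * dt
    u2, v2, w2, _ = interpolate(field, xs, ys, zs, t_end, strict=False)
    xn = x + direction * 0.5 * (u1 + u2) * dt
    yn = y + direction * 0.5 * (v1 + v2) * dt
    zn = z + direction * 0.5 * (w1 + w2) * dt

    if config.horizontal_diffusivity is not None:
        kh = np.full(x.shape, float(config.horizontal_diffusivity))
    else:
        kh = _smagorinsky_kh(field, x, y, z, t,
                             config.smagorinsky_coefficient)
    sigma_h = np.sqrt(2.0 * kh * dt)
    if np.any(sigma_h > 0):
        xn = xn + sigma_h * cloud.rng.standard_normal(x.size)
        yn = yn + sigma_h * cloud.rng.standard_normal(y.size)
    if config.vertical_diffusivity > 0:
        zn = zn + np.sqrt(2.0 * config.vertical_diffusivity * dt) \
            * cloud.rng.standard_normal(z.size)

    x_lo, x_hi = field.x_axis[0], field.x_axis[-1]
    y_lo, y_hi = field.y_axis[0], field.y_axis[-1]
    z_lo, z_hi = field.z_levels[0], field.z_levels[-1]
    if config.boundary_policy == "reflect":
        xn = _reflect(xn, x_lo, x_hi)
        yn = _reflect(yn, y_lo, y_hi)
    else:   # freeze: particles leaving the hull stop and deactivate
        out = (xn < x_lo) | (xn > x_hi) | (yn < y_lo) | (yn > y_hi)
        idx = np.flatnonzero(act)
        cloud.active[idx[out]] = False
        xn = np.where(out, x, xn)
        yn = np.where(out, y, yn)
    zn = _reflect(zn, z_lo, z_hi)   # surface/bottom always reflect

    # coast: a step ending on land is rejected (mass-conserving)
    on_land = field.is_land(xn, yn)
    xn = np.where(on_land, x, xn)
    yn = np.where(on_land, y, yn)

    cloud.x[act] = xn
    cloud.y[act] = yn
    cloud.z[act] = zn


def step_backward(cloud: ParticleCloud, field: FlowField, t,
                  config: TransportConfig) -> None:
    """Advance the cloud from t to t − dt (in place)."""
    _advect_step(cloud, field, np.datetime64(t, "ns"), config, direction=-1)


def step_forward(cloud: ParticleCloud, field: FlowField, t,
                 config: TransportConfig) -> None:
    """Advance the cloud from t to t + dt (in place); used by generators."""
    _advect_step(cloud, field, np.datetime64(t, "ns"), config, direction=+1)


# ---------------------------------------------------------------------------
# occupancy and the full hindcast
# ---------------------------------------------------------------------------

def occupancy(cloud: ParticleCloud, field: FlowField) -> np.ndarray:
    """Fraction of the cloud in each (y, x) cell (half-open cell bins).

    Probabilities are counts / n_total, so inactive (frozen) particles
    appear as missing mass.
    """
    if cloud.n == 0:
        raise ValueError("empty cloud")
    act = cloud.active
    ix = FlowField._cell_index(cloud.x[act], field.x_axis, field.dx)
    iy = FlowField._cell_index(cloud.y[act], field.y_axis, field.dy)
    ny, nx = field.y_axis.size, field.x_axis.size
    flat = np.bincount(iy * nx + ix, minlength=ny * nx)
    return flat.reshape(ny, nx) / cloud.n


def _cloud_mean_temperature(cloud, field, t):
    if field.temperature is None:
        return None
    act = cloud.active
    if not np.any(act):
        return np.nan
    _, _, _, temp = interpolate(field, cloud.x[act], cloud.y[act],
                                cloud.z[act], t, strict=False)
    return float(np.mean(temp))


def backtrack(record: CaptureRecord, field: FlowField,
              config: TransportConfig | None = None,
              n_particles: int = 5000, seed_radius_m: float = 5.0,
              return_trajectories: bool = False):
    """Hindcast a capture record to its hatch day.

    Seeds a cloud at the capture point and integrates backward
    ``age_days`` days, recording a daily occupancy grid (and, when the
    field carries temperature, the cloud-mean temperature).  Day d of
    the result is d days before capture; the last day is the hatch day.
    """
    config = config or TransportConfig()
    t_capture = record.capture_time
    t_hatch = t_capture - np.timedelta64(record.age_days * SECONDS_PER_DAY, "s")
    if not (field.time_in_span(t_capture) and field.time_in_span(t_hatch)):
        raise CoverageError(
            f"field span {field.times[0]}..{field.times[-1]} does not cover "
            f"{t_hatch}..{t_capture} needed for record {record.id}")

    cloud = seed_cloud(record, field, n=n_particles, radius_m=seed_radius_m,
                       seed=np.random.default_rng(config.seed))
    steps_per_day = SECONDS_PER_DAY // int(config.dt)
    grids = np.empty((record.age_days + 1, field.y_axis.size,
                      field.x_axis.size))
    temps = [] if field.temperature is not None else None
    traj = [] if return_trajectories else None

    grids[0] = occupancy(cloud, field)
    if temps is not None:
        temps.append(_cloud_mean_temperature(cloud, field, t_capture))
    if traj is not None:
        traj.append((cloud.x.copy(), cloud.y.copy(), cloud.z.copy()))
    t = t_capture
    for day in range(1, record.age_days + 1):
        for _ in range(steps_per_day):
            step_backward(cloud, field, t, config)
            t = t - np.timedelta64(int(config.dt), "s")
        grids[day] = occupancy(cloud, field)
        if temps is not None:
            temps.append(_cloud_mean_temperature(cloud, field, t))
        if traj is not None:
            traj.append((cloud.x.copy(), cloud.y.copy(), cloud.z.copy()))

    grid = OccupancyGrid(
        record_id=record.id, grids=grids,
        y_axis=field.y_axis, x_axis=field.x_axis,
        origin_lon=field.origin_lon, origin_lat=field.origin_lat,
        mean_temperature=np.array(temps) if temps is not None else None)
    if return_trajectories:
        return grid, traj
    return grid


def write_occupancy(grid: OccupancyGrid, path) -> None:
    """Write an occupancy grid to NetCDF (dims day, y, x)."""
    import xarray as xr

    ds = xr.Dataset(
        {"occupancy": (("day", "y", "x"), grid.grids)},
        coords={"day": np.arange(grid.n_days + 1),
                "y": grid.y_axis, "x": grid.x_axis},
        attrs={"record_id": grid.record_id,
               "origin_lon": grid.origin_lon,
               "origin_lat": grid.origin_lat})
    if grid.mean_temperature is not None:
        ds["mean_temperature"] = ("day", grid.mean_temperature)
    ds.to_netcdf(path, engine="scipy")
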