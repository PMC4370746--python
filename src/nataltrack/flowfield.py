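"""Gridded velocity/temperature fields that drive particle transport.

A :class:`FlowField` is a structured rectilinear analogue of hourly
hydrodynamic-model output: horizontal velocity (and optionally vertical
velocity and temperature) on a uniform (t, z, y, x) grid with a land
mask, georeferenced by a local equirectangular projection about a stored
lon/lat origin.  Interpolation is trilinear in space and linear in time
and is mask-aware: land cells never contribute velocity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

# mean metres per degree of latitude in the local equirectangular frame
M_PER_DEG_LAT = 111_320.0


class FieldFormatError(ValueError):
    """A gridded-field file is missing a variable or axis."""


class FieldValidationError(ValueError):
    """Field arrays violate a FlowField invariant."""


class OutOfDomainError(ValueError):
    """A space/time query falls outside the field's hull or time span."""


@dataclass
class RegionPartition:
    """Two-region split of the domain at a boundary latitude.

    Cells with centre latitude strictly north of ``boundary_latitude``
    belong to the north region; points exactly on the line are south
    (deterministic south-inclusive tie rule).
    """

    boundary_latitude: float = 41.81
    north_label: str = "NS"
    south_label: str = "SS"

    def label_of_latitude(self, lat):
        lat = np.asarray(lat)
        out = np.where(lat > self.boundary_latitude,
                       self.north_label, self.south_label)
        return out[()] if out.ndim == 0 else out


@dataclass
class FlowField:
    """Gridded u, v (, w, temperature) time series with a land mask.

    Axes are uniform and strictly increasing; ``x``/``y`` are metres in
    a local Cartesian frame whose (0, 0) maps to ``origin_lon/lat``;
    ``z`` is depth in metres, positive downward, surface first.
    Velocities are m/s; land cells carry zero velocity.
    """

    times: np.ndarray            # datetime64[ns], uniform spacing
    z_levels: np.ndarray         # metres depth, increasing from surface
    y_axis: np.ndarray           # cell-centre metres
    x_axis: np.ndarray
    u: np.ndarray                # (t, z, y, x) m/s
    v: np.ndarray
    w: np.ndarray | None = None
    temperature: np.ndarray | None = None
    land_mask: np.ndarray | None = None   # (y, x) bool, True = land
    origin_lon: float = -83.0
    origin_lat: float = 41.70

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        for name in ("z_levels", "y_axis", "x_axis", "u", "v"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.land_mask is None:
            self.land_mask = np.zeros(
                (self.y_axis.size, self.x_axis.size), dtype=bool)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        self._validate()
        self._t0 = self.times[0]
        self._t_sec = (self.times - self._t0) / np.timedelta64(1, "s")

    def _validate(self):
        shape = (self.times.size, self.z_levels.size,
                 self.y_axis.size, self.x_axis.size)
        if self.u.shape != shape or self.v.shape != shape:
            raise FieldValidationError(
                f"u/v shape {self.u.shape} does not match axes {shape}")
        for name in ("z_levels", "y_axis", "x_axis"):
            ax = getattr(self, name)
            if ax.size > 1:
                d = np.diff(ax)
                if np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-6):
                    raise FieldValidationError(
                        f"axis {name} must be strictly increasing "
                        "and uniformly spaced")
        if self.times.size > 1:
            dt = np.diff(self._times_as_sec())
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
                raise FieldValidationError("time axis must be uniform")
        water = ~self.land_mask
        if not np.all(np.isfinite(self.u[:, :, water])):
            raise FieldValidationError("non-finite u on water cells")
        if not np.all(np.isfinite(self.v[:, :, water])):
            raise FieldValidationError("non-finite v on water cells")
        # land carries no velocity by construction
        self.u[:, :, self.land_mask] = 0.0
        self.v[:, :, self.land_mask] = 0.0
        if self.w is not None:
            self.w = np.asarray(self.w, dtype=float)
            self.w[:, :, self.land_mask] = 0.0

    def _times_as_sec(self):
        return (self.times - self.times[0]) / np.timedelta64(1, "s")

    # -- geometry helpers -------------------------------------------------
    @property
    def dx(self) -> float:
        return float(self.x_axis[1] - self.x_axis[0]) if self.x_axis.size > 1 else 1.0

    @property
    def dy(self) -> float:
        return float(self.y_axis[1] - self.y_axis[0]) if self.y_axis.size > 1 else 1.0

    def xy_to_lonlat(self, x, y):
        """Local metres -> (lon, lat) under the equirectangular projection."""
        lat = self.origin_lat + np.asarray(y) / M_PER_DEG_LAT
        lon = self.origin_lon + np.asarray(x) / (
            M_PER_DEG_LAT * np.cos(np.deg2rad(self.origin_lat)))
        return lon, lat

    def lonlat_to_xy(self, lon, lat):
        y = (np.asarray(lat) - self.origin_lat) * M_PER_DEG_LAT
        x = (np.asarray(lon) - self.origin_lon) * (
            M_PER_DEG_LAT * np.cos(np.deg2rad(self.origin_lat)))
        return x, y

    def cell_latitudes(self):
        """Latitude of each y-row of cell centres."""
        return self.origin_lat + self.y_axis / M_PER_DEG_LAT

    def time_in_span(self, t) -> bool:
        t = np.datetime64(t, "ns")
        return self.times[0] <= t <= self.times[-1]

    def seconds_since_start(self, t) -> float:
        return float((np.datetime64(t, "ns") - self._t0)
                     / np.timedelta64(1, "s"))

    def is_land(self, x, y):
        """True where (x, y) falls in a land cell (half-open cell bins)."""
        ix = self._cell_index(np.asarray(x), self.x_axis, self.dx)
        iy = self._cell_index(np.asarray(y), self.y_axis, self.dy)
        return self.land_mask[iy, ix]

    @staticmethod
    def _cell_index(pos, axis, delta):
        idx = np.floor((pos - (axis[0] - delta / 2)) / delta).astype(int)
        return np.clip(idx, 0, axis.size - 1)


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------

def _axis_weights(q, axis):
    """Bracketing indices and linear weight along one uniform axis.

    Queries are clamped to the axis hull (callers police the domain).
    """
    q = np.asarray(q, dtype=float)
    if axis.size == 1:
        i0 = np.zeros(q.shape, dtype=int)
        return i0, i0, np.zeros(q.shape)
    step = axis[1] - axis[0]
    f = np.clip((q - axis[0]) / step, 0.0, axis.size - 1.0)
    i0 = np.minimum(f.astype(int), axis.size - 2)
    return i0, i0 + 1, f - i0


def _interp_spatial(arr2, iz0, iz1, wz, iy0, iy1, wy, ix0, ix1, wx,
                    wt0, wt1, water):
    """Mask-aware trilinear interpolation of a (2, z, y, x) time bracket.

    Corner weights on land cells are zeroed and the remainder
    renormalised; if every corner is land the result is 0.
    """
    total = 0.0
    wsum = 0.0
    for iz, fz in ((iz0, 1.0 - wz), (iz1, wz)):
        for iy, fy in ((iy0, 1.0 - wy), (iy1, wy)):
            for ix, fx in ((ix0, 1.0 - wx), (ix1, wx)):
                wgt = fz * fy * fx * water[iy, ix]
                val = wt0 * arr2[0][iz, iy, ix] + wt1 * arr2[1][iz, iy, ix]
                total = total + wgt * val
                wsum = wsum + wgt
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(wsum > 0, total / np.where(wsum > 0, wsum, 1.0), 0.0)
    return out


def interpolate(field: FlowField, x, y, z, t, *, strict: bool = True):
    """Sample (u, v, w, temperature) at points (x, y, z) and datetime t.

    Trilinear in space, linear in time, mask-aware in the horizontal.
    With ``strict`` a query outside the grid hull or time span raises
    :class:`OutOfDomainError`; callers integrating particles pass
    ``strict=False`` and decide the particle's fate themselves.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    ts = field.seconds_since_start(t)
    tsec = field._t_sec
    if strict:
        if not (tsec[0] <= ts <= tsec[-1]):
            raise OutOfDomainError(f"time {t} outside field span")
        if (np.any(x < field.x_axis[0]) or np.any(x > field.x_axis[-1])
                or np.any(y < field.y_axis[0]) or np.any(y > field.y_axis[-1])):
            raise OutOfDomainError("spatial query outside grid hull")

    if tsec.size == 1:
        it0 = it1 = 0
        wt1 = 0.0
    else:
        step = tsec[1] - tsec[0]
        f = np.clip(ts / step, 0.0, tsec.size - 1.0)
        it0 = min(int(f), tsec.size - 2)
        it1 = it0 + 1
        wt1 = f - it0
    wt0 = 1.0 - wt1

    iz0, iz1, wz = _axis_weights(z, field.z_levels)
    iy0, iy1, wy = _axis_weights(y, field.y_axis)
    ix0, ix1, wx = _axis_weights(x, field.x_axis)
    water = (~field.land_mask).astype(float)

    args = (iz0, iz1, wz, iy0, iy1, wy, ix0, ix1, wx, wt0, wt1, water)
    u = _interp_spatial((field.u[it0], field.u[it1]), *args)
    v = _interp_spatial((field.v[it0], field.v[it1]), *args)
    if field.w is not None:
        w = _interp_spatial((field.w[it0], field.w[it1]), *args)
    else:
        w = np.zeros_like(u)
    if field.temperature is not None:
        temp = _interp_spatial(
            (field.temperature[it0], field.temperature[it1]), *args)
    else:
        temp = None
    return u, v, w, temp


# ---------------------------------------------------------------------------
# NetCDF I/O (CF-style: dims time, z, y, x; attrs carry the projection)
# ---------------------------------------------------------------------------

def write_field(field: FlowField, path) -> None:
    """Write a FlowField to NetCDF (variables u, v[, w, temp], land_mask)."""
    data = {
        "u": (("time", "z", "y", "x"), field.u),
        "v": (("time", "z", "y", "x"), field.v),
        "land_mask": (("y", "x"), field.land_mask.astype(np.int8)),
    }
    if field.w is not None:
        data["w"] = (("time", "z", "y", "x"), field.w)
    if field.temperature is not None:
        data["temp"] = (("time", "z", "y", "x"), field.temperature)
    ds = xr.Dataset(
        data,
        coords={"time": field.times, "z": field.z_levels,
                "y": field.y_axis, "x": field.x_axis},
        attrs={"origin_lon": field.origin_lon,
               "origin_lat": field.origin_lat,
               "units_velocity": "m s-1"},
    )
    ds.to_netcdf(path, engine="scipy")


def read_field(path) -> FlowField:
    """Read a FlowField written by :func:`write_field` (or compatible)."""
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    for name in ("u", "v"):
        if name not in ds:
            raise FieldFormatError(f"field file lacks variable '{name}'")
    for dim in ("time", "z", "y", "x"):
        if dim not in ds.coords:
            raise FieldFormatError(f"field file lacks axis '{dim}'")
    mask = ds["land_mask"].values.astype(bool) if "land_mask" in ds else None
    return FlowField(
        times=ds["time"].values,
        z_levels=ds["z"].values,
        y_axis=ds["y"].values,
        x_axis=ds["x"].values,
        u=ds["u"].values,
        v=ds["v"].values,
        w=ds["w"].values if "w" in ds else None,
        temperature=ds["temp"].values if "temp" in ds else None,
        land_mask=mask,
        origin_lon=float(ds.attrs.get("origin_lon", -83.0)),
        origin_lat=float(ds.attrs.get("origin_lat", 41.70)),
    )


# ---------------------------------------------------------------------------
# synthetic analytic fields
# ---------------------------------------------------------------------------

def _grid(extent_m=(40_000.0, 40_000.0), cell_m=2_000.0, n_z=21,
          max_depth=10.0, start="2006-05-01", n_hours=241,
          origin_lon=-83.0, origin_lat=41.70):
    nx = int(round(extent_m[0] / cell_m))
    ny = int(round(extent_m[1] / cell_m))
    if nx < 1 or ny < 1:
        raise FieldValidationError("zero-size grid")
    x = (np.arange(nx) + 0.5) * cell_m
    y = (np.arange(ny) + 0.5) * cell_m
    z = np.linspace(0.0, max_depth, n_z)
    t0 = np.datetime64(start, "ns")
    times = t0 + np.arange(n_hours) * np.timedelta64(3600, "s")
    return times, z, y, x, origin_lon, origin_lat


def make_uniform(u=0.0, v=0.0, w=0.0, temperature=None, **grid_kw) -> FlowField:
    """Spatially and temporally constant field (|u|, |v| ≤ 2 m/s)."""
    _check_speed(u, v)
    times, z, y, x, lon0, lat0 = _grid(**grid_kw)
    shape = (times.size, z.size, y.size, x.size)
    return FlowField(
        times=times, z_levels=z, y_axis=y, x_axis=x,
        u=np.full(shape, float(u)), v=np.full(shape, float(v)),
        w=np.full(shape, float(w)) if w else None,
        temperature=np.full(shape, float(temperature))
        if temperature is not None else None,
        origin_lon=lon0, origin_lat=lat0)


def make_gyre(omega=1e-5, centre=None, **grid_kw) -> FlowField:
    """Solid-body rotation: u = −ω(y−yc), v = ω(x−xc) (divergence-free)."""
    times, z, y, x, lon0, lat0 = _grid(**grid_kw)
    if centre is None:
        centre = (x.mean(), y.mean())
    xc, yc = centre
    _check_speed(omega * max(abs(x - xc).max(), abs(y - yc).max()))
    X, Y = np.meshgrid(x, y)
    u2 = -omega * (Y - yc)
    v2 = omega * (X - xc)
    shape = (times.size, z.size, y.size, x.size)
    u = np.broadcast_to(u2, shape).copy()
    v = np.broadcast_to(v2, shape).copy()
    return FlowField(times=times, z_levels=z, y_axis=y, x_axis=x, u=u, v=v,
                     origin_lon=lon0, origin_lat=lat0)


def make_plume(v0=-0.15, jet_centre_x=None, jet_width=6_000.0,
               wind_amplitude=0.0, wind_period_h=72.0, temperature=None,
               **grid_kw) -> FlowField:
    """Southward jet crossing the domain, emulating a river-inflow plume.

    v(x, t) = v0 · exp(−((x−xc)/width)²) · (1 + a·sin(2πt/T)), u = 0.
    Since v varies only with x the field is divergence-free.  The default
    v0 < 0 carries north-shore water across the partition into the south.
    """
    _check_speed(v0 * (1 + abs(wind_amplitude)))
    times, z, y, x, lon0, lat0 = _grid(**grid_kw)
    if jet_centre_x is None:
        jet_centre_x = x.mean()
    profile = np.exp(-(((x - jet_centre_x) / jet_width) ** 2))  # (x,)
    th = (times - times[0]) / np.timedelta64(1, "h")
    mod = 1.0 + wind_amplitude * np.sin(
        2 * np.pi * th.astype(float) / wind_period_h)
    v = v0 * mod[:, None, None, None] * profile[None, None, None, :]
    v = np.broadcast_to(v, (times.size, z.size, y.size, x.size)).copy()
    u = np.zeros_like(v)
    temp = (np.full_like(v, float(temperature))
            if temperature is not None else None)
    return FlowField(times=times, z_levels=z, y_axis=y, x_axis=x, u=u, v=v,
                     temperature=temp, origin_lon=lon0, origin_lat=lat0)


def _check_speed(*speeds):
    if any(abs(float(s)) > 2.0 for s in speeds):
        raise FieldValidationError(
            "requested speed exceeds 2 m/s sanity bound")
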