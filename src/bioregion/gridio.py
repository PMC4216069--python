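"""Gridded-field containers and I/O.

Houses the grid conventions shared by the whole pipeline: regular
lat/lon grids with cell-center coordinates, a boolean land mask, and an
optional monthly (or finer) time axis.  Missing ocean data is encoded as
NaN; land cells never carry values.  All per-km gradient quantities
derive distances from a spherical Earth of radius 6371 km, with the
zonal spacing scaled by cos(latitude).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

EARTH_RADIUS_KM = 6371.0
#: kilometres per degree of latitude (and of longitude at the equator)
KM_PER_DEGREE = np.pi * EARTH_RADIUS_KM / 180.0

_SPACING_RTOL = 1e-6
_NC_ENGINE = "scipy"  # NetCDF3 classic; no external C library needed


def nanmean_quiet(values: np.ndarray, axis=None) -> np.ndarray:
    """nanmean with the all-NaN (land column) warning suppressed."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", "Mean of empty slice")
        with np.errstate(invalid="ignore"):
            return np.nanmean(values, axis=axis)


def _check_uniform(coords: np.ndarray, axis_name: str) -> float:
    """Return the uniform spacing of a 1-D ascending coordinate array."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 1 or coords.size < 2:
        raise ValueError(f"{axis_name} axis needs at least two cell centers")
    steps = np.diff(coords)
    if np.any(steps <= 0):
        raise ValueError(f"{axis_name} coordinates must be strictly ascending")
    step = steps.mean()
    if np.max(np.abs(steps - step)) > _SPACING_RTOL * max(abs(step), 1.0):
        raise ValueError(f"non-uniform grid spacing on the {axis_name} axis")
    return float(step)


@dataclass(frozen=True)
class Grid:
    """Regular lat/lon grid of cell centers with a land mask.

    Parameters
    ----------
    lon : array of longitudes in degrees east, ascending, uniform spacing
    lat : array of latitudes in degrees north, ascending, uniform spacing
    land_mask : boolean array of shape (n_lat, n_lon); True marks land
    """

    lon: np.ndarray
    lat: np.ndarray
    land_mask: np.ndarray = dc_field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        lon = np.asarray(self.lon, dtype=float)
        lat = np.asarray(self.lat, dtype=float)
        object.__setattr__(self, "lon", lon)
        object.__setattr__(self, "lat", lat)
        _check_uniform(lon, "longitude")
        _check_uniform(lat, "latitude")
        mask = self.land_mask
        if mask is None:
            mask = np.zeros((lat.size, lon.size), dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (lat.size, lon.size):
            raise ValueError(
                f"land_mask shape {mask.shape} != (n_lat, n_lon) = "
                f"{(lat.size, lon.size)}"
            )
        object.__setattr__(self, "land_mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat.size, self.lon.size)

    @property
    def dlon(self) -> float:
        return _check_uniform(self.lon, "longitude")

    @property
    def dlat(self) -> float:
        return _check_uniform(self.lat, "latitude")

    @property
    def ocean(self) -> np.ndarray:
        """Boolean (n_lat, n_lon) array, True on ocean cells."""
        return ~self.land_mask

    def dy_km(self) -> float:
        """Meridional cell extent in km."""
        return self.dlat * KM_PER_DEGREE

    def dx_km(self) -> np.ndarray:
        """Zonal cell extent in km per latitude row, shape (n_lat,)."""
        return self.dlon * KM_PER_DEGREE * np.cos(np.deg2rad(self.lat))

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.lon.shape == other.lon.shape
            and self.lat.shape == other.lat.shape
            and np.allclose(self.lon, other.lon)
            and np.allclose(self.lat, other.lat)
            and np.array_equal(self.land_mask, other.land_mask)
        )


@dataclass
class ScalarField:
    """One named variable on a Grid, optionally with a time axis.

    ``values`` has shape (n_time, n_lat, n_lon) when ``times`` is set,
    else (n_lat, n_lon).  NaN marks missing data; land cells are NaN.
    """

    grid: Grid
    values: np.ndarray
    times: pd.DatetimeIndex | None = None
    name: str = "field"
    units: str = ""

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        expected = self.grid.shape if self.times is None else (
            len(self.times), *self.grid.shape)
        if vals.shape != expected:
            raise ValueError(
                f"values shape {vals.shape} != expected {expected}")
        if self.times is not None:
            self.times = pd.DatetimeIndex(self.times)
            if len(self.times) > 1 and not self.times.is_monotonic_increasing:
                raise ValueError("time axis must be strictly increasing")
            if self.times.has_duplicates:
                raise ValueError("time axis has duplicate timestamps")
        # land never carries values
        vals = vals.copy()
        vals[..., self.grid.land_mask] = np.nan
        self.values = vals

    @property
    def n_time(self) -> int:
        return 1 if self.times is None else len(self.times)

    def layers(self) -> np.ndarray:
        """Values with an explicit leading time axis, shape (T, nlat, nlon)."""
        if self.times is None:
            return self.values[None, ...]
        return self.values

    def time_mean(self) -> "ScalarField":
        """Per-cell mean over time, ignoring missing samples."""
        if self.times is None:
            return replace(self, values=self.values.copy())
        mean = nanmean_quiet(self.values, axis=0)
        return ScalarField(self.grid, mean, None, self.name, self.units)

    def copy(self) -> "ScalarField":
        return ScalarField(self.grid, self.values.copy(),
                           None if self.times is None else self.times.copy(),
                           self.name, self.units)


@dataclass
class VelocityField:
    """Paired (u, v) velocity components sharing one grid and time axis."""

    u: ScalarField
    v: ScalarField

    def __post_init__(self):
        if not self.u.grid.same_geometry(self.v.grid):
            raise ValueError("u and v must share the same grid")
        ut, vt = self.u.times, self.v.times
        if (ut is None) != (vt is None) or (
                ut is not None and not ut.equals(vt)):
            raise ValueError("u and v must share the same time axis")
        if self.u.units != self.v.units:
            raise ValueError(
                f"velocity component units differ: {self.u.units!r} vs "
                f"{self.v.units!r}")

    @property
    def grid(self) -> Grid:
        return self.u.grid

    @property
    def times(self) -> pd.DatetimeIndex | None:
        return self.u.times

    @property
    def units(self) -> str:
        return self.u.units

    def speed_mps(self) -> tuple[np.ndarray, np.ndarray]:
        """(u, v) arrays converted to m/s."""
        factor = _to_mps_factor(self.units)
        return self.u.values * factor, self.v.values * factor


def _to_mps_factor(units: str) -> float:
    key = units.replace(" ", "").lower()
    table = {"m/s": 1.0, "ms-1": 1.0, "meterspersecond": 1.0,
             "cm/s": 0.01, "cms-1": 0.01, "": 1.0}
    if key not in table:
        raise ValueError(f"unsupported velocity units: {units!r}")
    return table[key]


def normalize_lon(lon: np.ndarray) -> np.ndarray:
    """Wrap longitudes into [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


# ---------------------------------------------------------------------------
# I/O


def write_field(field: ScalarField, path: str | Path) -> None:
    """Write a ScalarField as CF-style NetCDF (classic format).

    Coordinate variables lat/lon (and time if present) carry units
    attributes; missing cells are stored through ``_FillValue``.
    """
    path = Path(path)
    dims = ("lat", "lon") if field.times is None else ("time", "lat", "lon")
    coords = {"lat": ("lat", field.grid.lat, {"units": "degrees_north"}),
              "lon": ("lon", field.grid.lon, {"units": "degrees_east"})}
    if field.times is not None:
        coords["time"] = ("time", field.times.to_numpy())
    da = xr.DataArray(field.values, dims=dims, coords=coords,
                      name=field.name or "field",
                      attrs={"units": field.units})
    mask = xr.DataArray(field.grid.land_mask.astype(np.int8),
                        dims=("lat", "lon"),
                        attrs={"long_name": "land mask", "flag_values": "0 1",
                               "flag_meanings": "ocean land"})
    ds = xr.Dataset({da.name: da, "land_mask": mask})
    encoding = {da.name: {"_FillValue": np.float64(1e36), "dtype": "float64"}}
    try:
        ds.to_netcdf(path, engine=_NC_ENGINE, encoding=encoding)
    except OSError as exc:  # pragma: no cover - passthrough with context
        raise OSError(f"cannot write NetCDF to {path}: {exc}") from exc


def read_field(path: str | Path, variable: str,
               dialect: str = "netcdf") -> ScalarField:
    """Read a ScalarField from NetCDF or the lon,lat[,time],value CSV dialect.

    Longitudes are normalized to [-180, 180).  Raises a clear error when
    the variable is absent or the grid spacing is not uniform.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "netcdf":
        return _read_netcdf(path, variable)
    if dialect == "csv":
        return _read_csv(path, variable)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _read_netcdf(path: Path, variable: str) -> ScalarField:
    with xr.open_dataset(path, engine=_NC_ENGINE) as ds:
        if variable not in ds:
            raise KeyError(
                f"variable not found: {variable!r} (file has "
                f"{sorted(ds.data_vars)})")
        da = ds[variable].load()
        lon = normalize_lon(np.asarray(ds["lon"].values, dtype=float))
        lat = np.asarray(ds["lat"].values, dtype=float)
        order = np.argsort(lon)
        lon = lon[order]
        mask = None
        if "land_mask" in ds:
            mask = ds["land_mask"].values.astype(bool)[:, order]
        grid = Grid(lon, lat, mask)
        times = None
        vals = np.asarray(da.values, dtype=float)
        if "time" in da.dims:
            times = pd.DatetimeIndex(ds["time"].values)
            vals = vals[:, :, order]
        else:
            vals = vals[:, order]
        units = str(da.attrs.get("units", ""))
        if mask is None:
            # reconstruct land as all-time-missing cells only when no mask var
            grid = Grid(lon, lat, np.all(np.isnan(
                vals if times is not None else vals[None]), axis=0))
        return ScalarField(grid, vals, times, variable, units)


def _read_csv(path: Path, variable: str) -> ScalarField:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for needed in ("lon", "lat", "value"):
        if needed not in cols:
            raise KeyError(f"CSV dialect needs a {needed!r} column")
    lon_u = np.unique(normalize_lon(df[cols["lon"]].to_numpy(float)))
    lat_u = np.unique(df[cols["lat"]].to_numpy(float))
    grid = Grid(lon_u, lat_u)
    ilat = np.searchsorted(lat_u, df[cols["lat"]].to_numpy(float))
    ilon = np.searchsorted(lon_u, normalize_lon(df[cols["lon"]].to_numpy(float)))
    if "time" in cols:
        times = pd.DatetimeIndex(sorted(pd.to_datetime(df[cols["time"]]).unique()))
        vals = np.full((len(times), lat_u.size, lon_u.size), np.nan)
        it = times.get_indexer(pd.to_datetime(df[cols["time"]]))
        vals[it, ilat, ilon] = df[cols["value"]].to_numpy(float)
    else:
        times = None
        vals = np.full((lat_u.size, lon_u.size), np.nan)
        vals[ilat, ilon] = df[cols["value"]].to_numpy(float)
    return ScalarField(grid, vals, times, variable, "")


def write_velocity(vel: VelocityField, path: str | Path) -> None:
    """Write u and v components into one NetCDF file."""
    path = Path(path)
    dims = ("lat", "lon") if vel.times is None else ("time", "lat", "lon")
    coords = {"lat": ("lat", vel.grid.lat, {"units": "degrees_north"}),
              "lon": ("lon", vel.grid.lon, {"units": "degrees_east"})}
    if vel.times is not None:
        coords["time"] = ("time", vel.times.to_numpy())
    ds = xr.Dataset(
        {"u": xr.DataArray(vel.u.values, dims=dims, coords=coords,
                           attrs={"units": vel.units}),
         "v": xr.DataArray(vel.v.values, dims=dims, coords=coords,
                           attrs={"units": vel.units}),
         "land_mask": xr.DataArray(vel.grid.land_mask.astype(np.int8),
                                   dims=("lat", "lon"))})
    enc = {k: {"_FillValue": np.float64(1e36)} for k in ("u", "v")}
    ds.to_netcdf(path, engine=_NC_ENGINE, encoding=enc)


def read_velocity(path: str | Path) -> VelocityField:
    u = read_field(path, "u")
    v = read_field(path, "v")
    # components may differ in incidental all-NaN masks; unify
    mask = u.grid.land_mask & v.grid.land_mask
    grid = Grid(u.grid.lon, u.grid.lat, mask)
    u = ScalarField(grid, u.values, u.times, "u", u.units)
    v = ScalarField(grid, v.values, v.times, "v", v.units)
    return VelocityField(u, v)


# ---------------------------------------------------------------------------
# Transformations


def regrid(field: ScalarField, target: Grid,
           method: str = "bilinear") -> ScalarField:
    """Interpolate a field onto a target grid.

    ``bilinear`` propagates missingness (a target cell with any missing
    source neighbor becomes missing); ``nearest`` copies the nearest
    source cell.  No extrapolation beyond the source hull.
    """
    if method not in ("bilinear", "nearest"):
        raise ValueError(f"unknown regrid method: {method!r}")
    src = field.grid
    if (target.lon.min() > src.lon.max() or target.lon.max() < src.lon.min()
            or target.lat.min() > src.lat.max()
            or target.lat.max() < src.lat.min()):
        raise ValueError("target grid extent is disjoint from source")
    from scipy.interpolate import RegularGridInterpolator

    tlat, tlon = np.meshgrid(target.lat, target.lon, indexing="ij")
    pts = np.column_stack([tlat.ravel(), tlon.ravel()])
    kind = "linear" if method == "bilinear" else "nearest"
    out_layers = []
    for layer in field.layers():
        itp = RegularGridInterpolator(
            (src.lat, src.lon), layer, method=kind,
            bounds_error=False, fill_value=np.nan)
        out_layers.append(itp(pts).reshape(target.shape))
    out = np.stack(out_layers) if field.times is not None else out_layers[0]
    return ScalarField(target, out, field.times, field.name, field.units)


def monthly_mean(field: ScalarField) -> ScalarField:
    """Collapse sub-monthly samples into one layer per calendar month.

    Per-cell means ignore missing samples; a month with no valid sample
    at a cell is missing there.  Output timestamps are month starts.
    """
    if field.times is None or len(field.times) == 0:
        raise ValueError("monthly_mean needs a non-empty time axis")
    periods = field.times.to_period("M")
    uniq = periods.unique().sort_values()
    out = np.full((len(uniq), *field.grid.shape), np.nan)
    for i, p in enumerate(uniq):
        out[i] = nanmean_quiet(field.values[periods == p], axis=0)
    times = pd.DatetimeIndex([p.to_timestamp() for p in uniq])
    return ScalarField(field.grid, out, times, field.name, field.units)


def log_transform(field: ScalarField, offset: float = 0.0) -> ScalarField:
    """Natural log of (values + offset); rejects non-positive arguments."""
    if offset < 0:
        raise ValueError("offset must be >= 0")
    shifted = field.values + offset
    bad = np.isfinite(shifted) & (shifted <= 0)
    if bad.any():
        raise ValueError(
            f"log_transform: {int(bad.sum())} cell(s) non-positive after "
            f"offset {offset}")
    with np.errstate(invalid="ignore"):
        out = np.log(shifted)
    units = f"ln({field.units or '1'})"
    return ScalarField(field.grid, out, field.times, field.name, units)


def log_depth(bathymetry: ScalarField, offset: float = 1.0) -> ScalarField:
    """Natural log of depth magnitude for negative-down bathymetry.

    Bathymetry is stored negative-down (ETOPO-style); the log transform
    applies to |depth| + offset (in metres) and records the sign
    convention in the units string.
    """
    mag = ScalarField(bathymetry.grid, np.abs(bathymetry.values),
                      bathymetry.times, bathymetry.name, "m")
    out = log_transform(mag, offset)
    out.units = "ln(m), depth magnitude (negative-down source)"
    return out
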