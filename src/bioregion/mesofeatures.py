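"""Derived mesoscale ocean features.

Implements the four diagnostics the partitioning stage consumes:

* frontal gradients of a tracer via the 3x3 Sobel operator, in tracer
  units per km;
* eddy kinetic energy, EKE = (u^2 + v^2) / 2, from velocity anomalies;
* the Okubo-Weiss parameter W = s_n^2 + s_s^2 - omega^2, negative in
  vorticity-dominated eddy cores and positive in strain-dominated
  regions;
* backward finite-size Lyapunov exponents (FSLE): for every grid cell, a
  cross of four particles at initial separation delta0 is advected
  (backward in time by default) with the cell-center particle, and
  lambda = ln(deltaf / delta0) / tau* where tau* is the first time any
  pair separation reaches deltaf.  Cells whose separation never reaches
  deltaf within tau_max get lambda = 0.

Spatial derivatives use centered differences on the sphere-corrected
grid (zonal spacing scaled by cos latitude); boundary cells are left
missing rather than estimated one-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .gridio import Grid, ScalarField, VelocityField, KM_PER_DEGREE

_SOBEL_X = np.array([[-1, 0, 1],
                     [-2, 0, 2],
                     [-1, 0, 1]], dtype=float)
_SOBEL_Y = _SOBEL_X.T


@dataclass
class FsleParams:
    """FSLE integration parameters.

    delta0 and deltaf are separations in degrees; tau_max is the maximum
    integration time in days; integration_step the RK4 step in days.
    """

    delta0: float = 0.04
    deltaf: float = 0.6
    tau_max: float = 200.0
    integration_step: float = 0.25
    direction: str = "backward"

    def __post_init__(self):
        if not 0 < self.delta0 < self.deltaf:
            raise ValueError("need 0 < delta0 < deltaf")
        if self.tau_max <= 0 or self.integration_step <= 0:
            raise ValueError("tau_max and integration_step must be > 0")
        if self.direction not in ("backward", "forward"):
            raise ValueError(f"unknown direction: {self.direction!r}")


# ---------------------------------------------------------------------------
# Eulerian diagnostics


def frontal_gradient(field: ScalarField) -> ScalarField:
    """Sobel gradient magnitude of a tracer, in field units per km.

    The kernel response is normalized by 8x the cell spacing in km (the
    Sobel weights sum to 8 per spacing step), with the zonal spacing
    scaled by cos(latitude) row by row.  Any cell with a missing value
    in its 3x3 neighborhood — including the domain edge — is missing.
    """
    grid = field.grid
    if grid.shape[0] < 3 or grid.shape[1] < 3:
        raise ValueError("frontal_gradient needs at least a 3x3 grid")
    dx_km = grid.dx_km()[:, None]  # (n_lat, 1)
    dy_km = grid.dy_km()
    out = np.empty_like(field.layers())
    for i, layer in enumerate(field.layers()):
        gx = ndimage.correlate(layer, _SOBEL_X, mode="constant",
                               cval=np.nan) / (8.0 * dx_km)
        gy = ndimage.correlate(layer, _SOBEL_Y, mode="constant",
                               cval=np.nan) / (8.0 * dy_km)
        g = np.hypot(gx, gy)
        # any missing value in the 3x3 neighborhood (zero-weight kernel
        # entries included) invalidates the cell
        invalid = ndimage.binary_dilation(~np.isfinite(layer),
                                          structure=np.ones((3, 3)),
                                          border_value=1)
        g[invalid] = np.nan
        out[i] = g
    vals = out if field.times is not None else out[0]
    units = f"{field.units or '1'}/km"
    return ScalarField(grid, vals, field.times,
                       f"{field.name}_front", units)


def eke(velocity: VelocityField) -> ScalarField:
    """Eddy kinetic energy (u^2 + v^2) / 2 in squared velocity units."""
    u, v = velocity.u.values, velocity.v.values
    vals = 0.5 * (u * u + v * v)
    unit = velocity.units or "m/s"
    return ScalarField(velocity.grid, vals, velocity.times, "eke",
                       f"({unit})^2")


@dataclass
class StrainComponents:
    """Normal strain, shear strain and relative vorticity (all 1/s)."""

    normal_strain: ScalarField
    shear_strain: ScalarField
    relative_vorticity: ScalarField


def _centered_gradients(layer_u: np.ndarray, layer_v: np.ndarray,
                        grid: Grid) -> tuple[np.ndarray, ...]:
    """du/dx, du/dy, dv/dx, dv/dy in 1/s from m/s layers; edges NaN."""
    dx_m = grid.dx_km()[:, None] * 1000.0
    dy_m = grid.dy_km() * 1000.0

    def ddx(a):
        out = np.full_like(a, np.nan)
        out[:, 1:-1] = (a[:, 2:] - a[:, :-2]) / (2.0 * dx_m)
        return out

    def ddy(a):
        out = np.full_like(a, np.nan)
        out[1:-1, :] = (a[2:, :] - a[:-2, :]) / (2.0 * dy_m)
        return out

    return ddx(layer_u), ddy(layer_u), ddx(layer_v), ddy(layer_v)


def strain_vorticity(velocity: VelocityField) -> StrainComponents:
    """Strain components and relative vorticity via centered differences.

    s_n = du/dx - dv/dy, s_s = dv/dx + du/dy, omega = dv/dx - du/dy.
    Boundary cells (and cells with a missing neighbor) are missing.
    """
    grid = velocity.grid
    if grid.shape[0] < 3 or grid.shape[1] < 3:
        raise ValueError("strain_vorticity needs at least 3 cells per axis")
    u_all, v_all = velocity.speed_mps()
    u_all = u_all if velocity.times is not None else u_all[None]
    v_all = v_all if velocity.times is not None else v_all[None]
    sn = np.empty_like(u_all)
    ss = np.empty_like(u_all)
    om = np.empty_like(u_all)
    for i in range(u_all.shape[0]):
        dudx, dudy, dvdx, dvdy = _centered_gradients(u_all[i], v_all[i], grid)
        sn[i] = dudx - dvdy
        ss[i] = dvdx + dudy
        om[i] = dvdx - dudy
    if velocity.times is None:
        sn, ss, om = sn[0], ss[0], om[0]

    def wrap(vals, name):
        return ScalarField(grid, vals, velocity.times, name, "1/s")

    return StrainComponents(wrap(sn, "normal_strain"),
                            wrap(ss, "shear_strain"),
                            wrap(om, "relative_vorticity"))


def okubo_weiss(velocity: VelocityField) -> ScalarField:
    """Okubo-Weiss parameter W = s_n^2 + s_s^2 - omega^2 (1/s^2)."""
    c = strain_vorticity(velocity)
    w = (c.normal_strain.values ** 2 + c.shear_strain.values ** 2
         - c.relative_vorticity.values ** 2)
    return ScalarField(velocity.grid, w, velocity.times, "okubo_weiss",
                       "1/s^2")


# ---------------------------------------------------------------------------
# Lagrangian diagnostics


class _VelocitySampler:
    """Bilinear-in-space, linear-in-time velocity lookup in degrees/day.

    Positions are (lon, lat) in degrees.  Outside the grid hull, or on
    land, the sampled velocity is NaN (callers freeze such particles).
    """

    def __init__(self, velocity: VelocityField):
        self.grid = velocity.grid
        u, v = velocity.speed_mps()
        if velocity.times is None:
            self._u = u[None]
            self._v = v[None]
            self._tdays = None
        else:
            self._u = u
            self._v = v
            t0 = velocity.times[0]
            self._tdays = (
                (velocity.times - t0) / pd.Timedelta(days=1)).to_numpy()
            self._t0 = t0
        # m/s -> degrees/day
        sec_per_day = 86400.0
        m_per_deg_lat = KM_PER_DEGREE * 1000.0
        self._lat_factor = sec_per_day / m_per_deg_lat
        self.time_span = (None if self._tdays is None
                          else (self._tdays[0], self._tdays[-1]))

    def days_since_start(self, when: pd.Timestamp) -> float:
        if self._tdays is None:
            return 0.0
        return float((when - self._t0) / pd.Timedelta(days=1))

    def _interp_layer(self, layer: np.ndarray, lon: np.ndarray,
                      lat: np.ndarray) -> np.ndarray:
        g = self.grid
        fx = (lon - g.lon[0]) / g.dlon
        fy = (lat - g.lat[0]) / g.dlat
        nx, ny = g.lon.size, g.lat.size
        inside = (np.isfinite(fx) & np.isfinite(fy)
                  & (fx >= 0) & (fx <= nx - 1) & (fy >= 0) & (fy <= ny - 1))
        fx = np.where(inside, fx, 0.0)
        fy = np.where(inside, fy, 0.0)
        fx = np.clip(fx, 0, nx - 1 - 1e-12)
        fy = np.clip(fy, 0, ny - 1 - 1e-12)
        ix = np.minimum(fx.astype(int), nx - 2)
        iy = np.minimum(fy.astype(int), ny - 2)
        wx = fx - ix
        wy = fy - iy
        z = (layer[iy, ix] * (1 - wx) * (1 - wy)
             + layer[iy, ix + 1] * wx * (1 - wy)
             + layer[iy + 1, ix] * (1 - wx) * wy
             + layer[iy + 1, ix + 1] * wx * wy)
        z[~inside] = np.nan
        return z

    def _layers_at(self, t_days: float) -> tuple[np.ndarray, np.ndarray]:
        if self._tdays is None or len(self._tdays) == 1:
            return self._u[0], self._v[0]
        t = np.clip(t_days, self._tdays[0], self._tdays[-1])
        j = int(np.searchsorted(self._tdays, t, side="right") - 1)
        j = min(max(j, 0), len(self._tdays) - 2)
        w = (t - self._tdays[j]) / (self._tdays[j + 1] - self._tdays[j])
        u = (1 - w) * self._u[j] + w * self._u[j + 1]
        v = (1 - w) * self._v[j] + w * self._v[j + 1]
        return u, v

    def __call__(self, lon: np.ndarray, lat: np.ndarray,
                 t_days: float) -> tuple[np.ndarray, np.ndarray]:
        u_layer, v_layer = self._layers_at(t_days)
        u = self._interp_layer(u_layer, lon, lat)
        v = self._interp_layer(v_layer, lon, lat)
        coslat = np.cos(np.deg2rad(lat))
        dlon_dt = u * self._lat_factor / np.maximum(coslat, 1e-9)
        dlat_dt = v * self._lat_factor
        return dlon_dt, dlat_dt


def advect(seed_points: np.ndarray, velocity: VelocityField,
           t_start: pd.Timestamp | str | None = None,
           duration: float = 10.0, direction: str = "forward",
           step: float = 0.25,
           return_trajectory: bool = False) -> np.ndarray:
    """Integrate particle positions through a velocity field with RK4.

    ``seed_points`` is an (N, 2) array of (lon, lat) degrees.  The
    integrator uses a fixed step (days), bilinear spatial and linear
    temporal interpolation; ``backward`` integrates with negated time.
    Particles leaving the domain or touching land are frozen in place.

    Returns final positions (N, 2), or the full trajectory
    (n_steps + 1, N, 2) when ``return_trajectory`` is set.
    """
    if direction not in ("forward", "backward"):
        raise ValueError(f"unknown direction: {direction!r}")
    sampler = _VelocitySampler(velocity)
    t0 = 0.0
    if t_start is not None and velocity.times is not None:
        t0 = sampler.days_since_start(pd.Timestamp(t_start))
        sign = 1.0 if direction == "forward" else -1.0
        t_end = t0 + sign * duration
        span = sampler.time_span
        if span is not None and not (
                span[0] - 1e-9 <= min(t0, t_end)
                and max(t0, t_end) <= span[1] + 1e-9):
            raise ValueError(
                "integration window lies outside the velocity time axis")
    pos = np.array(seed_points, dtype=float).reshape(-1, 2).copy()
    pos, traj = _rk4_run(pos, sampler, t0, duration, direction, step,
                         keep_trajectory=return_trajectory)
    return traj if return_trajectory else pos


def _rk4_run(pos: np.ndarray, sampler: _VelocitySampler, t0: float,
             duration: float, direction: str, step: float,
             keep_trajectory: bool = False,
             stop_check=None) -> tuple[np.ndarray, np.ndarray | None]:
    """Shared fixed-step RK4 loop over a set of particles.

    ``stop_check(pos, elapsed_days, active)`` may freeze groups of
    particles by returning a boolean per-particle mask of finished ones.
    """
    sign = 1.0 if direction == "forward" else -1.0
    n_steps = int(np.ceil(duration / step - 1e-9))
    active = np.ones(pos.shape[0], dtype=bool)
    traj = [pos.copy()] if keep_trajectory else None
    elapsed = 0.0
    for istep in range(n_steps):
        dt = min(step, duration - elapsed)
        h = sign * dt
        if not active.any():
            if keep_trajectory:
                traj.append(pos.copy())
            elapsed += dt
            continue
        p = pos[active]
        lon, lat = p[:, 0], p[:, 1]
        t = t0 + sign * elapsed

        k1x, k1y = sampler(lon, lat, t)
        k2x, k2y = sampler(lon + 0.5 * h * k1x, lat + 0.5 * h * k1y,
                           t + 0.5 * h)
        k3x, k3y = sampler(lon + 0.5 * h * k2x, lat + 0.5 * h * k2y,
                           t + 0.5 * h)
        k4x, k4y = sampler(lon + h * k3x, lat + h * k3y, t + h)
        dlon = h / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
        dlat = h / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y)
        bad = ~np.isfinite(dlon) | ~np.isfinite(dlat)
        dlon[bad] = 0.0
        dlat[bad] = 0.0
        new = p + np.column_stack([dlon, dlat])
        pos[active] = new
        # freeze particles that left the hull or hit a NaN velocity
        idx = np.flatnonzero(active)
        active[idx[bad]] = False
        elapsed += dt
        if keep_trajectory:
            traj.append(pos.copy())
        if stop_check is not None:
            frozen = stop_check(pos, elapsed, active)
            if frozen is not None:
                active &= ~frozen
    return pos, (np.stack(traj) if keep_trajectory else None)


def fsle(velocity: VelocityField, params: FsleParams | None = None,
         eval_time: pd.Timestamp | str | None = None,
         allow_partial_history: bool = False) -> ScalarField:
    """Finite-size Lyapunov exponent map in 1/day.

    For each ocean cell, four neighbor particles at distance delta0
    (east/west/north/south) are advected together with the cell-center
    particle; lambda = ln(deltaf/delta0) / tau* with tau* the first time
    any neighbor's separation from the center reaches deltaf (separation
    in degrees with the zonal component scaled by cos of the pair's
    mid-latitude).  lambda = 0 where deltaf is never reached within
    tau_max.  Land cells are missing.
    """
    params = params or FsleParams()
    grid = velocity.grid
    sampler = _VelocitySampler(velocity)
    t0 = 0.0
    if eval_time is not None and velocity.times is not None:
        t0 = sampler.days_since_start(pd.Timestamp(eval_time))
        if params.direction == "backward" and not allow_partial_history:
            lo = t0 - params.tau_max
            if lo < sampler.time_span[0] - 1e-9:
                raise ValueError(
                    "velocity must span [eval_time - tau_max, eval_time] "
                    "for backward FSLE (pass allow_partial_history=True "
                    "to persist the earliest field instead)")

    ocean = grid.ocean
    iy, ix = np.nonzero(ocean)
    n_cells = iy.size
    lon_c = grid.lon[ix]
    lat_c = grid.lat[iy]
    d0 = params.delta0
    # particle layout: [center, east, west, north, south] x n_cells
    lon0 = np.concatenate([lon_c, lon_c + d0, lon_c - d0, lon_c, lon_c])
    lat0 = np.concatenate([lat_c, lat_c, lat_c, lat_c + d0, lat_c - d0])
    pos = np.column_stack([lon0, lat0])

    tau_star = np.full(n_cells, np.nan)
    disqualified = np.zeros(n_cells, dtype=bool)

    def separation(p):
        c = p[:n_cells]
        seps = np.empty((4, n_cells))
        for k in range(4):
            q = p[(k + 1) * n_cells:(k + 2) * n_cells]
            midlat = 0.5 * (c[:, 1] + q[:, 1])
            dlon = (q[:, 0] - c[:, 0]) * np.cos(np.deg2rad(midlat))
            dlat = q[:, 1] - c[:, 1]
            seps[k] = np.hypot(dlon, dlat)
        return seps.max(axis=0)

    def stop_check(p, elapsed, active):
        # a bundle losing any particle (domain exit / land) cannot cross:
        # its measured separation would reflect the freeze, not the flow
        lost = ~active.reshape(5, n_cells).all(axis=0)
        disqualified[lost & np.isnan(tau_star)] = True
        sep = separation(p)
        crossed = (sep >= params.deltaf) & np.isnan(tau_star) & ~disqualified
        tau_star[crossed] = elapsed
        done = ~np.isnan(tau_star) | disqualified
        return np.tile(done, 5)

    _rk4_run(pos, sampler, t0, params.tau_max, params.direction,
             params.integration_step, stop_check=stop_check)

    lam_cells = np.zeros(n_cells)
    hit = ~np.isnan(tau_star)
    lam_cells[hit] = np.log(params.deltaf / params.delta0) / tau_star[hit]
    lam = np.full(grid.shape, np.nan)
    lam[iy, ix] = lam_cells
    return ScalarField(grid, lam, None, "fsle", "1/day")
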