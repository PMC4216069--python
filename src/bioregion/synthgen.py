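"""Synthetic ocean scenes with known ground truth.

Generates the three ingredients the downstream pipeline consumes:

* province scenes — SST/chl/bathymetry monthly series over a rectangular
  basin partitioned into K contiguous Voronoi provinces, each with its
  own mean state, plus a dominant 12-month seasonal cycle, a weaker
  interannual sinusoid, and i.i.d. Gaussian observational noise;
* velocity scenes — analytic flow fields (solid-body and Rankine
  vortices, pure strain, uniform background, and superpositions) whose
  vorticity, strain and stirring rates are known in closed form;
* climate-index series — AR(1) or sinusoidal monthly stand-ins for
  large-scale atmospheric pattern indices (NAO/EA-style).

All randomness flows through one seeded generator per scene, so every
product is a pure function of its spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .gridio import Grid, ScalarField, VelocityField, KM_PER_DEGREE


@dataclass
class VortexSpec:
    """A rotating ingredient: solid-body inside, optionally 1/r outside."""

    center_lon: float
    center_lat: float
    radius_km: float
    peak_speed: float  # m/s at the radius
    kind: str = "rankine"  # rankine | solid_body


@dataclass
class StrainSpec:
    """Strain ingredient u = +gamma x', v = -gamma y' (x', y' in km).

    ``radius_km`` optionally tapers the flow with a Gaussian envelope
    exp(-r^2 / 2 R^2) so the strain region is localized; ``None`` keeps
    the ideal unbounded strain used by the analytic oracles.
    """

    center_lon: float
    center_lat: float
    gamma_per_day: float
    radius_km: float | None = None


@dataclass
class SceneSpec:
    """Parameters of a synthetic basin scene.

    Defaults describe the reference desk-scale scene: a 40x60-cell basin
    with 4 planted provinces observed for 60 months.  Province contrasts
    in the classical variables are strong relative to noise (separation
    well above 3x the noise SD), while the mesoscale circulation is a
    steady, spatially localized composite — mirroring a regime in which
    classical features dominate the regional contrast and mesoscale
    features add secondary structure.
    """

    lon_min: float = 0.0
    lon_max: float = 15.0
    lat_min: float = 32.0
    lat_max: float = 42.0
    n_lon: int = 60
    n_lat: int = 40
    n_months: int = 60
    start: str = "2002-01"
    k_true: int = 4
    # per-province means; length must equal k_true.  Trait combinations
    # are deliberately decorrelated across provinces (warm-oligotrophic,
    # cold-productive-shallow, ...) as in real basins, so provinces
    # occupy general position in feature space rather than one gradient.
    sst_means: tuple[float, ...] = (14.0, 18.0, 22.0, 26.0)  # degC
    chl_means: tuple[float, ...] = (0.9, 0.12, 2.0, 0.35)  # mg m-3
    depth_means: tuple[float, ...] = (80.0, 3200.0, 400.0, 1200.0)  # m, +down
    seasonal_amplitude: dict = dc_field(default_factory=lambda: {
        "sst": 3.0, "chl": 0.35})
    seasonal_phase_lag_months: float = 2.0  # SST lags chl
    interannual_amplitude: dict = dc_field(default_factory=lambda: {
        "sst": 0.5, "chl": 0.05})
    interannual_period_months: float = 36.0
    noise_sd: dict = dc_field(default_factory=lambda: {
        "sst": 0.32, "chl": 0.01, "depth": 20.0})
    # multiplicative noise: per-cell SD adds this fraction of the local
    # mean (chlorophyll noise scales with concentration)
    relative_noise: dict = dc_field(default_factory=lambda: {"chl": 0.25})
    # per-province scaling of a variable's noise SD (regional variability
    # contrast, e.g. shelf SST more variable than open basin); tuples are
    # interpolated to k_true entries when lengths differ
    noise_province_factors: dict = dc_field(default_factory=lambda: {
        "sst": (2.2, 0.6, 1.2, 4.0)})
    land_border_cells: int = 2  # land strip along the northern edge
    # Gaussian smoothing (sigma in cells) of the planted mean maps, so
    # province transitions are mesoscale-width gradients rather than
    # single-cell steps; 0 keeps hard edges
    mean_smoothing_cells: float = 0.75
    # seasonal meander of the tracer pattern (degrees): boundaries sway
    # around their mean position, as real fronts do, so time-averaged
    # frontal ridges are smeared rather than pinned to one cell column
    meander_amplitude_deg: float = 1.25
    vortices: tuple[VortexSpec, ...] = (
        VortexSpec(4.0, 35.0, 80.0, 0.05),)
    strains: tuple[StrainSpec, ...] = (
        StrainSpec(11.0, 39.0, 0.02, radius_km=120.0),)
    uniform_background: tuple[float, float] = (0.02, 0.01)  # m/s
    # monthly modulation of the whole circulation plus observational noise
    velocity_seasonal_amplitude: float = 0.3
    velocity_interannual_amplitude: float = 0.1
    velocity_noise_sd: float = 0.05  # m/s, i.i.d. per cell and week
    # per-province eddy-activity factors scaling the velocity noise SD;
    # None = uniform.  Length k_true when given.
    velocity_noise_province_factors: tuple[float, ...] | None = (
        2.0, 0.4, 4.0, 1.0)
    seed: int = 0

    def validate(self) -> None:
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if self.n_months < 12:
            raise ValueError("n_months must be >= 12")
        for name in ("sst_means", "chl_means", "depth_means"):
            if len(getattr(self, name)) != self.k_true:
                raise ValueError(
                    f"{name} must have k_true={self.k_true} entries")
        for table in (self.seasonal_amplitude, self.noise_sd):
            if any(v < 0 for v in table.values()):
                raise ValueError("amplitudes and noise SDs must be >= 0")

    def grid(self) -> Grid:
        lon = np.linspace(self.lon_min, self.lon_max, self.n_lon,
                          endpoint=False)
        lon = lon + (self.lon_max - self.lon_min) / self.n_lon / 2
        lat = np.linspace(self.lat_min, self.lat_max, self.n_lat,
                          endpoint=False)
        lat = lat + (self.lat_max - self.lat_min) / self.n_lat / 2
        mask = np.zeros((self.n_lat, self.n_lon), dtype=bool)
        if self.land_border_cells > 0:
            mask[-self.land_border_cells:, :] = True
        return Grid(lon, lat, mask)

    def months(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.n_months, freq="MS")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated scene."""

    province_labels: np.ndarray  # (n_lat, n_lon) int, 1..K on ocean, 0 on land
    seed_points: np.ndarray  # (K, 2) of (lat, lon) Voronoi generators
    spec: SceneSpec


def _voronoi_labels(grid: Grid, k: int, rng: np.random.Generator) -> tuple[
        np.ndarray, np.ndarray]:
    """Assign each ocean cell to its nearest of k random seed points.

    Distances use km-scaled coordinates so patches are contiguous and
    irregular like real subprovinces rather than stretched in longitude.
    """
    ocean = grid.ocean
    n_ocean = int(ocean.sum())
    if k > n_ocean:
        raise ValueError(f"k_true={k} exceeds ocean cell count {n_ocean}")
    lat2d, lon2d = np.meshgrid(grid.lat, grid.lon, indexing="ij")
    ocean_idx = np.flatnonzero(ocean.ravel())
    mean_lat = np.deg2rad(grid.lat.mean())
    y = (lat2d * KM_PER_DEGREE).ravel()
    x = (lon2d * KM_PER_DEGREE * np.cos(mean_lat)).ravel()
    # farthest-point (blue-noise) seeding: the first generator is random,
    # the rest maximize distance to those already chosen, which keeps the
    # province areas comparable across random layouts
    chosen = [int(rng.choice(ocean_idx))]
    if k > 1:
        d2min = np.full(ocean_idx.size, np.inf)
        for _ in range(k - 1):
            last = chosen[-1]
            d2_new = ((x[ocean_idx] - x[last]) ** 2
                      + (y[ocean_idx] - y[last]) ** 2)
            d2min = np.minimum(d2min, d2_new)
            chosen.append(int(ocean_idx[int(np.argmax(d2min))]))
    chosen = np.asarray(chosen)
    seeds = np.column_stack([lat2d.ravel()[chosen], lon2d.ravel()[chosen]])
    d2 = ((x[None, :] - x[chosen][:, None]) ** 2
          + (y[None, :] - y[chosen][:, None]) ** 2)
    labels = (np.argmin(d2, axis=0) + 1).reshape(grid.shape)
    labels[~ocean] = 0
    return labels, seeds


def _smooth_ocean(field2d: np.ndarray, ocean: np.ndarray,
                  sigma_cells: float) -> np.ndarray:
    """Gaussian smoothing over ocean cells (normalized convolution)."""
    from scipy.ndimage import gaussian_filter

    filled = np.where(ocean, field2d, 0.0)
    weight = ocean.astype(float)
    num = gaussian_filter(filled, sigma_cells)
    den = gaussian_filter(weight, sigma_cells)
    out = np.full_like(field2d, np.nan)
    good = ocean & (den > 1e-12)
    out[good] = num[good] / den[good]
    return out


def make_province_scene(spec: SceneSpec) -> tuple[
        dict[str, ScalarField], SyntheticTruth]:
    """Generate SST(t), chl(t) and static bathymetry with planted provinces.

    Returns a dict with keys ``sst``, ``chl``, ``bathymetry`` and the
    :class:`SyntheticTruth`.  Bathymetry is stored negative-down.
    Generation is bit-reproducible from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid()
    labels, seeds = _voronoi_labels(grid, spec.k_true, rng)
    ocean = grid.ocean
    months = spec.months()
    t = np.arange(spec.n_months, dtype=float)

    sst_mean = np.full(grid.shape, np.nan)
    chl_mean = np.full(grid.shape, np.nan)
    depth = np.full(grid.shape, np.nan)
    for p in range(1, spec.k_true + 1):
        cells = labels == p
        sst_mean[cells] = spec.sst_means[p - 1]
        chl_mean[cells] = spec.chl_means[p - 1]
        depth[cells] = spec.depth_means[p - 1]
    if spec.mean_smoothing_cells > 0:
        sst_mean = _smooth_ocean(sst_mean, ocean, spec.mean_smoothing_cells)
        chl_mean = _smooth_ocean(chl_mean, ocean, spec.mean_smoothing_cells)
        depth = _smooth_ocean(depth, ocean, spec.mean_smoothing_cells)

    # smooth within-province bathymetric relief: gentle basin-scale bowl
    lat2d, lon2d = np.meshgrid(grid.lat, grid.lon, indexing="ij")
    relief = 0.05 * depth * np.sin(np.deg2rad(4 * lon2d)) * np.cos(
        np.deg2rad(6 * lat2d))
    depth_noise = rng.normal(0.0, spec.noise_sd.get("depth", 0.0), grid.shape)
    bathy = -(depth + relief + depth_noise)
    bathy[~ocean] = np.nan

    omega_seas = 2 * np.pi / 12.0
    omega_inter = 2 * np.pi / spec.interannual_period_months
    lag = spec.seasonal_phase_lag_months

    # zero-mean seasonal meander of the tracer pattern, shared by SST
    # and chl so their fronts move together; jitter keeps it aperiodic
    amp = spec.meander_amplitude_deg
    phase_x, phase_y = rng.uniform(0, 2 * np.pi, 2)
    shift_lon = amp * np.sin(omega_seas * t + phase_x)
    shift_lat = 0.6 * amp * np.sin(omega_seas * t + phase_y)
    if amp > 0:
        shift_lon = shift_lon + rng.normal(0.0, amp / 2.0, spec.n_months)
        shift_lat = shift_lat + rng.normal(0.0, amp / 3.0, spec.n_months)

    def meandered(mean2d):
        """Per-month displaced copies of a mean map (land refilled)."""
        from scipy.ndimage import distance_transform_edt, map_coordinates

        filled = mean2d
        if np.isnan(mean2d).any():
            # extend ocean values onto land so shifts near the coast
            # pull in the nearest water value, not a fill constant
            _, (ri, ci) = distance_transform_edt(
                ~np.isfinite(mean2d), return_indices=True)
            filled = mean2d[ri, ci]
        rows = np.arange(grid.shape[0], dtype=float)
        cols = np.arange(grid.shape[1], dtype=float)
        cgrid, rgrid = np.meshgrid(cols, rows)
        out = np.empty((spec.n_months, *grid.shape))
        for i in range(spec.n_months):
            coords = [rgrid - shift_lat[i] / grid.dlat,
                      cgrid - shift_lon[i] / grid.dlon]
            out[i] = map_coordinates(filled, coords, order=1,
                                     mode="nearest")
        return out

    def series(mean2d, var):
        seas = spec.seasonal_amplitude.get(var, 0.0)
        inter = spec.interannual_amplitude.get(var, 0.0)
        phase = omega_seas * lag if var == "sst" else 0.0
        cyc = seas * np.sin(omega_seas * t - phase) + inter * np.sin(
            omega_inter * t)
        base = meandered(mean2d) if amp > 0 else mean2d[None, :, :]
        vals = base + cyc[:, None, None]
        sd_map = np.full(grid.shape, spec.noise_sd.get(var, 0.0))
        rel = spec.relative_noise.get(var, 0.0)
        if rel > 0:
            sd_map = sd_map + rel * np.abs(mean2d)
        factors = spec.noise_province_factors.get(var)
        if factors is not None:
            if len(factors) != spec.k_true:
                factors = np.interp(
                    np.linspace(0, len(factors) - 1, spec.k_true),
                    np.arange(len(factors)), factors)
            fmap = np.ones(grid.shape)
            for p in range(1, spec.k_true + 1):
                fmap[labels == p] = factors[p - 1]
            sd_map = sd_map * fmap
        if np.any(sd_map > 0):
            vals = vals + sd_map[None] * rng.standard_normal(vals.shape)
        vals[:, ~ocean] = np.nan
        return vals

    fields = {
        "sst": ScalarField(grid, series(sst_mean, "sst"), months, "sst",
                           "degC"),
        "chl": ScalarField(grid, series(chl_mean, "chl"), months, "chl",
                           "mg m-3"),
        "bathymetry": ScalarField(grid, bathy, None, "bathymetry", "m"),
    }
    # chlorophyll must stay positive for the later log transform
    chl = fields["chl"].values
    np.clip(chl, 1e-3, None, out=chl)
    chl[:, ~ocean] = np.nan
    return fields, SyntheticTruth(labels, seeds, spec)


def _km_offsets(grid: Grid, center_lon: float, center_lat: float) -> tuple[
        np.ndarray, np.ndarray]:
    # zonal offsets use each cell's own latitude so that analytic strain
    # and vorticity rates match sphere-corrected finite differences
    lat2d, lon2d = np.meshgrid(grid.lat, grid.lon, indexing="ij")
    x = (lon2d - center_lon) * KM_PER_DEGREE * np.cos(np.deg2rad(lat2d))
    y = (lat2d - center_lat) * KM_PER_DEGREE
    return x, y


def _vortex_uv(grid: Grid, vx: VortexSpec) -> tuple[np.ndarray, np.ndarray]:
    x, y = _km_offsets(grid, vx.center_lon, vx.center_lat)
    r = np.hypot(x, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        if vx.kind == "solid_body":
            speed = vx.peak_speed * r / vx.radius_km
        elif vx.kind == "rankine":
            speed = np.where(r <= vx.radius_km,
                             vx.peak_speed * r / vx.radius_km,
                             vx.peak_speed * vx.radius_km / np.maximum(r, 1e-9))
        else:
            raise ValueError(f"unknown vortex kind: {vx.kind!r}")
        u = np.where(r > 0, -speed * y / np.maximum(r, 1e-9), 0.0)
        v = np.where(r > 0, speed * x / np.maximum(r, 1e-9), 0.0)
    return u, v


def _strain_uv(grid: Grid, st: StrainSpec) -> tuple[np.ndarray, np.ndarray]:
    x, y = _km_offsets(grid, st.center_lon, st.center_lat)
    gamma = st.gamma_per_day / 86400.0  # 1/s
    u = gamma * x * 1000.0  # km -> m
    v = -gamma * y * 1000.0
    if st.radius_km is not None:
        env = np.exp(-(x ** 2 + y ** 2) / (2.0 * st.radius_km ** 2))
        u, v = u * env, v * env
    return u, v


def make_velocity_scene(spec: SceneSpec, kind: str = "composite",
                        mask_land: bool = True) -> VelocityField:
    """Build an analytic velocity field (m/s) on the scene grid.

    ``kind`` selects which ingredients enter: ``uniform``, ``solid_body``
    (first vortex as solid-body), ``rankine`` (first vortex), ``strain``
    (first strain region), or ``composite`` (all ingredients summed).
    The field is steady (no time axis).
    """
    grid = spec.grid()
    u = np.zeros(grid.shape)
    v = np.zeros(grid.shape)
    if kind == "uniform":
        u += spec.uniform_background[0]
        v += spec.uniform_background[1]
    elif kind in ("solid_body", "rankine"):
        if not spec.vortices:
            raise ValueError("spec has no vortex ingredient")
        vx = spec.vortices[0]
        vx = VortexSpec(vx.center_lon, vx.center_lat, vx.radius_km,
                        vx.peak_speed, kind)
        du, dv = _vortex_uv(grid, vx)
        u, v = u + du, v + dv
    elif kind == "strain":
        if not spec.strains:
            raise ValueError("spec has no strain ingredient")
        du, dv = _strain_uv(grid, spec.strains[0])
        u, v = u + du, v + dv
    elif kind == "composite":
        u += spec.uniform_background[0]
        v += spec.uniform_background[1]
        for vx in spec.vortices:
            du, dv = _vortex_uv(grid, vx)
            u, v = u + du, v + dv
        for st in spec.strains:
            du, dv = _strain_uv(grid, st)
            u, v = u + du, v + dv
    else:
        raise ValueError(f"unknown velocity scene kind: {kind!r}")
    if not mask_land:
        grid = Grid(grid.lon, grid.lat, np.zeros(grid.shape, dtype=bool))
    uf = ScalarField(grid, u, None, "u", "m/s")
    vf = ScalarField(grid, v, None, "v", "m/s")
    return VelocityField(uf, vf)


def make_velocity_series(spec: SceneSpec,
                         kind: str = "composite") -> VelocityField:
    """Weekly velocity-anomaly series: modulated analytic flow + noise.

    Each weekly layer is the steady ``kind`` scene scaled by a
    modulation factor m(t) = 1 + a_s sin(2 pi t / 12) + a_i sin(2 pi t /
    P) (floored at 0.1 so the circulation never reverses), plus Gaussian
    observational noise per cell redrawn every week.  The modulation
    gives the mesoscale diagnostics a seasonal cycle and an interannual
    signal; the weekly-decorrelating noise sustains chaotic stirring, so
    finite-size separations actually grow (a steady random field would
    trap particle pairs on closed streamlines).  Per-province noise
    factors emulate regionally contrasting eddy activity.
    """
    steady = make_velocity_scene(spec, kind)
    grid = steady.grid
    start = spec.months()[0]
    end = spec.months()[-1] + pd.offsets.MonthEnd(0)
    weeks = pd.date_range(start, end, freq="7D")
    t = ((weeks - start) / pd.Timedelta(days=1)).to_numpy() / 30.4375
    m = (1.0
         + spec.velocity_seasonal_amplitude * np.sin(2 * np.pi * t / 12.0)
         + spec.velocity_interannual_amplitude * np.sin(
             2 * np.pi * t / spec.interannual_period_months))
    m = np.maximum(m, 0.1)
    rng = np.random.default_rng((spec.seed, 0x5EA))
    u = steady.u.values[None] * m[:, None, None]
    v = steady.v.values[None] * m[:, None, None]
    if spec.velocity_noise_sd > 0:
        sd_map = np.full(grid.shape, spec.velocity_noise_sd)
        factors = spec.velocity_noise_province_factors
        if factors is not None:
            if len(factors) != spec.k_true:
                # spread the stated gradation over however many provinces
                factors = np.interp(
                    np.linspace(0, len(factors) - 1, spec.k_true),
                    np.arange(len(factors)), factors)
            # same labels as make_province_scene: first draw of the seed
            labels, _ = _voronoi_labels(grid, spec.k_true,
                                        np.random.default_rng(spec.seed))
            for p in range(1, spec.k_true + 1):
                sd_map[labels == p] *= factors[p - 1]
        u = u + sd_map[None] * rng.standard_normal(u.shape)
        v = v + sd_map[None] * rng.standard_normal(v.shape)
    uf = ScalarField(grid, u, weeks, "u", "m/s")
    vf = ScalarField(grid, v, weeks, "v", "m/s")
    return VelocityField(uf, vf)


def spread_province_traits(k: int) -> tuple[tuple, tuple, tuple]:
    """K province trait combinations in general position.

    SST means span 13-27 degC in index order; chl and depth values span
    realistic ranges but are permuted so no variable ordering mirrors
    another, maximizing the minimum pairwise distance between province
    centroids in standardized (SST, ln chl, ln depth) space.  The search
    is deterministic in k.
    """
    sst = np.linspace(13.0, 27.0, k)
    chl = np.geomspace(2.0, 0.1, k)
    dep = np.geomspace(80.0, 3200.0, k)

    def z(v):
        s = v.std()
        return (v - v.mean()) / (s if s > 0 else 1.0)

    rng = np.random.default_rng(k)
    best, best_d = (np.arange(k), np.arange(k)), -1.0
    for _ in range(200):
        pc, pd_ = rng.permutation(k), rng.permutation(k)
        pts = np.column_stack(
            [z(sst), z(np.log(chl[pc])), z(np.log(dep[pd_]))])
        d = min((np.linalg.norm(pts[i] - pts[j])
                 for i in range(k) for j in range(i)), default=np.inf)
        if d > best_d:
            best_d, best = d, (pc, pd_)
    return tuple(sst), tuple(chl[best[0]]), tuple(dep[best[1]])


def make_planted_scene(k_true: int, seed: int = 0,
                       **overrides) -> SceneSpec:
    """A clean planted-province scene for recovery studies.

    Provinces have spread trait combinations, uniform noise (separation
    at least 3x the noise SD), no boundary meander, and no regional
    variability factors — the minimal conditions under which the
    k-selection rule should find the planted count.
    """
    sst, chl, dep = spread_province_traits(k_true)
    base = dict(
        n_lon=24, n_lat=18, lon_min=0.0, lon_max=12.0, lat_min=33.0,
        lat_max=42.0, n_months=24, k_true=k_true,
        sst_means=sst, chl_means=chl, depth_means=dep,
        noise_sd={"sst": 0.3, "chl": 0.0, "depth": 30.0},
        relative_noise={"chl": 0.1}, noise_province_factors={},
        velocity_noise_province_factors=None,
        mean_smoothing_cells=0.0, meander_amplitude_deg=0.0,
        land_border_cells=1, seed=seed)
    base.update(overrides)
    return SceneSpec(**base)


def make_climate_index(n_months: int, kind: str = "ar1",
                       params: dict | None = None,
                       seed: int = 0) -> pd.Series:
    """Monthly climate-index stand-in: zero-mean AR(1) or sinusoid.

    AR(1): x_t = phi * x_{t-1} + eps_t with unit-variance innovations,
    initialized from the stationary distribution.  Sinusoid: amplitude
    and period in months, plus optional Gaussian noise.
    """
    if n_months < 2:
        raise ValueError("n_months must be >= 2")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    months = pd.date_range("2002-01", periods=n_months, freq="MS")
    if kind == "ar1":
        phi = float(params.get("phi", 0.5))
        if abs(phi) >= 1:
            raise ValueError("AR(1) coefficient must satisfy |phi| < 1")
        x = np.empty(n_months)
        x[0] = rng.normal(0.0, 1.0 / np.sqrt(1 - phi ** 2))
        eps = rng.normal(0.0, 1.0, n_months)
        for i in range(1, n_months):
            x[i] = phi * x[i - 1] + eps[i]
    elif kind == "sinusoid":
        period = float(params.get("period", 12.0))
        amp = float(params.get("amplitude", 1.0))
        noise = float(params.get("noise_sd", 0.0))
        t = np.arange(n_months, dtype=float)
        x = amp * np.sin(2 * np.pi * t / period)
        if noise > 0:
            x = x + rng.normal(0.0, noise, n_months)
    else:
        raise ValueError(f"unknown climate index kind: {kind!r}")
    x = x - x.mean()
    return pd.Series(x, index=months, name=f"{kind}_index")
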