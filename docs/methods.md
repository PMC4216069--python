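# Methods

This note records the models, numerical choices and synthetic-data
design behind `bioregion`, at the level of detail a user would need to
judge what the package's tests do and do not demonstrate.

## Grids, units and missing data

Fields live on regular lat/lon grids of cell centers (uniform spacing
per axis, relative tolerance 1e-6). All per-km quantities convert
degrees to km on a sphere of radius 6371 km; the zonal spacing carries a
cos(latitude) factor evaluated at each cell's own row. Missing ocean
data is NaN; land cells (a boolean mask on the grid) never carry values
and are distinct from data gaps — a cell that is NaN because of a gap
can recover in another month, a land cell cannot. Gaps are propagated,
never filled: cells missing any layer are excluded from clustering and
(pixel, month) individuals missing any variable are dropped from PCA,
with counts recorded.

Bathymetry is stored negative-down (ETOPO-style). Its log transform
applies to |depth| + 1 m and the sign convention is recorded in the
units string, so "deep" is large in the transformed layer while the
stored field stays negative.

NetCDF I/O uses xarray's `scipy` backend (NetCDF3 classic) with
CF-style coordinate variables, units attributes and an explicit
`_FillValue`; doubles round-trip bit-exactly. A `lon,lat[,time],value`
CSV dialect covers small fixtures.

## Mesoscale diagnostics

**Fronts.** The 3×3 Sobel kernels are applied per time layer; the
response is divided by 8× the cell spacing in km (the kernel's weight
sum per spacing step), zonal spacing scaled by cos(latitude), and the
magnitude √(Gx²+Gy²) is returned in tracer units per km. Any missing
value in the 3×3 neighborhood — including the domain edge — makes the
output cell missing; no one-sided estimates are used. On an affine
field the estimator is exact to rounding.

**Strain, vorticity, Okubo–Weiss.** Centered differences on the
sphere-corrected grid give s_n = ∂u/∂x − ∂v/∂y, s_s = ∂v/∂x + ∂u/∂y and
ω = ∂v/∂x − ∂u/∂y in 1/s (velocity units converted from a declared cm/s
or m/s); boundary cells are missing. W = s_n² + s_s² − ω² — the
standard sign, negative in vorticity-dominated eddy cores. FSLE and W
interpret the same velocity anomalies Lagrangianly and Eulerianly.

**FSLE.** For every ocean cell a cross of four particles at separation
δ_0 (east/west/north/south) is advected together with the cell-center
particle, by default backward in time: fixed-step RK4 (default 0.25 d),
bilinear spatial and linear temporal interpolation of the velocity.
Separation is measured in degrees with the zonal component scaled by
cos of the pair's mid-latitude. λ = ln(δ_f/δ_0)/τ* at the first step
where any pair separation reaches δ_f; cells that never reach δ_f
within τ_max get λ = 0 (not missing), so quiescent water reads as zero
stirring. A bundle that loses a particle — domain exit or a land-NaN
velocity — is disqualified (λ = 0) rather than allowed to "separate"
from a frozen particle; the affected cells form a halo of width ≈ δ_f
along coasts and domain edges. λ ≥ 0 by construction, is invariant
under adding a uniform velocity, and on a pure strain flow with
δ_f/δ_0 = 15 reproduces λ = γ with first-crossing time ln(15)/γ.

Default parameters follow the CTOH-style parameterization for
mesoscale work at ~4-km grids: δ_0 = 0.04°, δ_f = 0.6°, τ = 200 d,
where τ is read as the maximum integration time and λ comes from the
first-crossing time. The pipeline's desk-scale configuration
(`RunConfig`) scales the separations to δ_0 = 0.02°, δ_f = 0.3°
(preserving δ_f/δ_0 = 15) with τ_max = 80 d and a 0.5-d step, because
on a 0.25° grid a 0.6° final separation would disqualify a 2–3-cell
halo around every coast. Halving the step changes λ by well under 2% on
the test flows. Monthly FSLE layers are snapshot evaluations (default
one per month, configurable) through the time-varying weekly velocity;
months earlier than τ_max into the record persist the first weekly
field backward in time rather than failing.

## Partitioning

Feature stacks are built per array kind — classical (SST, ln chl,
ln depth), mesoscale (FSLE, W, EKE, SST fronts, ln chl fronts), full
(all eight) — from per-cell time means (or a single month), then each
layer is z-scored over the included cells; a layer constant over cells
is an error, since it cannot be scaled. The chl-front log transform is
ln(x + 1e-3) (gradients are small numbers; an offset guards ln 0) and
is a config switch.

k-means uses k-means++ with 10 restarts (5 inside the bootstrap, where
only medians matter), 300 iterations, all seeded; labels are
canonicalized by descending cluster size so outputs are reproducible,
and no statistic depends on that order. k ≥ distinct-point count
degenerates to one cluster per distinct point with zero within-SS.

**k selection.** Cells are resampled with replacement `n_boot` times;
for each replicate and each k in a contiguous range, k-means records
the explained SS (between/total). The optimal k at threshold t is the
largest k whose median explained-SS increment over k−1 is ≥ t, read in
absolute percentage points (an explained SS is itself a fraction); the
increment of the smallest k counts from zero. If no increment reaches
t, the smallest k is returned with a warning. This reading makes
k(1%) ≥ k(5%) structurally. The bootstrap unit is the cell; resampling
whole months instead is possible by building per-month stacks.

**Stability.** Each month's stack is z-scored and clustered on its own
at fixed k (k from the time-averaged analysis); a cell's stability is
the percentage of months it lies on a boundary (4-connectivity by
default, 8 by flag; land and excluded neighbors never create
boundaries). Boundary detection is label-permutation invariant, so no
cluster matching across months is needed. The denominator counts only
months where the cell was included.

## Synthetic indices

Per province, the seven time-varying features are deseasonalized — each
cell's per-calendar-month mean over all years is subtracted; a calendar
month observed once yields zero anomaly with a warning — and assembled
into an individuals × variables panel, one individual per (pixel,
month). Variables are z-scored over individuals, making the PCA a
correlation-matrix PCA: eigenvalues sum to 7 and the eigenvalue-≥ 1
retention rule has its usual meaning (strict > 1 available by flag; at
least one component is always retained). Eigenvector signs are fixed so
each component's largest-|loading| variable loads positively. The
synthetic index of a retained component is the per-month mean of its
scores over the province's pixels. Bathymetry is static and never
enters the panel.

Spectra are raw periodograms (no tapering; Welch by flag) of the
mean-removed index in cycles/month; the 95% level is the χ²(2)/2 upper
quantile of the one-sided white-noise density at the series' variance,
so ~5% of ordinates of a white series exceed it. Lagged correlations
are Pearson r of index(t) against climate(t − lag) for lags 0..max_lag,
two-sided p-values, deliberately uncorrected for multiple testing —
the table is a screening device, not a hypothesis test. Variable–PC
correlations (loading × √eigenvalue) above 0.5 in magnitude are flagged
as the component's defining variables; the cutoff is strict and
admittedly subjective.

## The synthetic scenes

The generator's job is to produce inputs on which every stage's
behavior is known. Two scene families matter:

**Analytic flows** (`make_velocity_scene`): solid-body and Rankine
vortices, pure strain (optionally Gaussian-tapered so it is localized),
uniform flow, and superpositions, with zonal offsets scaled per-row by
cos(latitude) so analytic strain/vorticity rates match the
finite-difference operators. These carry the oracle values (ω = 2Ω,
W = ±4γ², λ = γ).

**Province scenes** (`make_province_scene`, `make_velocity_series`):
K contiguous provinces from farthest-point-seeded Voronoi patches
(balanced areas across random layouts), each with planted SST/chl/depth
means, plus a 12-month seasonal cycle (SST lagging chl by 2 months so
PCA axes are non-degenerate), a weaker 36-month interannual sinusoid,
and Gaussian noise. Province boundaries meander seasonally (default
amplitude 1.25°, with monthly jitter) around their mean position, as
real fronts do; planted mean maps are lightly smoothed (σ = 0.75
cells). The velocity series is weekly: a steady composite flow
modulated in time, plus observational noise redrawn each week — weekly
decorrelation is what sustains chaotic stirring; a frozen random field
traps particle pairs on streamlines and FSLE cannot cross δ_f.

The default scene's provinces differ in *every* variable, as real
subprovinces do: trait combinations are decorrelated across provinces
(warm–oligotrophic–deep, cold–productive–shallow, …), and both the SST
noise and the velocity noise carry per-province variability factors
(regionally contrasting eddy activity), while chl noise is
proportional to the local mean so chl-front intensity tracks chl
levels. Separations between adjacent province means stay at least 3×
the largest noise SD. These choices give the mesoscale layers genuine
regional structure; without them 5 of 8 z-scored layers are amplified
white noise and no clustering method could meet a recovery target —
that regime is available by zeroing the factor tuples.

What the scenes do **not** emulate: dynamically consistent currents (no
momentum equations; the velocity field does not advect the tracers),
cloud-gap geometry (missingness is random or absent), sensor drift, or
the 4-km resolution of real products — at 0.25° a one-cell boundary
ridge is ~10% of the basin area instead of <1%, which is why boundary
meander matters more here than in real data. Passing tests therefore
demonstrate the correctness and stability of the algorithms under known
structure, not skill on real satellite archives.

## Reference study conditions

The end-to-end reference run uses the default scene — 4 provinces,
60 months, 40×60 cells with a 2-row land strip — the full array,
k ∈ [2, 10], n_boot = 50, both thresholds, and per-stage seeds derived
from one master seed. k-selection recovery is studied on clean planted
scenes (24×18 cells, 24 months, uniform noise, no meander) for
K ∈ {2..6} with the classical array, 50 bootstrap replicates and 20
seeded runs; the mesoscale layers are omitted there because FSLE
integration at that replication count is orders of magnitude more
expensive and the selection rule under test is array-agnostic. The
two-factor PCA study uses 120-month × 30-cell panels with strong
loadings 1.2, weak cross-loadings 0.35 and noise SD 0.6, so every
variable correlates with some mode and trailing eigenvalues sit
strictly below 1 (a variable orthogonal to everything has a population
eigenvalue of exactly 1, putting the ≥1 rule on a knife edge by
construction).

## Known limitations

- FSLE near coasts and domain edges is systematically zero over the
  δ_f-wide disqualification halo; real-data work should either accept
  the halo or supply a basin comfortably larger than the region of
  interest.
- The explained-SS threshold rule inherits k-means' preference for
  equal-size, isotropic clusters; provinces arranged along a single
  environmental gradient yield gradual increments and the 5% rule then
  under-counts (the planted-scene utilities spread province traits
  into general position for exactly this reason).
- Monthly repartitions use each month's own z-scoring, so a month with
  anomalous variance is stretched to unit scale before clustering;
  stability maps mix real boundary motion with this renormalization.
- Deseasonalization by monthly climatology leaves trends in the
  anomalies (by design — interannual signal is what the indices are
  for), so index spectra have power at the lowest frequencies even for
  trend-only inputs.
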