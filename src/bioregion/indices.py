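"""Per-province synthetic environmental indices via PCA.

After removing each cell's per-calendar-month climatology, the monthly
anomalies of the seven time-varying variables (SST, chl, EKE, FSLE, OW,
SST fronts, chl fronts) are z-scored over a province's (cell, month)
individuals and decomposed with a correlation-matrix PCA.  Principal
components with eigenvalue >= 1 are retained (a strict > 1 variant is
available); the monthly mean of a retained PC's scores over the
province's pixels is that province's synthetic index.  Bathymetry is
static and never enters the PCA.

Downstream diagnostics: periodograms with a white-noise 95% level, and
lagged Pearson correlations against climate-index anomaly series
(deliberately without multiple-testing correction, so the tables can be
read as raw screening statistics).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .gridio import ScalarField, nanmean_quiet as gridio_nanmean

PCA_VARIABLES = ("sst", "chl", "eke", "fsle", "okubo_weiss",
                 "sst_front", "chl_front")


def deseasonalize(field: ScalarField) -> ScalarField:
    """Remove each cell's per-calendar-month climatology.

    Needs at least 24 months covering every present calendar month at
    least twice for a meaningful climatology; a month observed only once
    yields zero anomaly there (with a warning).
    """
    if field.times is None:
        raise ValueError("deseasonalize needs a time axis")
    if len(field.times) < 24:
        raise ValueError("deseasonalize needs >= 24 months")
    months = field.times.month
    out = np.empty_like(field.values)
    singles = []
    for m in np.unique(months):
        sel = months == m
        if sel.sum() == 1:
            singles.append(int(m))
        clim = gridio_nanmean(field.values[sel], axis=0)
        out[sel] = field.values[sel] - clim[None]
    if singles:
        warnings.warn(f"calendar month(s) {singles} occur once; their "
                      f"anomalies are zero", stacklevel=2)
    return ScalarField(field.grid, out, field.times, field.name,
                       f"{field.units} anomaly")


def deseasonalize_series(series: pd.Series) -> pd.Series:
    """Per-calendar-month climatology removal for a 1-D monthly series."""
    months = pd.DatetimeIndex(series.index).month
    clim = series.groupby(months).transform("mean")
    return series - clim


@dataclass
class AnomalyPanel:
    """(cell, month) individuals by variable for one province.

    ``data`` is (n_individuals, n_variables): deseasonalized, z-scored
    anomalies.  ``month_index`` and ``cell_ids`` give each row's month
    position and flat grid cell.
    """

    province: int
    data: np.ndarray
    variables: tuple[str, ...]
    month_index: np.ndarray
    cell_ids: np.ndarray
    months: pd.DatetimeIndex
    n_dropped: int = 0


def build_panel(fields: dict[str, ScalarField], province_labels: np.ndarray,
                province: int,
                variables: tuple[str, ...] = PCA_VARIABLES) -> AnomalyPanel:
    """Assemble a province's anomaly panel from deseasonalized fields.

    ``fields`` maps variable names to monthly anomaly fields (static
    fields are broadcast across months).  Individuals with any missing
    variable are dropped and counted.  Each variable is z-scored over
    the surviving individuals.
    """
    missing = [v for v in variables if v not in fields]
    if missing:
        raise ValueError(f"panel variables absent: {missing}")
    times = None
    for v in variables:
        if fields[v].times is not None:
            times = fields[v].times
            break
    if times is None:
        raise ValueError("at least one panel variable must vary in time")
    cells = np.flatnonzero(province_labels.ravel() == province)
    if cells.size == 0:
        raise ValueError(f"province {province} has no cells")
    n_t = len(times)
    cols = []
    for v in variables:
        f = fields[v]
        flat = f.layers().reshape(f.n_time, -1)[:, cells]
        if f.times is None:
            flat = np.broadcast_to(flat, (n_t, cells.size))
        cols.append(flat.ravel())  # month-major: (month, cell)
    data = np.column_stack(cols)
    month_index = np.repeat(np.arange(n_t), cells.size)
    cell_ids = np.tile(cells, n_t)
    keep = np.all(np.isfinite(data), axis=1)
    n_dropped = int((~keep).sum())
    data = data[keep]
    month_index = month_index[keep]
    cell_ids = cell_ids[keep]
    mu = data.mean(axis=0)
    sd = data.std(axis=0, ddof=0)
    # degenerate only relative to the variable's own magnitude, so
    # physically tiny units (e.g. s^-2 diagnostics) are not rejected
    scale = np.maximum(np.abs(data).max(axis=0), 1e-300)
    degen = sd < 1e-12 * scale
    if np.any(degen):
        bad = [variables[i] for i in np.flatnonzero(degen)]
        raise ValueError(f"variable(s) constant over individuals: {bad}")
    data = (data - mu) / sd
    return AnomalyPanel(province, data, tuple(variables), month_index,
                        cell_ids, times, n_dropped)


@dataclass
class ProvinceIndex:
    """PCA decomposition and synthetic indices for one province."""

    province: int
    variables: tuple[str, ...]
    loadings: np.ndarray  # (n_variables, n_pcs) unit-norm eigenvectors
    eigenvalues: np.ndarray  # descending
    variance_explained: np.ndarray  # fractions summing to 1
    n_retained: int
    index_series: pd.DataFrame  # columns pc1..pcN over months

    def variable_pc_correlations(self) -> np.ndarray:
        """Loadings scaled to variable-PC correlations (loading * sqrt(ev))."""
        return self.loadings * np.sqrt(np.maximum(self.eigenvalues, 0.0))


def province_pca(panel: AnomalyPanel) -> tuple[np.ndarray, np.ndarray]:
    """Correlation-matrix PCA of a panel.

    Returns (loadings, eigenvalues) with eigenvalues descending and each
    eigenvector's sign fixed so its largest-|loading| variable loads
    positively.  Eigenvalues sum to the number of variables.
    """
    n, p = panel.data.shape
    if n < p:
        raise ValueError(f"panel has {n} individuals for {p} variables")
    corr = (panel.data.T @ panel.data) / n  # data is z-scored, ddof=0
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    for j in range(p):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    return evecs, evals


def retain_pcs(eigenvalues: np.ndarray, strict: bool = False) -> int:
    """Number of leading eigenvalues >= 1 (or > 1 when strict).

    At least one component is always retained.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if np.any(np.diff(ev) > 1e-9):
        raise ValueError("eigenvalues must be descending")
    count = int(np.sum(ev > 1.0 if strict else ev >= 1.0))
    return max(count, 1)


def index_series(panel: AnomalyPanel, loadings: np.ndarray,
                 pc: int) -> pd.Series:
    """Monthly synthetic index: per-month mean of PC scores over pixels.

    ``pc`` is zero-based.  Months with no surviving individuals are
    missing.
    """
    scores = panel.data @ loadings[:, pc]
    n_t = len(panel.months)
    sums = np.bincount(panel.month_index, weights=scores, minlength=n_t)
    counts = np.bincount(panel.month_index, minlength=n_t)
    with np.errstate(invalid="ignore", divide="ignore"):
        series = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.Series(series, index=panel.months, name=f"pc{pc + 1}")


def make_province_index(panel: AnomalyPanel,
                        strict_retention: bool = False) -> ProvinceIndex:
    """Full PCA-and-index pipeline for one province's panel."""
    loadings, evals = province_pca(panel)
    n_keep = retain_pcs(evals, strict=strict_retention)
    cols = {f"pc{j + 1}": index_series(panel, loadings, j)
            for j in range(n_keep)}
    frame = pd.DataFrame(cols)
    return ProvinceIndex(panel.province, panel.variables, loadings, evals,
                         evals / evals.sum(), n_keep, frame)


def power_spectrum(series: pd.Series, method: str = "periodogram",
                   nperseg: int | None = None) -> pd.DataFrame:
    """Spectrum of a monthly index with a white-noise 95% level.

    Returns a frame with columns (frequency, power, level95); frequency
    in cycles/month.  Gaps under 10% are linearly interpolated.  The 95%
    level is the chi-squared (2 dof) upper quantile of periodogram
    ordinates under a white-noise null with the series' variance.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 24:
        raise ValueError("power_spectrum needs >= 24 samples")
    bad = ~np.isfinite(x)
    if bad.mean() >= 0.10:
        raise ValueError("more than 10% of the series is missing")
    if bad.any():
        x = pd.Series(x).interpolate(limit_direction="both").to_numpy()
    x = x - x.mean()
    var = x.var(ddof=0)
    if var < 1e-30:
        warnings.warn("constant series: flat zero spectrum", stacklevel=2)
    if method == "periodogram":
        freqs, pxx = signal.periodogram(x, fs=1.0, detrend=False)
    elif method == "welch":
        freqs, pxx = signal.welch(x, fs=1.0, detrend=False,
                                  nperseg=nperseg or min(x.size, 256))
    else:
        raise ValueError(f"unknown spectral method: {method!r}")
    # white-noise null: one-sided density 2*var per unit frequency band,
    # ordinates ~ (mean level) * chi2_2 / 2
    mean_level = 2.0 * var
    level95 = mean_level * stats.chi2.ppf(0.95, 2) / 2.0
    out = pd.DataFrame({"frequency": freqs, "power": pxx})
    out["level95"] = level95
    return out.iloc[1:].reset_index(drop=True)  # drop the DC ordinate


def lagged_correlation(index: pd.Series, climate: pd.Series,
                       max_lag: int = 12) -> pd.DataFrame:
    """Pearson r of index(t) vs climate(t - lag) for lag = 0..max_lag.

    Series are aligned on their monthly index.  Rows with under 24
    overlapping months are omitted.  p-values are two-sided and not
    corrected for multiple testing.
    """
    idx = index.dropna()
    cli = climate.dropna()
    rows = []
    for lag in range(max_lag + 1):
        shifted = cli.copy()
        shifted.index = shifted.index + pd.DateOffset(months=lag)
        joined = pd.concat([idx, shifted], axis=1, join="inner").dropna()
        if len(joined) < 24:
            continue
        r, p = stats.pearsonr(joined.iloc[:, 0], joined.iloc[:, 1])
        rows.append((lag, float(r), float(p), len(joined)))
    return pd.DataFrame(rows, columns=["lag", "r", "p", "n"])


def significant_loadings(correlations: np.ndarray,
                         cutoff: float = 0.5) -> np.ndarray:
    """Flag variable-PC correlations with |r| strictly above the cutoff."""
    return np.abs(np.asarray(correlations, dtype=float)) > cutoff
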