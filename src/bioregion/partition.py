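"""Multivariate partitioning of the ocean into subprovinces.

Assembles "classical" (SST, chl, bathymetry), "mesoscale" (FSLE, OW,
EKE, SST fronts, chl fronts) or "full" feature stacks from co-registered
fields, selects the cluster count k by a bootstrapped explained-sum-of-
squares threshold rule, partitions with k-means, and quantifies the
temporal stability of the resulting boundaries across monthly
repartitions.

The k-selection statistic is the between-cluster sum of squares divided
by the total sum of squares ("explained SS").  Cells are resampled with
replacement across bootstrap replicates; the per-k curve statistic is
the median.  The optimal k at a threshold is the largest k whose
explained-SS increment over k-1 is at least the threshold, read in
absolute percentage points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .gridio import Grid, ScalarField, nanmean_quiet

CLASSICAL_LAYERS = ("sst", "chl", "bathymetry")
MESOSCALE_LAYERS = ("fsle", "okubo_weiss", "eke", "sst_front", "chl_front")
ARRAY_LAYERS = {
    "classical": CLASSICAL_LAYERS,
    "mesoscale": MESOSCALE_LAYERS,
    "full": CLASSICAL_LAYERS + MESOSCALE_LAYERS,
}


@dataclass
class FeatureStack:
    """Scaled per-cell feature matrix ready for clustering.

    ``data`` is (n_cells, n_layers) with every layer z-scored over the
    included cells; ``cell_index`` maps rows back to flat grid indices.
    """

    data: np.ndarray
    layer_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    cell_index: np.ndarray
    grid: Grid
    array_kind: str
    n_excluded: int = 0

    @property
    def n_cells(self) -> int:
        return self.data.shape[0]

    def labels_to_grid(self, labels: np.ndarray) -> np.ndarray:
        """Scatter per-row labels back onto the grid (NaN elsewhere)."""
        out = np.full(self.grid.shape, np.nan)
        out.ravel()[self.cell_index] = labels
        return out


def build_stack(features: dict[str, ScalarField], array_kind: str = "full",
                mode: str = "time_mean",
                month: pd.Timestamp | str | None = None) -> FeatureStack:
    """Assemble and z-score a feature stack.

    ``mode='time_mean'`` averages each field over time per cell;
    ``mode='single_month'`` takes the layer at ``month``.  Cells missing
    any layer are excluded (their count is recorded on the stack).
    """
    if array_kind not in ARRAY_LAYERS:
        raise ValueError(f"unknown array_kind: {array_kind!r}")
    names = ARRAY_LAYERS[array_kind]
    missing = [n for n in names if n not in features]
    if missing:
        raise ValueError(f"missing required layer(s) for {array_kind!r} "
                         f"array: {missing}")
    grid = features[names[0]].grid
    cols = []
    for n in names:
        f = features[n]
        if not f.grid.same_geometry(grid):
            raise ValueError(f"layer {n!r} is not co-registered")
        if mode == "time_mean":
            layer = f.time_mean().values
        elif mode == "single_month":
            if f.times is None:
                layer = f.values
            else:
                if month is None:
                    raise ValueError("single_month mode needs a month")
                per = pd.Timestamp(month).to_period("M")
                sel = f.times.to_period("M") == per
                if not sel.any():
                    raise ValueError(f"month {month} absent from {n!r}")
                layer = nanmean_quiet(f.values[sel], axis=0)
        else:
            raise ValueError(f"unknown mode: {mode!r}")
        cols.append(layer.ravel())
    mat = np.column_stack(cols)
    ocean_flat = grid.ocean.ravel()
    complete = ocean_flat & np.all(np.isfinite(mat), axis=1)
    n_excluded = int(ocean_flat.sum() - complete.sum())
    data = mat[complete]
    means = data.mean(axis=0)
    sds = data.std(axis=0, ddof=0)
    zero = sds < 1e-12 * np.maximum(np.abs(data).max(axis=0), 1e-300)
    if zero.any():
        bad = [names[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"layer(s) constant over included cells, cannot "
                         f"scale: {bad}")
    data = (data - means) / sds
    return FeatureStack(data, tuple(names), means, sds,
                        np.flatnonzero(complete), grid, array_kind,
                        n_excluded)


@dataclass
class PartitionResult:
    """Outcome of one k-means partition."""

    k: int
    labels: np.ndarray  # per included cell, 1..k, descending cluster size
    within_ss: float
    between_ss: float
    total_ss: float
    seed: int

    @property
    def explained_ss(self) -> float:
        return self.between_ss / self.total_ss if self.total_ss > 0 else 0.0


def _canonical_labels(raw: np.ndarray, k: int) -> np.ndarray:
    """Relabel clusters 1..k by descending size (ties by first index)."""
    sizes = np.bincount(raw, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    return remap[raw]


def kmeans_fit(stack: FeatureStack | np.ndarray, k: int,
               n_restarts: int = 10, seed: int = 0) -> PartitionResult:
    """k-means partition of a stack, best of ``n_restarts`` by within-SS.

    Uses k-means++ initialization; deterministic given ``seed``.  Labels
    are relabeled canonically by descending cluster size.
    """
    data = stack.data if isinstance(stack, FeatureStack) else np.asarray(stack)
    n = data.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of cells {n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    total_ss = float(((data - data.mean(axis=0)) ** 2).sum())
    if k == 1:
        labels = np.ones(n, dtype=int)
        return PartitionResult(1, labels, total_ss, 0.0, total_ss, seed)
    n_distinct = np.unique(data, axis=0).shape[0]
    if k >= n_distinct:
        # every distinct point its own cluster: zero within-SS
        _, raw = np.unique(data, axis=0, return_inverse=True)
        labels = _canonical_labels(raw, n_distinct)
        return PartitionResult(k, labels, 0.0, total_ss, total_ss, seed)
    km = KMeans(n_clusters=k, n_init=n_restarts, max_iter=300,
                random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = km.fit_predict(data)
    within = float(km.inertia_)
    labels = _canonical_labels(raw, k)
    return PartitionResult(k, labels, within, total_ss - within, total_ss,
                           seed)


def explained_ss_curve(stack: FeatureStack | np.ndarray,
                       k_range: range | tuple[int, int] = (2, 30),
                       n_boot: int = 1000, seed: int = 0,
                       n_restarts: int = 5) -> pd.DataFrame:
    """Bootstrap the explained-SS curve over a contiguous k range.

    Each replicate resamples cells with replacement and fits k-means for
    every k; returns a tidy frame with columns (k, replicate,
    explained_ss).  ``n_restarts`` is lower than for final fits since
    only the curve's medians enter k selection.
    """
    data = stack.data if isinstance(stack, FeatureStack) else np.asarray(stack)
    ks = (list(k_range) if isinstance(k_range, range)
          else list(range(k_range[0], k_range[1] + 1)))
    if not ks or max(ks) >= data.shape[0]:
        raise ValueError("k_max must be smaller than the number of cells")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    n = data.shape[0]
    for rep in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = data[idx]
        rep_seed = int(rng.integers(0, 2 ** 31 - 1))
        for k in ks:
            res = kmeans_fit(sample, k, n_restarts=n_restarts, seed=rep_seed)
            rows.append((k, rep, res.explained_ss))
    return pd.DataFrame(rows, columns=["k", "replicate", "explained_ss"])


def select_k(curve: pd.DataFrame, threshold: float = 0.05) -> int:
    """Optimal k from a bootstrapped explained-SS curve.

    Using the per-k median explained SS, the optimal k is the largest k
    whose increment over k-1 is at least ``threshold`` (increments in
    absolute fractions of explained SS; 0.05 means five percentage
    points).  The first k of the range counts its increment from an
    explained SS of zero, so a range starting at 2 can select k=2.
    Warns and returns the smallest k when no increment ever reaches the
    threshold.
    """
    med = curve.groupby("k")["explained_ss"].median().sort_index()
    ks = med.index.to_numpy()
    if np.any(np.diff(ks) != 1):
        raise ValueError("k range must be contiguous")
    inc = np.diff(np.concatenate([[0.0], med.to_numpy()]))
    passing = np.flatnonzero(inc >= threshold)
    if passing.size == 0:
        warnings.warn("no explained-SS increment reached the threshold; "
                      "returning the smallest k", stacklevel=2)
        return int(ks[0])
    return int(ks[passing[-1]])


def boundary_mask(labels: np.ndarray, grid: Grid,
                  connectivity: int = 4) -> np.ndarray:
    """True where a cell has an ocean neighbor with a different label.

    ``labels`` is an (n_lat, n_lon) float array with NaN on land or
    excluded cells.  Land and excluded neighbors never create
    boundaries.  The result is invariant to permuting label values.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    lab = np.asarray(labels, dtype=float)
    valid = np.isfinite(lab)
    out = np.zeros(lab.shape, dtype=bool)
    shifts = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        shifts += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    for dy, dx in shifts:
        a = np.full(lab.shape, np.nan)
        ys = slice(max(dy, 0), lab.shape[0] + min(dy, 0))
        yt = slice(max(-dy, 0), lab.shape[0] + min(-dy, 0))
        xs = slice(max(dx, 0), lab.shape[1] + min(dx, 0))
        xt = slice(max(-dx, 0), lab.shape[1] + min(-dx, 0))
        a[yt, xt] = lab[ys, xs]
        differs = valid & np.isfinite(a) & (a != lab)
        out |= differs
    out &= valid
    return out


@dataclass
class StabilityMap:
    """Percentage of months each cell sits on a cluster boundary."""

    percentage: np.ndarray  # (n_lat, n_lon), NaN where never included
    n_months: int
    grid: Grid


def stability_from_labels(label_grids: list[np.ndarray], grid: Grid,
                          connectivity: int = 4) -> StabilityMap:
    """Boundary-stability map from precomputed monthly label grids.

    A cell's stability is the percentage of months in which it lies on a
    cluster boundary; the denominator counts only the months where the
    cell carries a label.  Cells labeled in no month are missing.
    """
    if len(label_grids) < 2:
        raise ValueError("stability needs at least 2 monthly partitions")
    hits = np.zeros(grid.shape)
    counts = np.zeros(grid.shape)
    for lab_grid in label_grids:
        mask = boundary_mask(lab_grid, grid, connectivity)
        included = np.isfinite(lab_grid)
        hits[mask] += 1
        counts[included] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(counts > 0, 100.0 * hits / counts, np.nan)
    return StabilityMap(pct, len(label_grids), grid)


def stability(monthly_stacks: list[FeatureStack], k: int,
              connectivity: int = 4, seed: int = 0,
              n_restarts: int = 10) -> StabilityMap:
    """Boundary stability across monthly repartitions at fixed k.

    Each month's stack is clustered independently (its own z-scoring and
    its own k-means run); a cell's stability is the percentage of months
    in which it lies on a boundary.  Label matching across months is
    unnecessary because boundaries are label-permutation invariant.
    """
    if len(monthly_stacks) < 2:
        raise ValueError("stability needs at least 2 monthly stacks")
    grid = monthly_stacks[0].grid
    rng = np.random.default_rng(seed)
    label_grids = []
    for stack in monthly_stacks:
        month_seed = int(rng.integers(0, 2 ** 31 - 1))
        res = kmeans_fit(stack, k, n_restarts=n_restarts, seed=month_seed)
        label_grids.append(stack.labels_to_grid(res.labels))
    return stability_from_labels(label_grids, grid, connectivity)
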