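"""End-to-end orchestration of the bioregionalization pipeline.

Stages: simulate a synthetic scene (or load fields), derive mesoscale
features, regionalize with bootstrap-selected k, map boundary
stability, and extract per-province PCA indices.  Every stage consumes
and produces :class:`~bioregion.gridio.ScalarField` objects so synthetic
and real inputs are indistinguishable downstream.

Each stochastic stage draws its seed deterministically from one master
seed, making a full run bit-reproducible.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import gridio, indices, mesofeatures, partition, synthgen
from .gridio import ScalarField, VelocityField
from .mesofeatures import FsleParams
from .synthgen import SceneSpec


@dataclass
class RunConfig:
    """Configuration of a pipeline run (YAML-serializable)."""

    scene: SceneSpec = dc_field(default_factory=SceneSpec)
    array_kind: str = "full"
    fsle: FsleParams = dc_field(default_factory=lambda: FsleParams(
        delta0=0.02, deltaf=0.3, tau_max=80.0, integration_step=0.5))
    fsle_snapshots_per_month: int = 1
    k_min: int = 2
    k_max: int = 10
    n_boot: int = 50
    thresholds: tuple[float, ...] = (0.01, 0.05)
    connectivity: int = 4
    strict_retention: bool = False
    chl_front_log: bool = True  # natural log of the chl gradient field
    chl_front_log_offset: float = 1e-3  # gradient units, guards ln(0)
    seed: int = 0
    n_restarts: int = 10

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        h = np.uint32(self.seed)
        for ch in stage:
            h = np.uint32((int(h) * 31 + ord(ch)) % (2 ** 31 - 1))
        return int(h)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "scene" in kwargs:
            sc = dict(kwargs["scene"])
            for key, klass in (("vortices", synthgen.VortexSpec),
                               ("strains", synthgen.StrainSpec)):
                if key in sc:
                    sc[key] = tuple(klass(**d) for d in sc[key])
            for key in ("sst_means", "chl_means", "depth_means",
                        "uniform_background"):
                if key in sc:
                    sc[key] = tuple(sc[key])
            kwargs["scene"] = SceneSpec(**sc)
        if "fsle" in kwargs:
            kwargs["fsle"] = FsleParams(**kwargs["fsle"])
        if "thresholds" in kwargs:
            kwargs["thresholds"] = tuple(kwargs["thresholds"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = list(self.thresholds)
        return d


def simulate(config: RunConfig) -> tuple[
        dict[str, ScalarField], VelocityField, synthgen.SyntheticTruth]:
    """Generate the scene's scalar fields, velocity field, and truth."""
    fields, truth = synthgen.make_province_scene(config.scene)
    velocity = synthgen.make_velocity_series(config.scene, "composite")
    return fields, velocity, truth


def derive_features(fields: dict[str, ScalarField],
                    velocity: VelocityField,
                    config: RunConfig) -> dict[str, ScalarField]:
    """Compute the eight feature layers the partition stage clusters.

    Classical: SST, log-chl, log-depth bathymetry.  Mesoscale: FSLE, OW,
    EKE, SST fronts, chl fronts (optionally log(1+x)-compressed).  A
    steady velocity field yields time-invariant mesoscale layers, which
    are computed once.
    """
    out: dict[str, ScalarField] = {}
    out["sst"] = fields["sst"]
    out["chl"] = gridio.log_transform(fields["chl"], offset=0.0)
    out["bathymetry"] = gridio.log_depth(fields["bathymetry"])

    sst_front = mesofeatures.frontal_gradient(fields["sst"])
    chl_front = mesofeatures.frontal_gradient(fields["chl"])
    if config.chl_front_log:
        chl_front = gridio.log_transform(chl_front,
                                         config.chl_front_log_offset)
    out["sst_front"] = sst_front
    out["chl_front"] = chl_front

    eke_field = mesofeatures.eke(velocity)
    ow_field = mesofeatures.okubo_weiss(velocity)
    if velocity.times is None:
        out["eke"] = eke_field
        out["okubo_weiss"] = ow_field
        out["fsle"] = mesofeatures.fsle(velocity, config.fsle)
    else:
        # weekly diagnostics averaged into calendar-month layers
        out["eke"] = gridio.monthly_mean(eke_field)
        out["okubo_weiss"] = gridio.monthly_mean(ow_field)
        # FSLE snapshots integrated through the time-varying field;
        # months earlier than tau_max persist the first weekly layer
        snaps, times = [], []
        periods = velocity.times.to_period("M").unique().sort_values()
        for per in periods:
            for j in range(config.fsle_snapshots_per_month):
                frac = (j + 1) / (config.fsle_snapshots_per_month + 1)
                snap_t = per.to_timestamp() + pd.Timedelta(
                    days=frac * per.days_in_month)
                lam = mesofeatures.fsle(velocity, config.fsle, snap_t,
                                        allow_partial_history=True)
                snaps.append(lam.values)
                times.append(snap_t)
        snap_field = ScalarField(velocity.grid, np.stack(snaps),
                                 pd.DatetimeIndex(times), "fsle", "1/day")
        out["fsle"] = gridio.monthly_mean(snap_field)
    return out


@dataclass
class RegionalizationResult:
    """Chosen k per threshold and the partitions at those k."""

    curve: pd.DataFrame
    selected_k: dict[float, int]
    partitions: dict[float, partition.PartitionResult]
    stack: partition.FeatureStack

    def labels_grid(self, threshold: float) -> np.ndarray:
        return self.stack.labels_to_grid(
            self.partitions[threshold].labels)


def regionalize(features: dict[str, ScalarField],
                config: RunConfig) -> RegionalizationResult:
    """Select k by the bootstrap threshold rule and partition the stack."""
    stack = partition.build_stack(features, config.array_kind, "time_mean")
    curve = partition.explained_ss_curve(
        stack, (config.k_min, config.k_max), config.n_boot,
        seed=config.stage_seed("bootstrap"))
    selected, parts = {}, {}
    for thr in config.thresholds:
        k = partition.select_k(curve, thr)
        selected[thr] = k
        parts[thr] = partition.kmeans_fit(
            stack, k, n_restarts=config.n_restarts,
            seed=config.stage_seed("kmeans"))
    return RegionalizationResult(curve, selected, parts, stack)


def monthly_stability(features: dict[str, ScalarField], k: int,
                      config: RunConfig) -> partition.StabilityMap:
    """Repartition every month at fixed k and map boundary stability."""
    times = None
    for f in features.values():
        if f.times is not None:
            times = f.times
            break
    if times is None:
        raise ValueError("stability needs time-varying features")
    stacks = [partition.build_stack(features, config.array_kind,
                                    "single_month", month=t)
              for t in times]
    return partition.stability(stacks, k, config.connectivity,
                               seed=config.stage_seed("stability"))


def province_indices(features: dict[str, ScalarField],
                     labels_grid: np.ndarray,
                     config: RunConfig) -> dict[int, indices.ProvinceIndex]:
    """Deseasonalize the seven time-varying layers and run per-province PCA."""
    anomalies: dict[str, ScalarField] = {}
    for name in indices.PCA_VARIABLES:
        f = features[name]
        anomalies[name] = (indices.deseasonalize(f)
                           if f.times is not None else f)
    provinces = np.unique(labels_grid[np.isfinite(labels_grid)]).astype(int)
    out = {}
    for p in provinces:
        panel = indices.build_panel(anomalies, labels_grid, p)
        out[int(p)] = indices.make_province_index(
            panel, strict_retention=config.strict_retention)
    return out


@dataclass
class PipelineResult:
    """Everything a full run produces, for programmatic use."""

    config: RunConfig
    truth: synthgen.SyntheticTruth | None
    features: dict[str, ScalarField]
    regionalization: RegionalizationResult
    stability: partition.StabilityMap
    indices: dict[int, indices.ProvinceIndex]


def run_all(config: RunConfig | None = None) -> PipelineResult:
    """Simulate, derive features, regionalize, stability, indices."""
    config = config or RunConfig()
    fields, velocity, truth = simulate(config)
    features = derive_features(fields, velocity, config)
    region = regionalize(features, config)
    thr = max(config.thresholds)  # the coarser partition, as the headline map
    k5 = region.selected_k[thr]
    stab = monthly_stability(features, k5, config)
    labels = region.labels_grid(thr)
    prov = province_indices(features, labels, config)
    return PipelineResult(config, truth, features, region, stab, prov)


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    """Persist a run: NetCDF label/stability maps, CSV curves and indices."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = result.regionalization.stack.grid
    for thr, part in result.regionalization.partitions.items():
        lab = result.regionalization.stack.labels_to_grid(part.labels)
        pct = int(round(thr * 100))
        gridio.write_field(ScalarField(grid, lab, None,
                                       f"labels_{pct}pct", "province id"),
                           out / f"labels_{pct}pct.nc")
    gridio.write_field(ScalarField(grid, result.stability.percentage, None,
                                   "boundary_stability", "%"),
                       out / "stability.nc")
    result.regionalization.curve.to_csv(out / "explained_ss_curve.csv",
                                        index=False)
    rows = []
    for p, pi in result.indices.items():
        frame = pi.index_series.copy()
        frame.insert(0, "month", frame.index.strftime("%Y-%m"))
        frame.insert(0, "province", p)
        rows.append(frame)
    if rows:
        pd.concat(rows).to_csv(out / "province_indices.csv", index=False)
    manifest = {
        "config": result.config.to_dict(),
        "selected_k": {str(t): k for t, k in
                       result.regionalization.selected_k.items()},
        "retained_pcs": {str(p): pi.n_retained
                         for p, pi in result.indices.items()},
        "n_excluded_cells": result.regionalization.stack.n_excluded,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
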