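"""Scenario projection with clamping and mobility-oriented parity (MOP).

Projection evaluates a fitted model on a scenario predictor stack; with
clamping, each variable is clipped to its calibration range before
feature evaluation, so predictions beyond the sampled environment never
leave the calibration response surface.  MOP quantifies environmental
novelty: scenario cells with any variable outside its calibration range
are "strict extrapolation"; elsewhere similarity is one minus the
normalized mean distance (in standardized variable space) to the nearest
fraction of calibration cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .maxent import MaxEntModel, ReplicateSet
from .raster import RasterLayer, RasterStack


def project(model: MaxEntModel | ReplicateSet, scenario: RasterStack,
            clamp: bool = True) -> RasterLayer:
    """Cloglog suitability of a scenario stack (mean over replicates).

    The scenario must provide every model variable on the model's grid;
    nodata anywhere in the scenario propagates to the output.
    """
    ref = model.models[0] if isinstance(model, ReplicateSet) else model
    missing = [v for v in ref.variables if v not in scenario.names]
    if missing:
        raise KeyError(f"scenario stack missing model variables: {missing}")
    sub = scenario.subset(ref.variables)
    rows, cols = sub.data_cells()
    env = sub.env_table(rows, cols)
    if isinstance(model, ReplicateSet):
        pred, _ = model.cloglog_stats(env, clamp=clamp)
    else:
        pred = model.cloglog(env, clamp=clamp)
    grid = scenario.grid
    values = np.zeros(grid.shape)
    mask = np.ones(grid.shape, dtype=bool)
    values[rows, cols] = pred
    mask[rows, cols] = False
    return RasterLayer(grid, values, mask, name="suitability")


def project_sd(reps: ReplicateSet, scenario: RasterStack, clamp: bool = True
               ) -> RasterLayer:
    """Per-cell standard deviation of the replicate cloglog predictions."""
    sub = scenario.subset(reps.models[0].variables)
    rows, cols = sub.data_cells()
    _, sd = reps.cloglog_stats(sub.env_table(rows, cols), clamp=clamp)
    grid = scenario.grid
    values = np.zeros(grid.shape)
    mask = np.ones(grid.shape, dtype=bool)
    values[rows, cols] = sd
    mask[rows, cols] = False
    return RasterLayer(grid, values, mask, name="suitability_sd")


@dataclass
class MOPMap:
    similarity: RasterLayer
    strict_mask: RasterLayer   # 1 where strict extrapolation


def mop(calibration_stack: RasterStack, scenario: RasterStack,
        subset_frac: float = 0.10, sample_cap: int = 10000,
        seed: int | None = None) -> MOPMap:
    """Mobility-oriented parity of a scenario against the calibration domain.

    Variables are standardized by their calibration mean/sd.  A scenario
    cell is strict extrapolation when any variable leaves its calibration
    min–max; otherwise similarity = 1 − d/d_max, with d the mean Euclidean
    distance to the nearest ⌈subset_frac·n_ref⌉ calibration cells
    (reference cells subsampled to ``sample_cap``) and d_max the largest
    such distance over non-strict cells.
    """
    names = calibration_stack.names
    if set(names) - set(scenario.names):
        raise ValueError("scenario lacks calibration variables")
    cal_rows, cal_cols = calibration_stack.data_cells()
    if len(cal_rows) == 0:
        raise ValueError("calibration stack has no data cells")
    cal = calibration_stack.env_table(cal_rows, cal_cols)
    scen_stack = scenario.subset(names)
    sc_rows, sc_cols = scen_stack.data_cells()
    scen = scen_stack.env_table(sc_rows, sc_cols)

    mins, maxs = cal.min(), cal.max()
    mean, sd = cal.mean(), cal.std().replace(0.0, 1.0)
    strict = np.zeros(len(scen), dtype=bool)
    for v in names:
        strict |= (scen[v] < mins[v]).to_numpy() | (scen[v] > maxs[v]).to_numpy()

    cal_z = ((cal - mean) / sd).to_numpy()
    scen_z = ((scen - mean) / sd).to_numpy()
    rng = np.random.default_rng(seed)
    if len(cal_z) > sample_cap:
        take = rng.choice(len(cal_z), size=sample_cap, replace=False)
        cal_z = cal_z[take]
    k = max(1, int(np.ceil(subset_frac * len(cal_z))))
    sim = np.zeros(len(scen))
    idx = ~strict
    if idx.any():
        tree = cKDTree(cal_z)
        d, _ = tree.query(scen_z[idx], k=k, workers=-1)
        mean_d = d.mean(axis=1) if k > 1 else np.asarray(d, float)
        d_max = mean_d.max()
        sim[idx] = 1.0 - mean_d / d_max if d_max > 0 else 1.0

    grid = scenario.grid
    sim_vals = np.zeros(grid.shape)
    strict_vals = np.zeros(grid.shape)
    mask = np.ones(grid.shape, dtype=bool)
    sim_vals[sc_rows, sc_cols] = sim
    strict_vals[sc_rows, sc_cols] = strict.astype(float)
    mask[sc_rows, sc_cols] = False
    return MOPMap(RasterLayer(grid, sim_vals, mask, "mop_similarity"),
                  RasterLayer(grid, strict_vals, mask, "mop_strict"))
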