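"""Seeded synthetic landscapes with known truth for end-to-end testing.

Predictor fields are spatially autocorrelated Gaussian random fields
(low-pass-filtered white noise, standardized to zero mean / unit sd).
The true suitability surface is a logistic in two active variables with a
negative quadratic term on the second (a unimodal niche axis); the
remaining variables are inert noise, giving variable-importance and
pruning steps known winners and losers.  Future scenarios translate
and/or trend the active fields, so the true range shift is known by
construction.  Protected-area polygons are random rectangles grown until
they cover a requested fraction of the suitable area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import box

from .changes import BinaryMap, mpa_overlap
from .raster import (CellAreaLayer, Grid, RasterLayer, RasterStack,
                     RegionPolygons, cell_areas)


@dataclass
class LandscapeConfig:
    """Defaults give an ~10°×10° marine-scale grid at 0.05° resolution."""

    n_rows: int = 200
    n_cols: int = 200
    cell_size: float = 0.05
    origin_lon: float = 130.0
    origin_lat: float = 5.0      # near-equatorial: 1° lon ≈ 111 km everywhere
    n_vars: int = 5
    smoothness: float = 8.0      # gaussian-filter sigma, in cells
    structure_weight: float = 0.85  # large-scale envelope share of the first active field
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vars < 2:
            raise ValueError("need at least 2 variables")
        if self.smoothness <= 0:
            raise ValueError("smoothness must be positive")

    @property
    def grid(self) -> Grid:
        return Grid(self.origin_lon, self.origin_lat, self.cell_size,
                    self.n_rows, self.n_cols)


@dataclass
class TruthModel:
    """True suitability s = logistic(b0 + b1·v1 + b2·v2 + c2·v2²), c2 < 0."""

    active: tuple[int, int] = (0, 1)
    b0: float = -2.0
    b1: float = 2.0
    b2: float = 1.2
    c2: float = -2.0

    def __post_init__(self) -> None:
        if self.c2 >= 0:
            raise ValueError("quadratic coefficient must be negative (unimodal niche)")

    @property
    def optimum_v2(self) -> float:
        return -self.b2 / (2 * self.c2)


@dataclass
class ScenarioConfig:
    """Translation (degrees lon/lat) and additive trends on active fields."""

    d_lon: float = 1.0
    d_lat: float = 0.0
    trend: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_lon == 0 and self.d_lat == 0 and not any(self.trend.values()):
            raise ValueError("scenario must perturb something")


def make_landscape(cfg: LandscapeConfig) -> tuple[RasterStack, TruthModel]:
    """Generate standardized autocorrelated predictor fields plus the truth.

    Every field is low-pass-filtered seeded noise.  The first active
    field is dominated by a compact large-scale component (a smooth
    super-Gaussian plateau centered on the grid), emulating the
    large-scale structure of real climatological layers; it keeps the
    suitable habitat compact and well inside the grid for every
    realization, so that a scenario translation moves the true range by
    the stated offset rather than sliding a statistically uniform
    pattern onto itself or clipping habitat at the grid boundary.
    """
    rng = np.random.default_rng(cfg.seed)
    truth = TruthModel()
    yy, xx = np.meshgrid(np.linspace(-1, 1, cfg.n_rows),
                         np.linspace(-1, 1, cfg.n_cols), indexing="ij")
    r2 = xx ** 2 + yy ** 2
    bump = np.exp(-(r2 / 0.55 ** 2) ** 2)   # flat-topped, steep shoulders
    bump = (bump - bump.mean()) / bump.std()
    layers = []
    for i in range(cfg.n_vars):
        noise = rng.standard_normal((cfg.n_rows, cfg.n_cols))
        fieldv = gaussian_filter(noise, sigma=cfg.smoothness, mode="reflect")
        fieldv = (fieldv - fieldv.mean()) / fieldv.std()
        if i == truth.active[0]:
            fieldv = cfg.structure_weight * bump + (1 - cfg.structure_weight) * fieldv
            fieldv = (fieldv - fieldv.mean()) / fieldv.std()
        layers.append(RasterLayer(cfg.grid, fieldv,
                                  np.zeros((cfg.n_rows, cfg.n_cols), bool),
                                  name=f"var{i + 1}"))
    return RasterStack(layers), truth


def true_suitability(truth: TruthModel, stack: RasterStack) -> RasterLayer:
    """Closed-form evaluation of the truth surface on a stack."""
    i1, i2 = truth.active
    v1 = stack.layers[i1].values
    v2 = stack.layers[i2].values
    eta = truth.b0 + truth.b1 * v1 + truth.b2 * v2 + truth.c2 * v2 ** 2
    s = 1.0 / (1.0 + np.exp(-eta))
    return RasterLayer(stack.grid, s, stack.combined_mask.copy(), name="truth")


def sample_occurrences(truth_raster: RasterLayer, n: int,
                       bias_raster: RasterLayer | None = None,
                       seed: int | None = None) -> pd.DataFrame:
    """Draw presence records with cell probability ∝ suitability × bias.

    Coordinates are jittered uniformly within the sampled cell; records
    carry a ``year`` (2010–2020) and a ``basis`` label so the cleaning
    filters have realistic inputs.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    w = np.where(truth_raster.nodata_mask, 0.0, truth_raster.values).ravel()
    if bias_raster is not None:
        w = w * np.where(bias_raster.nodata_mask, 0.0, bias_raster.values).ravel()
    total = w.sum()
    if n > 0 and total <= 0:
        raise ValueError("all sampling weights are zero")
    grid = truth_raster.grid
    if n == 0:
        return pd.DataFrame(columns=["lon", "lat", "year", "basis"])
    idx = rng.choice(w.size, size=n, p=w / total)
    rows, cols = np.unravel_index(idx, grid.shape)
    lon = grid.origin_lon + (cols + rng.uniform(0, 1, n)) * grid.cell_size
    lat = grid.origin_lat - (rows + rng.uniform(0, 1, n)) * grid.cell_size
    return pd.DataFrame({
        "lon": lon, "lat": lat,
        "year": rng.integers(2010, 2021, size=n),
        "basis": rng.choice(["human_observation", "preserved_specimen"], size=n),
    })


def make_future(stack: RasterStack, scenario: ScenarioConfig,
                truth: TruthModel | None = None,
                static_vars: tuple[str, ...] = ()) -> RasterStack:
    """Translate/trend the active fields; copy static fields unchanged.

    Translation is by whole cells (the configured degrees are rounded to
    the grid resolution) with edge values held at the nearest interior
    value, so the true suitability pattern moves by the stated offset.
    """
    grid = stack.grid
    truth = truth or TruthModel()
    d_col = int(round(scenario.d_lon / grid.cell_size))
    d_row = int(round(-scenario.d_lat / grid.cell_size))
    if abs(d_col) >= grid.n_cols or abs(d_row) >= grid.n_rows:
        raise ValueError("translation exceeds the grid extent")
    active_names = {stack.layers[i].name for i in truth.active}
    out = []
    for layer in stack.layers:
        vals = layer.values
        if layer.name in active_names and layer.name not in static_vars:
            vals = _shift_field(vals, d_row, d_col)
        vals = vals + scenario.trend.get(layer.name, 0.0)
        out.append(RasterLayer(grid, vals, layer.nodata_mask.copy(), layer.name))
    return RasterStack(out)


def _shift_field(vals: np.ndarray, d_row: int, d_col: int) -> np.ndarray:
    """Integer-cell translation with nearest-edge padding.

    future(row, col) = present(row − d_row, col − d_col): a positive
    d_col moves the pattern east.
    """
    n_rows, n_cols = vals.shape
    src_r = np.clip(np.arange(n_rows) - d_row, 0, n_rows - 1)
    src_c = np.clip(np.arange(n_cols) - d_col, 0, n_cols - 1)
    return vals[np.ix_(src_r, src_c)]


def make_protected_areas(truth_binary: BinaryMap, coverage_frac: float,
                         seed: int | None = None, tol: float = 0.05,
                         max_attempts: int = 500) -> RegionPolygons:
    """Random rectangles until they cover ``coverage_frac`` of suitable area.

    Coverage is measured with the same center-in-polygon overlap rule the
    analysis uses; raises if the target band (± ``tol``) cannot be hit in
    ``max_attempts`` rectangle draws.
    """
    if not 0 < coverage_frac < 1:
        raise ValueError("coverage_frac must be in (0,1)")
    grid = truth_binary.layer.grid
    areas = cell_areas(grid)
    total = float(areas.area_km2[truth_binary.suitable].sum())
    if total == 0:
        raise ValueError("no suitable habitat to cover")
    rng = np.random.default_rng(seed)
    suit_rows, suit_cols = np.nonzero(truth_binary.suitable)
    lons = grid.lon_centers()[suit_cols]
    lats = grid.lat_centers()[suit_rows]
    rects: list = []
    for _ in range(max_attempts):
        i = rng.integers(len(lons))
        w = rng.uniform(2, 10) * grid.cell_size
        h = rng.uniform(2, 10) * grid.cell_size
        rects.append(box(lons[i] - w / 2, lats[i] - h / 2, lons[i] + w / 2, lats[i] + h / 2))
        region = RegionPolygons(rects)
        summ = mpa_overlap(truth_binary, region, areas, total)
        frac = summ.inside_km2 / total
        if frac > coverage_frac + tol:
            rects.pop()        # overshoot: discard and try a different rectangle
            continue
        if abs(frac - coverage_frac) <= tol:
            return RegionPolygons(rects, pd.DataFrame({
                "name": [f"mpa_{k}" for k in range(len(rects))]}))
    raise RuntimeError(f"could not reach coverage {coverage_frac} within "
                       f"{max_attempts} attempts")
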