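"""Occurrence-record cleaning, per-cell deduplication and spatial thinning.

Records arrive as a DataFrame with ``lon``/``lat`` columns and optional
``year`` and ``basis`` columns.  Cleaning applies, in a fixed (but
order-insensitive) sequence: a coordinate-presence filter, a minimum
collection-year filter, a range-polygon filter, and an optional land
(exclusion-polygon) filter.  Thinning then enforces a minimum pairwise
great-circle distance, mirroring the common occurrence-thinning heuristic:
repeatedly drop the record with the most neighbours closer than the
minimum distance (random, seeded tie-break), retrying several times and
keeping the largest surviving set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import EARTH_RADIUS_KM, Grid, RegionPolygons


@dataclass
class CleaningConfig:
    min_year: int = 1965
    range_polygons: RegionPolygons | None = None
    land_polygons: RegionPolygons | None = None
    require_date: bool = True

    def __post_init__(self) -> None:
        if self.min_year < 0:
            raise ValueError("min_year must be non-negative")


@dataclass
class ThinConfig:
    min_dist_km: float = 5.5
    n_attempts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_dist_km <= 0:
            raise ValueError("min_dist_km must be positive")
        if self.n_attempts < 1:
            raise ValueError("n_attempts must be >= 1")


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance on the authalic sphere, in km."""
    lon1, lat1, lon2, lat2 = map(np.radians, (np.asarray(lon1, float), np.asarray(lat1, float),
                                              np.asarray(lon2, float), np.asarray(lat2, float)))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def pairwise_distances_km(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    return haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])


def clean_occurrences(table: pd.DataFrame, cfg: CleaningConfig
                      ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the record-cleaning filters; return kept records and counts.

    The removal report attributes each dropped record to the first filter
    (in the order no-coordinates, pre-date, no-date, out-of-range, on-land)
    that rejects it; the retained set itself is filter-order independent
    because every filter is a pure per-record predicate.
    """
    if table.empty:
        raise ValueError("occurrence table is empty")
    df = table.reset_index(drop=True)
    n = len(df)
    lon = pd.to_numeric(df.get("lon"), errors="coerce")
    lat = pd.to_numeric(df.get("lat"), errors="coerce")
    has_coords = (lon.notna() & lat.notna()
                  & lon.between(-180, 180) & lat.between(-90, 90)).to_numpy()

    if "year" in df.columns:
        year = pd.to_numeric(df["year"], errors="coerce")
    else:
        year = pd.Series(np.nan, index=df.index)
    has_date = year.notna().to_numpy()
    pre_date = has_date & (year < cfg.min_year).to_numpy()
    no_date = ~has_date if cfg.require_date else np.zeros(n, dtype=bool)

    if cfg.range_polygons is not None:
        in_range = np.zeros(n, dtype=bool)
        in_range[has_coords] = cfg.range_polygons.contains_points(
            lon.to_numpy()[has_coords], lat.to_numpy()[has_coords])
    else:
        in_range = np.ones(n, dtype=bool)
    if cfg.land_polygons is not None:
        on_land = np.zeros(n, dtype=bool)
        on_land[has_coords] = cfg.land_polygons.contains_points(
            lon.to_numpy()[has_coords], lat.to_numpy()[has_coords])
    else:
        on_land = np.zeros(n, dtype=bool)

    keep = has_coords & ~pre_date & ~no_date & in_range & ~on_land
    reason = np.full(n, "", dtype=object)
    for name, bad in [("no_coords", ~has_coords), ("pre_date", pre_date),
                      ("no_date", no_date), ("out_of_range", ~in_range),
                      ("on_land", on_land)]:
        reason[(reason == "") & bad] = name
    report = {name: int((reason == name).sum())
              for name in ["no_coords", "pre_date", "no_date", "out_of_range", "on_land"]}
    report = {k: v for k, v in report.items() if v > 0}
    report["retained"] = int(keep.sum())
    return df[keep].reset_index(drop=True), report


def deduplicate(table: pd.DataFrame, grid: Grid) -> pd.DataFrame:
    """Keep at most one record per grid cell (the earliest-indexed one)."""
    if table.empty:
        return table.copy()
    row, col = grid.cell_index(table["lon"].to_numpy(), table["lat"].to_numpy())
    key = row.astype(np.int64) * (grid.n_cols + 1) + col
    first = pd.Series(np.arange(len(table))).groupby(key, sort=False).min().to_numpy()
    return table.iloc[np.sort(first)].reset_index(drop=True)


def thin(table: pd.DataFrame, cfg: ThinConfig) -> pd.DataFrame:
    """Enforce a minimum pairwise distance, keeping as many records as found.

    Runs the drop-most-crowded heuristic ``cfg.n_attempts`` times with a
    seeded RNG (random tie-breaks between equally crowded records) and
    returns the largest surviving set; deterministic given the seed.
    """
    n = len(table)
    if n <= 1:
        return table.reset_index(drop=True)
    lon = table["lon"].to_numpy(float)
    lat = table["lat"].to_numpy(float)
    dist = pairwise_distances_km(lon, lat)
    conflict = dist < cfg.min_dist_km
    np.fill_diagonal(conflict, False)

    rng = np.random.default_rng(cfg.seed)
    best: np.ndarray | None = None
    for _ in range(cfg.n_attempts):
        alive = np.ones(n, dtype=bool)
        counts = conflict.sum(axis=1).astype(float)
        while True:
            max_c = counts[alive].max() if alive.any() else 0
            if max_c == 0:
                break
            worst = np.flatnonzero(alive & (counts == max_c))
            victim = rng.choice(worst)
            alive[victim] = False
            counts[conflict[victim]] -= 1
            counts[victim] = 0
        if best is None or alive.sum() > best.sum():
            best = alive
    return table[best].reset_index(drop=True)
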