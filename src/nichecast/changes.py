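"""Binary range maps, change accounting, centroid shifts and MPA overlap.

Continuous suitability is binarized at the maximum training sensitivity
plus specificity (MTSS) threshold.  Current/future binary maps are
combined into a change map (never-suitable / lost / gained / maintained);
areas come from per-cell spherical areas and the published percentage
conventions are: category percentages relative to the CURRENT suitable
area, and total change = 100·(future − current)/current.  Centroid range
shifts report the WGS84 geodesic distance and initial bearing between
area-weighted centroids.  Protected-area overlap partitions suitable
cells by a center-in-polygon rule, with percentages again relative to the
current total suitable area.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .raster import CellAreaLayer, RasterLayer, RegionPolygons

# change-map codes
NEVER, LOST, GAINED, MAINTAINED = 0, 1, 2, 3

# WGS84 ellipsoid
_WGS84_A = 6378.137          # km
_WGS84_F = 1 / 298.257223563
_WGS84_B = _WGS84_A * (1 - _WGS84_F)


@dataclass
class ThresholdResult:
    threshold: float
    sensitivity: float
    specificity: float
    degenerate: bool = False


def mtss_threshold(presence_scores, background_scores) -> ThresholdResult:
    """Smallest threshold maximizing sensitivity + specificity.

    Candidate thresholds are the unique pooled scores; a cell is
    classified suitable when score ≥ t, so sensitivity is the presence
    fraction at or above t and specificity the background fraction below.
    """
    sp = np.asarray(list(presence_scores), float)
    sb = np.asarray(list(background_scores), float)
    if sp.size == 0 or sb.size == 0:
        raise ValueError("presence and background scores must be nonempty")
    cand = np.unique(np.concatenate([sp, sb]))
    sp_sorted = np.sort(sp)
    sb_sorted = np.sort(sb)
    sens_count = sp.size - np.searchsorted(sp_sorted, cand, side="left")
    spec_count = np.searchsorted(sb_sorted, cand, side="left")
    # maximize sens+spec in exact integer arithmetic (common denominator),
    # so ties are genuine ties and the first (smallest) maximizer wins
    total = sens_count * sb.size + spec_count * sp.size
    best = int(np.argmax(total))
    sens = sens_count / sp.size
    spec = spec_count / sb.size
    degenerate = cand.size == 1
    if degenerate:
        warnings.warn("all scores identical: degenerate MTSS threshold")
    return ThresholdResult(float(cand[best]), float(sens[best]),
                           float(spec[best]), degenerate)


@dataclass
class BinaryMap:
    layer: RasterLayer
    threshold: float

    @property
    def suitable(self) -> np.ndarray:
        """Boolean suitable-cell array (False on nodata)."""
        return (self.layer.values >= 0.5) & ~self.layer.nodata_mask


def binarize(suitability: RasterLayer, threshold: float) -> BinaryMap:
    """Suitable iff value ≥ threshold (equality counts as suitable)."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0,1]")
    vals = np.where(~suitability.nodata_mask,
                    (suitability.values >= threshold).astype(float), 0.0)
    return BinaryMap(RasterLayer(suitability.grid, vals, suitability.nodata_mask.copy(),
                                 name=f"{suitability.name}_binary"), threshold)


@dataclass
class ChangeMap:
    layer: RasterLayer   # codes NEVER/LOST/GAINED/MAINTAINED


def change_map(current: BinaryMap, future: BinaryMap) -> ChangeMap:
    if current.layer.grid != future.layer.grid:
        raise ValueError("current and future maps are on different grids")
    cur, fut = current.suitable, future.suitable
    codes = np.zeros(cur.shape, dtype=float)
    codes[cur & ~fut] = LOST
    codes[~cur & fut] = GAINED
    codes[cur & fut] = MAINTAINED
    mask = current.layer.nodata_mask | future.layer.nodata_mask
    codes[mask] = 0.0
    return ChangeMap(RasterLayer(current.layer.grid, codes, mask, name="change"))


@dataclass
class ChangeSummary:
    total_current_km2: float
    total_future_km2: float
    maintained_km2: float
    gained_km2: float
    lost_km2: float

    @property
    def pct_maintained(self) -> float:
        return 100.0 * self.maintained_km2 / self.total_current_km2

    @property
    def pct_gained(self) -> float:
        return 100.0 * self.gained_km2 / self.total_current_km2

    @property
    def pct_lost(self) -> float:
        return 100.0 * self.lost_km2 / self.total_current_km2

    @property
    def total_change_pct(self) -> float:
        return 100.0 * (self.total_future_km2 - self.total_current_km2) / self.total_current_km2


def change_summary(cm: ChangeMap, areas: CellAreaLayer) -> ChangeSummary:
    if cm.layer.grid != areas.grid:
        raise ValueError("change map and area layer are on different grids")
    codes = cm.layer.values
    ok = ~cm.layer.nodata_mask
    a = areas.area_km2
    maintained = float(a[ok & (codes == MAINTAINED)].sum())
    gained = float(a[ok & (codes == GAINED)].sum())
    lost = float(a[ok & (codes == LOST)].sum())
    return ChangeSummary(maintained + lost, maintained + gained,
                         maintained, gained, lost)


def summary_from_areas(current_km2: float, future_km2: float,
                       maintained_km2: float, gained_km2: float,
                       lost_km2: float) -> ChangeSummary:
    """Build a summary directly from area totals (e.g., published tables)."""
    s = ChangeSummary(current_km2, future_km2, maintained_km2, gained_km2, lost_km2)
    return s


def centroid(binary: BinaryMap, areas: CellAreaLayer) -> tuple[float, float]:
    """Area-weighted mean lon/lat of suitable cell centers."""
    suit = binary.suitable
    if not suit.any():
        raise ValueError("no suitable cells; centroid undefined")
    grid = binary.layer.grid
    if grid.origin_lon < -180 or grid.origin_lon + grid.n_cols * grid.cell_size > 180:
        raise ValueError("grid crosses the antimeridian; centroid on lon/lat unsupported")
    rows, cols = np.nonzero(suit)
    w = areas.area_km2[rows, cols]
    lon = grid.lon_centers()[cols]
    lat = grid.lat_centers()[rows]
    return float(np.average(lon, weights=w)), float(np.average(lat, weights=w))


@dataclass
class CentroidShift:
    from_lon: float
    from_lat: float
    to_lon: float
    to_lat: float
    distance_km: float
    bearing_deg: float


def _vincenty_inverse(lon1, lat1, lon2, lat2, tol=1e-12, max_iter=200):
    """Geodesic distance (km) and initial bearing (deg) on WGS84.

    Returns None when the classical iteration fails to converge
    (near-antipodal points).
    """
    if lon1 == lon2 and lat1 == lat2:
        return 0.0, 0.0
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    L = math.radians(lon2 - lon1)
    U1 = math.atan((1 - _WGS84_F) * math.tan(phi1))
    U2 = math.atan((1 - _WGS84_F) * math.tan(phi2))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)
    lam = L
    for _ in range(max_iter):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam)
        if sin_sigma == 0:
            return 0.0, 0.0
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1 - sin_alpha ** 2
        cos_2sigma_m = (cos_sigma - 2 * sinU1 * sinU2 / cos2_alpha) if cos2_alpha != 0 else 0.0
        C = _WGS84_F / 16 * cos2_alpha * (4 + _WGS84_F * (4 - 3 * cos2_alpha))
        lam_prev = lam
        lam = L + (1 - C) * _WGS84_F * sin_alpha * (
            sigma + C * sin_sigma * (cos_2sigma_m + C * cos_sigma *
                                     (-1 + 2 * cos_2sigma_m ** 2)))
        if abs(lam - lam_prev) < tol:
            break
    else:
        return None
    u2 = cos2_alpha * (_WGS84_A ** 2 - _WGS84_B ** 2) / _WGS84_B ** 2
    A = 1 + u2 / 16384 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
    B = u2 / 1024 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))
    delta_sigma = B * sin_sigma * (cos_2sigma_m + B / 4 * (
        cos_sigma * (-1 + 2 * cos_2sigma_m ** 2)
        - B / 6 * cos_2sigma_m * (-3 + 4 * sin_sigma ** 2)
        * (-3 + 4 * cos_2sigma_m ** 2)))
    dist = _WGS84_B * A * (sigma - delta_sigma)
    bearing = math.degrees(math.atan2(cosU2 * math.sin(lam),
                                      cosU1 * sinU2 - sinU1 * cosU2 * math.cos(lam)))
    return dist, bearing % 360.0


def shift(from_lonlat: tuple[float, float], to_lonlat: tuple[float, float]
          ) -> CentroidShift:
    """Geodesic distance and initial bearing between two points.

    Uses the WGS84 ellipsoid; falls back to the spherical great-circle
    formula (with a warning) for near-antipodal pairs where the ellipsoid
    iteration does not converge.  Coincident points report bearing 0.
    """
    lon1, lat1 = from_lonlat
    lon2, lat2 = to_lonlat
    for lon, lat in ((lon1, lat1), (lon2, lat2)):
        if not (-180 <= lon <= 180 and -90 <= lat <= 90):
            raise ValueError(f"invalid coordinate ({lon}, {lat})")
    res = _vincenty_inverse(lon1, lat1, lon2, lat2)
    if res is None:
        warnings.warn("near-antipodal points: falling back to spherical distance")
        from .occurrences import haversine_km
        dist = float(haversine_km(lon1, lat1, lon2, lat2))
        y = math.sin(math.radians(lon2 - lon1)) * math.cos(math.radians(lat2))
        x = (math.cos(math.radians(lat1)) * math.sin(math.radians(lat2))
             - math.sin(math.radians(lat1)) * math.cos(math.radians(lat2))
             * math.cos(math.radians(lon2 - lon1)))
        bearing = math.degrees(math.atan2(y, x)) % 360.0
    else:
        dist, bearing = res
    if dist == 0.0:
        bearing = 0.0
    return CentroidShift(lon1, lat1, lon2, lat2, dist, bearing)


@dataclass
class OverlapSummary:
    inside_km2: float
    outside_km2: float
    current_total_km2: float
    change_inside_km2: float | None = None
    change_inside_pct: float | None = None

    @property
    def total_km2(self) -> float:
        return self.inside_km2 + self.outside_km2

    @property
    def pct_inside(self) -> float:
        """Inside area as a percent of the CURRENT total suitable area."""
        return 100.0 * self.inside_km2 / self.current_total_km2

    @property
    def pct_outside(self) -> float:
        return 100.0 * self.outside_km2 / self.current_total_km2


def mpa_overlap(binary: BinaryMap, mpas: RegionPolygons, areas: CellAreaLayer,
                current_total_km2: float, current_inside_km2: float | None = None
                ) -> OverlapSummary:
    """Partition suitable habitat by protected-area membership.

    Suitable cells are inside when their center falls in any polygon.
    Percentages follow the published convention: relative to the current
    total suitable area.  When the current inside area is supplied, the
    change fields report the km² and percent change against it.
    """
    if current_total_km2 <= 0:
        raise ValueError("current_total_km2 must be positive")
    suit = binary.suitable
    grid = binary.layer.grid
    rows, cols = np.nonzero(suit)
    w = areas.area_km2[rows, cols]
    if not mpas.polygons:
        warnings.warn("empty protected-area polygon set")
        inside = np.zeros(len(rows), dtype=bool)
    else:
        inside = mpas.contains_points(grid.lon_centers()[cols], grid.lat_centers()[rows])
    inside_km2 = float(w[inside].sum())
    outside_km2 = float(w[~inside].sum())
    change_km2 = change_pct = None
    if current_inside_km2 is not None:
        change_km2 = inside_km2 - current_inside_km2
        change_pct = 100.0 * change_km2 / current_inside_km2
    return OverlapSummary(inside_km2, outside_km2, current_total_km2,
                          change_km2, change_pct)
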