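"""Home-range estimation: MCP, k-NNCH (LoCoH) isopleths and area stability.

The k-NNCH (local nearest-neighbor convex hull, a.k.a. k-LoCoH) estimator
builds, for every location, the convex hull of that location and its k-1
nearest neighbors, orders the local hulls by area (small hulls sit in
densely used terrain) and unions them in that order until a given
percentage of all locations is covered — the quantile isopleth.  The 100,
60 and 20 % isopleths are conventionally labelled HR1, HR2 and HR3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from shapely import MultiPoint, union_all
from shapely.geometry import Polygon
from sklearn.base import BaseEstimator

from .landscape import M2_PER_HA

__all__ = [
    "HomeRange",
    "AreaCurve",
    "LoCoH",
    "mcp",
    "k_nnch",
    "incremental_area",
    "homerange_radius",
]

_JITTER_M = 1e-6


@dataclass
class HomeRange:
    """MCP polygon plus nested k-NNCH isopleths for one individual."""

    individual: str
    mcp_polygon: Polygon
    mcp_area_ha: float
    isopleths: dict  # quantile (%) -> shapely geometry
    isopleth_areas_ha: dict  # quantile (%) -> ha
    k: int
    n_locations: int
    degenerate: bool = False

    @property
    def hr1(self):
        return self.isopleths[100]

    @property
    def hr2(self):
        return self.isopleths[60]

    @property
    def hr3(self):
        return self.isopleths[20]


@dataclass
class AreaCurve:
    """Cumulative-MCP area as locations accumulate, with a stability verdict."""

    n_locations: np.ndarray
    area_ha: np.ndarray
    asymptote_reached: bool
    threshold_n: int | None


def _dedupe_jitter(points: np.ndarray, rng_seed: int = 0) -> np.ndarray:
    """Jitter exact duplicates by 1e-6 m so hulls stay non-degenerate."""
    pts = np.asarray(points, dtype=float)
    _, inverse, counts = np.unique(pts, axis=0, return_inverse=True, return_counts=True)
    if counts.max() <= 1:
        return pts
    rng = np.random.default_rng(rng_seed)
    dup_mask = counts[inverse] > 1
    out = pts.copy()
    out[dup_mask] += rng.normal(0.0, _JITTER_M, size=(dup_mask.sum(), 2))
    return out


def mcp(points, percent: float = 100.0):
    """Minimum convex polygon of the locations.

    For ``percent`` < 100 the (100-percent)% of locations farthest from the
    centroid are dropped before hulling.  Fewer than 3 non-collinear points
    give a degenerate result (area 0, flagged).

    Returns (polygon, area_ha, degenerate_flag).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if percent < 100.0 and len(pts) > 0:
        centroid = pts.mean(axis=0)
        d = np.linalg.norm(pts - centroid, axis=1)
        keep = max(3, int(np.ceil(len(pts) * percent / 100.0)))
        pts = pts[np.argsort(d)[:keep]]
    hull = MultiPoint(pts).convex_hull
    if hull.geom_type != "Polygon" or hull.area == 0.0:
        return hull, 0.0, True
    return hull, hull.area / M2_PER_HA, False


class LoCoH(BaseEstimator):
    """k-NNCH (k-LoCoH) home-range estimator, sklearn style.

    Parameters
    ----------
    k : int, default 20
        Neighborhood size; each local hull uses a point and its k-1
        nearest neighbors.
    quantiles : tuple of int, default (100, 60, 20)
        Isopleth coverage percentages.

    Attributes (after ``fit``)
    --------------------------
    isopleths_ : dict quantile -> shapely geometry
    isopleth_areas_ha_ : dict quantile -> area in hectares
    mcp_ : shapely Polygon (100 % MCP of the same points)
    mcp_area_ha_ : float
    n_locations_ : int
    """

    def __init__(self, k: int = 20, quantiles: tuple = (100, 60, 20)):
        self.k = k
        self.quantiles = quantiles

    def fit(self, X, y=None):
        pts = np.asarray(X, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("X must be an (n, 2) coordinate array")
        n = len(pts)
        if n < self.k:
            raise ValueError(
                f"k-NNCH needs at least k={self.k} locations, got {n}; use a smaller k"
            )
        work = _dedupe_jitter(pts)
        tree = cKDTree(work)
        _, nbrs = tree.query(work, k=self.k)
        if self.k == 1:
            nbrs = nbrs[:, None]
        hulls = [MultiPoint(work[nbrs[i]]).convex_hull for i in range(n)]
        # order by hull area ascending (density proxy); ties by point index
        order = sorted(range(n), key=lambda i: (hulls[i].area, i))

        import shapely

        pts_geom = shapely.points(work)
        self.isopleths_ = {}
        self.isopleth_areas_ha_ = {}
        union = None
        covered = np.zeros(n, dtype=bool)
        targets = sorted(self.quantiles)  # ascending coverage
        ti = 0
        for rank, i in enumerate(order):
            union = hulls[i] if union is None else union_all([union, hulls[i]])
            todo = ~covered
            if todo.any():
                covered[todo] = shapely.covers(union, pts_geom[todo])
            frac = 100.0 * covered.sum() / n
            while ti < len(targets) and frac >= targets[ti] - 1e-9:
                q = targets[ti]
                self.isopleths_[q] = union
                self.isopleth_areas_ha_[q] = union.area / M2_PER_HA
                ti += 1
            if ti == len(targets):
                break
        # a quantile never reached (can't happen for q<=100, but be safe)
        for q in targets[ti:]:
            self.isopleths_[q] = union
            self.isopleth_areas_ha_[q] = union.area / M2_PER_HA

        self.mcp_, self.mcp_area_ha_, self.mcp_degenerate_ = mcp(pts)
        self.n_locations_ = n
        return self

    def home_range(self, individual: str = "ID") -> HomeRange:
        """Package fitted isopleths into a :class:`HomeRange` record."""
        return HomeRange(
            individual=individual,
            mcp_polygon=self.mcp_,
            mcp_area_ha=self.mcp_area_ha_,
            isopleths=dict(self.isopleths_),
            isopleth_areas_ha=dict(self.isopleth_areas_ha_),
            k=self.k,
            n_locations=self.n_locations_,
            degenerate=self.mcp_degenerate_,
        )


def k_nnch(points, k: int = 20, quantiles: tuple = (100, 60, 20)) -> dict:
    """Functional wrapper over :class:`LoCoH`; returns quantile -> (geometry, ha)."""
    est = LoCoH(k=k, quantiles=quantiles).fit(points)
    return {q: (est.isopleths_[q], est.isopleth_areas_ha_[q]) for q in quantiles}


def incremental_area(
    points_in_time_order, window: int = 10, tol: float = 0.05
) -> AreaCurve:
    """Incremental-area plot: cumulative MCP area as fixes accumulate.

    The home range is called stable (asymptote reached) at the first n
    where the relative area increase over the trailing half of the series
    (never fewer than ``window`` additions) falls below ``tol``.  Judging
    growth over a trailing block that scales with n separates residents
    from drifters: an unbounded walk roughly doubles its cumulative area
    over each doubling of fixes, while a resident's area saturates.
    """
    pts = np.asarray(points_in_time_order, dtype=float)
    if len(pts) < window + 3:
        raise ValueError(f"need at least window+3 = {window + 3} locations")
    ns, areas = [], []
    # running hull: hull(prefix) = hull(hull vertices so far + next point)
    hull_pts = pts[:3]
    for n in range(3, len(pts) + 1):
        if n > 3:
            hull_pts = np.vstack([hull_pts, pts[n - 1]])
        hull = MultiPoint(hull_pts).convex_hull
        if hull.geom_type == "Polygon":
            hull_pts = np.asarray(hull.exterior.coords)[:-1]
            area = hull.area / M2_PER_HA
        else:
            area = 0.0
        ns.append(n)
        areas.append(area)
    ns = np.asarray(ns)
    areas = np.asarray(areas)

    def stable_at(i):
        back = max(window, (i + 3) // 2)
        j = i - back
        if j < 0 or areas[j] <= 0:
            return False
        return (areas[i] - areas[j]) / areas[j] < tol

    asymptote = stable_at(len(areas) - 1)
    threshold_n = None
    if asymptote:
        # start of the stable tail: earliest n from which the criterion
        # holds at every later evaluation
        i = len(areas) - 1
        while i > 0 and stable_at(i - 1):
            i -= 1
        threshold_n = int(ns[i])
    return AreaCurve(ns, areas, asymptote, threshold_n)


def homerange_radius(polygon_or_area_ha) -> float:
    """Radius (m) of the circle with the same area as the home range.

    Accepts a shapely polygon or an area in hectares.
    """
    if hasattr(polygon_or_area_ha, "area"):
        area_m2 = polygon_or_area_ha.area
    else:
        area_m2 = float(polygon_or_area_ha) * M2_PER_HA
    if area_m2 <= 0:
        raise ValueError("home-range area must be positive")
    return float(np.sqrt(area_m2 / np.pi))
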