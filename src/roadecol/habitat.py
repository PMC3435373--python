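"""Used-vs-available habitat-selection design and the candidate model set.

Observed (used) radio locations are thinned to serial independence with
the Schoener ratio, matched 1:1 by random (available) points drawn inside
the individual's 100 % isopleth, and both are described by buffered road-
and landscape covariates.  Available points get traffic values resampled
from the individual's thinned-out locations, so used and available share
the same traffic exposure distribution.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .landscape import Landscape, TrafficSeries, buffered_covariates

__all__ = [
    "schoener_index",
    "thin_to_independence",
    "sample_available",
    "build_usage_design",
    "habitat_candidates",
]

#: interaction and covariate column names shared by the design tables
DXT = "d_highway_x_traffic"


def schoener_index(locations) -> float:
    """Schoener ratio t2/r2 of a time-ordered location series.

    t2 is the mean squared distance between successive locations, r2 the
    mean squared distance from the centroid.  Serially independent fixes
    give a ratio near 2; positive autocorrelation depresses it.
    """
    pts = np.asarray(locations, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 locations")
    steps = np.diff(pts, axis=0)
    t2 = float(np.mean(np.sum(steps**2, axis=1)))
    centroid = pts.mean(axis=0)
    r2 = float(np.mean(np.sum((pts - centroid) ** 2, axis=1)))
    if r2 == 0:
        raise ValueError("all locations coincide; Schoener ratio undefined")
    return t2 / r2


def thin_to_independence(
    locations, lo: float = 1.6, hi: float = 2.4
) -> tuple[np.ndarray, np.ndarray, int]:
    """Subsample every m-th fix until the Schoener ratio enters (lo, hi).

    Returns (kept_indices, dropped_indices, m).  If no m <= n/10 reaches
    the band, the m whose ratio is closest to 2 is returned with a warning.
    """
    pts = np.asarray(locations, dtype=float)
    n = len(pts)
    if n < 10:
        raise ValueError("need at least 10 locations to thin")
    best_m, best_gap = 1, np.inf
    for m in range(1, max(2, n // 10) + 1):
        idx = np.arange(0, n, m)
        if len(idx) < 3:
            break
        try:
            ratio = schoener_index(pts[idx])
        except ValueError:
            continue
        if lo < ratio < hi:
            kept = idx
            dropped = np.setdiff1d(np.arange(n), kept)
            return kept, dropped, m
        gap = abs(ratio - 2.0)
        if gap < best_gap:
            best_m, best_gap = m, gap
    warnings.warn(
        f"no thinning interval m <= n/10 reached the Schoener band ({lo}, {hi}); "
        f"returning best m={best_m}",
        stacklevel=2,
    )
    kept = np.arange(0, n, best_m)
    return kept, np.setdiff1d(np.arange(n), kept), best_m


def sample_available(homerange_polygon, n: int, seed: int = 0) -> np.ndarray:
    """n uniform random points inside the home-range polygon (rejection)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if homerange_polygon.area <= 0:
        raise ValueError("home-range polygon has zero area")
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = homerange_polygon.bounds
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(64, 2 * (n - got))
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        import shapely

        inside = shapely.covers(homerange_polygon, shapely.points(cand))
        take = cand[inside][: n - got]
        out[got : got + len(take)] = take
        got += len(take)
    return out


def build_usage_design(
    used: pd.DataFrame,
    available: dict,
    landscape: Landscape,
    traffic: TrafficSeries,
    species: str,
    error_radius: float,
    discarded: pd.DataFrame | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Assemble the used(1)/available(0) design table.

    ``used`` has columns individual, time, x, y (thinned locations);
    ``available`` maps individual -> (n_i, 2) coordinates; ``discarded``
    holds the thinned-out locations whose observed traffic values are
    resampled (with replacement, per individual) onto available rows.
    When an individual has no discarded fixes its used-location traffic
    pool is used instead.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for ind, grp in used.groupby("individual", sort=True):
        avail = np.asarray(available[ind])
        if len(avail) != len(grp):
            raise ValueError(
                f"individual {ind}: {len(avail)} available points for {len(grp)} used"
            )
        used_traffic = []
        for _, r in grp.iterrows():
            cov = buffered_covariates(
                (r["x"], r["y"]), error_radius, landscape, traffic, r["time"], species
            )
            used_traffic.append(cov.traffic)
            rows.append({"individual": ind, "response": 1, **cov.as_dict()})
        # traffic pool for available rows: the individual's discarded fixes
        pool = None
        if discarded is not None:
            dd = discarded[discarded["individual"] == ind]
            if len(dd):
                pool = np.array(
                    [float(traffic.at_hour(t)["total"]) for t in dd["time"]]
                )
        if pool is None or len(pool) == 0:
            pool = np.asarray(used_traffic, dtype=float)
        draw = rng.choice(pool, size=len(avail), replace=True)
        for (x, y), tr_total in zip(avail, draw):
            # geometry covariates are timestamp-free; reuse any covered hour
            cov = buffered_covariates(
                (x, y), error_radius, landscape, traffic,
                grp["time"].iloc[0], species,
            )
            d = cov.as_dict()
            d["traffic"] = float(tr_total)
            d[DXT] = d["d_highway"] * float(tr_total)
            rows.append({"individual": ind, "response": 0, **d})
    out = pd.DataFrame(rows)
    out["context"] = "usage"
    return out


def habitat_candidates(species: str) -> list:
    """The frozen 14-candidate habitat-selection model competition.

    Three families: road-related only, landscape only, and combined.  The
    suitable-habitat term is cropland area for the barn owl and forest
    area for the stone marten (both named ``habitat_area`` in the design).
    """
    road = [
        [DXT],
        ["d_paved"],
        ["d_unpaved"],
        [DXT, "d_paved", "d_unpaved"],
    ]
    landscape_only = [
        ["d_streams"],
        ["habitat_area"],
        ["d_urban"],
        ["d_buildings"],
        ["d_streams", "habitat_area"],
        ["d_streams", "d_urban", "d_buildings"],
    ]
    combined = [
        [DXT, "d_streams"],
        [DXT, "habitat_area"],
        [DXT, "d_streams", "habitat_area"],
        [DXT, "d_paved", "d_streams", "habitat_area"],
    ]
    specs = road + landscape_only + combined
    assert len(specs) == 14
    return specs
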