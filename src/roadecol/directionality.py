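"""Movement directionality relative to the highway: TOW/AWA segments.

Two successive fixes 30 +/- 15 minutes apart form a movement segment,
labelled TOW (toward) when the end lies closer to the highway than the
start, AWA (away) otherwise.  A within-home-range competition asks how
starting distance and traffic drive directionality; a near-highway
competition (segments starting within twice the telemetry error of the
road) adds verge vegetation and landscape deltas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .landscape import (
    Landscape,
    TrafficSeries,
    SPECIES_VERGE_VAR,
    buffered_covariates,
)

__all__ = [
    "MovementSegment",
    "build_segments",
    "within_hr_candidates",
    "near_highway_candidates",
    "threshold_distance",
    "near_highway_design",
]

D_START = "d_start"  # distance from segment start to the highway


@dataclass
class MovementSegment:
    individual: str
    t_start: pd.Timestamp
    t_end: pd.Timestamp
    start: tuple
    end: tuple
    label: str  # TOW | AWA
    d_start: float
    d_end: float


def build_segments(
    telemetry: pd.DataFrame,
    landscape: Landscape,
    min_gap_min: float = 15.0,
    max_gap_min: float = 45.0,
    tie_tol_m: float = 1e-9,
) -> tuple[list, int]:
    """Build labelled TOW/AWA segments from time-sorted telemetry.

    Consecutive fixes of the same individual with a 15-45 min gap become a
    segment.  Ties (|d_start - d_end| <= 1e-9 m) carry no direction and
    are excluded; their count is returned alongside the segments.
    """
    segments: list[MovementSegment] = []
    ties = 0
    hw = landscape.highway
    for ind, grp in telemetry.groupby("individual", sort=True):
        grp = grp.sort_values("time")
        t = pd.to_datetime(grp["time"]).to_numpy()
        xy = grp[["x", "y"]].to_numpy(dtype=float)
        d = np.array([Point(p).distance(hw) for p in xy])
        gaps = (t[1:] - t[:-1]) / np.timedelta64(1, "m")
        for i, gap in enumerate(gaps):
            if not (min_gap_min <= gap <= max_gap_min):
                continue
            if abs(d[i + 1] - d[i]) <= tie_tol_m:
                ties += 1
                continue
            segments.append(
                MovementSegment(
                    individual=ind,
                    t_start=pd.Timestamp(t[i]),
                    t_end=pd.Timestamp(t[i + 1]),
                    start=tuple(xy[i]),
                    end=tuple(xy[i + 1]),
                    label="TOW" if d[i + 1] < d[i] else "AWA",
                    d_start=float(d[i]),
                    d_end=float(d[i + 1]),
                )
            )
    return segments, ties


def segments_frame(segments: list) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual": [s.individual for s in segments],
            "t_start": [s.t_start for s in segments],
            "t_end": [s.t_end for s in segments],
            "label": [s.label for s in segments],
            "response": [1 if s.label == "TOW" else 0 for s in segments],
            D_START: [s.d_start for s in segments],
        }
    )


def within_hr_design(
    segments: list, traffic: TrafficSeries
) -> pd.DataFrame:
    """Design for the within-home-range competition: start distance + traffic."""
    out = segments_frame(segments)
    light, truck = [], []
    for s in segments:
        tr = traffic.at_hour(s.t_start)
        light.append(float(tr["light"]))
        truck.append(float(tr["truck"]))
    out["light_traffic"] = light
    out["truck_traffic"] = truck
    out["context"] = "directionality"
    return out


def within_hr_candidates() -> list:
    """Five candidate term sets over start distance and traffic by class."""
    return [
        [D_START],
        ["light_traffic"],
        ["truck_traffic"],
        [D_START, "light_traffic"],
        [D_START, "truck_traffic"],
    ]


def threshold_distance(fit) -> tuple[float, bool]:
    """Distance at which P(move toward the highway) = 0.5.

    For a logistic fit with intercept b0 and start-distance slope b1 the
    50 % point is -b0/b1.  Returns (distance_m, in_domain); a negative
    crossing point is returned flagged out-of-domain.
    """
    terms = getattr(fit, "terms", None)
    if terms is not None:
        b0 = fit.beta[0]
        if D_START not in terms:
            raise ValueError(f"fit lacks the {D_START!r} term")
        b1 = fit.beta[terms.index(D_START)]
    else:
        b0, b1 = fit  # (intercept, slope) pair
    if b1 == 0:
        raise ValueError("zero distance slope: P(TOW)=0.5 never crossed")
    x = -b0 / b1
    return float(x), x >= 0


def near_highway_design(
    segments: list,
    landscape: Landscape,
    traffic: TrafficSeries,
    species: str,
    error_mean: float,
    corridor_multiplier: float = 2.0,
) -> pd.DataFrame:
    """Design for the near-highway competition.

    Keeps segments starting within ``corridor_multiplier * error_mean`` of
    the highway; covariates are the start distance plus start-to-end deltas
    of light/truck traffic, suitable verge cover (herbaceous for the owl,
    tree+shrub for the marten), suitable-habitat area and stream distance,
    from buffers of radius ``error_mean`` at both endpoints.
    """
    cutoff = corridor_multiplier * error_mean
    keep = [s for s in segments if s.d_start <= cutoff]
    if not keep:
        raise ValueError(
            f"no segments start within {cutoff:.0f} m of the highway; "
            "simulate a wider corridor or more individuals"
        )
    verge_var = SPECIES_VERGE_VAR[species]
    rows = []
    for s in keep:
        cov_s = buffered_covariates(
            s.start, error_mean, landscape, traffic, s.t_start, species
        )
        cov_f = buffered_covariates(
            s.end, error_mean, landscape, traffic, s.t_end, species
        )
        tr_s = traffic.at_hour(s.t_start)
        tr_f = traffic.at_hour(s.t_end)

        def verge_pct(pt):
            chain = landscape.highway.project(Point(pt))
            seg = landscape.verge_at(
                min(chain, landscape.verge_segments[-1].chainage_end)
            )
            return getattr(seg, verge_var)

        rows.append(
            {
                "individual": s.individual,
                "response": 1 if s.label == "TOW" else 0,
                D_START: s.d_start,
                "delta_light": float(tr_f["light"]) - float(tr_s["light"]),
                "delta_truck": float(tr_f["truck"]) - float(tr_s["truck"]),
                "delta_verge": verge_pct(s.end) - verge_pct(s.start),
                "delta_habitat": cov_f.habitat_area - cov_s.habitat_area,
                "delta_streams": cov_f.d_streams - cov_s.d_streams,
            }
        )
    out = pd.DataFrame(rows)
    out["context"] = "directionality"
    return out


def near_highway_candidates() -> list:
    """Eleven candidate term sets in road / landscape / combined families."""
    road = [
        [D_START],
        ["delta_light"],
        ["delta_truck"],
        ["delta_verge"],
        [D_START, "delta_verge"],
    ]
    landscape_only = [
        ["delta_habitat"],
        ["delta_streams"],
        ["delta_habitat", "delta_streams"],
    ]
    combined = [
        [D_START, "delta_streams", "delta_verge"],
        [D_START, "delta_verge", "delta_habitat"],
        ["delta_verge", "delta_streams"],
    ]
    specs = road + landscape_only + combined
    assert len(specs) == 11
    return specs
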