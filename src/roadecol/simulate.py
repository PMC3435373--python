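"""Synthetic landscapes, traffic, nocturnal trajectories and road-kill events.

The generator emulates VHF radio-tracking of nocturnal animals living next
to a fenced four-lane highway: 30-minute fixes from dusk to dawn, triangu-
lation error of a couple hundred meters, a diurnal traffic cycle, traffic-
scaled highway avoidance, stream attraction, verge-habitat attraction, and
a Bernoulli kill gamble on every realized highway crossing.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, box

from .landscape import (
    GRADE_CLASSES,
    Landscape,
    TrafficSeries,
    VergeSegment,
)

__all__ = [
    "LandscapeConfig",
    "MovementParams",
    "SimOutput",
    "make_landscape",
    "make_traffic",
    "simulate_individual",
    "simulate_population",
    "add_telemetry_error",
]

VERGE_STEP_M = 100.0


# ---------------------------------------------------------------------------
# Landscape generation
# ---------------------------------------------------------------------------


@dataclass
class LandscapeConfig:
    """Extent and layer densities of a generated study landscape.

    The highway runs west-east through the middle of the extent; chainage 0
    is the western end.  Verge attribute ranges default to the spans seen on
    Iberian highway verges (width 2-20 m, herbaceous cover 15-99 %, tree and
    shrub cover 26-76 %).
    """

    width_m: float = 20_000.0
    height_m: float = 10_000.0
    n_streams: int = 4
    n_patches_cropland: int = 12
    n_patches_forest: int = 12
    patch_radius_m: tuple[float, float] = (300.0, 900.0)
    n_paved_roads: int = 2
    n_unpaved_roads: int = 4
    n_urban: int = 2
    n_buildings: int = 25
    passage_spacing_m: float = 2_000.0
    grade_probs: tuple[float, float, float] = (0.25, 0.50, 0.25)  # below/flat/above
    verge_width_range: tuple[float, float] = (2.0, 20.0)
    herb_range: tuple[float, float] = (15.0, 99.0)
    treeshrub_range: tuple[float, float] = (26.0, 76.0)


def make_landscape(config: LandscapeConfig | None = None, seed: int = 0) -> Landscape:
    """Generate a reproducible synthetic landscape around one highway."""
    cfg = config or LandscapeConfig()
    if cfg.width_m <= 0 or cfg.height_m <= 0:
        raise ValueError("landscape extent must be positive")
    rng = np.random.default_rng(seed)
    W, H = cfg.width_m, cfg.height_m
    y0 = 0.0  # highway axis; extent spans y in [-H/2, H/2]

    # Gently meandering west-east highway.
    xs = np.arange(0.0, W + 1, 1_000.0)
    ys = y0 + rng.normal(0.0, 40.0, size=xs.size)
    ys[0] = ys[-1] = y0
    highway = LineString(np.column_stack([xs, ys]))

    n_seg = int(np.ceil(highway.length / VERGE_STEP_M))
    grades = rng.choice(GRADE_CLASSES, size=n_seg, p=cfg.grade_probs)
    verges = []
    for i in range(n_seg):
        start = i * VERGE_STEP_M
        end = min((i + 1) * VERGE_STEP_M, highway.length)
        verges.append(
            VergeSegment(
                chainage_start=start,
                chainage_end=end,
                verge_width=float(rng.uniform(*cfg.verge_width_range)),
                grade_class=str(grades[i]),
                herb_pct=float(rng.uniform(*cfg.herb_range)),
                treeshrub_pct=float(rng.uniform(*cfg.treeshrub_range)),
            )
        )

    def random_crossing_polyline():
        # Streams and minor roads run roughly north-south across the extent.
        x = rng.uniform(0.05 * W, 0.95 * W)
        n_v = 6
        yy = np.linspace(-H / 2, H / 2, n_v)
        xx = x + np.cumsum(rng.normal(0, 200.0, n_v))
        return LineString(np.column_stack([xx, yy]))

    streams = [random_crossing_polyline() for _ in range(cfg.n_streams)]
    paved = [random_crossing_polyline() for _ in range(cfg.n_paved_roads)]
    unpaved = [random_crossing_polyline() for _ in range(cfg.n_unpaved_roads)]

    def random_patch():
        r = rng.uniform(*cfg.patch_radius_m)
        cx = rng.uniform(0, W)
        cy = rng.uniform(-H / 2 + r, H / 2 - r)
        return Point(cx, cy).buffer(r, quad_segs=16)

    patches = [(random_patch(), "cropland") for _ in range(cfg.n_patches_cropland)]
    patches += [(random_patch(), "forest") for _ in range(cfg.n_patches_forest)]

    urban = []
    for _ in range(cfg.n_urban):
        cx = rng.uniform(0, W)
        cy = rng.choice([-1, 1]) * rng.uniform(0.3 * H, 0.45 * H)
        half = rng.uniform(200, 500)
        urban.append(box(cx - half, cy - half, cx + half, cy + half))

    # buildings cluster around the urban centers (villages), with a minority
    # of isolated farmsteads scattered across the extent
    buildings = []
    centers = [u.centroid for u in urban] or [Point(W / 2, H / 4)]
    for _ in range(cfg.n_buildings):
        if rng.random() < 0.7:
            c = centers[rng.integers(len(centers))]
            buildings.append(
                Point(c.x + rng.normal(0, 600.0), c.y + rng.normal(0, 600.0))
            )
        else:
            buildings.append(Point(rng.uniform(0, W), rng.uniform(-H / 2, H / 2)))

    passages = []
    chain = rng.uniform(0, cfg.passage_spacing_m)
    while chain < highway.length:
        kind = str(rng.choice(["culvert", "underpass", "overpass"], p=[0.6, 0.25, 0.15]))
        passages.append((highway.interpolate(chain), kind))
        chain += rng.uniform(0.5, 1.5) * cfg.passage_spacing_m

    return Landscape(
        highway=highway,
        verge_segments=verges,
        streams=streams,
        paved_roads=paved,
        unpaved_roads=unpaved,
        habitat_patches=patches,
        urban=urban,
        buildings=buildings,
        passages=passages,
    )


# ---------------------------------------------------------------------------
# Traffic generation
# ---------------------------------------------------------------------------

NIGHT_HOURS = tuple(list(range(18, 24)) + list(range(0, 6)))  # 18:00-06:00

# Relative within-period hourly weights of the diurnal traffic cycle:
# evening peak fading to a pre-dawn minimum, morning/evening commuter peaks.
# Each period (night 18-06, day 06-18) is rescaled to its own share of the
# AADT, so the night block carries exactly the configured night volume in
# expectation while individual night hours still vary several-fold.
_NIGHT_SHAPE = {18: 3.0, 19: 2.5, 20: 2.0, 21: 1.5, 22: 1.2, 23: 1.0,
                0: 0.8, 1: 0.6, 2: 0.5, 3: 0.5, 4: 0.6, 5: 0.8}
_DAY_SHAPE = {6: 1.5, 7: 2.5, 8: 3.0, 9: 2.5, 10: 2.0, 11: 1.8, 12: 1.8,
              13: 1.8, 14: 1.8, 15: 2.0, 16: 2.5, 17: 3.0}


def make_traffic(
    aadt: float = 13_949.0,
    night_share: float = 5_536.0 / 13_949.0,
    seed: int = 0,
    days: int = 60,
    truck_share: float = 0.05,
    start: str = "2008-05-01",
    day_factor_sd: float = 0.5,
) -> TrafficSeries:
    """Hourly Poisson traffic with a diurnal cycle around a target AADT.

    ``night_share`` is the fraction of daily vehicles between 18:00 and
    06:00 (defaults match an AADT of 13949 with 5536 at night).  Counts are
    Poisson with hourly means summing exactly to ``aadt`` per day; trucks
    (vehicle classes 3-5) are a binomial thinning with rate ``truck_share``.
    Day-to-day volume (weekday/weekend structure) is emulated by a mean-one
    lognormal nightly factor with log-SD ``day_factor_sd``; each factor
    covers one dusk-to-dawn block so a whole night shares its traffic level.
    """
    if aadt <= 0:
        raise ValueError("aadt must be positive")
    if not 0 < night_share < 1:
        raise ValueError("night_share must lie in (0, 1)")
    if days <= 0:
        raise ValueError("days must be positive")
    rng = np.random.default_rng(seed)
    hourly_mean = np.empty(24)
    night_total = sum(_NIGHT_SHAPE.values())
    day_total = sum(_DAY_SHAPE.values())
    for h, w in _NIGHT_SHAPE.items():
        hourly_mean[h] = aadt * night_share * w / night_total
    for h, w in _DAY_SHAPE.items():
        hourly_mean[h] = aadt * (1 - night_share) * w / day_total

    hours = pd.date_range(start=start, periods=24 * days, freq="h")
    means = hourly_mean[hours.hour].astype(float)
    if day_factor_sd > 0:
        # block index: hours 00-17 belong to the night/day that started the
        # previous evening's date for the small hours, so a dusk-to-dawn
        # night shares one factor
        block = np.where(hours.hour < 6, -1, 0) + np.arange(len(hours)) // 24
        factors = np.exp(rng.normal(-day_factor_sd**2 / 2, day_factor_sd, days + 1))
        means = means * factors[block + 1]
    total = rng.poisson(means)
    truck = rng.binomial(total, truck_share)
    light = total - truck
    return TrafficSeries(pd.DataFrame({"hour": hours, "light": light, "truck": truck}))


# ---------------------------------------------------------------------------
# Movement simulation
# ---------------------------------------------------------------------------


@dataclass
class MovementParams:
    """Behavioral kernel of the step-selection simulator.

    Each 30-min candidate step is scored by

        beta_avoid * traffic_now * exp(-d_highway / avoid_scale)
        + beta_stream * d_streams + beta_verge * verge_quality
        + turn_concentration * cos(turn angle) - |end - home|^2 / (2 home_sigma^2)

    and one candidate is sampled from the softmax.  A step whose segment
    intersects the highway is realized as a crossing with probability
    logistic(cross_logit + grade_effect[grade]); a realized crossing kills
    with probability ``kill_prob``.  Negative ``beta_avoid`` means highway
    avoidance that strengthens with traffic; negative ``beta_stream`` means
    stream attraction (the score penalizes distance).
    """

    step_scale: float = 350.0  # mean 30-min step length, m
    turn_concentration: float = 0.5
    beta_avoid: float = -0.025  # per vehicles/h of proximity-scaled traffic
    beta_stream: float = -0.001  # per m of distance to the nearest stream
    beta_verge: float = 0.02  # per % suitable verge cover (proximity-scaled)
    cross_logit: float = 0.0
    grade_effect: dict = field(default_factory=lambda: {"below": 0.0, "flat": 0.0, "above": 0.0})
    kill_prob: float = 0.01
    activity_hours: float = 12.0
    avoid_scale: float = 1_000.0  # e-folding of the traffic-avoidance term, m
    home_sigma: float = 600.0  # home-range attraction scale, m
    disappear_prob_per_night: float = 0.0
    n_candidates: int = 24

    def __post_init__(self) -> None:
        if not 0 <= self.kill_prob <= 1:
            raise ValueError("kill_prob must lie in [0, 1]")
        if self.step_scale <= 0:
            raise ValueError("step_scale must be positive")
        if not 0 < self.activity_hours <= 24:
            raise ValueError("activity_hours must lie in (0, 24]")


@dataclass
class SimOutput:
    """One simulated individual: truth, observations, crossings and fate."""

    individual: str
    species: str
    true_trajectory: pd.DataFrame  # columns time, x, y
    observed_telemetry: pd.DataFrame  # columns time, x, y (with error)
    true_crossings: list  # of (time, chainage)
    kill_event: Optional[tuple]  # (time, chainage) or None
    fate: str  # alive | road-killed | disappeared

    def telemetry_frame(self) -> pd.DataFrame:
        out = self.observed_telemetry.copy()
        out.insert(0, "individual", self.individual)
        out.insert(1, "species", self.species)
        return out


def _verge_quality(landscape: Landscape, pt: np.ndarray, d_hwy: float, species: str) -> float:
    if d_hwy > 600.0:  # beyond any roadside influence
        return 0.0
    chain = landscape.highway.project(Point(pt))
    seg = landscape.verge_at(min(chain, landscape.verge_segments[-1].chainage_end))
    pct = seg.herb_pct if species == "barn_owl" else seg.treeshrub_pct
    return pct * float(np.exp(-d_hwy / 200.0))


def simulate_individual(
    landscape: Landscape,
    traffic: TrafficSeries,
    params: MovementParams,
    days: int,
    seed: int,
    species: str = "barn_owl",
    individual: str = "ID1",
    start_xy: tuple[float, float] | None = None,
    start_date: str = "2008-05-01",
) -> SimOutput:
    """Simulate one individual's nocturnal trajectory near the highway.

    Fixes every 30 min during a 19:00-07:00 activity window (12 h -> 24
    steps per night).  The animal is resident: steps are biased toward its
    home center so home ranges stabilize.  Crossing attempts that fail the
    crossing gamble are re-sampled among same-side candidates (the animal
    turns back at the fence).
    """
    rng = np.random.default_rng(seed)
    steps_per_night = int(round(params.activity_hours * 2))
    if start_xy is None:
        # captured < 1.5 km from the highway, like the study animals
        start_xy = (
            float(rng.uniform(0.25, 0.75) * landscape.highway.length),
            float(rng.choice([-1, 1]) * rng.uniform(300.0, 1_400.0)),
        )
    home = np.asarray(start_xy, dtype=float)
    pos = home.copy()
    heading = rng.uniform(0, 2 * np.pi)

    times, xs, ys = [], [], []
    crossings: list[tuple[pd.Timestamp, float]] = []
    kill_event = None
    fate = "alive"
    base = pd.Timestamp(start_date)
    hw = landscape.highway

    import shapely

    stream_union = shapely.union_all(landscape.streams) if landscape.streams else None
    hw_y = np.asarray(hw.coords)[:, 1]
    hw_band = (hw_y.min() - 1.0, hw_y.max() + 1.0)  # quick crossing reject

    done = False
    for night in range(days):
        if done:
            break
        if params.disappear_prob_per_night > 0 and rng.random() < params.disappear_prob_per_night:
            fate = "disappeared"
            break
        night_start = base + pd.Timedelta(days=night, hours=19)
        for k in range(steps_per_night):
            t = night_start + pd.Timedelta(minutes=30 * k)
            times.append(t)
            xs.append(pos[0])
            ys.append(pos[1])
            if k == steps_per_night - 1:
                break

            traffic_now = float(traffic.at_hour(t)["total"])
            # candidate steps
            ang = rng.uniform(0, 2 * np.pi, params.n_candidates)
            ln = rng.gamma(2.0, params.step_scale / 2.0, params.n_candidates)
            cand = pos + np.column_stack([ln * np.cos(ang), ln * np.sin(ang)])

            cand_pts = shapely.points(cand)
            d_hwy = shapely.distance(cand_pts, hw)
            if stream_union is not None:
                d_str = shapely.distance(cand_pts, stream_union)
            else:
                d_str = np.zeros(len(cand))
            vq = np.zeros(len(cand))
            for j in np.nonzero(d_hwy <= 600.0)[0]:
                vq[j] = _verge_quality(landscape, cand[j], d_hwy[j], species)
            score = (
                params.beta_avoid * traffic_now * np.exp(-d_hwy / params.avoid_scale)
                + params.beta_stream * d_str
                + params.beta_verge * vq
                + params.turn_concentration * np.cos(ang - heading)
                - np.sum((cand - home) ** 2, axis=1) / (2 * params.home_sigma**2)
            )
            w = np.exp(score - score.max())
            w /= w.sum()
            idx = rng.choice(params.n_candidates, p=w)
            lo_y = min(pos[1], cand[idx][1])
            hi_y = max(pos[1], cand[idx][1])
            may_cross = lo_y <= hw_band[1] and hi_y >= hw_band[0]
            inter = (
                LineString([pos, cand[idx]]).intersection(hw) if may_cross else None
            )

            if inter is not None and not inter.is_empty:
                # crossing attempt at the first intersection point
                pts_x = (
                    [inter] if inter.geom_type == "Point" else list(inter.geoms)
                )
                chain = hw.project(pts_x[0])
                grade = landscape.verge_at(
                    min(chain, landscape.verge_segments[-1].chainage_end)
                ).grade_class
                logit = params.cross_logit + params.grade_effect.get(grade, 0.0)
                p_cross = 1.0 / (1.0 + np.exp(-logit))
                if rng.random() < p_cross:
                    crossings.append((t + pd.Timedelta(minutes=15), float(chain)))
                    if rng.random() < params.kill_prob:
                        kill_event = (t + pd.Timedelta(minutes=15), float(chain))
                        fate = "road-killed"
                        # the kill truncates the trajectory at the crossing fix
                        heading = ang[idx]
                        pos = cand[idx]
                        times.append(t + pd.Timedelta(minutes=30))
                        xs.append(pos[0])
                        ys.append(pos[1])
                        done = True
                        break
                    heading = ang[idx]
                    pos = cand[idx]
                else:
                    # turned back at the fence: pick among same-side candidates
                    same_side = np.array(
                        [LineString([pos, c]).intersection(hw).is_empty for c in cand]
                    )
                    if same_side.any():
                        w2 = w * same_side
                        w2 /= w2.sum()
                        idx = rng.choice(params.n_candidates, p=w2)
                        heading = ang[idx]
                        pos = cand[idx]
                    # else stay put
            else:
                heading = ang[idx]
                pos = cand[idx]

    traj = pd.DataFrame({"time": times, "x": xs, "y": ys})
    return SimOutput(
        individual=individual,
        species=species,
        true_trajectory=traj,
        observed_telemetry=traj.copy(),
        true_crossings=crossings,
        kill_event=kill_event,
        fate=fate,
    )


def add_telemetry_error(
    trajectory: pd.DataFrame,
    error_mean_m: float,
    error_sd_m: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Displace each fix by an isotropic radial error.

    The radial error is Gamma-distributed with shape/scale chosen so its
    mean and SD equal the configured triangulation-error figures (a pure
    Rayleigh law cannot match an arbitrary mean/SD pair); the direction is
    uniform.  ``error_mean_m = 0`` returns the exact trajectory.
    """
    if error_mean_m < 0:
        raise ValueError("error_mean_m must be non-negative")
    out = trajectory.copy()
    if error_mean_m == 0:
        return out
    rng = np.random.default_rng(seed)
    n = len(out)
    shape = (error_mean_m / error_sd_m) ** 2
    scale = error_sd_m**2 / error_mean_m
    r = rng.gamma(shape, scale, n)
    theta = rng.uniform(0, 2 * np.pi, n)
    out["x"] = out["x"].to_numpy() + r * np.cos(theta)
    out["y"] = out["y"].to_numpy() + r * np.sin(theta)
    return out


def simulate_population(
    landscape: Landscape,
    traffic: TrafficSeries,
    params: MovementParams,
    n_individuals: int,
    days: int,
    seed: int,
    species: str = "barn_owl",
    error_mean_m: float = 196.0,
    error_sd_m: float = 124.0,
) -> list[SimOutput]:
    """Simulate several independent individuals and attach telemetry error."""
    ss = np.random.SeedSequence(seed)
    outs = []
    for i, child in enumerate(ss.spawn(n_individuals)):
        sub = np.random.default_rng(child)
        s_traj = int(sub.integers(0, 2**31 - 1))
        s_err = int(sub.integers(0, 2**31 - 1))
        sim = simulate_individual(
            landscape,
            traffic,
            params,
            days=days,
            seed=s_traj,
            species=species,
            individual=f"{'BO' if species == 'barn_owl' else 'SM'}{i + 1}",
        )
        sim.observed_telemetry = add_telemetry_error(
            sim.true_trajectory, error_mean_m, error_sd_m, seed=s_err
        )
        outs.append(sim)
    return outs
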