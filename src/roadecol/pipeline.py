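"""End-to-end pipeline: simulate -> home ranges -> habitat -> movement ->
crossings -> risk -> report, driven by one YAML config and one master seed.

Every stochastic stage derives its seed deterministically from the master
seed and the stage name, so a rerun with the same config is bytewise
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crossings as cr
from . import directionality as dr
from . import habitat as hb
from .glmm import aic_table, fit_binomial_glmm, model_average
from .homerange import LoCoH, incremental_area, mcp
from .simulate import (
    LandscapeConfig,
    MovementParams,
    make_landscape,
    make_traffic,
    simulate_population,
)

log = logging.getLogger("roadecol")

SPECIES_DEFAULTS = {
    "barn_owl": {"error_mean": 196.0, "error_sd": 124.0, "aadt": 13_949.0, "night": 5_536.0},
    "stone_marten": {"error_mean": 182.0, "error_sd": 155.0, "aadt": 8_373.0, "night": 3_011.0},
}


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    species: str = "barn_owl"
    seed: int = 0
    n_individuals: int = 6
    days: int = 60
    # analysis constants
    k_neighbors: int = 20
    isopleth_quantiles: tuple = (100, 60, 20)
    schoener_band: tuple = (1.6, 2.4)
    segment_gap_min: tuple = (15.0, 45.0)
    corridor_multiplier: float = 2.0
    delta_aic_support: float = 2.0
    corr_threshold: float = 0.5
    activity_hours: float = 12.0
    # species parameters (None -> defaults table)
    error_mean: float | None = None
    error_sd: float | None = None
    aadt: float | None = None
    night_volume: float | None = None
    # extrapolation
    density_ind_km2: float = 0.24
    strip_width_km: float = 2.0
    road_km: float = 100.0
    movement: dict = field(default_factory=dict)
    landscape: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.species not in SPECIES_DEFAULTS:
            raise ValueError(f"unknown species {self.species!r}")
        d = SPECIES_DEFAULTS[self.species]
        if self.error_mean is None:
            self.error_mean = d["error_mean"]
        if self.error_sd is None:
            self.error_sd = d["error_sd"]
        if self.aadt is None:
            self.aadt = d["aadt"]
        if self.night_volume is None:
            self.night_volume = d["night"]
        if not 0 < self.activity_hours <= 24:
            raise ValueError("activity_hours must lie in (0, 24]")
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals for mixed models")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def load_telemetry(path: str | Path) -> pd.DataFrame:
    """Read and validate a telemetry CSV (individual, time, x, y [, species]).

    Aborts naming the first offending row: unparseable timestamp or
    non-finite coordinate.
    """
    df = pd.read_csv(path)
    required = ["individual", "time", "x", "y"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"telemetry file lacks columns {missing}")
    t = pd.to_datetime(df["time"], errors="coerce")
    bad = np.nonzero(t.isna().to_numpy())[0]
    if len(bad):
        raise ValueError(f"telemetry row {bad[0]}: unparseable timestamp {df['time'].iloc[bad[0]]!r}")
    xy = df[["x", "y"]].apply(pd.to_numeric, errors="coerce")
    bad = np.nonzero(~np.isfinite(xy.to_numpy()).all(axis=1))[0]
    if len(bad):
        raise ValueError(f"telemetry row {bad[0]}: non-numeric coordinates")
    df["time"] = t
    df[["x", "y"]] = xy
    return df


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute every stage on simulated inputs and write all artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": _jsonable(asdict(config)), "stages": []}

    # -- simulate -----------------------------------------------------------
    land = make_landscape(
        LandscapeConfig(**config.landscape), seed=config.stage_seed("landscape")
    )
    traffic = make_traffic(
        aadt=config.aadt,
        night_share=config.night_volume / config.aadt,
        seed=config.stage_seed("traffic"),
        days=config.days + 2,
    )
    params = MovementParams(**config.movement) if config.movement else MovementParams()
    sims = simulate_population(
        land,
        traffic,
        params,
        n_individuals=config.n_individuals,
        days=config.days,
        seed=config.stage_seed("movement"),
        species=config.species,
        error_mean_m=config.error_mean,
        error_sd_m=config.error_sd,
    )
    telemetry = pd.concat([s.telemetry_frame() for s in sims], ignore_index=True)
    land.to_geojson_dir(outdir / "landscape")
    traffic.to_csv(outdir / "traffic.csv")
    telemetry.to_csv(outdir / "telemetry.csv", index=False)
    manifest["stages"].append({"stage": "simulate", "n_fixes": len(telemetry)})
    log.info("simulate: %d individuals, %d fixes", len(sims), len(telemetry))

    # -- home ranges --------------------------------------------------------
    hr_rows = []
    homeranges = {}
    for s in sims:
        pts = s.observed_telemetry[["x", "y"]].to_numpy()
        _, mcp_area, _ = mcp(pts)
        row = {
            "individual": s.individual,
            "n_locations": len(pts),
            "fate": s.fate,
            "mcp_ha": round(mcp_area, 1),
        }
        if len(pts) >= config.k_neighbors:
            est = LoCoH(k=config.k_neighbors, quantiles=config.isopleth_quantiles).fit(pts)
            homeranges[s.individual] = est.home_range(s.individual)
            for q in config.isopleth_quantiles:
                row[f"hr_{q}_ha"] = round(est.isopleth_areas_ha_[q], 1)
            curve = incremental_area(pts) if len(pts) >= 13 else None
            row["asymptote"] = bool(curve.asymptote_reached) if curve else False
        hr_rows.append(row)
    hr_table = pd.DataFrame(hr_rows)
    hr_table.to_csv(outdir / "homeranges.csv", index=False)
    manifest["stages"].append({"stage": "homerange", "n_individuals": len(hr_rows)})

    # -- habitat selection --------------------------------------------------
    used_parts, disc_parts, available = [], [], {}
    rng_av = config.stage_seed("available")
    for i, s in enumerate(sims):
        if s.individual not in homeranges:
            continue
        obs = s.observed_telemetry.reset_index(drop=True)
        kept, dropped, m = hb.thin_to_independence(obs[["x", "y"]].to_numpy())
        used = obs.iloc[kept].copy()
        used["individual"] = s.individual
        disc = obs.iloc[dropped].copy()
        disc["individual"] = s.individual
        used_parts.append(used)
        disc_parts.append(disc)
        available[s.individual] = hb.sample_available(
            homeranges[s.individual].hr1, len(used), seed=rng_av + i
        )
        log.info("thinning %s: %d -> %d fixes (m=%d)", s.individual, len(obs), len(used), m)
    used_all = pd.concat(used_parts, ignore_index=True)
    disc_all = pd.concat(disc_parts, ignore_index=True)
    design = hb.build_usage_design(
        used_all, available, land, traffic, config.species,
        config.error_mean, discarded=disc_all, seed=config.stage_seed("design"),
    )
    design.to_csv(outdir / "design_usage.csv", index=False)
    habitat_fits = [fit_binomial_glmm(design, [])]
    for spec in hb.habitat_candidates(config.species):
        try:
            habitat_fits.append(fit_binomial_glmm(design, spec))
        except Exception as e:  # degenerate simulated covariate sets
            log.warning("habitat spec %s failed: %s", spec, e)
    habitat_table = aic_table(habitat_fits)
    habitat_table.to_csv(outdir / "habitat_models.csv", index=False)
    _write_coefs(habitat_fits, config.delta_aic_support, outdir / "habitat_coefficients.csv")
    manifest["stages"].append(
        {"stage": "habitat", "n_design_rows": len(design), "n_models": len(habitat_fits)}
    )

    # -- movement directionality --------------------------------------------
    segments, ties = dr.build_segments(
        telemetry, land, config.segment_gap_min[0], config.segment_gap_min[1]
    )
    within = dr.within_hr_design(segments, traffic)
    within.to_csv(outdir / "segments.csv", index=False)
    within_fits = [fit_binomial_glmm(within, [])]
    for spec in dr.within_hr_candidates():
        try:
            within_fits.append(fit_binomial_glmm(within, spec))
        except Exception as e:
            log.warning("directionality spec %s failed: %s", spec, e)
    within_table = aic_table(within_fits)
    within_table.to_csv(outdir / "directionality_models.csv", index=False)
    _write_coefs(within_fits, config.delta_aic_support, outdir / "directionality_coefficients.csv")
    try:
        near = dr.near_highway_design(
            segments, land, traffic, config.species, config.error_mean,
            config.corridor_multiplier,
        )
        near_fits = [fit_binomial_glmm(near, [])]
        for spec in dr.near_highway_candidates():
            try:
                near_fits.append(fit_binomial_glmm(near, spec))
            except Exception:
                continue
        aic_table(near_fits).to_csv(outdir / "near_highway_models.csv", index=False)
    except ValueError as e:
        log.warning("near-highway stage skipped: %s", e)
    manifest["stages"].append(
        {"stage": "movement", "n_segments": len(segments), "n_ties_excluded": ties}
    )

    # -- crossings ----------------------------------------------------------
    events = cr.detect_crossings(telemetry, land.highway)
    pd.DataFrame(
        {
            "individual": [e.individual for e in events],
            "time": [e.time for e in events],
            "chainage_m": [e.chainage for e in events],
        }
    ).to_csv(outdir / "crossings.csv", index=False)
    if len(events) >= 5:
        xdesign = cr.build_crossing_design(
            events, land, traffic, seed=config.stage_seed("crossing_sites")
        )
        xtable, _ = cr.fit_crossing_models(xdesign, config.species)
        xtable.to_csv(outdir / "crossing_models.csv", index=False)
    manifest["stages"].append({"stage": "crossings", "n_events": len(events)})

    # -- risk ---------------------------------------------------------------
    tracked_hours = sum(
        (s.observed_telemetry["time"].iloc[-1] - s.observed_telemetry["time"].iloc[0])
        / pd.Timedelta(hours=1)
        - (len(set(s.observed_telemetry["time"].dt.date)) - 1) * 12.0
        for s in sims
        if len(s.observed_telemetry) > 1
    )
    kills = sum(1 for s in sims if s.fate == "road-killed")
    disappeared = sum(1 for s in sims if s.fate == "disappeared")
    days_total = sum(
        max(
            (s.observed_telemetry["time"].iloc[-1] - s.observed_telemetry["time"].iloc[0]).days,
            1,
        )
        for s in sims
        if len(s.observed_telemetry) > 1
    )
    if events:
        risk = cr.risk_estimate(
            crossings_observed=len(events),
            tracked_hours=max(tracked_hours, 1.0),
            kills_confirmed=kills,
            kills_disappeared=disappeared,
            tracking_days_total=days_total,
            activity_hours=config.activity_hours,
            density_ind_km2=config.density_ind_km2,
            strip_width_km=config.strip_width_km,
            road_km=config.road_km,
        )
        risk_dict = risk.as_dict()
        rate = risk.rate_per_day
    else:
        # no observed crossings: the rate is zero and per-crossing risk is
        # undefined (division by the estimated number of crossings)
        rate = 0.0
        risk_dict = {
            "crossings_observed": 0,
            "tracked_hours": tracked_hours,
            "activity_hours_per_day": config.activity_hours,
            "rate_per_day": 0.0,
            "kills_confirmed": kills,
            "kills_with_disappeared": kills + disappeared,
            "tracking_days_total": days_total,
            "r_confirmed": None,
            "r_upper": None,
        }
    (outdir / "risk.json").write_text(json.dumps(risk_dict, indent=2, default=str))
    manifest["stages"].append({"stage": "risk", "rate_per_day": rate})

    (outdir / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
    return outdir


def _write_coefs(fits, delta_max, path):
    try:
        avg = model_average(fits, delta_max=delta_max)
        avg.to_csv(path, index=False)
    except ValueError:
        pass


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def report(run_dir: str | Path) -> dict:
    """Collect a completed run's summary tables; errors list missing parts."""
    run_dir = Path(run_dir)
    required = [
        "manifest.json",
        "homeranges.csv",
        "habitat_models.csv",
        "directionality_models.csv",
        "risk.json",
    ]
    missing = [f for f in required if not (run_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"run directory incomplete; missing {missing}")
    out = {
        "manifest": json.loads((run_dir / "manifest.json").read_text()),
        "homeranges": pd.read_csv(run_dir / "homeranges.csv"),
        "habitat_models": pd.read_csv(run_dir / "habitat_models.csv"),
        "directionality_models": pd.read_csv(run_dir / "directionality_models.csv"),
        "risk": json.loads((run_dir / "risk.json").read_text()),
    }
    opt = run_dir / "crossing_models.csv"
    if opt.exists():
        out["crossing_models"] = pd.read_csv(opt)
    return out
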