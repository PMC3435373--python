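"""Spatial data model: highway, verges, landscape layers and covariate extraction.

All geometry lives in a single planar metric CRS (coordinates in meters).
Geographic (lon/lat) input is rejected rather than silently projected.
Distances are reported in meters, areas in hectares, highway chainage in
meters from the start vertex of the highway polyline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import (
    LineString,
    Point,
    Polygon,
    mapping,
    shape,
)

__all__ = [
    "VergeSegment",
    "Landscape",
    "TrafficSeries",
    "CovariateVector",
    "VergeVector",
    "GRADE_CLASSES",
    "grade_classify",
    "distance_to",
    "buffered_covariates",
    "verge_descriptors",
]

GRADE_CLASSES = ("below", "flat", "above")

#: species tag -> habitat patch tag considered suitable
SPECIES_HABITAT = {"barn_owl": "cropland", "stone_marten": "forest"}
#: species tag -> verge vegetation variable considered suitable
SPECIES_VERGE_VAR = {"barn_owl": "herb_pct", "stone_marten": "treeshrub_pct"}

M2_PER_HA = 10_000.0


class EmptyLayerError(ValueError):
    """Raised when a distance is requested against an empty layer."""


def grade_classify(slope_value: float, threshold: float = 20.0) -> str:
    """Classify a verge slope into below-grade / flat / above-grade.

    The slope is the inclination from the surrounding soil up to the road
    surface; sections sunk below the terrain have negative slope.  The
    default threshold of +/-20 is interpreted in degrees (a +/-20 *radian*
    threshold would be geometrically meaningless).
    """
    if not np.isfinite(slope_value):
        raise ValueError("slope_value must be finite")
    if slope_value < -threshold:
        return "below"
    if slope_value > threshold:
        return "above"
    return "flat"


@dataclass
class VergeSegment:
    """Road-verge attributes for one 100 m step of highway chainage."""

    chainage_start: float
    chainage_end: float
    verge_width: float
    grade_class: str
    herb_pct: float
    treeshrub_pct: float

    def __post_init__(self) -> None:
        if self.grade_class not in GRADE_CLASSES:
            raise ValueError(f"grade_class must be one of {GRADE_CLASSES}")
        if not (0 <= self.herb_pct <= 100 and 0 <= self.treeshrub_pct <= 100):
            raise ValueError("vegetation percentages must lie in [0, 100]")
        if self.verge_width <= 0:
            raise ValueError("verge_width must be positive")
        if self.chainage_end <= self.chainage_start:
            raise ValueError("chainage_end must exceed chainage_start")


def _check_planar(coords: np.ndarray) -> None:
    # Heuristic CRS guard: a full layer bundle whose every coordinate fits in
    # lon/lat bounds is almost certainly geographic and must be reprojected
    # by the caller first.
    if coords.size == 0:
        return
    x, y = coords[:, 0], coords[:, 1]
    if np.all(np.abs(x) <= 180.0) and np.all(np.abs(y) <= 90.0):
        raise ValueError(
            "coordinates look geographic (lon/lat); supply planar metric "
            "coordinates — on-the-fly reprojection is not supported"
        )


@dataclass
class Landscape:
    """All spatial layers of the study system around one highway.

    ``highway`` is a simple polyline; ``verge_segments`` tile its chainage
    in 100 m steps without gaps or overlap.  Habitat patches carry a tag in
    {"forest", "cropland"}; passages carry {"culvert", "underpass",
    "overpass"}.
    """

    highway: LineString
    verge_segments: list[VergeSegment]
    streams: list[LineString] = field(default_factory=list)
    paved_roads: list[LineString] = field(default_factory=list)
    unpaved_roads: list[LineString] = field(default_factory=list)
    habitat_patches: list[tuple[Polygon, str]] = field(default_factory=list)
    urban: list[Polygon] = field(default_factory=list)
    buildings: list[Point] = field(default_factory=list)
    passages: list[tuple[Point, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.highway.is_simple:
            raise ValueError("highway polyline must be simple (non-self-intersecting)")
        coords = np.asarray(self.highway.coords)
        _check_planar(coords)
        self._validate_verges()

    def _validate_verges(self) -> None:
        segs = sorted(self.verge_segments, key=lambda s: s.chainage_start)
        if not segs:
            raise ValueError("landscape requires at least one verge segment")
        if segs[0].chainage_start != 0.0:
            raise ValueError("verge segments must start at chainage 0")
        for a, b in zip(segs, segs[1:]):
            if abs(a.chainage_end - b.chainage_start) > 1e-6:
                raise ValueError("verge segments must tile the chainage without gaps/overlap")
        if segs[-1].chainage_end < self.highway.length - 1e-6:
            raise ValueError("verge segments must cover the full highway length")
        self.verge_segments = segs

    # -- layer access -------------------------------------------------------

    def layer(self, name: str) -> list:
        geoms = {
            "highway": [self.highway],
            "streams": self.streams,
            "paved_roads": self.paved_roads,
            "unpaved_roads": self.unpaved_roads,
            "habitat_patches": [g for g, _ in self.habitat_patches],
            "urban": self.urban,
            "buildings": self.buildings,
            "passages": [p for p, _ in self.passages],
        }
        if name not in geoms:
            raise KeyError(f"unknown layer {name!r}")
        return geoms[name]

    def habitat_union(self, tag: str):
        polys = [g for g, t in self.habitat_patches if t == tag]
        return shapely.union_all(polys) if polys else Polygon()

    def verge_at(self, chainage: float) -> VergeSegment:
        if chainage < 0 or chainage > self.verge_segments[-1].chainage_end + 1e-6:
            raise ValueError(f"chainage {chainage} outside highway extent")
        for seg in self.verge_segments:
            if seg.chainage_start - 1e-9 <= chainage <= seg.chainage_end + 1e-9:
                return seg
        raise ValueError(f"chainage {chainage} not covered by verge segments")

    def chainage_point(self, chainage: float) -> Point:
        return self.highway.interpolate(chainage)

    # -- GeoJSON round trip -------------------------------------------------

    def to_geojson_dir(self, outdir: str | Path) -> None:
        """Write one GeoJSON FeatureCollection per layer plus a manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

        def fc(features):
            return {"type": "FeatureCollection", "features": features}

        def feat(geom, props=None):
            return {"type": "Feature", "geometry": mapping(geom), "properties": props or {}}

        hw_features = [feat(self.highway, {"role": "highway"})]
        for s in self.verge_segments:
            seg_geom = _substring(self.highway, s.chainage_start, s.chainage_end)
            hw_features.append(
                feat(
                    seg_geom,
                    {
                        "role": "verge_segment",
                        "chainage_start": s.chainage_start,
                        "chainage_end": s.chainage_end,
                        "verge_width": s.verge_width,
                        "grade_class": s.grade_class,
                        "herb_pct": s.herb_pct,
                        "treeshrub_pct": s.treeshrub_pct,
                    },
                )
            )
        layers = {
            "highway": fc(hw_features),
            "streams": fc([feat(g) for g in self.streams]),
            "paved_roads": fc([feat(g) for g in self.paved_roads]),
            "unpaved_roads": fc([feat(g) for g in self.unpaved_roads]),
            "habitat_patches": fc([feat(g, {"habitat": t}) for g, t in self.habitat_patches]),
            "urban": fc([feat(g) for g in self.urban]),
            "buildings": fc([feat(g) for g in self.buildings]),
            "passages": fc([feat(g, {"kind": t}) for g, t in self.passages]),
        }
        manifest = {"layers": sorted(layers)}
        for name, collection in layers.items():
            (outdir / f"{name}.geojson").write_text(json.dumps(collection, sort_keys=True))
        (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True))

    @classmethod
    def from_geojson_dir(cls, indir: str | Path) -> "Landscape":
        indir = Path(indir)
        manifest = json.loads((indir / "manifest.json").read_text())

        def load(name):
            return json.loads((indir / f"{name}.geojson").read_text())["features"]

        if set(manifest["layers"]) != {
            "buildings", "habitat_patches", "highway", "passages",
            "paved_roads", "streams", "unpaved_roads", "urban",
        }:
            raise ValueError("manifest does not list the expected layers")

        hw_feats = load("highway")
        highway = None
        verges = []
        for f in hw_feats:
            props = f.get("properties") or {}
            if props.get("role") == "highway":
                highway = shape(f["geometry"])
            elif props.get("role") == "verge_segment":
                verges.append(
                    VergeSegment(
                        chainage_start=props["chainage_start"],
                        chainage_end=props["chainage_end"],
                        verge_width=props["verge_width"],
                        grade_class=props["grade_class"],
                        herb_pct=props["herb_pct"],
                        treeshrub_pct=props["treeshrub_pct"],
                    )
                )
        if highway is None:
            raise ValueError("highway layer lacks a feature with role 'highway'")
        return cls(
            highway=highway,
            verge_segments=verges,
            streams=[shape(f["geometry"]) for f in load("streams")],
            paved_roads=[shape(f["geometry"]) for f in load("paved_roads")],
            unpaved_roads=[shape(f["geometry"]) for f in load("unpaved_roads")],
            habitat_patches=[
                (shape(f["geometry"]), f["properties"]["habitat"]) for f in load("habitat_patches")
            ],
            urban=[shape(f["geometry"]) for f in load("urban")],
            buildings=[shape(f["geometry"]) for f in load("buildings")],
            passages=[(shape(f["geometry"]), f["properties"]["kind"]) for f in load("passages")],
        )


def _substring(line: LineString, start: float, end: float) -> LineString:
    from shapely.ops import substring

    return substring(line, start, end)


# ---------------------------------------------------------------------------
# Traffic
# ---------------------------------------------------------------------------


class TrafficSeries:
    """Hourly traffic counts split into light vehicles and trucks.

    Wraps a DataFrame with columns ``hour`` (hour-resolution timestamps,
    strictly increasing), ``light`` and ``truck`` (vehicles/h, >= 0).
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        frame["hour"] = pd.to_datetime(frame["hour"])
        if not frame["hour"].is_monotonic_increasing or frame["hour"].duplicated().any():
            raise ValueError("traffic hours must be strictly increasing")
        if (frame[["light", "truck"]] < 0).any().any():
            raise ValueError("traffic counts must be non-negative")
        frame["total"] = frame["light"] + frame["truck"]
        self.frame = frame
        self._index = frame.set_index("hour")

    def __len__(self) -> int:
        return len(self.frame)

    def at_hour(self, timestamp) -> pd.Series:
        """Counts for the hour containing ``timestamp`` (floored to the hour)."""
        hour = pd.Timestamp(timestamp).floor("h")
        try:
            return self._index.loc[hour]
        except KeyError:
            raise ValueError(f"timestamp {timestamp} outside traffic coverage") from None

    def covers(self, timestamp) -> bool:
        return pd.Timestamp(timestamp).floor("h") in self._index.index

    def to_csv(self, path: str | Path) -> None:
        out = self.frame[["hour", "light", "truck"]].copy()
        out.columns = ["hour_iso8601", "light", "truck"]
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrafficSeries":
        raw = pd.read_csv(path)
        raw = raw.rename(columns={"hour_iso8601": "hour"})
        return cls(raw[["hour", "light", "truck"]])


# ---------------------------------------------------------------------------
# Covariate extraction
# ---------------------------------------------------------------------------


def distance_to(point, layer: Sequence, layer_name: str = "layer") -> float:
    """Euclidean distance (m) from ``point`` to the nearest geometry of a layer.

    Zero when the point lies on a line or inside a polygon of the layer.
    """
    geoms = list(layer)
    if not geoms:
        raise EmptyLayerError(f"cannot compute distance to empty layer {layer_name!r}")
    pt = Point(point)
    return float(min(pt.distance(g) for g in geoms))


@dataclass
class CovariateVector:
    """Road- and landscape covariates at one buffered location."""

    d_highway: float
    d_paved: float
    d_unpaved: float
    d_streams: float
    d_urban: float
    d_buildings: float
    habitat_area: float  # ha of species-suitable habitat inside the buffer
    traffic: float  # vehicles/h at the location's hour
    d_highway_x_traffic: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def buffered_covariates(
    point,
    radius_m: float,
    landscape: Landscape,
    traffic: TrafficSeries,
    timestamp,
    species: str,
) -> CovariateVector:
    """Covariates within a telemetry-error buffer around one location.

    Distances are measured from the point itself; the suitable-habitat area
    (cropland for the barn owl, forest for the stone marten) is the patch
    area intersected with the buffer, in hectares.  Traffic is read at the
    hour containing ``timestamp``; the distance x traffic interaction is the
    exact product.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    if species not in SPECIES_HABITAT:
        raise ValueError(f"unknown species tag {species!r}; expected one of {sorted(SPECIES_HABITAT)}")
    pt = Point(point)
    buf = pt.buffer(radius_m, quad_segs=32)
    suitable = landscape.habitat_union(SPECIES_HABITAT[species])
    habitat_area = buf.intersection(suitable).area / M2_PER_HA if not suitable.is_empty else 0.0
    tr = traffic.at_hour(timestamp)
    d_hwy = distance_to(pt, [landscape.highway], "highway")
    return CovariateVector(
        d_highway=d_hwy,
        d_paved=distance_to(pt, landscape.paved_roads, "paved_roads"),
        d_unpaved=distance_to(pt, landscape.unpaved_roads, "unpaved_roads"),
        d_streams=distance_to(pt, landscape.streams, "streams"),
        d_urban=distance_to(pt, landscape.urban, "urban"),
        d_buildings=distance_to(pt, landscape.buildings, "buildings"),
        habitat_area=habitat_area,
        traffic=float(tr["total"]),
        d_highway_x_traffic=d_hwy * float(tr["total"]),
    )


@dataclass
class VergeVector:
    """Verge and traffic descriptors at one highway chainage."""

    verge_width: float
    d_below: float
    d_flat: float
    d_above: float
    herb_pct: float
    treeshrub_pct: float
    d_cropland: float
    d_forest: float
    d_allpassages: float
    total_traffic: float
    light_traffic: float
    truck_traffic: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _chainage_distance_to_class(landscape: Landscape, chainage: float, grade: str) -> float:
    """Along-highway distance to the nearest verge segment of a grade class.

    Returns inf when no segment of that class exists (capped by callers).
    """
    best = np.inf
    for seg in landscape.verge_segments:
        if seg.grade_class != grade:
            continue
        if seg.chainage_start <= chainage <= seg.chainage_end:
            return 0.0
        best = min(best, abs(chainage - seg.chainage_start), abs(chainage - seg.chainage_end))
    return best


def verge_descriptors(
    highway_chainage: float,
    landscape: Landscape,
    traffic: TrafficSeries,
    timestamp,
) -> VergeVector:
    """Describe the highway at a chainage: containing-verge attributes,
    along-highway distances to each grade class and to the nearest passage,
    planar distances to suitable habitat, and the hour's traffic by class.

    Grade classes absent from the landscape yield a distance equal to the
    full highway length (an explicit "farther than anything on this road").
    """
    seg = landscape.verge_at(highway_chainage)
    pt = landscape.chainage_point(highway_chainage)
    hw_len = landscape.highway.length

    def dclass(grade):
        d = _chainage_distance_to_class(landscape, highway_chainage, grade)
        return float(min(d, hw_len))

    if landscape.passages:
        chains = [landscape.highway.project(p) for p, _ in landscape.passages]
        d_pass = float(min(abs(highway_chainage - c) for c in chains))
    else:
        d_pass = float(hw_len)

    def dhab(tag):
        u = landscape.habitat_union(tag)
        return float(pt.distance(u)) if not u.is_empty else float(hw_len)

    tr = traffic.at_hour(timestamp)
    return VergeVector(
        verge_width=seg.verge_width,
        d_below=dclass("below"),
        d_flat=dclass("flat"),
        d_above=dclass("above"),
        herb_pct=seg.herb_pct,
        treeshrub_pct=seg.treeshrub_pct,
        d_cropland=dhab("cropland"),
        d_forest=dhab("forest"),
        d_allpassages=d_pass,
        total_traffic=float(tr["total"]),
        light_traffic=float(tr["light"]),
        truck_traffic=float(tr["truck"]),
    )
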