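"""Classified airfield surface maps.

An airfield surface map is a set of classified polygons — runways, taxiways
and the connecting strips between them (collectively the "tarmacked areas"
where aircraft manoeuvre, i.e. the strike-risk zone), plus apron, built
land, grassland, service roads and unknown surfaces. Each tarmacked surface
carries an activity status (active / semi-operational / inactive) describing
whether it was open to routine air traffic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .projection import TransverseMercator

HABITAT_CLASSES = frozenset(
    {
        "tarmac_runway",
        "tarmac_taxiway",
        "tarmac_connecting",
        "apron",
        "built_land",
        "grassland",
        "service_road",
        "unknown",
    }
)
TARMAC_CLASSES = frozenset({"tarmac_runway", "tarmac_taxiway", "tarmac_connecting"})
ACTIVITY_STATUSES = frozenset(
    {"active", "semi_operational", "inactive", "not_applicable"}
)


@dataclass(frozen=True)
class SurfacePolygon:
    surface_id: str
    geometry: BaseGeometry  # polygon or multipolygon, planar metric frame
    habitat_class: str
    activity_status: str = "not_applicable"
    label: str = ""

    @property
    def is_tarmac(self) -> bool:
        return self.habitat_class in TARMAC_CLASSES

    @property
    def area_m2(self) -> float:
        return self.geometry.area


@dataclass
class SurfaceMap:
    polygons: list[SurfacePolygon]
    boundary: BaseGeometry | None = None
    crs_descriptor: str = "local-metric"

    def __iter__(self):
        return iter(self.polygons)

    def __len__(self) -> int:
        return len(self.polygons)

    def by_class(self, *classes: str) -> list[SurfacePolygon]:
        return [p for p in self.polygons if p.habitat_class in classes]

    def total_area_m2(self) -> float:
        return sum(p.area_m2 for p in self.polygons)


def _validate_polygon(surface_id: str, geom: BaseGeometry) -> BaseGeometry:
    """Repair or reject an invalid geometry.

    Only conservative zero-buffer repairs are accepted: if the repair
    changes the shoelace area by more than 1% (e.g. a bow-tie ring whose
    lobes cancel), the geometry is genuinely ill-formed and rejected.
    """
    if geom.is_valid and geom.area > 0:
        return geom
    repaired = geom.buffer(0)
    if (
        repaired.is_valid
        and repaired.area > 0
        and abs(repaired.area - geom.area) <= 0.01 * repaired.area
    ):
        return repaired
    raise ValueError(f"invalid geometry for surface {surface_id!r}")


def validate_surface_map(smap: SurfaceMap) -> SurfaceMap:
    """Check class/status enums and tarmac-overlap constraints.

    Tarmacked polygons may share edges (runway abutting a connecting strip)
    but any positive-area overlap between two tarmacked polygons is an
    error, since it would double-count interactions.
    """
    for p in smap.polygons:
        if p.habitat_class not in HABITAT_CLASSES:
            raise ValueError(
                f"surface {p.surface_id!r}: unknown habitat_class {p.habitat_class!r}"
            )
        if p.activity_status not in ACTIVITY_STATUSES:
            raise ValueError(
                f"surface {p.surface_id!r}: unknown activity_status {p.activity_status!r}"
            )
        if p.is_tarmac and p.activity_status == "not_applicable":
            raise ValueError(
                f"tarmacked surface {p.surface_id!r} must carry an activity status"
            )
    tarmac = [p for p in smap.polygons if p.is_tarmac]
    for i, a in enumerate(tarmac):
        for b in tarmac[i + 1 :]:
            if a.geometry.intersection(b.geometry).area > 1e-9:
                raise ValueError(
                    f"tarmacked surfaces {a.surface_id!r} and {b.surface_id!r} overlap"
                )
    return smap


def load_surface_map(
    path, projection: TransverseMercator | None = None
) -> SurfaceMap:
    """Load a surface map from a GeoJSON FeatureCollection.

    Features must carry ``surface_id``, ``habitat_class`` and (for tarmac
    classes) ``activity_status`` properties. If ``projection`` is given,
    coordinates are treated as lon/lat and re-projected to the planar frame;
    otherwise they are taken to be planar metres already. A feature with
    ``"role": "boundary"`` supplies the airfield perimeter.
    """
    data = json.loads(Path(path).read_text())
    if data.get("type") != "FeatureCollection":
        raise ValueError("surface map must be a GeoJSON FeatureCollection")
    polygons: list[SurfacePolygon] = []
    boundary = None
    for feat in data.get("features", []):
        props = feat.get("properties") or {}
        geom = shape(feat["geometry"])
        if projection is not None:
            geom = _reproject(geom, projection)
        if props.get("role") == "boundary":
            boundary = _validate_polygon("<boundary>", geom)
            continue
        sid = str(props.get("surface_id", ""))
        if not sid:
            raise ValueError("feature missing surface_id property")
        geom = _validate_polygon(sid, geom)
        polygons.append(
            SurfacePolygon(
                surface_id=sid,
                geometry=geom,
                habitat_class=str(props.get("habitat_class", "unknown")),
                activity_status=str(props.get("activity_status", "not_applicable")),
                label=str(props.get("label", "")),
            )
        )
    smap = SurfaceMap(polygons=polygons, boundary=boundary)
    return validate_surface_map(smap)


def _reproject(geom: BaseGeometry, projection: TransverseMercator) -> BaseGeometry:
    from shapely.ops import transform

    return transform(lambda lon, lat: projection.forward(lon, lat), geom)


def dump_surface_map(smap: SurfaceMap, path) -> None:
    """Write a SurfaceMap as a GeoJSON FeatureCollection (planar coords)."""
    features = []
    for p in smap.polygons:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(p.geometry),
                "properties": {
                    "surface_id": p.surface_id,
                    "habitat_class": p.habitat_class,
                    "activity_status": p.activity_status,
                    "label": p.label,
                },
            }
        )
    if smap.boundary is not None:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(smap.boundary),
                "properties": {"role": "boundary"},
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, sort_keys=True)
    )


def tarmacked_subset(smap: SurfaceMap) -> SurfaceMap:
    """Runways, taxiways and connecting strips, regardless of activity status."""
    return SurfaceMap(
        polygons=[p for p in smap.polygons if p.is_tarmac],
        boundary=smap.boundary,
        crs_descriptor=smap.crs_descriptor,
    )


def tarmac_union(smap: SurfaceMap):
    """Union geometry of all tarmacked surfaces (for habitat composition)."""
    geoms = [p.geometry for p in tarmacked_subset(smap).polygons]
    return unary_union(geoms) if geoms else None
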