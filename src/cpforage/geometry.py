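"""Geographic primitives: great-circle distance, polygon membership, and
trip-level inside/outside-fjord classification.

Coordinates are WGS84 decimal degrees throughout.  Polygon operations are
performed in the raw lon/lat plane (no projection), which is adequate for the
synthetic rectangular study geometry; for real high-latitude coastlines a
projected CRS would be preferable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Point, Polygon, shape

__all__ = [
    "GeoPoint",
    "PolygonRegion",
    "StudyArea",
    "haversine_km",
    "haversine_km_vec",
    "point_in_polygon",
    "points_in_polygon",
    "classify_trip",
    "load_study_area",
]

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 position (decimal degrees)."""

    lon: float
    lat: float

    def __post_init__(self):
        if not (math.isfinite(self.lon) and math.isfinite(self.lat)):
            raise ValueError("coordinates must be finite")
        if not (-180.0 <= self.lon <= 180.0 and -90.0 <= self.lat <= 90.0):
            raise ValueError(f"invalid coordinates lon={self.lon}, lat={self.lat}")


@dataclass(frozen=True)
class PolygonRegion:
    """A closed ring with a semantic label (``fjord`` or ``land``)."""

    ring: tuple  # of GeoPoint
    label: str = "fjord"
    _poly: Polygon = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        pts = [(p.lon, p.lat) for p in self.ring]
        if pts[0] != pts[-1]:
            pts.append(pts[0])
        if len(set(pts[:-1])) < 3:
            raise ValueError("polygon ring needs at least 3 distinct vertices")
        poly = Polygon(pts)
        if poly.area == 0:
            raise ValueError("polygon ring has zero area")
        object.__setattr__(self, "_poly", poly)

    @property
    def shapely(self) -> Polygon:
        return self._poly


@dataclass(frozen=True)
class StudyArea:
    """Fjord boundary, land mask and colony locations of one study system."""

    fjord: PolygonRegion
    land: tuple = ()
    colonies: dict = field(default_factory=dict)

    def __post_init__(self):
        for cid, pt in self.colonies.items():
            if not point_in_polygon(pt, self.fjord):
                raise ValueError(f"colony {cid!r} lies outside the fjord ring")


def haversine_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    return float(
        haversine_km_vec(
            np.asarray(a.lon), np.asarray(a.lat), np.asarray(b.lon), np.asarray(b.lat)
        )
    )


def haversine_km_vec(lon1, lat1, lon2, lat2):
    """Vectorised haversine distance (km) between coordinate arrays."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    if not all(np.all(np.isfinite(v)) for v in (lon1, lat1, lon2, lat2)):
        raise ValueError("coordinates must be finite")
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def point_in_polygon(p: GeoPoint, poly: PolygonRegion) -> bool:
    """Even-odd membership in the lon/lat plane; boundary points count as inside."""
    return bool(poly.shapely.covers(Point(p.lon, p.lat)))


def points_in_polygon(lon, lat, poly: PolygonRegion) -> np.ndarray:
    """Vectorised membership test (boundary counts as inside)."""
    # for a point, intersecting a polygon's closure == covered by it
    return shapely.intersects_xy(poly.shapely, np.asarray(lon, float), np.asarray(lat, float))


def classify_trip(trip, area: StudyArea) -> str:
    """Label a trip ``outside`` iff at least one fix falls strictly outside
    the fjord ring, else ``inside``.

    Birds that stay within the fjord boundary (including exactly on it) keep
    the inside label; the outside label encodes a fjord crossing, however
    brief.
    """
    lon, lat = trip.lon_lat_arrays()
    if lon.size == 0:
        raise ValueError("cannot classify an empty trip")
    inside = points_in_polygon(lon, lat, area.fjord)
    return "inside" if bool(np.all(inside)) else "outside"


def load_study_area(path) -> StudyArea:
    """Read a StudyArea from GeoJSON.

    Expects one Polygon feature with property ``label="fjord"``, any number of
    Polygon features with ``label="land"``, and Point features carrying a
    ``colony_id`` property.
    """
    with open(path) as fh:
        gj = json.load(fh)
    fjord = None
    land = []
    colonies = {}
    for feat in gj["features"]:
        geom = shape(feat["geometry"])
        props = feat.get("properties") or {}
        if geom.geom_type == "Polygon":
            ring = tuple(GeoPoint(x, y) for x, y in geom.exterior.coords)
            region = PolygonRegion(ring=ring, label=props.get("label", "fjord"))
            if region.label == "fjord":
                if fjord is not None:
                    raise ValueError("multiple fjord polygons in GeoJSON")
                fjord = region
            else:
                land.append(region)
        elif geom.geom_type == "Point":
            colonies[props["colony_id"]] = GeoPoint(geom.x, geom.y)
    if fjord is None:
        raise ValueError("GeoJSON contains no polygon labelled 'fjord'")
    return StudyArea(fjord=fjord, land=tuple(land), colonies=colonies)


def study_area_to_geojson(area: StudyArea, path) -> None:
    """Write a StudyArea back to the GeoJSON layout read by load_study_area."""
    feats = []

    def poly_feature(region):
        coords = [[p.lon, p.lat] for p in region.ring]
        if coords[0] != coords[-1]:
            coords.append(coords[0])
        return {
            "type": "Feature",
            "properties": {"label": region.label},
            "geometry": {"type": "Polygon", "coordinates": [coords]},
        }

    feats.append(poly_feature(area.fjord))
    feats.extend(poly_feature(r) for r in area.land)
    for cid, pt in area.colonies.items():
        feats.append(
            {
                "type": "Feature",
                "properties": {"colony_id": cid},
                "geometry": {"type": "Point", "coordinates": [pt.lon, pt.lat]},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh, indent=1)
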