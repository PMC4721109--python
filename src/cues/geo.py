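"""Offline geocoding and nearest-anchor lookup.

Residence strings in "City, State" form are resolved against a packaged
gazetteer (an exact-match, case-insensitive lookup — no fuzzy guessing), and
each point is mapped to its nearest anchor city by Haversine great-circle
distance on a sphere of mean Earth radius 6371.0 km.

The resolver contract is pluggable: any callable ``place -> GeoPoint`` can
stand in for :func:`geocode` wherever a resolver is accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd

from .anchors import AnchorCity
from .errors import TableError, UnknownPlaceError

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoPoint",
    "default_gazetteer_path",
    "load_gazetteer",
    "normalize_place",
    "geocode",
    "haversine_km",
    "nearest_anchor",
]

#: Mean Earth radius, km (spherical model).
EARTH_RADIUS_KM = 6371.0

Gazetteer = Mapping[str, "GeoPoint"]


@dataclass(frozen=True)
class GeoPoint:
    """A latitude/longitude pair in decimal degrees."""

    latitude: float
    longitude: float

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")


def default_gazetteer_path() -> Path:
    return Path(resources.files("cues.data") / "gazetteer.csv")


def normalize_place(place: str) -> str:
    """Canonical form of a "City, State" string: lower case, single spaces,
    exactly one comma-space separator."""
    parts = [p.strip() for p in place.split(",")]
    parts = [" ".join(p.split()) for p in parts if p]
    return ", ".join(parts).lower()


def load_gazetteer(source: Union[str, Path, None] = None) -> dict[str, GeoPoint]:
    """Load a gazetteer CSV (header ``city,state,latitude,longitude``) into a
    dict keyed by normalized "city, st" strings."""
    if source is None:
        source = default_gazetteer_path()
    df = pd.read_csv(source, comment="#", skipinitialspace=True)
    missing = [c for c in ("city", "state", "latitude", "longitude") if c not in df.columns]
    if missing:
        raise TableError(f"gazetteer missing columns: {missing}")
    out: dict[str, GeoPoint] = {}
    for _, row in df.iterrows():
        key = normalize_place(f"{row['city']}, {row['state']}")
        out[key] = GeoPoint(float(row["latitude"]), float(row["longitude"]))
    if not out:
        raise TableError("empty gazetteer")
    return out


def geocode(place: str, gazetteer: Union[Gazetteer, str, Path, None] = None) -> GeoPoint:
    """Resolve a "City, State" string to coordinates.

    Matching is case-insensitive and whitespace-normalized but otherwise
    exact; an unresolvable place raises :class:`UnknownPlaceError` carrying
    the input verbatim. ``gazetteer`` may be a loaded mapping, a CSV path,
    ``None`` (packaged default), or any callable ``place -> GeoPoint`` — the
    resolver contract is pluggable.
    """
    if not place or not place.strip():
        raise UnknownPlaceError(place)
    if callable(gazetteer):
        return gazetteer(place)
    if gazetteer is None or isinstance(gazetteer, (str, Path)):
        gazetteer = load_gazetteer(gazetteer)
    try:
        return gazetteer[normalize_place(place)]
    except KeyError:
        raise UnknownPlaceError(place) from None


def haversine_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance between two points, km, on a sphere of radius
    6371.0 km."""
    phi1, phi2 = math.radians(a.latitude), math.radians(b.latitude)
    dphi = phi2 - phi1
    dlam = math.radians(b.longitude - a.longitude)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def nearest_anchor(point: GeoPoint, table: Iterable[AnchorCity]) -> AnchorCity:
    """Anchor city minimizing Haversine distance to ``point``.

    Exact distance ties (measure zero in practice) are broken by
    lexicographic (name, state) key for reproducibility.
    """
    cities = list(table)
    if not cities:
        raise TableError("no anchor cities")
    return min(
        cities,
        key=lambda c: (haversine_km(point, GeoPoint(c.latitude, c.longitude)), c.key()),
    )
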