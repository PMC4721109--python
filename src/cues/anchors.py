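"""Anchor-city annual UV index reference table.

Each anchor city carries an average annual UV index (UVI). The UV index is a
standardized, linear measure of erythemally-weighted irradiance: one UVI unit
corresponds to 0.025 W/m². Theoretically the UVI lies in [0, 43]; average
annual values for US cities typically fall between 1 and 11, from 1.9 in
Anchorage, AK to 10.3 in San Juan, PR.

The packaged default table ships only the four cities with published annual
indices; users supply the full table as a CSV with header
``name,state,latitude,longitude,annual_uvi``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from .errors import TableError

__all__ = [
    "AnchorCity",
    "UVI_HARD_MAX",
    "UVI_TYPICAL_RANGE",
    "WATTS_PER_UVI",
    "default_anchor_path",
    "load_anchor_table",
    "uvi_to_irradiance",
    "table_extrema",
]

#: Hard upper bound for a physically meaningful UV index.
UVI_HARD_MAX = 43.0
#: Typical range for US average annual UV indices; values outside warn.
UVI_TYPICAL_RANGE = (1.0, 11.0)
#: Erythemal irradiance per UV index unit, W/m².
WATTS_PER_UVI = 0.025

_COLUMNS = ["name", "state", "latitude", "longitude", "annual_uvi"]


@dataclass(frozen=True)
class AnchorCity:
    """A reference city with coordinates and an average annual UV index."""

    name: str
    state: str
    latitude: float
    longitude: float
    annual_uvi: float

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise TableError(f"latitude out of range for {self.key()}: {self.latitude}")
        if not -180.0 <= self.longitude <= 180.0:
            raise TableError(f"longitude out of range for {self.key()}: {self.longitude}")
        if not 0.0 <= self.annual_uvi <= UVI_HARD_MAX:
            raise TableError(
                f"annual UV index for {self.key()} outside [0, {UVI_HARD_MAX:g}]: "
                f"{self.annual_uvi}"
            )
        lo, hi = UVI_TYPICAL_RANGE
        if not lo <= self.annual_uvi <= hi:
            warnings.warn(
                f"annual UV index {self.annual_uvi} for {self.key()} is outside the "
                f"typical US annual range [{lo:g}, {hi:g}]",
                stacklevel=3,
            )

    def key(self) -> tuple[str, str]:
        """(name, state) identity used for uniqueness and tie-breaking."""
        return (self.name, self.state)


def default_anchor_path() -> Path:
    """Path of the packaged default anchor table."""
    return Path(resources.files("cues.data") / "anchors.csv")


def load_anchor_table(source: Union[str, Path, None] = None) -> list[AnchorCity]:
    """Load and validate an anchor-city table from CSV.

    Parameters
    ----------
    source
        CSV path with header ``name,state,latitude,longitude,annual_uvi``
        (``#`` lines are comments). ``None`` loads the packaged default.

    Returns
    -------
    list of :class:`AnchorCity`, in file order.

    Raises
    ------
    TableError
        If the table is empty, a row fails validation (UVI outside [0, 43],
        bad coordinates), or a (name, state) key is duplicated.
    """
    if source is None:
        source = default_anchor_path()
    df = pd.read_csv(source, comment="#", skipinitialspace=True)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise TableError(f"anchor table missing columns: {missing}")
    if len(df) == 0:
        raise TableError("no anchor cities")
    cities: list[AnchorCity] = []
    seen: set[tuple[str, str]] = set()
    for i, row in df.iterrows():
        try:
            city = AnchorCity(
                name=str(row["name"]).strip(),
                state=str(row["state"]).strip(),
                latitude=float(row["latitude"]),
                longitude=float(row["longitude"]),
                annual_uvi=float(row["annual_uvi"]),
            )
        except TableError as exc:
            raise TableError(f"row {i + 1}: {exc}") from None
        if city.key() in seen:
            raise TableError(f"duplicate anchor city: {city.key()}")
        seen.add(city.key())
        cities.append(city)
    return cities


def write_anchor_table(cities: Iterable[AnchorCity], path: Union[str, Path]) -> None:
    """Write an anchor table back to the CSV schema used by :func:`load_anchor_table`."""
    df = pd.DataFrame([vars(c) for c in cities], columns=_COLUMNS)
    df.to_csv(path, index=False)


def uvi_to_irradiance(uvi: float) -> float:
    """Convert a UV index to erythemal irradiance in W/m² (0.025 W/m² per unit)."""
    if uvi < 0:
        raise ValueError(f"UV index must be non-negative, got {uvi}")
    return uvi * WATTS_PER_UVI


def table_extrema(table: Iterable[AnchorCity]) -> tuple[AnchorCity, AnchorCity]:
    """Cities attaining the minimum and maximum annual UVI.

    Ties are broken by lexicographic (name, state) key so the result is
    deterministic on any table.
    """
    cities = list(table)
    if not cities:
        raise TableError("no anchor cities")
    lo = min(cities, key=lambda c: (c.annual_uvi, c.key()))
    hi_uvi = max(c.annual_uvi for c in cities)
    hi = min((c for c in cities if c.annual_uvi == hi_uvi), key=lambda c: c.key())
    return lo, hi


def find_city(table: Iterable[AnchorCity], name: str, state: str) -> AnchorCity:
    """Look up an anchor by (name, state), case-insensitively."""
    want = (name.strip().lower(), state.strip().lower())
    for c in table:
        if (c.name.lower(), c.state.lower()) == want:
            return c
    raise TableError(f"anchor city not found: {name}, {state}")
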