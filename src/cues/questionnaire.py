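"""Questionnaire data model, eligibility rules and skip patterns.

The instrument collects, per respondent: age and Fitzpatrick skin type;
personal and family skin-cancer history (with type and age at first
diagnosis for personal history); six sun-behavior items (tanning-bed visits,
blistering sunburns, and the frequency of sunscreen, long-sleeve, hat and
shade use — the latter four on a never…always scale); hours of peak-window
(10 am – 4 pm) sun exposure per weekday and weekend day within six fixed age
epochs; and a complete residential history as "City, State" entries with age
ranges.

Respondents with a personal history answer the six behavior items twice
(before and after first diagnosis). Skip patterns mean the number of items
actually presented ranges from 10 (no personal or family history) to 17
(both present). Eligibility requires age ≥ 18 and no non-US residence of a
year or more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .geo import Gazetteer, UnknownPlaceError, geocode

__all__ = [
    "AGE_BANDS",
    "AGE_BAND_LABELS",
    "TANNING_LEVELS",
    "BURN_LEVELS",
    "FREQUENCY_LEVELS",
    "CANCER_TYPES",
    "ResidencePeriod",
    "ExposureEpoch",
    "BehaviorSet",
    "Respondent",
    "ValidationReport",
    "validate_respondent",
    "items_presented",
    "ordinal_codes",
    "band_for_age",
]

#: Half-open exposure age epochs [start, end); the last band is open-ended.
AGE_BANDS: tuple[tuple[int, Optional[int]], ...] = (
    (0, 13),
    (13, 20),
    (20, 40),
    (40, 65),
    (65, 80),
    (80, None),
)
AGE_BAND_LABELS = tuple(
    f"{lo}-{hi}" if hi is not None else f"{lo}+" for lo, hi in AGE_BANDS
)

TANNING_LEVELS = ("0", "1-5", "6-10", "11-100", ">100")
BURN_LEVELS = ("0", "1-5", "6-10", ">10")
FREQUENCY_LEVELS = ("never", "rarely", "sometimes", "often", "always")
CANCER_TYPES = ("BCC", "SCC", "melanoma", "other", "don't know")

#: Peak-window cap: at most 6 hours of 10 am – 4 pm exposure per day.
MAX_DAILY_HOURS = 6.0

#: Text marker identifying a residence outside the United States.
NON_US_MARKER = "non-us"


def band_for_age(age: int) -> str:
    """Label of the exposure epoch containing an (integer) age-year."""
    for (lo, hi), label in zip(AGE_BANDS, AGE_BAND_LABELS):
        if age >= lo and (hi is None or age < hi):
            return label
    raise ValueError(f"no age band for age {age}")


@dataclass(frozen=True)
class ResidencePeriod:
    """One residence spell: "City, State" occupied over [start_age, end_age)."""

    place: str
    start_age: int
    end_age: int

    def __post_init__(self):
        if not 0 <= self.start_age < self.end_age:
            raise ValueError(
                f"invalid residence ages [{self.start_age}, {self.end_age}) for "
                f"{self.place!r}"
            )


@dataclass(frozen=True)
class ExposureEpoch:
    """Peak-window sun hours per day within one age band."""

    age_band: str
    weekday_hours_per_day: float
    weekend_hours_per_day: float

    def __post_init__(self):
        if self.age_band not in AGE_BAND_LABELS:
            raise ValueError(f"unknown age band {self.age_band!r}")
        for v in (self.weekday_hours_per_day, self.weekend_hours_per_day):
            if not 0.0 <= v <= MAX_DAILY_HOURS:
                raise ValueError(
                    f"daily hours must lie in [0, {MAX_DAILY_HOURS:g}], got {v}"
                )


@dataclass(frozen=True)
class BehaviorSet:
    """The six sun-behavior items (one reporting period)."""

    tanning_bed_visits: str
    blistering_sunburns: str
    sunscreen: str
    long_sleeves: str
    hat: str
    shade_seeking: str

    def __post_init__(self):
        checks = [
            ("tanning_bed_visits", self.tanning_bed_visits, TANNING_LEVELS),
            ("blistering_sunburns", self.blistering_sunburns, BURN_LEVELS),
            ("sunscreen", self.sunscreen, FREQUENCY_LEVELS),
            ("long_sleeves", self.long_sleeves, FREQUENCY_LEVELS),
            ("hat", self.hat, FREQUENCY_LEVELS),
            ("shade_seeking", self.shade_seeking, FREQUENCY_LEVELS),
        ]
        for name, value, levels in checks:
            if value not in levels:
                raise ValueError(f"{name}: {value!r} not in {levels}")


@dataclass
class Respondent:
    """One questionnaire response."""

    age: int
    fitzpatrick: int
    personal_hx: bool
    behaviors_before: BehaviorSet
    epochs: Sequence[ExposureEpoch]
    residences: Sequence[ResidencePeriod]
    dx_age: Optional[int] = None
    dx_type: Optional[str] = None
    behaviors_after: Optional[BehaviorSet] = None
    family_hx: frozenset = field(default_factory=frozenset)
    id: Optional[str] = None


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_respondent`: passes iff no violations."""

    violations: list[str]

    @property
    def passed(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy iff valid
        return self.passed


def validate_respondent(
    r: Respondent, gazetteer: Optional[Gazetteer] = None
) -> ValidationReport:
    """Check eligibility, internal consistency and residential completeness.

    Violations are collected and returned, never raised. A record passes iff:
    age ≥ 18; personal-history fields (dx age/type, post-diagnosis behaviors)
    are present exactly when a personal history is reported; residences cover
    [0, age] with no gaps or overlaps; every residence geocodes against the
    gazetteer; and no residence of ≥1 year is marked non-US.
    """
    v: list[str] = []
    if r.age < 18:
        v.append("age under 18")
    if not 1 <= r.fitzpatrick <= 6:
        v.append(f"Fitzpatrick type out of range: {r.fitzpatrick}")
    has_dx = r.dx_age is not None and r.dx_type is not None
    if r.personal_hx:
        if not has_dx:
            v.append("personal history reported without diagnosis age/type")
        if r.behaviors_after is None:
            v.append("personal history reported without post-diagnosis behaviors")
        if r.dx_type is not None and r.dx_type not in CANCER_TYPES:
            v.append(f"unknown diagnosis type: {r.dx_type!r}")
    else:
        if r.dx_age is not None or r.dx_type is not None:
            v.append("diagnosis details present without personal history")
        if r.behaviors_after is not None:
            v.append("post-diagnosis behaviors present without personal history")
    for t in r.family_hx:
        if t not in CANCER_TYPES:
            v.append(f"unknown family-history type: {t!r}")

    # residential history: sort by start age, require exact tiling of [0, age]
    res = sorted(r.residences, key=lambda p: (p.start_age, p.end_age))
    if not res:
        v.append("incomplete residential history: no residences")
    else:
        cursor = 0
        ok = True
        for p in res:
            if p.start_age > cursor:
                v.append(
                    f"incomplete residential history: ages {cursor}-{p.start_age} uncovered"
                )
                ok = False
            elif p.start_age < cursor:
                v.append(
                    f"overlapping residential history at age {p.start_age} ({p.place!r})"
                )
                ok = False
            cursor = max(cursor, p.end_age)
        if ok and cursor < r.age:
            v.append(
                f"incomplete residential history: ages {cursor}-{r.age} uncovered"
            )

    for p in r.residences:
        if NON_US_MARKER in p.place.lower() and p.end_age - p.start_age >= 1:
            v.append(f"non-US residence of >=1 year: {p.place!r}")
            continue
        try:
            geocode(p.place, gazetteer)
        except UnknownPlaceError:
            v.append(f"unresolvable residence: {p.place!r}")

    # epoch coverage: every band overlapping [0, age) exactly once
    seen = [e.age_band for e in r.epochs]
    if len(seen) != len(set(seen)):
        v.append("duplicate exposure epochs")
    for (lo, hi), label in zip(AGE_BANDS, AGE_BAND_LABELS):
        if lo < r.age and label not in seen:
            v.append(f"missing exposure epoch {label}")
    return ValidationReport(v)


# Item tally used by items_presented. The instrument has 17 items in total;
# skip patterns reduce the minimal path to 10:
#   always (10): age, Fitzpatrick, personal history (a compound item whose
#     diagnosis age/type fields appear only when answered yes), family
#     history yes/no, and the six behavior items;
#   +1 family-history type item when a family history is reported;
#   +6 repeated behavior items when a personal history is reported.
# The exposure-epoch and residential-history blocks are dynamic tables
# collected outside the fixed item tally.
_BASE_ITEMS = 10
_FAMILY_TYPE_ITEMS = 1
_REPEATED_BEHAVIOR_ITEMS = 6


def items_presented(r: Respondent) -> int:
    """Number of questionnaire items shown to a respondent after skip logic.

    Lies in [10, 17]: 10 on the minimal path (no personal, no family
    history), 17 on the maximal path (both present).
    """
    n = _BASE_ITEMS
    if r.family_hx:
        n += _FAMILY_TYPE_ITEMS
    if r.personal_hx:
        n += _REPEATED_BEHAVIOR_ITEMS
    return n


def ordinal_codes(b: BehaviorSet) -> dict[str, int]:
    """0-based integer codes for the six behavior items, in category order.

    Protective frequency items (sunscreen, long sleeves, hat, shade) ascend
    with protection (never=0 … always=4); exposure-count items (tanning
    visits, sunburns) ascend with exposure. Factor-score signs depend on this
    convention.
    """
    return {
        "tanning_bed_visits": TANNING_LEVELS.index(b.tanning_bed_visits),
        "blistering_sunburns": BURN_LEVELS.index(b.blistering_sunburns),
        "sunscreen": FREQUENCY_LEVELS.index(b.sunscreen),
        "long_sleeves": FREQUENCY_LEVELS.index(b.long_sleeves),
        "hat": FREQUENCY_LEVELS.index(b.hat),
        "shade_seeking": FREQUENCY_LEVELS.index(b.shade_seeking),
    }
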