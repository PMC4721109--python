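"""Cumulative UV Exposure Score (CUES) engine.

A respondent's lifetime is divided into one-year intervals. Each interval is
assigned (a) annual peak-window sun hours from the exposure epoch containing
that age and (b) the average annual UV index of the anchor city nearest the
residence occupied at the start of that age-year. The score is

    CUES = Σ over year intervals (hours of exposure × UV index),

formally proportional to W·h/m² but reported unitless as a relative measure,
analogous to the smoking pack-year. For respondents with a skin-cancer
history the score splits exactly into before- and after-diagnosis parts,
with the diagnosis year counted as "before".

Annual hours combine weekday and weekend reports as (5·weekday + 2·weekend)
hours/week × 52 weeks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .anchors import AnchorCity, UVI_HARD_MAX
from .errors import CuesError, ExclusionError, UnknownPlaceError
from .geo import Gazetteer, geocode, nearest_anchor
from .questionnaire import ExposureEpoch, MAX_DAILY_HOURS, Respondent, band_for_age

__all__ = [
    "YearInterval",
    "CuesResult",
    "annual_hours",
    "decompose_lifetime",
    "compute_cues",
    "score_respondent",
    "split_at_diagnosis",
    "annualized_cues",
    "band_classify",
    "default_band_thresholds",
    "quartilize",
]

#: Weeks per year used when annualizing weekly hours.
WEEKS_PER_YEAR = 52
_MAX_ANNUAL_HOURS = MAX_DAILY_HOURS * 366  # generous per-year bound


@dataclass(frozen=True)
class YearInterval:
    """One year of life with its assigned exposure hours and UV index."""

    age_index: int  # 0-based year of life, the half-open year [a, a+1)
    hours: float
    uvi: float
    anchor: Optional[AnchorCity] = None

    def __post_init__(self):
        if self.age_index < 0:
            raise ValueError(f"age_index must be >= 0, got {self.age_index}")
        if not 0.0 <= self.hours <= _MAX_ANNUAL_HOURS:
            raise ValueError(f"annual hours out of range: {self.hours}")
        if not 0.0 <= self.uvi <= UVI_HARD_MAX:
            raise ValueError(f"UV index out of range: {self.uvi}")

    @property
    def dose(self) -> float:
        """Annual UV dose estimate: hours × UVI."""
        return self.hours * self.uvi


@dataclass
class CuesResult:
    """CUES totals with the per-year decomposition behind them."""

    total: float
    total_hours: float
    per_year: list[YearInterval]
    before_dx: Optional[float] = None
    after_dx: Optional[float] = None


def annual_hours(e: ExposureEpoch) -> float:
    """Annual peak-window exposure hours implied by one epoch's daily reports:
    (5·weekday + 2·weekend) × 52."""
    return (5.0 * e.weekday_hours_per_day + 2.0 * e.weekend_hours_per_day) * WEEKS_PER_YEAR


def _epoch_hours_by_band(epochs: Sequence[ExposureEpoch]) -> dict[str, float]:
    out = {}
    for e in epochs:
        if e.age_band in out:
            raise CuesError(f"duplicate exposure epoch {e.age_band}")
        out[e.age_band] = annual_hours(e)
    return out


def decompose_lifetime(
    r: Respondent,
    table: Iterable[AnchorCity],
    gazetteer: Optional[Gazetteer] = None,
    _anchor_cache: Optional[dict] = None,
) -> list[YearInterval]:
    """Decompose a validated respondent into one interval per year of life.

    Produces exactly ``r.age`` intervals (ages 0 … age−1). Each year's hours
    come from its age band's epoch; its UV index from the anchor city nearest
    the residence occupied at the start of the age-year (mid-year moves
    resolve to the earlier residence, which covers the year's start).

    ``_anchor_cache`` lets batch callers reuse place→anchor resolutions.
    """
    anchors = list(table)
    hours_by_band = _epoch_hours_by_band(r.epochs)
    cache = _anchor_cache if _anchor_cache is not None else {}

    # map each age-year to its residence place (residences tile [0, age])
    res = sorted(r.residences, key=lambda p: p.start_age)
    intervals: list[YearInterval] = []
    ri = 0
    for age in range(r.age):
        while ri < len(res) - 1 and age >= res[ri].end_age:
            ri += 1
        place = res[ri].place
        if age < res[ri].start_age or (ri == len(res) - 1 and age >= res[ri].end_age):
            raise CuesError(f"residential history does not cover age {age}")
        if place not in cache:
            try:
                point = geocode(place, gazetteer)
            except UnknownPlaceError as exc:
                raise UnknownPlaceError(place) from exc
            cache[place] = nearest_anchor(point, anchors)
        anchor = cache[place]
        band = band_for_age(age)
        if band not in hours_by_band:
            raise CuesError(f"missing exposure epoch {band} needed for age {age}")
        intervals.append(
            YearInterval(
                age_index=age,
                hours=hours_by_band[band],
                uvi=anchor.annual_uvi,
                anchor=anchor,
            )
        )
    return intervals


def compute_cues(intervals: Sequence[YearInterval]) -> CuesResult:
    """Sum per-year doses into a CUES total (and total exposure hours)."""
    if not intervals:
        raise CuesError("no year intervals")
    total = math.fsum(iv.hours * iv.uvi for iv in intervals)
    total_hours = math.fsum(iv.hours for iv in intervals)
    return CuesResult(total=total, total_hours=total_hours, per_year=list(intervals))


def score_respondent(
    r: Respondent,
    table: Iterable[AnchorCity],
    gazetteer: Optional[Gazetteer] = None,
    _anchor_cache: Optional[dict] = None,
) -> CuesResult:
    """Full scoring: decompose, sum, and split at diagnosis for cases."""
    result = compute_cues(decompose_lifetime(r, table, gazetteer, _anchor_cache))
    if r.personal_hx and r.dx_age is not None:
        result.before_dx, result.after_dx = split_at_diagnosis(result, r.dx_age)
        # redefine the total as the sum of its two halves so conservation
        # (before + after = total) holds bit-exactly; the difference from the
        # single-pass sum is at most one rounding step
        result.total = result.before_dx + result.after_dx
    return result


def split_at_diagnosis(result: CuesResult, dx_age: int) -> tuple[float, float]:
    """Split a score at first skin-cancer diagnosis.

    ``before`` sums intervals with age_index < dx_age (exposure up to and
    including the diagnosis year's start); ``after`` sums the rest. Cases
    first diagnosed before 18 are excluded, mirroring the study rule.
    """
    max_age = max(iv.age_index for iv in result.per_year) + 1
    if dx_age < 18:
        raise ExclusionError(
            f"first skin-cancer diagnosis before age 18 (dx_age={dx_age}) is excluded"
        )
    if dx_age > max_age:
        raise CuesError(f"dx_age {dx_age} exceeds lifetime of {max_age} years")
    before = math.fsum(iv.dose for iv in result.per_year if iv.age_index < dx_age)
    after = math.fsum(iv.dose for iv in result.per_year if iv.age_index >= dx_age)
    return before, after


def annualized_cues(score: float, years: int) -> float:
    """Score per year of the period it accumulated over."""
    if years <= 0:
        raise ValueError(f"years must be positive, got {years}")
    return score / years


# Band thresholds: the published cohort medians (205,379 for respondents
# without a skin-cancer history, 242,074 for those with) rounded to the
# nearest thousand, as in the comparison table distributed with the tool.
_CONTROL_MEDIAN = 205_379.0
_CASE_MEDIAN = 242_074.0


def default_band_thresholds() -> tuple[float, float]:
    """(low, high) = cohort medians rounded to the nearest thousand."""
    low = round(_CONTROL_MEDIAN / 1000.0) * 1000.0
    high = round(_CASE_MEDIAN / 1000.0) * 1000.0
    return low, high


def band_classify(
    score: float, low: Optional[float] = None, high: Optional[float] = None
) -> int:
    """Compare a score with the study cohort: band 1 below the no-history
    median, band 3 above the skin-cancer median, band 2 between.

    Bands are half-open: band 1 is score < low, band 2 is low ≤ score ≤ high,
    band 3 is score > high, so every score falls in exactly one band.
    """
    d_low, d_high = default_band_thresholds()
    low = d_low if low is None else low
    high = d_high if high is None else high
    if not low < high:
        raise ValueError(f"band thresholds must satisfy low < high, got {low}, {high}")
    if score < low:
        return 1
    if score <= high:
        return 2
    return 3


def quartilize(scores: Sequence[float]) -> np.ndarray:
    """Sample-quartile labels 1–4 per score.

    Cut points use the averaged-inverted-cdf quantile definition (the
    SAS-compatible "type 2" rule); a score equal to a cut point falls in the
    lower quartile, so fully tied data all land in quartile 1. On distinct
    data with n divisible by 4 the groups are exactly equal-sized.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.ndim != 1 or arr.size < 4:
        raise CuesError(f"need at least 4 scores to quartilize, got {arr.size}")
    cuts = np.quantile(arr, [0.25, 0.5, 0.75], method="averaged_inverted_cdf")
    labels = np.ones(arr.size, dtype=int)
    for c in cuts:
        labels += (arr > c).astype(int)
    return labels
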