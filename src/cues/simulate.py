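"""Synthetic respondent cohorts with the statistical structure of the study.

The generator emulates the survey cohort: ages truncated-normal around 46
(SD 15) on [18, 81]; roughly 13% with a personal skin-cancer history;
Fitzpatrick types at the published cohort frequencies; multi-residence
histories sampled as piecewise-constant paths over gazetteer cities with a
Poisson number of moves; epoch-wise peak-window exposure hours; and
diagnosis-triggered shifts toward protective behavior (ordinal upshift of
protective items, fewer tanning visits and sunburns, and a multiplicative
reduction of exposure hours in epochs starting after diagnosis).

Case status is sampled from a logistic model in the cohort CUES quartile, a
family-history indicator and a latent protection score, with the intercept
calibrated so the expected prevalence matches the target. The latent
quantities behind each draw are recoverable via :func:`ground_truth` for
parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
from scipy.optimize import brentq
from scipy.special import expit

from .anchors import AnchorCity, load_anchor_table
from .errors import CuesError
from .geo import load_gazetteer, nearest_anchor, normalize_place
from .questionnaire import (
    AGE_BANDS,
    AGE_BAND_LABELS,
    BURN_LEVELS,
    CANCER_TYPES,
    FREQUENCY_LEVELS,
    TANNING_LEVELS,
    BehaviorSet,
    ExposureEpoch,
    ResidencePeriod,
    Respondent,
)
from .scoring import WEEKS_PER_YEAR, quartilize

__all__ = ["CohortParams", "generate_cohort", "ground_truth"]

#: Fitzpatrick type frequencies in the full study cohort (types 4-6 split
#: within the published pooled 23%).
DEFAULT_FITZPATRICK_PROBS = (0.0716, 0.3846, 0.3131, 0.1300, 0.0700, 0.0307)

#: Per-band (weekday mean, weekend mean) daily peak-window hours; childhood
#: and adolescence carry more outdoor time. SD applies to both.
DEFAULT_EPOCH_HOURS = {
    "0-13": (2.5, 3.5),
    "13-20": (2.0, 3.0),
    "20-40": (1.5, 2.5),
    "40-65": (1.5, 2.5),
    "65-80": (1.5, 2.0),
    "80+": (1.0, 1.5),
}

_DX_TYPE_PROBS = (0.62, 0.13, 0.11, 0.05, 0.09)  # BCC, SCC, melanoma, other, don't know
#: Age at first skin-cancer diagnosis in the emulated cohort (mean, SD),
#: truncated to [18, current age].
DX_AGE_MEAN, DX_AGE_SD = 51.4, 13.8


@dataclass
class CohortParams:
    """Parameters of the synthetic cohort generator."""

    n: int = 1000
    age_mean: float = 46.0
    age_sd: float = 15.0
    age_range: tuple[int, int] = (18, 81)
    prevalence: float = 0.13
    fitzpatrick_probs: Sequence[float] = DEFAULT_FITZPATRICK_PROBS
    move_rate: float = 2.0
    epoch_hour_dist: dict = field(default_factory=lambda: dict(DEFAULT_EPOCH_HOURS))
    epoch_hour_sd: float = 1.0
    risk_log_or_per_cues_quartile: float = 0.3
    family_log_or: float = 1.1
    factor_log_or: float = -0.5
    family_hx_rate: float = 0.33
    behavior_shift_after_dx: float = 1.0
    post_dx_hours_factor: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise CuesError("cohort size must be >= 1")
        if not 0.0 <= self.prevalence < 1.0:
            raise CuesError(f"prevalence must lie in [0, 1), got {self.prevalence}")
        probs = np.asarray(self.fitzpatrick_probs, dtype=float)
        if probs.size != 6 or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-6:
            raise CuesError("fitzpatrick_probs must be 6 non-negative values summing to 1")
        if self.move_rate < 0 or self.epoch_hour_sd < 0:
            raise CuesError("rates and spreads must be non-negative")
        if not 0.0 <= self.post_dx_hours_factor <= 1.0:
            raise CuesError("post_dx_hours_factor must lie in [0, 1]")
        lo, hi = self.age_range
        if not 18 <= lo < hi:
            raise CuesError(f"age_range must satisfy 18 <= lo < hi, got {self.age_range}")


def _ordinal_from_latent(rng, center: float, slope_u: float, u: float, n_levels: int) -> int:
    raw = center + slope_u * u + rng.normal(0.0, 0.9)
    return int(np.clip(round(raw), 0, n_levels - 1))


def _behaviors_from_latent(rng, u: float) -> BehaviorSet:
    return BehaviorSet(
        tanning_bed_visits=TANNING_LEVELS[
            _ordinal_from_latent(rng, 0.9, -0.6, u, len(TANNING_LEVELS))
        ],
        blistering_sunburns=BURN_LEVELS[
            _ordinal_from_latent(rng, 1.3, -0.7, u, len(BURN_LEVELS))
        ],
        sunscreen=FREQUENCY_LEVELS[_ordinal_from_latent(rng, 2.0, 0.9, u, 5)],
        long_sleeves=FREQUENCY_LEVELS[_ordinal_from_latent(rng, 2.0, 0.9, u, 5)],
        hat=FREQUENCY_LEVELS[_ordinal_from_latent(rng, 1.8, 0.9, u, 5)],
        shade_seeking=FREQUENCY_LEVELS[_ordinal_from_latent(rng, 2.0, 0.9, u, 5)],
    )


def _shift_protective(b: BehaviorSet, shift: int) -> BehaviorSet:
    """Post-diagnosis behavior change: protective items up, exposure items down."""
    up = lambda levels, v: levels[min(len(levels) - 1, levels.index(v) + shift)]
    down = lambda levels, v: levels[max(0, levels.index(v) - shift)]
    return BehaviorSet(
        tanning_bed_visits=down(TANNING_LEVELS, b.tanning_bed_visits),
        blistering_sunburns=down(BURN_LEVELS, b.blistering_sunburns),
        sunscreen=up(FREQUENCY_LEVELS, b.sunscreen),
        long_sleeves=up(FREQUENCY_LEVELS, b.long_sleeves),
        hat=up(FREQUENCY_LEVELS, b.hat),
        shade_seeking=up(FREQUENCY_LEVELS, b.shade_seeking),
    )


def _uvi_by_place(
    places: Sequence[str], gazetteer: dict, anchors: Sequence[AnchorCity]
) -> dict[str, float]:
    out = {}
    for place in places:
        pt = gazetteer[normalize_place(place)]
        out[place] = nearest_anchor(pt, anchors).annual_uvi
    return out


def _annual_hours_by_age(epoch_hours: dict[str, tuple[float, float]], max_age: int) -> np.ndarray:
    """Annual hours per age-year 0..max_age-1 given per-band daily hours."""
    hours = np.empty(max_age)
    for (lo, hi), label in zip(AGE_BANDS, AGE_BAND_LABELS):
        hi_eff = max_age if hi is None else min(hi, max_age)
        if lo >= max_age:
            continue
        wk, we = epoch_hours[label]
        hours[lo:hi_eff] = (5.0 * wk + 2.0 * we) * WEEKS_PER_YEAR
    return hours


def _generate(p: CohortParams):
    p.validate()
    rng = np.random.default_rng(p.seed)
    lo, hi = p.age_range
    gazetteer = load_gazetteer()
    anchors = load_anchor_table()
    # display-form place names, deterministic order
    places = sorted({k.title().rsplit(", ", 1)[0] + ", " + k.rsplit(", ", 1)[1].upper()
                     for k in gazetteer})
    uvi_of = _uvi_by_place(places, gazetteer, anchors)

    a, b = (lo - p.age_mean) / p.age_sd, (hi + 1 - p.age_mean) / p.age_sd
    ages = np.floor(
        sps.truncnorm.rvs(a, b, loc=p.age_mean, scale=p.age_sd, size=p.n, random_state=rng)
    ).astype(int)
    ages = np.clip(ages, lo, hi)
    fitz = rng.choice(np.arange(1, 7), size=p.n, p=np.asarray(p.fitzpatrick_probs, float))
    u = rng.normal(0.0, 1.0, size=p.n)  # latent protection score
    fam = rng.random(p.n) < p.family_hx_rate

    subjects = []
    dose_rows = []
    for i in range(p.n):
        age = int(ages[i])
        n_moves = rng.poisson(p.move_rate)
        move_ages = np.unique(rng.integers(1, age, size=n_moves)) if n_moves and age > 1 else []
        bounds = [0, *move_ages, age]
        residences = [
            ResidencePeriod(
                place=places[rng.integers(len(places))],
                start_age=int(bounds[j]),
                end_age=int(bounds[j + 1]),
            )
            for j in range(len(bounds) - 1)
        ]
        epoch_hours = {
            label: (
                float(np.clip(rng.normal(wm, p.epoch_hour_sd), 0.0, 6.0)),
                float(np.clip(rng.normal(em, p.epoch_hour_sd), 0.0, 6.0)),
            )
            for label, (wm, em) in p.epoch_hour_dist.items()
        }
        behaviors = _behaviors_from_latent(rng, u[i])
        uvi_year = np.empty(age)
        for r in residences:
            uvi_year[r.start_age:r.end_age] = uvi_of[r.place]
        hours_year = _annual_hours_by_age(epoch_hours, age)
        subjects.append(
            {
                "id": f"S{i:05d}",
                "age": age,
                "fitz": int(fitz[i]),
                "fam": bool(fam[i]),
                "residences": residences,
                "epoch_hours": epoch_hours,
                "behaviors": behaviors,
                "uvi_year": uvi_year,
                "hours_year": hours_year,
            }
        )
        dose_rows.append(float(np.dot(uvi_year, hours_year)))

    cues_total = np.asarray(dose_rows)
    quart = quartilize(cues_total)
    lp_partial = (
        p.risk_log_or_per_cues_quartile * (quart - 1)
        + p.family_log_or * fam.astype(float)
        + p.factor_log_or * u
    )
    if p.prevalence == 0.0:
        prob = np.zeros(p.n)
    else:
        f = lambda alpha: expit(alpha + lp_partial).mean() - p.prevalence
        alpha = brentq(f, -30.0, 30.0)
        prob = expit(alpha + lp_partial)
    is_case = rng.random(p.n) < prob

    respondents: list[Respondent] = []
    truth_rows = []
    for i, s in enumerate(subjects):
        age = s["age"]
        dx_age = None
        dx_type = None
        behaviors_after = None
        epoch_hours = s["epoch_hours"]
        hours_year = s["hours_year"]
        if is_case[i]:
            a = (18 - DX_AGE_MEAN) / DX_AGE_SD
            b = (age + 1 - DX_AGE_MEAN) / DX_AGE_SD
            dx_age = int(
                np.clip(
                    np.floor(
                        sps.truncnorm.rvs(
                            a, b, loc=DX_AGE_MEAN, scale=DX_AGE_SD, random_state=rng
                        )
                    ),
                    18,
                    age,
                )
            )
            dx_type = CANCER_TYPES[rng.choice(len(CANCER_TYPES), p=_DX_TYPE_PROBS)]
            shift = int(rng.poisson(p.behavior_shift_after_dx))
            behaviors_after = _shift_protective(s["behaviors"], shift)
            # exposure falls in epochs beginning at/after diagnosis
            reduced = {}
            for (blo, bhi), label in zip(AGE_BANDS, AGE_BAND_LABELS):
                wk, we = epoch_hours[label]
                if blo >= dx_age:
                    wk, we = wk * p.post_dx_hours_factor, we * p.post_dx_hours_factor
                reduced[label] = (wk, we)
            epoch_hours = reduced
            hours_year = _annual_hours_by_age(epoch_hours, age)
        doses = hours_year * s["uvi_year"]
        epochs = [
            ExposureEpoch(label, wk, we) for label, (wk, we) in epoch_hours.items()
        ]
        respondents.append(
            Respondent(
                id=s["id"],
                age=age,
                fitzpatrick=s["fitz"],
                personal_hx=bool(is_case[i]),
                dx_age=dx_age,
                dx_type=dx_type,
                behaviors_before=s["behaviors"],
                behaviors_after=behaviors_after,
                family_hx=frozenset({"BCC"}) if s["fam"] else frozenset(),
                epochs=epochs,
                residences=s["residences"],
            )
        )
        truth_rows.append(
            {
                "id": s["id"],
                "is_case": bool(is_case[i]),
                "dx_age": dx_age,
                "latent_cues_total": float(cues_total[i]),
                "risk_quartile": int(quart[i]),
                "linear_predictor": float(lp_partial[i]),
                "case_prob": float(prob[i]),
                "latent_protection": float(u[i]),
                "true_cues": float(doses.sum()),
                "annual_doses": doses,
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("id")
    return respondents, truth


def generate_cohort(p: CohortParams) -> list[Respondent]:
    """Generate a cohort of synthetic respondents, deterministic under
    ``p.seed``."""
    respondents, _ = _generate(p)
    return respondents


def ground_truth(p: CohortParams, cohort: Sequence[Respondent]) -> pd.DataFrame:
    """Latent per-subject values behind a cohort generated by this module.

    Columns include the sampled case probability and linear predictor, the
    latent protection score, the risk quartile, and the true per-year doses
    whose sum equals the engine-computed CUES exactly. A cohort that was not
    produced by :func:`generate_cohort` with these parameters is rejected.
    """
    regenerated, truth = _generate(p)
    if len(regenerated) != len(cohort) or any(
        a.id != b.id or a.age != b.age or a.personal_hx != b.personal_hx
        for a, b in zip(regenerated, cohort)
    ):
        raise CuesError("cohort was not generated with these parameters")
    return truth
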