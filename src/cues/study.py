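"""Batch scoring and the matched case-control study pipeline.

``run_score`` validates and scores a stream of respondents, reporting
rejected records with their reasons instead of aborting the batch (partial
failure is normal: the original cohort retained 99.8% of submissions).

``run_full_study`` reproduces the study's analysis plan on a cohort:
bivariate summaries; 1:2 age matching of cases (age at first diagnosis) to
controls (age at survey) by propensity score; quartilized CUES as the
predictor of interest in conditional logistic regression, univariate and
adjusted for family history and the one-factor behavior score; and, among
cases, before/after-diagnosis comparisons (annualized CUES by signed-rank
test, behavior items by Bowker's test of symmetry).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .anchors import AnchorCity, load_anchor_table
from .errors import CuesError, ExclusionError
from .geo import Gazetteer, load_gazetteer
from .questionnaire import Respondent, ordinal_codes, validate_respondent
from .scoring import annualized_cues, band_classify, quartilize, score_respondent
from .stats import (
    MatchedSet,
    bowker_test,
    conditional_logistic,
    icc_agreement,
    one_factor_scores,
    percent_absolute_agreement,
    propensity_age_match,
    rank_tests,
    weighted_kappa,
)

logger = logging.getLogger(__name__)

__all__ = ["run_score", "StudyResult", "run_full_study", "retest_reliability"]


def run_score(
    respondents: Iterable[Respondent],
    anchors: Optional[Sequence[AnchorCity]] = None,
    gazetteer: Optional[Gazetteer] = None,
    band_low: Optional[float] = None,
    band_high: Optional[float] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate, score and band each respondent.

    Returns ``(report, rejections)``: one report row per valid respondent
    (id, total, before/after-diagnosis split, total hours, cohort band) and
    one rejection row per invalid record with its violations. The inclusion
    fraction is logged.
    """
    anchors = list(anchors) if anchors is not None else load_anchor_table()
    gazetteer = gazetteer if gazetteer is not None else load_gazetteer()
    cache: dict = {}
    rows, rejects = [], []
    for i, r in enumerate(respondents):
        ident = r.id if r.id is not None else f"record-{i}"
        report = validate_respondent(r, gazetteer)
        if not report.passed:
            rejects.append({"id": ident, "violations": "; ".join(report.violations)})
            continue
        try:
            res = score_respondent(r, anchors, gazetteer, _anchor_cache=cache)
        except (CuesError, ExclusionError) as exc:
            rejects.append({"id": ident, "violations": str(exc)})
            continue
        rows.append(
            {
                "id": ident,
                "cues_total": res.total,
                "cues_before_dx": res.before_dx,
                "cues_after_dx": res.after_dx,
                "total_hours": res.total_hours,
                "band": band_classify(
                    res.before_dx if res.before_dx is not None else res.total,
                    band_low,
                    band_high,
                ),
            }
        )
    n = len(rows) + len(rejects)
    if n == 0:
        logger.warning("empty respondent stream")
    else:
        logger.info("scored %d/%d records (%.1f%% included)", len(rows), n, 100 * len(rows) / max(n, 1))
    report_df = pd.DataFrame(
        rows, columns=["id", "cues_total", "cues_before_dx", "cues_after_dx", "total_hours", "band"]
    )
    reject_df = pd.DataFrame(rejects, columns=["id", "violations"])
    return report_df, reject_df


@dataclass
class StudyResult:
    """Tables produced by :func:`run_full_study`."""

    summary: pd.DataFrame
    sets: list[MatchedSet]
    unadjusted: pd.DataFrame
    adjusted: pd.DataFrame
    before_after: pd.DataFrame
    factor_retained: bool
    n_cases: int
    n_controls: int


_BEHAVIOR_FIELDS = (
    "tanning_bed_visits",
    "sunscreen",
    "long_sleeves",
    "hat",
    "shade_seeking",
    "blistering_sunburns",
)
_BEHAVIOR_LEVELS = {
    "tanning_bed_visits": 5,
    "blistering_sunburns": 4,
    "sunscreen": 5,
    "long_sleeves": 5,
    "hat": 5,
    "shade_seeking": 5,
}


def _factor_matrix(respondents: Sequence[Respondent]) -> np.ndarray:
    rows = []
    for r in respondents:
        codes = ordinal_codes(r.behaviors_before)
        rows.append(
            [
                codes["hat"],
                codes["long_sleeves"],
                codes["shade_seeking"],
                codes["sunscreen"],
                r.fitzpatrick - 1,
                codes["blistering_sunburns"],
                codes["tanning_bed_visits"],
            ]
        )
    return np.asarray(rows, dtype=float)


def run_full_study(
    cohort: Sequence[Respondent],
    anchors: Optional[Sequence[AnchorCity]] = None,
    gazetteer: Optional[Gazetteer] = None,
    ratio: int = 2,
    seed: int = 0,
) -> StudyResult:
    """Run the full matched case-control analysis on a scored cohort."""
    anchors = list(anchors) if anchors is not None else load_anchor_table()
    gazetteer = gazetteer if gazetteer is not None else load_gazetteer()
    cache: dict = {}

    cases, controls, excluded = [], [], 0
    scores: dict[str, object] = {}
    for i, r in enumerate(cohort):
        if r.id is None:
            r.id = f"R{i:05d}"
        try:
            res = score_respondent(r, anchors, gazetteer, _anchor_cache=cache)
        except ExclusionError:
            excluded += 1  # e.g. first diagnosis before age 18
            continue
        scores[r.id] = res
        (cases if r.personal_hx else controls).append(r)
    if not cases:
        raise CuesError("cohort contains no eligible cases")
    if len(controls) < ratio * len(cases):
        raise CuesError(
            f"insufficient controls for 1:{ratio} matching: "
            f"{len(cases)} cases, {len(controls)} controls"
        )

    # predictor of interest: CUES before diagnosis (cases) / total (controls)
    cues_of = {
        r.id: (scores[r.id].before_dx if r.personal_hx else scores[r.id].total)
        for r in cases + controls
    }

    sets = propensity_age_match(
        [(r.id, r.dx_age) for r in cases],
        [(r.id, r.age) for r in controls],
        ratio=ratio,
        seed=seed,
    )
    matched_ids = [s.case_id for s in sets] + [c for s in sets for c in s.control_ids]
    matched_cues = np.array([cues_of[i] for i in matched_ids])
    quart = dict(zip(matched_ids, quartilize(matched_cues)))

    by_id = {r.id: r for r in cases + controls}
    matrix = _factor_matrix([by_id[i] for i in matched_ids])
    factor = one_factor_scores(matrix)
    factor_scores = (
        dict(zip(matched_ids, factor.scores))
        if factor.retained
        else {i: 0.0 for i in matched_ids}
    )

    cov = pd.DataFrame(
        {
            "cues_q1": [float(quart[i] == 1) for i in matched_ids],
            "cues_q2": [float(quart[i] == 2) for i in matched_ids],
            "cues_q3": [float(quart[i] == 3) for i in matched_ids],
            "family_hx": [float(bool(by_id[i].family_hx)) for i in matched_ids],
            "factor_score": [factor_scores[i] for i in matched_ids],
        },
        index=pd.Index(matched_ids, name="subject_id"),
    )
    unadjusted = conditional_logistic(sets, cov, columns=["cues_q1", "cues_q2", "cues_q3"])
    adj_cols = ["cues_q1", "cues_q2", "cues_q3", "family_hx"]
    if factor.retained:
        adj_cols.append("factor_score")
    adjusted = conditional_logistic(sets, cov, columns=adj_cols)

    # before/after-diagnosis comparisons among cases
    pairs_by_item = {f: [] for f in _BEHAVIOR_FIELDS}
    for r in cases:
        for f in _BEHAVIOR_FIELDS:
            pairs_by_item[f].append(
                (ordinal_codes(r.behaviors_before)[f], ordinal_codes(r.behaviors_after)[f])
            )
    # annualized CUES: signed-rank over cases with at least one post-dx year
    aligned = [
        (
            annualized_cues(scores[r.id].before_dx, r.dx_age),
            annualized_cues(scores[r.id].after_dx, r.age - r.dx_age),
        )
        for r in cases
        if r.age > r.dx_age
    ]
    ba_rows = []
    if len(aligned) >= 2:
        b, a = map(np.asarray, zip(*aligned))
        stat, p = rank_tests(b, a, paired=True)
        ba_rows.append(
            {
                "item": "annual_cues",
                "median_before": float(np.median(b)),
                "median_after": float(np.median(a)),
                "agreement_pct": np.nan,
                "statistic": stat,
                "p": p,
            }
        )
    for f in _BEHAVIOR_FIELDS:
        pairs = pairs_by_item[f]
        k = _BEHAVIOR_LEVELS[f]
        table = np.zeros((k, k))
        for i, j in pairs:
            table[i, j] += 1
        stat, _, p = bowker_test(table)
        ba_rows.append(
            {
                "item": f,
                "median_before": float(np.median([i for i, _ in pairs])),
                "median_after": float(np.median([j for _, j in pairs])),
                "agreement_pct": percent_absolute_agreement(pairs),
                "statistic": stat,
                "p": p,
            }
        )
    before_after = pd.DataFrame(ba_rows).set_index("item")

    case_cues = np.array([cues_of[r.id] for r in cases])
    ctrl_cues = np.array([cues_of[r.id] for r in controls])
    summary = pd.DataFrame(
        {
            "cases": {
                "n": len(cases),
                "age_mean": float(np.mean([r.age for r in cases])),
                "median_cues": float(np.median(case_cues)),
                "family_hx_pct": 100.0 * np.mean([bool(r.family_hx) for r in cases]),
            },
            "controls": {
                "n": len(controls),
                "age_mean": float(np.mean([r.age for r in controls])),
                "median_cues": float(np.median(ctrl_cues)),
                "family_hx_pct": 100.0 * np.mean([bool(r.family_hx) for r in controls]),
            },
        }
    )
    return StudyResult(
        summary=summary,
        sets=sets,
        unadjusted=unadjusted,
        adjusted=adjusted,
        before_after=before_after,
        factor_retained=factor.retained,
        n_cases=len(sets),
        n_controls=len(sets) * ratio,
    )


def retest_reliability(
    first: Sequence[Respondent],
    second: Sequence[Respondent],
    anchors: Optional[Sequence[AnchorCity]] = None,
    gazetteer: Optional[Gazetteer] = None,
) -> pd.DataFrame:
    """Test-retest reliability over two administrations of the questionnaire.

    ``first`` and ``second`` hold the same subjects (paired by id) at the
    two time points. The CUES score gets an intraclass correlation (two-way
    absolute-agreement, single measure); categorical items get a linear
    weighted kappa and percent absolute agreement. Items whose paired table
    degenerates (a single-category margin) are reported with NaN kappa.
    """
    anchors = list(anchors) if anchors is not None else load_anchor_table()
    gazetteer = gazetteer if gazetteer is not None else load_gazetteer()
    second_by_id = {r.id: r for r in second}
    pairs = [(r, second_by_id[r.id]) for r in first if r.id in second_by_id]
    if len(pairs) < 3:
        raise CuesError("need at least 3 paired respondents for reliability")

    cache: dict = {}
    cues_pairs = [
        (
            score_respondent(a, anchors, gazetteer, _anchor_cache=cache).total,
            score_respondent(b, anchors, gazetteer, _anchor_cache=cache).total,
        )
        for a, b in pairs
    ]
    icc, (icc_lo, icc_hi) = icc_agreement(cues_pairs)
    rows = [
        {
            "item": "cues",
            "coefficient": icc,
            "ci_low": icc_lo,
            "ci_high": icc_hi,
            "agreement_pct": np.nan,
            "method": "ICC(A,1)",
        }
    ]

    def _paired_codes(item: str):
        if item == "fitzpatrick":
            return [(a.fitzpatrick - 1, b.fitzpatrick - 1) for a, b in pairs], 6
        if item == "family_hx":
            return [(int(bool(a.family_hx)), int(bool(b.family_hx))) for a, b in pairs], 2
        k = _BEHAVIOR_LEVELS[item]
        return [
            (ordinal_codes(a.behaviors_before)[item], ordinal_codes(b.behaviors_before)[item])
            for a, b in pairs
        ], k

    for item in ("fitzpatrick", "family_hx", *_BEHAVIOR_FIELDS):
        coded, k = _paired_codes(item)
        table = np.zeros((k, k))
        for i, j in coded:
            table[i, j] += 1
        try:
            kappa, (lo, hi) = weighted_kappa(table, weights="linear")
        except CuesError:
            kappa, lo, hi = np.nan, np.nan, np.nan
        rows.append(
            {
                "item": item,
                "coefficient": kappa,
                "ci_low": lo,
                "ci_high": hi,
                "agreement_pct": percent_absolute_agreement(coded),
                "method": "weighted kappa (linear)",
            }
        )
    return pd.DataFrame(rows).set_index("item")
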