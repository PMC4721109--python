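"""Association and reliability statistics for the case-control study design.

Covers: age matching of cases to controls by propensity score (1:2, greedy
nearest-neighbor without replacement), conditional logistic regression over
matched sets, Bowker's test of symmetry for paired categorical items,
weighted kappa and intraclass correlation for test-retest reliability,
percent absolute agreement, Cronbach's alpha, a one-factor principal-axis
scoring of the sun-behavior items, and thin wrappers over the Wilcoxon rank
tests.

Conventions: kappa weights default to linear (Cicchetti-Allison); the ICC is
the two-way, absolute-agreement, single-measure form ICC(A,1); no multiple
testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from statsmodels.discrete.conditional_models import ConditionalLogit

from .errors import ConvergenceError, CuesError

__all__ = [
    "MatchedSet",
    "propensity_age_match",
    "conditional_logistic",
    "bowker_test",
    "weighted_kappa",
    "icc_agreement",
    "percent_absolute_agreement",
    "cronbach_alpha",
    "FactorResult",
    "one_factor_scores",
    "rank_tests",
]


@dataclass(frozen=True)
class MatchedSet:
    """One case with its age-matched controls."""

    case_id: object
    control_ids: tuple
    matching_age: float


# ---------------------------------------------------------------------------
# matching


def propensity_age_match(
    cases: Sequence[tuple],
    controls: Sequence[tuple],
    ratio: int = 2,
    seed: int = 0,
) -> list[MatchedSet]:
    """Match each case to ``ratio`` controls on age via propensity scores.

    ``cases`` and ``controls`` are (id, age) sequences; for cases the age is
    the age at first diagnosis, for controls the age at survey. A
    single-covariate logistic model of case status on age yields the
    propensity score; matching is greedy nearest-neighbor without
    replacement, iterating cases in an order randomized by ``seed``.
    """
    cases = list(cases)
    controls = list(controls)
    if len(controls) < ratio * len(cases):
        raise CuesError(
            f"insufficient controls: need {ratio * len(cases)}, have {len(controls)}"
        )
    if not cases:
        return []
    ages = np.array([a for _, a in cases] + [a for _, a in controls], dtype=float)
    status = np.array([1] * len(cases) + [0] * len(controls))
    X = sm.add_constant(ages)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ps = sm.Logit(status, X).fit(disp=0).predict(X)
    case_ps = ps[: len(cases)]
    ctrl_ps = ps[len(cases):]

    case_age = np.array([a for _, a in cases], dtype=float)
    ctrl_age = np.array([a for _, a in controls], dtype=float)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    available = np.ones(len(controls), dtype=bool)
    sets: list[MatchedSet] = []
    for ci in order:
        d = np.abs(ctrl_ps - case_ps[ci])
        d[~available] = np.inf
        # propensity distances can tie (the score is monotone in the single
        # covariate); break ties by raw age distance, then control index
        d_age = np.abs(ctrl_age - case_age[ci])
        d_age[~available] = np.inf
        picks = np.lexsort((d_age, d))[:ratio]
        if not np.all(np.isfinite(d[picks])):
            raise CuesError("ran out of controls during matching")
        available[picks] = False
        sets.append(
            MatchedSet(
                case_id=cases[ci][0],
                control_ids=tuple(controls[j][0] for j in picks),
                matching_age=float(cases[ci][1]),
            )
        )
    case_order = {cid: i for i, (cid, _) in enumerate(cases)}
    sets.sort(key=lambda s: case_order[s.case_id])
    return sets


# ---------------------------------------------------------------------------
# conditional logistic regression


def matched_long_table(
    sets: Sequence[MatchedSet], covariates: pd.DataFrame
) -> pd.DataFrame:
    """Long-format table for conditional logistic fits: one row per subject
    in a matched set, with ``set_id`` and binary ``case`` columns joined to
    the subject's covariates (``covariates`` is indexed by subject id)."""
    rows = []
    for k, s in enumerate(sets):
        rows.append({"set_id": k, "case": 1, "subject_id": s.case_id})
        for cid in s.control_ids:
            rows.append({"set_id": k, "case": 0, "subject_id": cid})
    long = pd.DataFrame(rows)
    return long.join(covariates, on="subject_id")


def conditional_logistic(
    sets: Sequence[MatchedSet],
    covariates: pd.DataFrame,
    columns: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Conditional (matched-set) logistic regression.

    Maximizes the conditional likelihood over matched sets and returns one
    row per covariate with the coefficient, its standard error, the odds
    ratio exp(coef) and a Wald 95% CI.

    Covariates constant within every set carry no information in the
    conditional likelihood; they are reported with coefficient 0, OR 1 and an
    undefined (NaN) CI rather than fitted.
    """
    if not sets:
        raise CuesError("no matched sets")
    long = matched_long_table(sets, covariates)
    cols = list(columns) if columns is not None else list(covariates.columns)
    if long[cols].isna().any().any():
        raise CuesError("missing covariate values in matched subjects")

    nuniq = long.groupby("set_id")[cols].nunique()
    informative = [c for c in cols if (nuniq[c] > 1).any()]
    rows = []
    if informative:
        model = ConditionalLogit(
            long["case"].to_numpy(),
            long[informative].to_numpy(dtype=float),
            groups=long["set_id"].to_numpy(),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = model.fit(disp=0, maxiter=200)
            except Exception as exc:  # noqa: BLE001 - surfaced as ConvergenceError
                raise ConvergenceError(f"conditional logistic fit failed: {exc}") from exc
        params = np.asarray(fit.params, dtype=float)
        bse = np.asarray(fit.bse, dtype=float)
        if (
            not (np.all(np.isfinite(params)) and np.all(np.isfinite(bse)))
            or np.any(np.abs(params) > 30)
            or np.any(bse > 20)
        ):
            raise ConvergenceError(
                "conditional logistic fit did not converge (possible complete separation)"
            )
        fitted = dict(zip(informative, zip(params, bse)))
    else:
        fitted = {}
    z = sps.norm.ppf(0.975)
    for c in cols:
        if c in fitted:
            b, se = fitted[c]
            rows.append(
                {
                    "covariate": c,
                    "coef": b,
                    "se": se,
                    "odds_ratio": float(np.exp(b)),
                    "ci_low": float(np.exp(b - z * se)),
                    "ci_high": float(np.exp(b + z * se)),
                }
            )
        else:
            rows.append(
                {
                    "covariate": c,
                    "coef": 0.0,
                    "se": np.nan,
                    "odds_ratio": 1.0,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                }
            )
    return pd.DataFrame(rows).set_index("covariate")


# ---------------------------------------------------------------------------
# paired categorical tests and agreement


def _as_square(t) -> np.ndarray:
    arr = np.asarray(t, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise CuesError(f"expected a square table, got shape {arr.shape}")
    if np.any(arr < 0):
        raise CuesError("table counts must be non-negative")
    return arr


def bowker_test(t) -> tuple[float, int, float]:
    """Bowker's chi-square test of symmetry for a k×k paired table.

    statistic = Σ_{i<j} (n_ij − n_ji)² / (n_ij + n_ji) over off-diagonal
    pairs with a positive sum; df = number of such pairs. For k = 2 this is
    McNemar's test. A table with no discordant pairs is degenerate: the
    statistic is 0 on 0 df and p = 1, with a warning.
    """
    n = _as_square(t)
    k = n.shape[0]
    if k < 2:
        raise CuesError("Bowker's test needs a table of size k >= 2")
    stat = 0.0
    df = 0
    for i in range(k):
        for j in range(i + 1, k):
            s = n[i, j] + n[j, i]
            if s > 0:
                stat += (n[i, j] - n[j, i]) ** 2 / s
                df += 1
    if df == 0:
        warnings.warn("no discordant pairs; Bowker's test is degenerate (p = 1)")
        return 0.0, 0, 1.0
    p = float(sps.chi2.sf(stat, df))
    return float(stat), df, p


def _disagreement_weights(k: int, weights: str) -> np.ndarray:
    i, j = np.indices((k, k))
    d = np.abs(i - j) / (k - 1)
    if weights == "linear":
        return d
    if weights == "quadratic":
        return d**2
    raise ValueError(f"weights must be 'linear' or 'quadratic', got {weights!r}")


def weighted_kappa(
    t, weights: str = "linear", alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Weighted kappa for a k×k paired table, with a large-sample CI.

    kappa = 1 − Σ w_ij p_ij / Σ w_ij e_ij with disagreement weights w
    (linear |i−j|/(k−1) by default, quadratic optional) and chance expecteds
    e_ij from the margins. The CI uses the asymptotic variance of the
    weighted kappa (Fleiss, Cohen & Everitt), truncated to [−1, 1].
    """
    n = _as_square(t)
    total = n.sum()
    if total <= 0:
        raise CuesError("table has no observations")
    p = n / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    if np.count_nonzero(r) < 2 or np.count_nonzero(c) < 2:
        raise CuesError("weighted kappa undefined: a margin has a single category")
    k = n.shape[0]
    w = _disagreement_weights(k, weights)
    e = np.outer(r, c)
    denom = float((w * e).sum())
    if denom == 0:
        raise CuesError("weighted kappa undefined: zero expected disagreement")
    kappa = 1.0 - float((w * p).sum()) / denom

    # asymptotic variance via agreement weights v = 1 - w
    v = 1.0 - w
    po = float((v * p).sum())
    pe = float((v * e).sum())
    vi = (v * c[None, :]).sum(axis=1)  # row-wise expected agreement weight
    vj = (v * r[:, None]).sum(axis=0)
    term = (v - np.add.outer(vi, vj) * (1.0 - kappa)) ** 2
    var = ((p * term).sum() - (kappa - pe * (1.0 - kappa)) ** 2) / (
        total * (1.0 - pe) ** 2
    )
    se = float(np.sqrt(max(var, 0.0)))
    z = sps.norm.ppf(1 - alpha / 2)
    lo = max(-1.0, kappa - z * se)
    hi = min(1.0, kappa + z * se)
    return float(kappa), (float(lo), float(hi))


def icc_agreement(
    pairs: Sequence[tuple[float, float]], alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Test-retest ICC: two-way, absolute-agreement, single-measure ICC(A,1).

    ``pairs`` holds (time-1, time-2) scores per subject. The estimate comes
    from the two-way ANOVA decomposition (subjects × occasions) and the CI
    from the F-distribution method of McGraw & Wong. Zero between-subject
    variance yields ICC 0 with a warning.
    """
    Y = np.asarray(pairs, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != 2:
        raise CuesError("pairs must be an n×2 array of (t1, t2) scores")
    n, k = Y.shape
    if n < 3:
        raise CuesError("need at least 3 subjects for the ICC")
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_tot = ((Y - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if ss_tot == 0 or msr <= 1e-15:
        warnings.warn("zero between-subject variance; ICC set to 0")
        return 0.0, (0.0, 0.0)
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # McGraw & Wong CI for ICC(A,1)
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and mse > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    else:
        lo = hi = 1.0
    return float(icc), (float(max(-1.0, lo)), float(min(1.0, hi)))


def percent_absolute_agreement(pairs: Sequence[tuple]) -> float:
    """Percent of pairs whose two responses are identical, as an integer
    percent (for display alongside kappa)."""
    pairs = list(pairs)
    if not pairs:
        raise CuesError("no pairs")
    same = sum(1 for a, b in pairs if a == b)
    return float(round(100.0 * same / len(pairs)))


# ---------------------------------------------------------------------------
# internal consistency and factor scoring


def cronbach_alpha(items, standardized: bool = False) -> float:
    """Cronbach's alpha over a subjects × items matrix.

    Raw form: (k/(k−1))·(1 − Σ var_i / var_total) with the total score's
    variance in the denominator; standardized form uses the mean inter-item
    correlation r̄: k·r̄ / (1 + (k−1)·r̄).
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 2:
        raise CuesError("need at least 2 subjects and 2 items")
    k = X.shape[1]
    if standardized:
        R = np.corrcoef(X, rowvar=False)
        if not np.all(np.isfinite(R)):
            raise CuesError("alpha undefined: an item has zero variance")
        rbar = (R.sum() - k) / (k * (k - 1))
        return float(k * rbar / (1 + (k - 1) * rbar))
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise CuesError("alpha undefined: total score has zero variance")
    return float(k / (k - 1) * (1 - item_vars.sum() / total_var))


@dataclass
class FactorResult:
    """Outcome of the one-factor principal-axis analysis."""

    retained: bool
    eigenvalue: float
    loadings: Optional[np.ndarray] = None
    scoring_coefficients: Optional[np.ndarray] = None
    scores: Optional[np.ndarray] = None


#: Column order expected by one_factor_scores; the first four are the
#: protective-frequency items that define the score's sign.
FACTOR_ITEMS = (
    "hat",
    "long_sleeves",
    "shade_seeking",
    "sunscreen",
    "fitzpatrick",
    "blistering_sunburns",
    "tanning_bed_visits",
)
_N_PROTECTIVE = 4


def one_factor_scores(items, max_iter: int = 200, tol: float = 1e-8) -> FactorResult:
    """One-factor principal-axis scoring of the coded behavior items.

    Columns follow :data:`FACTOR_ITEMS` (hat, long sleeves, shade, sunscreen,
    Fitzpatrick type, sunburns, tanning visits), already ordinal-coded.
    Columns are standardized; principal-axis factoring iterates communalities
    on the correlation matrix. The eigenvalue-1 retention rule is applied to
    the reduced correlation matrix (squared multiple correlations on the
    diagonal), so sampling noise alone cannot retain a factor from
    uncorrelated items; if no eigenvalue exceeds 1 a ``retained=False``
    result is returned. Scores use the regression method. The sign is fixed
    so protective items load positively: a higher factor score means more
    sun-protective behavior.
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(FACTOR_ITEMS):
        raise CuesError(f"expected {len(FACTOR_ITEMS)} item columns {FACTOR_ITEMS}")
    n, k = X.shape
    if n <= k:
        raise CuesError("need more subjects than items")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise CuesError("an item has zero variance")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)

    # communalities initialized at squared multiple correlations
    try:
        h2 = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        h2 = np.full(k, 0.5)
    h2 = np.clip(h2, 0.0, 0.999)
    R_reduced = R.copy()
    np.fill_diagonal(R_reduced, h2)
    eigval = float(np.linalg.eigvalsh(R_reduced)[-1])
    if eigval <= 1.0:
        return FactorResult(retained=False, eigenvalue=eigval)
    loadings = None
    for _ in range(max_iter):
        Rh = R.copy()
        np.fill_diagonal(Rh, h2)
        vals, vecs = np.linalg.eigh(Rh)
        lam, vec = vals[-1], vecs[:, -1]
        loadings = vec * np.sqrt(max(lam, 0.0))
        new_h2 = np.clip(loadings**2, 0.0, 0.999)
        if np.max(np.abs(new_h2 - h2)) < tol:
            h2 = new_h2
            break
        h2 = new_h2
    if loadings[: _N_PROTECTIVE].mean() < 0:
        loadings = -loadings
    coef = np.linalg.solve(R, loadings)  # regression-method scoring weights
    scores = Z @ coef
    return FactorResult(
        retained=True,
        eigenvalue=eigval,
        loadings=loadings,
        scoring_coefficients=coef,
        scores=scores,
    )


# ---------------------------------------------------------------------------
# rank tests (thin delegation)


def rank_tests(x, y, paired: bool = False) -> tuple[float, float]:
    """Wilcoxon rank-sum (unpaired) or signed-rank (paired) test.

    Delegates to scipy (`mannwhitneyu` / `wilcoxon`). Identical paired
    samples return statistic 0 with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise CuesError("empty input to rank test")
    if paired:
        if x.size != y.size:
            raise CuesError("paired samples must have equal length")
        if np.all(x == y):
            return 0.0, 1.0
        res = sps.wilcoxon(x, y)
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
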