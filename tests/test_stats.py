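import numpy as np
import pandas as pd
import pytest

from cues.errors import ConvergenceError, CuesError
from cues.stats import (
    MatchedSet,
    bowker_test,
    conditional_logistic,
    cronbach_alpha,
    icc_agreement,
    one_factor_scores,
    percent_absolute_agreement,
    propensity_age_match,
    rank_tests,
    weighted_kappa,
)


class TestMatching:
    def test_exact_age_controls_matched_exactly(self):
        cases = [(f"c{i}", 40 + i) for i in range(5)]
        controls = [(f"k{i}{j}", 40 + i) for i in range(5) for j in range(3)]
        sets = propensity_age_match(cases, controls, ratio=2, seed=1)
        ages = dict(controls)
        for s in sets:
            assert all(ages[c] == s.matching_age for c in s.control_ids)

    def test_set_counts_and_no_replacement(self):
        rng = np.random.default_rng(3)
        cases = [(f"c{i}", int(a)) for i, a in enumerate(rng.integers(30, 70, 149))]
        controls = [(f"k{i}", int(a)) for i, a in enumerate(rng.integers(25, 75, 400))]
        sets = propensity_age_match(cases, controls, ratio=2, seed=0)
        assert len(sets) == 149
        used = [c for s in sets for c in s.control_ids]
        assert len(used) == 298 and len(set(used)) == 298

    def test_seed_determinism(self):
        cases = [(f"c{i}", 40 + i % 7) for i in range(20)]
        controls = [(f"k{i}", 38 + i % 10) for i in range(60)]
        assert propensity_age_match(cases, controls, seed=9) == propensity_age_match(
            cases, controls, seed=9
        )

    def test_insufficient_controls(self):
        with pytest.raises(CuesError, match="insufficient"):
            propensity_age_match([("c", 40)], [("k", 40)], ratio=2)


def _paired_sets(exposures):
    """Build 1:1 sets with given (case_x, control_x) binary exposures."""
    sets, cov = [], {}
    for k, (xc, xk) in enumerate(exposures):
        sets.append(MatchedSet(f"c{k}", (f"k{k}",), 50.0))
        cov[f"c{k}"], cov[f"k{k}"] = float(xc), float(xk)
    return sets, pd.DataFrame({"x": pd.Series(cov)})


class TestConditionalLogistic:
    def test_no_discordance_gives_or_one(self):
        sets, cov = _paired_sets([(1, 1)] * 10 + [(0, 0)] * 10)
        res = conditional_logistic(sets, cov)
        assert res.loc["x", "coef"] == 0.0
        assert res.loc["x", "odds_ratio"] == 1.0

    def test_paired_binary_or_equals_discordant_ratio(self):
        # 30 (case exposed, control not) vs 15 reversed -> OR = 2
        sets, cov = _paired_sets(
            [(1, 0)] * 30 + [(0, 1)] * 15 + [(1, 1)] * 20 + [(0, 0)] * 20
        )
        res = conditional_logistic(sets, cov)
        assert res.loc["x", "odds_ratio"] == pytest.approx(30 / 15, rel=1e-4)

    def test_complete_separation_raises(self):
        sets, cov = _paired_sets([(1, 0)] * 25)
        with pytest.raises(ConvergenceError):
            conditional_logistic(sets, cov)

    def test_ci_coverage_of_true_or(self):
        """1:2 sets generated under a conditional OR of 2.0; the Wald CI
        should cover it in at least 90% of replicates."""
        beta = np.log(2.0)
        rng = np.random.default_rng(2024)
        n_sets, reps, covered = 500, 200, 0
        for _ in range(reps):
            x = rng.integers(0, 2, size=(n_sets, 3)).astype(float)
            w = np.exp(beta * x)
            pick = (rng.random(n_sets)[:, None] < (w.cumsum(1) / w.sum(1)[:, None])).argmax(1)
            sets, cov = [], {}
            for k in range(n_sets):
                members = [f"s{k}m{j}" for j in range(3)]
                sets.append(
                    MatchedSet(members[pick[k]], tuple(m for j, m in enumerate(members) if j != pick[k]), 50.0)
                )
                for j, m in enumerate(members):
                    cov[m] = x[k, j]
            res = conditional_logistic(sets, pd.DataFrame({"x": pd.Series(cov)}))
            if res.loc["x", "ci_low"] <= 2.0 <= res.loc["x", "ci_high"]:
                covered += 1
        assert covered / reps >= 0.90


class TestBowker:
    def test_symmetric_table_statistic_zero(self):
        t = np.array([[5, 3, 2], [3, 8, 4], [2, 4, 9]])
        stat, df, p = bowker_test(t)
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_reduces_to_mcnemar_for_2x2(self):
        t = np.array([[10, 7], [3, 12]])
        stat, df, p = bowker_test(t)
        assert stat == pytest.approx((7 - 3) ** 2 / (7 + 3))
        assert df == 1

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.contingency_tables import SquareTable

        rng = np.random.default_rng(8)
        t = rng.integers(0, 25, size=(5, 5)).astype(float)
        stat, df, p = bowker_test(t)
        oracle = SquareTable(t, shift_zeros=False).symmetry(method="bowker")
        assert stat == pytest.approx(oracle.statistic, abs=1e-10)
        assert p == pytest.approx(oracle.pvalue, abs=1e-10)

    def test_invariant_under_simultaneous_permutation(self):
        rng = np.random.default_rng(9)
        t = rng.integers(0, 20, size=(4, 4)).astype(float)
        perm = rng.permutation(4)
        stat1, _, _ = bowker_test(t)
        stat2, _, _ = bowker_test(t[np.ix_(perm, perm)])
        assert stat1 == pytest.approx(stat2, abs=1e-10)

    def test_degenerate_diagonal_table(self):
        with pytest.warns(UserWarning, match="degenerate"):
            stat, df, p = bowker_test(np.diag([4, 5, 6]))
        assert (stat, df, p) == (0.0, 0, 1.0)


def _hand_weighted_kappa(t, quadratic=False):
    """Independent textbook evaluation with explicit loops."""
    t = np.asarray(t, float)
    n = t.sum()
    k = t.shape[0]
    po = pe = 0.0
    for i in range(k):
        for j in range(k):
            d = abs(i - j) / (k - 1)
            w = 1 - (d**2 if quadratic else d)
            po += w * t[i, j] / n
            pe += w * t[i].sum() * t[:, j].sum() / n**2
    return (po - pe) / (1 - pe)


class TestWeightedKappa:
    def test_perfect_agreement(self):
        k, (lo, hi) = weighted_kappa(np.diag([10, 20, 30]))
        assert k == pytest.approx(1.0)

    def test_chance_agreement_is_zero(self):
        r = np.array([0.2, 0.5, 0.3])
        c = np.array([0.4, 0.4, 0.2])
        t = 200 * np.outer(r, c)
        k, _ = weighted_kappa(t)
        assert k == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("weights", ["linear", "quadratic"])
    def test_matches_hand_formula_and_sklearn(self, weights):
        from sklearn.metrics import cohen_kappa_score

        t = np.array([[20, 5, 1], [3, 15, 4], [0, 2, 10]], float)
        k, _ = weighted_kappa(t, weights)
        assert k == pytest.approx(_hand_weighted_kappa(t, weights == "quadratic"), abs=1e-10)
        y1 = [i for i in range(3) for j in range(3) for _ in range(int(t[i, j]))]
        y2 = [j for i in range(3) for j in range(3) for _ in range(int(t[i, j]))]
        assert k == pytest.approx(cohen_kappa_score(y1, y2, weights=weights), abs=1e-10)

    def test_range_and_diagonal_characterization(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            t = rng.integers(0, 15, size=(4, 4)).astype(float)
            t += np.diag(rng.integers(1, 10, 4))  # ensure both margins populated
            k, (lo, hi) = weighted_kappa(t)
            assert -1.0 <= lo <= k <= hi <= 1.0
            if k == 1.0:
                assert np.all(t == np.diag(np.diag(t)))

    def test_single_category_margin_errors(self):
        with pytest.raises(CuesError):
            weighted_kappa(np.array([[10, 0], [0, 0]], float))


def _hand_icc_a1(Y):
    """ANOVA-decomposition oracle computed with explicit sums."""
    Y = np.asarray(Y, float)
    n, k = Y.shape
    grand = Y.mean()
    msr = k * sum((Y[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((Y[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (Y[i, j] - Y[i].mean() - Y[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_pairs_give_one(self):
        x = np.arange(10.0)
        icc, (lo, hi) = icc_agreement(np.column_stack([x, x]))
        assert icc == pytest.approx(1.0)

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(21)
        t1 = rng.normal(0, 1, 1000)
        t2 = t1 + rng.normal(0, 50, 1000)  # retest dominated by noise
        icc, _ = icc_agreement(np.column_stack([t1, t2]))
        assert abs(icc) < 0.05

    def test_six_subject_dataset_matches_anova_oracle(self):
        Y = np.array([[9, 2], [1, 10], [8, 8], [2, 6], [10, 6], [6, 4]], float)
        icc, _ = icc_agreement(Y)
        assert icc == pytest.approx(_hand_icc_a1(Y), abs=1e-8)

    def test_matches_pingouin(self):
        import pingouin as pg

        rng = np.random.default_rng(42)
        Y = rng.normal(10, 3, size=(15, 1)) + rng.normal(0, 1, size=(15, 2))
        icc, (lo, hi) = icc_agreement(Y)
        long = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(15), 2),
                "rater": np.tile([0, 1], 15),
                "y": Y.ravel(),
            }
        )
        row = pg.intraclass_corr(long, "subj", "rater", "y").set_index("Type").loc["ICC(A,1)"]
        assert icc == pytest.approx(row.ICC, abs=1e-8)
        assert (lo, hi) == pytest.approx(tuple(row.CI95), abs=5e-3)

    def test_zero_between_subject_variance(self):
        with pytest.warns(UserWarning):
            icc, _ = icc_agreement(np.ones((5, 2)))
        assert icc == 0.0


class TestAgreementAndAlpha:
    @pytest.mark.parametrize(
        "pairs,expected",
        [
            ([(1, 1), (2, 2)], 100.0),
            ([(1, 2), (2, 3)], 0.0),
            ([(1, 1), (2, 3)], 50.0),
        ],
    )
    def test_percent_agreement(self, pairs, expected):
        assert percent_absolute_agreement(pairs) == expected

    def test_alpha_duplicated_items_is_one(self):
        x = np.random.default_rng(1).normal(size=100)
        X = np.column_stack([x, x, x])
        assert cronbach_alpha(X) == pytest.approx(1.0)

    def test_alpha_independent_items_near_zero(self):
        X = np.random.default_rng(2).normal(size=(5000, 6))
        assert abs(cronbach_alpha(X)) < 0.05
        assert abs(cronbach_alpha(X, standardized=True)) < 0.05

    def test_standardized_two_item_closed_form(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        y = 0.6 * x + rng.normal(size=500)
        X = np.column_stack([x, y])
        r = np.corrcoef(x, y)[0, 1]
        assert cronbach_alpha(X, standardized=True) == pytest.approx(2 * r / (1 + r), abs=1e-12)

    def test_alpha_degenerate_errors(self):
        with pytest.raises(CuesError):
            cronbach_alpha(np.ones((10, 3)))


class TestOneFactor:
    def test_single_latent_recovered(self):
        rng = np.random.default_rng(0)
        latent = rng.normal(size=800)
        X = latent[:, None] + 0.05 * rng.normal(size=(800, 7))
        res = one_factor_scores(X)
        assert res.retained
        assert abs(np.corrcoef(res.scores, latent)[0, 1]) > 0.99
        assert res.loadings[:4].mean() > 0  # protective items load positively

    def test_uncorrelated_items_retain_nothing(self):
        X = np.random.default_rng(1).normal(size=(1000, 7))
        res = one_factor_scores(X)
        assert not res.retained
        assert res.scores is None

    def test_sign_flip_of_inputs_flips_scores(self):
        rng = np.random.default_rng(5)
        latent = rng.normal(size=300)
        X = latent[:, None] + 0.1 * rng.normal(size=(300, 7))
        a = one_factor_scores(X)
        b = one_factor_scores(-X)
        assert np.allclose(a.scores, -b.scores, atol=1e-8)


class TestRankTests:
    def test_identical_paired_samples(self):
        x = np.arange(10.0)
        assert rank_tests(x, x, paired=True) == (0.0, 1.0)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 100)
        y = rng.normal(3, 1, 100)
        _, p = rank_tests(x, y)
        assert p < 1e-3

    def test_type_i_error_near_nominal(self):
        rng = np.random.default_rng(12)
        rejections = 0
        reps = 400
        for _ in range(reps):
            x = rng.normal(size=25)
            y = rng.normal(size=25)
            _, p = rank_tests(x, y)
            rejections += p < 0.05
        assert 0.02 <= rejections / reps <= 0.08

    def test_empty_inputs(self):
        with pytest.raises(CuesError):
            rank_tests([], [1.0])
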