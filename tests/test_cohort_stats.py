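"""Contingency tests, Mann-Whitney, odds ratios and ROC arithmetic."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats as sps

from spatialtme import (ConfigError, ContingencyTable, ValidationError,
                        build_contingency, categorical_test, chi2_test,
                        dichotomize, fisher_exact_2x2, mann_whitney,
                        median_iqr, odds_ratio_2x2, roc_curve, univariate_or)


class TestContingency:
    def test_build_from_clinical_table(self):
        df = pd.DataFrame({
            "histology": ["SCC"] * 4 + ["ADC"] * 3,
            "MPR": [1, 1, 0, 0, 1, 0, 0],
            "regimen": ["NAIC", "NAIC", "NAC", "NAIC", "NAC", "NAC", "NAIC"],
        })
        ct = build_contingency(df, "MPR", "histology", row_order=[1, 0],
                               col_order=["SCC", "ADC"])
        assert ct.counts.tolist() == [[2, 1], [2, 2]]
        sub = build_contingency(df, "MPR", "histology",
                                {"regimen": "NAIC"}, row_order=[1, 0],
                                col_order=["SCC", "ADC"])
        assert sub.counts.tolist() == [[2, 0], [1, 1]]

    def test_empty_filter_errors(self):
        df = pd.DataFrame({"a": [1], "b": [2]})
        with pytest.raises(ConfigError, match="matches no patients"):
            build_contingency(df, "a", "b", {"a": 99})

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValidationError):
            chi2_test([[0, 0], [5, 5]])


class TestChi2:
    def test_independence_gives_p_one(self):
        res = chi2_test([[10, 10], [10, 10]])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_yates_never_exceeds_pearson(self, rng):
        for _ in range(50):
            t = rng.integers(1, 40, (2, 2))
            yates = chi2_test(t, correction="on").statistic
            plain = chi2_test(t, correction="off").statistic
            assert yates <= plain + 1e-12

    def test_transposition_invariance(self, rng):
        for _ in range(25):
            t = rng.integers(1, 40, (2, 3))
            a, b = chi2_test(t), chi2_test(t.T)
            assert a.p == pytest.approx(b.p) and a.df == b.df

    def test_rxc_uses_pearson(self):
        res = chi2_test([[5, 10, 3], [8, 2, 9]])
        assert res.method == "pearson_chi2" and res.df == 2


class TestFisher:
    def test_perfect_separation_enumeration(self):
        """[[5,0],[0,5]]: 6 tables share the margins; only the two extreme
        ones have point probability <= observed -> p = 2/C(10,5)."""
        res = fisher_exact_2x2([[5, 0], [0, 5]])
        assert res.p == pytest.approx(2 / 252)

    def test_flat_table_p_one(self):
        assert fisher_exact_2x2([[1, 1], [1, 1]]).p == pytest.approx(1.0)

    def test_two_sided_at_least_one_sided(self, rng):
        for _ in range(25):
            t = rng.integers(0, 15, (2, 2)) + np.array([[1, 0], [0, 1]])
            two = fisher_exact_2x2(t).p
            one = min(sps.fisher_exact(t, alternative="less")[1],
                      sps.fisher_exact(t, alternative="greater")[1])
            assert two >= one - 1e-12

    def test_matches_hypergeometric_enumeration(self, rng):
        """Independent oracle: enumerate every table with the observed
        margins and sum hypergeometric point probabilities <= observed."""
        for _ in range(20):
            t = rng.integers(0, 12, (2, 2)) + 1
            r1, r2 = t.sum(1)
            c1 = t[:, 0].sum()
            n = t.sum()
            p_obs = sps.hypergeom.pmf(t[0, 0], n, r1, c1)
            p = sum(
                sps.hypergeom.pmf(a, n, r1, c1)
                for a in range(max(0, c1 - r2), min(r1, c1) + 1)
                if sps.hypergeom.pmf(a, n, r1, c1) <= p_obs * (1 + 1e-7)
            )
            assert fisher_exact_2x2(t).p == pytest.approx(p, rel=1e-6)


class TestDispatch:
    def test_low_expected_count_goes_to_fisher(self):
        # min expected count 13*11/35 = 4.09 < 5
        assert categorical_test([[9, 13], [2, 11]]).method == "fisher_exact"

    def test_ample_counts_go_to_yates(self):
        assert categorical_test([[23, 23], [13, 45]]).method == "yates_chi2"


def brute_force_mw_p(x, y):
    """Full enumeration of group assignments (independent oracle)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    ranks = sps.rankdata(pooled)
    mu = n1 * (n - n1) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    hits = total = 0
    for idx in itertools.combinations(range(n), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        hits += abs(u - mu) >= abs(u_obs - mu) - 1e-9
    return hits / total


class TestMannWhitney:
    def test_exact_two_and_two(self):
        res = mann_whitney([1, 2], [3, 4], mode="exact")
        assert res.statistic == 0.0
        assert res.p == pytest.approx(2 / 6)

    def test_identical_samples_p_one(self):
        assert mann_whitney([1, 2, 3], [1, 2, 3], mode="exact").p == 1.0

    def test_degenerate_data_warns(self):
        res = mann_whitney([5, 5], [5, 5, 5])
        assert res.p == 1.0 and res.warnings

    def test_asymptotic_u3_sizes_7_4(self):
        """U=3 at sizes (7,4): z = 11/sqrt(28), two-sided p ≈ 0.038."""
        y = [2, 3, 4, 5]
        x = [2.5, 6, 7, 8, 9, 10, 11]  # U for x = 25, i.e. U' = 3
        res = mann_whitney(x, y, mode="asymptotic")
        assert res.p == pytest.approx(2 * sps.norm.sf(11 / math.sqrt(28)),
                                      rel=1e-9)
        assert f"{res.p:.3f}" == "0.038"

    def test_asymptotic_matches_scipy_with_ties(self, rng):
        for _ in range(20):
            x = rng.integers(0, 6, rng.integers(3, 15)).astype(float)
            y = rng.integers(0, 6, rng.integers(3, 15)).astype(float)
            if len(np.unique(np.concatenate([x, y]))) == 1:
                continue
            ours = mann_whitney(x, y, mode="asymptotic")
            ref = sps.mannwhitneyu(x, y, method="asymptotic",
                                   use_continuity=False)
            assert ours.p == pytest.approx(float(ref.pvalue), rel=1e-9)

    def test_exact_equals_enumeration_oracle(self, rng):
        """Both exact branches (recursion, tie enumeration) against the
        brute-force permutation oracle for n1+n2 <= 10."""
        for tie in (False, True):
            for _ in range(15):
                n1, n2 = rng.integers(2, 6, 2)
                if tie:
                    x = rng.integers(0, 4, n1).astype(float)
                    y = rng.integers(0, 4, n2).astype(float)
                    if len(np.unique(np.concatenate([x, y]))) == 1:
                        continue
                else:
                    vals = rng.permutation(np.arange(n1 + n2, dtype=float))
                    x, y = vals[:n1], vals[n1:]
                res = mann_whitney(x, y, mode="exact")
                assert res.p == pytest.approx(brute_force_mw_p(x, y))

    def test_auto_dispatch(self):
        small = mann_whitney([1, 2, 3], [4, 5, 6], mode="auto")
        assert small.method == "mw_exact"
        big = mann_whitney(list(range(10)), list(range(10, 23)), mode="auto")
        assert big.method == "mw_asymptotic"
        tied = mann_whitney([1, 1, 2], [2, 3, 4], mode="auto")
        assert tied.method == "mw_asymptotic"


class TestSummaries:
    @pytest.mark.parametrize("vals, expected", [
        ([1, 2, 3, 4, 5], (3, 2, 4)),
        ([7], (7, 7, 7)),
        ([1, 2, 3, 4], (2.5, 1.75, 3.25)),
    ])
    def test_median_iqr_linear(self, vals, expected):
        assert median_iqr(vals) == pytest.approx(expected)

    def test_haverage_convention(self):
        # (n+1)p positions: Q1 at 1.25 -> 1.25, Q3 at 3.75 -> 3.75
        med, q1, q3 = median_iqr([1, 2, 3, 4], convention="haverage")
        assert (med, q1, q3) == pytest.approx((2.5, 1.25, 3.75))

    def test_dichotomize_median_rule(self):
        assert dichotomize([1, 2, 3, 4]).tolist() == \
            ["low", "low", "high", "high"]
        assert dichotomize([1, 2, 3, 4, 5]).tolist() == \
            ["low", "low", "high", "high", "high"]  # tie at cut -> high

    def test_dichotomize_constant_errors(self):
        with pytest.raises(ValidationError):
            dichotomize([5, 5, 5])

    def test_dichotomize_explicit_threshold(self):
        assert dichotomize([1, 9], rule=5.0).tolist() == ["low", "high"]


class TestOddsRatio:
    def test_cross_product_36(self):
        res = odds_ratio_2x2([[6, 1], [1, 6]])
        assert res.odds_ratio == pytest.approx(36.0)
        se = math.sqrt(1 / 6 + 1 + 1 + 1 / 6)
        assert res.ci_lower == pytest.approx(36 * math.exp(-1.96 * se))
        assert res.ci_upper == pytest.approx(36 * math.exp(1.96 * se))
        assert not res.corrected

    def test_null_table(self):
        res = odds_ratio_2x2([[5, 5], [5, 5]])
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_lower < 1 < res.ci_upper

    def test_zero_cell_haldane_corrected(self):
        res = odds_ratio_2x2([[6, 0], [1, 6]])
        assert res.corrected and np.isfinite(res.odds_ratio)
        assert res.odds_ratio == pytest.approx((6.5 * 6.5) / (0.5 * 1.5))

    def test_from_labels_matches_statsmodels(self):
        import statsmodels.api as sm
        pred = ["low"] * 7 + ["high"] * 7
        out = [1] * 6 + [0] + [1] + [0] * 6
        res = univariate_or(pred, out, predictor_positive="low",
                            outcome_positive=1)
        assert res.odds_ratio == pytest.approx(36.0)
        t22 = sm.stats.Table2x2(np.array([[6, 1], [1, 6]]))
        assert res.odds_ratio == pytest.approx(t22.oddsratio)
        lo, hi = t22.oddsratio_confint()
        # statsmodels uses z = 1.959964; we use the conventional 1.96
        assert (res.ci_lower, res.ci_upper) == pytest.approx((lo, hi),
                                                             rel=1e-3)

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValidationError):
            univariate_or(["low", "high"], [1, 1], outcome_positive=1)


class TestRoc:
    def test_perfect_separation(self):
        res = roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0

    def test_all_scores_equal_auc_half(self):
        res = roc_curve([5, 5, 5, 5], [0, 1, 0, 1])
        assert res.auc == pytest.approx(0.5)

    def test_constructed_three_discordant_pairs(self):
        """7 positives, 4 negatives, exactly 3 discordant pairs, no ties:
        AUC = 25/28, Youden point sens 6/7 / spec 1.0."""
        scores = [2.5, 6, 7, 8, 9, 10, 11] + [2, 3, 4, 5]
        labels = [1] * 7 + [0] * 4
        res = roc_curve(scores, labels)
        assert res.auc == pytest.approx(25 / 28)
        assert res.sensitivity == pytest.approx(6 / 7)
        assert res.specificity == 1.0
        assert not res.flipped

    def test_orientation_flip_recorded(self):
        res = roc_curve([1, 2, 3, 10, 11], [1, 1, 1, 0, 0])
        assert res.flipped and res.auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_curve([1, 2], [1, 1])

    @given(hst.integers(0, 2 ** 31 - 1))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_auc_identities(self, seed):
        """Trapezoidal AUC equals the concordance U-statistic; AUC is
        invariant under strictly increasing transforms; AUC(s)+AUC(-s)=1."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        scores = np.round(rng.normal(size=n), 1)  # rounding creates ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        pos, neg = scores[labels == 1], scores[labels == 0]
        diff = pos[:, None] - neg[None, :]
        u_auc = ((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size
        res = roc_curve(scores, labels)
        expected = max(u_auc, 1 - u_auc)  # orientation auto-flip
        assert res.auc == pytest.approx(expected, abs=1e-12)
        mono = roc_curve(np.exp(scores), labels)
        assert mono.auc == pytest.approx(res.auc, abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        for _ in range(10):
            n = int(rng.integers(6, 50))
            scores = rng.normal(size=n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            ours = roc_curve(scores, labels)
            ref = roc_auc_score(labels, scores)
            assert ours.auc == pytest.approx(max(ref, 1 - ref), abs=1e-12)
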