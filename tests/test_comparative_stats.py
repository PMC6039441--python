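"""Overlap enrichment, proportion contrasts, ANOVA/Tukey and caste labels."""

import math

import numpy as np
import pytest
import scipy.stats

from mksel.comparative_stats import (
    CasteLabel,
    classify_caste_bias,
    compare_two_proportions,
    gamma_by_class,
    overlap_fisher,
    positive_fraction,
    threeway_overlap_test,
    tukey_kramer,
)
from mksel.io_formats import ExpressionRow


def hypergeom_upper_tail(n_universe, n_a, n_b, overlap):
    """Oracle: exhaustive sum P(X >= overlap) for X ~ Hypergeom."""
    kmax = min(n_a, n_b)
    total = math.comb(n_universe, n_b)
    s = sum(
        math.comb(n_a, k) * math.comb(n_universe - n_a, n_b - k)
        for k in range(overlap, kmax + 1)
    )
    return s / total


class TestCasteClassification:
    def test_queen_biased_rule(self):
        rows = [ExpressionRow("g", 0.01, 5.0, 1.2)]
        assert classify_caste_bias(rows)[0].label == "queen_biased"

    def test_high_fdr_is_nondeg_regardless_of_fpkm(self):
        rows = [ExpressionRow("g", 0.2, 50.0, 0.1)]
        assert classify_caste_bias(rows)[0].label == "non_deg"

    def test_fpkm_threshold_strict(self):
        # biased direction must exceed 1 FPKM
        rows = [ExpressionRow("g", 0.01, 1.0, 0.2)]
        assert classify_caste_bias(rows)[0].label == "non_deg"

    def test_worker_symmetric(self):
        rows = [ExpressionRow("g", 0.001, 0.5, 8.0)]
        assert classify_caste_bias(rows)[0].label == "worker_biased"


class TestOverlapFisher:
    def test_matches_exhaustive_enumeration(self):
        universe = {f"g{i}" for i in range(100)}
        ids = sorted(universe)
        set_a, set_b = set(ids[:30]), set(ids[18:38])  # overlap 12
        res = overlap_fisher(set_a, set_b, universe)
        assert res.contingency_table[0][0] == 12
        assert res.p_value == pytest.approx(
            hypergeom_upper_tail(100, 30, 20, 12), rel=1e-9
        )

    @pytest.mark.parametrize("n,na,nb", [(40, 12, 9), (60, 25, 18), (25, 5, 5)])
    def test_enumeration_grid(self, n, na, nb):
        ids = [f"g{i}" for i in range(n)]
        universe = set(ids)
        rng = np.random.default_rng(n)
        set_a = set(rng.choice(ids, na, replace=False))
        set_b = set(rng.choice(ids, nb, replace=False))
        res = overlap_fisher(set_a, set_b, universe)
        k = len(set_a & set_b)
        assert res.p_value == pytest.approx(
            hypergeom_upper_tail(n, na, nb, k), rel=1e-9
        )

    def test_independence_scale_overlap_not_enriched(self):
        # overlap exactly |A||B|/N: no enrichment signal
        universe = {f"g{i}" for i in range(100)}
        ids = sorted(universe)
        set_a = set(ids[:50])
        set_b = set(ids[25:75])  # overlap 25 = 50*50/100
        res = overlap_fisher(set_a, set_b, universe)
        assert res.p_value > 0.5

    def test_empty_set_flagged(self):
        universe = {"a", "b"}
        res = overlap_fisher(set(), {"a"}, universe)
        assert res.odds_ratio is None and res.p_value == 1.0


class TestTwoProportions:
    def test_chi2_closed_form_identity(self):
        k1, n1, k2, n2 = 22, 114, 32, 287
        a, b, c, d = k1, n1 - k1, k2, n2 - k2
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        stat, _ = compare_two_proportions(k1, n1, k2, n2, method="chisq")
        assert stat == pytest.approx(closed, rel=1e-12)

    def test_wasp_caste_contrast_yates_near_printed_value(self):
        # 22/114 vs 32/287 with continuity correction: chi2 ~ 4.0, p ~ 0.046
        stat, p = compare_two_proportions(22, 114, 32, 287, method="chisq_yates")
        assert stat == pytest.approx(3.98, abs=0.01)
        assert p == pytest.approx(0.046, abs=0.001)

    def test_equal_proportions_zero_statistic(self):
        stat, p = compare_two_proportions(10, 40, 5, 20, method="chisq")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_tiny_symmetric_fisher(self):
        _, p = compare_two_proportions(1, 2, 1, 2, method="fisher")
        assert p == pytest.approx(1.0)

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            compare_two_proportions(5, 4, 1, 2)


class TestThreeWayOverlap:
    def test_full_universe_trivial(self):
        u = {f"g{i}" for i in range(50)}
        obs, exp, chi2, p = threeway_overlap_test(u, u, u, u)
        assert obs == exp == 50
        assert chi2 == 0.0 and p == 1.0

    def test_statistic_grows_with_enrichment(self):
        ids = [f"g{i}" for i in range(1000)]
        u = set(ids)
        chis = []
        for core_size in (10, 30, 60):
            core = set(ids[:core_size])
            rng = np.random.default_rng(core_size)
            others = ids[core_size:]
            sets = [
                core | set(rng.choice(others, 150 - core_size, replace=False))
                for _ in range(3)
            ]
            chis.append(threeway_overlap_test(*sets, u)[2])
        assert chis[0] < chis[1] < chis[2]

    def test_type_one_error_calibrated(self):
        # independent memberships: rejection rate at alpha=0.05 should sit
        # near nominal over 1000 seeded replicates
        rng = np.random.default_rng(99)
        n, p_member = 1000, 0.3
        genes = np.arange(n)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            m = rng.random((3, n)) < p_member
            sets = [set(genes[m[i]]) for i in range(3)]
            _, _, chi2, p = threeway_overlap_test(*sets, set(genes))
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07


class TestGammaByClass:
    def _labels(self, sizes):
        out = []
        i = 0
        for lab, k in zip(("queen_biased", "worker_biased", "non_deg"), sizes):
            for _ in range(k):
                out.append(CasteLabel(f"g{i}", lab))
                i += 1
        return out

    def test_identical_values_zero_F(self):
        labels = self._labels((5, 5, 5))
        gamma = {f"g{i}": 0.7 for i in range(15)}
        res = gamma_by_class(gamma, labels)
        assert res["anova_F"] == 0.0 and res["anova_p"] == 1.0

    def test_anova_type_one_error_calibrated(self):
        rng = np.random.default_rng(17)
        labels = self._labels((40, 60, 100))
        reps, rejections = 1000, 0
        for _ in range(reps):
            gamma = {f"g{i}": float(x) for i, x in enumerate(rng.normal(0.5, 0.2, 200))}
            res = gamma_by_class(gamma, labels)
            rejections += res["anova_p"] < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_tukey_kramer_matches_statsmodels(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(23)
        groups = [rng.normal(0, 1, 30), rng.normal(0.5, 1, 55), rng.normal(0.2, 1, 80)]
        ours = tukey_kramer(groups)
        data = np.concatenate(groups)
        lab = np.repeat([0, 1, 2], [30, 55, 80])
        sm = pairwise_tukeyhsd(data, lab)
        for (i, j, diff, p), p_sm in zip(ours, sm.pvalues):
            assert p == pytest.approx(p_sm, abs=1e-8)

    def test_tukey_kramer_reduces_to_classic_tukey_equal_sizes(self):
        rng = np.random.default_rng(29)
        groups = [rng.normal(m, 1, 25) for m in (0.0, 0.3, 0.6)]
        ours = {(i, j): p for i, j, _, p in tukey_kramer(groups)}
        # classic Tukey: q = |mean_i - mean_j| / sqrt(MSW / n_per_group)
        k, n_per = 3, 25
        means = [g.mean() for g in groups]
        msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / (3 * 25 - 3)
        for (i, j), p in ours.items():
            q = abs(means[i] - means[j]) / np.sqrt(msw / n_per)
            p_classic = scipy.stats.studentized_range.sf(q, k, 3 * 25 - 3)
            assert p == pytest.approx(p_classic, abs=1e-10)

    def test_power_detects_planted_queen_shift(self):
        # queen mean shifted by +0.15 at study-like group sizes and spreads
        # (sigma = SEM * sqrt(n)); the queen vs non-DEG Tukey contrast
        # should be significant in at least 80% of replicates
        rng = np.random.default_rng(31)
        labels = self._labels((114, 287, 7211))
        hits = 0
        reps = 50
        for _ in range(reps):
            vals = np.concatenate([
                rng.normal(0.481 + 0.15, 0.527, 114),  # sem 0.0493 * sqrt(114)
                rng.normal(0.481, 0.454, 287),         # sem 0.0268 * sqrt(287)
                rng.normal(0.481, 0.439, 7211),        # sem 0.00517 * sqrt(7211)
            ])
            gamma = {f"g{i}": float(v) for i, v in enumerate(vals)}
            res = gamma_by_class(gamma, labels)
            hits += res["tukey_p"][("queen_biased", "non_deg")] < 0.05
        assert hits / reps >= 0.8


class TestPositiveFraction:
    @pytest.mark.parametrize(
        "k,n,expected",
        [(22, 114, 19.3), (32, 287, 11.1), (58, 185, 31.4), (34, 192, 17.7),
         (0, 10, 0.0)],
    )
    def test_rounding_half_up_one_decimal(self, k, n, expected):
        labels = [CasteLabel(f"g{i}", "queen_biased") for i in range(n)]
        positive = {f"g{i}" for i in range(k)}
        out = positive_fraction(labels, positive)
        assert out["queen_biased"] == (k, n, expected)

    def test_label_permutation_invariant(self):
        labels = [CasteLabel(f"g{i}", "worker_biased") for i in range(20)]
        positive = {f"g{i}" for i in range(0, 20, 3)}
        a = positive_fraction(labels, positive)
        b = positive_fraction(labels[::-1], positive)
        assert a == b
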