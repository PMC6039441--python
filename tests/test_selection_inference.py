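"""PRF math, classic MK statistics and the hierarchical fit."""

import math

import numpy as np
import pytest

from mksel.mk_tables import MKTable
from mksel.selection_inference import (
    ModelConfig,
    classify_positive,
    effect_from_gamma,
    fit_hierarchical_mk,
    gamma_from_effect,
    mk_fisher,
    neutrality_stats,
    per_gene_prf_mle,
    prf_H,
    prf_Q,
    prf_Qratio,
)
from mksel.synthetic_data import SimulationTruth, simulate_mk_counts


def fisher_enumeration(dn, ds, pn, ps):
    """Exact hypergeometric enumeration over all tables with fixed margins."""
    n_total = dn + ds + pn + ps
    r1, c1 = dn + ds, dn + pn
    kmin, kmax = max(0, r1 + c1 - n_total), min(r1, c1)
    weights = {
        k: math.comb(c1, k) * math.comb(n_total - c1, r1 - k)
        for k in range(kmin, kmax + 1)
    }
    total = sum(weights.values())
    obs = weights[dn]
    p_two = sum(w for w in weights.values() if w <= obs) / total
    p_one = sum(w for k, w in weights.items() if k >= dn) / total
    return p_two, p_one


class TestPrfMath:
    def test_H_at_zero_is_one_by_continuity(self):
        assert prf_H(0.0) == 1.0
        assert prf_H(1e-9) == pytest.approx(1.0, abs=1e-8)

    def test_H_reflection_identity(self):
        # H(g)/H(-g) = e^g
        for g in (0.5, 3.0, 10.0):
            assert prf_H(g) / prf_H(-g) == pytest.approx(np.exp(g), rel=1e-12)

    def test_H_of_two(self):
        assert prf_H(2.0) == pytest.approx(2.0 / (1.0 - np.exp(-2.0)), rel=1e-12)

    def test_Qratio_at_zero_is_one(self):
        assert prf_Qratio(0.0, 20) == 1.0

    def test_Q_matches_riemann_sum_oracle(self):
        # midpoint Riemann sum with 10^6 points as an independent quadrature
        x = (np.arange(1_000_000) + 0.5) / 1_000_000
        for g in (-5.0, 0.0, 1.7, 8.0):
            sfs = (1 - x**20 - (1 - x) ** 20) / (x * (1 - x))
            if g == 0:
                sel = 1 - x
            else:
                sel = np.expm1(-g * (1 - x)) / np.expm1(-g)
            riemann = float(np.mean(sel * sfs))
            assert prf_Q(g, 20) == pytest.approx(riemann, rel=1e-6)

    def test_link_monotone_increasing_in_gamma(self):
        grid = np.linspace(-20, 20, 81)
        vals = [effect_from_gamma(g, 20) for g in grid]
        assert np.all(np.diff(vals) > 0)

    def test_gamma_round_trip_to_1e8(self):
        for g in np.linspace(-20, 20, 41):
            S = effect_from_gamma(float(g), 20)
            assert gamma_from_effect(S, 20) == pytest.approx(float(g), abs=1e-8)

    def test_effect_monotone_maps_to_monotone_gamma(self):
        s_grid = np.linspace(-3, 3, 25)
        g = [gamma_from_effect(float(s), 20) for s in s_grid]
        assert np.all(np.diff(g) > 0)

    def test_zero_effect_is_zero_gamma(self):
        assert gamma_from_effect(0.0, 20) == 0.0

    def test_nonfinite_effect_rejected(self):
        with pytest.raises(ValueError):
            gamma_from_effect(float("nan"), 20)


class TestMkFisher:
    def test_worked_example_against_enumeration(self):
        t = MKTable("g", PN=2, PS=42, DN=7, DS=17)
        odds, p_two, p_one = mk_fisher(t)
        e_two, e_one = fisher_enumeration(7, 17, 2, 42)
        assert p_two == pytest.approx(e_two, rel=1e-9)
        assert p_one == pytest.approx(e_one, rel=1e-9)
        assert p_two == pytest.approx(0.0073, abs=5e-4)

    def test_balanced_table(self):
        odds, p_two, _ = mk_fisher(MKTable("g", PN=5, PS=5, DN=5, DS=5))
        assert odds == pytest.approx(1.0)
        assert p_two == pytest.approx(1.0)

    def test_all_zero_undefined(self):
        assert mk_fisher(MKTable("g")) == (None, None, None)


class TestNeutralityStats:
    def test_worked_example(self):
        ni, alpha = neutrality_stats(MKTable("g", PN=2, PS=42, DN=7, DS=17))
        assert ni == pytest.approx((2 / 42) / (7 / 17), rel=1e-12)
        assert alpha == pytest.approx(1 - ni, rel=1e-12)

    def test_zero_margins_flagged(self):
        assert neutrality_stats(MKTable("g", PN=1, PS=0, DN=2, DS=3)) == (None, None)
        assert neutrality_stats(MKTable("g", PN=1, PS=5, DN=2, DS=0)) == (None, None)

    def test_neutral_simulation_mean_ni_near_one(self):
        truth = SimulationTruth.from_gamma(np.zeros(3000), theta_s=30.0, z=1.0)
        tables, _ = simulate_mk_counts(truth, seed=9)
        nis = [neutrality_stats(t)[0] for t in tables]
        nis = [x for x in nis if x is not None]
        # NI is a ratio of ratios: noisy and slightly biased upward at
        # finite counts, so the tolerance is loose but two-sided
        assert np.mean(nis) == pytest.approx(1.0, abs=0.1)


class TestPerGeneMle:
    def test_recovers_gamma_two_from_expected_counts(self):
        g, n, z, d, theta = 2.0, 20, 1.0, 1.0, 40.0
        table = MKTable(
            "g",
            PS=round(theta),
            PN=round(theta * z * prf_Qratio(g, n)),
            DS=round(theta * d),
            DN=round(theta * d * z * prf_H(g)),
        )
        est = per_gene_prf_mle(table, n, z, d)
        assert est == pytest.approx(2.0, abs=0.2)

    def test_neutral_ratio_gives_zero(self):
        t = MKTable("g", PN=10, PS=10, DN=10, DS=10)
        assert per_gene_prf_mle(t, 20, 1.0, 1.0) == pytest.approx(0.0, abs=0.05)

    def test_zero_ps_flagged(self):
        assert per_gene_prf_mle(MKTable("g", PN=3, DS=2, DN=1), 20, 2.5, 1.0) is None


class TestHierarchicalFit:
    def test_requires_twenty_informative_genes(self):
        tables = [MKTable(f"g{i}", PN=1, PS=1, DN=1, DS=1) for i in range(10)]
        with pytest.raises(ValueError):
            fit_hierarchical_mk(tables, ModelConfig(estimator="empirical_bayes"))

    def test_all_zero_gene_reported_not_dropped(self):
        rng = np.random.default_rng(0)
        tables = [
            MKTable(f"g{i}", *rng.poisson(5, size=4)) for i in range(40)
        ] + [MKTable("empty")]
        est = fit_hierarchical_mk(tables, ModelConfig(estimator="empirical_bayes"))
        assert len(est) == 41
        empty = [e for e in est if e.gene_id == "empty"][0]
        assert not empty.converged and np.isnan(empty.gamma)
        assert not empty.classified_positive

    def test_mcmc_reproducible_bit_for_bit(self, recovery_sim):
        _, tables, _ = recovery_sim
        cfg = ModelConfig(estimator="mcmc", seed=5, chains=2, iterations=400, warmup=200)
        e1 = fit_hierarchical_mk(tables[:100], cfg)
        e2 = fit_hierarchical_mk(tables[:100], cfg)
        assert [e.gamma for e in e1] == [e.gamma for e in e2]
        assert [e.gamma_ci for e in e1] == [e.gamma_ci for e in e2]

    def test_mcmc_converges_when_variances_identified(self):
        # per-gene variation in the nonsyn/syn opportunity keeps sigma_r off
        # its boundary, the regime where split R-hat is meaningful
        rng = np.random.default_rng(21)
        n = 300
        gamma = rng.normal(0, 1.5, n)
        truth = SimulationTruth(
            gamma=gamma,
            theta_s=np.exp(rng.normal(np.log(15), 1.0, n)),
            d=np.full(n, 1.0),
            z=2.5 * np.exp(rng.normal(0, 0.3, n)),
        )
        tables, _ = simulate_mk_counts(truth, seed=21)
        est = fit_hierarchical_mk(tables, ModelConfig(estimator="mcmc", seed=3))
        assert all(e.converged for e in est if np.isfinite(e.gamma))

    def test_estimators_agree_on_recovery_sim(self, recovery_sim, eb_estimates):
        from scipy.stats import spearmanr

        _, tables, _ = recovery_sim
        mcmc = fit_hierarchical_mk(tables, ModelConfig(estimator="mcmc", seed=2))
        g_m = np.array([e.gamma for e in mcmc])
        g_e = np.array([e.gamma for e in eb_estimates])
        fin = np.isfinite(g_m) & np.isfinite(g_e)
        assert spearmanr(g_m[fin], g_e[fin]).statistic > 0.98

    def test_ci_brackets_point_estimate(self, eb_estimates):
        for e in eb_estimates:
            if np.isfinite(e.gamma):
                assert e.gamma_ci[0] <= e.gamma <= e.gamma_ci[1]

    def test_label_symmetry_flips_selection_sign(self):
        # swapping nonsyn and syn counts under z=1 mirrors the model: the
        # mean selection effect changes sign direction
        rng = np.random.default_rng(8)
        truth = SimulationTruth.from_gamma(
            rng.normal(1.0, 0.5, 100), theta_s=20.0, z=1.0
        )
        tables, _ = simulate_mk_counts(truth, seed=8)
        swapped = [
            MKTable(t.gene_id, PN=t.PS, PS=t.PN, DN=t.DS, DS=t.DN) for t in tables
        ]
        cfg = ModelConfig(estimator="empirical_bayes")
        s_orig = np.nanmean([e.S for e in fit_hierarchical_mk(tables, cfg)])
        s_swap = np.nanmean([e.S for e in fit_hierarchical_mk(swapped, cfg)])
        assert s_orig > 0 > s_swap


class TestClassification:
    def test_strict_boundary(self):
        from mksel.selection_inference import SelectionEstimate

        def est(g):
            return SelectionEstimate("g%.2f" % g, 0.0, g, (g - 1, g + 1), 0.5, g > 1)

        assert classify_positive([est(1.0)]) == set()
        assert classify_positive([est(1.01)]) == {"g1.01"}
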