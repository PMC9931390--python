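"""Luria–Delbrück estimator: pmf recursions, MLE, profile CI, rate ratios."""

import math

import numpy as np
import pytest
from scipy import stats

from gemscreen.fluctuation import (FluctuationDesign, FluctuationModel, clone_pmf,
                                   count_pmf, mle_m, mutation_rate, profile_ci,
                                   rate_ratio)
from gemscreen.synthetic import FluctuationSimConfig, simulate_fluctuation


class TestClonePMF:
    def test_full_plating_closed_form(self):
        q = clone_pmf(1.0, 3)
        assert q[0] == 0.0
        np.testing.assert_allclose(q[1:], [1 / 2, 1 / 6, 1 / 12])

    def test_q0_closed_form_half_plating(self):
        # sum_j (1-eps)^j / (j(j+1)) = 1 + (eps/(1-eps)) ln eps
        q = clone_pmf(0.5, 5)
        assert q[0] == pytest.approx(1.0 + math.log(0.5), abs=1e-12)
        assert q[0] == pytest.approx(0.3069, abs=5e-5)

    @pytest.mark.parametrize("eps", [0.5, 1 / 40])
    def test_matches_monte_carlo_thinning(self, eps, rng):
        """Truncated series equals binomial thinning of floor(1/U) clones."""
        u = rng.random(500_000)
        j = np.floor(1.0 / u).astype(np.int64)
        obs = rng.binomial(j, eps)
        kmax = 8
        emp = np.bincount(np.minimum(obs, kmax + 1), minlength=kmax + 2)
        q = clone_pmf(eps, kmax)
        expected = np.append(q, 1.0 - q.sum()) * len(u)
        keep = expected > 5
        chi2 = ((emp[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        crit = stats.chi2.ppf(0.99, keep.sum() - 1)
        assert chi2 < crit

    def test_epsilon_validation(self):
        with pytest.raises(ValueError):
            clone_pmf(0.0, 5)
        with pytest.raises(ValueError):
            clone_pmf(1.2, 5)


class TestCountPMF:
    def test_poisson_zero_class(self):
        p = count_pmf(1.0, 1.0, 5)
        assert p[0] == pytest.approx(math.exp(-1), rel=1e-12)

    def test_recursion_by_hand(self):
        p = count_pmf(1.0, 1.0, 2)
        e = math.exp(-1)
        assert p[1] == pytest.approx(e / 2, rel=1e-12)
        assert p[2] == pytest.approx(0.5 * (e / 3 + e / 4), rel=1e-12)

    def test_plating_consistency_with_classic_recursion(self):
        """At eps=1 the compound recursion equals p_n=(m/n)sum p_i/(n-i+1)."""
        m, nmax = 1.7, 40
        p = count_pmf(m, 1.0, nmax)
        ref = np.zeros(nmax + 1)
        ref[0] = math.exp(-m)
        for n in range(1, nmax + 1):
            ref[n] = (m / n) * sum(ref[i] / (n - i + 1) for i in range(n))
        np.testing.assert_allclose(p, ref, atol=1e-12)

    @pytest.mark.parametrize("m,eps", [(0.5, 1.0), (2.0, 0.25), (4.0, 1 / 40)])
    def test_valid_distribution(self, m, eps):
        p = count_pmf(m, eps, 200)
        assert np.all(p >= 0)
        assert p.sum() <= 1.0 + 1e-12

    def test_simulator_agrees_with_pmf(self):
        """Empirical counts from the generative model match the recursion."""
        cfg = FluctuationSimConfig(mu=2e-8, N0=730, Nt=1e8, epsilon=0.25,
                                   n_cultures=50_000, seed=2)
        counts = simulate_fluctuation(cfg)
        m = cfg.mu * (cfg.Nt - cfg.N0)
        kmax = 12
        p = count_pmf(m, cfg.epsilon, kmax)
        expected = np.append(p, 1 - p.sum()) * cfg.n_cultures
        emp = np.bincount(np.minimum(counts, kmax + 1), minlength=kmax + 2)
        keep = expected > 5
        chi2 = ((emp[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        assert chi2 < stats.chi2.ppf(0.99, keep.sum() - 1)


class TestMLE:
    def test_all_zero_boundary(self):
        assert mle_m([0, 0, 0, 0]).m == 0.0

    def test_analytic_stationary_point(self):
        # logL = -4m + ln m - ln 2 has its maximum at m = 1/4
        res = mle_m([0, 0, 0, 1])
        assert res.m == pytest.approx(0.25, abs=1e-7)

    @pytest.mark.parametrize("counts,eps", [
        ([0, 1, 3, 0, 7], 1.0),
        ([2, 0, 11, 1, 0, 4], 0.5),
        ([0, 0, 1, 0, 2, 0, 0, 5], 1 / 40),
    ])
    def test_matches_grid_search_oracle(self, counts, eps):
        res = mle_m(counts, eps)
        grid = np.arange(1e-4, max(4.0, 4 * res.m), 1e-4)
        ll = [FluctuationModel(counts, eps).loglike(m) for m in grid]
        assert res.m == pytest.approx(grid[int(np.argmax(ll))], abs=1e-3)


class TestProfileCI:
    def test_all_zero_closed_form_upper(self):
        # logL = -C m; 2 C m = chi2_1(0.95) => m = 1.9207 / C
        res = mle_m([0] * 4)
        assert res.ci[0] == 0.0
        assert res.ci[1] == pytest.approx(stats.chi2.ppf(0.95, 1) / (2 * 4), rel=1e-6)

    def test_interval_contains_mle(self):
        res = mle_m([0, 2, 0, 1, 9, 0])
        assert res.ci[0] <= res.m <= res.ci[1]

    def test_coverage_with_plating(self):
        """95% profile CI covers true m in [0.90, 0.99] of simulations."""
        m_true = 2.0
        mu = m_true / (1e8 - 730)
        hits = 0
        n_sims = 100
        for s in range(n_sims):
            cfg = FluctuationSimConfig(mu=mu, N0=730, Nt=1e8, epsilon=1 / 40,
                                       n_cultures=10, seed=s)
            res = FluctuationModel(simulate_fluctuation(cfg), cfg.epsilon).fit()
            hits += res.ci[0] <= m_true <= res.ci[1]
        assert 0.90 <= hits / n_sims <= 0.99


class TestRates:
    DESIGN = FluctuationDesign(N0=730, Nt=1e7, epsilon=1.0, gene_length=1000)

    def test_rate_arithmetic(self):
        res = mle_m([0, 0, 0, 1])
        mu, mu_kb = mutation_rate(res, self.DESIGN)
        assert mu == pytest.approx(0.25 / (1e7 - 730))
        assert mu_kb == pytest.approx(mu)

    def test_gene_length_normalization_is_linear(self):
        res = mle_m([0, 0, 0, 1])
        d500 = FluctuationDesign(N0=730, Nt=1e7, epsilon=1.0, gene_length=500)
        _, kb500 = mutation_rate(res, d500)
        _, kb1000 = mutation_rate(res, self.DESIGN)
        assert kb500 == pytest.approx(2 * kb1000)

    def test_nt_divisor_convention(self):
        res = mle_m([0, 0, 0, 1])
        mu_div, _ = mutation_rate(res, self.DESIGN, divisor="divisions")
        mu_nt, _ = mutation_rate(res, self.DESIGN, divisor="nt")
        assert mu_nt == pytest.approx(0.25 / 1e7)
        assert mu_div > mu_nt

    def test_identical_datasets_ratio_one(self):
        res = mle_m([0, 1, 0, 3])
        out = rate_ratio(res, res, self.DESIGN, self.DESIGN)
        assert out["ratio"] == pytest.approx(1.0)

    def test_zero_denominator_sentinel(self):
        a = mle_m([0, 0, 1, 2])
        b = mle_m([0, 0, 0, 0])
        out = rate_ratio(a, b, self.DESIGN, self.DESIGN)
        assert math.isinf(out["ratio"])

    def test_planted_fivefold_difference_recovered(self):
        """Median estimated ratio of a true 5x rate difference lands in [4, 6.25]."""
        mu_b = 2.0 / 1e8
        ratios = []
        for s in range(12):
            ca = simulate_fluctuation(FluctuationSimConfig(
                mu=5 * mu_b, N0=730, Nt=1e8, epsilon=1.0, n_cultures=60, seed=s))
            cb = simulate_fluctuation(FluctuationSimConfig(
                mu=mu_b, N0=730, Nt=1e8, epsilon=1.0, n_cultures=60, seed=1000 + s))
            d = FluctuationDesign(N0=730, Nt=1e8, epsilon=1.0)
            ratios.append(rate_ratio(mle_m(ca), mle_m(cb), d, d)["ratio"])
        assert 4.0 <= np.median(ratios) <= 6.25


def test_simulator_determinism_and_zero_rate():
    cfg = FluctuationSimConfig(mu=1e-8, seed=7)
    np.testing.assert_array_equal(simulate_fluctuation(cfg), simulate_fluctuation(cfg))
    zero = FluctuationSimConfig(mu=0.0, seed=7)
    assert simulate_fluctuation(zero).sum() == 0
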