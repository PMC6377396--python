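"""One-tailed correlation tests, Bayes factors, partial correlations, sweep."""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

from lbalink.correlations import (
    _log_reduced_likelihood_ratio,
    bf_kendall_negative,
    bf_pearson_negative,
    kendall_one_tailed,
    kendall_tau_sd,
    pearson_one_tailed,
    posterior_sweep,
    residualize,
)


class TestPearson:
    def test_perfect_anticorrelation(self, rng):
        x = rng.normal(size=20)
        res = pearson_one_tailed(x, -x + 5.0)
        assert res.r == pytest.approx(-1.0)
        assert res.p_one_tailed < 1e-10

    def test_p_matches_permutation_oracle(self, rng):
        x = rng.normal(size=20)
        y = -0.5 * x + rng.normal(size=20)
        res = pearson_one_tailed(x, y)
        n_perm = 100_000
        perms = np.array([rng.permutation(y) for _ in range(n_perm)])
        xc = x - x.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        rs = (pc @ xc) / np.sqrt((pc**2).sum(axis=1) * (xc**2).sum())
        p_perm = np.mean(rs <= res.r)
        assert res.p_one_tailed == pytest.approx(p_perm, abs=0.01)

    def test_constant_input_named(self, rng):
        with pytest.raises(ValueError, match="variable y"):
            pearson_one_tailed(rng.normal(size=10), np.ones(10))


class TestKendall:
    def test_strictly_decreasing(self):
        x = np.arange(10.0)
        res = kendall_one_tailed(x, -(x**3))
        assert res.r == pytest.approx(-1.0)

    def test_bruteforce_pair_counts(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        conc = disc = 0
        for i in range(5):
            for j in range(i + 1, 5):
                s = np.sign((x[i] - x[j]) * (y[i] - y[j]))
                conc += s > 0
                disc += s < 0
        res = kendall_one_tailed(x, y)
        assert res.r == pytest.approx((conc - disc) / 10.0)

    def test_symmetry(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        assert kendall_one_tailed(x, y).r == kendall_one_tailed(y, x).r


class TestPearsonBayesFactor:
    def test_null_centered_data_favors_null(self):
        assert bf_pearson_negative(0.0, 126) < 1.0

    def test_quadrature_matches_monte_carlo(self, rng):
        r, n = -0.21, 126
        rho = rng.uniform(-1, 0, 400_000)
        mc = np.exp(_log_reduced_likelihood_ratio(rho, r, n)).mean()
        assert bf_pearson_negative(r, n) == pytest.approx(mc, rel=0.02)

    def test_one_sided_exceeds_two_sided_for_negative_r(self):
        r, n = -0.21, 126
        two, _ = integrate.quad(
            lambda rho: 0.5 * np.exp(_log_reduced_likelihood_ratio(rho, r, n)), -1, 1
        )
        assert bf_pearson_negative(r, n) > two

    def test_matches_pingouin_one_sided(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.normal(size=80)
        y = -0.3 * x + rng.normal(size=80)
        r = float(np.corrcoef(x, y)[0, 1])
        ref = float(pg.corr(x, y, alternative="less")["BF10"].iloc[0])
        assert bf_pearson_negative(r, 80) == pytest.approx(ref, rel=0.01)


class TestKendallBayesFactor:
    def test_null_tau_favors_null(self):
        assert bf_kendall_negative(0.0, 126) < 1.0

    def test_matches_simulation_oracle(self, rng):
        # simulate tau-hat under prior draws and form the same density ratio
        tau, n = -0.13, 126
        sd = kendall_tau_sd(n)
        rho = rng.uniform(-1, 0, 500_000)
        tpop = 2.0 / np.pi * np.arcsin(rho)
        num = norm.pdf(tau, tpop, sd).mean()  # MC average over the prior
        mc = num / norm.pdf(tau, 0.0, sd)
        assert bf_kendall_negative(tau, n) == pytest.approx(mc, rel=0.10)

    def test_monotone_in_effect_size(self):
        vals = [bf_kendall_negative(t, 126) for t in (-0.05, -0.1, -0.15, -0.2)]
        assert np.all(np.diff(vals) > 0)


class TestResidualize:
    def test_exact_fit_gives_zero_residuals(self, rng):
        cov = rng.normal(size=50)
        assert np.allclose(residualize(2.0 * cov + 1.0, cov), 0.0, atol=1e-10)

    def test_ols_identities(self, rng):
        cov = rng.normal(size=50)
        y = cov + rng.normal(size=50)
        res = residualize(y, cov)
        assert res.mean() == pytest.approx(0.0, abs=1e-10)
        assert abs(res @ cov) < 1e-8 * 50

    def test_matches_partial_correlation_formula(self, rng):
        x, y, m = rng.normal(size=(3, 60))
        y = y + 0.5 * m
        x = x + 0.7 * m
        r_part = np.corrcoef(residualize(x, m), residualize(y, m))[0, 1]
        rxy = np.corrcoef(x, y)[0, 1]
        rxm = np.corrcoef(x, m)[0, 1]
        rym = np.corrcoef(y, m)[0, 1]
        closed = (rxy - rxm * rym) / np.sqrt((1 - rxm**2) * (1 - rym**2))
        assert r_part == pytest.approx(closed, abs=1e-10)

    def test_constant_covariate_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            residualize(rng.normal(size=10), np.full(10, 2.0))


class TestPosteriorSweep:
    def _point_draws(self, urgencies):
        # each "posterior" concentrated at a single urgency value
        return [np.full(50, u) for u in urgencies]

    def test_degenerate_posteriors_give_constant_sweep(self, rng):
        urg = rng.uniform(0.8, 2.0, 30)
        ela_log = rng.uniform(0, 3, 30)
        sw = posterior_sweep(self._point_draws(urg), ela_log, n_draws=40, seed=0)
        point_r = np.corrcoef(np.log(urg), ela_log)[0, 1]
        assert np.allclose(sw.r, point_r)
        assert len(sw.r) == 40

    def test_median_r_within_sweep_range(self, rng):
        draws = [rng.uniform(0.5, 2.5, 200) for _ in range(25)]
        ela_log = rng.uniform(0, 3, 25)
        sw = posterior_sweep(draws, ela_log, n_draws=200, seed=1)
        med_r = np.corrcoef(np.log([np.median(d) for d in draws]), ela_log)[0, 1]
        lo, hi = sw.r_range
        assert lo <= med_r <= hi

    def test_seed_determinism(self, rng):
        draws = [rng.uniform(0.5, 2.5, 100) for _ in range(15)]
        ela_log = rng.uniform(0, 3, 15)
        a = posterior_sweep(draws, ela_log, n_draws=30, seed=5)
        b = posterior_sweep(draws, ela_log, n_draws=30, seed=5)
        assert np.array_equal(a.r, b.r) and np.array_equal(a.bf10, b.bf10)
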