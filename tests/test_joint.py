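"""Joint model: prior specs, Savage-Dickey machinery, blocked fits."""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

from lbalink.demcmc import SamplerConfig, run_de_mcmc
from lbalink.joint import (
    JointData,
    JointPriorSpec,
    _bvn_logpdf,
    credible_interval,
    fit_joint,
    fit_partial_joint,
    joint_loglik,
    savage_dickey_bf,
)
from lbalink.synth import GeneratorConfig, generate_study

SMALL_FIT = SamplerConfig(n_chains=9, n_iter=400, burn_in=200, seed=31)


@pytest.fixture(scope="module")
def small_joint_inputs():
    st = generate_study(
        GeneratorConfig(n_participants=14, trials_per_participant=60, true_rho=-0.4, seed=55)
    )
    tables = [st.trial_tables[p] for p in st.participants]
    ela_log = np.log1p(st.latents["ela_count"].to_numpy(dtype=float))
    md = st.latents["md_realized"].to_numpy(dtype=float)
    return tables, ela_log, md


class TestPriorSpec:
    def test_density_at_zero(self):
        assert JointPriorSpec("uniform_onesided").density_at_zero() == 1.0
        assert JointPriorSpec("estimation").density_at_zero() == 0.5
        half = JointPriorSpec("halfnormal_onesided").density_at_zero()
        assert half == pytest.approx(2.0 * norm.pdf(0.0, 0.0, 0.1), rel=1e-4)

    def test_log_prior_support(self):
        for kind in ("uniform_onesided", "halfnormal_onesided"):
            spec = JointPriorSpec(kind)
            assert spec.log_prior_rho(0.2) == -np.inf
            assert np.isfinite(spec.log_prior_rho(-0.2))
        est = JointPriorSpec("estimation")
        assert np.isfinite(est.log_prior_rho(0.2))
        assert est.log_prior_rho(1.2) == -np.inf

    def test_prior_normalized(self):
        for kind in ("uniform_onesided", "halfnormal_onesided", "estimation"):
            spec = JointPriorSpec(kind)
            lo, hi = spec.support
            val, _ = integrate.quad(lambda r: np.exp(spec.log_prior_rho(r)), lo, hi)
            assert val == pytest.approx(1.0, abs=1e-6)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            JointPriorSpec("flat")


class TestJointLoglik:
    def test_rho_zero_factorizes(self, rng):
        zu, ze = rng.normal(size=(2, 40))
        joint = _bvn_logpdf(zu, ze, 0.1, 0.4, 0.8, 1.2, 0.0)
        split = norm.logpdf(zu, 0.1, 0.8) + norm.logpdf(ze, 0.4, 1.2)
        assert np.allclose(joint, split, atol=1e-10)

    def test_participant_permutation_invariance(self, small_joint_inputs):
        tables, ela_log, _ = small_joint_inputs
        data = JointData.from_tables(tables, ela_log, min_trials=10)
        rng = np.random.default_rng(0)
        part = np.stack(
            [
                rng.normal(3, 0.2, (2, len(tables))),
                rng.normal(1, 0.2, (2, len(tables))),
                rng.uniform(0.5, 1.0, (2, len(tables))),
                rng.normal(0.2, 0.1, (2, len(tables))),
                rng.uniform(0.1, 0.15, (2, len(tables))),
            ],
            axis=-1,
        )
        group = np.tile([0.2, 2.0, 0.3, 1.0, -0.3], (2, 1))
        spec = JointPriorSpec("estimation")
        base = joint_loglik(part, group, data, spec)
        perm = rng.permutation(len(tables))
        data_p = JointData.from_tables(
            [tables[i] for i in perm], ela_log[perm], min_trials=10
        )
        permuted = joint_loglik(part[:, perm, :], group, data_p, spec)
        assert np.allclose(base, permuted, atol=1e-8)

    def test_outside_support_is_minus_inf_not_exception(self, small_joint_inputs):
        tables, ela_log, _ = small_joint_inputs
        data = JointData.from_tables(tables, ela_log, min_trials=10)
        part = np.tile([3.0, 1.0, 0.8, 0.2, 0.12], (1, len(tables), 1))
        group = np.array([[0.2, 2.0, -0.3, 1.0, -0.3]])  # sig_u < 0
        assert joint_loglik(part, group, data, JointPriorSpec("estimation"))[0] == -np.inf


class TestSavageDickey:
    def test_known_boundary_density(self, rng):
        # posterior = Normal(-0.4, 0.2) truncated to (-1, 0): the analytic
        # density at rho = 0 gives BF10 = 1 / f(0) under the uniform prior
        from scipy.stats import truncnorm

        mu, sd = -0.4, 0.2
        a, b = (-1 - mu) / sd, (0 - mu) / sd
        draws = truncnorm.rvs(a, b, loc=mu, scale=sd, size=60_000, random_state=rng)
        f0 = truncnorm.pdf(0.0, a, b, loc=mu, scale=sd)
        bf = savage_dickey_bf(draws, JointPriorSpec("uniform_onesided"))
        assert bf == pytest.approx(1.0 / f0, rel=0.10)

    @pytest.mark.parametrize("kind", ["uniform_onesided", "halfnormal_onesided", "estimation"])
    def test_prior_as_posterior_gives_unit_bf(self, kind, rng):
        spec = JointPriorSpec(kind)
        draws = spec.sample_rho(60_000, rng)
        assert savage_dickey_bf(draws, spec) == pytest.approx(1.0, rel=0.10)

    def test_requires_enough_draws(self):
        with pytest.raises(ValueError):
            savage_dickey_bf(np.full(10, -0.2), JointPriorSpec())

    def test_reduced_model_matches_quadrature(self, rng):
        # observed bivariate-normal data with known means/scales: sample rho
        # with the DE machinery, Savage-Dickey BF vs direct 1-D marginal-
        # likelihood quadrature
        # moderate evidence so the posterior keeps visible mass at rho = 0
        # (Savage-Dickey needs draws near the null value)
        n = 50
        true_rho = -0.15
        cov = np.array([[1.0, true_rho], [true_rho, 1.0]])
        z = rng.multivariate_normal([0, 0], cov, size=n)

        def loglik(rho):
            return np.sum(_bvn_logpdf(z[:, 0][None, :], z[:, 1][None, :], 0.0, 0.0, 1.0, 1.0, np.asarray(rho).reshape(-1, 1)), axis=-1)

        spec = JointPriorSpec("uniform_onesided")

        def log_post(x):
            return loglik(x[:, 0]) + spec.log_prior_rho(x[:, 0])

        init = spec.sample_rho((12, 1), np.random.default_rng(1))
        cfg = SamplerConfig(n_chains=12, n_iter=4000, burn_in=1000, seed=2)
        draws, _ = run_de_mcmc(log_post, init, cfg)
        bf_sd = savage_dickey_bf(draws[..., 0], spec)

        ll0 = loglik(np.array([0.0]))[0]
        num, _ = integrate.quad(
            lambda r: np.exp(loglik(np.array([r]))[0] - ll0), -1, 0, limit=200
        )
        bf_quad = num  # uniform prior density 1 on (-1, 0)
        assert bf_sd == pytest.approx(bf_quad, rel=0.10)


class TestCredibleInterval:
    def test_uniform_sample_quantiles(self, rng):
        draws = rng.uniform(-1, 0, 1_000_000)
        lo, hi = credible_interval(draws)
        assert lo == pytest.approx(-0.975, abs=0.005)
        assert hi == pytest.approx(-0.025, abs=0.005)

    def test_constant_and_ordering(self, rng):
        assert credible_interval(np.full(100, -0.3)) == (-0.3, -0.3)
        d = rng.normal(size=1000)
        lo, hi = credible_interval(d)
        assert lo <= np.median(d) <= hi


class TestFitJoint:
    def test_seed_determinism(self, small_joint_inputs):
        tables, ela_log, _ = small_joint_inputs
        a = fit_joint(tables, ela_log, config=SMALL_FIT, min_trials=10, warmup=100)
        b = fit_joint(tables, ela_log, config=SMALL_FIT, min_trials=10, warmup=100)
        assert np.array_equal(a.rho_draws, b.rho_draws)
        assert a.bf10 == b.bf10 and a.ci95 == b.ci95

    def test_draws_respect_prior_support(self, small_joint_inputs):
        tables, ela_log, _ = small_joint_inputs
        res = fit_joint(
            tables,
            ela_log,
            prior=JointPriorSpec("uniform_onesided"),
            config=SMALL_FIT,
            min_trials=10,
            warmup=100,
        )
        assert np.all((res.rho_flat > -1) & (res.rho_flat < 0))
        assert res.ci95[0] <= res.ci95[1]
        assert res.bf10 > 0

    def test_needs_enough_participants_and_trials(self, small_joint_inputs):
        tables, ela_log, _ = small_joint_inputs
        with pytest.raises(ValueError, match=">= 10 participants"):
            fit_joint(tables[:5], ela_log[:5], config=SMALL_FIT)
        with pytest.raises(ValueError, match="trials"):
            fit_joint(tables, ela_log, config=SMALL_FIT, min_trials=100)

    def test_partial_constant_deprivation_matches_marginal(self, small_joint_inputs):
        # a constant covariate carries no variance: the partial model's rho
        # posterior overlaps the marginal one
        tables, ela_log, _ = small_joint_inputs
        marg = fit_joint(
            tables,
            ela_log,
            prior=JointPriorSpec("estimation"),
            config=SMALL_FIT,
            min_trials=10,
            warmup=100,
        )
        part = fit_partial_joint(
            tables,
            ela_log,
            np.full(len(tables), 1.8),
            prior=JointPriorSpec("estimation"),
            config=SMALL_FIT,
            min_trials=10,
            warmup=100,
        )
        lo1, hi1 = marg.ci95
        lo2, hi2 = part.ci95
        assert max(lo1, lo2) < min(hi1, hi2)  # intervals overlap
        assert abs(np.median(marg.rho_flat) - np.median(part.rho_flat)) < 0.35

    def test_simulation_based_calibration_ranks_uniform(self):
        """Scaled SBC: rank of the generating rho within thinned posterior
        draws is approximately uniform across replicates (chi-squared not
        rejected at alpha = 0.01)."""
        from scipy.stats import chisquare

        rng = np.random.default_rng(42)
        ranks = []
        n_rep, L = 20, 50
        for rep in range(n_rep):
            rho_star = float(rng.uniform(-0.95, 0.95))
            cfg = GeneratorConfig(
                n_participants=20,
                trials_per_participant=80,
                true_rho=rho_star,
                rho_md_urg=0.0,
                rho_md_ela=0.0,
                seed=5000 + rep,
            )
            st = generate_study(cfg)
            tables = [st.trial_tables[p] for p in st.participants]
            ela_log = np.log1p(st.latents["ela_count"].to_numpy(dtype=float))
            res = fit_joint(
                tables,
                ela_log,
                prior=JointPriorSpec("estimation"),
                config=SamplerConfig(n_chains=9, n_iter=1000, burn_in=500, seed=6000 + rep),
                min_trials=40,
            )
            thin = res.rho_flat[:: max(1, res.rho_flat.size // L)][:L]
            ranks.append(np.sum(thin < rho_star) / (L + 1))
        hist, _ = np.histogram(ranks, bins=np.linspace(0, 1, 5))
        stat, p = chisquare(hist)
        assert p > 0.01, f"rank histogram {hist}, p = {p:.4f}"

    def test_partial_needs_deprivation(self, small_joint_inputs):
        tables, ela_log, _ = small_joint_inputs
        with pytest.raises(ValueError, match="deprivation"):
            fit_joint(
                tables,
                ela_log,
                prior=JointPriorSpec("estimation", partial=True),
                config=SMALL_FIT,
                min_trials=10,
            )
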