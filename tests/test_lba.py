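"""LBA density, likelihood, and simulator checks against quadrature and
Monte-Carlo oracles."""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

from lbalink.lba import (
    LbaParams,
    accumulator_cdf,
    accumulator_pdf,
    block_loglik,
    read_trial_table,
    simulate_trials,
    trial_loglik,
    urgency,
    write_trial_table,
)


class TestAccumulatorDensity:
    def test_unreachable_threshold_limit(self):
        # at t -> 0 no start point can have reached b
        assert accumulator_pdf(1e-3, b=2.0, A=1.0, v=3.0, s=1.0) < 1e-12
        assert accumulator_cdf(1e-3, b=2.0, A=1.0, v=3.0, s=1.0) < 1e-12

    @pytest.mark.parametrize("A", [0.0, 0.5, 1.0])
    def test_total_finishing_mass(self, A):
        # the accumulator finishes iff its sampled drift is positive
        # (independent of the start point), so F(inf) = 1 - Phi(-v/s)
        v, s, b = 1.2, 1.0, 1.5
        total, err = integrate.quad(
            lambda t: accumulator_pdf(t, b, A, v, s), 0, np.inf, limit=200
        )
        assert total == pytest.approx(1.0 - norm.cdf(-v / s), abs=1e-6)

    def test_pdf_integrates_to_cdf(self):
        b, A, v, s = 1.5, 0.8, 2.5, 1.0
        for t in (0.3, 0.6, 1.2):
            val, _ = integrate.quad(
                lambda u: accumulator_pdf(u, b, A, v, s), 1e-12, t, limit=200
            )
            assert val == pytest.approx(accumulator_cdf(t, b, A, v, s), abs=1e-6)

    def test_cdf_derivative_matches_pdf(self):
        b, A, v, s = 1.5, 0.8, 2.5, 1.0
        t = np.linspace(0.2, 1.5, 25)
        h = 1e-5
        num = (accumulator_cdf(t + h, b, A, v, s) - accumulator_cdf(t - h, b, A, v, s)) / (2 * h)
        assert np.allclose(num, accumulator_pdf(t, b, A, v, s), atol=1e-6)

    def test_cdf_monotone_bounded_random_params(self, rng):
        # 1e4 random parameter draws: CDF in [0,1] and nondecreasing in t
        n = 10_000
        A = rng.uniform(0, 2, n)
        k = rng.uniform(0.05, 2, n)
        v = rng.uniform(-1, 5, n)
        s = rng.uniform(0.3, 2, n)
        t1 = rng.uniform(0.05, 2, n)
        t2 = t1 + rng.uniform(0.01, 1, n)
        F1 = accumulator_cdf(t1, A + k, A, v, s)
        F2 = accumulator_cdf(t2, A + k, A, v, s)
        assert np.all((F1 >= 0) & (F2 <= 1))
        assert np.all(F2 >= F1 - 1e-12)

    def test_density_matches_simulated_finishing_times(self, rng):
        # single-accumulator MC oracle: max CDF error < 0.005 at 1e6 draws
        v, s, b, A = 3.0, 1.0, 2.0, 1.0
        n = 1_000_000
        drifts = rng.normal(v, s, n)
        starts = rng.uniform(0, A, n)
        finite = drifts > 0
        times = (b - starts[finite]) / drifts[finite]
        grid = np.quantile(times, np.linspace(0.01, 0.99, 50))
        emp = np.searchsorted(np.sort(times), grid) / n  # defective empirical CDF
        ana = accumulator_cdf(grid, b, A, v, s)
        assert np.max(np.abs(emp - ana)) < 0.005

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            accumulator_pdf(-0.1, 2.0, 1.0, 3.0, 1.0)
        with pytest.raises(ValueError):
            accumulator_cdf(0.5, 1.0, 1.5, 3.0, 1.0)  # b <= A


class TestTrialLoglik:
    def test_rt_at_or_below_t0_gives_minus_inf(self, ref_params):
        assert trial_loglik(ref_params.t0, True, ref_params) == -np.inf
        assert trial_loglik(0.01, False, ref_params) == -np.inf

    def test_defective_densities_integrate_to_race_mass(self, ref_params):
        # sum of choice probabilities = 1 - P(both sampled drifts <= 0)
        p = ref_params

        def dens(t, correct):
            return np.exp(trial_loglik(t + p.t0, correct, p))

        pc, _ = integrate.quad(dens, 0, np.inf, args=(True,), limit=300)
        pe, _ = integrate.quad(dens, 0, np.inf, args=(False,), limit=300)
        p_both_neg = norm.cdf(-p.v_c / p.s) * norm.cdf(-p.v_e / p.s)
        assert pc + pe == pytest.approx(1.0 - p_both_neg, abs=1e-4)

    def test_loglik_peaks_near_generating_drift(self, ref_params, ref_trials):
        # brute-force grid over v_c holding other parameters at truth
        grid = np.linspace(1.0, 5.0, 41)
        lls = []
        for v in grid:
            p = LbaParams(v, ref_params.v_e, ref_params.A, ref_params.k, ref_params.t0)
            lls.append(
                np.sum(trial_loglik(ref_trials["rt"].to_numpy(), ref_trials["correct"].to_numpy(), p))
            )
        assert abs(grid[np.argmax(lls)] - ref_params.v_c) < 0.5

    def test_left_right_relabeling_invariance(self, ref_params, ref_trials):
        # the likelihood depends only on (rt, correct), not on which side
        flipped = ref_trials.assign(
            stimulus=ref_trials["response"].where(ref_trials["correct"], ref_trials["stimulus"]),
        )
        a = trial_loglik(ref_trials["rt"].to_numpy(), ref_trials["correct"].to_numpy(), ref_params)
        b = trial_loglik(flipped["rt"].to_numpy(), flipped["correct"].to_numpy(), ref_params)
        assert np.array_equal(a, b)

    def test_block_kernel_matches_reference_path(self, ref_params, ref_trials):
        # compiled kernel vs the vectorized numpy route
        rt = ref_trials["rt"].to_numpy()[None, :]
        correct = ref_trials["correct"].to_numpy()[None, :]
        mask = np.ones_like(rt)
        theta = np.tile(ref_params.to_array(), (3, 1, 1))
        theta[1, 0, 0] += 0.5
        theta[2, 0, 3] -= 0.2
        out = block_loglik(rt, correct, mask, theta)
        for c in range(3):
            p = LbaParams.from_array(theta[c, 0])
            ref = np.sum(trial_loglik(rt[0], correct[0], p))
            assert out[c, 0] == pytest.approx(ref, rel=1e-9, abs=1e-5)


class TestSimulator:
    def test_all_rts_exceed_t0(self, ref_trials, ref_params):
        assert (ref_trials["rt"] > ref_params.t0).all()

    def test_deterministic_race_limit(self):
        # A = 0 and tiny s: rt = t0 + k / v of the faster accumulator
        p = LbaParams(v_c=3.0, v_e=1.0, A=0.0, k=0.9, t0=0.2, s=1e-9)
        t = simulate_trials(p, 500, seed=5)
        assert np.allclose(t["rt"], 0.2 + 0.9 / 3.0, atol=1e-6)
        assert t["correct"].all()

    def test_accuracy_matches_quadrature(self):
        p = LbaParams(v_c=3.0, v_e=1.0, A=0.5, k=0.5, t0=0.2)
        n = 100_000
        t = simulate_trials(p, n, seed=7)

        def dens(u):
            return np.exp(trial_loglik(u + p.t0, True, p))

        pc, _ = integrate.quad(dens, 0, np.inf, limit=300)
        p_both_neg = norm.cdf(-p.v_c) * norm.cdf(-p.v_e)
        analytic = pc / (1.0 - p_both_neg)  # simulator resamples stuck trials
        se = np.sqrt(analytic * (1 - analytic) / n)
        assert abs(t["correct"].mean() - analytic) < 2 * se + 1e-9

    def test_balanced_stimuli_and_seed_determinism(self, ref_params):
        a = simulate_trials(ref_params, 100, seed=9)
        b = simulate_trials(ref_params, 100, seed=9)
        assert a.equals(b)
        assert abs((a["stimulus"] == "left").sum() - 50) <= 0


class TestUrgency:
    def test_arithmetic(self):
        assert urgency(LbaParams(3, 1, A=1.0, k=1.0, t0=0.2)) == 1.5  # b=2, A=1
        assert urgency(LbaParams(3, 1, A=0.0, k=2.0, t0=0.2)) == 2.0  # A=0 -> b

    def test_equals_mean_evidence_to_threshold(self, rng):
        p = LbaParams(3, 1, A=0.9, k=0.6, t0=0.2)
        starts = rng.uniform(0, p.A, 1_000_000)
        mc = (p.b - starts).mean()
        se = starts.std() / 1000.0
        assert abs(urgency(p) - mc) < 3 * se


class TestTrialTableIO:
    def test_round_trip(self, tmp_path, ref_trials):
        path = tmp_path / "trials.csv"
        write_trial_table(ref_trials, path)
        back = read_trial_table(path)
        assert back["rt"].tolist() == pytest.approx(ref_trials["rt"].tolist())
        assert (back["correct"] == ref_trials["correct"]).all()

    def test_millisecond_conversion(self, tmp_path, ref_trials):
        path = tmp_path / "ms.csv"
        ms = ref_trials.assign(rt=ref_trials["rt"] * 1000.0)
        write_trial_table(ms, path)
        back = read_trial_table(path, rt_in_ms=True)
        assert back["rt"].tolist() == pytest.approx(ref_trials["rt"].tolist())

    def test_correct_column_must_agree(self, tmp_path, ref_trials):
        path = tmp_path / "bad.csv"
        bad = ref_trials.copy()
        bad.loc[0, "correct"] = not bad.loc[0, "correct"]
        bad.to_csv(path, index=False)
        with pytest.raises(ValueError, match="disagrees"):
            read_trial_table(path)
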