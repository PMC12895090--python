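"""The dispersal-observation likelihood against independent oracles:
scipy.stats.t, numerical quadrature and Monte-Carlo simulation."""

import math

import numpy as np
import pytest
from scipy import integrate
from scipy import stats

import streammove as sm
from streammove.likelihood import marginal_loglik, ReplicateData


CFG = sm.ModelConfig()


def make_rep(x0=215.0, x1=None, y=0, eta=93.0, cov=None, rid="r0"):
    return sm.MovementReplicate(
        replicate_id=rid, tag_id=rid, species="s", occasion_t=1,
        x0=x0, x1=x1, y=y, eta_days=eta, covariates=cov or {},
    )


class TestLogSigma:
    def test_identity(self):
        p = sm.ModelParams(0.0, np.zeros(2), 0.5)
        assert sm.log_sigma(p, [0.0, 0.0], 1.0) == 0.0

    def test_intercept_only(self):
        p = sm.ModelParams(math.log(2.0), np.zeros(1), 0.5)
        assert sm.log_sigma(p, [0.0], 1.0) == pytest.approx(math.log(2.0))

    def test_interval_offset(self):
        p = sm.ModelParams(0.0, np.zeros(1), 0.5)
        assert sm.log_sigma(p, [0.0], 93.0) == pytest.approx(math.log(93.0))

    def test_dimension_mismatch(self):
        p = sm.ModelParams(0.0, np.zeros(2), 0.5)
        with pytest.raises(ValueError):
            sm.log_sigma(p, [0.0], 93.0)


class TestTLogpdf:
    def test_symmetry(self, rng):
        for _ in range(10):
            x0 = rng.uniform(0, 430)
            delta = rng.uniform(0, 100)
            sigma = rng.uniform(0.5, 50)
            nu = rng.uniform(1, 30)
            left = sm.t_logpdf(x0 - delta, x0, sigma, nu)
            right = sm.t_logpdf(x0 + delta, x0, sigma, nu)
            assert left == pytest.approx(right, rel=1e-12)

    def test_matches_scipy_location_scale(self, rng):
        for _ in range(20):
            x0 = rng.uniform(0, 430)
            x1 = rng.uniform(-100, 530)
            sigma = rng.uniform(0.1, 100)
            nu = rng.choice([1.0, 5.0, 50.0])
            assert sm.t_logpdf(x1, x0, sigma, nu) == pytest.approx(
                stats.t.logpdf(x1, nu, loc=x0, scale=sigma), rel=1e-10
            )

    def test_normal_limit(self):
        for z in np.linspace(-3, 3, 13):
            t_val = math.exp(sm.t_logpdf(z, 0.0, 1.0, 1e6))
            n_val = stats.norm.pdf(z)
            assert abs(t_val - n_val) < 1e-4

    @pytest.mark.parametrize("nu", [1.0, 5.0, 50.0])
    def test_integrates_to_one(self, nu):
        val, _ = integrate.quad(
            lambda x: math.exp(sm.t_logpdf(x, 0.0, 1.0, nu)),
            -np.inf, np.inf,
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_sigma_guard(self):
        with pytest.raises(ValueError):
            sm.t_logpdf(0.0, 0.0, 0.0, 5.0)


class TestStayProb:
    def test_degenerate_kernel_stays(self):
        assert sm.stay_prob(215.0, 1e-9, 5.0, 430.0) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_infinite_spread_escapes(self):
        assert sm.stay_prob(215.0, 1e12, 5.0, 430.0) < 1e-6

    def test_midpoint_symmetry_formula(self):
        sigma, nu, L = 37.0, 5.0, 430.0
        expected = 1.0 - 2.0 * stats.t.cdf(-L / (2 * sigma), nu)
        assert sm.stay_prob(L / 2, sigma, nu, L) == pytest.approx(expected)

    def test_matches_quadrature_of_kernel(self, rng):
        for _ in range(5):
            x0 = rng.uniform(0, 430)
            sigma = rng.uniform(5, 150)
            val, _ = integrate.quad(
                lambda x: math.exp(sm.t_logpdf(x, x0, sigma, 5.0)), 0.0, 430.0
            )
            assert sm.stay_prob(x0, sigma, 5.0, 430.0) == pytest.approx(
                val, abs=1e-8
            )

    def test_complement_is_mass_outside_reach(self, rng):
        x0, sigma = 100.0, 60.0
        outside_low, _ = integrate.quad(
            lambda x: math.exp(sm.t_logpdf(x, x0, sigma, 5.0)), -np.inf, 0.0
        )
        outside_high, _ = integrate.quad(
            lambda x: math.exp(sm.t_logpdf(x, x0, sigma, 5.0)), 430.0, np.inf
        )
        total = sm.stay_prob(x0, sigma, 5.0, 430.0) + outside_low + outside_high
        assert total == pytest.approx(1.0, abs=1e-8)


class TestStayIndicator:
    @pytest.mark.parametrize(
        "x1,expected",
        [(-0.1, 0), (0.0, 1), (215.0, 1), (430.0, 1), (430.1, 0)],
    )
    def test_closed_interval(self, x1, expected):
        assert sm.stay_indicator(x1, 430.0) == expected


class TestReplicateLoglik:
    def test_phi_zero_never_recaptured(self):
        # phi = 0 sits outside the prior support but the likelihood itself
        # is well defined: Y=0 is certain whatever the movement
        p = sm.ModelParams(0.0, np.zeros(0), 0.0)
        rep = make_rep(y=0)
        assert sm.replicate_loglik(rep, p, CFG) == pytest.approx(0.0)

    def test_certain_recapture_contradicts_y0(self):
        from streammove.likelihood import clip_counter

        p = sm.ModelParams(-25.0, np.zeros(0), 1.0)
        rep = make_rep(y=0, eta=1.0)
        clip_counter.reset()
        val = sm.replicate_loglik(rep, p, CFG)
        assert val < -600  # floored near log(1e-300), not -inf
        assert np.isfinite(val)
        assert clip_counter.count == 1  # the clipped evaluation is flagged

    def test_marginalized_matches_monte_carlo(self, rng):
        """P(Y=0) = E[1 - phi*z(X1)] over kernel draws of X1."""
        for _ in range(3):
            x0 = rng.uniform(30, 400)
            beta0 = rng.uniform(-1, 1)
            eta = 93.0
            phi = rng.uniform(0.2, 0.8)
            sigma = math.exp(beta0 + math.log(eta))
            draws = x0 + sigma * rng.standard_t(5.0, size=1_000_000)
            z = (draws >= 0) & (draws <= 430.0)
            vals = 1.0 - phi * z
            mc = vals.mean()
            se = vals.std(ddof=1) / 1000.0
            p = sm.ModelParams(beta0, np.zeros(0), phi)
            got = math.exp(sm.replicate_loglik(make_rep(x0=x0), p, CFG))
            assert abs(got - mc) < 3 * se

    def test_y0_loglik_increases_with_spread(self):
        rep = make_rep(x0=215.0, y=0)
        vals = [
            sm.replicate_loglik(
                rep, sm.ModelParams(b0, np.zeros(0), 0.5), CFG
            )
            for b0 in np.linspace(-3, 1, 9)
        ]
        assert np.all(np.diff(vals) > 0)

    def test_missing_x1_errors(self):
        rep = make_rep(y=0)
        rep.y = 1  # mutate post-validation to hit the likelihood guard
        with pytest.raises(ValueError):
            sm.replicate_loglik(rep, sm.ModelParams(0.0, np.zeros(0), 0.5), CFG)


class TestLogPrior:
    def test_phi_outside_support(self):
        assert sm.log_prior(sm.ModelParams(0.0, np.zeros(1), 1.2), CFG) == -np.inf
        assert sm.log_prior(sm.ModelParams(0.0, np.zeros(1), -0.1), CFG) == -np.inf

    def test_intercept_contribution_closed_form(self):
        at_zero = sm.log_prior(sm.ModelParams(0.0, np.zeros(0), 0.5), CFG)
        shifted = sm.log_prior(sm.ModelParams(2.5, np.zeros(0), 0.5), CFG)
        # N(0, 2.5^2): moving one prior sd from the mode costs exactly 1/2
        assert at_zero - shifted == pytest.approx(0.5)

    def test_truncated_phi_prior_normalized(self):
        # isolate the phi factor of the prior and integrate it over (0, 1)
        base = sm.log_prior(sm.ModelParams(0.0, np.zeros(0), 0.5), CFG)
        dens_at_half = stats.truncnorm.pdf(0.5, -0.5, 0.5, loc=0.5, scale=1.0)

        def phi_density(phi):
            lp = sm.log_prior(sm.ModelParams(0.0, np.zeros(0), phi), CFG)
            return math.exp(lp - base) * dens_at_half

        val, _ = integrate.quad(phi_density, 0.0, 1.0)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_matches_scipy_truncnorm(self, rng):
        for phi in rng.uniform(0.01, 0.99, size=5):
            full = sm.log_prior(sm.ModelParams(0.0, np.zeros(0), phi), CFG)
            beta_part = stats.norm.logpdf(0.0, scale=2.5)
            phi_part = stats.truncnorm.logpdf(
                phi, -0.5, 0.5, loc=0.5, scale=1.0
            )
            assert full == pytest.approx(beta_part + phi_part, rel=1e-10)


class TestLogPosterior:
    def _random_reps(self, rng, n=25):
        reps = []
        for i in range(n):
            y = int(rng.uniform() < 0.4)
            x1 = float(rng.uniform(0, 430)) if y else None
            reps.append(
                make_rep(
                    x0=float(rng.uniform(0, 430)), x1=x1, y=y,
                    eta=float(rng.choice([93.0, 171.0])),
                    cov={"body_size": float(rng.normal())},
                    rid=f"r{i}",
                )
            )
        return reps

    def test_empty_data_returns_prior_with_warning(self):
        p = sm.ModelParams(0.3, np.zeros(0), 0.5)
        with pytest.warns(UserWarning):
            assert sm.log_posterior([], p, CFG) == sm.log_prior(p, CFG)

    def test_matches_brute_force_loop(self, rng):
        reps = self._random_reps(rng)
        p = sm.ModelParams(-1.0, np.array([0.4]), 0.5, ("body_size",))
        manual = sm.log_prior(p, CFG) + sum(
            sm.replicate_loglik(r, p, CFG) for r in reps
        )
        assert sm.log_posterior(reps, p, CFG) == pytest.approx(
            manual, abs=1e-12
        )

    def test_order_invariant(self, rng):
        reps = self._random_reps(rng)
        p = sm.ModelParams(-1.0, np.array([0.4]), 0.5, ("body_size",))
        forward = sm.log_posterior(reps, p, CFG)
        backward = sm.log_posterior(list(reversed(reps)), p, CFG)
        assert forward == pytest.approx(backward, rel=1e-12)

    def test_vectorized_container_matches_per_replicate(self, rng):
        reps = self._random_reps(rng)
        p = sm.ModelParams(-1.0, np.array([0.4]), 0.5, ("body_size",))
        data = ReplicateData.from_replicates(reps)
        vec = marginal_loglik(data, p.beta0, p.beta, p.phi, CFG)
        loop = sum(sm.replicate_loglik(r, p, CFG) for r in reps)
        assert vec == pytest.approx(loop, abs=1e-10)
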