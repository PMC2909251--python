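"""Model fitters: likelihood oracles, ICC/design-effect estimators, GEE, RE."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

import statsmodels.api as sm

from composite_het import (
    NotConvergedError,
    ScenarioSpec,
    TrialData,
    composite_main_effect_test,
    estimate_icc_anova,
    fit_gee,
    fit_logistic,
    fit_re_logistic,
    fit_weighted_dd,
    fit_weighted_rs,
    generate_trial,
    wald_test,
)
from composite_het.models import ModelFit


def logit(p):
    return math.log(p / (1 - p))


def _bernoulli_nll(beta, X, y, w=None):
    eta = X @ beta
    ll = y * eta - np.logaddexp(0.0, eta)
    if w is not None:
        ll = w * ll
    return -ll.sum()


class TestFitLogistic:
    def test_saturated_model_equals_cell_logits(self, cell_count_trial):
        """With one parameter per cell the MLE is the empirical log-odds."""
        fit = fit_logistic(cell_count_trial)
        assert fit.converged
        b0, b1, b2, b3 = fit.coefficients
        assert b0 == pytest.approx(logit(0.30), abs=1e-6)
        assert b2 == pytest.approx(logit(0.20) - logit(0.30), abs=1e-6)
        assert b1 == pytest.approx(logit(0.15) - logit(0.30), abs=1e-6)
        assert b3 == pytest.approx(
            logit(0.25) - logit(0.15) - logit(0.20) + logit(0.30), abs=1e-6
        )

    def test_uniform_weights_leave_coefficients_scale_ses(self, random_small_trial):
        base = fit_logistic(random_small_trial)
        w = np.full(len(random_small_trial.event), 2.5)
        weighted = fit_logistic(random_small_trial, weights=w)
        np.testing.assert_allclose(weighted.coefficients, base.coefficients, atol=1e-8)
        np.testing.assert_allclose(weighted.se, base.se / math.sqrt(2.5), rtol=1e-7)

    def test_matches_brute_force_optimizer(self, random_small_trial):
        """IRLS solution equals an independent BFGS maximization to 1e-6."""
        X = random_small_trial.design_matrix()
        y = random_small_trial.event.astype(float)

        def grad(beta, X, y):
            return -(X.T @ (y - expit(X @ beta)))

        oracle = minimize(
            _bernoulli_nll, np.zeros(4), args=(X, y), jac=grad,
            method="BFGS", options={"gtol": 1e-12},
        )
        fit = fit_logistic(random_small_trial)
        np.testing.assert_allclose(fit.coefficients, oracle.x, atol=1e-6)

    def test_matches_statsmodels(self, medium_trial):
        fit = fit_logistic(medium_trial)
        ref = sm.Logit(medium_trial.event, medium_trial.design_matrix()).fit(disp=0)
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-8)
        np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-8)


class TestIccAnova:
    def test_perfect_duplication_gives_one(self):
        rng = np.random.default_rng(0)
        n = 200
        y = rng.integers(0, 2, n)
        data = TrialData(
            participant_id=np.repeat(np.arange(n), 2),
            arm=np.repeat(np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)], 2),
            component=np.tile(np.array([0, 1]), n),
            event=np.repeat(y, 2).astype(np.int64),
        )
        assert estimate_icc_anova(data) == pytest.approx(1.0)

    def test_recovers_zero_and_target_icc(self):
        for rho in (0.0, 0.10):
            spec = ScenarioSpec(or1=1.0, or2=1.0, icc=rho, n_participants=100_000)
            data = generate_trial(spec, 13)
            assert estimate_icc_anova(data) == pytest.approx(rho, abs=0.01)

    def test_degenerate_outcomes_raise(self):
        n = 10
        data = TrialData(
            participant_id=np.repeat(np.arange(n), 2),
            arm=np.repeat(np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)], 2),
            component=np.tile(np.array([0, 1]), n),
            event=np.ones(2 * n, dtype=np.int64),
        )
        with pytest.raises(ValueError, match="degenerate"):
            estimate_icc_anova(data)


class TestWeightedModels:
    def test_dd_zero_icc_equals_plain_logistic(self):
        spec = ScenarioSpec(or1=0.8, or2=0.9, icc=0.0, n_participants=4000)
        data = generate_trial(spec, 21)
        dd = fit_weighted_dd(data)
        plain = fit_logistic(data)
        # rho_hat ~ 0 so weights ~ 1: coefficients identical, SEs near-identical
        np.testing.assert_allclose(dd.coefficients, plain.coefficients, atol=1e-8)
        np.testing.assert_allclose(dd.se, plain.se, rtol=0.05)

    def test_dd_weight_algebra(self, medium_trial):
        """Uniform DD weight scales all SEs by sqrt(1 + rho_hat) exactly."""
        dd = fit_weighted_dd(medium_trial)
        plain = fit_logistic(medium_trial)
        rho_hat = dd.extras["icc"]
        np.testing.assert_allclose(dd.coefficients, plain.coefficients, atol=1e-8)
        np.testing.assert_allclose(dd.se, plain.se * math.sqrt(1 + rho_hat), rtol=1e-7)

    def test_rs_duplicated_outcomes_give_design_effect_two(self):
        rng = np.random.default_rng(3)
        n = 4000
        y = rng.binomial(1, 0.3, n)
        data = TrialData(
            participant_id=np.repeat(np.arange(n), 2),
            arm=np.repeat(np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)], 2),
            component=np.tile(np.array([0, 1]), n),
            event=np.repeat(y, 2).astype(np.int64),
        )
        rs = fit_weighted_rs(data)
        assert rs.extras["vif_control"] == pytest.approx(2.0, abs=0.08)
        assert rs.extras["vif_treatment"] == pytest.approx(2.0, abs=0.08)

    def test_rs_independent_components_near_unit_weights(self):
        spec = ScenarioSpec(or1=1.0, or2=1.0, icc=0.0, n_participants=50_000)
        data = generate_trial(spec, 4)
        rs = fit_weighted_rs(data)
        assert rs.extras["vif_control"] == pytest.approx(1.0, abs=0.03)
        assert rs.extras["vif_treatment"] == pytest.approx(1.0, abs=0.03)


class TestGee:
    def test_independence_working_equals_logistic_coefficients(self, medium_trial):
        gee = fit_gee(medium_trial, working="independence")
        plain = fit_logistic(medium_trial)
        np.testing.assert_allclose(gee.coefficients, plain.coefficients, atol=1e-8)
        # sandwich and model-based SEs differ under correlation
        assert not np.allclose(gee.se, plain.se, rtol=1e-3)

    def test_matches_statsmodels_gee(self, medium_trial):
        """Coefficients, sandwich SEs and working correlation vs statsmodels.

        For clusters of size 2 the exchangeable structure coincides with the
        single-off-diagonal unstructured one.
        """
        mine = fit_gee(medium_trial)
        cov = sm.cov_struct.Exchangeable()
        ref = sm.GEE(
            medium_trial.event,
            medium_trial.design_matrix(),
            groups=medium_trial.participant_id,
            family=sm.families.Binomial(),
            cov_struct=cov,
        ).fit()
        np.testing.assert_allclose(mine.coefficients, np.asarray(ref.params), atol=1e-8)
        np.testing.assert_allclose(mine.se, np.asarray(ref.bse), atol=1e-6)
        assert mine.extras["working_corr"] == pytest.approx(float(cov.dep_params), abs=2e-3)

    def test_working_correlation_recovers_icc(self):
        spec = ScenarioSpec(or1=1.0, or2=1.0, n_participants=100_000)
        data = generate_trial(spec, 17)
        gee = fit_gee(data)
        assert gee.extras["working_corr"] == pytest.approx(0.10, abs=0.01)

    def test_sandwich_matches_model_se_under_independence(self):
        spec = ScenarioSpec(or1=0.8, or2=0.8, icc=0.0, n_participants=50_000)
        data = generate_trial(spec, 8)
        gee = fit_gee(data)
        plain = fit_logistic(data)
        np.testing.assert_allclose(gee.se, plain.se, rtol=0.05)


class TestRandomEffects:
    def test_degenerate_random_effect_matches_logistic(self):
        spec = ScenarioSpec(or1=0.8, or2=1.0, icc=0.0, n_participants=4000)
        data = generate_trial(spec, 31)
        re = fit_re_logistic(data)
        plain = fit_logistic(data)
        assert re.extras["sigma2"] < 0.05
        np.testing.assert_allclose(re.coefficients, plain.coefficients, atol=2e-2)

    def test_marginal_likelihood_matches_trapezoid_oracle(self):
        """AGQ marginal log-likelihood vs dense numerical integration."""
        # icc 0.3 so the variance estimate is interior (away from sigma = 0)
        spec = ScenarioSpec(or1=0.65, or2=1.0, icc=0.3, n_participants=20)
        data = generate_trial(spec, 5)
        re = fit_re_logistic(data, n_quadrature=30)
        assert re.converged
        theta = np.append(re.coefficients, math.sqrt(re.extras["sigma2"]))
        sigma = theta[4]
        assert sigma > 0.1
        arm, y = data.pairs()
        grid = np.linspace(-8 * sigma, 8 * sigma, 8001)
        total = 0.0
        for i in range(data.n_participants):
            eta0 = theta[0] + theta[1] * arm[i]
            eta1 = eta0 + theta[2] + theta[3] * arm[i]
            ll = (
                y[i, 0] * (eta0 + grid) - np.logaddexp(0, eta0 + grid)
                + y[i, 1] * (eta1 + grid) - np.logaddexp(0, eta1 + grid)
            )
            dens = np.exp(ll) * np.exp(-0.5 * (grid / sigma) ** 2) / (
                sigma * math.sqrt(2 * math.pi)
            )
            total += math.log(np.trapezoid(dens, grid))
        assert -total == pytest.approx(re.extras["nll"], abs=1e-6)

    def test_recovers_variance_on_correlated_data(self):
        spec = ScenarioSpec(or1=0.65, or2=1.0, n_participants=2000)
        data = generate_trial(spec, 42)
        re = fit_re_logistic(data)
        assert re.converged
        assert re.extras["sigma2"] > 0.1  # rho = 0.10 implies a clearly positive variance


class TestWaldAndMainEffect:
    def test_zero_estimate_never_rejects(self):
        fit = ModelFit("independent", np.array([0.1, 0.2, 0.3, 0.0]),
                       np.eye(4) * 0.01, True, 3)
        res = wald_test(fit, "interaction", 0.05)
        assert res.z == 0.0 and res.p == pytest.approx(1.0) and not res.reject

    def test_arithmetic(self):
        vcov = np.eye(4) * 0.1408**2
        fit = ModelFit("gee", np.array([0.0, 0.0, 0.0, 0.4308]), vcov, True, 5)
        res = wald_test(fit, "interaction", 0.05)
        assert res.z == pytest.approx(3.0597, abs=1e-3)
        assert res.p == pytest.approx(0.00222, abs=5e-4)
        assert res.reject

    def test_unconverged_fit_refused(self):
        fit = ModelFit("gee", np.zeros(4), np.eye(4), False, 100, reason="diverged")
        with pytest.raises(NotConvergedError):
            wald_test(fit)

    def test_main_effect_methods_agree_directionally(self, medium_trial):
        a = composite_main_effect_test(medium_trial, "collapsed_chisq")
        b = composite_main_effect_test(medium_trial, "gee_no_interaction")
        assert (a.estimate < 0) == (b.estimate < 0)
        assert a.p < 0.05 or b.p < 0.05  # strong true effect in this scenario
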