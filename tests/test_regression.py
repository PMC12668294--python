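import numpy as np
import pytest

from autovi.regression import (
    EpochRecord,
    SKLFit,
    estimate_skl_to_opt,
    fit_iteration_model,
    fit_skl_regression,
    inefficiency,
    regression_weights,
)


def make_records(gammas, deltas, n_iters=None):
    """Epoch records with delta[0] attached to epoch t=1."""
    recs = [EpochRecord(t=0, gamma=gammas[0], lam_avg=np.zeros(2),
                        n_iters=1000 if n_iters is None else n_iters[0])]
    for t, (g, d) in enumerate(zip(gammas[1:], deltas), start=1):
        recs.append(
            EpochRecord(t=t, gamma=g, lam_avg=np.zeros(2),
                        n_iters=1000 if n_iters is None else n_iters[t],
                        delta=d)
        )
    return recs


def geometric_gammas(gamma0, rho, n):
    return [gamma0 * rho**t for t in range(n)]


class TestRegressionWeights:
    def test_latest_weight_is_one(self):
        for T in (1, 3, 10):
            assert regression_weights(T)[-1] == 1.0

    def test_lag_three_value(self):
        w = regression_weights(5)
        assert w[1] == pytest.approx((1 + 9 / 32) ** -0.25)
        assert w[1] == pytest.approx(0.9399, abs=2e-4)

    def test_strictly_decreasing_with_age(self):
        w = regression_weights(8)
        assert np.all(np.diff(w) > 0)

    def test_invalid(self):
        with pytest.raises(ValueError):
            regression_weights(0)


class TestFitSklRegression:
    def test_noiseless_kappa_fixed_recovery(self):
        rho, c_true = 0.5, 0.5
        gammas = geometric_gammas(0.3, rho, 6)
        deltas = [c_true * g**2 * (1 / rho - 1) ** 2 for g in gammas[1:]]
        fit = fit_skl_regression(make_records(gammas, deltas), rho)
        assert fit.C_hat == pytest.approx(c_true, rel=0.05)
        assert fit.kappa_hat == 1.0

    def test_noiseless_kappa_free_recovery(self):
        rho, c_true, kappa = 0.5, 2.0, 0.7
        gammas = geometric_gammas(0.3, rho, 7)
        deltas = [
            c_true * g ** (2 * kappa) * (1 / rho**kappa - 1) ** 2
            for g in gammas[1:]
        ]
        fit = fit_skl_regression(make_records(gammas, deltas), rho, "kappa_free")
        assert abs(fit.kappa_hat - kappa) < 0.05

    def test_single_observation_posterior_mode(self):
        rho, delta = 0.5, 0.01
        gammas = geometric_gammas(0.3, rho, 2)
        fit = fit_skl_regression(make_records(gammas, [delta]), rho)
        implied_log_c = (
            np.log(delta) - 2 * np.log(1 / rho - 1) - 2 * np.log(gammas[1])
        )
        mode = fit.log_c_grid[np.argmax(fit.log_c_marginal)]
        spacing = fit.log_c_grid[1] - fit.log_c_grid[0]
        assert abs(mode - implied_log_c) <= spacing

    def test_grid_refinement_stability(self):
        rho = 0.5
        rng = np.random.default_rng(7)
        gammas = geometric_gammas(0.3, rho, 6)
        deltas = [
            0.8 * g**2 * (1 / rho - 1) ** 2 * np.exp(rng.normal(0, 0.3))
            for g in gammas[1:]
        ]
        recs = make_records(gammas, deltas)
        coarse = fit_skl_regression(recs, rho, n_grid_c=1001, n_grid_sigma=81)
        fine = fit_skl_regression(recs, rho, n_grid_c=4001, n_grid_sigma=241)
        assert coarse.C_hat == pytest.approx(fine.C_hat, rel=0.02)

    def test_nonpositive_deltas_dropped_with_warning(self):
        rho = 0.5
        gammas = geometric_gammas(0.3, rho, 4)
        with pytest.warns(UserWarning, match="non-positive"):
            fit = fit_skl_regression(
                make_records(gammas, [0.01, 0.0, 0.002]), rho
            )
        assert fit.C_hat > 0

    def test_too_few_observations_refused(self):
        gammas = geometric_gammas(0.3, 0.5, 2)
        recs = make_records(gammas, [0.01])
        with pytest.raises(ValueError, match="at least"):
            fit_skl_regression(recs, 0.5, "kappa_free")
        with pytest.raises(ValueError):
            fit_skl_regression(make_records([0.3], []), 0.5)

    def test_invalid_args(self):
        recs = make_records(geometric_gammas(0.3, 0.5, 3), [0.01, 0.005])
        with pytest.raises(ValueError):
            fit_skl_regression(recs, rho=1.5)
        with pytest.raises(ValueError):
            fit_skl_regression(recs, rho=0.5, mode="kappa_frozen")

    def test_posterior_draws(self, rng):
        recs = make_records(geometric_gammas(0.3, 0.5, 4), [0.01, 0.003])
        fit = fit_skl_regression(recs, 0.5)
        draws = fit.posterior_draws(500, rng)
        assert np.all(draws["kappa"] == 1.0)
        assert np.isfinite(draws["log_C"]).all()


class TestEstimateSklToOpt:
    def test_single_delta_simplification(self):
        # with rho = 0.5 and kappa = 1, C implied by one gap gives back the
        # gap itself: rho^2 / (1 - rho)^2 = 1
        rho, gamma, delta = 0.5, 0.075, 0.004
        c_implied = delta * rho**2 / (gamma**2 * (1 - rho) ** 2)
        fit = SKLFit(
            C_hat=c_implied, kappa_hat=1.0, mode="kappa_fixed_1", rho=rho,
            weights=np.ones(1), log_c_grid=np.zeros(1),
            log_c_marginal=np.ones(1),
        )
        assert estimate_skl_to_opt(fit, gamma) == pytest.approx(delta)

    def test_monotone_and_power_law(self):
        fit = SKLFit(
            C_hat=2.0, kappa_hat=1.0, mode="kappa_fixed_1", rho=0.5,
            weights=np.ones(1), log_c_grid=np.zeros(1),
            log_c_marginal=np.ones(1),
        )
        vals = [estimate_skl_to_opt(fit, g) for g in (0.4, 0.2, 0.1, 0.05)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert estimate_skl_to_opt(fit, 0.2) == pytest.approx(
            4 * estimate_skl_to_opt(fit, 0.1)
        )
        with pytest.raises(ValueError):
            estimate_skl_to_opt(fit, 0.0)

    def test_pipeline_self_consistency(self):
        # generate gaps exactly from the mean structure and check the
        # round-trip estimate matches the generative law
        rho, c_true, kappa = 0.5, 1.3, 0.8
        gammas = geometric_gammas(0.3, rho, 8)
        deltas = [
            c_true * g ** (2 * kappa) * (1 / rho**kappa - 1) ** 2
            for g in gammas[1:]
        ]
        fit = fit_skl_regression(make_records(gammas, deltas), rho, "kappa_free")
        g_last = gammas[-1]
        assert estimate_skl_to_opt(fit, g_last) == pytest.approx(
            c_true * g_last ** (2 * kappa), rel=0.15
        )


class TestFitIterationModel:
    def test_exact_power_law(self):
        gammas = [0.5, 0.25, 0.125]
        ks = [1000 / g for g in gammas]
        recs = make_records(gammas, [0.01, 0.01], n_iters=ks)
        alpha, beta, k_next, heuristic = fit_iteration_model(recs, rho=0.5)
        assert alpha == pytest.approx(-1.0, abs=1e-10)
        assert beta == pytest.approx(np.log(1000), abs=1e-10)
        assert k_next == pytest.approx(1000 / 0.0625)
        assert not heuristic

    def test_constant_iterations(self):
        gammas = geometric_gammas(0.3, 0.5, 4)
        recs = make_records(gammas, [0.1] * 3, n_iters=[500] * 4)
        alpha, _, k_next, _ = fit_iteration_model(recs, rho=0.5)
        assert alpha == pytest.approx(0.0, abs=1e-10)
        assert k_next == pytest.approx(500.0)

    def test_noisy_prediction_quality(self):
        rho = 0.5
        gammas = geometric_gammas(0.3, rho, 6)
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ks = [100 / g * np.exp(rng.normal(0, 0.1)) for g in gammas]
            recs = make_records(gammas, [0.1] * 5, n_iters=ks)
            _, _, k_next, _ = fit_iteration_model(recs, rho)
            truth = 100 / (rho * gammas[-1])
            if abs(k_next - truth) / truth < 0.25:
                hits += 1
        assert hits >= 95

    def test_single_record_heuristic(self):
        recs = [EpochRecord(t=0, gamma=0.3, lam_avg=np.zeros(2), n_iters=800)]
        alpha, beta, k_next, heuristic = fit_iteration_model(recs, rho=0.5)
        assert heuristic
        assert k_next == pytest.approx(1600.0)
        assert np.isnan(alpha) and np.isnan(beta)

    def test_empty_refused(self):
        with pytest.raises(ValueError):
            fit_iteration_model([], rho=0.5)


def _fit(c_hat=1.0, kappa=1.0, rho=0.5):
    return SKLFit(
        C_hat=c_hat, kappa_hat=kappa, mode="kappa_fixed_1", rho=rho,
        weights=np.ones(1), log_c_grid=np.zeros(1), log_c_marginal=np.ones(1),
    )


class TestInefficiency:
    def test_rskl_formula(self):
        d = inefficiency(_fit(), k_next_hat=1000, k_gamma_t=1000,
                         gamma_t=0.1, xi=0.1, k0=1000)
        assert d.rskl_hat == pytest.approx(1.5)

    def test_full_decision(self):
        d = inefficiency(_fit(), k_next_hat=3000, k_gamma_t=1000,
                         gamma_t=0.1, xi=0.1, k0=1000, tau=1.0)
        assert d.ri_hat == pytest.approx(1.5)
        assert d.inefficiency_hat == pytest.approx(2.25)
        assert d.terminate
        assert d.inefficiency_hat == pytest.approx(d.rskl_hat * d.ri_hat)

    def test_vanishing_xi_limit(self):
        d = inefficiency(_fit(c_hat=123.0, kappa=0.9), k_next_hat=10,
                         k_gamma_t=10, gamma_t=5.0, xi=1e-12, k0=1)
        assert d.rskl_hat == pytest.approx(0.5**0.9, rel=1e-6)

    def test_monotone_in_tau(self):
        for tau in (0.5, 1.0, 2.0, 5.0):
            d = inefficiency(_fit(), k_next_hat=3000, k_gamma_t=1000,
                             gamma_t=0.1, xi=0.1, k0=1000, tau=tau)
            assert d.terminate == (2.25 > tau)

    def test_rskl_monotonicities(self):
        # increasing in xi; decreasing in gamma * sqrt(C)
        base = dict(k_next_hat=100, k_gamma_t=100, k0=100)
        xis = [0.01, 0.1, 1.0]
        vals = [
            inefficiency(_fit(), gamma_t=0.1, xi=x, **base).rskl_hat
            for x in xis
        ]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        gcs = [(0.05, 1.0), (0.1, 1.0), (0.1, 4.0)]
        vals = [
            inefficiency(_fit(c_hat=c), gamma_t=g, xi=0.1, **base).rskl_hat
            for g, c in gcs
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_positivity_validation(self):
        with pytest.raises(ValueError):
            inefficiency(_fit(), k_next_hat=0, k_gamma_t=1, gamma_t=0.1,
                         xi=0.1, k0=1)
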