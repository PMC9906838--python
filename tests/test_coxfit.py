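import numpy as np
import pytest

from predictgrs.coxfit import (compare_models, fit_offset_cox, offset_loglik,
                               rescale_grs_term)

from conftest import brute_force_efron_loglik


def simulate_survival(n, beta, rng, offset_sd=0.5, base_rate=0.08,
                      censor_rate=0.04):
    """Exponential-baseline proportional-hazards data with a known truth."""
    g = rng.standard_normal(n)
    offset = offset_sd * rng.standard_normal(n)
    eta = offset + beta * g
    t_event = rng.exponential(1.0 / (base_rate * np.exp(eta)))
    t_cens = rng.exponential(1.0 / censor_rate, n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event, offset, g


class TestOffsetOnlyLoglik:
    def test_matches_brute_force_on_toy(self):
        time = np.array([2.0, 5.0, 1.0, 8.0, 3.0, 7.0])
        event = np.array([1, 0, 1, 1, 0, 1])
        offset = np.array([0.2, -0.5, 1.0, 0.0, 0.3, -0.2])
        assert offset_loglik(time, event, offset) == pytest.approx(
            brute_force_efron_loglik(time, event, offset), abs=1e-10)

    def test_matches_brute_force_with_ties(self):
        time = np.array([1.0, 2.0, 2.0, 2.0, 4.0, 4.0, 6.0, 7.0])
        event = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        offset = np.array([0.5, -0.1, 0.4, 0.0, -0.6, 0.2, 0.1, 0.9])
        assert offset_loglik(time, event, offset) == pytest.approx(
            brute_force_efron_loglik(time, event, offset), abs=1e-10)

    def test_location_invariance(self):
        rng = np.random.default_rng(0)
        time, event, offset, g = simulate_survival(80, 0.4, rng)
        a = fit_offset_cox(time, event, offset, g)
        b = fit_offset_cox(time, event, offset + 3.7, g)
        assert a.beta == pytest.approx(b.beta, abs=1e-8)
        assert 2 * (a.loglik - a.loglik_null) == pytest.approx(
            2 * (b.loglik - b.loglik_null), abs=1e-8)


class TestFitOffsetCox:
    def test_no_covariate_returns_offset_only_loglik(self):
        time = np.array([2.0, 5.0, 1.0, 8.0, 3.0, 7.0])
        event = np.array([1, 0, 1, 1, 0, 1])
        offset = np.array([0.2, -0.5, 1.0, 0.0, 0.3, -0.2])
        fit = fit_offset_cox(time, event, offset)
        assert fit.beta is None
        assert fit.loglik == pytest.approx(
            brute_force_efron_loglik(time, event, offset), abs=1e-10)

    def test_fitted_loglik_matches_brute_force_at_beta_hat(self):
        rng = np.random.default_rng(3)
        time, event, offset, g = simulate_survival(8, 0.6, rng, censor_rate=0.02)
        fit = fit_offset_cox(time, event, offset, g)
        assert fit.loglik == pytest.approx(
            brute_force_efron_loglik(time, event, offset + fit.beta * g), abs=1e-10)
        assert fit.loglik >= fit.loglik_null - 1e-12

    def test_constant_covariate_rejected(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 1, 0])
        with pytest.raises(ValueError, match="no variation"):
            fit_offset_cox(time, event, None, np.ones(4))

    def test_fewer_than_two_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            fit_offset_cox(np.array([1.0, 2.0]), np.array([1, 0]), None,
                           np.array([0.1, 0.2]))

    def test_matches_lifelines_without_offset(self):
        from lifelines import CoxPHFitter
        import pandas as pd
        rng = np.random.default_rng(8)
        time, event, _, g = simulate_survival(300, 0.5, rng, offset_sd=0.0)
        fit = fit_offset_cox(time, event, None, g)
        df = pd.DataFrame({"T": time, "E": event, "g": g})
        cph = CoxPHFitter().fit(df, "T", "E")
        assert fit.beta == pytest.approx(cph.params_["g"], abs=1e-6)
        assert fit.se_beta == pytest.approx(cph.standard_errors_["g"], abs=1e-6)
        assert fit.loglik == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_matches_lifelines_with_tied_times(self):
        from lifelines import CoxPHFitter
        import pandas as pd
        rng = np.random.default_rng(12)
        time = np.round(rng.exponential(5.0, 120), 0) + 1.0   # heavy ties
        event = rng.random(120) < 0.7
        g = rng.standard_normal(120)
        fit = fit_offset_cox(time, event.astype(int), None, g)
        df = pd.DataFrame({"T": time, "E": event.astype(int), "g": g})
        cph = CoxPHFitter().fit(df, "T", "E")
        assert fit.beta == pytest.approx(cph.params_["g"], abs=1e-5)
        assert fit.loglik == pytest.approx(cph.log_likelihood_, abs=1e-5)

    def test_parameter_recovery_single_replicate(self):
        rng = np.random.default_rng(100)
        time, event, offset, g = simulate_survival(2000, 0.5, rng)
        fit = fit_offset_cox(time, event, offset, g)
        lo, hi = fit.ci_95
        assert lo < 0.5 < hi
        assert fit.beta == pytest.approx(0.5, abs=0.15)

    def test_standardised_fit_maps_back_to_original_scale(self):
        rng = np.random.default_rng(21)
        time, event, offset, g = simulate_survival(400, 0.5, rng)
        plain = fit_offset_cox(time, event, offset, 3.0 * g)
        standardised = fit_offset_cox(time, event, offset, 3.0 * g,
                                      standardise=True)
        assert plain.beta == pytest.approx(standardised.beta, abs=1e-6)
        assert plain.loglik == pytest.approx(standardised.loglik, abs=1e-8)


class TestRescale:
    def test_constant_scores_give_zero_terms(self):
        c, adj = rescale_grs_term(1.7, np.full(10, 4.2))
        np.testing.assert_allclose(adj, 0.0, atol=1e-12)

    def test_binary_scores_hand_arithmetic(self):
        c, adj = rescale_grs_term(np.log(2.0), np.array([0.0, 1.0]))
        assert c == pytest.approx(np.log(1.5), abs=1e-12)
        np.testing.assert_allclose(np.exp(adj), [2 / 3, 4 / 3], atol=1e-12)
        assert np.exp(adj).mean() == pytest.approx(1.0, abs=1e-10)

    def test_zero_beta_gives_zero(self):
        c, adj = rescale_grs_term(0.0, np.random.default_rng(0).normal(size=50))
        assert c == 0.0
        np.testing.assert_allclose(adj, 0.0)

    def test_mean_hazard_ratio_is_one(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            g = rng.normal(scale=rng.uniform(0.1, 5.0), size=rng.integers(2, 500))
            beta = rng.uniform(-3, 3)
            _, adj = rescale_grs_term(beta, g)
            assert np.exp(adj).mean() == pytest.approx(1.0, abs=1e-10)

    def test_extreme_values_do_not_overflow(self):
        g = np.array([0.0, 500.0, 1000.0])
        c, adj = rescale_grs_term(5.0, g)
        assert np.isfinite(c) and np.isfinite(adj).all()
        # mean of exp(adjusted) is dominated by the largest term; stays finite
        assert np.exp(adj - adj.max()).sum() > 0

    def test_ordering_preserved(self):
        rng = np.random.default_rng(5)
        g = rng.normal(size=100)
        for beta in (0.3, 2.0):
            _, adj = rescale_grs_term(beta, g)
            assert (np.argsort(adj) == np.argsort(beta * g)).all()


class TestCompareModels:
    def test_equal_logliks_give_p_one(self):
        assert compare_models(-100.0, -100.0, 1) == pytest.approx(1.0)

    def test_chi_squared_quantile_identity(self):
        assert compare_models(-100.0, -100.0 + 3.841 / 2, 1) == pytest.approx(
            0.05, abs=1e-3)

    def test_nesting_violation_rejected(self):
        with pytest.raises(ValueError):
            compare_models(-100.0, -101.0, 1)
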