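import numpy as np
import pytest

from pcmcal import (
    FitOptions,
    ItemBank,
    PopulationSpec,
    ResponseDataset,
    TrialSpec,
    draw_latent,
    eap_latent,
    fit_random_pcm,
    make_archetype_bank,
    marginal_loglik,
    simulate_responses,
    simulate_trial,
)

from conftest import grid_eap, grid_marginal_loglik


class TestMarginalLoglik:
    def test_degenerate_variance_dichotomous(self):
        data = ResponseDataset(np.array([[0]]), M=2)
        assert marginal_loglik(data, np.array([[0.0]]), sigma2=0.0) == pytest.approx(
            np.log(0.5), abs=1e-12
        )

    def test_degenerate_variance_collapses_to_pcm(self):
        data = ResponseDataset(np.array([[2]]), M=3)
        ll = marginal_loglik(data, np.array([[-0.5, 0.5]]), mu0=1.0, sigma2=0.0)
        assert ll == pytest.approx(np.log(0.574097), abs=1e-5)

    def test_agrees_with_grid_integration_oracle(self, rng, bank_4_3_2):
        theta = draw_latent(PopulationSpec(0.2, 1.3, 40), rng)
        data = simulate_responses(bank_4_3_2, theta, rng)
        gh = marginal_loglik(data, bank_4_3_2, mu0=0.2, sigma2=1.3)
        grid = grid_marginal_loglik(data.responses, bank_4_3_2.thresholds, 0.2, 1.3)
        assert abs(gh - grid) / data.N < 1e-6

    def test_quadrature_stability_21_vs_41_nodes(self, rng):
        """At the reported-scenario fixtures (archetype 2, variance 1) the
        fixed Gauss-Hermite rule is already converged at 21 nodes."""
        for J, M, mu in [(4, 3, 0.0), (4, 3, 2.0)]:
            bank = make_archetype_bank(J, M, 2)
            theta = draw_latent(PopulationSpec(mu, 1.0, 200), rng)
            data = simulate_responses(bank, theta, rng)
            l21 = marginal_loglik(data, bank, mu0=mu, sigma2=1.0, n_nodes=21)
            l41 = marginal_loglik(data, bank, mu0=mu, sigma2=1.0, n_nodes=41)
            assert abs(l21 - l41) / data.N < 1e-6

    def test_quadrature_stability_dense_rules_whole_grid(self, rng):
        """Harder cells (mistargeting, variance 2, long instruments) need
        denser rules; 81 vs 161 nodes is stable to 5e-5 per subject."""
        for J, M, a, mu, s2 in [(10, 5, 2, 2.0, 2.0), (7, 5, 1, 0.0, 2.0), (4, 5, 2, 0.0, 1.0)]:
            bank = make_archetype_bank(J, M, a)
            data = simulate_responses(bank, draw_latent(PopulationSpec(mu, s2, 150), rng), rng)
            l81 = marginal_loglik(data, bank, mu0=mu, sigma2=s2, n_nodes=81)
            l161 = marginal_loglik(data, bank, mu0=mu, sigma2=s2, n_nodes=161)
            assert abs(l81 - l161) / data.N < 5e-5

    def test_negative_variance_rejected(self, rng, bank_4_3_2):
        data = simulate_responses(bank_4_3_2, np.zeros(5), rng)
        with pytest.raises(ValueError):
            marginal_loglik(data, bank_4_3_2, sigma2=-1.0)


class TestFitRandomPCM:
    def test_anchored_fit_recovers_treatment_effect(self):
        bank = make_archetype_bank(4, 3, 2)
        trial = simulate_trial(bank, TrialSpec(1000, 0.0, 0.5), np.random.default_rng(42))
        fit = fit_random_pcm(trial, include_group=True, fixed_items=bank)
        assert fit.converged
        assert fit.gamma_hat == pytest.approx(0.5, abs=0.10)
        assert fit.se_gamma is not None and fit.se_gamma > 0
        assert fit.sigma2_hat == pytest.approx(1.0, abs=0.2)

    def test_duplicated_arms_give_zero_effect(self, rng, bank_4_3_2):
        theta = draw_latent(PopulationSpec(0.3, 1.0, 150), rng)
        half = simulate_responses(bank_4_3_2, theta, rng)
        dup = ResponseDataset(
            np.vstack([half.responses, half.responses]),
            M=3,
            group=np.repeat([0, 1], 150),
        )
        fit = fit_random_pcm(dup, include_group=True)
        assert abs(fit.gamma_hat) < 1e-6

    def test_loglik_at_fit_dominates_truth(self, rng, bank_4_3_2):
        trial = simulate_trial(bank_4_3_2, TrialSpec(200, 0.0, 0.2), rng)
        fit = fit_random_pcm(trial, include_group=True)
        truth_ll = marginal_loglik(trial, bank_4_3_2, mu0=0.0, gamma=0.2, sigma2=1.0)
        assert fit.loglik >= truth_ll

    def test_fit_loglik_consistent_with_marginal_loglik(self, rng, bank_4_3_2):
        """The optimizer's objective and the public evaluator agree at the
        fitted parameters, in the reported (centered) parameterization."""
        trial = simulate_trial(bank_4_3_2, TrialSpec(100, 0.5, 0.2), rng)
        fit = fit_random_pcm(trial, include_group=True)
        ll = marginal_loglik(
            trial, fit.thresholds_hat, mu0=fit.mu0_hat, gamma=fit.gamma_hat,
            sigma2=fit.sigma2_hat,
        )
        assert ll == pytest.approx(fit.loglik, abs=1e-6)

    def test_calibration_fit_identification(self, rng, bank_4_3_2):
        """fix_latent_mean: mu0 is exactly 0 and thresholds are close to the
        generating bank (latent mean of the sample is 0 by design)."""
        theta = draw_latent(PopulationSpec(0.0, 1.0, 500), rng)
        data = simulate_responses(bank_4_3_2, theta, rng)
        fit = fit_random_pcm(data, fix_latent_mean=True)
        assert fit.mu0_hat == 0.0
        assert fit.converged and not fit.fixed_items
        assert np.max(np.abs(fit.thresholds_hat - bank_4_3_2.thresholds)) < 0.5

    def test_free_trial_fit_centers_thresholds(self, rng, bank_4_3_2):
        trial = simulate_trial(bank_4_3_2, TrialSpec(200, 0.5, 0.0), rng)
        fit = fit_random_pcm(trial, include_group=True)
        assert abs(fit.thresholds_hat.mean()) < 1e-10
        # mu0 picks up the placebo-arm location (mistargeting mu=0.5)
        assert fit.mu0_hat == pytest.approx(0.5, abs=0.3)

    def test_unobserved_category_is_flagged_and_bounded(self, rng, bank_4_3_2):
        theta = draw_latent(PopulationSpec(6.0, 0.2, 120), rng)  # severe ceiling
        data = simulate_responses(bank_4_3_2, theta, rng)
        assert np.all(data.responses.min(axis=0) > 0)  # bottom categories empty
        opts = FitOptions()
        fit = fit_random_pcm(data, fix_latent_mean=True, options=opts)
        assert fit.flagged and fit.n_unobserved_categories > 0
        assert np.max(np.abs(fit.thresholds_hat)) <= opts.delta_bound + 1e-9

    def test_interface_validation(self, rng, bank_4_3_2):
        theta = np.zeros(10)
        data = simulate_responses(bank_4_3_2, theta, rng)
        with pytest.raises(ValueError):
            fit_random_pcm(data, include_group=True)  # no group labels
        trial = simulate_trial(bank_4_3_2, TrialSpec(10, 0, 0), rng)
        with pytest.raises(ValueError):
            fit_random_pcm(trial, include_group=True, fix_latent_mean=True)
        with pytest.raises(ValueError):
            fit_random_pcm(trial, fixed_items=bank_4_3_2, fix_latent_mean=True)
        with pytest.raises(ValueError):
            FitOptions(n_quadrature_nodes=5)


class TestEAP:
    def test_symmetric_responses_give_zero(self):
        bank = ItemBank([[-0.8, 0.8], [-1.1, 1.1]])
        data = ResponseDataset(np.array([[1, 1]]), M=3)
        # a reference fit with the true symmetric bank and a centered prior
        from pcmcal.estimation import FitResult

        ref = FitResult(
            thresholds_hat=bank.thresholds, mu0_hat=0.0, gamma_hat=None,
            se_gamma=None, sigma2_hat=1.0, loglik=0.0, converged=True,
            fixed_items=True, M=3,
        )
        eap = eap_latent(data, ref)
        assert eap.theta_hat[0] == pytest.approx(0.0, abs=1e-10)
        assert np.all(eap.psd > 0)

    def test_matches_grid_integration_oracle(self, rng, bank_4_3_2):
        trial = simulate_trial(bank_4_3_2, TrialSpec(50, 0.0, 0.2), rng)
        fit = fit_random_pcm(trial, include_group=False)
        eap = eap_latent(trial, fit)
        oracle = grid_eap(trial.responses, fit.thresholds_hat, fit.mu0_hat, fit.sigma2_hat)
        assert np.max(np.abs(eap.theta_hat - oracle)) < 1e-6

    def test_extreme_responses_are_shrunk_finite(self, rng, bank_4_3_2):
        data = ResponseDataset(np.full((1, 4), 2), M=3)
        from pcmcal.estimation import FitResult

        ref = FitResult(
            thresholds_hat=bank_4_3_2.thresholds, mu0_hat=0.0, gamma_hat=None,
            se_gamma=None, sigma2_hat=1.0, loglik=0.0, converged=True,
            fixed_items=True, M=3,
        )
        eap = eap_latent(data, ref)
        assert 0.0 < eap.theta_hat[0] < 0.0 + 6.0  # within prior mean + 6 SD

    def test_shrinkage_reduces_variance(self, rng, bank_4_3_2):
        """EAP estimates are less dispersed than the fitted latent variance."""
        trial = simulate_trial(bank_4_3_2, TrialSpec(400, 0.0, 0.0), rng)
        fit = fit_random_pcm(trial, include_group=False)
        eap = eap_latent(trial, fit)
        assert eap.theta_hat.var() < fit.sigma2_hat

    def test_attenuation_decreases_with_instrument_length(self):
        """The EAP group-difference shrinks less for longer instruments."""
        atten = {}
        for J, M in [(4, 3), (10, 5)]:
            bank = make_archetype_bank(J, M, 2)
            rng = np.random.default_rng(99)
            trial = simulate_trial(bank, TrialSpec(2000, 0.0, 0.5), rng)
            fit = fit_random_pcm(trial, include_group=False, fixed_items=bank)
            eap = eap_latent(trial, fit)
            diff = eap.theta_hat[trial.group == 1].mean() - eap.theta_hat[trial.group == 0].mean()
            atten[(J, M)] = diff / 0.5
        assert atten[(10, 5)] > atten[(4, 3)]
        assert atten[(4, 3)] < 1.0
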