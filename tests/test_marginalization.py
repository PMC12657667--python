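import math

import numpy as np
import pytest
from scipy.special import expit, logit

from gmaic import ScenarioConfig, aggregate_ipd, estimate_weights, fit_outcome_model
from gmaic import dgp_scenarios as dgp
from gmaic.marginalization import (
    ald_log_or,
    bucher,
    dirichlet_concentration,
    gcomp_parametric,
    gmaic,
    simulate_ald_population,
)
from gmaic.outcome_regression import PosteriorSample
from gmaic.trial_data import ALDSummary


def degenerate_posterior(beta0=0.0, beta_t=0.0, pf=0.0, em=0.0, K=1, L=5):
    return PosteriorSample(
        beta0=np.full(L, float(beta0)),
        beta_t=np.full(L, float(beta_t)),
        beta_pf=np.full((L, K), float(pf)),
        beta_em=np.full((L, K), float(em)),
        diagnostics={},
    )


class TestALDLogOR:
    def test_textbook_two_by_two(self):
        ald = ALDSummary([0.5], [0.1], n_B=100, n_C=100, events_B=30, events_C=50)
        est, se = ald_log_or(ald)
        assert est == pytest.approx(math.log(3 / 7), abs=1e-10)
        assert se == pytest.approx(math.sqrt(1 / 30 + 1 / 70 + 1 / 50 + 1 / 50), abs=1e-10)

    def test_equal_odds_give_zero(self):
        ald = ALDSummary([0.5], [0.1], n_B=80, n_C=120, events_B=20, events_C=30)
        assert ald_log_or(ald)[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_cell_continuity_corrected(self):
        ald = ALDSummary([0.5], [0.1], n_B=100, n_C=100, events_B=30, events_C=0)
        est, se = ald_log_or(ald)
        assert np.isfinite(est) and np.isfinite(se)


class TestBucher:
    def test_pythagorean_se(self):
        est = bucher((-1.0, 0.3), (-0.5, 0.4))
        assert est.point == pytest.approx(-0.5)
        assert est.se == pytest.approx(0.5)
        assert est.ci_low == pytest.approx(-0.5 - 1.96 * 0.5)

    def test_identical_contrasts_cancel(self):
        assert bucher((-0.7, 0.2), (-0.7, 0.1)).point == pytest.approx(0.0)

    def test_zero_component_se(self):
        assert bucher((0.1, 0.0), (0.0, 0.25)).se == pytest.approx(0.25)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            bucher((np.inf, 0.1), (0.0, 0.1))


class TestGcompParametric:
    def test_all_zero_posterior_gives_minus_anchor(self, rng):
        post = degenerate_posterior()
        ald = ALDSummary([0.5], [0.2], n_B=100, n_C=100, events_B=30, events_C=50)
        est = gcomp_parametric(post, ald, "mvn", np.eye(1), ald_log_or(ald), rng=rng)
        assert est.point == pytest.approx(-ald_log_or(ald)[0], abs=1e-12)
        assert np.allclose(est.draws, 0.0)

    def test_collapsible_case_returns_conditional_effect(self, rng):
        c = -0.8
        post = degenerate_posterior(beta0=0.2, beta_t=c)
        ald = ALDSummary([0.5], [0.2], n_B=100, n_C=100, events_B=40, events_C=40)
        est = gcomp_parametric(post, ald, "mvn", np.eye(1), (0.0, 0.0), rng=rng)
        assert est.point == pytest.approx(c, abs=1e-10)

    def test_quadrature_oracle_one_covariate(self, rng):
        """Marginal logit contrast over an mvn population matches 1-D
        Gauss-Hermite integration of the logistic model."""
        b0, bt, bpf, bem = -0.4, -1.0, 0.6, 0.8
        post = degenerate_posterior(b0, bt, bpf, bem, L=3)
        mean, sd = 0.5, 0.3
        ald = ALDSummary([mean], [sd], n_B=100, n_C=100, events_B=30, events_C=30)
        nodes, wts = np.polynomial.hermite_e.hermegauss(64)
        x = mean + sd * nodes
        mu1 = np.sum(wts * expit(b0 + bt + x * (bpf + bem))) / np.sum(wts)
        mu0 = np.sum(wts * expit(b0 + x * bpf)) / np.sum(wts)
        oracle = logit(mu1) - logit(mu0)
        est = gcomp_parametric(
            post, ald, "mvn", np.eye(1), (0.0, 0.0), n_star=100_000, rng=rng
        )
        assert est.point == pytest.approx(oracle, abs=5e-3)

    def test_population_moment_matching(self, rng):
        """Simulated populations reproduce the ALD moments for both
        parametric families, and Bernoulli columns for flagged binaries."""
        ald = ALDSummary(
            [0.6, 0.4], [0.2, np.nan], n_B=50, n_C=50, events_B=10, events_C=10
        )
        corr = np.eye(2)
        mvn = simulate_ald_population(ald, "mvn", corr, 200_000, rng)
        assert np.allclose(mvn.mean(axis=0), [0.6, 0.4], atol=0.01)
        gam = simulate_ald_population(
            ald, "mvgamma", corr, 200_000, rng, binary_cols=np.array([False, True])
        )
        assert np.allclose(gam.mean(axis=0), [0.6, 0.4], atol=0.01)
        assert np.all(gam[:, 0] > 0)
        assert set(np.unique(gam[:, 1])) <= {0.0, 1.0}

    def test_degenerate_draws_counted_and_invalid_when_all_lost(self, rng):
        post = degenerate_posterior(beta0=800.0)  # saturates to p=1
        ald = ALDSummary([0.5], [0.2], n_B=100, n_C=100, events_B=30, events_C=30)
        est = gcomp_parametric(post, ald, "mvn", np.eye(1), (0.0, 0.1), rng=rng)
        assert not est.valid
        assert est.info["degenerate_draws"] == 5


class TestDirichletWeights:
    def test_mean_matches_normalized_weights(self, rng):
        w = estimate_weights(rng.normal(size=(30, 2)), rng.normal(size=2) * 0.1 + 0.0)
        assert w.converged
        a = dirichlet_concentration(w)
        draws = rng.dirichlet(a, size=10_000)
        mc_se = draws.std(axis=0) / math.sqrt(10_000)
        assert np.all(np.abs(draws.mean(axis=0) - w.w_norm) < 4 * mc_se + 1e-12)
        np.testing.assert_allclose(draws.sum(axis=1), 1.0, atol=1e-12)

    def test_concentration_sums_to_n(self, rng):
        w = estimate_weights(rng.normal(size=(25, 2)), np.zeros(2))
        assert dirichlet_concentration(w).sum() == pytest.approx(25.0)

    def test_tempering_raises_concentration_ess(self, rng):
        from gmaic import ess

        w = estimate_weights(rng.normal(size=(60, 2)), np.full(2, 0.5))
        assert ess(dirichlet_concentration(w, temper=0.5)) > ess(dirichlet_concentration(w))

    def test_invalid_temper_rejected(self, rng):
        w = estimate_weights(rng.normal(size=(10, 1)), np.zeros(1))
        with pytest.raises(ValueError):
            dirichlet_concentration(w, temper=0.0)


class TestGMAIC:
    def _weighted_trial(self, rng, n=80):
        cfg = ScenarioConfig(n_ipd=n, overlap="moderate", structure="normal")
        trial = dgp.simulate_trial(cfg, "AC", rng)
        target = dgp.resolve_models(cfg)["BC"].means
        weights = estimate_weights(trial.X, target)
        assert weights.converged
        return trial, weights

    def test_zero_posterior_gives_zero_contrast_any_weights(self, rng):
        trial, weights = self._weighted_trial(rng)
        post = degenerate_posterior(K=5, L=8)
        est = gmaic(post, trial, weights, (0.3, 0.1), rng=rng)
        assert np.allclose(est.draws, 0.0)
        assert est.point == pytest.approx(-0.3)

    def test_large_concentration_collapses_to_fixed_weight_gcomp(self, rng):
        """Scaling the Dirichlet concentration by 1e6 recovers plain
        G-computation over the reweighted empirical distribution."""
        trial, weights = self._weighted_trial(rng)
        post = fit_outcome_model(trial, L=20, rng=rng, method="laplace")
        est = gmaic(post, trial, weights, (0.0, 0.0), rng=rng, concentration_scale=1e6)
        from gmaic.outcome_regression import predict_prob_matrix

        mu1 = weights.w_norm @ predict_prob_matrix(post, trial.X, 1)
        mu0 = weights.w_norm @ predict_prob_matrix(post, trial.X, 0)
        oracle = logit(mu1) - logit(mu0)
        np.testing.assert_allclose(est.draws, oracle, atol=2e-3)

    def test_single_profile_population(self, rng):
        """With n=1 the Dirichlet is a point mass and the contrast is the
        profile-level logit difference."""
        from gmaic import IPDTrial
        from gmaic.maic_core import MAICWeights

        trial = IPDTrial(y=[1], t=[1], X=[[0.4]], covariate_names=["x1"])
        w = MAICWeights(
            alpha=np.zeros(1), w=np.ones(1), w_norm=np.ones(1), ess=1.0,
            converged=True, balance_residual=np.zeros(1),
        )
        post = degenerate_posterior(beta0=0.1, beta_t=-0.7, pf=0.5, em=0.2, L=4)
        est = gmaic(post, trial, w, (0.0, 0.0), rng=rng)
        eta0 = 0.1 + 0.4 * 0.5
        eta1 = 0.1 - 0.7 + 0.4 * (0.5 + 0.2)
        assert est.point == pytest.approx(eta1 - eta0, abs=1e-10)

    def test_unconverged_weights_invalidate(self, rng):
        trial, weights = self._weighted_trial(rng)
        weights.converged = False
        post = degenerate_posterior(K=5)
        est = gmaic(post, trial, weights, (0.0, 0.1), rng=rng)
        assert not est.valid

    def test_tempering_strictly_flattens_concentration(self, rng):
        """Tempering with an exponent below one strictly increases the ESS
        of the Dirichlet concentration whenever the weights are non-uniform
        (the total concentration stays n), pulling the mean of the random
        weights toward uniformity."""
        from gmaic.maic_core import MAICWeights, ess as kish

        for seed in range(5):
            r = np.random.default_rng(seed)
            w_norm = r.dirichlet(np.full(40, 0.3))
            weights = MAICWeights(
                alpha=np.zeros(1), w=w_norm * 40, w_norm=w_norm, ess=kish(w_norm),
                converged=True, balance_residual=np.zeros(1),
            )
            a_full = dirichlet_concentration(weights)
            a_temp = dirichlet_concentration(weights, temper=0.5)
            assert a_temp.sum() == pytest.approx(40.0)
            assert kish(a_temp) > kish(a_full)
            # tempered mean weights sit between the original and uniform
            assert a_temp.max() < a_full.max()
            assert a_temp.min() > a_full.min()


class TestAnchoringIdentity:
    def test_point_plus_anchor_reconstructs_adjusted_contrast(self, rng):
        """For every marginal method, adding back the BC log-OR recovers
        the adjusted A-vs-C contrast (the mean per-draw contrast)."""
        cfg = ScenarioConfig(n_ipd=150, overlap="high", structure="normal")
        trial = dgp.simulate_trial(cfg, "AC", rng)
        bc = dgp.simulate_trial(cfg, "BC", rng)
        ald = aggregate_ipd(bc)
        anchor = ald_log_or(ald)
        post = fit_outcome_model(trial, L=100, rng=rng, method="laplace")
        weights = estimate_weights(trial.X, ald.cov_means)
        corr = np.corrcoef(trial.X, rowvar=False)
        g = gcomp_parametric(post, ald, "mvn", corr, anchor, rng=rng)
        gm = gmaic(post, trial, weights, anchor, rng=rng)
        for est in (g, gm):
            assert est.point + anchor[0] == pytest.approx(float(est.draws.mean()), abs=1e-12)


class TestGMAICGcompConsistency:
    def test_agreement_when_ald_is_aggregated_ipd(self):
        """When the 'ALD' is the aggregated IPD itself (same population,
        correct covariate family), G-MAIC and parametric G-computation
        agree within 3 combined SEs."""
        cfg = ScenarioConfig(n_ipd=600, overlap="high", structure="normal")
        n_agree, n_total = 0, 60
        for seed in range(n_total):
            rng = np.random.default_rng(1000 + seed)
            trial = dgp.simulate_trial(cfg, "AC", rng)
            ald = aggregate_ipd(trial)
            anchor = ald_log_or(ald)
            post = fit_outcome_model(trial, L=300, rng=rng, method="laplace")
            weights = estimate_weights(trial.X, ald.cov_means)
            corr = np.corrcoef(trial.X, rowvar=False)
            g = gcomp_parametric(post, ald, "mvn", corr, anchor, rng=rng)
            gm = gmaic(post, trial, weights, anchor, rng=rng)
            if abs(g.point - gm.point) < 3 * math.sqrt(g.se**2 + gm.se**2):
                n_agree += 1
        assert n_agree >= n_total - 1
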