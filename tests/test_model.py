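"""Gibbs sampler correctness: conditionals, oracles, reductions, recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

import pleiomr as pm
from pleiomr.ld import BlockLD
from pleiomr.model import (ModelState, _BlockData, _class_precision,
                           kron_precision, init_state)
from .conftest import make_pairs


class TestDecomposeCHP:
    @pytest.mark.parametrize("rho,sa,sg,delta,sat", [
        (0.0, 0.3, 0.1, 0.0, 0.3),            # uncorrelated limit
        (1.0, 0.3, 0.1, 3.0, 0.0),            # pure shared confounding
        (0.2, 0.1, 0.1, 0.2, 0.1 * np.sqrt(0.96)),
    ])
    def test_arithmetic(self, rho, sa, sg, delta, sat):
        d, s = pm.decompose_chp(rho, sa, sg)
        assert d == pytest.approx(delta)
        assert s == pytest.approx(sat)

    def test_invalid_inputs(self):
        with pytest.raises(pm.ConfigurationError):
            pm.decompose_chp(0.2, -1.0, 0.1)
        with pytest.raises(pm.ConfigurationError):
            pm.decompose_chp(1.5, 0.1, 0.1)


class TestInitState:
    def test_deterministic_and_positive_variances(self):
        pairs = make_pairs(p=12, L=3)
        data = _BlockData(pairs, pm.identity_ld(pairs), 0.0)
        a = init_state(data, pm.Hyperpriors(), 0.0)
        b = init_state(data, pm.Hyperpriors(), 0.0)
        assert a.sigma_gamma2 == b.sigma_gamma2 > 0
        assert a.tau1_2 > 0 and a.tau2_2 > a.tau1_2
        assert a.beta1 == a.beta2 == 0.0

    def test_degenerate_all_zero_outcome_keeps_variance_floor(self):
        pairs = make_pairs(p=8, L=2)
        pairs["Gamma_hat"] = 0.0
        data = _BlockData(pairs, pm.identity_ld(pairs), 0.0)
        st = init_state(data, pm.Hyperpriors(), 0.0)
        assert st.tau1_2 >= 1e-8


class TestRelabel:
    def _state(self, tau1, tau2, xi2=1.0):
        return ModelState(beta1=0.1, beta2=0.5, gamma=np.zeros(2),
                          Gamma=np.zeros(2), eta=np.array([1, 0], dtype=np.int8),
                          sigma_gamma2=1.0, tau1_2=tau1, tau2_2=tau2, xi2=xi2,
                          omega=0.2, rho_e=0.0)

    def test_well_ordered_state_unchanged(self):
        st = self._state(0.1, 0.5)
        pm.relabel(st)
        assert (st.beta1, st.beta2) == (0.1, 0.5)
        assert st.relabel_count == 0

    def test_swap_restores_variance_ordering(self):
        st = self._state(0.5, 0.1, xi2=2.0)   # xi2*tau1 = 1.0 > tau2 = 0.1
        pm.relabel(st)
        assert (st.beta1, st.beta2) == (0.5, 0.1)
        assert st.tau1_2 == 0.1 and st.tau2_2 == 1.0 and st.xi2 == 1.0
        assert st.eta.tolist() == [0, 1]
        assert st.omega == pytest.approx(0.8)
        assert st.tau2_2 >= st.xi2 * st.tau1_2

    def test_idempotent(self):
        st = self._state(0.5, 0.1)
        pm.relabel(st)
        c = st.relabel_count
        pm.relabel(st)
        assert st.relabel_count == c


def dense_joint_precision(R, s_g, s_G, rho_e, b, t2, sg2):
    """Independent dense oracle for one block's (u, v) conditional precision.

    Likelihood: z ~ N(M w, R_e (x) R), M = blockdiag(R, R); prior:
    u ~ N(0, sg2 * S_g^-2), v | u ~ N(b * S_G^-1 S_g u, t2 * S_G^-2).
    Assembled with explicit Kronecker products and inverses.
    """
    m = len(s_g)
    Re = np.array([[1.0, rho_e], [rho_e, 1.0]])
    Sigma = np.kron(Re, R)
    M = np.zeros((2 * m, 2 * m))
    M[:m, :m] = R
    M[m:, m:] = R
    lik = M.T @ np.linalg.inv(Sigma) @ M
    A = np.diag(s_g / s_G)
    Cu = sg2 * np.diag(1.0 / s_g ** 2)
    Cw = np.zeros((2 * m, 2 * m))
    Cw[:m, :m] = Cu
    Cw[:m, m:] = b * Cu @ A
    Cw[m:, :m] = b * A @ Cu
    Cw[m:, m:] = b * b * A @ Cu @ A + t2 * np.diag(1.0 / s_G ** 2)
    return lik + np.linalg.inv(Cw)


class TestLatentConditional:
    """The batched per-block update vs a dense Kronecker-assembly oracle."""

    @pytest.mark.parametrize("rho_e", [0.0, 0.3, -0.4])
    def test_precision_matches_dense_oracle(self, rho_e):
        rng = np.random.default_rng(0)
        pairs = make_pairs(p=10, L=2, seed=1)
        ld = []
        for b, sub in pairs.groupby("block_index"):
            m = len(sub)
            X = rng.standard_normal((40, m))
            R = pm.shrink_corr(np.corrcoef(X, rowvar=False), 0.85)
            ld.append(BlockLD(int(b), sub["variant_id"].tolist(), R))
        data = _BlockData(pairs, ld, rho_e)
        b_val, t2, sg2 = 0.3, 0.02, 0.5
        for cls in data.classes:
            P = _class_precision(cls, np.full(len(cls.block_ids), b_val),
                                 np.full(len(cls.block_ids), t2), sg2)
            for i, blk in enumerate(cls.block_ids):
                R = ld[blk].R
                oracle = dense_joint_precision(
                    R, cls.s_gamma[i], cls.s_Gamma[i], rho_e, b_val, t2, sg2)
                np.testing.assert_allclose(P[i], oracle, atol=1e-10)

    def test_zero_overlap_reduces_to_block_diagonal_likelihood(self):
        """rho_e = 0 collapses the joint likelihood precision to the two
        independent per-trait multivariate normals."""
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 4))
        R = pm.shrink_corr(np.corrcoef(X, rowvar=False), 0.85)
        Q = kron_precision(R, 0.0)
        expected = np.zeros((8, 8))
        expected[:4, :4] = R
        expected[4:, 4:] = R
        np.testing.assert_array_equal(Q, expected)


def grid_posterior_oracle(pairs, R, rho_e, fixed, sigma_beta2,
                          grid=np.arange(-1.0, 1.0005, 0.001)):
    """Dense numerical posterior of (beta1, eta) for a single block.

    Marginalises the latent effects analytically: given (beta1, eta) the
    scaled observations z are zero-mean Gaussian with covariance
    R_e (x) R + M C_w M'; the grid enumerates beta1 x eta in {0, 1}.
    """
    s_g = pairs["s_gamma"].to_numpy()
    s_G = pairs["s_Gamma"].to_numpy()
    z = np.concatenate([pairs["gamma_hat"] / s_g, pairs["Gamma_hat"] / s_G])
    m = len(s_g)
    Re = np.array([[1.0, rho_e], [rho_e, 1.0]])
    Sigma = np.kron(Re, R)
    M = np.zeros((2 * m, 2 * m))
    M[:m, :m] = R
    M[m:, m:] = R
    A = np.diag(s_g / s_G)
    Cu = fixed["sigma_gamma2"] * np.diag(1.0 / s_g ** 2)

    def loglik(b, t2):
        Cw = np.zeros((2 * m, 2 * m))
        Cw[:m, :m] = Cu
        Cw[:m, m:] = b * Cu @ A
        Cw[m:, :m] = b * A @ Cu
        Cw[m:, m:] = b * b * A @ Cu @ A + t2 * np.diag(1.0 / s_G ** 2)
        return stats.multivariate_normal.logpdf(z, cov=Sigma + M @ Cw @ M.T)

    omega = fixed["omega"]
    var0 = fixed["xi2"] * fixed["tau1_2"]
    lp = np.empty((len(grid), 2))
    ll_eta1 = loglik(fixed["beta2"], fixed["tau2_2"])  # independent of beta1
    for i, b1 in enumerate(grid):
        prior = stats.norm.logpdf(b1, scale=np.sqrt(sigma_beta2))
        lp[i, 0] = prior + np.log1p(-omega) + loglik(b1, var0)
        lp[i, 1] = prior + np.log(omega) + ll_eta1
    w = np.exp(lp - lp.max())
    w /= w.sum()
    return float((w.sum(axis=1) * grid).sum()), float(w[:, 1].sum())


class TestGridOracle:
    def test_joint_posterior_matches_dense_grid_integration(self):
        """Gibbs marginal posterior of (beta1, eta) on a 2-instrument
        single-block problem equals exhaustive grid integration."""
        rng = np.random.default_rng(3)
        R = np.array([[1.0, 0.4], [0.4, 1.0]])
        s = 0.02
        pairs = pd.DataFrame({
            "variant_id": ["a", "b"], "chrom": "1", "pos": [1, 2],
            "effect_allele": "A", "other_allele": "G",
            "gamma_hat": [0.12, 0.08], "s_gamma": s,
            "Gamma_hat": [0.05, 0.02], "s_Gamma": s,
            "block_index": 0,
        })
        fixed = {"sigma_gamma2": 0.01, "tau1_2": 4e-4, "tau2_2": 4e-3,
                 "xi2": 1.0, "omega": 0.2, "beta2": 0.6}
        # beta1 prior sd = 0.2 keeps essentially all prior mass inside the
        # integration grid, so truncation error is negligible
        hyper = pm.Hyperpriors(sigma_beta2=0.04)
        rho_e = 0.25
        oracle_mean, oracle_pr = grid_posterior_oracle(
            pairs, R, rho_e, fixed, hyper.sigma_beta2)
        fit = pm.run_mcmc(pairs, [BlockLD(0, ["a", "b"], R)], hyper=hyper,
                          rho_e=rho_e, n_iter=42_000, burn_in=2_000,
                          seed=5, fixed=fixed, relabel_enabled=False)
        assert fit.beta1_hat == pytest.approx(oracle_mean, abs=0.01)
        assert fit.pr_eta[0] == pytest.approx(oracle_pr, abs=0.01)


class TestReductions:
    def test_fit_independent_is_singleton_identity_mcmc(self):
        pairs = make_pairs(p=10, L=2, seed=2)
        a = pm.fit_independent(pairs, seed=11, n_iter=300, burn_in=100)
        singles = pm.singleton_blocks(pairs)
        b = pm.run_mcmc(singles, pm.identity_ld(singles), rho_e=0.0,
                        seed=11, n_iter=300, burn_in=100)
        for k in a.chains:
            np.testing.assert_array_equal(a.chains[k], b.chains[k])
        np.testing.assert_array_equal(a.pr_eta, b.pr_eta)

    def test_identity_ld_equals_shrunk_identity(self):
        pairs = make_pairs(p=9, L=3, seed=4)
        ld_a = pm.identity_ld(pairs)
        ld_b = [BlockLD(b.block_index, b.variant_ids,
                        pm.shrink_corr(np.eye(len(b.variant_ids)), 0.85))
                for b in ld_a]
        a = pm.run_mcmc(pairs, ld_a, seed=3, n_iter=300, burn_in=100)
        b = pm.run_mcmc(pairs, ld_b, seed=3, n_iter=300, burn_in=100)
        np.testing.assert_array_equal(a.chains["beta1"], b.chains["beta1"])

    def test_ivw_limit_of_beta1_conditional(self):
        """With all labels clean, latents at the observed effects and the
        residual variance sent to zero, the beta1 full conditional collapses
        to the fixed-effect IVW slope (equal outcome standard errors)."""
        from pleiomr.model import beta_conditional_moments
        pairs = make_pairs(p=30, L=1, seed=5, beta1=0.25)
        g = pairs["gamma_hat"].to_numpy()
        G = pairs["Gamma_hat"].to_numpy()
        ivw_beta, ivw_se, _ = pm.ivw_baseline(pairs)
        mean, var = beta_conditional_moments(g, G, 1e-12, sigma_beta2=100.0)
        assert mean == pytest.approx(ivw_beta, rel=1e-6)
        assert var < 1e-9


class TestSamplerBehaviour:
    def test_deterministic_given_seed(self):
        pairs = make_pairs(p=12, L=4, seed=7)
        a = pm.run_mcmc(pairs, pm.identity_ld(pairs), seed=1, n_iter=400, burn_in=100)
        b = pm.run_mcmc(pairs, pm.identity_ld(pairs), seed=1, n_iter=400, burn_in=100)
        assert a.beta1_hat == b.beta1_hat
        np.testing.assert_array_equal(a.chains["omega"], b.chains["omega"])

    def test_chain_bookkeeping_with_thinning(self):
        pairs = make_pairs(p=8, L=2)
        fit = pm.run_mcmc(pairs, pm.identity_ld(pairs), seed=2, n_iter=1_000,
                          burn_in=400, thin=3)
        assert fit.n_kept == 200
        assert len(fit.chains["beta1"]) == 200
        assert np.all((fit.pr_eta >= 0) & (fit.pr_eta <= 1))

    def test_null_data_chain_is_stationary_around_zero(self):
        """All-zero observations with unit errors: beta1 wanders around 0."""
        p = 20
        pairs = make_pairs(p=p, L=4)
        pairs[["gamma_hat", "Gamma_hat"]] = 0.0
        pairs[["s_gamma", "s_Gamma"]] = 1.0
        fit = pm.run_mcmc(pairs, pm.identity_ld(pairs), seed=8, n_iter=2_000,
                          burn_in=500)
        assert abs(fit.beta1_hat) < 3 * fit.beta1_sd

    def test_degenerate_prior_pins_labels_and_recovers_beta1(self):
        """omega ~ Beta(1, 1e9) pins every block clean; on pleiotropy-free
        data the posterior mean recovers the generating slope."""
        pairs = make_pairs(p=60, L=12, seed=9, beta1=0.2)
        hyper = pm.Hyperpriors(a_omega=1.0, b_omega=1e9)
        fit = pm.run_mcmc(pairs, pm.identity_ld(pairs), hyper=hyper,
                          seed=10, n_iter=1_500, burn_in=500)
        assert fit.pr_eta.max() < 0.05
        assert fit.beta1_hat == pytest.approx(0.2, abs=0.02)

    def test_nonfinite_input_raises(self):
        pairs = make_pairs(p=6, L=2)
        pairs.loc[0, "s_gamma"] = -1.0
        with pytest.raises(pm.ConfigurationError):
            pm.run_mcmc(pairs, pm.identity_ld(pairs), seed=0, n_iter=10, burn_in=1)


class TestCHPClassification:
    def test_threshold_rule(self):
        s = pm.PosteriorSummary(
            beta1_hat=0.1, beta1_sd=0.01, beta1_ci=(0.08, 0.12), p_value=0.0,
            delta_hat=0.2, pr_eta=np.array([0.9, 0.5]),
            chp_blocks=np.array([0]), ess_beta1=10, n_kept=10, relabel_frac=0,
            variant_ids=np.array(["a", "b", "c", "d"]),
            block_of_iv=np.array([0, 0, 1, 1]))
        blocks, table = pm.classify_chp(s, 0.8)
        assert blocks.tolist() == [0]
        assert table["is_chp"].tolist() == [True, True, False, False]
        blocks_all, _ = pm.classify_chp(s, 0.0)
        assert blocks_all.tolist() == [0, 1]
        assert table["chp_strength"].max() <= 16.0

    def test_detection_auc_on_strong_chp(self, chp_study, chp_fit):
        """Posterior block probabilities separate pleiotropic from clean
        blocks (AUC > 0.8 at h2_alpha = 0.1)."""
        auc = roc_auc_score(chp_study.truth.eta_true, chp_fit.pr_eta)
        assert auc > 0.8

    def test_relabel_rare_on_well_separated_data(self, chp_fit):
        assert chp_fit.relabel_frac < 0.05

    def test_pr_eta_monotone_in_chp_heritability(self):
        """Stronger correlated pleiotropy raises the mean posterior label
        probability on truly pleiotropic blocks."""
        means = {}
        for h2a in (0.05, 0.1):
            study = pm.simulate_study(pm.SimConfig(
                n_x=10_000, n_y=10_000, n_r=1_000, p=300, L=30,
                h2_alpha=h2a, seed=21))
            fit = pm.run_mcmc(study.pairs, study.ld, n_iter=1_200,
                              burn_in=400, seed=21)
            means[h2a] = fit.pr_eta[study.truth.eta_true].mean()
        assert means[0.1] >= means[0.05]

    def test_estimator_facade_exposes_fit_attributes(self, chp_study):
        est = pm.CorrelatedPleiotropyMR(n_iter=400, burn_in=100,
                                        random_state=0)
        est.fit(chp_study.pairs, ld=chp_study.ld)
        assert est.p_value_ <= 1.0
        assert len(est.pr_eta_) == 50
        assert est.beta1_ci_[0] <= est.beta1_ <= est.beta1_ci_[1]
        params = est.get_params()
        assert params["n_iter"] == 400
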