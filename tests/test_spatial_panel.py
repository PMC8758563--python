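"""Panel diagnostics, spatial ML estimation, effects, model selection."""

import numpy as np
import pytest
from scipy import stats

from healthprod.spatial_panel import (
    SpatialPanelFit,
    decompose_effects,
    fit_panel_fe,
    fit_panel_re,
    fit_spatial_panel,
    hausman_test,
    ht_unit_root,
    lm_diagnostics,
    lr_wald_degeneracy,
    select_model,
)
from healthprod.synthetic import SDMSpec, generate_sdm_panel
from healthprod.weights import SpatialWeightMatrix

BETA = np.array([1.0, -0.5, 0.3])
THETA = np.array([0.2, 0.1, -0.3])


class TestHTUnitRoot:
    def test_random_walk_fixed_T_plim(self):
        """Demeaned random walks: pooled AR(1) -> 1 - 3/(T+1) = 0.75 at T=11."""
        rng = np.random.default_rng(1)
        rhos = [ht_unit_root(np.cumsum(rng.normal(size=(200, 12)), axis=1))[0]
                for _ in range(10)]
        assert abs(np.mean(rhos) - 0.75) < 0.02

    def test_iid_noise_rejects_unit_root(self):
        rng = np.random.default_rng(2)
        _, _, p = ht_unit_root(rng.normal(size=(100, 12)))
        assert p < 0.01

    def test_random_walk_not_rejected(self):
        rng = np.random.default_rng(3)
        _, _, p = ht_unit_root(np.cumsum(rng.normal(size=(200, 12)), axis=1))
        assert p > 0.01

    def test_too_short_panel_rejected(self):
        with pytest.raises(ValueError):
            ht_unit_root(np.zeros((5, 2)))

    def test_unbalanced_panel_rejected(self):
        panel = np.ones((5, 6))
        panel[0, 3] = np.nan
        with pytest.raises(ValueError, match="balanced"):
            ht_unit_root(panel)


class TestLMDiagnostics:
    def test_all_statistics_nonnegative(self, china_w):
        rng = np.random.default_rng(0)
        for seed in range(5):
            s = SDMSpec(W=china_w, n_years=6, rho=0.3, beta=BETA[:2],
                        theta_durbin=THETA[:2], seed=seed)
            y, X = generate_sdm_panel(s)
            lm = lm_diagnostics(y, X, china_w)
            for stat, p in lm.values():
                assert stat >= 0.0
                assert 0.0 <= p <= 1.0

    def test_spatial_lag_dgp_detected(self, china_w):
        s = SDMSpec(W=china_w, n_years=11, rho=0.5, beta=BETA[:2],
                    fixed_effects="none", seed=4)
        y, X = generate_sdm_panel(s)
        lm = lm_diagnostics(y, X, china_w)
        assert lm["lm_lag"][1] < 0.01

    def test_orthogonal_residual_zero_lm_error(self, china_w):
        """LM-error is the squared residual cross-product e'We: a panel
        whose OLS residuals are spatially uncorrelated gives a tiny value."""
        rng = np.random.default_rng(8)
        T, n = 40, 31
        X = rng.normal(size=(T, n, 2))
        y = X @ BETA[:2] + rng.normal(size=(T, n))
        lm = lm_diagnostics(y, X, china_w)
        assert lm["lm_error"][0] < stats.chi2(1).ppf(0.99)


class TestSpatialML:
    def test_zero_weight_matrix_collapses_to_ols(self, china_w):
        s = SDMSpec(W=china_w, n_years=11, rho=0.4, beta=BETA,
                    theta_durbin=THETA, fixed_effects="time", sigma=0.5, seed=1)
        y, X = generate_sdm_panel(s)
        W0 = SpatialWeightMatrix(list(range(31)), np.zeros((31, 31)),
                                 standardized="row")
        slm = fit_spatial_panel(y, X, W0, "SLM", "time")
        ols = fit_spatial_panel(y, X, W0, "OLS", "time")
        assert slm.rho == 0.0
        np.testing.assert_allclose(slm.beta, ols.beta, atol=1e-12)
        assert slm.loglik == pytest.approx(ols.loglik, abs=1e-8)

    def test_sdm_parameter_recovery(self, china_w):
        """Bias and SD over 50 seeded replicates at rho=0.4, time FE."""
        rhos, betas = [], []
        for rep in range(50):
            s = SDMSpec(W=china_w, n_years=11, rho=0.4, beta=BETA,
                        theta_durbin=THETA, fixed_effects="time", sigma=0.5,
                        seed=5000 + rep)
            y, X = generate_sdm_panel(s)
            f = fit_spatial_panel(y, X, china_w, "SDM", "time")
            rhos.append(f.rho)
            betas.append(f.beta)
        assert abs(np.mean(rhos) - 0.4) < 2 * np.std(rhos) / np.sqrt(50) + 0.02
        bias = np.abs(np.mean(betas, axis=0) - BETA)
        assert (bias < 2 * np.std(betas, axis=0) / np.sqrt(50) + 0.02).all()

    def test_sem_recovers_error_coefficient(self, china_w):
        # SEM DGP: y = Xb + (I - lam W)^{-1} eps
        rng = np.random.default_rng(10)
        lam, T, n = 0.5, 11, 31
        A = np.linalg.inv(np.eye(n) - lam * china_w.w)
        lams = []
        for rep in range(20):
            rg = np.random.default_rng(600 + rep)
            X = rg.normal(size=(T, n, 2))
            eps = np.einsum("ij,tj->ti", A, rg.normal(size=(T, n), scale=0.5))
            y = X @ BETA[:2] + eps
            f = fit_spatial_panel(y, X, china_w, "SEM", "none")
            lams.append(f.lambda_err)
        assert abs(np.mean(lams) - lam) < 0.08

    def test_durbin_wx_coefficients_estimated(self, china_w):
        s = SDMSpec(W=china_w, n_years=11, rho=0.4, beta=BETA,
                    theta_durbin=THETA, fixed_effects="time", sigma=0.3, seed=2)
        y, X = generate_sdm_panel(s)
        f = fit_spatial_panel(y, X, china_w, "SDM", "time")
        se = np.sqrt(np.diag(f.cov))[3:6]
        assert (np.abs(f.theta_durbin - THETA) < 4 * se).all()


class TestHausman:
    def _fits(self):
        f1 = SpatialPanelFit(model="OLS", effects="individual",
                             beta=np.array([1.0, 2.0]), sigma2=1.0, loglik=0.0,
                             r2=0.5, cov=np.eye(2) * 0.5,
                             param_names=["a", "b"])
        f2 = SpatialPanelFit(model="OLS", effects="random",
                             beta=np.array([1.0, 2.0]), sigma2=1.0, loglik=0.0,
                             r2=0.5, cov=np.eye(2) * 0.2,
                             param_names=["a", "b"])
        return f1, f2

    def test_identical_estimates_give_zero(self):
        stat, df, p = hausman_test(*self._fits())
        assert stat == 0.0 and df == 2 and p == 1.0

    def test_reordering_invariance(self, china_w):
        rng = np.random.default_rng(12)
        T, n = 11, 31
        X = rng.normal(size=(T, n, 3))
        alpha = rng.normal(size=(1, n)) + X.mean(axis=(0, 2))
        y = X @ BETA + alpha + rng.normal(size=(T, n))
        s1 = hausman_test(fit_panel_fe(y, X), fit_panel_re(y, X))[0]
        Xr = X[:, :, ::-1].copy()
        s2 = hausman_test(fit_panel_fe(y, Xr), fit_panel_re(y, Xr))[0]
        assert s1 == pytest.approx(s2, rel=1e-8)

    def test_size_under_re_consistent_dgp(self):
        """Uncorrelated unit effects: rejections at 5% stay below 10%."""
        rej = 0
        for rep in range(200):
            rg = np.random.default_rng(4000 + rep)
            X = rg.normal(size=(11, 31, 3))
            alpha = rg.normal(size=(1, 31))
            y = X @ BETA + alpha + rg.normal(size=(11, 31))
            rej += hausman_test(fit_panel_fe(y, X), fit_panel_re(y, X))[2] < 0.05
        assert rej / 200 <= 0.10


class TestLRWald:
    def _three_fits(self, china_w, theta, seed=1):
        s = SDMSpec(W=china_w, n_years=11, rho=0.4, beta=BETA,
                    theta_durbin=theta, fixed_effects="time", sigma=0.5, seed=seed)
        y, X = generate_sdm_panel(s)
        return (fit_spatial_panel(y, X, china_w, "SDM", "time"),
                fit_spatial_panel(y, X, china_w, "SEM", "time"),
                fit_spatial_panel(y, X, china_w, "SLM", "time"))

    def test_lr_nonnegative_and_chisq_scaled(self, china_w):
        sdm, sem, slm = self._three_fits(china_w, THETA)
        out = lr_wald_degeneracy(sdm, sem, slm)
        assert (out["LR"] >= 0).all()
        assert ((out["LR_p"] >= 0) & (out["LR_p"] <= 1)).all()
        assert (out["Wald"] >= 0).all()

    def test_strong_durbin_keeps_sdm(self, china_w):
        sdm, sem, slm = self._three_fits(china_w, np.array([0.5, 0.4, -0.5]))
        out = lr_wald_degeneracy(sdm, sem, slm)
        assert (out["LR_p"] < 0.01).all()
        assert (out["Wald_p"] < 0.01).all()

    def test_restricted_equals_full_gives_zero_lr(self, china_w):
        sdm, sem, slm = self._three_fits(china_w, THETA)
        out = lr_wald_degeneracy(sdm, sem, sdm)  # "SLM" slot holds the SDM itself
        assert out.loc["SLM", "LR"] == pytest.approx(0.0, abs=1e-9)

    def test_negative_lr_raises(self, china_w):
        sdm, sem, slm = self._three_fits(china_w, THETA)
        broken = SpatialPanelFit(model="SEM", effects="time", beta=sem.beta,
                                 sigma2=sem.sigma2, loglik=sdm.loglik + 50,
                                 r2=0.0)
        with pytest.raises(RuntimeError, match="LR"):
            lr_wald_degeneracy(sdm, broken, slm)


class TestEffects:
    def test_rho_zero_identity(self, china_w):
        """With rho = 0, direct = beta and indirect = theta exactly."""
        fit = SpatialPanelFit(model="SDM", effects="time", beta=BETA,
                              sigma2=1.0, loglik=0.0, r2=0.5, rho=0.0,
                              theta_durbin=THETA)
        eff = decompose_effects(fit, china_w, n_draws=0)
        np.testing.assert_allclose(eff.direct, BETA, atol=1e-12)
        np.testing.assert_allclose(eff.indirect, THETA, atol=1e-12)

    def test_total_is_direct_plus_indirect(self, china_w):
        fit = SpatialPanelFit(model="SDM", effects="time", beta=BETA,
                              sigma2=1.0, loglik=0.0, r2=0.5, rho=0.35,
                              theta_durbin=THETA)
        eff = decompose_effects(fit, china_w, n_draws=0)
        np.testing.assert_allclose(eff.total, eff.direct + eff.indirect,
                                   atol=1e-10)

    def test_three_unit_hand_computation(self):
        """rho=0.5, beta=1, theta=0, uniform off-diagonal W: effects match
        the explicit (I - rho W)^{-1} inversion."""
        w = (np.ones((3, 3)) - np.eye(3)) / 2
        W = SpatialWeightMatrix(["a", "b", "c"], w, standardized="row")
        fit = SpatialPanelFit(model="SDM", effects="none",
                              beta=np.array([1.0]), sigma2=1.0, loglik=0.0,
                              r2=0.5, rho=0.5, theta_durbin=np.array([0.0]))
        eff = decompose_effects(fit, W, n_draws=0)
        A = np.linalg.inv(np.eye(3) - 0.5 * w)
        assert eff.direct[0] == pytest.approx(np.trace(A) / 3, abs=1e-12)
        assert eff.total[0] == pytest.approx(A.sum() / 3, abs=1e-12)

    def test_unstable_rho_rejected(self, china_w):
        fit = SpatialPanelFit(model="SDM", effects="time", beta=BETA,
                              sigma2=1.0, loglik=0.0, r2=0.5, rho=1.2,
                              theta_durbin=THETA)
        with pytest.raises(ValueError, match="rho"):
            decompose_effects(fit, china_w, n_draws=0)

    def test_simulation_se_reproducible(self, china_w):
        fit = SpatialPanelFit(model="SDM", effects="time", beta=BETA,
                              sigma2=1.0, loglik=0.0, r2=0.5, rho=0.3,
                              theta_durbin=THETA,
                              cov=np.eye(7) * 0.01,
                              param_names=[f"b{i}" for i in range(7)])
        a = decompose_effects(fit, china_w, n_draws=200, seed=3)
        b = decompose_effects(fit, china_w, n_draws=200, seed=3)
        np.testing.assert_array_equal(a.direct_se, b.direct_se)


class TestSelectModel:
    def _sdm_dgp(self, china_w, seed=1):
        s = SDMSpec(W=china_w, n_years=11, rho=0.4, beta=BETA,
                    theta_durbin=np.array([0.5, 0.4, -0.5]),
                    fixed_effects="time", sigma=0.3, effect_scale=2.0,
                    x_between_scale=3.0, unit_effect_corr=1.5, seed=seed)
        return generate_sdm_panel(s)

    def test_sdm_time_fe_dgp_selected(self, china_w):
        y, X = self._sdm_dgp(china_w, seed=1)
        fit, report = select_model(y, X, china_w, seed=1)
        assert report.chosen == {"model": "SDM", "effects": "time"}
        assert report.hausman[2] < 0.05
        assert (report.lr_wald["LR_p"] < 0.05).all()

    def test_iid_dgp_returns_ols(self, china_w):
        s = SDMSpec(W=china_w, n_years=11, rho=0.0, beta=BETA,
                    fixed_effects="none", sigma=1.0, seed=3)
        y, X = generate_sdm_panel(s)
        fit, report = select_model(y, X, china_w, seed=3)
        assert report.chosen["model"] == "OLS"

    def test_covariate_scaling_invariance(self, china_w):
        y, X = self._sdm_dgp(china_w, seed=1)
        _, r1 = select_model(y, X, china_w, seed=1)
        scale = np.array([100.0, 0.01, 5.0])
        _, r2 = select_model(y, X * scale, china_w, seed=1)
        assert r1.chosen == r2.chosen
        assert r1.hausman[0] == pytest.approx(r2.hausman[0], rel=1e-6)
        assert r1.lm["lm_lag"][0] == pytest.approx(r2.lm["lm_lag"][0], rel=1e-8)
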