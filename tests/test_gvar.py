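"""Panel GVAR: implied moments, FIML, saturated fit, prune/step-up, indices."""

import numpy as np
import pytest

from panelnet import (CohortSpec, GVARParameters, detrend_and_standardize,
                      fiml_loglik, fit_gvar, fit_indices, fit_saturated_gvar,
                      implied_moments, prune_stepup, simulate_panel)
from panelnet.fiml import pattern_stats, saturated_loglik
from panelnet.gvar import (StationarityError, _negloglik_factory,
                           _negloglik_grad_factory, _numerical_gradient,
                           _Parameterization, spectral_radius)

from conftest import sparse_truth_p4


def scalar_params(b=0.5, zeta_var=0.75, between_var=0.5):
    return GVARParameters(mu=np.zeros((3, 1)), B=[[b]],
                          K_zeta=[[1.0 / zeta_var]],
                          K_B=[[1.0 / between_var]])


def standardized_truth_params(truth, T=3):
    """Truth mapped to the pooled-standardized scale of the observed panel."""
    SW = truth.stationary_within_cov()
    tot = np.diag(truth.Sigma_B) + np.diag(SW)
    D = np.diag(1.0 / np.sqrt(tot))
    Bs = D @ truth.B @ np.linalg.inv(D)
    Kz = np.linalg.inv(D @ np.linalg.inv(truth.K_zeta) @ D)
    KB = np.linalg.inv(D @ truth.Sigma_B @ D)
    return GVARParameters(mu=np.zeros((T, truth.p)), B=Bs, K_zeta=Kz, K_B=KB)


@pytest.fixture(scope="module")
def recovery_fit():
    truth = sparse_truth_p4()
    spec = CohortSpec(n_persons=2000, p=4, retention=(1, 1, 1), seed=7)
    panel = detrend_and_standardize(simulate_panel(truth, spec))
    fit = fit_saturated_gvar(panel, n_starts=2, seed=0)
    return truth, panel, fit


class TestImpliedMoments:
    def test_scalar_worked_case(self):
        # within-variance 1 = 0.25*1 + 0.75; total 1.5; lag-1 0.5 + 0.5*1
        m = implied_moments(scalar_params(), T=3)
        assert m.cov[0, 0] == pytest.approx(1.5)
        assert m.cov[1, 0] == pytest.approx(1.0)
        assert m.cov[2, 0] == pytest.approx(0.5 + 0.25)

    def test_no_temporal_effects_gives_flat_between_blocks(self):
        P = GVARParameters(mu=np.zeros((3, 2)), B=np.zeros((2, 2)),
                           K_zeta=np.eye(2), K_B=np.linalg.inv(
                               np.array([[0.5, 0.2], [0.2, 0.5]])))
        m = implied_moments(P, T=3)
        SB = np.array([[0.5, 0.2], [0.2, 0.5]])
        np.testing.assert_allclose(m.cov[2:4, 0:2], SB, atol=1e-10)
        np.testing.assert_allclose(m.cov[4:6, 2:4], SB, atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_lyapunov_residual_and_pd(self, seed):
        rng = np.random.default_rng(seed)
        p = 4
        B = rng.uniform(-0.3, 0.3, (p, p))
        B *= 0.6 / max(0.6, spectral_radius(B))
        A = rng.standard_normal((p, p)) * 0.4
        Kz = A @ A.T + np.eye(p)
        C = rng.standard_normal((p, p)) * 0.4
        KB = C @ C.T + np.eye(p)
        P = GVARParameters(mu=np.zeros((3, p)), B=B, K_zeta=Kz, K_B=KB)
        m = implied_moments(P, T=3)
        resid = m.Sigma_W - B @ m.Sigma_W @ B.T - np.linalg.inv(Kz)
        assert np.linalg.norm(resid) < 1e-10
        assert np.linalg.eigvalsh(m.cov).min() > 0

    def test_nonstationary_rejected(self):
        with pytest.raises(StationarityError):
            GVARParameters(mu=np.zeros((3, 1)), B=[[1.05]],
                           K_zeta=[[1.0]], K_B=[[1.0]])


class TestFimlLoglik:
    def test_single_observed_cell_standard_normal(self):
        P = scalar_params(b=0.0, zeta_var=1.0, between_var=1e-12)
        data = np.array([[0.0, np.nan, np.nan]])
        ll = fiml_loglik(P, data)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-6)

    def test_complete_data_equals_closed_form_at_sample_moments(self):
        rng = np.random.default_rng(7)
        data = rng.standard_normal((300, 6))  # p=2, T=3 stacked
        stats = pattern_stats(data)
        ll_sat, mu_hat, S_hat = saturated_loglik(stats)
        n, k = data.shape
        sign, logdet = np.linalg.slogdet(S_hat)
        closed = -0.5 * n * (k * np.log(2 * np.pi) + logdet + k)
        np.testing.assert_allclose(ll_sat, closed, rtol=1e-8)

    def test_diagonal_covariance_factorizes(self):
        P = GVARParameters(mu=np.zeros((2, 2)), B=np.zeros((2, 2)),
                           K_zeta=np.eye(2) * 2.0, K_B=np.eye(2) * 1e12)
        rng = np.random.default_rng(8)
        data = rng.standard_normal((20, 4))
        data[:7, 1] = np.nan
        ll = fiml_loglik(P, data)
        var = 0.5 + 1e-12
        expected = 0.0
        for j in range(4):
            col = data[:, j]
            col = col[~np.isnan(col)]
            expected += np.sum(-0.5 * (np.log(2 * np.pi * var)
                                       + col ** 2 / var))
        np.testing.assert_allclose(ll, expected, rtol=1e-9)

    def test_analytic_gradient_matches_finite_differences(self):
        truth = sparse_truth_p4()
        spec = CohortSpec(n_persons=150, p=4, seed=5,
                          retention=(1.0, 0.9, 0.7))
        panel = simulate_panel(truth, spec)
        from panelnet import apply_attrition
        panel = apply_attrition(panel, spec)
        stats = pattern_stats(panel.stacked())
        par = _Parameterization(4, 3, np.ones((4, 4), bool),
                                ~np.eye(4, dtype=bool), ~np.eye(4, dtype=bool))
        theta = par.pack(standardized_truth_params(truth))
        f, g = _negloglik_grad_factory(par, stats)(theta)
        gn = _numerical_gradient(_negloglik_factory(par, stats), theta,
                                 rel_eps=1e-6)
        np.testing.assert_allclose(g, gn, rtol=1e-4, atol=1e-3)


class TestFitRecovery:
    def test_temporal_matrix_recovered(self, recovery_fit):
        truth, _, fit = recovery_fit
        Bs = standardized_truth_params(truth).B
        assert np.abs(fit.params.B - Bs).max() < 0.08
        strong = np.abs(Bs) >= 0.15
        assert np.all(np.sign(fit.params.B[strong]) == np.sign(Bs[strong]))

    def test_null_truth_estimates_near_zero(self):
        p = 3
        truth_params = GVARParameters(
            mu=np.zeros((3, p)), B=np.zeros((p, p)),
            K_zeta=np.eye(p), K_B=np.eye(p) * (1 / 0.7))
        rng_spec = CohortSpec(n_persons=2000, p=p, retention=(1, 1, 1),
                              seed=77)
        from panelnet import GroundTruth
        truth = GroundTruth(B=np.zeros((p, p)), K_zeta=np.eye(p),
                            Sigma_B=np.eye(p) * 0.7,
                            trend_lin=0, trend_quad=0, mu=0)
        panel = detrend_and_standardize(simulate_panel(truth, rng_spec))
        fit = fit_saturated_gvar(panel, n_starts=1, seed=0)
        off = fit.params.B[~np.eye(p, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_refit_from_truth_never_worse(self, recovery_fit):
        truth, panel, fit = recovery_fit
        P0 = standardized_truth_params(truth)
        ll_truth = fiml_loglik(P0, panel)
        refit = fit_gvar(panel, start=P0, n_starts=1)
        assert refit.loglik >= ll_truth - 1e-6


class TestPruneStepup:
    def test_alpha_one_prunes_nothing(self, recovery_fit):
        _, _, fit = recovery_fit
        pruned, trace = prune_stepup(fit, alpha=1.0)
        np.testing.assert_array_equal(pruned.params.B, fit.params.B)
        assert trace == []

    def test_prune_keeps_strong_edges_and_loglik_order(self, recovery_fit):
        truth, _, fit = recovery_fit
        pruned, trace = prune_stepup(fit, alpha=0.05)
        Bs = standardized_truth_params(truth).B
        strong = np.abs(Bs) >= 0.15
        assert np.all(pruned.params.free_B[strong])
        assert pruned.loglik <= fit.loglik + 1e-6
        assert pruned.n_params < fit.n_params
        assert all(step["step"] in ("prune", "step-up", "oscillation-stop")
                   for step in trace)

    def test_partials_symmetric_and_bounded(self, recovery_fit):
        _, _, fit = recovery_fit
        for P in (fit.params.contemporaneous_partials(),
                  fit.params.between_partials()):
            np.testing.assert_allclose(P, P.T, atol=1e-10)
            assert np.all(np.abs(P) <= 1.0)


class TestFitIndices:
    def test_saturated_self_comparison(self):
        rng = np.random.default_rng(9)
        data = rng.standard_normal((200, 4))
        stats = pattern_stats(data)
        ll_sat, _, _ = saturated_loglik(stats)
        k = 4
        mf = fit_indices(ll_sat, k + k * (k + 1) // 2, stats)
        assert mf.chi2 == pytest.approx(0.0, abs=1e-6)
        assert mf.rmsea == 0.0
        assert mf.cfi == 1.0

    def test_independence_target_has_zero_cfi(self):
        rng = np.random.default_rng(10)
        A = np.array([[1.0, 0.0], [0.8, 0.6]])
        data = rng.standard_normal((300, 2)) @ A.T
        stats = pattern_stats(data)
        from panelnet.fiml import independence_loglik
        ll_ind, n_ind = independence_loglik(stats)
        mf = fit_indices(ll_ind, n_ind, stats)
        assert mf.cfi == pytest.approx(0.0, abs=1e-9)

    def test_true_structure_fits_well(self, recovery_fit):
        truth, panel, _ = recovery_fit
        free_B = np.abs(truth.B) > 1e-8
        free_Kz = np.abs(truth.K_zeta) > 1e-8
        np.fill_diagonal(free_Kz, False)
        free_KB = np.abs(np.linalg.inv(truth.Sigma_B)) > 1e-8
        np.fill_diagonal(free_KB, False)
        fit = fit_gvar(panel, free_B=free_B, free_K_zeta=free_Kz,
                       free_K_B=free_KB, n_starts=1, seed=0)
        mf = fit_indices(fit.loglik, fit.n_params, fit.stats)
        assert mf.rmsea < 0.05
        assert mf.cfi > 0.95
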