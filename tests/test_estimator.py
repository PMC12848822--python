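import numpy as np
import pytest

from helpers import brute_force_min, tiny_dataset
from solvemat import (
    DesignData,
    SimulationSpec,
    fit_closed_form,
    fit_mm,
    generate_dataset,
    latent_loadings,
    linear_predictor,
    relative_error,
)
from solvemat.estimator import coefficients_original_scale
from solvemat.linalg import reparametrize
from solvemat.losses import loss_value


class TestClosedForm:
    def test_collapses_to_ols_without_Z_and_latent(self, rng):
        X = rng.standard_normal((12, 3))
        Y = rng.standard_normal((12, 5))
        data = DesignData(Y=Y, X=X)
        fit = fit_closed_form(data, 0)
        ols = np.linalg.pinv(X) @ Y
        assert np.allclose(fit.A, ols, atol=1e-10)
        assert np.allclose(fit.C, 0.0)
        assert fit.B.shape == (12, 0)

    def test_noiseless_data_recovered_exactly(self):
        sim, data = tiny_dataset(n=30, m=20, p=3, q=2, r=4,
                                 sigma2=1e-24, seed=3)
        fit = fit_closed_form(data, 4)
        assert relative_error(fit.A, sim.A_star) < 1e-8
        assert relative_error(fit.B, sim.B_star) < 1e-8
        assert relative_error(fit.C, sim.C_star) < 1e-8

    def test_recovery_error_decreases_with_noise(self):
        errs = []
        for sigma2 in (4.0, 1.0, 0.25, 1e-12):
            sim, data = tiny_dataset(n=40, m=30, p=3, q=2, r=2,
                                     sigma2=sigma2, seed=5)
            fit = fit_closed_form(data, 2)
            errs.append(relative_error(fit.A, sim.A_star)
                        + relative_error(fit.B, sim.B_star)
                        + relative_error(fit.C, sim.C_star))
        assert all(a > b for a, b in zip(errs, errs[1:]))

    def test_achieves_brute_force_optimum_on_tiny_instance(self):
        _, data = tiny_dataset(n=6, m=5, p=2, q=1, r=1, seed=7)
        fit = fit_closed_form(data, 1)
        assert fit.loss <= brute_force_min(data, 1, seed=7) + 1e-6

    def test_beats_random_feasible_points(self, rng):
        _, data = tiny_dataset(n=7, m=6, p=2, q=2, r=2, seed=9)
        fit = fit_closed_form(data, 2)
        P = data.projectors
        for _ in range(500):
            A0 = rng.standard_normal((data.p, data.m))
            B0 = rng.standard_normal((data.n, data.q))
            C0 = rng.standard_normal((data.n, 2)) @ rng.standard_normal((2, data.m))
            A, B, C = reparametrize(A0, B0, C0, P)
            eta = data.Xd @ A + B @ data.Zd + C
            assert fit.loss <= loss_value(eta, data.Y, "gaussian") + 1e-9

    def test_rejects_wrong_family_and_bad_rank(self):
        _, data = tiny_dataset(family="bernoulli_logit", seed=1)
        with pytest.raises(ValueError, match="gaussian"):
            fit_closed_form(data, 1)
        _, gdata = tiny_dataset(seed=1)
        with pytest.raises(ValueError, match="rank"):
            fit_closed_form(gdata, 99)


class TestMMIteration:
    def test_gaussian_rho_one_matches_closed_form_in_one_step(self):
        for seed in range(3):
            _, data = tiny_dataset(n=15, m=10, p=3, q=2, r=2, seed=seed)
            cf = fit_closed_form(data, 2)
            mm = fit_mm(data, 2, rho=1.0)
            assert np.allclose(mm.A, cf.A, atol=1e-10)
            assert np.allclose(mm.B, cf.B, atol=1e-10)
            assert np.allclose(mm.C, cf.C, atol=1e-10)
            assert np.isclose(mm.loss, cf.loss, rtol=1e-12)

    def test_logistic_loss_trace_is_non_increasing(self):
        _, data = tiny_dataset(n=10, m=8, p=2, q=2, r=1,
                               family="bernoulli_logit", seed=4)
        fit = fit_mm(data, 1, rho=0.25, max_iter=200, tol=1e-10)
        assert np.all(np.diff(fit.loss_trace) <= 1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_logistic_matches_brute_force_loss_on_regular_instances(self, seed):
        # weak signal + several observations per parameter keep the logistic
        # likelihood strongly curved, so a finite optimum exists; the MM
        # limit and a multi-start quasi-Newton optimizer over the factorized
        # feasible set must then agree on the objective value
        _, data = tiny_dataset(n=30, m=24, p=2, q=1, r=1,
                               family="bernoulli_logit", seed=seed,
                               coef_scale=0.2)
        with pytest.warns(RuntimeWarning):
            fit = fit_mm(data, 1, tol=1e-13, max_iter=20000)
        bf = brute_force_min(data, 1, n_starts=6, seed=seed)
        assert fit.loss <= bf * 1.01

    def test_quantified_descent_inequality_for_rho_above_L(self):
        # l(t) - l(t+1) >= (rho - L)/2 * ||eta_t - eta_{t+1}||_F^2
        _, data = tiny_dataset(n=9, m=7, p=2, q=1, r=1,
                               family="bernoulli_logit", seed=8)
        rho, L = 0.3, 0.25
        etas, losses = [], []
        for k in range(1, 9):
            with pytest.warns(RuntimeWarning):
                f = fit_mm(data, 1, rho=rho, tol=0.0, max_iter=k)
            etas.append(f.eta)
            losses.append(f.loss)
        for t in range(len(etas) - 1):
            gap = losses[t] - losses[t + 1]
            assert gap >= (rho - L) / 2 * np.linalg.norm(
                etas[t] - etas[t + 1]) ** 2 - 1e-10

    def test_max_iter_exhaustion_warns_but_returns(self):
        _, data = tiny_dataset(n=10, m=8, p=2, q=1, r=1,
                               family="bernoulli_logit", seed=2)
        with pytest.warns(RuntimeWarning, match="did not reach tolerance"):
            fit = fit_mm(data, 1, tol=1e-14, max_iter=3)
        assert not fit.converged
        assert fit.n_iter == 3

    def test_init_with_excessive_rank_rejected(self, rng):
        _, data = tiny_dataset(n=8, m=6, p=2, q=1, r=1, seed=0)
        C0 = rng.standard_normal((8, 6))  # full rank > 1
        with pytest.raises(ValueError, match="rank"):
            fit_mm(data, 1, init=(np.zeros((2, 6)), np.zeros((8, 1)), C0))


class TestFitInvariants:
    @pytest.mark.parametrize("family,solver", [
        ("gaussian", "closed_form"),
        ("gaussian", "mm"),
        ("bernoulli_logit", "mm"),
    ])
    def test_constraints_and_pythagoras(self, family, solver):
        _, data = tiny_dataset(n=20, m=15, p=3, q=2, r=2, family=family,
                               seed=11)
        if solver == "closed_form":
            fit = fit_closed_form(data, 2)
        else:
            fit = fit_mm(data, 2, tol=1e-10, max_iter=500)
        res = fit.constraint_residuals()
        scale = max(np.linalg.norm(fit.eta), 1.0)
        assert all(v < 1e-8 * scale for v in res.values())
        # eta decomposes orthogonally into the three components
        parts = (np.linalg.norm(data.Xd @ fit.A) ** 2
                 + np.linalg.norm(fit.B @ data.Zd) ** 2
                 + np.linalg.norm(fit.C) ** 2)
        assert np.isclose(np.linalg.norm(fit.eta) ** 2, parts, rtol=1e-6)
        # eta equals X A + B Z + C
        assert np.allclose(fit.eta,
                           data.Xd @ fit.A + fit.B @ data.Zd + fit.C,
                           atol=1e-10 * scale)

    def test_rank_constraint_respected(self):
        _, data = tiny_dataset(n=20, m=15, p=3, q=2, r=4, seed=12)
        fit = fit_closed_form(data, 3)
        s = np.linalg.svd(fit.C, compute_uv=False)
        assert (s > s[0] * 1e-10).sum() <= 3


class TestLinearPredictor:
    def test_zero_kernels_give_zero(self):
        _, data = tiny_dataset(n=8, m=6, p=2, q=1, r=1, seed=0)
        eta = linear_predictor(np.zeros((2, 6)), np.zeros((8, 1)),
                               np.zeros((8, 6)), data)
        assert np.array_equal(eta, np.zeros((8, 6)))

    def test_A_only_term(self, rng):
        _, data = tiny_dataset(n=8, m=6, p=2, q=1, r=1, seed=0)
        A0 = rng.standard_normal((2, 6))
        eta = linear_predictor(A0, np.zeros((8, 1)), np.zeros((8, 6)), data)
        assert np.allclose(eta, data.Xd @ A0, atol=1e-12)

    def test_consistent_with_reparametrized_sum(self, rng):
        _, data = tiny_dataset(n=9, m=7, p=2, q=2, r=2, seed=1)
        A0 = rng.standard_normal((2, 7))
        B0 = rng.standard_normal((9, 2))
        C0 = rng.standard_normal((9, 7))
        A, B, C = reparametrize(A0, B0, C0, data.projectors)
        eta = linear_predictor(A0, B0, C0, data)
        assert np.allclose(eta, data.Xd @ A + B @ data.Zd + C, atol=1e-12)


class TestLatentLoadings:
    def test_rank_one_structure_recovered(self):
        _, data = tiny_dataset(n=20, m=15, p=2, q=2, r=1, sigma2=1e-12,
                               seed=13)
        fit = fit_closed_form(data, 1)
        U, s, V = latent_loadings(fit)
        assert U.shape == (20, 1) and V.shape == (15, 1) and s.shape == (1,)
        assert np.allclose(fit.C, (U * s) @ V.T, atol=1e-8)

    def test_loadings_orthonormal_and_orthogonal_to_X(self):
        _, data = tiny_dataset(n=25, m=18, p=3, q=2, r=3, seed=14)
        fit = fit_closed_form(data, 3)
        U, s, V = latent_loadings(fit)
        assert np.allclose(U.T @ U, np.eye(U.shape[1]), atol=1e-10)
        assert np.allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-10)
        assert np.all(np.diff(s) <= 0)
        assert np.linalg.norm(data.Xd.T @ U) < 1e-8

    def test_zero_C_warns_and_returns_empty(self):
        _, data = tiny_dataset(n=8, m=6, p=2, q=1, r=1, seed=0)
        fit = fit_closed_form(data, 0)
        with pytest.warns(RuntimeWarning, match="numerically zero"):
            U, s, V = latent_loadings(fit)
        assert U.shape == (8, 0) and s.size == 0


class TestPreprocessing:
    def test_standardized_coefficients_map_back_to_original_scale(self):
        spec = SimulationSpec(n=40, m=25, p=3, q=2, true_rank=2, sigma2=1.0,
                              seed=21, coef_scale=1.0)
        sim = generate_dataset(spec, 0)
        raw = DesignData(Y=sim.Y, X=sim.X, Z=sim.Z, intercept_rows=True,
                         intercept_cols=True)
        std = DesignData(Y=sim.Y, X=sim.X, Z=sim.Z, standardize_X=True,
                         standardize_Z=True, intercept_rows=True,
                         intercept_cols=True)
        fr = fit_closed_form(raw, 2)
        fs = fit_closed_form(std, 2)
        A_back, B_back = coefficients_original_scale(fs, std)
        A_raw, B_raw = coefficients_original_scale(fr, raw)
        # same fitted surface, same original-scale slopes
        assert np.allclose(fs.eta, fr.eta, atol=1e-8)
        assert np.allclose(A_back[1:], A_raw[1:], atol=1e-8)
        assert np.allclose(B_back[:, 1:], B_raw[:, 1:], atol=1e-8)

    def test_missing_values_are_a_hard_error(self, rng):
        Y = rng.standard_normal((10, 5))
        Y[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            DesignData(Y=Y, X=rng.standard_normal((10, 2)))

    def test_dimension_regime_enforced(self, rng):
        with pytest.raises(ValueError, match="n > p"):
            DesignData(Y=rng.standard_normal((3, 5)),
                       X=rng.standard_normal((3, 3)))
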