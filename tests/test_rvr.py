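"""Sparse Bayesian regression: kernels, evidence-maximisation updates,
prediction identities and the primal-weight fold-back."""

import numpy as np
import pytest

from restvs.rvr import (
    RVR,
    KernelSpec,
    RvrConfig,
    build_kernel,
    fit_rvr_kernel,
    predict,
    primal_weights,
)


def slow_reference_rvr(K, y, max_iter=1000, tol=1e-6, prune_at=1e12):
    """Deliberately naive re-implementation of the update equations.

    Explicit matrix inversion each step, boolean masking instead of index
    bookkeeping; used as the independent oracle for the fast path.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    Phi = np.column_stack([np.ones(n), np.asarray(K, dtype=float)])
    alpha = np.full(n + 1, 1.0 / n**2)
    var_y = y.var()
    sigma2 = 0.1 * var_y if var_y > 0 else 1e-6
    floor = max(1e-12 * var_y, 1e-30)
    keep = np.ones(n + 1, dtype=bool)
    mu = np.zeros(n + 1)
    for _ in range(max_iter):
        P = Phi[:, keep]
        a = alpha[keep]
        Sigma = np.linalg.inv(P.T @ P / sigma2 + np.diag(a))
        mu_k = Sigma @ P.T @ y / sigma2
        gamma = 1.0 - a * np.diag(Sigma)
        resid = y - P @ mu_k
        sigma2 = max(float(resid @ resid) / max(n - gamma.sum(), 1e-12), floor)
        new_a = np.maximum(gamma, 1e-12) / np.maximum(mu_k**2, 1e-300)
        sub_keep = new_a <= prune_at
        if not sub_keep.any():
            sub_keep[np.argmin(new_a)] = True
        delta = np.abs(np.log(new_a[sub_keep]) - np.log(a[sub_keep])).max()
        alpha[keep] = new_a
        keep[np.flatnonzero(keep)[~sub_keep]] = False
        if delta < tol:
            break
    P = Phi[:, keep]
    mu_k = np.linalg.solve(P.T @ P / sigma2 + np.diag(alpha[keep]), P.T @ y) / sigma2
    full_mu = np.zeros(n + 1)
    full_mu[keep] = mu_k
    return full_mu, alpha, keep, sigma2


class TestBuildKernel:
    def test_orthonormal_rows_give_identity(self):
        X = np.eye(4)[:3]
        K = build_kernel(X, X, KernelSpec(center=False))
        np.testing.assert_allclose(K, np.eye(3))

    def test_centred_gram_sums_to_zero(self, rng):
        X = rng.standard_normal((6, 4))
        K = build_kernel(X, X, KernelSpec(center=True))
        np.testing.assert_allclose(K.sum(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(K.sum(axis=1), 0.0, atol=1e-10)

    def test_matches_bruteforce_dot_products(self, rng):
        X = rng.standard_normal((4, 3))
        Z = rng.standard_normal((2, 3))
        K = build_kernel(X, Z, KernelSpec(center=False))
        for i in range(2):
            for j in range(4):
                assert K[i, j] == pytest.approx(float(Z[i] @ X[j]))

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            build_kernel(rng.standard_normal((4, 3)), rng.standard_normal((2, 5)))

    def test_nonlinear_kind_rejected(self):
        with pytest.raises(ValueError):
            KernelSpec(kind="rbf")


class TestFit:
    def test_noiseless_single_column_recovery(self, rng):
        X = rng.standard_normal((20, 8))
        K = build_kernel(X, X)
        y = 1.7 * K[:, 4]
        m = fit_rvr_kernel(K, y)
        Phi = np.column_stack([np.ones(20), K])
        pred = Phi[:, m.retained + 1] @ m.mu
        np.testing.assert_allclose(pred, y, atol=1e-6)
        assert m.retained.size < 21  # pruning produced a sparse basis

    def test_constant_targets_bias_dominated(self, rng):
        X = rng.standard_normal((12, 5))
        K = build_kernel(X, X)
        m = fit_rvr_kernel(K, np.full(12, 2.5))
        Phi = np.column_stack([np.ones(12), K])
        pred = Phi[:, m.retained + 1] @ m.mu
        np.testing.assert_allclose(pred, 2.5, atol=1e-6)

    def test_preconditions(self, rng):
        with pytest.raises(ValueError):
            fit_rvr_kernel(np.eye(2), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            fit_rvr_kernel(np.eye(4), np.array([1.0, np.nan, 0.0, 2.0]))

    def test_scale_equivariance(self, rng):
        X = rng.standard_normal((18, 6))
        w = np.zeros(6)
        w[2] = 1.0
        y = X @ w + rng.normal(0, 0.2, 18)
        K = build_kernel(X, X)
        m1 = fit_rvr_kernel(K, y)
        m3 = fit_rvr_kernel(K, 3.0 * y)
        Phi = np.column_stack([np.ones(18), K])
        p1 = Phi[:, m1.retained + 1] @ m1.mu
        p3 = Phi[:, m3.retained + 1] @ m3.mu
        np.testing.assert_allclose(p3, 3.0 * p1, rtol=1e-4, atol=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_evidence_non_decreasing_in_well_posed_regime(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((25, 10))
        y = X @ rng.standard_normal(10) + rng.normal(0, 1.0, 25)
        m = fit_rvr_kernel(build_kernel(X, X), y)
        diffs = np.diff(m.evidence_trace)
        assert diffs.min() >= -1e-8

    def test_noise_targets_sparser_than_structured(self):
        # pure-noise targets collapse toward the bias; structured noiseless
        # targets keep the relevance vectors needed to interpolate
        n_noise, n_struct = [], []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((30, 12))
            K = build_kernel(X, X)
            m_noise = fit_rvr_kernel(K, rng.standard_normal(30))
            y = X @ (rng.standard_normal(12) * (rng.random(12) < 0.4))
            m_struct = fit_rvr_kernel(K, y)
            n_noise.append(m_noise.retained.size)
            n_struct.append(m_struct.retained.size)
        assert np.mean(n_noise) < np.mean(n_struct)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(4))
    def test_fast_path_matches_explicit_inversion(self, seed):
        rng = np.random.default_rng(seed)
        n, d = int(rng.integers(6, 13)), int(rng.integers(2, 7))
        X = rng.standard_normal((n, d))
        y = X @ rng.standard_normal(d) + rng.normal(0, 0.5, n)
        K = build_kernel(X, X)
        m = fit_rvr_kernel(K, y)
        mu_ref, _, keep_ref, _ = slow_reference_rvr(K, y)
        Phi = np.column_stack([np.ones(n), K])
        pred_fast = Phi[:, m.retained + 1] @ m.mu
        pred_ref = Phi @ mu_ref
        assert np.abs(pred_fast - pred_ref).max() < 1e-6


class TestPredictAndPrimal:
    def test_training_rows_reproduce_fitted_values(self, rng):
        X = rng.standard_normal((15, 5))
        model = RVR(X @ np.array([1.0, 0, 0, -2.0, 0]) + rng.normal(0, 0.1, 15), X)
        res = model.fit()
        np.testing.assert_allclose(res.predict(X), res.fittedvalues, atol=1e-12)

    def test_misaligned_kernel_rejected(self, rng):
        X = rng.standard_normal((10, 4))
        m = fit_rvr_kernel(build_kernel(X, X), rng.standard_normal(10))
        with pytest.raises(ValueError):
            predict(m, np.zeros((3, m.retained_samples.size + 2)))

    def test_bias_only_model_constant_predictions(self, rng):
        X = rng.standard_normal((12, 4))
        m = fit_rvr_kernel(build_kernel(X, X), np.full(12, 1.5))
        w, b = primal_weights(m, X)
        if m.retained_samples.size == 0:
            np.testing.assert_allclose(w, 0.0)
        pred = X @ w + b
        np.testing.assert_allclose(pred, 1.5, atol=1e-6)

    @pytest.mark.parametrize("center", [True, False])
    def test_primal_dual_prediction_identity(self, center, rng):
        spec = KernelSpec(center=center)
        X = rng.standard_normal((20, 7))
        y = X @ rng.standard_normal(7) + rng.normal(0, 0.3, 20)
        model = RVR(y, X, kernel=spec)
        res = model.fit()
        w, b = res.primal_weights()
        X_new = rng.standard_normal((9, 7))
        np.testing.assert_allclose(res.predict(X_new), X_new @ w + b, atol=1e-8)

    def test_single_retained_sample_weights(self):
        # mu = 1 on one sample without centring: primal weights equal that
        # sample's features
        X = np.array([[1.0, 2.0, -1.0], [0.5, 0.0, 3.0], [2.0, 1.0, 1.0]])
        from restvs.rvr import RvrModel
        m = RvrModel(alpha=np.array([1.0]), sigma2=1.0, mu=np.array([1.0]),
                     retained=np.array([1]), n_train=3, n_iter=1,
                     converged=True, final_delta=0.0)
        w, b = primal_weights(m, X, KernelSpec(center=False))
        np.testing.assert_allclose(w, X[1])
        assert b == 0.0


class TestModelApi:
    def test_summary_reports_fit_facts(self, rng):
        X = rng.standard_normal((14, 4))
        res = RVR(X[:, 0] * 2.0 + rng.normal(0, 0.1, 14), X).fit()
        text = res.summary()
        assert "Relevance Vector Regression" in text
        assert "Relevance vectors:" in text
        assert str(res.state.n_train) in text

    def test_from_dataframe(self, rng):
        import pandas as pd
        df = pd.DataFrame(rng.standard_normal((12, 3)), columns=["a", "b", "y"])
        res = RVR.from_dataframe(df, target="y").fit()
        assert res.predict(df[["a", "b"]].to_numpy()).shape == (12,)

    def test_json_round_trip_prediction(self, tmp_path, rng):
        X = rng.standard_normal((16, 5))
        y = X @ rng.standard_normal(5) + rng.normal(0, 0.2, 16)
        res = RVR(y, X).fit()
        path = tmp_path / "model.json"
        res.to_json(path)
        X_new = rng.standard_normal((6, 5))
        np.testing.assert_allclose(
            res.predict(X_new),
            type(res).predict_from_json(path, X_new), atol=1e-10)

    def test_fit_override_kwargs(self, rng):
        X = rng.standard_normal((10, 3))
        res = RVR(rng.standard_normal(10), X).fit(max_iter=5)
        assert res.state.n_iter <= 5
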