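import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.optimize import minimize

from spectclust import (
    GaussianGateParams,
    SoftmaxGateParams,
    gaussian_gate,
    regularize_covariance,
    softmax_gate,
    update_gaussian_gate,
    update_softmax_gate,
)
from spectclust.errors import ParameterError, SPDViolationError
from spectclust.gating import softmax_gate_q


class TestSoftmaxGate:
    def test_zero_coefficients_give_uniform_weights(self, rng):
        params = SoftmaxGateParams.zeros(3)
        w = softmax_gate(rng.normal(size=(10, 3)), params)
        np.testing.assert_allclose(w, 1.0 / 3.0)

    def test_single_class_is_degenerate(self, rng):
        w = softmax_gate(rng.normal(size=(5, 3)), SoftmaxGateParams.zeros(1))
        np.testing.assert_array_equal(w, np.ones((5, 1)))

    def test_intercept_only_log3(self):
        # logit ln 3 for class 1 vs the reference: weights (0.75, 0.25)
        params = SoftmaxGateParams(alpha=[[0.0, 0.0, 0.0, np.log(3.0)]], K=2)
        w = softmax_gate(np.zeros((1, 3)), params)
        np.testing.assert_allclose(w, [[0.75, 0.25]], atol=1e-12)

    def test_no_overflow_for_extreme_coordinates(self):
        params = SoftmaxGateParams(alpha=[[50.0, 0.0, 0.0, 0.0]], K=2)
        w = softmax_gate([[1e4, 0, 0], [-1e4, 0, 0]], params)
        assert np.isfinite(w).all()
        np.testing.assert_allclose(w.sum(axis=1), 1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        coords=arrays(float, (7, 3), elements=st.floats(-50, 50)),
        alpha=arrays(float, (2, 4), elements=st.floats(-3, 3)),
    )
    def test_rows_are_exact_simplices(self, coords, alpha):
        w = softmax_gate(coords, SoftmaxGateParams(alpha=alpha, K=3))
        assert (w >= 0).all()
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)


class TestGaussianGate:
    def _two_comp(self):
        return GaussianGateParams(
            weights=[0.5, 0.5],
            means=[[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]],
            covariances=np.stack([np.eye(3)] * 2),
            lambda_reg=1.0,
        )

    def test_single_component(self, rng):
        p = GaussianGateParams(
            weights=[1.0], means=[[0, 0, 0]], covariances=np.eye(3)[None]
        )
        w = gaussian_gate(rng.normal(size=(6, 3)), p)
        np.testing.assert_array_equal(w, np.ones((6, 1)))

    def test_equidistant_point_is_split_evenly(self):
        w = gaussian_gate([[1.0, 5.0, -3.0]], self._two_comp())
        np.testing.assert_allclose(w, 0.5, atol=1e-12)

    def test_density_ratio_hand_value(self):
        # at v = mu_1, the log density ratio is exp(-2): weights
        # (1/(1+e^-2), e^-2/(1+e^-2))
        w = gaussian_gate([[0.0, 0.0, 0.0]], self._two_comp())
        e2 = np.exp(-2.0)
        np.testing.assert_allclose(w, [[1 / (1 + e2), e2 / (1 + e2)]], atol=1e-12)
        np.testing.assert_allclose(w, [[0.8808, 0.1192]], atol=1e-4)

    def test_singular_covariance_rejected(self):
        p = GaussianGateParams(
            weights=[1.0], means=[[0, 0, 0]], covariances=np.zeros((1, 3, 3))
        )
        with pytest.raises(SPDViolationError):
            gaussian_gate([[0.0, 0.0, 0.0]], p)

    def test_component_permutation_permutes_columns(self, rng):
        coords = rng.normal(size=(20, 3)) * 3
        p = GaussianGateParams(
            weights=[0.2, 0.3, 0.5],
            means=rng.normal(size=(3, 3)),
            covariances=np.stack([np.eye(3)] * 3),
        )
        perm = [2, 0, 1]
        q = GaussianGateParams(
            weights=p.weights[perm],
            means=p.means[perm],
            covariances=p.covariances[perm],
        )
        np.testing.assert_allclose(
            gaussian_gate(coords, q), gaussian_gate(coords, p)[:, perm], atol=1e-12
        )


class TestGaussianGateUpdate:
    def test_one_hot_reduction_to_cluster_statistics(self, rng):
        coords = rng.normal(size=(30, 3)) * 4
        labels = rng.integers(0, 2, size=30)
        resp = np.eye(2)[labels]
        lam = 0.5
        params = update_gaussian_gate(coords, resp, lambda_reg=lam)
        for k in range(2):
            sel = coords[labels == k]
            np.testing.assert_allclose(params.weights[k], sel.shape[0] / 30)
            np.testing.assert_allclose(params.means[k], sel.mean(axis=0), atol=1e-12)
            ml_cov = np.cov(sel.T, bias=True)
            np.testing.assert_allclose(
                params.covariances[k], regularize_covariance(ml_cov, lam), atol=1e-10
            )

    def test_uniform_responsibilities_collapse_means(self, rng):
        coords = rng.normal(size=(25, 3))
        resp = np.full((25, 2), 0.5)
        params = update_gaussian_gate(coords, resp, lambda_reg=1.0)
        np.testing.assert_allclose(params.means[0], coords.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(params.means[0], params.means[1], atol=1e-12)

    def test_matches_numerical_maximizer_of_gate_q(self, rng):
        """The closed-form update maximizes sum_ik tau_ik log[w_k phi3(v_i)]."""
        n, K = 50, 2
        coords = rng.normal(size=(n, 3)) * 2
        resp = rng.dirichlet(np.ones(K), size=n)
        params = update_gaussian_gate(coords, resp, lambda_reg=1.0)

        def gate_q(w, means, covs):
            from spectclust.gating import log_gaussian_joint

            p = GaussianGateParams(weights=w, means=means, covariances=covs)
            return float(np.sum(resp * log_gaussian_joint(coords, p)))

        # undo the SPD floor for the comparison (floor is 1e-6 relative)
        q_closed = gate_q(params.weights, params.means, params.covariances)

        def neg(x):
            logit = x[0]
            w = np.array([1.0, np.exp(logit)])
            w /= w.sum()
            means = x[1:7].reshape(2, 3)
            covs = []
            for k in range(2):
                Lf = np.zeros((3, 3))
                Lf[np.tril_indices(3)] = x[7 + 6 * k: 13 + 6 * k]
                Lf[np.diag_indices(3)] = np.exp(np.diag(Lf))
                covs.append(Lf @ Lf.T)
            try:
                return -gate_q(w, means, np.stack(covs))
            except Exception:
                return 1e12

        x0 = np.concatenate([[0.0], coords.mean(0), coords.mean(0) + 0.5, [0, 0, 0, 0, 0, 0], [0, 0, 0, 0, 0, 0]])
        res = minimize(neg, x0, method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
        assert q_closed >= -res.fun - 1e-4


class TestRegularizeCovariance:
    def test_identity_when_lambda_is_one(self):
        R = np.diag([2.0, 3.0, 4.0])
        out = regularize_covariance(R, 1.0)
        np.testing.assert_allclose(out, R, rtol=1e-5)

    def test_scaling(self):
        out = regularize_covariance(np.eye(3), 0.1)
        np.testing.assert_allclose(out, 0.1 * np.eye(3), rtol=1e-5)

    def test_determinant_scales_cubically(self, rng):
        A = rng.normal(size=(3, 3))
        R = A @ A.T + np.eye(3)
        lam = 0.075
        out = regularize_covariance(R, lam)
        np.testing.assert_allclose(
            np.linalg.det(out), lam**3 * np.linalg.det(R), rtol=1e-4
        )

    @pytest.mark.parametrize("lam", [0.0, -0.5, 1.5])
    def test_lambda_out_of_range(self, lam):
        with pytest.raises(ParameterError):
            regularize_covariance(np.eye(3), lam)

    def test_degenerate_covariance_gets_floored(self):
        out = regularize_covariance(np.zeros((3, 3)), 0.5)
        assert np.all(np.linalg.eigvalsh(out) > 0)


class TestSoftmaxGateUpdate:
    def test_stationary_point_is_kept(self, rng):
        coords = rng.normal(size=(40, 3))
        init = SoftmaxGateParams(alpha=rng.normal(size=(1, 4)) * 0.5, K=2)
        resp = softmax_gate(coords, init)
        out = update_softmax_gate(coords, resp, init)
        np.testing.assert_allclose(out.alpha, init.alpha, atol=1e-4)

    def test_ascent_property(self, rng):
        for _ in range(5):
            coords = rng.normal(size=(30, 3)) * 2
            resp = rng.dirichlet(np.ones(3), size=30)
            init = SoftmaxGateParams.zeros(3)
            out = update_softmax_gate(coords, resp, init)
            assert softmax_gate_q(coords, resp, out) >= softmax_gate_q(
                coords, resp, init
            ) - 1e-12

    def test_matches_generic_optimizer_on_separable_instance(self, rng):
        coords = np.vstack([
            rng.normal(size=(25, 3)) + [4, 0, 0],
            rng.normal(size=(25, 3)) - [4, 0, 0],
        ])
        resp = np.zeros((50, 2))
        resp[:25, 0] = 1.0
        resp[25:, 1] = 1.0
        init = SoftmaxGateParams.zeros(2)
        out = update_softmax_gate(coords, resp, init, max_iter=50)
        q_ours = softmax_gate_q(coords, resp, out)

        def neg(a):
            return -softmax_gate_q(
                coords, resp, SoftmaxGateParams(alpha=a.reshape(1, 4), K=2)
            )

        res = minimize(neg, np.zeros(4), method="BFGS", options={"maxiter": 2000})
        assert q_ours >= -res.fun - 1e-3
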