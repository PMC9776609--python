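import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import multivariate_normal
from sklearn.metrics import adjusted_rand_score

from spectclust import (
    CurveDataset,
    FitConfig,
    GaussianGateParams,
    RegressionComponent,
    SoftmaxGateParams,
    bayes_allocate,
    component_curve_loglik,
    default_curve_components,
    e_step_functional,
    fit,
    m_step_regression,
    ols_projection,
    sample_sgmfr,
    softmax_gate,
)
from spectclust.errors import ParameterError
from spectclust.gating import log_gaussian_joint


def _three_cluster_gate(lam=1.0):
    return GaussianGateParams(
        weights=np.ones(3) / 3,
        means=[[0, 0, 0], [10, 0, 0], [0, 10, 0]],
        covariances=np.stack([2.0 * np.eye(3)] * 3),
        lambda_reg=lam,
    )


class TestComponentLoglik:
    def test_zero_residual_value(self, design, energies):
        beta = np.ones(design.n_basis)
        ds = CurveDataset(
            coords=np.zeros((3, 3)),
            curves=np.tile(design.values @ beta, (3, 1)),
            energies=energies,
        )
        ll = component_curve_loglik(ds, design, RegressionComponent(beta=beta, sigma2=1.0))
        np.testing.assert_allclose(ll, -(21 / 2) * np.log(2 * np.pi), atol=1e-10)

    def test_variance_doubling_identity(self, design, energies):
        beta = np.zeros(design.n_basis)
        ds = CurveDataset(
            coords=np.zeros((1, 3)), curves=np.zeros((1, 21)), energies=energies
        )
        ll1 = component_curve_loglik(ds, design, RegressionComponent(beta=beta, sigma2=1.0))
        ll2 = component_curve_loglik(ds, design, RegressionComponent(beta=beta, sigma2=2.0))
        np.testing.assert_allclose(ll1 - ll2, (21 / 2) * np.log(2.0), atol=1e-12)

    def test_matches_generic_multivariate_normal(self, design, random_dataset, rng):
        comp = RegressionComponent(beta=rng.normal(size=design.n_basis) * 10, sigma2=40.0)
        ll = component_curve_loglik(random_dataset, design, comp)
        mean = design.values @ comp.beta
        expected = multivariate_normal.logpdf(
            random_dataset.curves, mean=mean, cov=comp.sigma2 * np.eye(21)
        )
        np.testing.assert_allclose(ll, expected, atol=1e-8)

    def test_nonpositive_sigma_rejected(self, design):
        with pytest.raises(ParameterError):
            RegressionComponent(beta=np.zeros(design.n_basis), sigma2=0.0)


class TestEStep:
    def test_single_component_gives_unit_responsibilities(self, design, random_dataset):
        gate = GaussianGateParams(
            weights=[1.0], means=[[0, 0, 0]], covariances=25 * np.eye(3)[None]
        )
        comp = RegressionComponent(beta=np.zeros(design.n_basis), sigma2=100.0)
        resp, ll = e_step_functional(random_dataset, design, gate, [comp])
        np.testing.assert_array_equal(resp, np.ones((40, 1)))
        expected = component_curve_loglik(random_dataset, design, comp) + \
            log_gaussian_joint(random_dataset.coords, gate)[:, 0]
        np.testing.assert_allclose(ll, expected.sum(), atol=1e-8)

    def test_identical_components_split_evenly(self, design, random_dataset):
        gate = GaussianGateParams(
            weights=[0.5, 0.5],
            means=[[0, 0, 0]] * 2,
            covariances=np.stack([25 * np.eye(3)] * 2),
        )
        comp = RegressionComponent(beta=np.zeros(design.n_basis), sigma2=100.0)
        resp, _ = e_step_functional(random_dataset, design, gate, [comp, comp])
        np.testing.assert_allclose(resp, 0.5, atol=1e-12)

    def test_matches_brute_force_posterior(self, design, energies, rng):
        """tau_ik from direct density products, without log-space tricks."""
        n, K = 20, 2
        ds = CurveDataset(
            coords=rng.normal(size=(n, 3)) * 3,
            curves=rng.normal(size=(n, 21)) * 10,
            energies=energies,
        )
        gate = GaussianGateParams(
            weights=[0.4, 0.6],
            means=[[0, 0, 0], [1, 1, 1]],
            covariances=np.stack([np.eye(3), 2 * np.eye(3)]),
        )
        comps = [
            RegressionComponent(beta=rng.normal(size=design.n_basis), sigma2=90.0),
            RegressionComponent(beta=rng.normal(size=design.n_basis), sigma2=120.0),
        ]
        resp, ll = e_step_functional(ds, design, gate, comps)
        joint = np.zeros((n, K))
        for k in range(K):
            spatial = multivariate_normal.pdf(
                ds.coords, mean=gate.means[k], cov=gate.covariances[k]
            )
            curve = multivariate_normal.pdf(
                ds.curves,
                mean=design.values @ comps[k].beta,
                cov=comps[k].sigma2 * np.eye(21),
            )
            joint[:, k] = gate.weights[k] * spatial * curve
        np.testing.assert_allclose(resp, joint / joint.sum(1, keepdims=True), atol=1e-9)
        np.testing.assert_allclose(ll, np.log(joint.sum(1)).sum(), rtol=1e-9)

    def test_softmax_gate_conditional_form(self, design, energies, rng):
        n = 15
        ds = CurveDataset(
            coords=rng.normal(size=(n, 3)),
            curves=rng.normal(size=(n, 21)) * 5,
            energies=energies,
        )
        gate = SoftmaxGateParams(alpha=rng.normal(size=(1, 4)), K=2)
        comps = [
            RegressionComponent(beta=rng.normal(size=design.n_basis), sigma2=25.0)
            for _ in range(2)
        ]
        resp, ll = e_step_functional(ds, design, gate, comps)
        pis = softmax_gate(ds.coords, gate)
        dens = np.column_stack([
            multivariate_normal.pdf(
                ds.curves, mean=design.values @ c.beta, cov=c.sigma2 * np.eye(21)
            )
            for c in comps
        ])
        joint = pis * dens
        np.testing.assert_allclose(resp, joint / joint.sum(1, keepdims=True), atol=1e-9)
        np.testing.assert_allclose(ll, np.log(joint.sum(1)).sum(), rtol=1e-9)


class TestMStepRegression:
    def test_unit_responsibilities_reduce_to_pooled_ols(self, design, random_dataset):
        comp = m_step_regression(random_dataset, design, np.ones((40, 1)))[0]
        coeffs = ols_projection(random_dataset, design).values
        np.testing.assert_allclose(comp.beta, coeffs.mean(axis=0), atol=1e-8)
        resid = random_dataset.curves - design.values @ comp.beta
        np.testing.assert_allclose(comp.sigma2, (resid**2).sum() / (40 * 21), rtol=1e-10)

    def test_noise_free_one_hot_recovery(self, design, energies, rng):
        beta_true = rng.normal(size=(2, design.n_basis)) * 5
        labels = rng.integers(0, 2, size=30)
        ds = CurveDataset(
            coords=rng.normal(size=(30, 3)),
            curves=beta_true[labels] @ design.values.T,
            energies=energies,
        )
        comps = m_step_regression(ds, design, np.eye(2)[labels])
        for k in range(2):
            np.testing.assert_allclose(comps[k].beta, beta_true[k], atol=1e-8)
            assert comps[k].sigma2 == pytest.approx(1e-8)  # floored

    def test_matches_numerical_maximizer_of_component_q(self, design, random_dataset, rng):
        resp = rng.dirichlet(np.ones(2), size=40)
        comps = m_step_regression(random_dataset, design, resp)

        def q_term(k, beta, sigma2):
            c = RegressionComponent(beta=beta, sigma2=sigma2)
            return float(resp[:, k] @ component_curve_loglik(random_dataset, design, c))

        for k in range(2):
            q_closed = q_term(k, comps[k].beta, comps[k].sigma2)

            def neg(x):
                return -q_term(k, x[:-1], np.exp(x[-1]))

            x0 = np.concatenate([comps[k].beta + rng.normal(size=design.n_basis), [0.0]])
            res = minimize(neg, x0, method="BFGS", options={"maxiter": 5000})
            assert q_closed >= -res.fun - 1e-6


class TestBayesAllocate:
    def test_argmax_rows(self):
        labels = bayes_allocate([[0.9, 0.1], [0.2, 0.8]])
        np.testing.assert_array_equal(labels, [1, 2])

    def test_tie_goes_to_lowest_class(self):
        assert bayes_allocate([[0.5, 0.5]])[0] == 1

    def test_one_hot(self):
        np.testing.assert_array_equal(
            bayes_allocate(np.eye(3)[[2, 0, 1]]), [3, 1, 2]
        )


class TestFit:
    def test_recovers_well_separated_clusters(self, design):
        comps = default_curve_components(design, 5)
        comps = [comps[0], comps[2], comps[3]]
        ds, truth = sample_sgmfr(_three_cluster_gate(), comps, design, n=900, seed=11)
        res = fit(ds, design, FitConfig(K=3, seed=11, lambda_reg=1.0, max_iter=200))
        assert adjusted_rand_score(truth, res.labels) >= 0.95
        assert res.converged

    def test_k1_reaches_closed_form_in_one_iteration(self, design, random_dataset):
        res = fit(random_dataset, design, FitConfig(K=1, seed=0, max_iter=10))
        coeffs = ols_projection(random_dataset, design).values
        np.testing.assert_allclose(
            res.components[0].beta, coeffs.mean(axis=0), atol=1e-10
        )
        diffs = np.abs(np.diff(res.loglik_trace))
        assert diffs.max() < 1e-10

    def test_loglik_trace_is_monotone(self, design):
        comps = default_curve_components(design, 3)
        ds, _ = sample_sgmfr(_three_cluster_gate(), comps, design, n=400, seed=3)
        for gate_kind in ("gaussian", "softmax"):
            res = fit(
                ds, design,
                FitConfig(gate_kind=gate_kind, K=3, seed=3, lambda_reg=1.0, max_iter=60),
            )
            ell = res.loglik_trace
            assert np.all(np.diff(ell) >= -1e-8 * np.abs(ell[:-1]))

    def test_labels_are_argmax_of_responsibilities(self, design):
        comps = default_curve_components(design, 3)
        ds, _ = sample_sgmfr(_three_cluster_gate(), comps, design, n=300, seed=5)
        res = fit(ds, design, FitConfig(K=3, seed=5, max_iter=50))
        np.testing.assert_array_equal(res.labels, res.responsibilities.argmax(1) + 1)

    def test_overfull_k_prunes_to_active_clusters(self, design):
        comps = default_curve_components(design, 3)
        ds, _ = sample_sgmfr(_three_cluster_gate(), comps, design, n=300, seed=9)
        res = fit(ds, design, FitConfig(K=8, seed=9, max_iter=100))
        assert res.active_K <= 8
        assert res.responsibilities.shape[1] == res.active_K
        assert res.labels.max() <= res.active_K

    def test_n_not_larger_than_k_rejected(self, design, energies, rng):
        ds = CurveDataset(
            coords=rng.normal(size=(3, 3)),
            curves=rng.normal(size=(3, 21)),
            energies=energies,
        )
        with pytest.raises(ParameterError):
            fit(ds, design, FitConfig(K=3))
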