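"""Weighted Gaussian mixture EM: closed forms, oracles, invariants."""

import math

import numpy as np
import pytest
from scipy import optimize

import contourbin as cb
from contourbin.density import InitialBinning
from contourbin.mixture import complete_data_loglik

from test_density import make_table


class TestBivariateNormalLogpdf:
    def test_standard_normal_at_mean(self):
        val = cb.bivariate_normal_logpdf([0, 0], [0, 0], np.eye(2))
        assert val == pytest.approx(-math.log(2 * math.pi))

    def test_translation_invariance(self, rng):
        x, mu, c = rng.normal(size=2), rng.normal(size=2), rng.normal(size=2)
        a = rng.normal(size=(2, 2))
        sigma = a @ a.T + 0.5 * np.eye(2)
        assert cb.bivariate_normal_logpdf(x + c, mu + c, sigma) == pytest.approx(
            cb.bivariate_normal_logpdf(x, mu, sigma)
        )

    def test_singular_sigma_errors(self):
        with pytest.raises(ValueError):
            cb.bivariate_normal_logpdf([0, 0], [0, 0], np.array([[1.0, 1.0], [1.0, 1.0]]))

    def test_matches_scipy(self, rng):
        from scipy.stats import multivariate_normal

        mu = rng.normal(size=2)
        a = rng.normal(size=(2, 2))
        sigma = a @ a.T + 0.5 * np.eye(2)
        x = rng.normal(size=(10, 2))
        ours = cb.bivariate_normal_logpdf(x, mu, sigma)
        assert ours == pytest.approx(multivariate_normal(mu, sigma).logpdf(x))


class TestMStep:
    def test_weighted_mean_two_points(self):
        points = np.array([[0.0, 0.0], [2.0, 0.0]])
        params = cb.m_step(points, np.array([0.25, 0.75]), np.ones((2, 1)))
        assert params.mu[0] == pytest.approx([1.5, 0.0])

    def test_one_hot_truth_recovers_per_cluster_means(self, rng):
        a = rng.normal([-5, 0], 0.5, size=(40, 2))
        b = rng.normal([5, 2], 0.5, size=(60, 2))
        points = np.vstack([a, b])
        w = rng.random(100) + 0.1
        w /= w.sum()
        z = np.zeros((100, 2))
        z[:40, 0] = 1
        z[40:, 1] = 1
        params = cb.m_step(points, w, z)
        assert params.mu[0] == pytest.approx(w[:40] @ a / w[:40].sum())
        assert params.mu[1] == pytest.approx(w[40:] @ b / w[40:].sum())
        assert params.tau[0] == pytest.approx(w[:40].sum())

    def test_collapsed_component_stays_positive_definite(self):
        points = np.zeros((4, 2))
        params = cb.m_step(points, np.full(4, 0.25), np.ones((4, 1)))
        assert np.linalg.eigvalsh(params.sigma[0])[0] > 0

    def test_closed_form_maximizes_complete_data_loglik(self, rng):
        """Numerical-optimization oracle on a 5-point, 2-component instance."""
        points = rng.normal(size=(5, 2))
        w = rng.random(5) + 0.2
        w /= w.sum()
        z = rng.dirichlet([1.0, 1.0], size=5)
        closed = cb.m_step(points, w, z)
        lc_closed = complete_data_loglik(points, w, z, closed)

        def unpack(theta):
            tau = np.array([1, math.exp(theta[0])])
            tau /= tau.sum()
            mu = theta[1:5].reshape(2, 2)
            sigma = np.zeros((2, 2, 2))
            for k in range(2):
                l11, l21, l22 = theta[5 + 3 * k : 8 + 3 * k]
                L = np.array([[math.exp(l11), 0.0], [l21, math.exp(l22)]])
                sigma[k] = L @ L.T
            return cb.MixtureParams(tau=tau, mu=mu, sigma=sigma)

        def negative_lc(theta):
            return -complete_data_loglik(points, w, z, unpack(theta))

        theta0 = np.concatenate([
            [math.log(closed.tau[1] / closed.tau[0])],
            closed.mu.ravel() + rng.normal(scale=0.3, size=4),
            np.tile([0.0, 0.1, 0.0], 2),
        ])
        res = optimize.minimize(negative_lc, theta0, method="Nelder-Mead",
                                options={"maxiter": 20000, "xatol": 1e-10,
                                         "fatol": 1e-12})
        assert -res.fun <= lc_closed + 1e-6  # nothing beats the closed form
        assert lc_closed >= -res.fun - 1e-6


class TestEStep:
    def test_single_component_all_ones(self, rng):
        params = cb.MixtureParams(np.array([1.0]), np.zeros((1, 2)),
                                  np.eye(2)[None])
        z = cb.e_step(rng.normal(size=(10, 2)), params)
        assert z == pytest.approx(np.ones((10, 1)))

    def test_equidistant_point_splits_evenly(self):
        params = cb.MixtureParams(
            np.array([0.5, 0.5]),
            np.array([[-1.0, 0.0], [1.0, 0.0]]),
            np.stack([np.eye(2)] * 2),
        )
        z = cb.e_step(np.array([[0.0, 0.0]]), params)
        assert z[0] == pytest.approx([0.5, 0.5])

    def test_point_at_a_separated_mean_is_decisive(self):
        params = cb.MixtureParams(
            np.array([0.5, 0.5]),
            np.array([[0.0, 0.0], [10.0, 0.0]]),
            np.stack([np.eye(2)] * 2),
        )
        z = cb.e_step(np.array([[0.0, 0.0]]), params)
        assert z[0, 0] > 0.99

    def test_rows_sum_to_one(self, rng):
        params = cb.MixtureParams(
            np.array([0.3, 0.7]),
            rng.normal(size=(2, 2)),
            np.stack([np.eye(2)] * 2),
        )
        z = cb.e_step(rng.normal(size=(50, 2)), params)
        assert z.sum(axis=1) == pytest.approx(np.ones(50), abs=1e-10)
        assert ((z >= 0) & (z <= 1)).all()


class TestWeightedObservedLoglik:
    def test_single_point_at_mean_reduces_to_logpdf(self):
        params = cb.MixtureParams(np.array([1.0]), np.zeros((1, 2)), np.eye(2)[None])
        val = cb.weighted_observed_loglik(np.zeros((1, 2)), np.array([1.0]), params)
        assert val == pytest.approx(-math.log(2 * math.pi))

    def test_linear_in_weights_under_duplication(self, rng):
        params = cb.MixtureParams(
            np.array([0.4, 0.6]), rng.normal(size=(2, 2)), np.stack([np.eye(2)] * 2)
        )
        pts = rng.normal(size=(20, 2))
        w = rng.random(20)
        w /= w.sum()
        a = cb.weighted_observed_loglik(pts, w, params)
        b = cb.weighted_observed_loglik(
            np.vstack([pts, pts]), np.concatenate([w, w]) / 2, params
        )
        assert a == pytest.approx(b)


def _table_and_init(points, weights, labels):
    n = len(points)
    lengths = np.asarray(weights, float) * 1e6
    table = cb.FeatureTable(
        ids=[f"s{i}" for i in range(n)],
        x1=points[:, 0], x2=points[:, 1], lengths=lengths,
        weights=lengths / lengths.sum(),
        kde_mask=np.ones(n, bool), fpkm=np.abs(points[:, 1]),
    )
    init = InitialBinning(
        level=1.0, n_groups=int(max(labels)),
        labels={f"s{i}": int(l) for i, l in enumerate(labels)},
    )
    return table, init


@pytest.fixture(scope="module")
def two_gauss():
    rng = np.random.default_rng(11)
    n1, n2 = 300, 200
    a = rng.normal([-3, 0], [0.5, 1.0], size=(n1, 2))
    b = rng.normal([3, 5], [0.7, 0.6], size=(n2, 2))
    points = np.vstack([a, b])
    w = rng.random(n1 + n2) + 0.5
    w /= w.sum()
    labels = np.array([1] * n1 + [2] * n2)
    # leave a few points unlabeled so the noise component is populated
    labels[rng.choice(n1 + n2, 25, replace=False)] = 0
    return points, w, labels


class TestFitEm:
    def test_parameter_recovery_on_separated_gaussians(self, two_gauss):
        points, w, labels = two_gauss
        table, init = _table_and_init(points, w, labels)
        fit = cb.fit_em(table, init)
        assert fit.converged
        mus = fit.params.mu[:2]
        order = np.argsort(mus[:, 0])
        # standard error of the mean ~ sd / sqrt(n)
        assert np.allclose(mus[order[0]], [-3, 0], atol=3 * 1.0 / math.sqrt(300))
        assert np.allclose(mus[order[1]], [3, 5], atol=3 * 0.7 / math.sqrt(200))
        true_share = np.array([0.6, 0.4])
        assert np.allclose(np.sort(fit.params.tau[:2])[::-1], true_share, atol=0.05)

    def test_loglik_trace_non_decreasing(self, two_gauss):
        points, w, labels = two_gauss
        table, init = _table_and_init(points, w, labels)
        fit = cb.fit_em(table, init)
        diffs = np.diff(fit.loglik_trace)
        assert (diffs >= -1e-8).all()

    def test_tau_and_z_normalized_sigma_pd(self, two_gauss):
        points, w, labels = two_gauss
        table, init = _table_and_init(points, w, labels)
        fit = cb.fit_em(table, init)
        assert fit.params.tau.sum() == pytest.approx(1.0, abs=1e-12)
        assert fit.z.sum(axis=1) == pytest.approx(np.ones(len(points)), abs=1e-10)
        for k in range(fit.params.G):
            assert np.linalg.eigvalsh(fit.params.sigma[k])[0] > 0

    def test_single_group_init_on_unimodal_data(self, rng):
        points = rng.normal(size=(300, 2))
        w = np.full(300, 1 / 300)
        labels = np.ones(300, int)
        labels[rng.choice(300, 30, replace=False)] = 0
        table, init = _table_and_init(points, w, labels)
        fit = cb.fit_em(table, init)
        assert fit.params.G == 2
        assert fit.noise_component is not None
        assert fit.params.tau[fit.noise_component] < 0.5

    def test_zero_groups_is_an_error(self, rng):
        points = rng.normal(size=(20, 2))
        table, init = _table_and_init(points, np.full(20, 0.05), np.zeros(20, int))
        with pytest.raises(ValueError, match="contour level"):
            cb.fit_em(table, init)

    def test_permutation_invariance(self, two_gauss, rng):
        points, w, labels = two_gauss
        table, init = _table_and_init(points, w, labels)
        fit = cb.fit_em(table, init)
        perm = rng.permutation(len(points))
        table2, init2 = _table_and_init(points[perm], w[perm], labels[perm])
        fit2 = cb.fit_em(table2, init2)
        assert np.allclose(np.sort(fit.params.tau), np.sort(fit2.params.tau), atol=1e-8)
        assert fit.loglik_trace[-1] == pytest.approx(fit2.loglik_trace[-1], abs=1e-8)

    def test_equal_weights_match_sklearn_oracle(self):
        """With w_i = 1/N the weighted EM must coincide with a standard GMM
        run from the same starting parameters for the same iteration count."""
        sklearn = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(3)
        a = rng.normal([-2, 0], 0.8, size=(150, 2))
        b = rng.normal([2, 3], 0.6, size=(100, 2))
        points = np.vstack([a, b])
        n = len(points)
        w = np.full(n, 1.0 / n)
        z0 = np.zeros((n, 2))
        z0[:150, 0] = 1
        z0[150:, 1] = 1

        t = 11
        z = z0
        for _ in range(t):
            params = cb.m_step(points, w, z)
            z = cb.e_step(points, params)

        p0 = cb.m_step(points, w, z0)
        gm = sklearn.GaussianMixture(
            n_components=2, covariance_type="full", tol=0.0, reg_covar=0.0,
            max_iter=t - 1, weights_init=p0.tau, means_init=p0.mu,
            precisions_init=np.linalg.inv(p0.sigma),
        )
        gm.fit(points)
        assert np.allclose(params.tau, gm.weights_, atol=1e-6)
        assert np.allclose(params.mu, gm.means_, atol=1e-6)
        assert np.allclose(params.sigma, gm.covariances_, atol=1e-6)


class TestHardAssign:
    @staticmethod
    def _fitted(z, noise):
        G = z.shape[1]
        params = cb.MixtureParams(
            np.full(G, 1 / G), np.zeros((G, 2)), np.stack([np.eye(2)] * G)
        )
        return cb.FittedMixture(params=params, z=z, loglik_trace=[0.0],
                                converged=True, noise_component=noise)

    def test_confident_point_gets_its_bin(self):
        fit = self._fitted(np.array([[0.9, 0.05, 0.05]]), noise=2)
        assert cb.hard_assign(fit, ["s"]) == {"s": 1}

    def test_below_threshold_goes_to_noise(self):
        fit = self._fitted(np.array([[0.3, 0.3, 0.4]]), noise=2)
        assert cb.hard_assign(fit, ["s"]) == {"s": cb.NOISE}

    def test_tie_breaks_toward_lower_index(self):
        fit = self._fitted(np.array([[0.5, 0.5, 0.0]]), noise=2)
        assert cb.hard_assign(fit, ["s"]) == {"s": 1}

    def test_noise_posterior_must_be_beaten(self):
        fit = self._fitted(np.array([[0.45, 0.0, 0.55]]), noise=2)
        assert cb.hard_assign(fit, ["s"], min_posterior=0.4) == {"s": cb.NOISE}
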