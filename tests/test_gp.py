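"""ARD-kernel Gaussian process: kernel algebra, likelihood, prediction."""

import numpy as np
import pytest

from gazecal.gp import (
    GazeGP,
    GPHyperParams,
    ard_kernel,
    build_kernel_matrix,
    cross_kernel,
    lml_and_gradient,
    log_marginal_likelihood,
    optimize_hyperparameters,
    predict_por,
    train_gaze_gp,
)


def _theta(ss=2.0, sn=0.5, ls=None, d=8):
    return GPHyperParams(ss, sn, np.full(d, 1.0) if ls is None else np.asarray(ls, float))


class TestKernel:
    def test_zero_distance_gives_signal_variance(self, rng):
        x = rng.normal(size=8)
        th = _theta()
        assert ard_kernel(x, x, th) == pytest.approx(th.sigma_s)

    def test_single_dimension_closed_form(self):
        """|dx| = 2l gives sigma_s * exp(-1) under the printed form."""
        th = GPHyperParams(3.0, 0.1, [2.0])
        assert ard_kernel([0.0], [4.0], th) == pytest.approx(3.0 * np.exp(-1.0))

    def test_squared_form_closed_form(self):
        th = GPHyperParams(3.0, 0.1, [2.0])
        # (dx/l)^2 = 4 -> exp(-2)
        assert ard_kernel([0.0], [4.0], th, form="squared") == pytest.approx(
            3.0 * np.exp(-2.0)
        )

    def test_symmetry(self, rng):
        th = _theta(ls=rng.uniform(0.5, 3, 8))
        a, b = rng.normal(size=(2, 8))
        assert ard_kernel(a, b, th) == pytest.approx(ard_kernel(b, a, th))

    def test_positive_and_bounded(self, rng):
        th = _theta()
        X = rng.normal(size=(20, 8))
        K = cross_kernel(X, X, th)
        assert np.all(K > 0)
        assert np.all(K <= th.sigma_s + 1e-12)

    def test_nonpositive_lengthscale_rejected(self):
        with pytest.raises(ValueError):
            GPHyperParams(1.0, 1.0, [1.0, 0.0])


class TestKernelMatrix:
    def test_n1_matrix(self):
        th = _theta(ss=2.0, sn=0.5, d=3)
        K = build_kernel_matrix(np.zeros((1, 3)), th)
        assert K.shape == (1, 1)
        assert K[0, 0] == pytest.approx(2.0 + 0.25)

    def test_duplicate_rows(self):
        th = _theta(ss=2.0, sn=0.5, d=2)
        K = build_kernel_matrix(np.zeros((2, 2)), th)
        assert K[0, 1] == pytest.approx(2.0)
        assert K[0, 0] == pytest.approx(2.25)

    def test_matches_elementwise_double_loop(self, rng):
        th = _theta(ls=rng.uniform(0.5, 3, 8))
        X = rng.normal(size=(7, 8))
        K = build_kernel_matrix(X, th)
        # brute-force oracle
        ref = np.empty((7, 7))
        for i in range(7):
            for j in range(7):
                ref[i, j] = th.sigma_s * np.exp(
                    -0.5 * np.sum(np.abs(X[i] - X[j]) / th.lengthscales)
                )
                if i == j:
                    ref[i, j] += th.sigma_n**2
        assert np.allclose(K, ref, atol=1e-12)


class TestMarginalLikelihood:
    def test_n1_closed_form(self):
        th = _theta(ss=2.0, sn=0.5, d=1)
        lml = log_marginal_likelihood(th, [[0.0]], [0.0])
        assert lml == pytest.approx(-0.5 * np.log(2.25) - 0.5 * np.log(2 * np.pi))

    def test_matches_dense_inverse_oracle(self, rng):
        th = _theta(ls=rng.uniform(0.5, 2, 8))
        X = rng.normal(size=(5, 8))
        y = rng.normal(size=5)
        K = build_kernel_matrix(X, th)
        ref = (
            -0.5 * y @ np.linalg.inv(K) @ y
            - 0.5 * np.log(np.linalg.det(K))
            - 2.5 * np.log(2 * np.pi)
        )
        assert log_marginal_likelihood(th, X, y) == pytest.approx(ref, rel=1e-9)

    def test_gradient_matches_finite_differences(self, rng):
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        lt = np.log(np.r_[1.7, 0.6, rng.uniform(0.5, 2, 3)])
        _, g = lml_and_gradient(lt, X, y)
        eps = 1e-6
        for i in range(len(lt)):
            lp, lm = lt.copy(), lt.copy()
            lp[i] += eps
            lm[i] -= eps
            fd = (
                lml_and_gradient(lp, X, y)[0] - lml_and_gradient(lm, X, y)[0]
            ) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_inflating_noise_worsens_noiseless_fit(self, rng):
        """On clean, well-fit data the likelihood drops when sigma_n grows."""
        X = np.linspace(0, 10, 30).reshape(-1, 1)
        y = np.sin(X[:, 0])
        good = GPHyperParams(1.0, 1e-3, [1.0])
        bad = GPHyperParams(1.0, 1.0, [1.0])
        assert log_marginal_likelihood(good, X, y) > log_marginal_likelihood(bad, X, y)


class TestPrediction:
    def test_single_point_interpolation(self):
        th = GPHyperParams(2.0, 1e-6, [1.0])
        gp = GazeGP(np.array([[0.0]]), np.array([5.0]), th)
        mu, var = gp.predict([[0.0]])
        assert mu[0] == pytest.approx(5.0, abs=1e-5)
        assert var[0] == pytest.approx(0.0, abs=1e-5)

    def test_prior_limit_far_from_data(self):
        th = GPHyperParams(2.0, 0.1, [1.0])
        gp = GazeGP(np.array([[0.0]]), np.array([5.0]), th)
        mu, var = gp.predict([[1e4]])
        # mean reverts to the training mean, variance to the prior k(x*,x*)
        assert mu[0] == pytest.approx(gp.y_mean, abs=1e-8)
        assert var[0] == pytest.approx(2.0, abs=1e-8)

    def test_matches_gaussian_conditioning_oracle(self, rng):
        """3-point GP prediction equals direct conditioning of the joint
        multivariate normal to 1e-9."""
        th = GPHyperParams(1.5, 0.3, rng.uniform(0.5, 2, 4))
        X = rng.normal(size=(3, 4))
        xs = rng.normal(size=(1, 4))
        y = rng.normal(size=3)
        gp = GazeGP(X, y, th)
        mu, var = gp.predict(xs)
        # oracle: joint covariance of (y, f*) conditioned on y
        K = build_kernel_matrix(X, th)
        ks = cross_kernel(xs, X, th)[0]
        kss = th.sigma_s
        yc = y - y.mean()
        mu_ref = y.mean() + ks @ np.linalg.solve(K, yc)
        var_ref = kss - ks @ np.linalg.solve(K, ks)
        assert mu[0] == pytest.approx(mu_ref, abs=1e-9)
        assert var[0] == pytest.approx(var_ref, abs=1e-9)

    def test_variance_nonnegative(self, rng):
        th = GPHyperParams(1.0, 1e-3, rng.uniform(0.5, 2, 2))
        X = rng.normal(size=(40, 2))
        gp = GazeGP(X, rng.normal(size=40), th)
        _, var = gp.predict(rng.normal(size=(100, 2)) * 3)
        assert np.all(var >= 0)

    def test_sigma_grows_with_distance(self):
        """Predictive sigma increases monotonically while moving away from
        the training cloud along one axis."""
        th = GPHyperParams(1.0, 0.1, np.ones(8))
        rngl = np.random.default_rng(0)
        X = rngl.normal(size=(30, 8))
        gp_u = GazeGP(X, rngl.normal(size=30), th)
        gp_v = GazeGP(X, rngl.normal(size=30), th)
        base = np.zeros(8)
        sigmas = []
        for d in np.linspace(0, 20, 9):
            q = base.copy()
            q[3] = d
            pred = predict_por((gp_u, gp_v), q)
            sigmas.append(pred.mean_sigma)
        assert np.all(np.diff(sigmas) >= -1e-12)

    def test_variance_free_path_same_means(self, rng):
        th = GPHyperParams(1.0, 0.1, np.ones(3))
        X = rng.normal(size=(15, 3))
        gp = GazeGP(X, rng.normal(size=15), th)
        q = rng.normal(size=(10, 3))
        mu1, _ = gp.predict(q, return_var=True)
        mu2, _ = gp.predict(q, return_var=False)
        assert np.array_equal(mu1, mu2)


class TestHyperOptimization:
    def test_requires_min_samples(self, rng):
        with pytest.raises(ValueError):
            optimize_hyperparameters(rng.normal(size=(5, 2)), rng.normal(size=5))

    def test_lml_not_below_all_ones_start(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        th = optimize_hyperparameters(X, y)
        start = GPHyperParams(1.0, 1.0, np.ones(3))
        assert log_marginal_likelihood(th, X, y) >= log_marginal_likelihood(start, X, y) - 1e-6

    def test_bounds_respected(self, rng):
        X = rng.normal(size=(30, 2)) * 100
        y = rng.normal(size=30) * 50
        th = optimize_hyperparameters(X, y)
        hi = np.exp(10.0)
        assert 0 < th.sigma_s <= hi
        assert 0 < th.sigma_n <= hi
        assert np.all((th.lengthscales > 0) & (th.lengthscales <= hi))

    def test_lml_recovery_from_known_gp(self, rng):
        """Data simulated from a GP with known Theta: the fitted Theta's
        likelihood comes within 1% of the generating Theta's likelihood
        (the raw hyperparameters themselves are weakly identified)."""
        gen = GPHyperParams(2.0, 0.3, [1.5, 0.8])
        X = rng.uniform(-3, 3, size=(200, 2))
        K = build_kernel_matrix(X, gen)
        y = np.linalg.cholesky(K) @ rng.normal(size=200)
        th = optimize_hyperparameters(X, y)
        l_fit = log_marginal_likelihood(th, X, y)
        l_gen = log_marginal_likelihood(gen, X, y)
        assert l_fit >= l_gen - 0.01 * abs(l_gen)

    def test_noise_floor_on_clean_linear_data(self, rng):
        """Noise-free linear targets drive sigma_n toward its lower bound."""
        X = rng.uniform(-2, 2, size=(60, 2))
        y = 0.7 * X[:, 0] - 0.2 * X[:, 1]
        th = optimize_hyperparameters(X, y)
        assert th.sigma_n < 1e-2


class TestTrainGazeGP:
    def test_interpolates_training_data(self, noiseless_walking_session):
        cfg, ds = noiseless_walking_session
        calib = ds.phase("dynamic").time_slice(0, 120)
        gps = train_gaze_gp(calib, subset_size=150, max_train=400)
        sub = calib.subsample(400)
        uv, _sigma = predict_por(gps, sub.X)
        err = np.linalg.norm(uv - sub.targets, axis=1)
        assert np.mean(err) < 5.0  # px, noiseless interpolation

    def test_subset_larger_than_data_uses_all(self, noiseless_walking_session):
        cfg, ds = noiseless_walking_session
        small = ds.phase("dynamic").subsample(60)
        gps = train_gaze_gp(small, subset_size=10_000, max_train=10_000)
        assert len(gps[0].train_y) == len(small)
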