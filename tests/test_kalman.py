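"""Kalman-filter likelihood: dense-Gaussian oracle equivalence, invariances,
steady-state acceleration, MAP optimization and Hessian errors."""

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import multivariate_normal

import viscotrap as vt


def dense_neg_loglik(x, params, dt, calib=1.0):
    """Brute-force joint-Gaussian density: C_ij = [expm(-lam|i-j|dt) sigma]_00
    scaled by calib^2.  Independent of the filter implementation."""
    n = x.size
    lam = params.drift_matrix()
    sigma = params.stationary_cov()
    row = np.array([(expm(-lam * (i * dt)) @ sigma)[0, 0] for i in range(n)])
    idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    cov = row[idx] * calib**2
    return -multivariate_normal.logpdf(x, mean=np.zeros(n), cov=cov)


@pytest.fixture(scope="module")
def short_series(study_params, tau_s):
    traj = vt.simulate_trajectory(
        vt.SimConfig(params=study_params, dt=tau_s, n_samples=120, seed=10)
    )
    return traj


class TestNegLoglik:
    def test_single_observation_is_gaussian_marginal(self, study_params):
        x = np.array([3.1e-8])
        s11 = study_params.stationary_cov()[0, 0]
        expected = 0.5 * (np.log(2 * np.pi) + np.log(s11) + x[0] ** 2 / s11)
        got = vt.kalman_neg_loglik(x, study_params, dt=0.01)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_matches_dense_gaussian_oracle(self, study_params, short_series):
        """Central correctness property: the filter likelihood equals the
        dense stationary-Gaussian density to 1e-8 relative (N = 120)."""
        x, dt = short_series.x, short_series.dt
        got = vt.kalman_neg_loglik(x, study_params, dt)
        want = dense_neg_loglik(x, study_params, dt)
        assert got == pytest.approx(want, rel=1e-8)

    def test_oracle_agreement_off_truth(self, study_params, short_series):
        """Equality must hold at any candidate parameters, not just the truth."""
        x, dt = short_series.x, short_series.dt
        off = study_params.replace(eta0=2e-3, eta1=0.03, tau1=0.4)
        got = vt.kalman_neg_loglik(x, off, dt)
        want = dense_neg_loglik(x, off, dt)
        assert got == pytest.approx(want, rel=1e-8)

    def test_calibration_change_of_variables(self, study_params, short_series):
        """neg_loglik(c x | calib=c) = neg_loglik(x | calib=1) + N ln c."""
        x, dt = short_series.x, short_series.dt
        c = 2.4e6  # e.g. pixels per meter
        base = vt.kalman_neg_loglik(x, study_params, dt)
        scaled = vt.kalman_neg_loglik(
            c * x, study_params, dt, obs=vt.ObsModel(calib=c)
        )
        assert scaled == pytest.approx(base + x.size * np.log(c), rel=1e-10)

    def test_time_reversal_invariance(self, study_params, short_series):
        """The stationary Gaussian process is reversible: the likelihood of
        the reversed series is identical."""
        x, dt = short_series.x, short_series.dt
        fwd = vt.kalman_neg_loglik(x, study_params, dt)
        bwd = vt.kalman_neg_loglik(x[::-1].copy(), study_params, dt)
        assert bwd == pytest.approx(fwd, rel=1e-8)

    def test_steady_state_path_equals_full_loop(self, study_params, tau_s):
        traj = vt.simulate_trajectory(
            vt.SimConfig(params=study_params, dt=tau_s, n_samples=8000, seed=44)
        )
        fast = vt.kalman_neg_loglik(traj.x, study_params, tau_s)
        slow = vt.kalman_neg_loglik(traj.x, study_params, tau_s, steady_tol=-1.0)
        assert fast == pytest.approx(slow, rel=1e-10)

    def test_approx_init_difference_vanishes_per_observation(
        self, study_params, tau_s
    ):
        """The small-dt prior for the first point perturbs the total by a
        bounded amount (the filter forgets it over one slow relaxation), so
        the per-observation difference shrinks as the series grows."""
        traj = vt.simulate_trajectory(
            vt.SimConfig(params=study_params, dt=tau_s, n_samples=40000, seed=45)
        )
        diffs = []
        for n in (4000, 40000):
            a = vt.kalman_neg_loglik(
                traj.x[:n], study_params, tau_s, init_mode="stationary"
            )
            b = vt.kalman_neg_loglik(
                traj.x[:n], study_params, tau_s, init_mode="approx"
            )
            assert a != b
            diffs.append(abs(a - b) / n)
        assert diffs[1] < 0.5 * diffs[0]

    def test_standardized_innovations_white(self, study_params, tau_s):
        traj = vt.simulate_trajectory(
            vt.SimConfig(params=study_params, dt=tau_s, n_samples=20000, seed=46)
        )
        _, innov = vt.kalman_neg_loglik(
            traj.x, study_params, tau_s, return_innovations=True
        )
        n = innov.size
        assert abs(innov.mean()) < 4 / np.sqrt(n)
        assert innov.var() == pytest.approx(1.0, abs=4 * np.sqrt(2 / n))
        lag1 = np.corrcoef(innov[1:], innov[:-1])[0, 1]
        assert abs(lag1) < 4 / np.sqrt(n)


@pytest.fixture(scope="module")
def fitted(study_params, tau_s):
    traj = vt.simulate_trajectory(
        vt.SimConfig(params=study_params, dt=tau_s, n_samples=20000, seed=314)
    )
    k_est = vt.estimate_stiffness(traj.x)
    est = vt.fit_map(traj.x, traj.dt, k_fixed=k_est.k_star)
    return traj, est


class TestFitMAP:

    def test_optimum_beats_truth(self, study_params, fitted):
        traj, est = fitted
        at_truth = vt.kalman_neg_loglik(
            traj.x, study_params.replace(k=est.k_fixed), traj.dt
        )
        assert est.neg_loglik <= at_truth + 1e-6

    def test_recovery_within_sampling_error(self, study_params, fitted):
        # Ts ~ 195 s; likelihood-level relative errors are ~2-8 percent here
        _, est = fitted
        assert est.theta["eta0"] == pytest.approx(study_params.eta0, rel=0.10)
        assert est.theta["eta1"] == pytest.approx(study_params.eta1, rel=0.25)
        assert est.theta["tau1"] == pytest.approx(study_params.tau1, rel=0.25)
        assert est.converged

    def test_errors_positive_and_relative_scale(self, fitted):
        _, est = fitted
        for name in ("eta0", "eta1", "tau1"):
            assert 0 < est.std_errors[name] < est.theta[name]

    def test_grid_oracle(self, study_params, tau_s):
        """The optimizer argmin coincides (within one grid cell) with an
        exhaustive log-grid search around the data-driven start."""
        traj = vt.simulate_trajectory(
            vt.SimConfig(params=study_params, dt=tau_s, n_samples=2000, seed=271)
        )
        k_est = vt.estimate_stiffness(traj.x)
        est = vt.fit_map(traj.x, traj.dt, k_fixed=k_est.k_star, with_errors=False)
        theta_map = np.array([est.theta[n] for n in ("eta0", "eta1", "tau1")])
        # 7^3 grid spanning +-0.5 decades around the MAP-agnostic start
        u_center = np.log(vt.moment_init(traj.x, traj.dt, k_est.k_star))
        step = 0.5 * np.log(10) / 3
        offsets = np.arange(-3, 4) * step
        best_val, best_u = np.inf, None
        for d0 in offsets:
            for d1 in offsets:
                for d2 in offsets:
                    u = u_center + [d0, d1, d2]
                    th = np.exp(u)
                    val = vt.kalman_neg_loglik(
                        traj.x,
                        vt.FluidTrapParams(th[0], th[1], th[2], k_est.k_star),
                        traj.dt,
                    )
                    if val < best_val:
                        best_val, best_u = val, u
        assert est.neg_loglik <= best_val + 1e-6
        assert np.abs(np.log(theta_map) - best_u).max() <= step + 1e-9

    def test_deterministic(self, study_params, tau_s):
        traj = vt.simulate_trajectory(
            vt.SimConfig(params=study_params, dt=tau_s, n_samples=3000, seed=8)
        )
        a = vt.fit_map(traj.x, traj.dt, k_fixed=1e-7, with_errors=False)
        b = vt.fit_map(traj.x, traj.dt, k_fixed=1e-7, with_errors=False)
        assert a.theta == b.theta


class TestHessianErrors:
    def test_1d_quadratic(self):
        """For -ln P = (theta - theta0)^2 / (2 s^2) the error equals s."""
        theta0, s = 2.0, 0.3

        def nll(th):
            return (th[0] - theta0) ** 2 / (2 * s**2)

        err = vt.hessian_std_errors(nll, np.array([theta0]))
        assert err[0] == pytest.approx(s, rel=1e-4)

    def test_3d_quadratic_analytic_inverse(self):
        """Known quadratic form in log space: errors equal the closed-form
        sqrt of the inverse diagonal (delta method to natural scale)."""
        A = np.array([[4.0, 1.0, 0.5], [1.0, 3.0, 0.2], [0.5, 0.2, 2.0]])
        u0 = np.log(np.array([1.5, 0.2, 7.0]))

        def nll(th):
            d = np.log(th) - u0
            return 0.5 * d @ A @ d

        theta0 = np.exp(u0)
        err = vt.hessian_std_errors(nll, theta0)
        expected = theta0 * np.sqrt(np.diag(np.linalg.inv(A)))
        assert np.allclose(err, expected, rtol=1e-5)

    def test_indefinite_hessian_raises(self):
        def nll(th):
            return -((np.log(th[0])) ** 2)  # maximum, not minimum

        with pytest.raises(np.linalg.LinAlgError, match="eigenvalues"):
            vt.hessian_std_errors(nll, np.array([1.0]))


class TestJointFit:
    def test_joint_k_fits_four_parameters(self, study_params, tau_s):
        traj = vt.simulate_trajectory(
            vt.SimConfig(params=study_params, dt=tau_s, n_samples=8000, seed=606)
        )
        k_seed = vt.estimate_stiffness(traj.x).k_star
        est = vt.fit_map(traj.x, traj.dt, k_fixed=k_seed, joint_k=True,
                         with_errors=False)
        assert set(est.theta) == {"eta0", "eta1", "tau1", "k"}
        assert est.k_fixed == est.theta["k"]
        # the joint optimum can only improve on the two-stage likelihood
        fixed = vt.fit_map(traj.x, traj.dt, k_fixed=k_seed, with_errors=False)
        assert est.neg_loglik <= fixed.neg_loglik + 1e-6
        assert est.theta["eta0"] == pytest.approx(study_params.eta0, rel=0.2)
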