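"""Model ACF backends, the empirical estimator, fitting and the range sweep."""

import numpy as np
import pytest
from hypothesis import given

import viscotrap as vt
from test_model import params_strategy


class TestModelACF:
    @given(params_strategy)
    def test_lag_zero_is_equipartition(self, params):
        assert vt.model_acf(params, 0.0) == pytest.approx(
            params.kBT / params.k, rel=1e-12
        )

    def test_backends_agree(self, study_params):
        """Matrix form [expm(-lam t) sigma]_00 vs the literal analytic
        two-exponential expression, over [0, 5 tau1]."""
        t = np.linspace(0.0, 5.0, 400)
        m = vt.model_acf(study_params, t, backend="matrix")
        a = vt.model_acf(study_params, t, backend="analytic")
        assert np.abs(m - a).max() <= 1e-10 * m[0]

    @given(params_strategy)
    def test_backends_agree_generic(self, params):
        t = np.array([0.0, 0.3 * params.tau1, params.tau1, 4.0 * params.tau1])
        m = vt.model_acf(params, t, backend="matrix")
        a = vt.model_acf(params, t, backend="analytic")
        assert np.abs(m - a).max() <= 1e-9 * m[0]

    def test_decays_monotonically_beyond_fast_time(self, study_params, tau_s):
        t = np.linspace(5 * tau_s, 200.0, 500)
        f = vt.model_acf(study_params, t)
        assert np.all(np.diff(f) < 0)
        assert f[-1] < 1e-2 * vt.model_acf(study_params, 0.0)

    def test_negative_lag_rejected(self, study_params):
        with pytest.raises(ValueError):
            vt.model_acf(study_params, -0.1)

    def test_tail_rate_matches_slow_eigenvalue(self, study_params):
        """Log-linear fit of the far tail recovers the slow drift eigenvalue
        to 1 percent — consistency of the coefficients with the spectrum."""
        mu_slow = vt.acf_coefficients(study_params).rates[0]
        t = np.linspace(50.0, 100.0, 50)
        f = vt.model_acf(study_params, t)
        slope = -np.polyfit(t, np.log(f), 1)[0]
        assert slope == pytest.approx(mu_slow, rel=0.01)


class TestEmpiricalACF:
    def test_matches_direct_double_loop(self):
        """FFT estimator equals the direct O(N L) lag sum to 1e-12 relative."""
        rng = np.random.default_rng(5)
        x = rng.standard_normal(64) * 1e-7
        dt = 0.01
        acf = vt.empirical_acf(x, dt, max_lag=0.2, center=True)
        xc = x - x.mean()
        n = x.size
        direct = np.array(
            [np.sum(xc[: n - l] * xc[l:]) / n for l in range(acf.lags.size)]
        )
        assert np.abs(acf.values - direct).max() <= 1e-12 * direct[0]

    def test_all_zero_series(self):
        acf = vt.empirical_acf(np.zeros(100), 0.01, max_lag=0.1)
        assert np.all(acf.values == 0.0)

    def test_uncentered_lag0_is_mean_square(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(500) * 1e-7
        acf = vt.empirical_acf(x, 0.01, max_lag=0.05, center=False)
        assert acf.values[0] == pytest.approx(np.mean(x * x), rel=1e-12)

    def test_max_lag_bound(self):
        with pytest.raises(ValueError):
            vt.empirical_acf(np.zeros(100), 0.01, max_lag=1.0)

    def test_converges_to_model(self, fast_params):
        traj = vt.simulate_trajectory(
            vt.SimConfig(params=fast_params, dt=0.005, n_samples=400_000, seed=77)
        )
        acf = vt.empirical_acf(traj.x, traj.dt, max_lag=0.05, center=False)
        model = vt.model_acf(fast_params, acf.lags)
        assert np.abs(acf.values / model - 1.0).max() < 0.05


class TestFitACF:
    def test_noiseless_recovery(self, study_params):
        """ACF values generated from the model at the truth: the fit recovers
        the generating parameters to optimizer tolerance."""
        dt = 0.001
        lags = np.arange(0, 501) * dt
        data = vt.ACFData(
            lags=lags, values=vt.model_acf(study_params, lags), n_source=10**6
        )
        res = vt.fit_acf(data, k_fixed=study_params.k, fit_range=0.5)
        assert res.theta["eta0"] == pytest.approx(study_params.eta0, rel=1e-4)
        assert res.theta["eta1"] == pytest.approx(study_params.eta1, rel=1e-4)
        assert res.theta["tau1"] == pytest.approx(study_params.tau1, rel=1e-4)
        assert res.S < 1e-6 * data.values[0] ** 2

    def test_user_init_respected(self, study_params):
        dt = 0.001
        lags = np.arange(0, 501) * dt
        data = vt.ACFData(
            lags=lags, values=vt.model_acf(study_params, lags), n_source=10**6
        )
        res = vt.fit_acf(
            data, k_fixed=study_params.k, fit_range=0.5,
            init=(study_params.eta0, study_params.eta1, study_params.tau1),
        )
        assert res.theta["tau1"] == pytest.approx(study_params.tau1, rel=1e-6)

    def test_too_few_lags_rejected(self, study_params):
        lags = np.arange(0, 100) * 0.01
        data = vt.ACFData(
            lags=lags, values=vt.model_acf(study_params, lags), n_source=1000
        )
        with pytest.raises(ValueError, match="at least 5"):
            vt.fit_acf(data, k_fixed=study_params.k, fit_range=0.02)

    def test_scale_equivariance(self, study_params, tau_s):
        """Scaling positions by c with the stiffness re-estimated from the
        scaled data: every decay rate is preserved, so tau1 and the viscosity
        ratio are invariant while k* and both viscosities scale by c^-2
        (dimensional consistency), and the residual variance S scales by c^4."""
        traj = vt.simulate_trajectory(
            vt.SimConfig(params=study_params, dt=0.1 * tau_s, n_samples=100_000,
                         seed=303)
        )
        c = 3.0
        out = []
        for scale in (1.0, c):
            x = traj.x * scale
            k_fix = vt.estimate_stiffness(x).k_star
            acf = vt.empirical_acf(x, traj.dt, max_lag=0.52, center=False)
            out.append(vt.fit_acf(acf, k_fixed=k_fix, fit_range=0.5))
        a, b = out
        assert b.theta["tau1"] == pytest.approx(a.theta["tau1"], rel=1e-4)
        assert b.theta["eta0"] == pytest.approx(a.theta["eta0"] / c**2, rel=1e-4)
        assert b.theta["eta1"] == pytest.approx(a.theta["eta1"] / c**2, rel=1e-4)
        assert b.S == pytest.approx(a.S * c**4, rel=1e-3)


class TestFitRangeSweep:
    def test_single_range_equals_fit_acf(self, study_params):
        dt = 0.001
        lags = np.arange(0, 601) * dt
        rng = np.random.default_rng(9)
        values = vt.model_acf(study_params, lags) * (
            1.0 + 1e-3 * rng.standard_normal(lags.size)
        )
        data = vt.ACFData(lags=lags, values=values, n_source=10**6)
        sweep = vt.fit_range_sweep(data, k_fixed=study_params.k, ranges=[0.5])
        single = vt.fit_acf(data, k_fixed=study_params.k, fit_range=0.5)
        assert sweep.results[0].theta == single.theta
        assert sweep.best_index == 0

    def test_unsorted_ranges_rejected(self, study_params):
        data = vt.ACFData(
            lags=np.arange(0, 100) * 0.01,
            values=np.ones(100) * 1e-14,
            n_source=100,
        )
        with pytest.raises(ValueError, match="sorted"):
            vt.fit_range_sweep(data, k_fixed=1e-7, ranges=[1.0, 0.5])
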