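"""Position autocorrelation function: closed form, estimation and fitting.

The stationary position ACF of the trapped probe is a mixture of two real
decaying exponentials whose rates are the eigenvalues ``(c -+ nu)/2`` of the
drift matrix:

    f(t) = s00 [ (mu2 - q) e^{-mu1 t} + (q - mu1) e^{-mu2 t} ] / (mu2 - mu1),

with ``s00 = kB T / k`` (equipartition), ``q = k/gamma0``,
``c = k/gamma0 + (1 + eta1/eta0)/tau1``, ``omega0 = k/(tau1 gamma0)`` and
``nu = sqrt(c^2 - 4 omega0)``.  Two evaluation backends are provided: the
matrix form ``[expm(-lam t) sigma]_00`` (default, regime-robust) and the
literal analytic expression in terms of ``(a, b, omega0, c, nu)``; they agree
to 1e-10 and are cross-checked in the tests.

Fitting maximizes a Gaussian likelihood that treats the measured ACF value at
every lag as independent with a common unknown variance ``S``.  Profiling
``S`` out analytically reduces this to unweighted least squares on ``f(t)``;
``S`` is reported as the mean squared residual at the optimum.  The
independence assumption is known to fail at long lags — neighbouring ACF
estimates share the same slow fluctuations — which is precisely why the
fitted values drift as the fit range grows; the sweep utility quantifies
this and designates the best range by minimal summed relative standard error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .model import (
    DEFAULT_RADIUS,
    DEFAULT_TEMPERATURE,
    KB,
    FluidTrapParams,
    _drift_spectrum,
    _expm_neg,
)

__all__ = [
    "ACFCoefficients",
    "ACFData",
    "ACFFitResult",
    "ACFSweepResult",
    "acf_coefficients",
    "model_acf",
    "empirical_acf",
    "fit_acf",
    "fit_range_sweep",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ACFCoefficients:
    """Coefficients of the closed-form ACF.

    ``rate_sum`` is the sum of the two decay rates (the trace of the drift
    matrix) and ``nu`` their separation; the rates themselves are
    ``(rate_sum -+ nu)/2``, identical to the drift-matrix eigenvalues.
    """

    a_coef: float  # m^2/s^3
    b_coef: float  # m^2/s
    omega0: float  # 1/s^2
    rate_sum: float  # 1/s
    nu: float  # 1/s

    @property
    def rates(self) -> tuple[float, float]:
        return 0.5 * (self.rate_sum - self.nu), 0.5 * (self.rate_sum + self.nu)


def acf_coefficients(params: FluidTrapParams) -> ACFCoefficients:
    g0 = params.gamma0
    ratio = params.eta1 / params.eta0
    kBT = params.kBT
    a = 2.0 * kBT / (g0 * params.tau1**2) * (1.0 + ratio)
    b = 2.0 * kBT / g0
    omega0 = params.k / (params.tau1 * g0)
    c = params.k / g0 + (1.0 + ratio) / params.tau1
    nu = np.sqrt(max(c * c - 4.0 * omega0, 0.0))
    return ACFCoefficients(a_coef=a, b_coef=b, omega0=omega0, rate_sum=c, nu=nu)


def _acf_mixture(params: FluidTrapParams) -> tuple[float, float, float, float]:
    """(w_slow, w_fast, mu_slow, mu_fast) of the two-exponential ACF."""
    lam = params.drift_matrix()
    mu1, mu2, nu = _drift_spectrum(lam)
    s00 = params.kBT / params.k
    q = params.k / params.gamma0
    if nu == 0.0:  # degenerate double rate; callers fall back to expm
        return np.nan, np.nan, mu1, mu2
    return s00 * (mu2 - q) / nu, s00 * (q - mu1) / nu, mu1, mu2


def model_acf(
    params: FluidTrapParams, t: np.ndarray, backend: str = "matrix"
) -> np.ndarray:
    """Model position ACF at lag(s) ``t`` (seconds), in m^2.

    ``backend='matrix'`` evaluates ``[expm(-lam t) sigma]_00`` through the
    spectral decomposition of the drift matrix; ``backend='analytic'``
    evaluates the literal two-term expression in ``(a, b, omega0, c, nu)``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("lags must be non-negative")
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    if backend == "matrix":
        w1, w2, mu1, mu2 = _acf_mixture(params)
        if np.isnan(w1):
            lam, sigma = params.drift_matrix(), params.stationary_cov()
            out = np.array([(_expm_neg(lam, ti) @ sigma)[0, 0] for ti in t_arr])
        else:
            out = w1 * np.exp(-mu1 * t_arr) + w2 * np.exp(-mu2 * t_arr)
    elif backend == "analytic":
        co = acf_coefficients(params)
        c, nu, a, b, om0 = co.rate_sum, co.nu, co.a_coef, co.b_coef, co.omega0
        sm, sp = 0.5 * (c - nu), 0.5 * (c + nu)
        den_m = sm * sm + sm * c + om0
        den_p = sp * sp + sp * c + om0
        out = (
            (a - b * sm * sm) / den_m * np.exp(-sm * t_arr)
            + (b * sp * sp - a) / den_p * np.exp(-sp * t_arr)
        ) / nu
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return float(out[0]) if scalar else out


@dataclass
class ACFData:
    """An estimated autocovariance sequence on a uniform lag grid."""

    lags: np.ndarray  # s, ascending multiples of dt starting at 0
    values: np.ndarray  # m^2
    n_source: int  # number of samples the estimate came from

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0])


def empirical_acf(
    x: np.ndarray, dt: float, max_lag: float, center: bool = True
) -> ACFData:
    """Biased (1/N-normalized) autocovariance of ``x`` up to ``max_lag`` seconds.

    Computed with an FFT (statsmodels ``acovf``); identical to the direct
    O(N L) lag sum.  The 1/N normalization is preferred over 1/(N-lag) for
    its lower mean-squared error and positive-semidefinite sequence.
    ``center=True`` subtracts the sample mean first (instrumental offsets in
    real data); disable for zero-mean simulation output.
    """
    from statsmodels.tsa.stattools import acovf

    x = np.asarray(x, dtype=float)
    n = x.size
    if not max_lag < n * dt:
        raise ValueError(
            f"max_lag {max_lag!r} s must be shorter than the series "
            f"duration {n * dt!r} s"
        )
    nlag = int(round(max_lag / dt))
    values = acovf(x, demean=center, fft=True, nlag=nlag)
    return ACFData(lags=np.arange(nlag + 1) * dt, values=values, n_source=n)


@dataclass
class ACFFitResult:
    """Least-squares / Gaussian-likelihood fit of the model ACF over one range."""

    theta: dict  # {'eta0', 'eta1', 'tau1'} natural units
    std_errors: dict
    S: float  # residual variance (mean squared residual), m^4
    fit_range: tuple[float, float]  # (0, t_max), s
    residuals: np.ndarray = field(repr=False)
    converged: bool = True
    n_lags: int = 0


@dataclass
class ACFSweepResult:
    """Results of fitting one ACF over several nested lag ranges."""

    results: list  # ACFFitResult or None for failed ranges
    ranges: list  # t_max values, s
    best_index: Optional[int]

    @property
    def best(self) -> Optional[ACFFitResult]:
        return None if self.best_index is None else self.results[self.best_index]

    def to_frame(self):
        """Tabular view (pandas DataFrame) in the units of the printed table:
        mPa s for the viscosities, seconds for the relaxation time."""
        import pandas as pd

        rows = []
        for t_max, res in zip(self.ranges, self.results):
            if res is None:
                rows.append({"fit_range_s": f"0-{t_max:g}"})
                continue
            rows.append(
                {
                    "fit_range_s": f"0-{t_max:g}",
                    "eta0_mPas": res.theta["eta0"] * 1e3,
                    "eta0_err_mPas": res.std_errors["eta0"] * 1e3,
                    "eta1_mPas": res.theta["eta1"] * 1e3,
                    "eta1_err_mPas": res.std_errors["eta1"] * 1e3,
                    "tau1_s": res.theta["tau1"],
                    "tau1_err_s": res.std_errors["tau1"],
                    "best": False,
                }
            )
        frame = pd.DataFrame(rows)
        if self.best_index is not None:
            frame.loc[self.best_index, "best"] = True
        return frame


def _rate_param_model(
    lags: np.ndarray, u: np.ndarray, s00: float
) -> np.ndarray:
    """ACF in the ordered-rate parametrization u = log(mu1, q-mu1, mu2-q)."""
    mu1 = np.exp(u[0])
    q = mu1 + np.exp(u[1])
    mu2 = q + np.exp(u[2])
    return s00 * ((mu2 - q) * np.exp(-mu1 * lags) + (q - mu1) * np.exp(-mu2 * lags)) / (
        mu2 - mu1
    )


def _rates_to_theta(
    u: np.ndarray, k: float, radius: float
) -> np.ndarray:
    """Invert (mu1, q, mu2) to (eta0, eta1, tau1) at fixed stiffness."""
    mu1 = np.exp(u[0])
    q = mu1 + np.exp(u[1])
    mu2 = q + np.exp(u[2])
    gamma0 = k / q
    eta0 = gamma0 / (6.0 * np.pi * radius)
    tau1 = q / (mu1 * mu2)
    ratio = (mu1 + mu2 - q) * tau1 - 1.0
    return np.array([eta0, max(ratio, 1e-12) * eta0, tau1])


def _theta_to_rates(theta: np.ndarray, k: float, radius: float) -> np.ndarray:
    p = FluidTrapParams(theta[0], theta[1], theta[2], k, radius)
    mu1, mu2, _ = _drift_spectrum(p.drift_matrix())
    q = k / p.gamma0
    q = np.clip(q, mu1 * (1 + 1e-12), mu2 * (1 - 1e-12))
    return np.log([mu1, q - mu1, mu2 - q])


def _moment_init_rates(
    acf: ACFData, lags: np.ndarray, values: np.ndarray, s00: float
) -> np.ndarray:
    """Data-driven start in the rate parametrization (see kalman.moment_init)."""
    dt = acf.dt
    tmax = lags[-1]
    ia = max(1, int(0.3 * lags.size))
    ib = max(ia + 1, int(0.9 * lags.size) - 1)
    a_val = max(values[ia], 1e-30 * abs(values[0]))
    b_val = max(values[ib], 0.5e-6 * a_val)
    mu1 = max(np.log(a_val / b_val) / (lags[ib] - lags[ia]), 1e-3 / tmax)
    q = max((values[0] - values[1]) / (dt * s00), 2.0 * mu1)
    w1 = min(a_val * np.exp(min(mu1 * lags[ia], 50.0)), 0.999 * values[0])
    amp_fast = max(values[0] - w1, 1e-4 * abs(values[0]))
    mu2 = mu1 + s00 * max(q - mu1, mu1) / amp_fast
    if mu2 <= 1.5 * q:
        mu2 = 3.0 * q
    return np.log([mu1, q - mu1, mu2 - q])


def fit_acf(
    acf: ACFData,
    k_fixed: float,
    fit_range: float,
    radius: float = DEFAULT_RADIUS,
    temperature: float = DEFAULT_TEMPERATURE,
    init: Optional[Sequence[float]] = None,
    grid_halfwidth: float = 1.5,
    grid_points: int = 7,
) -> ACFFitResult:
    """Fit ``(eta0, eta1, tau1)`` to an estimated ACF over lags ``[0, fit_range]``.

    The Gaussian likelihood with common unknown residual variance ``S`` is
    maximized with ``S`` profiled out, i.e. unweighted least squares on the
    model ACF.  Optimization runs in an ordered-rate parametrization
    ``mu1 < q < mu2`` (slow rate, solvent rate ``k/gamma0``, fast rate) which
    is far better conditioned than the raw viscosities; starts are the
    data-driven moment estimate refined by a coarse log-grid search
    (``grid_points`` per axis over +-``grid_halfwidth`` decades), followed by
    Nelder-Mead and a Powell polish.  Standard errors come from the
    finite-difference Hessian of the profiled negative log-likelihood
    ``(N/2) log SSR`` mapped to the natural parameters.

    A failed optimization is returned with ``converged=False``, not raised.
    """
    sel = acf.lags <= fit_range * (1 + 1e-9)
    lags = acf.lags[sel]
    values = acf.values[sel]
    if lags.size < 5:
        raise ValueError(
            f"fit range 0-{fit_range!r} s contains only {lags.size} lags; "
            "need at least 5"
        )
    kBT = KB * temperature
    s00 = kBT / k_fixed
    n_lags = lags.size

    def ssr(u: np.ndarray) -> float:
        if np.any(np.abs(u) > 80.0):
            return np.inf
        r = values - _rate_param_model(lags, u, s00)
        return float(np.dot(r, r))

    obj = lambda u: np.log(max(ssr(u), 1e-300))

    if init is not None:
        u0 = _theta_to_rates(np.asarray(init, dtype=float), k_fixed, radius)
        starts = [u0]
    else:
        u0 = _moment_init_rates(acf, lags, values, s00)
        # coarse global refinement around the moment start
        grid = np.linspace(-grid_halfwidth * np.log(10), grid_halfwidth * np.log(10),
                           grid_points)
        best_u, best_f = u0, obj(u0)
        for d0 in grid:
            for d1 in grid:
                for d2 in grid:
                    u_try = u0 + np.array([d0, d1, d2])
                    f_try = obj(u_try)
                    if f_try < best_f:
                        best_f, best_u = f_try, u_try
        starts = [u0, best_u, best_u + 0.3, best_u - 0.3]

    best = None
    for u_start in starts:
        res = minimize(
            obj,
            u_start,
            method="Nelder-Mead",
            options=dict(fatol=1e-12, xatol=1e-10, maxiter=6000, maxfev=6000),
        )
        if best is None or res.fun < best.fun:
            best = res
    polish = minimize(obj, best.x, method="Powell",
                      options=dict(ftol=1e-12, xtol=1e-10))
    if polish.fun < best.fun:
        best = polish
    converged = bool(np.isfinite(best.fun))

    u_star = best.x
    theta_star = _rates_to_theta(u_star, k_fixed, radius)
    ssr_star = ssr(u_star)
    S = ssr_star / n_lags
    residuals = values - _rate_param_model(lags, u_star, s00)

    # profiled Gaussian likelihood: -ln L(theta) = (N/2) ln SSR(theta) + const
    names = ("eta0", "eta1", "tau1")
    errors = dict(zip(names, [np.nan] * 3))
    try:
        from .kalman import hessian_std_errors

        def profiled_nll(theta: np.ndarray) -> float:
            u = _theta_to_rates(theta, k_fixed, radius)
            return 0.5 * n_lags * np.log(max(ssr(u), 1e-300))

        err = hessian_std_errors(profiled_nll, theta_star)
        errors = dict(zip(names, err.tolist()))
    except (np.linalg.LinAlgError, ValueError):
        logger.warning("ACF-fit Hessian not positive definite; errors set to NaN")
        converged = False

    return ACFFitResult(
        theta=dict(zip(names, theta_star.tolist())),
        std_errors=errors,
        S=S,
        fit_range=(0.0, float(fit_range)),
        residuals=residuals,
        converged=converged,
        n_lags=n_lags,
    )


def fit_range_sweep(
    acf: ACFData,
    k_fixed: float,
    ranges: Sequence[float],
    radius: float = DEFAULT_RADIUS,
    temperature: float = DEFAULT_TEMPERATURE,
) -> ACFSweepResult:
    """Fit the same ACF over several nested ranges ``[0, t_max]``.

    The best range is designated where the summed relative standard error of
    the three parameters is minimal (the criterion used to pick the "best
    fitting" in range-sweep tables).  A range whose fit fails is recorded as
    ``None`` and skipped in the designation.
    """
    ranges = list(ranges)
    if sorted(ranges) != ranges:
        raise ValueError("ranges must be sorted ascending")
    results = []
    for t_max in ranges:
        try:
            results.append(
                fit_acf(acf, k_fixed, t_max, radius=radius, temperature=temperature)
            )
        except (ValueError, RuntimeError) as exc:
            logger.warning("fit over 0-%g s failed: %s", t_max, exc)
            results.append(None)
    best_index = None
    best_score = np.inf
    for i, res in enumerate(results):
        if res is None or not res.converged:
            continue
        score = sum(
            res.std_errors[name] / res.theta[name] for name in ("eta0", "eta1", "tau1")
        )
        if np.isfinite(score) and score < best_score:
            best_score, best_index = score, i
    return ACFSweepResult(results=results, ranges=ranges, best_index=best_index)
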