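"""Exact marginal likelihood of the observed positions and MAP rheology fit.

The observed position is one component of the two-state OU process, so the
trajectory likelihood is that of a linear-Gaussian state-space model,

    Y_n = F Y_{n-1} + eps_n,        x_n = C Y_n,   C = [c, 0],

computed exactly by the Kalman filter: the negative log-likelihood is

    (1/2) sum_n [ log 2 pi + log Omega_{n|n-1}
                  + (x_n - xhat_{n|n-1})^2 / Omega_{n|n-1} ],

where ``xhat`` and ``Omega`` are the one-step predictive mean and variance of
the observation.  With the filter initialized at the stationary prior
(``Yhat_{1|0} = 0``, ``omega_{1|0} = sigma``) this equals the density of the
N-dimensional stationary Gaussian with covariance
``C_ij = [expm(-lam |i-j| dt) sigma]_00 c^2`` — the property the test suite
checks against dense linear algebra.  ``init_mode='approx'`` instead starts
from ``omega_{1|0} = D D^T dt``, the small-dt approximation of the one-step
covariance; the two differ by a vanishing O(1/N) amount on long series.

The MAP stage maximizes this likelihood over ``(eta0, eta1, tau1)`` in log
space (flat prior in the log parameters, guaranteeing positivity) with the
trap stiffness held fixed at the stage-I estimate; standard errors come from
the finite-difference Hessian at the optimum.

Performance: the predictive covariance obeys a Riccati recursion that
converges geometrically to a steady state.  Once converged, the gain and
innovation variance are frozen and the remaining innovation pass — a linear
constant-coefficient recursion in the observations — is evaluated with
``scipy.signal.lfilter``, making million-point likelihoods fast.  The frozen
pass is exact to the convergence tolerance (1e-13 of ||sigma||), verified
against the plain loop in the tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.optimize import minimize
from scipy.signal import lfilter, lfiltic

from .model import (
    DEFAULT_RADIUS,
    DEFAULT_TEMPERATURE,
    FluidTrapParams,
    build_ou_system,
)

__all__ = [
    "ObsModel",
    "MAPEstimate",
    "kalman_neg_loglik",
    "fit_map",
    "hessian_std_errors",
    "moment_init",
]

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))

#: Riccati steady-state tolerance, relative to ||sigma||_max.
STEADY_TOL = 1e-13


class FilterConditioningError(RuntimeError):
    """The predictive variance became non-positive at some step."""


@dataclass(frozen=True)
class ObsModel:
    """Observation model ``x_n = [calib, 0] Y_n``.

    ``calib`` converts meters to the recorded trajectory units (set to 1 when
    the data are already in meters).
    """

    calib: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.calib) or self.calib <= 0:
            raise ValueError(f"calib must be positive, got {self.calib!r}")


@dataclass
class MAPEstimate:
    """MAP rheological parameters with Hessian standard errors."""

    theta: dict  # {'eta0': Pa s, 'eta1': Pa s, 'tau1': s}
    std_errors: dict
    k_fixed: float  # N/m
    neg_loglik: float  # nats
    converged: bool
    n_function_evals: int
    init_mode: str

    @property
    def params(self) -> FluidTrapParams:
        return self._params

    _params: FluidTrapParams = field(default=None, repr=False)


def kalman_neg_loglik(
    x: np.ndarray,
    params: FluidTrapParams,
    dt: float,
    obs: ObsModel = ObsModel(),
    init_mode: str = "stationary",
    return_innovations: bool = False,
    steady_tol: float = STEADY_TOL,
):
    """Negative log-likelihood of an observed position series.

    Parameters
    ----------
    x : array_like
        Observations, in the recorded units (meters when ``obs.calib == 1``).
    params : FluidTrapParams
        Candidate physical parameters (including the trap stiffness).
    dt : float
        Sampling step, s.
    init_mode : {'stationary', 'approx'}
        Prior for the first observation: the exact stationary covariance, or
        the small-dt approximation ``D D^T dt``.
    return_innovations : bool
        Also return the standardized one-step prediction errors (useful as a
        whiteness diagnostic; they are iid N(0, 1) under the model).
    steady_tol : float
        Riccati freeze threshold; pass a negative value to disable the
        steady-state fast path (plain filter loop).

    Returns
    -------
    float, or (float, ndarray) when ``return_innovations`` is set.
    """
    x = np.asarray(x, dtype=float)
    n_obs = x.size
    if n_obs < 1:
        raise ValueError("need at least one observation")
    sys_ = build_ou_system(params, dt)
    F, sigma, Sigma = sys_.F, sys_.sigma, sys_.Sigma_dt
    c = obs.calib
    c2 = c * c
    if init_mode == "stationary":
        P = sigma.copy()
    elif init_mode == "approx":
        P = sys_.Dmat @ sys_.Dmat.T * dt
    else:
        raise ValueError(f"unknown init_mode {init_mode!r}")
    y = np.zeros(2)
    nrm = steady_tol * np.abs(sigma).max() if steady_tol > 0 else -1.0

    total = 0.0
    innovations = np.empty(n_obs) if return_innovations else None
    m = None  # first observation index handled by the frozen pass
    p_prev = np.nan
    for n in range(n_obs):
        omega = c2 * P[0, 0]
        if not omega > 0.0:
            raise FilterConditioningError(
                f"non-positive predictive variance at step {n} (dt={dt!r})"
            )
        innov = x[n] - c * y[0]
        total += 0.5 * (_LOG2PI + np.log(omega) + innov * innov / omega)
        if return_innovations:
            innovations[n] = innov / np.sqrt(omega)
        gain = P[:, 0] * (c / omega)
        y_f = y + gain * innov
        P_f = P - np.outer(P[:, 0], P[0, :]) * (c2 / omega)
        p_old = c * y[0]
        y = F @ y_f
        P_new = F @ P_f @ F.T + Sigma
        if nrm > 0 and 2 <= n < n_obs - 1 and np.abs(P_new - P).max() < nrm:
            P = P_new
            m = n + 1
            p_prev = p_old
            break
        P = P_new

    if m is None:
        if return_innovations:
            return total, innovations
        return total

    # Frozen steady-state innovation pass.  With constant gain K the predicted
    # observation obeys p_n = tr(A) p_{n-1} - det(A) p_{n-2}
    #                         + c b0 x_{n-1} + c (A01 b1 - A11 b0) x_{n-2}
    # for A = F (I - K C), b = F K.
    omega = c2 * P[0, 0]
    K = P[:, 0] * (c / omega)
    A = F @ (np.eye(2) - np.outer(K, [c, 0.0]))
    b = F @ K
    trA = A[0, 0] + A[1, 1]
    detA = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    num = [0.0, c * b[0], c * (A[0, 1] * b[1] - A[1, 1] * b[0])]
    den = [1.0, -trA, detA]
    p_m = c * y[0]
    zi = lfiltic(num, den, y=[p_m, p_prev], x=[x[m], x[m - 1]])
    tail, _ = lfilter(num, den, x[m + 1 :], zi=zi)
    preds = np.concatenate([[p_m], tail])
    innov = x[m:] - preds
    total += 0.5 * np.sum(_LOG2PI + np.log(omega) + innov * innov / omega)
    if return_innovations:
        innovations[m:] = innov / np.sqrt(omega)
        return total, innovations
    return total


def moment_init(
    x: np.ndarray,
    dt: float,
    k_fixed: float,
    radius: float = DEFAULT_RADIUS,
    temperature: float = DEFAULT_TEMPERATURE,
    max_lag: Optional[float] = None,
) -> np.ndarray:
    """Truth-agnostic starting point ``(eta0, eta1, tau1)`` from ACF moments.

    The model ACF is a two-exponential mixture
    ``f(t) = s00 [(mu2 - q) e^{-mu1 t} + (q - mu1) e^{-mu2 t}] / (mu2 - mu1)``
    with ``q = k/gamma0`` and rates ``mu1 < q < mu2``.  Crude estimates:
    the initial slope gives ``q`` (``f'(0) = -s00 q``), a log-linear fit of
    the tail gives ``mu1``, and the amplitude left above the extrapolated
    slow mode at lag 0 gives ``mu2``.  The inverse map then yields the
    physical parameters.  Only used to seed the optimizer.
    """
    from statsmodels.tsa.stattools import acovf

    x = np.asarray(x, dtype=float)
    kBT = 1.380649e-23 * temperature
    s00 = kBT / k_fixed
    n = x.size
    if max_lag is None:
        max_lag = min(0.2 * n * dt, 1000.0 * dt)
    nlag = max(int(round(max_lag / dt)), 5)
    nlag = min(nlag, n - 1)
    ac = acovf(x, demean=False, fft=True, nlag=nlag)
    lags = np.arange(nlag + 1) * dt
    tmax = lags[-1]
    ia = max(1, int(0.3 * lags.size))
    ib = max(ia + 1, int(0.9 * lags.size) - 1)
    a_val = max(ac[ia], 1e-30 * abs(ac[0]))
    b_val = max(ac[ib], 0.5e-6 * a_val)
    mu1 = max(np.log(a_val / b_val) / (lags[ib] - lags[ia]), 1e-3 / tmax)
    q = max((ac[0] - ac[1]) / (dt * s00), 2.0 * mu1)
    w1 = min(a_val * np.exp(min(mu1 * lags[ia], 50.0)), 0.999 * ac[0])
    amp_fast = max(ac[0] - w1, 1e-4 * abs(ac[0]))
    mu2 = mu1 + s00 * max(q - mu1, mu1) / amp_fast
    if mu2 <= 1.5 * q:
        mu2 = 3.0 * q
    gamma0 = k_fixed / q
    eta0 = gamma0 / (6.0 * np.pi * radius)
    tau1 = q / (mu1 * mu2)
    ratio = max((mu1 + mu2 - q) * tau1 - 1.0, 0.05)
    return np.array([eta0, ratio * eta0, tau1])


def _neg_loglik_factory(
    x: np.ndarray,
    dt: float,
    k_fixed: float,
    radius: float,
    temperature: float,
    obs: ObsModel,
    init_mode: str,
    joint_k: bool = False,
) -> Callable[[np.ndarray], float]:
    """Objective over u = log(eta0, eta1, tau1[, k]); robust to invalid trials."""

    def fun(u: np.ndarray) -> float:
        if np.any(np.abs(u) > 80.0):
            return 1e300
        vals = np.exp(u)
        eta0, eta1, tau1 = vals[:3]
        k_val = vals[3] if joint_k else k_fixed
        try:
            params = FluidTrapParams(
                eta0=eta0,
                eta1=eta1,
                tau1=tau1,
                k=k_val,
                radius=radius,
                temperature=temperature,
            )
            val = kalman_neg_loglik(x, params, dt, obs=obs, init_mode=init_mode)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError,
                FilterConditioningError):
            return 1e300
        return val if np.isfinite(val) else 1e300

    return fun


def fit_map(
    x: np.ndarray,
    dt: float,
    k_fixed: float,
    radius: float = DEFAULT_RADIUS,
    temperature: float = DEFAULT_TEMPERATURE,
    obs: ObsModel = ObsModel(),
    init_mode: str = "stationary",
    init: Optional[np.ndarray] = None,
    with_errors: bool = True,
    joint_k: bool = False,
) -> MAPEstimate:
    """MAP fit of ``(eta0, eta1, tau1)`` with the trap stiffness held fixed.

    Three starting points are used unless ``init`` is given: the ACF
    method-of-moments estimate and its x10 and /10 perturbations.  Each start
    runs a Nelder-Mead simplex in log-parameter space, and the best result is
    polished with Powell.  Deterministic given data and options.

    ``joint_k=True`` frees the stiffness and fits all four parameters jointly
    (``k_fixed`` then only seeds the ``k`` dimension); the two-stage workflow
    remains the default.
    """
    x = np.asarray(x, dtype=float)
    fun = _neg_loglik_factory(
        x, dt, k_fixed, radius, temperature, obs, init_mode, joint_k=joint_k
    )
    if init is not None:
        starts = [np.log(np.asarray(init, dtype=float))]
    else:
        u0 = np.log(moment_init(x, dt, k_fixed, radius, temperature))
        shift = np.log(10.0)
        starts = [u0, u0 + shift, u0 - shift]
    if joint_k:
        log_k = np.log(k_fixed)
        starts = [np.append(u, log_k) for u in starts]
    best = None
    nfev = 0
    for u_start in starts:
        res = minimize(
            fun,
            u_start,
            method="Nelder-Mead",
            options=dict(fatol=1e-8, xatol=1e-7, maxiter=4000, maxfev=4000),
        )
        nfev += res.nfev
        if best is None or res.fun < best.fun:
            best = res
    if best.fun >= 1e300:
        raise RuntimeError("likelihood non-finite at every starting point")
    polish = minimize(
        fun, best.x, method="Powell", options=dict(ftol=1e-10, xtol=1e-8)
    )
    nfev += polish.nfev
    converged = bool(best.success or polish.success)
    if polish.fun < best.fun:
        best = polish
    theta_star = np.exp(best.x)
    names = ("eta0", "eta1", "tau1", "k")[: theta_star.size]
    errors = np.full(theta_star.size, np.nan)
    if with_errors:
        try:
            errors = hessian_std_errors(
                lambda th: fun(np.log(th)), theta_star
            )
        except np.linalg.LinAlgError:
            logger.warning("indefinite Hessian at the MAP; errors set to NaN")
            converged = False
    k_star = theta_star[3] if joint_k else k_fixed
    est = MAPEstimate(
        theta=dict(zip(names, theta_star.tolist())),
        std_errors=dict(zip(names, errors.tolist())),
        k_fixed=k_star,
        neg_loglik=float(best.fun),
        converged=converged,
        n_function_evals=nfev,
        init_mode=init_mode,
    )
    est._params = FluidTrapParams(
        eta0=theta_star[0],
        eta1=theta_star[1],
        tau1=theta_star[2],
        k=k_star,
        radius=radius,
        temperature=temperature,
    )
    return est


def hessian_std_errors(
    neg_loglik_fn: Callable[[np.ndarray], float],
    theta_star: np.ndarray,
    rel_step: float = 1e-4,
) -> np.ndarray:
    """Standard errors from the curvature of the negative log-posterior.

    The Hessian is computed by central finite differences in log-parameter
    space (step ``rel_step`` in log units, i.e. relative); errors are
    ``sqrt(diag(H^{-1}))`` mapped to the natural scale with the delta method
    (``se_nat = theta * se_log``).  Raises ``numpy.linalg.LinAlgError`` when
    the Hessian is not positive definite, reporting its eigenvalues —
    indicating non-convergence or a flat direction.
    """
    theta_star = np.asarray(theta_star, dtype=float)
    u0 = np.log(theta_star)
    p = u0.size
    g = lambda u: float(neg_loglik_fn(np.exp(u)))
    h = rel_step
    H = np.empty((p, p))
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h
        H[i, i] = (g(u0 + 2 * ei) - 2.0 * g(u0) + g(u0 - 2 * ei)) / (4.0 * h * h)
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h
            H[i, j] = H[j, i] = (
                g(u0 + ei + ej) - g(u0 + ei - ej) - g(u0 - ei + ej) + g(u0 - ei - ej)
            ) / (4.0 * h * h)
    eigvals = np.linalg.eigvalsh(H)
    if np.any(eigvals <= 0.0):
        raise np.linalg.LinAlgError(
            "Hessian is not positive definite (eigenvalues "
            f"{eigvals.tolist()}); the optimum may not have converged or a "
            "direction is flat"
        )
    cov_log = np.linalg.inv(H)
    return theta_star * np.sqrt(np.diag(cov_log))
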