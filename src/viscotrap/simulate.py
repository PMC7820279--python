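"""Exact trajectory sampling from the AR(1) representation, plus an Euler oracle.

``simulate_trajectory`` draws from the exact discrete-time law
``Y_n = F Y_{n-1} + eps_n`` (no time-discretization error at any step size);
``simulate_euler_oracle`` integrates the continuous-time system with
Euler-Maruyama substeps and serves as an independent cross-check of the
exact sampler.

Both samplers reduce to linear constant-coefficient recursions driven by
Gaussian noise, which are evaluated at C speed with ``scipy.signal.lfilter``:
eliminating one state component from ``Y_n = M Y_{n-1} + e_n`` leaves a
second-order scalar recursion per component,

    x_n = tr(M) x_{n-1} - det(M) x_{n-2} + e0_n - M11 e0_{n-1} + M01 e1_{n-1},

seeded with the first two states computed directly.  This is bit-equivalent
to the naive loop (asserted in the test suite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import lfilter, lfiltic

from .model import FluidTrapParams, OUSystem, Trajectory, build_ou_system, timescales

__all__ = ["SimConfig", "simulate_trajectory", "simulate_euler_oracle"]

logger = logging.getLogger(__name__)


class NumericalConditioningError(RuntimeError):
    pass


@dataclass
class SimConfig:
    """Configuration of one simulated trajectory.

    ``init_mode='stationary'`` draws ``Y_0 ~ N(0, sigma)`` so every marginal is
    stationary (the continuous model is prepared at t = -infinity, hence no
    burn-in is needed); ``init_mode='given'`` starts from ``init_state`` and
    optionally discards ``burn_in`` initial samples.
    """

    params: FluidTrapParams
    dt: float
    n_samples: int
    seed: object = 0
    init_mode: str = "stationary"
    init_state: Optional[np.ndarray] = None
    burn_in: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.init_mode not in ("stationary", "given"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if self.init_mode == "given" and self.init_state is None:
            raise ValueError("init_mode='given' requires init_state")


def _safe_cholesky(mat: np.ndarray, what: str, dt: float) -> np.ndarray:
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        jitter = 1e-12 * np.trace(mat)
        try:
            return np.linalg.cholesky(mat + jitter * np.eye(2))
        except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological
            raise NumericalConditioningError(
                f"Cholesky factorization of {what} failed at dt={dt!r} "
                f"even after jitter {jitter:.3e}"
            ) from exc


def _ar1_sample(
    M: np.ndarray, e: np.ndarray, y0: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the vector recursion Y_n = M Y_{n-1} + e_n exactly.

    Parameters
    ----------
    M : (2, 2) ndarray
        Transition matrix.
    e : (n-1, 2) ndarray
        Innovation vectors e_1 .. e_{n-1}.
    y0 : (2,) ndarray
        Initial state Y_0.
    """
    n = e.shape[0] + 1
    x = np.empty(n)
    X = np.empty(n)
    x[0], X[0] = y0
    if n == 1:
        return x, X
    x[1] = M[0, 0] * x[0] + M[0, 1] * X[0] + e[0, 0]
    X[1] = M[1, 0] * x[0] + M[1, 1] * X[0] + e[0, 1]
    if n == 2:
        return x, X
    tr = M[0, 0] + M[1, 1]
    det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
    den = [1.0, -tr, det]
    g = e[1:, 0] - M[1, 1] * e[:-1, 0] + M[0, 1] * e[:-1, 1]
    x[2:], _ = lfilter([1.0], den, g, zi=lfiltic([1.0], den, y=[x[1], x[0]]))
    h = e[1:, 1] - M[0, 0] * e[:-1, 1] + M[1, 0] * e[:-1, 0]
    X[2:], _ = lfilter([1.0], den, h, zi=lfiltic([1.0], den, y=[X[1], X[0]]))
    return x, X


def _initial_state(
    cfg: SimConfig, sigma: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    if cfg.init_mode == "stationary":
        return _safe_cholesky(sigma, "sigma", cfg.dt) @ rng.standard_normal(2)
    return np.asarray(cfg.init_state, dtype=float)


def simulate_trajectory(cfg: SimConfig, system: Optional[OUSystem] = None) -> Trajectory:
    """Draw one trajectory from the exact discrete-time law.

    Returns a :class:`Trajectory` carrying both the observable position ``x``
    and the hidden auxiliary component ``hidden_X``.  Reproducible: the same
    ``cfg.seed`` yields a bit-identical trajectory.
    """
    sys_ = system if system is not None else build_ou_system(cfg.params, cfg.dt)
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_samples + cfg.burn_in
    y0 = _initial_state(cfg, sys_.sigma, rng)
    L = _safe_cholesky(sys_.Sigma_dt, "Sigma(dt)", cfg.dt)
    e = rng.standard_normal((n_total - 1, 2)) @ L.T
    x, X = _ar1_sample(sys_.F, e, y0)
    if cfg.burn_in:
        x, X = x[cfg.burn_in :], X[cfg.burn_in :]
    return Trajectory(dt=cfg.dt, x=x, hidden_X=X)


def simulate_euler_oracle(cfg: SimConfig, substeps: int) -> Trajectory:
    """Euler-Maruyama integration of the coupled Langevin system.

    Integrates ``dY = -lam Y dt + D dW`` with ``substeps`` sub-intervals per
    output sample, driven by the two independent unit-variance white noises,
    then keeps every ``substeps``-th point.  Distributional summaries converge
    to those of :func:`simulate_trajectory` as ``substeps`` grows; the two
    samplers are otherwise fully independent code paths.
    """
    if substeps < 10:
        raise ValueError("substeps must be >= 10")
    params = cfg.params
    h = cfg.dt / substeps
    tau_s, _ = timescales(params)
    if h > tau_s / 10.0:
        logger.warning(
            "Euler substep %.3g s exceeds tau_S/10 = %.3g s; discretization "
            "bias may be visible",
            h,
            tau_s / 10.0,
        )
    lam = params.drift_matrix()
    M = np.eye(2) - lam * h
    Dmat = params.noise_matrix()
    rng = np.random.default_rng(cfg.seed)
    y0 = _initial_state(cfg, params.stationary_cov(), rng)
    n_total = cfg.n_samples + cfg.burn_in
    n_fine = (n_total - 1) * substeps + 1
    e = rng.standard_normal((n_fine - 1, 2)) * (np.sqrt(h) * np.diag(Dmat))
    x, X = _ar1_sample(M, e, y0)
    if not (np.isfinite(x[-1]) and np.isfinite(X[-1])):
        raise NumericalConditioningError(
            "Euler integration diverged; decrease dt or increase substeps"
        )
    x, X = x[::substeps], X[::substeps]
    if cfg.burn_in:
        x, X = x[cfg.burn_in :], X[cfg.burn_in :]
    return Trajectory(dt=cfg.dt, x=x, hidden_X=X)
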