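"""Trap-stiffness estimation from the stationary distribution (Bayesian stage I).

With a flat prior, the posterior over the stationary covariance given the
observed positions is maximized by the sample second moment, and the trap
stiffness follows from equipartition:

    k* = N kB T / sum_n x_n^2,      SE(k*) = k* / sqrt(N).

The quoted standard error assumes the N samples were drawn independently from
the stationary distribution.  Trajectory samples are strongly correlated
(the position decorrelates over (gamma0+gamma1)/k, which for soft traps in
polymer solutions is tens of seconds), so that error is optimistic.
:func:`effective_stiffness_error` additionally reports an
autocorrelation-corrected error based on the effective sample size; it is an
extension beyond the plain estimator and is labelled as such in its output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import KB, DEFAULT_TEMPERATURE

__all__ = [
    "StiffnessEstimate",
    "estimate_stiffness",
    "estimate_stationary_cov",
    "effective_stiffness_error",
]


@dataclass(frozen=True)
class StiffnessEstimate:
    """MAP trap stiffness with its (independence-assumption) standard error."""

    k_star: float  # N/m
    std_error: float  # N/m, equals k_star/sqrt(n_used)
    n_used: int
    temperature: float  # K


def estimate_stiffness(
    x: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
    center: bool = False,
) -> StiffnessEstimate:
    """MAP estimate of the trap stiffness from positions about the trap center.

    Parameters
    ----------
    x : array_like
        Positions in meters.  The model is zero-mean, so by default no mean is
        subtracted; pass ``center=True`` for real data with an instrumental
        offset (a deviation from the plain second-moment estimator).
    temperature : float
        Bath temperature, K.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("positions contain non-finite values")
    if center:
        x = x - x.mean()
    ssq = float(np.dot(x, x))
    if ssq == 0.0:
        raise ZeroDivisionError("all positions are zero; stiffness undefined")
    n = x.size
    k_star = n * KB * temperature / ssq
    return StiffnessEstimate(
        k_star=k_star,
        std_error=k_star / np.sqrt(n),
        n_used=n,
        temperature=temperature,
    )


def estimate_stationary_cov(Y: np.ndarray) -> np.ndarray:
    """Sample second-moment matrix (1/N) sum_n Y_n Y_n^T of the full state.

    ``Y`` is an (N, 2) array of ``(x, X)`` rows — available from the simulator
    only, since experiments observe the position alone.  On long stationary
    runs this converges to the model's stationary covariance ``sigma``.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != 2:
        raise ValueError("Y must be an (N, 2) array of state rows")
    return Y.T @ Y / Y.shape[0]


def effective_stiffness_error(
    x: np.ndarray,
    dt: float,
    temperature: float = DEFAULT_TEMPERATURE,
) -> tuple[float, float]:
    """Autocorrelation-corrected standard error of ``k*`` and the effective N.

    For a stationary Gaussian series the variance of the sample second moment
    is inflated by ``sum_l rho_l^2`` over all lags; the effective number of
    independent draws is ``N_eff = N / sum_l rho_l^2`` and the corrected
    relative error of the variance (hence of ``k*`` to first order) is
    ``sqrt(2 / N_eff)``.  The lag sum is taken from the empirical position
    autocorrelation, truncated at its first zero crossing.

    Returns ``(std_error_eff, n_eff)`` with the error in N/m.
    """
    from statsmodels.tsa.stattools import acovf

    x = np.asarray(x, dtype=float)
    est = estimate_stiffness(x, temperature=temperature)
    n = x.size
    nlag = n - 1
    ac = acovf(x, demean=False, fft=True, nlag=nlag)
    rho = ac / ac[0]
    neg = np.nonzero(rho <= 0.0)[0]
    cut = int(neg[0]) if neg.size else rho.size
    lag_weights = 1.0 - np.arange(cut) / n
    s = 1.0 + 2.0 * float(np.sum(lag_weights[1:] * rho[1:cut] ** 2))
    n_eff = n / s
    rel_sd = np.sqrt(2.0 / n_eff)
    return est.k_star * rel_sd, n_eff
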