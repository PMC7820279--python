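"""Physical parameterization and exact discrete-time form of the trapped-probe process.

A micron-sized bead held in a harmonic optical trap (stiffness ``k``) inside a
Jeffreys fluid — a viscous solvent (viscosity ``eta0``) in parallel with a
single Maxwell element (polymer viscosity ``eta1``, stress-relaxation time
``tau1``) — performs overdamped Brownian motion with an exponential memory
kernel.  Augmenting the position ``x`` with one auxiliary variable ``X``
(a noisy exponential average of the past positions) restores Markovianity:
the pair ``Y = (x, X)`` is a two-dimensional Ornstein-Uhlenbeck process

    dY = -lam Y dt + D dW,

whose drift matrix ``lam``, stationary covariance ``sigma`` and noise matrix
``D`` are closed-form functions of the physical parameters.  Sampled at a
uniform step ``dt`` the process is an exact AR(1),

    Y_n = F Y_{n-1} + eps_n,   F = expm(-lam dt),  Cov(eps_n) = Sigma(dt),

with ``Sigma(dt) = sigma - F sigma F^T``.  Everything downstream — the exact
simulator, the Kalman-filter likelihood and the model autocorrelation
function — is built from the quantities assembled here.

Internal units are strictly SI (m, s, Pa s, N/m, K).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import expm

__all__ = [
    "KB",
    "DEFAULT_TEMPERATURE",
    "DEFAULT_RADIUS",
    "FluidTrapParams",
    "OUSystem",
    "Trajectory",
    "build_ou_system",
    "timescales",
]

#: Boltzmann constant, J/K (2019 SI exact value).
KB = 1.380649e-23

#: Default bath temperature, K (25 C).
DEFAULT_TEMPERATURE = 298.15

#: Default probe radius, m (polystyrene beads used in the experiments).
DEFAULT_RADIUS = 1.95e-6


class ParameterError(ValueError):
    """A physical parameter is outside its domain (non-positive or non-finite)."""


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ParameterError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class FluidTrapParams:
    """Physical parameters of the fluid, probe and trap.

    Parameters
    ----------
    eta0 : float
        Solvent viscosity, Pa s.
    eta1 : float
        Polymer viscosity, Pa s.
    tau1 : float
        Stress-relaxation time of the Maxwell element, s.
    k : float
        Trap stiffness, N/m.
    radius : float
        Probe radius, m.  Drag coefficients follow Stokes' law
        ``gamma = 6 pi eta radius``.
    temperature : float
        Absolute temperature, K.
    """

    eta0: float
    eta1: float
    tau1: float
    k: float
    radius: float = DEFAULT_RADIUS
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        _require_positive(
            eta0=self.eta0,
            eta1=self.eta1,
            tau1=self.tau1,
            k=self.k,
            radius=self.radius,
            temperature=self.temperature,
        )

    # -- derived drags and noise amplitudes ---------------------------------

    @property
    def gamma0(self) -> float:
        """Solvent drag coefficient 6 pi eta0 a, N s/m."""
        return 6.0 * np.pi * self.eta0 * self.radius

    @property
    def gamma1(self) -> float:
        """Polymer drag coefficient 6 pi eta1 a, N s/m."""
        return 6.0 * np.pi * self.eta1 * self.radius

    @property
    def kBT(self) -> float:
        """Thermal energy, J."""
        return KB * self.temperature

    @property
    def D0(self) -> float:
        """Solvent noise amplitude sqrt(2 kB T / gamma0), m/sqrt(s)."""
        return np.sqrt(2.0 * self.kBT / self.gamma0)

    @property
    def D1(self) -> float:
        """Polymer noise amplitude sqrt(2 kB T / gamma1), m/sqrt(s)."""
        return np.sqrt(2.0 * self.kBT / self.gamma1)

    # -- model matrices ------------------------------------------------------

    def drift_matrix(self) -> np.ndarray:
        """Drift matrix ``lam`` of the embedded 2-state OU process, 1/s."""
        b = self.gamma1 / (self.gamma0 * self.tau1)
        return np.array(
            [
                [self.k / self.gamma0 + b, -b],
                [-1.0 / self.tau1, 1.0 / self.tau1],
            ]
        )

    def noise_matrix(self) -> np.ndarray:
        """Diagonal noise matrix ``D = diag(D0, D1)``, m/sqrt(s)."""
        return np.diag([self.D0, self.D1])

    def stationary_cov(self) -> np.ndarray:
        """Stationary covariance ``sigma`` of ``(x, X)``, m^2.

        The (x, x) element is the equipartition variance ``kB T / k``.
        """
        v = self.kBT / self.k
        return v * np.array(
            [[1.0, 1.0], [1.0, 1.0 + self.k * self.tau1 / self.gamma1]]
        )

    def replace(self, **changes) -> "FluidTrapParams":
        """Return a copy with some fields replaced."""
        fields = dict(
            eta0=self.eta0,
            eta1=self.eta1,
            tau1=self.tau1,
            k=self.k,
            radius=self.radius,
            temperature=self.temperature,
        )
        fields.update(changes)
        return FluidTrapParams(**fields)


def timescales(params: FluidTrapParams) -> tuple[float, float]:
    """Shortest and longest intrinsic time scales ``(tau_S, tau1)`` in seconds.

    ``tau_S = 1 / (k/gamma0 + gamma1/(gamma0 tau1))`` is the fast relaxation
    time of the process and sets the sampling requirement ``dt <~ tau_S``;
    the slowest memory scale is ``tau1`` itself.
    """
    tau_s = 1.0 / (
        params.k / params.gamma0 + params.gamma1 / (params.gamma0 * params.tau1)
    )
    return tau_s, params.tau1


def _drift_spectrum(lam: np.ndarray) -> tuple[float, float, float]:
    """Return (mu_slow, mu_fast, nu) for the 2x2 drift matrix.

    Both eigenvalues (c +- nu)/2 are real and positive for every valid
    parameter set: the discriminant equals (k/gamma0 - (1+eta1/eta0)/tau1)^2
    plus a positive remainder.
    """
    c = lam[0, 0] + lam[1, 1]
    det = lam[0, 0] * lam[1, 1] - lam[0, 1] * lam[1, 0]
    nu = np.sqrt(max(c * c - 4.0 * det, 0.0))
    return 0.5 * (c - nu), 0.5 * (c + nu), nu


def _expm_neg(lam: np.ndarray, dt: float) -> np.ndarray:
    """Numerically robust ``expm(-lam dt)`` for the 2x2 drift matrix.

    Uses the closed-form spectral formula when the eigenvalue gap resolves,
    and scipy's scaling-and-squaring near the degenerate point nu -> 0 where
    the spectral formula cancels catastrophically.
    """
    mu1, mu2, nu = _drift_spectrum(lam)
    if nu * dt < 1e-6:
        return expm(-lam * dt)
    eye = np.eye(2)
    return (
        np.exp(-mu1 * dt) * (mu2 * eye - lam) + np.exp(-mu2 * dt) * (lam - mu1 * eye)
    ) / nu


@dataclass(frozen=True)
class OUSystem:
    """Exact discrete-time representation of the embedded OU process at step ``dt``.

    Attributes
    ----------
    lam : (2, 2) ndarray
        Drift matrix, 1/s.
    sigma : (2, 2) ndarray
        Stationary covariance, m^2.
    Dmat : (2, 2) ndarray
        Diagonal noise matrix, m/sqrt(s); satisfies the stationarity
        (fluctuation-dissipation) identity ``lam sigma + (lam sigma)^T = D D^T``.
    dt : float
        Sampling step, s.
    F : (2, 2) ndarray
        One-step transition matrix ``expm(-lam dt)``.
    Sigma_dt : (2, 2) ndarray
        One-step noise covariance ``sigma - F sigma F^T``, m^2.
    """

    params: FluidTrapParams
    dt: float
    lam: np.ndarray
    sigma: np.ndarray
    Dmat: np.ndarray
    F: np.ndarray
    Sigma_dt: np.ndarray

    @property
    def eigenrates(self) -> tuple[float, float]:
        """Relaxation rates (slow, fast) of the drift matrix, 1/s."""
        mu1, mu2, _ = _drift_spectrum(self.lam)
        return mu1, mu2


def build_ou_system(params: FluidTrapParams, dt: float) -> OUSystem:
    """Assemble the exact AR(1) representation at sampling step ``dt``.

    ``dt = 0`` is allowed and yields ``F = I``, ``Sigma_dt = 0``.
    """
    if not np.isfinite(dt) or dt < 0:
        raise ParameterError(f"dt must be non-negative and finite, got {dt!r}")
    lam = params.drift_matrix()
    sigma = params.stationary_cov()
    Dmat = params.noise_matrix()
    F = _expm_neg(lam, dt)
    Sigma_dt = sigma - F @ sigma @ F.T
    # enforce exact symmetry against roundoff
    Sigma_dt = 0.5 * (Sigma_dt + Sigma_dt.T)
    return OUSystem(
        params=params, dt=dt, lam=lam, sigma=sigma, Dmat=Dmat, F=F, Sigma_dt=Sigma_dt
    )


@dataclass
class Trajectory:
    """A uniformly sampled probe trajectory.

    ``x`` holds positions in meters about the trap center.  ``hidden_X`` is
    the auxiliary state component; the simulator fills it for full-state
    self-tests but inference operations never consume it (they see the
    partial observation ``x`` only).
    """

    dt: float
    x: np.ndarray
    hidden_X: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.dt <= 0 or not np.isfinite(self.dt):
            raise ParameterError(f"dt must be positive, got {self.dt!r}")
        if self.hidden_X is not None:
            self.hidden_X = np.asarray(self.hidden_X, dtype=float)
            if self.hidden_X.shape != self.x.shape:
                raise ValueError("hidden_X must have the same length as x")

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def duration(self) -> float:
        """Total sampling time, s."""
        return self.n * self.dt
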