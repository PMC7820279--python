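import numpy as np
import pytest
from hypothesis import settings

import viscotrap as vt

settings.register_profile("suite", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_params():
    """The numerical-study input set: 1 mPa s solvent, 100 mPa s polymer,
    1 s relaxation time, 0.1 uN/m trap, 1.95 um bead at 25 C."""
    return vt.STUDY_INPUT_PARAMS


@pytest.fixture(scope="session")
def tau_s(study_params):
    return vt.timescales(study_params)[0]


@pytest.fixture(scope="session")
def fast_params():
    """A parameter set with short correlation times (slow relaxation ~0.1 s),
    convenient for distributional tests that need many effectively
    independent samples."""
    return vt.FluidTrapParams(eta0=1e-3, eta1=5e-3, tau1=0.05, k=1e-6, radius=1e-6)


@pytest.fixture(scope="session")
def medium_traj(study_params, tau_s):
    """A mid-sized trajectory at the study conditions (Ts ~ 195 s)."""
    cfg = vt.SimConfig(params=study_params, dt=tau_s, n_samples=20000, seed=12345)
    return vt.simulate_trajectory(cfg)


def integrated_corr_time(params):
    """tau_int = integral of rho(t)^2 dt from the closed-form two-exponential
    ACF; used to inflate variance standard errors on correlated series."""
    f0 = vt.model_acf(params, 0.0)
    mu1, mu2 = vt.build_ou_system(params, 0.0).eigenrates
    w1 = vt.model_acf(params, np.array([0.0]))  # placeholder; exact below
    # weights from two model evaluations
    t1, t2 = 0.5 / mu2, 5.0 / mu2
    # solve w1, w2 from values at two lags (exact since 2-exponential)
    import numpy.linalg as la

    A = np.array(
        [
            [np.exp(-mu1 * t1), np.exp(-mu2 * t1)],
            [np.exp(-mu1 * t2), np.exp(-mu2 * t2)],
        ]
    )
    vals = vt.model_acf(params, np.array([t1, t2]))
    w = la.solve(A, vals) / f0
    return w[0] ** 2 / (2 * mu1) + 2 * w[0] * w[1] / (mu1 + mu2) + w[1] ** 2 / (2 * mu2)
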