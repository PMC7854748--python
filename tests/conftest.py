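import numpy as np
import pytest

import pfefit as pf


@pytest.fixture(scope="session")
def wt_rates() -> pf.RateConstants:
    """Wild-type pH 7 rate constants (k_react at the oxidative potential)."""
    return pf.WT_PH7


@pytest.fixture(scope="session")
def step_protocol() -> pf.Protocol:
    """The reference step program: -0.31/-0.21 V alternation, 50 s holds, 3 cycles."""
    return pf.make_step_protocol()


@pytest.fixture(scope="session")
def wt_truth(wt_rates) -> dict:
    """Per-potential ground truth: the tabulated k_react at the oxidative step,
    reactivation one decade faster at the 100 mV more reductive step."""
    return {-0.31: wt_rates.with_k_react(wt_rates.k_react * 10), -0.21: wt_rates}


@pytest.fixture(scope="session")
def wt_noisy_trace(step_protocol, wt_truth) -> pf.Trace:
    trace, _ = pf.generate_chronoamperogram(
        step_protocol, wt_truth, noise=pf.NoiseSpec(relative_sd=0.01, seed=1234)
    )
    return trace


@pytest.fixture(scope="session")
def wt_noiseless_trace(step_protocol, wt_truth) -> pf.Trace:
    trace, _ = pf.generate_chronoamperogram(
        step_protocol, wt_truth, noise=pf.NoiseSpec(relative_sd=0.0, seed=0)
    )
    return trace


def rk4_propagate(generator: np.ndarray, p0: np.ndarray, dt: float, h: float) -> np.ndarray:
    """Independent fixed-step 4th-order Runge-Kutta master-equation integrator."""
    n = max(1, int(np.ceil(dt / h)))
    h = dt / n
    y = np.asarray(p0, dtype=float).copy()
    for _ in range(n):
        k1 = generator @ y
        k2 = generator @ (y + 0.5 * h * k1)
        k3 = generator @ (y + 0.5 * h * k2)
        k4 = generator @ (y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return y
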