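import numpy as np
import pytest

from kymoflow import SyntheticScenario, recover_scenario, simulate_pde
from kymoflow.containers import Kymograph, TimeWindow
from kymoflow.kymograph import normalize, subtract_background

# study conditions for the parameter-recovery grid: velocities and diffusion
# coefficients spanning the physiological range, 1% additive noise
RECOVERY_V = (0.05, 0.2, 0.4, 0.6)
RECOVERY_K = (0.1, 0.4)
RECOVERY_SEED = 42


def field_kymograph(scenario: SyntheticScenario, factor: int = 20) -> Kymograph:
    """Kymograph built straight from the simulated concentration field.

    Block-averages the fine simulation grid onto the analysis grid
    (factor 20 → Δr = 2.05 µm) and uses the whole simulated duration as the
    analysis window; isolates the gradient regression from window detection
    and rendering.
    """
    field = simulate_pde(scenario)
    n_blocks = len(field.r) // factor
    values = (
        field.phi[:, : n_blocks * factor]
        .reshape(len(field.t), n_blocks, factor)
        .mean(axis=2)
        .T
    )
    kymo = Kymograph(
        values=values,
        dr=scenario.dr_sim * factor,
        dt=float(field.t[1] - field.t[0]),
        window=TimeWindow(0.0, float(field.t[-1])),
    )
    kymo = subtract_background(kymo)
    return normalize(kymo)


@pytest.fixture(scope="session")
def recovery_grid():
    """Full-pipeline recoveries over the (v, k) grid with 1% noise."""
    out = {}
    for v in RECOVERY_V:
        for k in RECOVERY_K:
            sc = SyntheticScenario(v=v, k=k, noise_sd=0.01, seed=RECOVERY_SEED)
            out[(v, k)] = recover_scenario(sc)
    return out


@pytest.fixture(scope="session")
def recovery_grid_noiseless():
    out = {}
    for v in RECOVERY_V:
        for k in RECOVERY_K:
            sc = SyntheticScenario(v=v, k=k, noise_sd=0.0)
            out[(v, k)] = recover_scenario(sc)
    return out


@pytest.fixture(scope="session")
def pressure_series():
    """Recoveries for an increasing-velocity series (synthetic pressure ramp)."""
    out = {}
    for v in (0.1, 0.2, 0.4, 0.6):
        sc = SyntheticScenario(v=v, k=0.3, noise_sd=0.01, seed=7)
        out[v] = recover_scenario(sc)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(0)
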