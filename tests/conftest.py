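import warnings

import numpy as np
import pytest

from assrmix.scenario import ScenarioConfig, simulate_scenario

# The quick-profile sampling rate under-resolves the electrode-interface
# transient by design; the warning is exercised explicitly in test_cochlea.
warnings.filterwarnings(
    "ignore", message="sampling rate is low relative to the interface pole"
)

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:
    pass


@pytest.fixture(scope="session")
def default_sim():
    """One default-scenario simulation (20 kHz, 10 s) shared across tests."""
    return simulate_scenario(ScenarioConfig(), seed=1)


@pytest.fixture(scope="session")
def bench_result():
    """The scaled-down in-silico benchmark: 10 seeds x 3 depths x 4 algorithms.

    16 s mixtures (~29 averaging epochs per amplitude estimate) are the
    shortest at which the separation noise of the weaker algorithms stops
    masking the modulation-depth effect, while keeping the full pipeline
    (simulation, four ICA decompositions, rejection, scoring) within the
    suite's runtime budget.
    """
    from assrmix.icabench import benchmark

    cfg = ScenarioConfig(duration_s=16.0)
    return benchmark(cfg, n_sims=10, md_values=(1.0, 0.75, 0.2))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
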