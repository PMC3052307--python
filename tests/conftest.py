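import numpy as np
import pytest

from ubilys import SimulationParams, benchmark_params, simulate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset():
    """A quick synthetic proteome for cross-module smoke tests."""
    params = SimulationParams(n_proteins=40, length_range=(60, 100))
    return simulate(params, seed=7)


@pytest.fixture(scope="session")
def distant_signal_dataset():
    """Benchmark-scale proteome with signal planted only beyond ±5."""
    return simulate(benchmark_params("distant"), seed=101)
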