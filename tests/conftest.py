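import numpy as np
import pytest

from rcatseq.pipeline import run_end_benchmark

BENCH_SEED = 1


@pytest.fixture(scope="session")
def benchmark():
    """Full default-scale synthetic benchmark (shared across tests)."""
    return run_end_benchmark(seed=BENCH_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
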