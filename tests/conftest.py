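import numpy as np
import pytest

from nbel.experiment import benchmark_replicate, derive_seed, run_benchmark

BENCH_SEED = 101
N_REPLICATES = 10


@pytest.fixture(scope="session")
def benchmark_cells():
    """Scaled-down contamination benchmark shared across slow tests.

    Levels 0 (clean), 3 (~27% induced error) and 5 (>70%), ten replicates
    each at n=1000 pairs / 250 interacting / p=4, short chains (600 sweeps,
    100 burn-in).
    """
    return run_benchmark([0, 3, 5], N_REPLICATES, global_seed=BENCH_SEED)


@pytest.fixture(scope="session")
def level5_fixed_nu():
    """Level-5 replicates rerun with nu pinned at the true proportion 0.25."""
    errs = [
        benchmark_replicate(
            5, derive_seed(BENCH_SEED, 2, r), nu_fixed=0.25, methods=("nbel",)
        )["reports"]["nbel"].misclassification
        for r in range(N_REPLICATES)
    ]
    return float(np.mean(errs))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
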