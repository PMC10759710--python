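import numpy as np
import pytest

from parityclock import GammaRates, ParityProblem, sample_rates, simulate_counts


@pytest.fixture
def rng():
    return np.random.default_rng(20240102)


@pytest.fixture
def small_problem(rng):
    """100-site problem simulated from the mtDNA-like Gamma rate profile."""
    lam = sample_rates(GammaRates(), 100, rng)
    return simulate_counts(lam, 0.05, rng)


@pytest.fixture
def large_problem():
    """Transversion-free mtDNA-scale problem at a known distance."""
    rng = np.random.default_rng(7)
    lam = sample_rates(GammaRates(), 15629, rng)
    return simulate_counts(lam, 0.05, rng), lam, 0.05


@pytest.fixture
def tiny_problem():
    return ParityProblem(counts=[2, 1], parity=[0, 1])
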