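import numpy as np
import pytest

from templink import LocusPanel, SimConfig, TemporalDesign


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def design():
    """Sampling design of the first simulation-study regime."""
    return TemporalDesign(s0=50, st=50, t=10)


@pytest.fixture
def small_panel():
    return LocusPanel(
        chrom=np.array(["1", "1", "1", "2"]),
        pos=np.array([100, 1500, 2500, 300]),
        x0=np.array([0.5, 0.2, 0.4, 0.3]),
        xt=np.array([0.6, 0.3, 0.35, 0.3]),
    )


@pytest.fixture(scope="session")
def tiny_sim():
    """A small, fast chromosome simulation shared across tests."""
    from templink import simulate_chromosome

    cfg = SimConfig(
        ne=200, length_bp=20_000, k_target=60, k_init=200, burn_in=80, t=10, s0=30,
        st=30, initialization="forward",
    )
    return simulate_chromosome(cfg, rng=np.random.default_rng(777))
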