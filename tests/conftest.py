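import pytest

from polyfam.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A compact noisy genome shared by read-only tests."""
    return simulate(SimConfig(seed=7, n_groups=42))


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free limit: no copy loss, no expansion, no motif ablation."""
    return simulate(
        SimConfig(
            seed=5,
            n_groups=42,
            p_loss=0.0,
            p_tandem=0.0,
            p_proximal=0.0,
            p_dispersed=0.0,
            n_singletons=0,
            p_nc=0.0,
        )
    )
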