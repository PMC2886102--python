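import numpy as np
import pytest

from soaesim import ChainConfig, AlphaProfileSpec, simulate


@pytest.fixture(scope="session")
def short_uniform_chain():
    """Small elastically coupled chain, short record — shared cheap trace."""
    cfg = ChainConfig(N=30, gamma=1.0, seed=5,
                      t_total=480.0, t_equilibrate=160.0)
    return simulate(cfg)


@pytest.fixture(scope="session")
def single_unit_trace():
    """Two uncoupled units (unit 1 at 1 kHz, alpha = 1), 400-ms record."""
    cfg = ChainConfig(N=2, alpha_profile=AlphaProfileSpec(kind="uniform"),
                      seed=3, t_total=560.0, t_equilibrate=160.0)
    return simulate(cfg)


def pair_config(beta=0.0, gamma=0.0, t_total=1160.0, seed=0):
    """Two near-identical oscillators (frequency mismatch ~1e-9)."""
    return ChainConfig(N=2, freq_exponent_denominator=10**9, beta=beta,
                       gamma=gamma, seed=seed, t_total=t_total,
                       t_equilibrate=0.0, sample_interval=0.016)
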