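"""Shared fixtures: small networks and cached full-size builds/simulations."""

import functools
import warnings

import numpy as np
import pytest

import anisonet as an
from anisonet.dynamics import NoiseInput, simulate

warnings.filterwarnings("ignore", category=FutureWarning)

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50,
                              deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def toy_inet():
    """Small inhibitory net for structural unit tests (20x20, 40 conns)."""
    return an.build_I_network(nrow=20, ncol=20, n_conn=40,
                              configuration="perlin", perlin_scale=10, seed=7)


@pytest.fixture(scope="session")
def toy_ei():
    """Small EI net (24x24 / 12x12) with proportionally scaled profiles."""
    return an.build_EI_network(nrow_E=24, ncol_E=24, nrow_I=12, ncol_I=12,
                               sigma_EE=3.0, sigma_EI=1.5, sigma_IE=4.0,
                               sigma_II=2.0, configuration="perlin",
                               perlin_scale=6, seed=7)


@functools.lru_cache(maxsize=None)
def full_network(model: str, configuration: str, shift: int = 1,
                 perlin_scale: int = 20, seed: int = 1):
    """Full published-size network, cached across the session."""
    if model == "I":
        return an.build_I_network(configuration=configuration, shift=shift,
                                  perlin_scale=perlin_scale, seed=seed)
    return an.build_EI_network(configuration=configuration, shift=shift,
                               perlin_scale=perlin_scale, seed=seed)


@functools.lru_cache(maxsize=8)
def full_sim(model: str, configuration: str, shift: int = 1,
             perlin_scale: int = 20, seed: int = 1, duration_ms: float = 2200.0):
    """Cached simulation of a full network under its default drive."""
    net = full_network(model, configuration, shift, perlin_scale, seed)
    mu = 700.0 if model == "I" else 350.0
    return net, simulate(net, noise=NoiseInput(mu, 100.0),
                         duration_ms=duration_ms, seed=seed)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
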