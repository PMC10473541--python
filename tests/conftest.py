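"""Shared fixtures: small synthetic networks generated at test time."""

import numpy as np
import pytest

from grnattract import (EvolutionConfig, NetworkArchitecture,
                        generate_attractor_profiles, generate_reference_grn)
from grnattract.benchmark import default_kinetics


@pytest.fixture(scope="session")
def small_reference():
    """Deterministic 3-gene multistable reference: (anet, params)."""
    rng = np.random.default_rng(5)
    return generate_reference_grn(3, min_attractors=3, rng=rng)


@pytest.fixture(scope="session")
def small_profiles(small_reference):
    """Noiseless attractor profiles of the 3-gene reference."""
    anet, params = small_reference
    return generate_attractor_profiles(anet, params, noise_sd=0.0,
                                       rng=np.random.default_rng(11))


@pytest.fixture(scope="session")
def bistable_gene():
    """1-gene independent self-activator with low basal expression:
    a textbook bistable switch."""
    params = default_kinetics(1).with_estimates(f0=[0.05], k=[6.0])
    anet = NetworkArchitecture([[1]])
    return anet, params


@pytest.fixture
def quick_config():
    """Small evolutionary settings for fast unit-level checks."""
    return EvolutionConfig(population_size=10, generations=20, n_runs=2)
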