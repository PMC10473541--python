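"""Seed-regenerated synthetic reference fixtures.

A bundle of five reference networks at 5–9 genes, each with at least nine
fixed-point attractors and no oscillatory grid starts, mirroring the scale
of the validation networks the method was designed around.  Nothing is
shipped on disk: every fixture is regenerated deterministically from its
seed, so the bundle doubles as a reproducibility check.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .benchmark import generate_attractor_profiles, generate_reference_grn

__all__ = ["reference_network", "reference_profiles", "REFERENCE_SIZES"]

REFERENCE_SIZES = (5, 6, 7, 8, 9)

#: per-size base seeds for the shipped fixture bundle (arbitrary, fixed)
_FIXTURE_SEEDS = {5: 105, 6: 106, 7: 107, 8: 108, 9: 109}


@lru_cache(maxsize=None)
def reference_network(n_genes: int, seed: int | None = None,
                      min_attractors: int = 9):
    """The fixture reference network of the given size: ``(anet, params)``.

    With ``seed=None`` the bundled per-size seed is used, making the
    returned network part of the package's fixed fixture bundle.
    """
    if seed is None:
        if n_genes not in _FIXTURE_SEEDS:
            raise ValueError(f"no bundled fixture for {n_genes} genes; pass a seed")
        seed = _FIXTURE_SEEDS[n_genes]
    rng = np.random.default_rng(seed)
    return generate_reference_grn(n_genes, min_attractors=min_attractors, rng=rng)


@lru_cache(maxsize=None)
def reference_profiles(n_genes: int, noise_sd: float = 0.2,
                       seed: int | None = None, min_attractors: int = 9):
    """Noisy attractor profiles of the fixture network of the given size.

    Gaussian noise (sd on the per-gene-max scale, default 0.2) is applied
    with a seed derived from the network seed, so repeated calls return the
    same profile set.
    """
    anet, params = reference_network(n_genes, seed, min_attractors)
    noise_seed = (seed if seed is not None else _FIXTURE_SEEDS[n_genes]) + 7919
    rng = np.random.default_rng(noise_seed)
    return generate_attractor_profiles(anet, params, noise_sd=noise_sd, rng=rng)
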