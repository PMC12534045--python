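"""Shared fixtures for the obsim test suite."""

import numpy as np
import pytest
from hypothesis import settings

from obsim import ModelParams, SynapseMatrix, default_params

# Derandomized hypothesis profile so CI failures are reproducible.
settings.register_profile("ci", derandomize=True, deadline=None,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def params():
    """Full default parameters (225 MCs, 900 initial GCs)."""
    return default_params()


@pytest.fixture
def micro_params():
    """A very small network for fast simulation-loop tests."""
    return ModelParams(n_mc=60, n_gc_init=120, n_add=2, n_conn=12, n_init=4,
                      n_shuffles=200)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_synapses(rng):
    """A 6-MC / 8-GC synapse matrix with 4-site fields, 2 consolidated."""
    n_mc, n_gc = 6, 8
    mask = np.zeros((n_mc, n_gc), dtype=bool)
    state = np.zeros((n_mc, n_gc), dtype=np.int8)
    for j in range(n_gc):
        fld = rng.choice(n_mc, size=4, replace=False)
        mask[fld, j] = True
        state[rng.choice(fld, size=2, replace=False), j] = 2
    return SynapseMatrix(mask, state)
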