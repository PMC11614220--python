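"""Shared fixtures: networks, constraint sets, and one sampled mode set."""

from __future__ import annotations

import pytest

from stromaefm import (
    FluxMode,
    compress,
    decompress,
    default_constraint_set,
    generate_toy_network,
    sample_constrained_efms,
    synthetic_core_network,
    synthetic_stroma_network,
    table1_constants,
    translate_constraints,
)
from stromaefm.synthetic_data import DEFAULT_EXCHANGE_ALIASES


@pytest.fixture(scope="session")
def aliases():
    return dict(DEFAULT_EXCHANGE_ALIASES)


@pytest.fixture(scope="session")
def table():
    return table1_constants()


@pytest.fixture(scope="session")
def core_net():
    return synthetic_core_network()


@pytest.fixture(scope="session")
def stroma_net():
    return synthetic_stroma_network()


@pytest.fixture(scope="session")
def constraint_set(stroma_net, table, aliases):
    return default_constraint_set(table, stroma_net, aliases=aliases)


@pytest.fixture(scope="session")
def compressed(stroma_net):
    return compress(stroma_net)


@pytest.fixture(scope="session")
def sampled_modes(stroma_net, constraint_set, compressed):
    """~30 constrained EFMs of the stand-in model (compressed sampling)."""
    comp, cmap = compressed
    ccs = translate_constraints(constraint_set, cmap)
    raw = sample_constrained_efms(comp, ccs, n=30, seed=11, time_limit=240)
    modes = [
        FluxMode(
            {k: v for k, v in decompress(m.vector, cmap).items() if v != 0.0}
        ).normalized()
        for m in raw
    ]
    assert len(modes) >= 10, "sampler produced too few modes for the suite"
    return modes


@pytest.fixture
def diamond():
    return generate_toy_network("diamond")


@pytest.fixture
def chain():
    return generate_toy_network("chain", size=6)
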