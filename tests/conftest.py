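"""Shared fixtures: reduced morphologies and channel sets.

Everything is generated programmatically; no data files are read from disk
except the packaged default channel-parameter file.
"""

import pytest

from pcseq.channels import ChannelSet, ChannelSpec, load_channel_set
from pcseq.morphology import (Compartment, CType, Morphology, Passive,
                              ReducedSpec, generate_reduced)


@pytest.fixture(scope="session")
def channel_set():
    return load_channel_set()


@pytest.fixture()
def linear11():
    """The canonical 11-compartment chain: soma, 2 main, 3 smooth, 5 spiny."""
    return generate_reduced(ReducedSpec(n_main=2, n_smooth=3, n_spiny=5))


@pytest.fixture()
def reduced_default():
    """The default reduced tree used by the scaled-down experiments."""
    return generate_reduced()


def leak_only_set(g_leak: float = 0.1, e_rev: float = -80.0) -> ChannelSet:
    """A channel set with only a (possibly zero) leak conductance."""
    g = {ct: g_leak for ct in CType}
    return ChannelSet([ChannelSpec(name="Leak", e_rev=e_rev, g_max=g)])


def uniform_chain(n: int, length: float = 20.0, radius: float = 2.0,
                  passive: Passive | None = None) -> Morphology:
    """An unbranched uniform cable of n compartments (root labeled soma)."""
    comps = [Compartment(1, None, CType.SOMA, length, radius)]
    for i in range(2, n + 1):
        comps.append(Compartment(i, i - 1, CType.SPINY, length, radius))
    return Morphology(comps, passive or Passive(spine_factor=1.0))
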