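"""Shared fixtures.

The synthetic community (9 species, 5 target + 24 non-target genomes,
planted clade-unique marker plus a ~36%-identity homolog in one non-target
species) is generated once per session; tests needing replicate communities
generate their own with explicit seeds.
"""

from __future__ import annotations

import random

import pytest

from panmarker.simulate import generate_community, scaled_spec


@pytest.fixture(scope="session")
def community():
    """(GenomeSet, GroundTruth) for one scaled synthetic community."""
    return generate_community(scaled_spec(seed=0))


@pytest.fixture()
def rng():
    return random.Random(12345)
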