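"""Shared synthetic fixtures: a desk-scale two-fold (helix vs hairpin) system."""

from __future__ import annotations

import numpy as np
import pytest

import foldswitch as fs
from foldswitch.structures import fixture_sequence

FIXTURE_LENGTH = 12


@pytest.fixture(scope="session")
def helix_conformers():
    return fs.generate_fixture_set(fs.FixtureSpec(
        length=FIXTURE_LENGTH, topology="helix-bundle", n_conformers=2,
        jitter_sd=0.1, seed=1))


@pytest.fixture(scope="session")
def hairpin_conformers():
    return fs.generate_fixture_set(fs.FixtureSpec(
        length=FIXTURE_LENGTH, topology="hairpin-sheet", n_conformers=2,
        jitter_sd=0.1, seed=2))


@pytest.fixture(scope="session")
def map_A(helix_conformers):
    return fs.consensus_map(helix_conformers, fold_label="A")


@pytest.fixture(scope="session")
def map_B(hairpin_conformers):
    return fs.consensus_map(hairpin_conformers, fold_label="B")


@pytest.fixture(scope="session")
def fixture_seq():
    return fixture_sequence(FIXTURE_LENGTH)


@pytest.fixture(scope="session")
def empty_map():
    from foldswitch.contacts import ConsensusMap
    return ConsensusMap(fold_label="empty", contacts=[], n_conformers=1,
                        length=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
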