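"""Shared fixtures: deterministic RNGs, fixture consensuses, small genomes."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mitedyn.core_io import GenomeAssembly
from mitedyn.kmer import decode
from mitedyn.synthetic_data import (
    mariam_like_consensuses,
    random_sequence,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def mariam_pair():
    """Fixture subfamily consensus pair (300 bp / 291 bp, shared ends)."""
    return mariam_like_consensuses(np.random.default_rng(7))


@pytest.fixture
def small_genome(rng):
    """100-kb single-chromosome assembly of random sequence."""
    return GenomeAssembly("SP", {"A1": decode(random_sequence(rng, 100_000))})


def plant(seq: str, pos: int, insert: str, tsd_len: int = 0) -> str:
    """Insert ``insert`` at ``pos`` duplicating the preceding tsd_len bases."""
    return seq[:pos] + insert + seq[pos - tsd_len : pos] + seq[pos:]
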