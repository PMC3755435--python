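"""Shared fixtures: small seeded databases and indexes."""

import pytest

from openpepid import (
    DigestionParams, build_index, generate_synthetic_fasta,
)


@pytest.fixture(scope="session")
def small_proteins():
    """Ten seeded random proteins, 60-150 residues."""
    return generate_synthetic_fasta(10, 60, 150, seed=42)


@pytest.fixture(scope="session")
def small_index(small_proteins):
    return build_index(small_proteins, DigestionParams())


@pytest.fixture()
def default_params():
    return DigestionParams()
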