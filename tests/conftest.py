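"""Shared fixtures: small deterministic synthetic datasets and toy tables."""

from __future__ import annotations

import numpy as np
import pytest

from leafendo.synthetic import SyntheticSpec, generate_dataset
from leafendo.tables import CountTable, SampleMetadata


def make_table(counts, kingdom="unspecified", prefix="t", sample_prefix="s"):
    counts = np.asarray(counts)
    taxa = tuple(f"{prefix}{i}" for i in range(counts.shape[0]))
    samples = tuple(f"{sample_prefix}{j}" for j in range(counts.shape[1]))
    return CountTable(taxa, samples, counts, kingdom)


@pytest.fixture(scope="session")
def small_dataset():
    """120 taxa x (10+10) samples with 8 differential taxa and 2 blocks."""
    spec = SyntheticSpec(
        n_taxa=120,
        n_samples_per_group=10,
        reads_per_sample=(2000, 8000),
        n_differential=8,
        n_corr_blocks=2,
        block_size=6,
        seed=42,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def two_group_meta():
    return SampleMetadata(
        {f"HL{i:02d}": "HL" for i in range(1, 11)}
        | {f"NL{i:02d}": "NL" for i in range(1, 11)}
    )
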