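"""Shared fixtures: schemas, small FASTA files, and a trained final model.

The expensive session-scoped fixtures (the 100-sequence synthetic training
table and the 1500-tree final model fitted on it) are built once and shared
across the ranking and acceptance tests.
"""

from pathlib import Path

import pytest

from depp import (
    GroupSchema,
    generate_positive_like_set,
    synthetic_training_table,
    train_final_model,
)

TABLE_SEED = 7


@pytest.fixture(scope="session")
def schema() -> GroupSchema:
    return GroupSchema.default()


@pytest.fixture
def fasta_factory(tmp_path: Path):
    """Write a FASTA file from (header, sequence) pairs; returns its path."""

    def _write(entries, name="input.faa") -> Path:
        path = tmp_path / name
        with open(path, "w") as out:
            for header, seq in entries:
                out.write(f">{header}\n{seq}\n")
        return path

    return _write


@pytest.fixture(scope="session")
def synth_table():
    """The bundled synthetic study condition: 50 positive-like + 50 negatives."""
    return synthetic_training_table(seed=TABLE_SEED)


@pytest.fixture(scope="session")
def training_positives():
    """The positive-like records underlying ``synth_table`` (same seed)."""
    return generate_positive_like_set(50, seed=TABLE_SEED)


@pytest.fixture(scope="session")
def final_model(synth_table):
    """The shipped final RF configuration fitted on the synthetic table."""
    return train_final_model(synth_table)
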