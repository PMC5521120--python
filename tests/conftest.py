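"""Shared fixtures: small synthetic datasets and featurized matrices."""

from __future__ import annotations

import numpy as np
import pytest

from afseq import (
    FeaturizeConfig,
    SyntheticSpec,
    featurize,
    generate,
)
from afseq.seq_io import LabeledDataset, SequenceRecord


@pytest.fixture(scope="session")
def tiny_dataset() -> LabeledDataset:
    """Ten short sequences per class with a strong G/H/R composition shift."""
    spec = SyntheticSpec(n_per_class=10, length_range=(40, 80), seed=11)
    return generate(spec)


@pytest.fixture(scope="session")
def tiny_matrix(tiny_dataset):
    """0D+1D descriptors of the tiny dataset (one index to stay small)."""
    cfg = FeaturizeConfig(indices=("HP", "Z1"))
    return featurize(tiny_dataset, cfg)


@pytest.fixture(scope="session")
def study_dataset() -> LabeledDataset:
    """The study conditions: 100 sequences/class, 3x G/H/R positive-class
    frequency boost, generator defaults otherwise."""
    return generate(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def study_matrix(study_dataset):
    """Full 0D+1D descriptor matrix of the study dataset (shared because
    featurization is the most expensive step of the end-to-end tests)."""
    return featurize(study_dataset, FeaturizeConfig(vicinity=("NO", "ES")))


def make_records(*sequences: str) -> list[SequenceRecord]:
    return [SequenceRecord(id=f"s{i}", sequence=s) for i, s in enumerate(sequences)]
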