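"""Shared fixtures: similarity measures, toy datasets and the standard
synthetic benchmark (computed once per session — the heavy leave-one-out and
split protocols are reused across tests)."""

from __future__ import annotations

import numpy as np
import pytest

from paas import (
    LabeledDataset,
    Sequence,
    SimilarityMeasure,
    SyntheticSpec,
    generate_dataset,
    loo_cross_validate,
    multi_split_validate,
    train,
)

BENCHMARK_FRAME = 25
MULTISPLIT_SEED = 0


@pytest.fixture(scope="session")
def identity_measure() -> SimilarityMeasure:
    return SimilarityMeasure.identity()


@pytest.fixture(scope="session")
def blosum_measure() -> SimilarityMeasure:
    return SimilarityMeasure.blosum62_normalized()


@pytest.fixture(scope="session")
def raw_measure() -> SimilarityMeasure:
    return SimilarityMeasure.raw()


@pytest.fixture(scope="session")
def benchmark():
    """The package's standard benchmark: 5 motif classes x 20 sequences,
    motif length 12, mutation rate 0.1, lengths 80-300, one null class."""
    spec = SyntheticSpec()
    dataset, truth = generate_dataset(spec)
    return spec, dataset, truth


@pytest.fixture(scope="session")
def benchmark_loo25(benchmark):
    _, dataset, _ = benchmark
    return loo_cross_validate(dataset, frames=[BENCHMARK_FRAME])


@pytest.fixture(scope="session")
def benchmark_split(benchmark):
    _, dataset, _ = benchmark
    return multi_split_validate(
        dataset, F=BENCHMARK_FRAME, repeats=20, train_fraction=2 / 3,
        seed=MULTISPLIT_SEED,
    )


@pytest.fixture(scope="session")
def benchmark_model(benchmark):
    _, dataset, _ = benchmark
    return train(dataset, F=BENCHMARK_FRAME, min_class_size=10)


@pytest.fixture(scope="session")
def two_family_dataset():
    """Two disjoint, well-separated motif families (noise-free, small)."""
    spec = SyntheticSpec(
        n_classes=2, sequences_per_class=6, motif_length=(10, 10),
        sequence_length=(40, 80), mutation_rate=0.0, null_classes=0, seed=11,
    )
    dataset, _ = generate_dataset(spec)
    return dataset


def planted_classes(report_classes) -> list[str]:
    return [c for c in report_classes if c.startswith("C")]


def null_classes(report_classes) -> list[str]:
    return [c for c in report_classes if c.startswith("R")]
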