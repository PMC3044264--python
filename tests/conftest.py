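"""Shared fixtures: toy datasets, random dataset factory, simulated data."""

from __future__ import annotations

import numpy as np
import pytest

from epifilter import (
    GenotypeDataset,
    SimulationConfig,
    make_penetrance_model,
    model_config,
    simulate_dataset,
)


@pytest.fixture
def toy_dataset() -> GenotypeDataset:
    """4 samples, 2 SNPs; hand-traceable ReliefF gives W = (+1, -1) at K=1."""
    return GenotypeDataset(
        genotypes=np.array([[0, 0], [0, 1], [2, 0], [2, 1]]),
        labels=np.array([1, 1, 0, 0]),
        snp_names=("SNP1", "SNP2"),
    )


def random_dataset(
    rng: np.random.Generator,
    m: int | None = None,
    n: int | None = None,
    min_per_class: int = 2,
) -> GenotypeDataset:
    """Random valid dataset with at least ``min_per_class`` per class."""
    if m is None:
        m = int(rng.integers(2 * min_per_class, 13))
    if n is None:
        n = int(rng.integers(1, 5))
    genotypes = rng.integers(0, 3, size=(m, n))
    labels = np.zeros(m, dtype=int)
    labels[: m // 2] = 1
    rng.shuffle(labels)
    while labels.sum() < min_per_class or (m - labels.sum()) < min_per_class:
        labels = rng.integers(0, 2, size=m)
    return GenotypeDataset(
        genotypes=genotypes,
        labels=labels,
        snp_names=tuple(f"X{j}" for j in range(n)),
    )


@pytest.fixture(scope="session")
def sim_400() -> GenotypeDataset:
    """One benchmark dataset: 1000 SNPs, 200 cases / 200 controls, h2 = 0.1."""
    cfg = model_config("Epistatic_400_0.1", seed=1)
    model = make_penetrance_model(cfg.h2, cfg.maf, cfg.prevalence, seed=2)
    return simulate_dataset(cfg, model, seed=3)


@pytest.fixture(scope="session")
def sim_small() -> GenotypeDataset:
    """Small simulated dataset (60 samples, 60 SNPs) for fast k-NN tests."""
    cfg = SimulationConfig(n_snps=60, n_cases=30, n_controls=30, h2=0.2)
    model = make_penetrance_model(cfg.h2, cfg.maf, cfg.prevalence, seed=4)
    return simulate_dataset(cfg, model, seed=5)
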