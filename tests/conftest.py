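import numpy as np
import pandas as pd
import pytest

from wssgwas.pedigree import Pedigree
from wssgwas.qc import apply_qc
from wssgwas.simulate import SimulationConfig, simulate_dataset


def trio_pedigree() -> Pedigree:
    """Sire, dam, one offspring."""
    return Pedigree(["s", "d", "o"], np.array([-1, -1, 0]), np.array([-1, -1, 1]))


def full_sib_pedigree() -> Pedigree:
    return Pedigree(
        ["s", "d", "o1", "o2"],
        np.array([-1, -1, 0, 0]),
        np.array([-1, -1, 1, 1]),
    )


def random_pedigree(n: int, seed: int, n_founders: int | None = None) -> Pedigree:
    """Random-mating pedigree for property tests."""
    rng = np.random.default_rng(seed)
    n_founders = n_founders or max(2, n // 4)
    animals = [f"a{i}" for i in range(n)]
    sire = np.full(n, -1)
    dam = np.full(n, -1)
    for i in range(n_founders, n):
        sire[i], dam[i] = sorted(rng.choice(i, size=2, replace=False))
    return Pedigree(animals, sire, dam)


@pytest.fixture(scope="session")
def small_dataset():
    """One modest simulation shared by read-only tests."""
    cfg = SimulationConfig(
        seed=11,
        n_founders=60,
        n_generations=2,
        n_animals_target=200,
        n_snps=600,
        n_chromosomes=3,
        chrom_length_bp=8_000_000,
        prop_genotyped=0.7,
        prop_phenotyped=0.7,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_qc_panel(small_dataset):
    panel, report = apply_qc(small_dataset.panel)
    return panel
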