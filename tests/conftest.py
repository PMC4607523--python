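from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sweepscan.matrix import HaplotypeMatrix
from sweepscan.synthetic import DemographyModel, SimulationParams, simulate_neutral


def make_matrix(
    alleles,
    positions=None,
    population: str = "pop0",
    polarized: bool = True,
) -> HaplotypeMatrix:
    """Build a HaplotypeMatrix from a plain 0/1 array (one pop, all phased)."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n_hap, n_sites = alleles.shape
    assert n_hap % 2 == 0
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10
    return HaplotypeMatrix(
        alleles=alleles,
        positions=np.asarray(positions),
        samples=[f"s{i}" for i in range(n_hap // 2)],
        populations=[population] * (n_hap // 2),
        polarized=np.full(n_sites, polarized),
    )


def random_matrix(rng, n_hap=None, n_sites=None) -> HaplotypeMatrix:
    """Random small polarized matrix (n <= 12, S <= 50) for oracle checks."""
    if n_hap is None:
        n_hap = int(rng.integers(2, 7)) * 2
    if n_sites is None:
        n_sites = int(rng.integers(5, 51))
    # random frequencies so columns are not all half-half
    freqs = rng.uniform(0.05, 0.95, size=n_sites)
    alleles = (rng.random((n_hap, n_sites)) < freqs).astype(np.int8)
    return make_matrix(alleles)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def neutral_matrix():
    """A moderately sized neutral single-population dataset."""
    params = SimulationParams(
        n_haplotypes_per_pop=40, region_length=100_000,
        mutation_rate=2e-8, recombination_rate=1e-8,
    )
    dem = DemographyModel.constant_size(10_000)
    return simulate_neutral(params, dem, seed=99)


@pytest.fixture(scope="session")
def three_pop_matrix():
    params = SimulationParams(
        n_haplotypes_per_pop=20, region_length=50_000,
        mutation_rate=2e-8, recombination_rate=1e-8,
    )
    dem = DemographyModel.default_three_population()
    return simulate_neutral(params, dem, seed=7)
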