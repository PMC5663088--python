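"""Shared fixtures: small simulated populations reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from comapper import simdata
from comapper.variants import SNVMatrix


@pytest.fixture(scope="session")
def small_layout():
    return simdata.GenomeLayout.uniform(2, 1_000_000)


@pytest.fixture(scope="session")
def small_parents(small_layout):
    return simdata.simulate_parents(small_layout, snv_density=400, seed=101)


@pytest.fixture(scope="session")
def clean_population(small_parents):
    """High coverage, error-free population: genotypes reveal haplotypes exactly."""
    return simdata.simulate_population(
        small_parents, n_individuals=30, lambda_co=1.0, coverage=20.0,
        base_error=0.0, seed=202,
    )


@pytest.fixture(scope="session")
def noisy_population(small_parents):
    """Moderate-coverage population with sequencing error."""
    return simdata.simulate_population(
        small_parents, n_individuals=40, lambda_co=1.0, coverage=4.0,
        base_error=0.01, seed=303,
    )


def make_matrix(genotypes, positions=None, chrom="chr01", depth=None):
    """Helper to build an SNVMatrix from a genotype array (individuals x sites)."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_ind, n_sites = genotypes.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": np.asarray(positions, dtype=int), "ref": "A", "alt": "C"}
    )
    if depth is None:
        depth = np.full_like(genotypes, 10, dtype=np.int32)
    return SNVMatrix(sites=sites, genotypes=genotypes, depth=depth)
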