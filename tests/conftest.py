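"""Shared fixtures and small dataset builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pathgwas.datasets import GenotypeDataset
from pathgwas.synth import SimConfig, simulate_cohort


def make_dataset(
    genotypes,
    phenotype=None,
    bp=None,
    chrom="1",
    batch=None,
    rsids=None,
) -> GenotypeDataset:
    """Build a GenotypeDataset from a raw genotype matrix (n x m)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    if phenotype is None:
        phenotype = np.array([1] * (n // 2) + [0] * (n - n // 2))
    if bp is None:
        bp = np.arange(1, m + 1) * 1000
    if rsids is None:
        rsids = [f"rs{j + 1:04d}" for j in range(m)]
    variants = pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "rsid": rsids,
            "bp": np.asarray(bp, dtype=np.int64),
            "a1": ["A"] * m,
            "a2": ["G"] * m,
        }
    )
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:04d}" for i in range(n)],
            "phenotype": np.asarray(phenotype, dtype=np.int8),
            "batch": ["B1"] * n if batch is None else list(batch),
            "sex": ["unknown"] * n,
        }
    )
    return GenotypeDataset(g, variants, samples)


@pytest.fixture(scope="session")
def small_cohort():
    """A small clean null cohort shared by read-only tests."""
    cfg = SimConfig(n_cases=120, n_controls=120, n_blocks=8, block_size=25,
                    genes_per_block=6, n_sets=8, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """A cohort at the generator's default panel shape (smaller sample)."""
    cfg = SimConfig(n_cases=150, n_controls=150, seed=7)
    return simulate_cohort(cfg)
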