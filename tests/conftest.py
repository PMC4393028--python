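import numpy as np
import pandas as pd
import pytest

from canepop.genotype_io import GenotypeDataset, HaplotypeSet
from canepop.synthetic_data import (
    bottleneck28_scenario,
    simulate,
    simulate_sib_lines,
)


def make_dataset(genotypes, chrom=None, bp=None, sample_ids=None):
    """Small GenotypeDataset from a literal matrix (rows = samples)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    if chrom is None:
        chrom = ["1"] * m
    if bp is None:
        bp = list(range(100_000, 100_000 * (m + 1), 100_000))
    variants = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chrom": [str(c) for c in chrom],
            "bp": bp,
            "allele1": ["A"] * m,
            "allele2": ["B"] * m,
        }
    )
    ids = sample_ids or [f"ind{i}" for i in range(n)]
    return GenotypeDataset(ids, variants, g)


def make_haplotypes(hap_matrix, chrom=None, bp=None, sample_ids=None):
    h = np.asarray(hap_matrix, dtype=np.int8)
    n2, m = h.shape
    assert n2 % 2 == 0
    if chrom is None:
        chrom = ["1"] * m
    if bp is None:
        bp = list(range(100_000, 100_000 * (m + 1), 100_000))
    variants = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(m)],
            "chrom": [str(c) for c in chrom],
            "bp": bp,
            "allele1": ["A"] * m,
            "allele2": ["B"] * m,
        }
    )
    ids = sample_ids or [f"ind{i}" for i in range(n2 // 2)]
    return HaplotypeSet(ids, variants, h)


@pytest.fixture(scope="session")
def bottleneck28():
    """One bottlenecked 28-dog dataset shared across the suite."""
    return simulate(bottleneck28_scenario(seed=1))


@pytest.fixture(scope="session")
def sib_lines():
    """Full-sib mating lines of depths 0..6 (4 lines each, 28 individuals)."""
    depths = [d for d in range(7) for _ in range(4)]
    # a few hundred cM of genome so realized IBD tracks pedigree
    # expectation, and a mild base stock so depth-0 individuals carry
    # little background autozygosity
    return simulate_sib_lines(
        depths, seed=3, n_chrom=6, chrom_length_bp=30_000_000,
        founder_sites_per_chrom=500, base_ne=100, base_generations=8,
    )
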