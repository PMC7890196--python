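"""Shared fixtures: small hand-built genotype tables and simulation helpers."""

import numpy as np
import pandas as pd
import pytest

from landqg.tables import GenotypeTable


def make_genotypes(pop_blocks, loci=None, landscape_of=None, cohort="adult"):
    """Build a GenotypeTable from {pop: list-of-individual-genotypes}.

    Each individual genotype is a list of (a, b) allele pairs, one per locus.
    Populations are assigned to landscapes via ``landscape_of`` (default: all
    in one landscape).
    """
    rows, allele_rows = [], []
    for pop, inds in pop_blocks.items():
        land = landscape_of.get(pop, "L1") if landscape_of else "L1"
        for i, geno in enumerate(inds):
            rows.append((f"{pop}_{i}", pop, land, cohort))
            allele_rows.append([list(pair) for pair in geno])
    meta = pd.DataFrame(rows, columns=["individual_id", "population_id", "landscape_id", "cohort"])
    alleles = np.array(allele_rows, dtype=np.int64)
    n_loci = alleles.shape[1]
    return GenotypeTable(meta, alleles, loci or [f"M{j}" for j in range(n_loci)])


@pytest.fixture
def two_pop_fixed():
    """Two populations fixed for different alleles at one locus."""
    return make_genotypes(
        {
            "A": [[(10, 10)] for _ in range(10)],
            "B": [[(20, 20)] for _ in range(10)],
        }
    )


@pytest.fixture
def two_pop_p2_p8():
    """Two pops with allele frequencies (0.2, 0.8) and (0.8, 0.2), 10 diploids each."""
    pop_a = [[(1, 1)]] * 2 + [[(2, 2)]] * 8  # 4 copies of allele 1, 16 of allele 2
    pop_b = [[(1, 1)]] * 8 + [[(2, 2)]] * 2
    return make_genotypes({"A": pop_a, "B": pop_b})
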