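"""Shared fixtures: the 5-individual / 10-marker worked example and helpers.

The worked-example genotypes (four haplotype alleles over ten SNPs) are
the canonical small instance for the similarity algebra; every expected
matrix frozen in the tests was recomputed by hand from the haplotype
strings below.
"""

import numpy as np
import pandas as pd
import pytest

from genekin import PhasedGenotypes

HAPLOTYPES = {
    "hap1": "1011110100",
    "hap2": "0001001010",
    "hap3": "1110001101",
    "hap4": "0111001010",
}

# individual -> (paternal, maternal) haplotype
INDIVIDUAL_GAMETES = [
    ("hap1", "hap4"),
    ("hap2", "hap1"),
    ("hap3", "hap4"),
    ("hap2", "hap2"),
    ("hap2", "hap3"),
]


def make_example_genotypes() -> PhasedGenotypes:
    n, m = len(INDIVIDUAL_GAMETES), 10
    alleles = np.zeros((n, m, 2), dtype=np.int8)
    for i, (pat, mat) in enumerate(INDIVIDUAL_GAMETES):
        alleles[i, :, 0] = [int(c) for c in HAPLOTYPES[pat]]
        alleles[i, :, 1] = [int(c) for c in HAPLOTYPES[mat]]
    markers = pd.DataFrame(
        {
            "chrom": ["chr1"] * m,
            "pos": np.arange(100, 100 + 100 * m, 100),
            "marker_id": [f"M{k + 1}" for k in range(m)],
        }
    )
    return PhasedGenotypes([f"id{i + 1}" for i in range(n)], markers, alleles)


@pytest.fixture
def example_genotypes() -> PhasedGenotypes:
    return make_example_genotypes()


def random_genotypes(
    rng: np.random.Generator, n_individuals: int, n_markers: int, chrom: str = "chr1"
) -> PhasedGenotypes:
    """Unstructured random phased genotypes for property tests."""
    alleles = rng.integers(0, 2, size=(n_individuals, n_markers, 2), dtype=np.int8)
    markers = pd.DataFrame(
        {
            "chrom": [chrom] * n_markers,
            "pos": np.arange(1, n_markers + 1) * 100,
            "marker_id": [f"{chrom}_m{k}" for k in range(n_markers)],
        }
    )
    ids = [f"s{i}" for i in range(n_individuals)]
    return PhasedGenotypes(ids, markers, alleles)
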