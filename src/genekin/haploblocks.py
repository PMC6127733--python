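"""Haploblock construction by allele-count-threshold growth.

Blocks grow greedily left to right inside a scope (a gene's mapped
markers, or a whole chromosome in naive mode): starting from one SNP,
the next SNP is appended as long as the number of distinct haplotype
alleles across all 2n gametes stays within ``max_alleles``; the SNP whose
inclusion pushes the count strictly above the threshold is removed from
the current block and becomes the first SNP of the next block.  A block
with exactly ``max_alleles`` alleles is therefore allowed.  The blocks
partition each scope's marker list: contiguous, non-overlapping,
exhaustive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .annotation import MarkerGeneMap
from .io_formats import PhasedGenotypes

logger = logging.getLogger(__name__)

DEFAULT_MAX_ALLELES = 10


@dataclass
class Haploblock:
    """A contiguous run of markers with its distinct haplotype alleles.

    ``allele_table`` lists the distinct haplotype strings over {0,1} in
    first-seen order scanning gametes individual-by-individual (slot 0
    before slot 1); ``gamete_alleles`` holds, per individual, the two
    indices into ``allele_table`` carried by its gametes.
    """

    scope_id: str
    marker_indices: np.ndarray
    allele_table: list[str]
    gamete_alleles: np.ndarray  # (n_individuals, 2) indices

    @property
    def n_snps(self) -> int:
        return len(self.marker_indices)

    @property
    def n_alleles(self) -> int:
        return len(self.allele_table)

    def haplotype_of(self, individual: int, slot: int) -> str:
        return self.allele_table[self.gamete_alleles[individual, slot]]


def _gamete_matrix(genotypes: PhasedGenotypes, marker_indices: np.ndarray) -> np.ndarray:
    """(2n, m) matrix of gamete haplotypes over the given markers, rows
    ordered individual-by-individual with slot 0 before slot 1."""
    sub = genotypes.alleles[:, marker_indices, :]  # (n, m, 2)
    return sub.transpose(0, 2, 1).reshape(-1, len(marker_indices))


def _distinct_alleles(gametes: np.ndarray) -> tuple[list[str], np.ndarray]:
    """First-seen-order allele table and per-gamete allele indices."""
    table: list[str] = []
    seen: dict[str, int] = {}
    codes = np.empty(len(gametes), dtype=np.intp)
    for g, row in enumerate(gametes):
        key = "".join(map(str, row))
        if key not in seen:
            seen[key] = len(table)
            table.append(key)
        codes[g] = seen[key]
    return table, codes


def build_blocks_for_scope(
    genotypes: PhasedGenotypes,
    marker_indices: np.ndarray,
    max_alleles: int = DEFAULT_MAX_ALLELES,
    scope_id: str = "scope",
) -> list[Haploblock]:
    """Partition one scope's markers into haploblocks by greedy growth."""
    if max_alleles < 2:
        raise ValueError("max_alleles must be at least 2")
    marker_indices = np.asarray(marker_indices)
    if marker_indices.size == 0:
        raise ValueError(f"empty marker list for scope {scope_id}")
    gametes = _gamete_matrix(genotypes, marker_indices)
    n_local = marker_indices.size
    blocks: list[Haploblock] = []
    start = 0
    while start < n_local:
        # grow incrementally, re-labelling gametes as columns are appended
        labels = np.asarray(gametes[:, start], dtype=np.intp)
        n_alleles = len(np.unique(labels))
        # a single bi-allelic SNP can never exceed max_alleles >= 2
        assert n_alleles <= max_alleles
        end = start + 1
        while end < n_local:
            combined = labels * 2 + gametes[:, end]
            uniq, new_labels = np.unique(combined, return_inverse=True)
            if len(uniq) > max_alleles:
                break
            labels = new_labels
            n_alleles = len(uniq)
            end += 1
        block_idx = marker_indices[start:end]
        table, codes = _distinct_alleles(gametes[:, start:end])
        if len(table) == 1:
            logger.warning(
                "monomorphic haploblock in scope %s (markers %d-%d)",
                scope_id,
                block_idx[0],
                block_idx[-1],
            )
        blocks.append(
            Haploblock(
                scope_id=scope_id,
                marker_indices=block_idx,
                allele_table=table,
                gamete_alleles=codes.reshape(-1, 2),
            )
        )
        start = end
    return blocks


def build_genic_blocks(
    genotypes: PhasedGenotypes,
    gene_map: MarkerGeneMap,
    max_alleles: int = DEFAULT_MAX_ALLELES,
) -> list[Haploblock]:
    """Haploblocks per gene; a gene with one mapped SNP yields a
    single-marker block."""
    blocks: list[Haploblock] = []
    for gene_id, idx in gene_map.gene_markers.items():
        blocks.extend(
            build_blocks_for_scope(genotypes, idx, max_alleles, scope_id=gene_id)
        )
    return blocks


def build_naive_blocks(
    genotypes: PhasedGenotypes,
    max_alleles: int = DEFAULT_MAX_ALLELES,
) -> list[Haploblock]:
    """Annotation-free haploblocks over each chromosome's full marker list."""
    blocks: list[Haploblock] = []
    for chrom in genotypes.chromosomes():
        idx = genotypes.marker_indices_for_chrom(chrom)
        blocks.extend(
            build_blocks_for_scope(genotypes, idx, max_alleles, scope_id=chrom)
        )
    return blocks
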