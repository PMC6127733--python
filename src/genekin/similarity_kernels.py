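"""Haplotype-allele similarity kernels and individual relatedness matrices.

Three allele-level similarity measures over a haploblock of N SNPs:

* ``H1`` — proportion of matched loci, h1 = n_s / N, where n_s is the
  number of positions at which the two haplotypes carry the same allele.
* ``H2`` — segment-length-weighted similarity.  Matched positions are
  grouped into maximal runs of consecutive SNPs; a run of n_sl matching
  SNPs scores n_sl^2 (a single matching SNP scores 1).  The run scores
  are summed, normalized by the perfect-match score N^2, and the square
  root is taken so the score lives on [0, 1]:
  h2 = sqrt( sum_l n_sl^2 / N^2 ).
* ``HI`` — identity: 1 for identical haplotype strings, 0 otherwise.

Individual relatedness for a block is the half-sum of the four
cross-gamete allele similarities,
S(i, j) = [h(i_P, j_P) + h(i_P, j_M) + h(i_M, j_P) + h(i_M, j_M)] / 2,
giving diagonals in [1, 2] (2 iff the two gametes carry identical
alleles).  Block matrices are averaged element-wise into the genome-wide
kernel, which may optionally be standardized by its global maximum.

The VanRaden SNP kernel G = MM' / (2 sum_k p_k (1 - p_k)) with
allele-frequency-centered dosages is provided for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .haploblocks import Haploblock
from .io_formats import PhasedGenotypes

logger = logging.getLogger(__name__)

SIMILARITY_METHODS = ("HI", "H1", "H2")


@dataclass
class AlleleSimilarityMatrix:
    """A x A similarity among a block's haplotype alleles; symmetric,
    unit diagonal, entries in [0, 1]."""

    block: Haploblock
    values: np.ndarray
    method: str


@dataclass
class RelatednessMatrix:
    """n x n individual kernel with provenance
    {per_block, averaged, standardized, vanraden, loaded}."""

    individual_ids: list[str]
    values: np.ndarray
    provenance: str
    n_markers: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def restrict(self, row_ids, col_ids=None) -> np.ndarray:
        """Sub-matrix for the given id lists (values only)."""
        index = {iid: i for i, iid in enumerate(self.individual_ids)}
        rows = [index[i] for i in row_ids]
        cols = rows if col_ids is None else [index[i] for i in col_ids]
        return self.values[np.ix_(rows, cols)]


def _segment_score(a: np.ndarray, b: np.ndarray) -> float:
    """Sum of squared lengths of maximal runs of matching positions."""
    match = (a == b).astype(np.int64)
    if not match.any():
        return 0.0
    # run lengths via diff of padded match indicator
    padded = np.concatenate(([0], match, [0]))
    edges = np.flatnonzero(np.diff(padded))
    starts, ends = edges[::2], edges[1::2]
    lengths = ends - starts
    return float((lengths**2).sum())


def allele_similarity(block: Haploblock, method: str) -> AlleleSimilarityMatrix:
    """Compute the block's A x A allele similarity matrix (HI, H1 or H2)."""
    if method not in SIMILARITY_METHODS:
        raise ValueError(f"unknown similarity method {method!r}; use one of {SIMILARITY_METHODS}")
    A = block.n_alleles
    N = block.n_snps
    haps = np.array(
        [[int(c) for c in s] for s in block.allele_table], dtype=np.int8
    )
    values = np.eye(A)
    if method == "HI":
        return AlleleSimilarityMatrix(block, values, method)
    for i in range(A):
        for j in range(i + 1, A):
            if method == "H1":
                score = float((haps[i] == haps[j]).sum()) / N
            else:  # H2: sqrt of summed squared run lengths over N^2
                score = np.sqrt(_segment_score(haps[i], haps[j]) / (N * N))
            values[i, j] = values[j, i] = score
    return AlleleSimilarityMatrix(block, values, method)


def block_relatedness(
    block: Haploblock, sim: AlleleSimilarityMatrix, individual_ids: list[str]
) -> RelatednessMatrix:
    """Half-sum of the four cross-gamete allele similarities, per pair."""
    if sim.block is not block and sim.values.shape[0] != block.n_alleles:
        raise ValueError("similarity matrix does not match block")
    g0 = block.gamete_alleles[:, 0]
    g1 = block.gamete_alleles[:, 1]
    H = sim.values
    S = 0.5 * (
        H[np.ix_(g0, g0)] + H[np.ix_(g0, g1)] + H[np.ix_(g1, g0)] + H[np.ix_(g1, g1)]
    )
    return RelatednessMatrix(
        list(individual_ids), S, provenance="per_block", n_markers=block.n_snps
    )


def aggregate_kernel(blocks: list[RelatednessMatrix]) -> RelatednessMatrix:
    """Element-wise mean of per-block kernels (equal weight per block)."""
    if not blocks:
        raise ValueError("cannot aggregate an empty block list")
    ids = blocks[0].individual_ids
    for b in blocks[1:]:
        if b.individual_ids != ids:
            raise ValueError("per-block kernels cover different individual sets")
    total = np.zeros_like(blocks[0].values)
    n_markers = 0
    for b in blocks:
        total += b.values
        n_markers += b.n_markers
    return RelatednessMatrix(
        list(ids), total / len(blocks), provenance="averaged", n_markers=n_markers
    )


def standardize_kernel(kernel: RelatednessMatrix) -> RelatednessMatrix:
    """Divide every entry (diagonal included) by the global maximum."""
    m = kernel.values.max()
    if m <= 0:
        raise ValueError("kernel maximum must be positive to standardize")
    return RelatednessMatrix(
        list(kernel.individual_ids),
        kernel.values / m,
        provenance="standardized",
        n_markers=kernel.n_markers,
    )


def haplotype_kernel(
    genotypes: PhasedGenotypes,
    blocks: list[Haploblock],
    method: str = "H2",
    standardize: bool = False,
) -> RelatednessMatrix:
    """Genome-wide haplotype-similarity kernel: per-block relatedness from
    the chosen similarity measure, averaged over blocks."""
    per_block = [
        block_relatedness(b, allele_similarity(b, method), genotypes.individual_ids)
        for b in blocks
    ]
    kernel = aggregate_kernel(per_block)
    if standardize:
        kernel = standardize_kernel(kernel)
    return kernel


def vanraden_grm(genotypes: PhasedGenotypes) -> RelatednessMatrix:
    """VanRaden genomic relationship matrix from ALT-allele dosages.

    G = MM' / (2 sum_k p_k (1 - p_k)) where M holds dosages centered by
    twice the sample ALT-allele frequency.  Monomorphic markers carry no
    information and are excluded from both M and the denominator.
    """
    dosage = genotypes.alleles.sum(axis=2).astype(float)  # (n, m)
    p = dosage.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    n_mono = int((~poly).sum())
    if not poly.any():
        raise ValueError("all markers monomorphic; VanRaden denominator is zero")
    if n_mono:
        logger.info("excluded %d monomorphic markers from the VanRaden kernel", n_mono)
    M = dosage[:, poly] - 2 * p[poly]
    denom = 2.0 * float((p[poly] * (1 - p[poly])).sum())
    G = M @ M.T / denom
    return RelatednessMatrix(
        list(genotypes.individual_ids), G, provenance="vanraden", n_markers=int(poly.sum())
    )
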