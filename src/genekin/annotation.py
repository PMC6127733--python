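"""Map SNPs to extended protein-coding gene regions.

A marker belongs to a gene when it falls inside the gene's span extended
by ``flank_bp`` (default 5000 bp) on both sides, to capture proximal
regulatory variation.  Intervals are closed on both ends in 1-based
coordinates.  A SNP inside several overlapping extended genes is kept in
every such gene's set; genes end up with independent haploblock kernels
that are averaged, so no de-duplication is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import GeneAnnotation, PhasedGenotypes

logger = logging.getLogger(__name__)

DEFAULT_FLANK_BP = 5000


@dataclass
class MarkerGeneMap:
    """Per-gene ordered marker indices plus the reverse marker->genes index."""

    gene_markers: dict[str, np.ndarray]
    flank_bp: int = DEFAULT_FLANK_BP
    marker_genes: dict[int, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.marker_genes:
            rev: dict[int, list[str]] = {}
            for gene_id, idx in self.gene_markers.items():
                for m in idx:
                    rev.setdefault(int(m), []).append(gene_id)
            self.marker_genes = rev

    @property
    def n_genes(self) -> int:
        return len(self.gene_markers)

    @property
    def n_mapped_markers(self) -> int:
        return len(self.marker_genes)


def map_snps_to_genes(
    genotypes: PhasedGenotypes,
    genes: GeneAnnotation,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> MarkerGeneMap:
    """Assign each marker to every gene whose extended span contains it.

    Marker ``m`` maps to gene ``g`` iff the chromosomes match and
    ``start - flank_bp <= pos <= end + flank_bp`` (lower bound clipped at
    1).  Genes with no mapped marker are omitted.  Gene chromosomes absent
    from the genotypes produce a warning, not an error.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be non-negative")
    geno_chroms = set(genotypes.chromosomes())
    gene_markers: dict[str, np.ndarray] = {}
    missing_chroms = set()
    for rec in genes.records.itertuples(index=False):
        if rec.chrom not in geno_chroms:
            missing_chroms.add(rec.chrom)
            continue
        chrom_idx = genotypes.marker_indices_for_chrom(rec.chrom)
        pos = genotypes.markers["pos"].to_numpy()[chrom_idx]
        lo = max(1, rec.start - flank_bp)
        hi = rec.end + flank_bp
        hit = chrom_idx[(pos >= lo) & (pos <= hi)]
        if hit.size:
            gene_markers[rec.gene_id] = hit
    if missing_chroms:
        logger.warning(
            "gene chromosomes absent from genotypes: %s", sorted(missing_chroms)
        )
    result = MarkerGeneMap(gene_markers, flank_bp=flank_bp)
    logger.info(
        "mapped %d SNPs to %d genes (flank %d bp)",
        result.n_mapped_markers,
        result.n_genes,
        flank_bp,
    )
    return result
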