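"""Synthetic phased genotypes, gene annotation and phenotypes.

The generator emulates the data layout the pipeline consumes: phased
bi-allelic SNPs on a few chromosomes, protein-coding genes whose mapped
SNPs form multi-allelic haploblocks, and polygenic phenotypes at a
stated heritability.  Each gene (and each intergenic segment) carries a
small pool of founder haplotypes; a gamete is assembled by walking the
scopes along a chromosome, keeping the previous scope's founder index
with probability 1 - r and resampling it otherwise, which creates
gene-structured linkage disequilibrium with tunable between-scope decay.

Founder pools have a mutational genealogy: a few ancestral haplotypes
per scope, with each founder copied from a random ancestor and mutated
at each position with a small probability.  Genetic effects attach to
founder haplotype alleles of QTL genes and are inherited along that
genealogy (ancestral effect plus a per-mutation innovation), so
sequence-similar haplotype alleles carry correlated effects — the
identity-by-state ~ identity-by-descent premise that haplotype
similarity kernels exploit in real data.  A SNP-effect mode is provided
for contrast experiments.

This is a fixture generator for desk-scale experiments, not a
population-genetics simulator: no mutation, no demography, no
recombination inside a scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GeneAnnotation, PhasedGenotypes, PhenotypeTable

_GENE_SPACING = 30_000  # bp between gene starts; keeps 5 kb flanks disjoint
_SNP_SPACING = 200  # bp between SNPs inside a scope
_INTERGENIC_OFFSET = 15_000  # intergenic SNPs sit this far before the next gene


@dataclass
class SimulationConfig:
    """Study conditions of one synthetic dataset.

    Defaults give 300 individuals, 20 genes on 2 chromosomes with 4-8
    SNPs each, 8 founder haplotypes per scope, between-scope
    recombination 0.3, and a trait at heritability 0.5 driven by
    haplotype-allele effects in half of the genes.
    """

    n_individuals: int = 300
    n_chromosomes: int = 2
    genes_per_chromosome: int = 10
    snps_per_gene: tuple[int, int] = (4, 8)
    intergenic_snps: tuple[int, int] = (2, 5)
    founder_haplotypes_per_gene: int = 8
    ancestral_haplotypes_per_gene: int = 3
    mutation_rate: float = 0.15  # per-position founder-from-ancestor mutation
    effect_innovation_sd: float = 0.5  # per-mutation effect drift
    recombination_rate_between_blocks: float = 0.3
    h2: float = 0.5
    qtl_gene_fraction: float = 0.5
    effect_distribution: str = "normal"
    effect_target: str = "haplotype"  # or "snp"
    seed: int = 0

    def validate(self) -> None:
        if min(
            self.n_individuals,
            self.n_chromosomes,
            self.genes_per_chromosome,
            self.founder_haplotypes_per_gene,
            *self.snps_per_gene,
        ) <= 0:
            raise ValueError("all counts must be positive")
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must lie in [0, 1]")
        if not 0 <= self.recombination_rate_between_blocks <= 1:
            raise ValueError("recombination rate must lie in [0, 1]")
        if not 0 <= self.qtl_gene_fraction <= 1:
            raise ValueError("qtl_gene_fraction must lie in [0, 1]")
        if self.effect_distribution != "normal":
            raise ValueError("only normal effect distributions are supported")
        if self.effect_target not in ("haplotype", "snp"):
            raise ValueError("effect_target must be 'haplotype' or 'snp'")
        if self.founder_haplotypes_per_gene > 2 * self.n_individuals:
            raise ValueError(
                "more founder haplotypes per gene than gametes to carry them"
            )
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.ancestral_haplotypes_per_gene <= 0:
            raise ValueError("need at least one ancestral haplotype per gene")
        if self.founder_haplotypes_per_gene > 2 ** self.snps_per_gene[0]:
            raise ValueError(
                f"{self.founder_haplotypes_per_gene} distinct founder haplotypes "
                f"cannot exist over only {self.snps_per_gene[0]} SNPs"
            )


@dataclass
class _Scope:
    """One stretch of SNPs sharing a founder pool (gene or intergenic)."""

    scope_id: str
    chrom: str
    positions: np.ndarray
    founders: np.ndarray  # (n_founders, n_snps) binary, all rows distinct
    ancestor_of: np.ndarray  # (n_founders,) ancestral-haplotype index
    n_mutations: np.ndarray  # (n_founders,) positions mutated from ancestor
    is_gene: bool
    start: int = 0
    end: int = 0


def _draw_founders(
    rng: np.random.Generator,
    n_founders: int,
    n_snps: int,
    n_ancestors: int,
    mutation_rate: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Genealogical founder pool: distinct descendants of a few ancestors.

    Each founder copies a random ancestral haplotype and flips every
    position with probability ``mutation_rate``; candidates colliding
    with an existing founder are redrawn, so haplotype alleles (distinct
    strings) map one-to-one onto founders.
    """
    n_ancestors = min(n_ancestors, n_founders, 2**n_snps)
    ancestors = _distinct_random(rng, n_ancestors, n_snps)
    seen: set[bytes] = set()
    rows, anc_of, n_mut = [], [], []
    while len(rows) < n_founders:
        a = int(rng.integers(0, n_ancestors))
        flips = rng.random(n_snps) < mutation_rate
        cand = np.where(flips, 1 - ancestors[a], ancestors[a]).astype(np.int8)
        key = cand.tobytes()
        if key not in seen:
            seen.add(key)
            rows.append(cand)
            anc_of.append(a)
            n_mut.append(int(flips.sum()))
    return np.array(rows, dtype=np.int8), np.array(anc_of), np.array(n_mut)


def _distinct_random(rng: np.random.Generator, n: int, n_snps: int) -> np.ndarray:
    seen: set[bytes] = set()
    rows = []
    while len(rows) < n:
        cand = rng.integers(0, 2, size=n_snps, dtype=np.int8)
        if cand.tobytes() not in seen:
            seen.add(cand.tobytes())
            rows.append(cand)
    return np.array(rows, dtype=np.int8)


def _build_scopes(config: SimulationConfig, rng: np.random.Generator) -> list[_Scope]:
    scopes: list[_Scope] = []
    F = config.founder_haplotypes_per_gene
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        for g in range(config.genes_per_chromosome):
            gene_start = 1 + (g + 1) * _GENE_SPACING
            # intergenic segment ahead of the gene, outside both flanks
            n_inter = int(rng.integers(config.intergenic_snps[0], config.intergenic_snps[1] + 1))
            if n_inter > 0:
                pos0 = gene_start - _INTERGENIC_OFFSET
                positions = pos0 + _SNP_SPACING * np.arange(n_inter)
                founders, anc, mut = _draw_founders(
                    rng,
                    min(F, 2**n_inter),
                    n_inter,
                    config.ancestral_haplotypes_per_gene,
                    config.mutation_rate,
                )
                scopes.append(
                    _Scope(
                        scope_id=f"{chrom}_ig{g + 1}",
                        chrom=chrom,
                        positions=positions,
                        founders=founders,
                        ancestor_of=anc,
                        n_mutations=mut,
                        is_gene=False,
                    )
                )
            n_snps = int(rng.integers(config.snps_per_gene[0], config.snps_per_gene[1] + 1))
            positions = gene_start + _SNP_SPACING * np.arange(n_snps)
            founders, anc, mut = _draw_founders(
                rng,
                F,
                n_snps,
                config.ancestral_haplotypes_per_gene,
                config.mutation_rate,
            )
            scopes.append(
                _Scope(
                    scope_id=f"{chrom}_gene{g + 1}",
                    chrom=chrom,
                    positions=positions,
                    founders=founders,
                    ancestor_of=anc,
                    n_mutations=mut,
                    is_gene=True,
                    start=gene_start,
                    end=int(positions[-1]),
                )
            )
    return scopes


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[PhasedGenotypes, GeneAnnotation, PhenotypeTable, dict]:
    """Generate one dataset; returns (genotypes, genes, phenotypes, truth).

    The truth record stores the simulated genetic values, the per-allele
    (or per-SNP) effects, the QTL gene ids and the realized heritability
    var(g) / var(y).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    scopes = _build_scopes(config, rng)
    n = config.n_individuals
    n_gametes = 2 * n

    # founder choice per gamete per scope, with between-scope carry-over
    r = config.recombination_rate_between_blocks
    scope_choice = np.empty((len(scopes), n_gametes), dtype=np.intp)
    prev_chrom = None
    for s, scope in enumerate(scopes):
        F_s = scope.founders.shape[0]
        fresh = rng.integers(0, F_s, size=n_gametes)
        if scope.chrom != prev_chrom:
            scope_choice[s] = fresh
        else:
            recomb = rng.random(n_gametes) < r
            carried = np.mod(scope_choice[s - 1], F_s)
            scope_choice[s] = np.where(recomb, fresh, carried)
        prev_chrom = scope.chrom

    # assemble genotypes
    marker_rows = []
    allele_cols = []
    for s, scope in enumerate(scopes):
        haps = scope.founders[scope_choice[s]]  # (2n, n_snps)
        allele_cols.append(haps)
        for k, pos in enumerate(scope.positions):
            marker_rows.append((scope.chrom, int(pos), f"{scope.scope_id}_m{k + 1}"))
    gametes = np.concatenate(allele_cols, axis=1)  # (2n, m)
    m = gametes.shape[1]
    alleles = gametes.reshape(n, 2, m).transpose(0, 2, 1)  # (n, m, 2)
    individual_ids = [f"ind{i + 1:04d}" for i in range(n)]
    markers = pd.DataFrame(marker_rows, columns=["chrom", "pos", "marker_id"])
    genotypes = PhasedGenotypes(individual_ids, markers, alleles)

    gene_scopes = [s for s in scopes if s.is_gene]
    genes = GeneAnnotation(
        pd.DataFrame(
            [
                (s.scope_id, s.chrom, s.start, s.end, "protein_coding")
                for s in gene_scopes
            ],
            columns=["gene_id", "chrom", "start", "end", "biotype"],
        )
    )

    # genetic values
    n_qtl = max(1, round(config.qtl_gene_fraction * len(gene_scopes))) if config.qtl_gene_fraction > 0 else 0
    qtl_idx = rng.choice(len(gene_scopes), size=n_qtl, replace=False) if n_qtl else np.array([], dtype=int)
    gene_index = {id(s): i for i, s in enumerate(scopes)}
    g_values = np.zeros(n)
    effects: dict[str, np.ndarray] = {}
    for qi in sorted(qtl_idx):
        scope = gene_scopes[qi]
        s = gene_index[id(scope)]
        if config.effect_target == "haplotype":
            # effects inherited along the founder genealogy: ancestral
            # effect plus one innovation per mutated position
            anc_eff = rng.normal(0.0, 1.0, size=scope.ancestor_of.max() + 1)
            drift = config.effect_innovation_sd * np.sqrt(scope.n_mutations)
            eff = anc_eff[scope.ancestor_of] + drift * rng.normal(
                0.0, 1.0, size=scope.founders.shape[0]
            )
            per_gamete = eff[scope_choice[s]]  # (2n,)
            g_values += per_gamete.reshape(n, 2).sum(axis=1)
        else:  # additive SNP effects within the QTL gene
            eff = rng.normal(0.0, 1.0, size=scope.founders.shape[1])
            dosage = scope.founders[scope_choice[s]].reshape(n, 2, -1).sum(axis=1)
            g_values += dosage @ eff
        effects[scope.scope_id] = eff

    var_g = float(np.var(g_values))
    if config.h2 >= 1.0:
        y = g_values.copy()
    elif config.h2 <= 0.0 or var_g == 0.0:
        y = rng.normal(0.0, 1.0, size=n)
    else:
        sigma_e = np.sqrt(var_g * (1 - config.h2) / config.h2)
        y = g_values + rng.normal(0.0, sigma_e, size=n)
    var_y = float(np.var(y))
    realized_h2 = var_g / var_y if var_y > 0 and config.h2 > 0 else 0.0
    if config.h2 <= 0.0:
        realized_h2 = 0.0

    phenotypes = PhenotypeTable(
        individual_ids,
        pd.DataFrame({"trait": y}),
        pd.DataFrame(index=range(n)),
    )
    truth = {
        "genetic_values": g_values,
        "allele_effects": effects,
        "qtl_genes": [gene_scopes[qi].scope_id for qi in sorted(qtl_idx)],
        "realized_h2": realized_h2,
        "config": config,
    }
    return genotypes, genes, phenotypes, truth
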