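"""Input/output for the formats the pipeline touches.

Phased genotypes come from VCF (phased GT fields required, bi-allelic SNPs
only, no missing calls), gene annotation from GFF3 or a minimal 5-column
gene table, phenotypes from a headered TSV.  Relatedness kernels are
written either as a square TSV (header of ids + full matrix) or as a
GCTA-style text GRM (lower triangle plus companion ``.id`` file).

All coordinates are 1-based inclusive throughout, matching VCF and GFF3;
no half-open conversion is ever performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class PhasedGenotypes:
    """Phased bi-allelic genotypes for a set of diploid individuals.

    Parameters
    ----------
    individual_ids : list of str
        Sample identifiers, order fixed.
    markers : pandas.DataFrame
        One row per marker with columns ``chrom``, ``pos`` (1-based),
        ``marker_id``; positions strictly increasing within a chromosome.
    alleles : numpy.ndarray
        ``(n_individuals, n_markers, 2)`` array of {0, 1} codes; REF is 0
        and ALT is 1.  Slot 0 is the first ("paternal") gamete, slot 1 the
        second ("maternal") gamete, as phased in the input.
    """

    individual_ids: list[str]
    markers: pd.DataFrame
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        n, m = len(self.individual_ids), len(self.markers)
        if self.alleles.shape != (n, m, 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} does not match "
                f"{n} individuals x {m} markers x 2 gametes"
            )
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("allele codes must all be 0 or 1")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids are not unique")
        if self.markers["marker_id"].duplicated().any():
            dups = self.markers.loc[self.markers["marker_id"].duplicated(), "marker_id"]
            raise ValueError(f"duplicate marker ids: {sorted(set(dups))}")
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def chromosomes(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        return list(dict.fromkeys(self.markers["chrom"]))

    def marker_indices_for_chrom(self, chrom: str) -> np.ndarray:
        return np.flatnonzero((self.markers["chrom"] == chrom).to_numpy())


@dataclass
class GeneAnnotation:
    """Protein-coding gene records (gene_id, chrom, start, end, biotype)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "start", "end", "biotype"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"gene annotation missing columns: {sorted(missing)}")
        bad = self.records["start"] > self.records["end"]
        if bad.any():
            offending = self.records.loc[bad, "gene_id"].tolist()
            raise ValueError(f"gene start > end for: {offending}")
        if self.records["gene_id"].duplicated().any():
            dups = self.records.loc[self.records["gene_id"].duplicated(), "gene_id"]
            raise ValueError(f"duplicate gene ids: {sorted(set(dups))}")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class PhenotypeTable:
    """Phenotypes and optional fixed-effect factors, one row per individual."""

    individual_ids: list[str]
    traits: pd.DataFrame
    factors: pd.DataFrame = field(default_factory=pd.DataFrame)

    def trait(self, name: str) -> np.ndarray:
        y = self.traits[name].to_numpy(dtype=float)
        if np.isnan(y).any():
            n_missing = int(np.isnan(y).sum())
            logger.warning("trait %s has %d missing values", name, n_missing)
        return y

    def align_to(self, individual_ids: list[str]) -> "PhenotypeTable":
        """Reorder rows to match a genotype id order; error on absent ids."""
        index = {iid: i for i, iid in enumerate(self.individual_ids)}
        missing = [iid for iid in individual_ids if iid not in index]
        if missing:
            raise ValueError(f"phenotype table lacks individuals: {missing}")
        order = [index[iid] for iid in individual_ids]
        return PhenotypeTable(
            individual_ids=list(individual_ids),
            traits=self.traits.iloc[order].reset_index(drop=True),
            factors=self.factors.iloc[order].reset_index(drop=True)
            if len(self.factors)
            else self.factors,
        )


def read_phased_vcf(path: str, require_phased: bool = True) -> PhasedGenotypes:
    """Read phased bi-allelic SNPs from a VCF into a :class:`PhasedGenotypes`.

    REF is coded 0 and ALT 1.  Unphased or missing genotypes and
    multi-allelic records are hard errors: the downstream similarity
    algebra has no missing-data rule, so nothing is imputed.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    rows = []
    allele_rows = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {variant.CHROM}:{variant.POS} "
                f"({variant.REF}->{variant.ALT}); only bi-allelic SNPs supported"
            )
        gts = variant.genotypes  # [a0, a1, phased] per sample
        codes = np.empty((len(samples), 2), dtype=np.int8)
        for s, (a0, a1, phased) in enumerate(gts):
            if a0 < 0 or a1 < 0:
                raise ValueError(
                    f"missing genotype for individual {samples[s]} at "
                    f"{variant.CHROM}:{variant.POS}"
                )
            if require_phased and not phased:
                raise ValueError(
                    f"unphased genotype for individual {samples[s]} at "
                    f"{variant.CHROM}:{variant.POS}"
                )
            codes[s, 0], codes[s, 1] = a0, a1
        marker_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        rows.append((variant.CHROM, variant.POS, marker_id))
        allele_rows.append(codes)
    if not rows:
        raise ValueError(f"no markers in VCF {path}")
    markers = pd.DataFrame(rows, columns=["chrom", "pos", "marker_id"])
    alleles = np.stack(allele_rows, axis=1)  # (n, m, 2)
    return PhasedGenotypes(samples, markers, alleles)


def _read_gff3(path: str) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for feat in db.features_of_type("gene"):
        biotype = (
            feat.attributes.get("gene_biotype")
            or feat.attributes.get("biotype")
            or ["unknown"]
        )[0]
        gene_id = (feat.attributes.get("ID") or feat.attributes.get("gene_id") or [feat.id])[0]
        rows.append((gene_id, feat.seqid, feat.start, feat.end, biotype))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "biotype"])


def _read_gene_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["gene_id", "chrom", "start", "end", "biotype"],
        dtype={"gene_id": str, "chrom": str},
    )
    return df


def read_gene_annotation(path: str, dialect: str = "gff3") -> GeneAnnotation:
    """Read gene records, keeping only biotype ``protein_coding``.

    Non-protein-coding records are counted and logged, never silently lost.
    """
    if dialect == "gff3":
        df = _read_gff3(path)
    elif dialect == "gene_table":
        df = _read_gene_table(path)
    else:
        raise ValueError(f"unknown annotation dialect: {dialect!r}")
    n_total = len(df)
    kept = df[df["biotype"] == "protein_coding"].reset_index(drop=True)
    n_dropped = n_total - len(kept)
    if n_dropped:
        logger.info(
            "dropped %d of %d gene records with biotype != protein_coding",
            n_dropped,
            n_total,
        )
    return GeneAnnotation(kept)


def read_phenotypes(path: str, id_column: str | None = None) -> PhenotypeTable:
    """Read a headered phenotype TSV; first column is the individual id
    unless ``id_column`` names another.  Numeric columns become traits,
    non-numeric columns fixed-effect factors."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if id_column is None:
        id_column = df.columns[0]
    ids = df[id_column].astype(str).tolist()
    rest = df.drop(columns=[id_column])
    numeric = rest.select_dtypes(include=[np.number])
    factors = rest.drop(columns=numeric.columns)
    return PhenotypeTable(ids, numeric.reset_index(drop=True), factors.reset_index(drop=True))


def write_kernel(matrix, path: str, format: str = "square_tsv", header_lines=()) -> None:
    """Write a relatedness matrix; see module docstring for the two formats.

    ``header_lines`` are emitted as leading ``#`` comments (provenance).
    """
    values = np.asarray(matrix.values, dtype=float)
    ids = list(matrix.individual_ids)
    if values.shape != (len(ids), len(ids)):
        raise ValueError("kernel is not square over its individual ids")
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError("refusing to write an asymmetric kernel")
    n_markers = getattr(matrix, "n_markers", 0) or 0
    if format == "square_tsv":
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("\t".join(ids) + "\n")
            for row in values:
                fh.write("\t".join(f"{x:.6f}" for x in row) + "\n")
    elif format == "gcta_grm_text":
        id_path = _grm_id_path(path)
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            for i in range(len(ids)):
                for j in range(i + 1):
                    fh.write(f"{i + 1}\t{j + 1}\t{n_markers}\t{values[i, j]:.6f}\n")
        with open(id_path, "w") as fh:
            for iid in ids:
                fh.write(f"0\t{iid}\n")
    else:
        raise ValueError(f"unknown kernel format: {format!r}")


def _grm_id_path(path: str) -> str:
    if path.endswith(".grm.txt"):
        return path[: -len(".grm.txt")] + ".grm.id"
    return path + ".id"


def read_kernel(path: str, format: str = "square_tsv"):
    """Read a kernel written by :func:`write_kernel`; inverse to 1e-6."""
    from .similarity_kernels import RelatednessMatrix

    if format == "square_tsv":
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
        ids = lines[0].split("\t")
        values = np.array([[float(x) for x in ln.split("\t")] for ln in lines[1:]])
        return RelatednessMatrix(ids, values, provenance="loaded")
    elif format == "gcta_grm_text":
        id_path = _grm_id_path(path)
        with open(id_path) as fh:
            ids = [ln.split("\t")[1].strip() for ln in fh if ln.strip()]
        n = len(ids)
        values = np.zeros((n, n))
        n_markers = 0
        with open(path) as fh:
            for ln in fh:
                if ln.startswith("#") or not ln.strip():
                    continue
                i, j, nm, v = ln.split("\t")
                i, j = int(i) - 1, int(j) - 1
                values[i, j] = values[j, i] = float(v)
                n_markers = int(nm)
        return RelatednessMatrix(ids, values, provenance="loaded", n_markers=n_markers)
    raise ValueError(f"unknown kernel format: {format!r}")


def write_phased_vcf(genotypes: PhasedGenotypes, path: str) -> None:
    """Write genotypes as an uncompressed VCF 4.2 with phased GT fields."""
    chroms = genotypes.chromosomes()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=genekin\n")
        for chrom in chroms:
            grp = genotypes.markers[genotypes.markers["chrom"] == chrom]
            fh.write(f"##contig=<ID={chrom},length={int(grp['pos'].max()) + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.individual_ids)
            + "\n"
        )
        for m, row in enumerate(genotypes.markers.itertuples(index=False)):
            gts = "\t".join(
                f"{genotypes.alleles[i, m, 0]}|{genotypes.alleles[i, m, 1]}"
                for i in range(genotypes.n_individuals)
            )
            fh.write(f"{row.chrom}\t{row.pos}\t{row.marker_id}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def write_gene_annotation(genes: GeneAnnotation, path: str, dialect: str = "gff3") -> None:
    """Write gene records as GFF3 or the minimal tab-delimited gene table."""
    if dialect == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for rec in genes.records.itertuples(index=False):
                attrs = f"ID={rec.gene_id};biotype={rec.biotype}"
                fh.write(
                    f"{rec.chrom}\tgenekin\tgene\t{rec.start}\t{rec.end}\t.\t+\t.\t{attrs}\n"
                )
    elif dialect == "gene_table":
        genes.records[["gene_id", "chrom", "start", "end", "biotype"]].to_csv(
            path, sep="\t", header=False, index=False
        )
    else:
        raise ValueError(f"unknown annotation dialect: {dialect!r}")


def write_phenotypes(pheno: PhenotypeTable, path: str) -> None:
    df = pd.concat(
        [pd.DataFrame({"id": pheno.individual_ids}), pheno.factors, pheno.traits],
        axis=1,
    )
    df.to_csv(path, sep="\t", index=False)
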