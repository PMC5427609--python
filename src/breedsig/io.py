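"""Genotype I/O and the two genotype encodings.

Reads phased biallelic VCF panels with a breed label table, recodes alleles
to the global major/minor binary representation (0 = "conserved" major
allele, 1 = "mutated" minor allele), collapses haplotype pairs to ternary
genotype codes (0 = major homozygote, 1 = heterozygote, 2 = alternative
homozygote), and assigns SNP sites to gene intervals.

Internal coordinates are 0-based half-open; VCF positions are 1-based and
converted only at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]


class GenotypeIOError(ValueError):
    """Malformed or unusable genotype input."""


@dataclass
class SamplePanel:
    """Sample identifiers with one breed label per sample."""

    sample_ids: np.ndarray
    breed_labels: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.breed_labels = np.asarray(self.breed_labels, dtype=object)
        if len(self.sample_ids) != len(self.breed_labels):
            raise GenotypeIOError("one breed label required per sample")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise GenotypeIOError("sample ids must be unique")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class HaplotypePanel:
    """Phased panel: two haplotypes per sample over sorted biallelic sites.

    ``haplotypes`` has shape (2 * n_samples, n_sites); sample *i* owns rows
    2i and 2i+1. Allele codes are 0/1: REF/ALT under the ``"refalt"``
    encoding, major/minor under ``"major_minor"``.
    """

    samples: SamplePanel
    sites: pd.DataFrame  # chrom, pos (1-based), ref, alt
    haplotypes: np.ndarray
    encoding: str = "refalt"
    major_is_ref: np.ndarray | None = None  # per-site, set by recoding

    def __post_init__(self) -> None:
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.shape != (2 * self.samples.n_samples, len(self.sites)):
            raise GenotypeIOError(
                f"haplotype matrix shape {self.haplotypes.shape} does not match "
                f"{self.samples.n_samples} samples x {len(self.sites)} sites"
            )
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise GenotypeIOError("allele codes must be 0/1")

    @property
    def n_samples(self) -> int:
        return self.samples.n_samples

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def hap_breeds(self) -> np.ndarray:
        """Breed label of each haplotype (each carries its sample's label)."""
        return np.repeat(self.samples.breed_labels, 2)

    def breed_mask(self, breed: str) -> np.ndarray:
        return self.samples.breed_labels == breed

    def hap_mask(self, breed: str) -> np.ndarray:
        return np.repeat(self.breed_mask(breed), 2)

    def copy(self) -> "HaplotypePanel":
        return replace(
            self,
            sites=self.sites.copy(),
            haplotypes=self.haplotypes.copy(),
            major_is_ref=None if self.major_is_ref is None else self.major_is_ref.copy(),
        )


@dataclass
class TernaryGenotypeMatrix:
    """Per-sample genotype codes in {0, 1, 2}; shape (n_samples, n_sites)."""

    samples: SamplePanel
    sites: pd.DataFrame
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.ascontiguousarray(self.codes, dtype=np.uint8)
        if self.codes.shape != (self.samples.n_samples, len(self.sites)):
            raise GenotypeIOError("genotype matrix shape mismatch")
        if self.codes.size and self.codes.max() > 2:
            raise GenotypeIOError("ternary codes must be in {0,1,2}")

    @property
    def n_samples(self) -> int:
        return self.samples.n_samples

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class GeneSNPMap:
    """gene_id -> ordered array of site indices (a site may hit several genes)."""

    assignments: dict

    def sites_for(self, gene_id: str) -> np.ndarray:
        return self.assignments[gene_id]

    def sizes(self) -> pd.Series:
        return pd.Series(
            {g: len(v) for g, v in self.assignments.items()}, name="n_snps"
        ).rename_axis("gene_id")

    @property
    def gene_ids(self) -> list:
        return list(self.assignments)


def read_labels(path) -> pd.DataFrame:
    """Read a two-column ``sample_id<TAB>breed`` table (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if list(df.columns[:2]) != ["sample_id", "breed"]:
        # headerless: first row was data
        df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
        df.columns = ["sample_id", "breed"] + list(df.columns[2:])
    return df[["sample_id", "breed"]]


def read_vcf(path, labels: pd.DataFrame, allow_unphased: bool = False) -> HaplotypePanel:
    """Read phased biallelic SNPs from a VCF into a REF/ALT-coded panel.

    Non-biallelic/non-SNP records are dropped (and counted); unphased or
    missing genotypes raise unless ``allow_unphased`` (which degrades the
    panel to genotype-level use: haplotype order within a sample is then
    arbitrary).
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    vcf_samples = list(vcf.samples)
    wanted = labels["sample_id"].tolist()
    missing = [s for s in wanted if s not in vcf_samples]
    if missing:
        raise GenotypeIOError(f"{path}: labeled samples absent from VCF: {missing}")
    order = [vcf_samples.index(s) for s in wanted]

    chroms, poss, refs, alts, rows = [], [], [], [], []
    n_dropped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_dropped += 1
            continue
        gts = rec.genotypes  # [a, b, phased] per sample
        col = np.empty(2 * len(order), dtype=np.int16)
        for k, idx in enumerate(order):
            a, b, phased = gts[idx][0], gts[idx][1], gts[idx][2]
            if (a < 0 or b < 0) or (not phased and not allow_unphased):
                raise GenotypeIOError(
                    f"{path}: unphased or missing genotype at "
                    f"{rec.CHROM}:{rec.POS} sample {wanted[k]} "
                    "(pass allow_unphased to accept genotype-level data)"
                )
            col[2 * k] = max(a, 0)
            col[2 * k + 1] = max(b, 0)
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        rows.append(col)
    if n_dropped:
        logger.info("%s: dropped %d non-biallelic-SNP records", path, n_dropped)
    if not rows:
        raise GenotypeIOError(f"{path}: no usable sites")

    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    hap = np.stack(rows, axis=1).astype(np.uint8)
    site_order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    sites = sites.iloc[site_order].reset_index(drop=True)
    hap = hap[:, site_order]
    panel = HaplotypePanel(
        samples=SamplePanel(labels["sample_id"].to_numpy(), labels["breed"].to_numpy()),
        sites=sites,
        haplotypes=hap,
    )
    return panel


def write_vcf(panel: HaplotypePanel, path) -> Path:
    """Write a panel as an uncompressed phased VCF 4.2 (REF/ALT codes as stored)."""
    path = Path(path)
    sites = panel.sites
    hap = panel.haplotypes
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=breedsig\n")
        for chrom in pd.unique(sites["chrom"]):
            length = int(sites.loc[sites["chrom"] == chrom, "pos"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, panel.samples.sample_ids))
            + "\n"
        )
        for j in range(panel.n_sites):
            gts = "\t".join(
                f"{hap[2 * i, j]}|{hap[2 * i + 1, j]}" for i in range(panel.n_samples)
            )
            fh.write(
                f"{sites['chrom'].iat[j]}\t{sites['pos'].iat[j]}\t.\t"
                f"{sites['ref'].iat[j]}\t{sites['alt'].iat[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )
    return path


def recode_major_minor(panel: HaplotypePanel) -> HaplotypePanel:
    """Recode each site so the most frequent allele over ALL haplotypes is 0.

    An exact 50/50 tie keeps the REF allele (or, on an already-recoded
    panel, the current 0 allele) as major, making the recode deterministic
    under any input ordering and idempotent. Monomorphic sites come out
    all-0 ("conserved").
    """
    hap = panel.haplotypes
    n_hap = hap.shape[0]
    count1 = hap.sum(axis=0, dtype=np.int64)
    flip = count1 * 2 > n_hap  # strict majority of allele 1; ties keep REF as major
    out = np.where(flip[None, :], 1 - hap, hap).astype(np.uint8)
    major_is_ref = ~flip if panel.encoding == "refalt" else None
    new = replace(panel, haplotypes=out, encoding="major_minor")
    if major_is_ref is not None:
        new.major_is_ref = major_is_ref
    return new


def ternary_encode(panel: HaplotypePanel) -> TernaryGenotypeMatrix:
    """Collapse the two binary haplotypes of each sample to a 0/1/2 code."""
    if panel.encoding != "major_minor":
        raise GenotypeIOError("ternary encoding requires a major/minor recoded panel")
    codes = panel.haplotypes[0::2, :].astype(np.uint8) + panel.haplotypes[1::2, :]
    return TernaryGenotypeMatrix(samples=panel.samples, sites=panel.sites, codes=codes)


def read_genes(path) -> pd.DataFrame:
    """Read gene intervals from BED (0-based half-open) or GFF3 (converted).

    Returns a frame with gene_id, chrom, start, end (0-based half-open) and
    strand, sorted by (chrom, start).
    """
    import pyranges as pr

    path = str(path)
    if path.endswith((".gff", ".gff3")):
        df = pr.read_gff3(path).df
        df = df[df["Feature"] == "gene"]
        gene_id = df["ID"] if "ID" in df else df["Name"]
        out = pd.DataFrame(
            {
                "gene_id": gene_id.astype(str),
                "chrom": df["Chromosome"].astype(str),
                "start": df["Start"].astype(int),  # pyranges already 0-based
                "end": df["End"].astype(int),
                "strand": df.get("Strand", "."),
            }
        )
    else:
        df = pr.read_bed(path).df
        out = pd.DataFrame(
            {
                "gene_id": df["Name"].astype(str),
                "chrom": df["Chromosome"].astype(str),
                "start": df["Start"].astype(int),
                "end": df["End"].astype(int),
                "strand": df["Strand"] if "Strand" in df else ".",
            }
        )
    if out["gene_id"].duplicated().any():
        raise GenotypeIOError(f"{path}: duplicate gene ids")
    if (out["start"] >= out["end"]).any():
        raise GenotypeIOError(f"{path}: empty or inverted gene interval")
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_genes_bed(genes: pd.DataFrame, path) -> Path:
    path = Path(path)
    bed = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"],
            "end": genes["end"],
            "name": genes["gene_id"],
            "score": 0,
            "strand": genes.get("strand", "."),
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)
    return path


def map_snps_to_genes(sites: pd.DataFrame, genes: pd.DataFrame, flank_bp: int = 0) -> GeneSNPMap:
    """Assign each SNP to every gene whose flanked interval contains it.

    A site at 1-based position p belongs to a gene iff p-1 lies in
    [start - flank_bp, end + flank_bp). Genes without SNPs get empty lists.
    """
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples(index=False):
        lo = row.start - flank_bp
        hi = row.end + flank_bp
        if hi > lo:
            trees.setdefault(row.chrom, IntervalTree()).addi(lo, hi, row.gene_id)
    hits: dict[str, list] = {g: [] for g in genes["gene_id"]}
    chrom_arr = sites["chrom"].to_numpy()
    pos0 = sites["pos"].to_numpy() - 1
    for j in range(len(sites)):
        tree = trees.get(chrom_arr[j])
        if tree is None:
            continue
        for iv in tree.at(int(pos0[j])):
            hits[iv.data].append(j)
    return GeneSNPMap({g: np.asarray(sorted(v), dtype=np.int64) for g, v in hits.items()})
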