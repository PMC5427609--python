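"""Multi-breed genotype panel simulator with planted signatures and sweeps.

The generator stands in for a multi-breed resequencing panel: a handful of
breeds of ~10 diploid samples each, tens of thousands of biallelic SNPs on
one chromosome, breed differentiation produced by Balding-Nichols drift
(per-breed allele frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F) around an
ancestral frequency p), plus planted truth:

* signature genes — one breed near-fixed homozygous for the alternative
  haplotype at every SNP of the gene, the other breeds monomorphic major
  (a breed-private fixed difference, the pattern weighted-MI ranking is
  meant to recover);
* an "opposite-zygosity" gene — the contrast breed heterozygous at every
  gene SNP while the other breeds are major-homozygous, so its ternary-mean
  profile is affine-anticorrelated with the signature-gene profiles and
  should surface as the top negative-edge hub of the gene network;
* hard-sweep footprints — a fraction of one breed's haplotypes replaced by
  copies of a core haplotype, copy fidelity decaying linearly toward the
  footprint edges, giving the long-range haplotype homozygosity XP-EHH
  detects.

Sites are independent outside sweep footprints; there is no recombination
map or demography (see the methods note for what this does and does not
emulate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import HaplotypePanel, SamplePanel, write_genes_bed, write_vcf

_ALLELE_PAIRS = [("A", "T"), ("A", "G"), ("A", "C"), ("C", "G"), ("C", "T"), ("G", "T")]


class SimulationError(ValueError):
    """Infeasible simulation configuration."""


@dataclass
class SweepSpec:
    """A planted hard sweep: breed index, core bp, carrier fraction, footprint bp."""

    breed: int
    core_pos: int
    carrier_fraction: float
    footprint: int


@dataclass
class SimConfig:
    """Study conditions for one simulated panel.

    Defaults emulate the scale of a two-breed contrast drawn from a cattle
    resequencing panel: 10 vs 9 diploid samples, 20,000 SNPs on a 10-Mb
    chromosome (1 SNP / 500 bp), 200 genes of 20 kb tiling the chromosome,
    moderate drift (FST 0.1), 10 signature genes plus one opposite-zygosity
    gene, and one hard sweep (carrier fraction 0.9, 150-kb footprint).
    """

    n_breeds: int = 2
    samples_per_breed: tuple = (10, 9)
    n_sites: int = 20_000
    chrom_length: int = 10_000_000
    chrom: str = "chr1"
    base_freq_beta: tuple = (0.8, 0.8)
    fst: float = 0.1
    n_genes: int = 200
    gene_length: int = 20_000
    signature_genes: int = 10
    signature_breed: int = 0
    opposite_genes: int = 1
    sweep_specs: tuple = ((0, 5_000_000, 0.9, 150_000),)
    seed: int = 42

    def __post_init__(self) -> None:
        self.samples_per_breed = tuple(int(n) for n in self.samples_per_breed)
        self.sweep_specs = tuple(
            s if isinstance(s, SweepSpec) else SweepSpec(*s) for s in self.sweep_specs
        )
        if self.n_breeds < 1 or len(self.samples_per_breed) != self.n_breeds:
            raise SimulationError("need one positive sample count per breed")
        if any(n < 1 for n in self.samples_per_breed):
            raise SimulationError("sample counts must be positive")
        if not (0.0 < self.fst < 1.0):
            raise SimulationError("fst must lie strictly inside (0, 1)")
        if self.n_sites < 1 or self.n_sites > self.chrom_length:
            raise SimulationError("n_sites must be in [1, chrom_length]")
        if self.n_genes * self.gene_length > self.chrom_length:
            raise SimulationError("gene tiling does not fit inside the chromosome")
        if self.signature_genes + self.opposite_genes > self.n_genes:
            raise SimulationError("more planted genes than genes in the annotation")
        if self.signature_breed >= self.n_breeds:
            raise SimulationError("signature_breed out of range")
        for s in self.sweep_specs:
            if not (0 <= s.core_pos < self.chrom_length):
                raise SimulationError(f"sweep core {s.core_pos} outside chromosome")
            if not (0.0 <= s.carrier_fraction <= 1.0):
                raise SimulationError("sweep carrier fraction must be in [0, 1]")
            if s.breed >= self.n_breeds:
                raise SimulationError("sweep breed index out of range")

    @property
    def breed_names(self) -> list:
        return [f"breed{i}" for i in range(self.n_breeds)]


@dataclass
class SimTruth:
    """What was planted: gene ids, sweep windows, ancestral frequencies."""

    planted_gene_ids: list
    opposite_gene_ids: list
    sweep_windows: list  # (chrom, start, end) 0-based half-open
    per_site_ancestral_freq: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = [("signature", g, "", "") for g in self.planted_gene_ids]
        rows += [("opposite_zygosity", g, "", "") for g in self.opposite_gene_ids]
        rows += [
            ("sweep_window", f"{c}:{s}-{e}", s, e) for c, s, e in self.sweep_windows
        ]
        return pd.DataFrame(rows, columns=["kind", "id", "start", "end"])


def tile_genes(config: SimConfig) -> pd.DataFrame:
    """Evenly spaced, non-overlapping gene intervals covering the chromosome."""
    stride = config.chrom_length / config.n_genes
    starts = np.floor(np.arange(config.n_genes) * stride).astype(np.int64)
    return pd.DataFrame(
        {
            "gene_id": [f"g{k:04d}" for k in range(config.n_genes)],
            "chrom": config.chrom,
            "start": starts,
            "end": starts + config.gene_length,
            "strand": ".",
        }
    )


def _sites_in_interval(sites: pd.DataFrame, chrom: str, start: int, end: int) -> np.ndarray:
    pos0 = sites["pos"].to_numpy() - 1
    mask = (sites["chrom"].to_numpy() == chrom) & (pos0 >= start) & (pos0 < end)
    return np.flatnonzero(mask)


def plant_signature_gene(panel: HaplotypePanel, gene, target_breed: int) -> HaplotypePanel:
    """Fix the target breed homozygous for the minor allele across a gene.

    The minor allele at each gene SNP is determined from the panel *before*
    planting (ties break toward allele 1); every haplotype of the target
    breed is set to it. Other breeds are untouched. Modifies and returns the
    panel.
    """
    idx = _sites_in_interval(panel.sites, gene["chrom"], gene["start"], gene["end"])
    if len(idx) == 0:
        raise SimulationError(f"gene {gene.get('gene_id', '?')} contains no SNP sites")
    breed = f"breed{target_breed}" if isinstance(target_breed, (int, np.integer)) else target_breed
    rows = np.flatnonzero(panel.hap_mask(breed))
    if len(rows) == 0:
        raise SimulationError(f"no haplotypes for breed {breed!r}")
    n_hap = panel.haplotypes.shape[0]
    count1 = panel.haplotypes[:, idx].sum(axis=0)
    minor = (count1 * 2 <= n_hap).astype(np.uint8)  # allele 1 minor on ties
    panel.haplotypes[np.ix_(rows, idx)] = minor[None, :]
    return panel


def plant_opposite_gene(panel: HaplotypePanel, gene, het_breed: int) -> HaplotypePanel:
    """Make one breed uniformly heterozygous (and the rest major-hom) in a gene.

    The heterozygous breed gets allele 1 on its first haplotype and 0 on its
    second at every gene SNP; all other breeds are set to 0. The resulting
    ternary-mean profile (1 in the het breed, 0 elsewhere) is exactly
    anticorrelated with a signature-gene profile.
    """
    idx = _sites_in_interval(panel.sites, gene["chrom"], gene["start"], gene["end"])
    if len(idx) == 0:
        raise SimulationError(f"gene {gene.get('gene_id', '?')} contains no SNP sites")
    breed = f"breed{het_breed}" if isinstance(het_breed, (int, np.integer)) else het_breed
    panel.haplotypes[:, idx] = 0
    rows = np.flatnonzero(panel.hap_mask(breed))
    panel.haplotypes[np.ix_(rows[0::2], idx)] = 1
    return panel


def plant_sweep(
    panel: HaplotypePanel, spec: SweepSpec, rng: np.random.Generator, decay: str = "linear"
) -> HaplotypePanel:
    """Copy a core haplotype into a fraction of one breed over a footprint.

    A carrier haplotype takes the template's allele at a footprint site with
    probability equal to the copy fidelity: 1 at the core, decaying linearly
    to 0 at the footprint edge (``decay="none"`` keeps fidelity 1
    throughout). Carrier fraction 0 is a no-op.
    """
    if not (0.0 <= spec.carrier_fraction <= 1.0):
        raise SimulationError("carrier fraction must be in [0, 1]")
    if spec.carrier_fraction == 0.0:
        return panel
    half = spec.footprint / 2.0
    idx = _sites_in_interval(
        panel.sites,
        panel.sites["chrom"].iat[0],
        int(spec.core_pos - half),
        int(spec.core_pos + half),
    )
    if len(idx) == 0:
        return panel
    rows = np.flatnonzero(panel.hap_mask(f"breed{spec.breed}"))
    template = panel.haplotypes[rows[0], idx].copy()
    n_carriers = int(round(spec.carrier_fraction * len(rows)))
    carriers = rng.choice(rows, size=n_carriers, replace=False)
    dist = np.abs(panel.sites["pos"].to_numpy()[idx] - 1 - spec.core_pos)
    if decay == "linear":
        fidelity = np.clip(1.0 - dist / max(half, 1.0), 0.0, 1.0)
    elif decay == "none":
        fidelity = np.ones(len(idx))
    else:
        raise ValueError(f"unknown decay {decay!r}")
    for r in carriers:
        take = rng.random(len(idx)) < fidelity
        panel.haplotypes[r, idx[take]] = template[take]
    return panel


def simulate_panel(config: SimConfig):
    """Draw a panel under the drift model and plant the configured truth.

    Returns ``(panel, genes, truth)``. Identical config + seed reproduce the
    output bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    genes = tile_genes(config)

    positions = np.sort(rng.choice(config.chrom_length, size=config.n_sites, replace=False)) + 1
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=config.n_sites)
    refs = np.array([p[0] for p in _ALLELE_PAIRS], dtype=object)[pair_idx]
    alts = np.array([p[1] for p in _ALLELE_PAIRS], dtype=object)[pair_idx]
    sites = pd.DataFrame({"chrom": config.chrom, "pos": positions, "ref": refs, "alt": alts})

    a, b = config.base_freq_beta
    ancestral = np.clip(rng.beta(a, b, size=config.n_sites), 1e-4, 1 - 1e-4)
    f = config.fst
    n_total = sum(config.samples_per_breed)
    hap = np.empty((2 * n_total, config.n_sites), dtype=np.uint8)
    sample_ids, breed_labels = [], []
    row = 0
    for bi, n_b in enumerate(config.samples_per_breed):
        breed_freq = rng.beta(ancestral * (1 - f) / f, (1 - ancestral) * (1 - f) / f)
        draws = rng.random((2 * n_b, config.n_sites)) < breed_freq[None, :]
        hap[row : row + 2 * n_b] = draws
        row += 2 * n_b
        sample_ids += [f"breed{bi}_s{k:02d}" for k in range(n_b)]
        breed_labels += [f"breed{bi}"] * n_b

    panel = HaplotypePanel(
        samples=SamplePanel(np.array(sample_ids, dtype=object), np.array(breed_labels, dtype=object)),
        sites=sites,
        haplotypes=hap,
    )

    # choose planted genes among genes that actually contain SNPs
    has_snp = np.array(
        [
            len(_sites_in_interval(sites, g.chrom, g.start, g.end)) > 0
            for g in genes.itertuples(index=False)
        ]
    )
    eligible = np.flatnonzero(has_snp)
    n_planted = config.signature_genes + config.opposite_genes
    if len(eligible) < n_planted:
        raise SimulationError(
            f"only {len(eligible)} genes contain SNPs; cannot plant {n_planted}"
        )
    chosen = rng.choice(eligible, size=n_planted, replace=False)
    sig_idx = chosen[: config.signature_genes]
    opp_idx = chosen[config.signature_genes :]

    for gi in sig_idx:
        gene = genes.iloc[int(gi)]
        idx = _sites_in_interval(sites, gene["chrom"], gene["start"], gene["end"])
        # breed-private fixed difference: others monomorphic major, target alt-hom
        panel.haplotypes[:, idx] = 0
        rows = np.flatnonzero(panel.hap_mask(f"breed{config.signature_breed}"))
        panel.haplotypes[np.ix_(rows, idx)] = 1
    # Opposite-zygosity genes: after global major/minor recoding, a signature
    # gene's ternary profile is high in the signature breed if that breed holds
    # at most half the haplotypes, and high in the rest of the panel otherwise
    # (the planted allele then recodes to 0). A gene made heterozygous in one
    # breed always keeps its zygosity in that breed (its allele is the minor
    # one), so planting the heterozygous breed on the *other* side of that
    # split yields an exactly anticorrelated profile.
    n_sig = config.samples_per_breed[config.signature_breed]
    sig_profile_in_signature_breed = 2 * n_sig <= n_total
    if sig_profile_in_signature_breed:
        het_breed = (config.signature_breed + 1) % config.n_breeds
    else:
        het_breed = config.signature_breed
    for gi in opp_idx:
        plant_opposite_gene(panel, genes.iloc[int(gi)], het_breed)

    sweep_windows = []
    for spec in config.sweep_specs:
        plant_sweep(panel, spec, rng)
        half = spec.footprint // 2
        sweep_windows.append(
            (
                config.chrom,
                max(spec.core_pos - half, 0),
                min(spec.core_pos + half, config.chrom_length),
            )
        )

    truth = SimTruth(
        planted_gene_ids=sorted(genes["gene_id"].iloc[sig_idx].tolist()),
        opposite_gene_ids=sorted(genes["gene_id"].iloc[opp_idx].tolist()),
        sweep_windows=sweep_windows,
        per_site_ancestral_freq=ancestral,
    )
    return panel, genes, truth


def write_fixture(panel: HaplotypePanel, genes: pd.DataFrame, truth: SimTruth, out_dir) -> dict:
    """Write VCF + BED + labels TSV + truth TSV; returns the file paths."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": write_vcf(panel, out / "panel.vcf"),
            "genes": write_genes_bed(genes, out / "genes.bed"),
            "labels": out / "labels.tsv",
            "truth": out / "truth.tsv",
        }
        pd.DataFrame(
            {"sample_id": panel.samples.sample_ids, "breed": panel.samples.breed_labels}
        ).to_csv(paths["labels"], sep="\t", index=False)
        truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"writing fixture under {out}: {exc}") from exc
    return paths
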