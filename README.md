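# breedsig

Discovery of breed-specific genetic signatures from multi-breed genotype
panels. The package reimplements, as a tested and reusable pipeline, a
combined information-theoretic and population-genetic workflow for
contrasting one target breed (think trypanotolerant N'Dama cattle) against
a susceptible contrast breed (think Ogaden): which SNPs, genes and genomic
windows set the target breed apart, and how do the zygosity patterns of
those genes covary?

It is aimed at population-genetics practitioners who have phased biallelic
genotypes (VCF), a sample-to-breed label table (TSV) and gene annotations
(BED/GFF3), and want a desk-scale, fully seeded version of this analysis —
plus a synthetic multi-breed panel generator so every stage can be
exercised and validated without any data download.

## What it computes

**Encodings.** Alleles are recoded per site against the panel-wide major
allele ("conserved" → 0, "mutated" → 1); a sample's two binary haplotypes
sum to the ternary genotype code 0/1/2 (major-hom / het / alt-hom).

**Mutual information SNP selection.** For marker *SNP* and breed label *C*,

    I(SNP; C) = Σ_snp Σ_c p(snp, c) ln [ p(snp, c) / (p(snp) p(c)) ]   (nats)

bounded by min(H(SNP), H(C)); a perfectly breed-separating marker in a
10-vs-9 panel attains H(C) ≈ 0.6918 nats. Discriminative selection scans
consecutive same-chromosome site pairs with the two-locus estimator
MIE = I(C; SNP1, SNP2) (chain rule: I(C; SNP1 | SNP2) + I(C; SNP2)),
keeping pairs with MIE > θ and a label-permutation p below a cutoff.

**Weighted-MI gene ranking.** Gene *i* with SNP set g_i scores

    wMI_i = α · Ī(g_i; C) + (1 − α) · |g_i| / max_g |g|

interpolating mean per-SNP MI and normalized SNP count (α = 0.5 by
default); significance from a sample-label permutation null.

**Selection scans.** A full XP-EHH implementation (EHH decay, trapezoidal
iHH, ln(iHH_A/iHH_B) normalized genome-wide, 50-kb windows, SNP-count bins
of 500, within-bin empirical p) and a simplified XP-CLR-style windowed
drift-inflation composite likelihood (600-SNP cap, 0.95 redundancy
down-weighting, top-1% rule). Selected windows ± 25 kb map to candidate
genes; candidate lists intersect with the MI gene list.

**Association tests.** Per-chromosome Fisher enrichment of selected SNPs,
and dominant / recessive (Fisher exact) plus co-dominant (Cochran-Armitage
trend) case-control tests with Bonferroni correction.

**Networks.** Per gene and sample, the mean ternary code is the gene's
"variation"; Pearson correlations of these profiles, thresholded (e.g.
r > 0.45 or r < −0.25), give a signed gene network whose negative-edge
hubs carry zygosity opposite to most of the network.

## Worked example

```python
from breedsig.pipeline import PipelineConfig, run_full_pipeline
from breedsig.simulate import SimConfig

cfg = PipelineConfig(sim=SimConfig(), out_dir="demo_out", seed=17)
report = run_full_pipeline(cfg)
print(report.provenance["stage_counts"])
```

prints (exactly, for this config and seed):

```
{'selected_pairs': 422, 'mi_genes': 13, 'wmi_genes': 173,
 'xpehh_selected_windows': 2, 'xpclr_selected_windows': 2,
 'mi_and_xpclr': 2, 'mi_and_xpehh': 2}
```

Reading: the default simulated panel (2 breeds × (10, 9) samples, 20,000
SNPs on 10 Mb, 200 genes, 10 planted signature genes, one hard sweep at
5 Mb) yields 422 adjacent SNP pairs above θ = 0.5 nats with permutation
p < 1e-3; those pairs fall in 13 genes. 173 genes pass the wMI permutation
cutoff (drift at FST 0.1 is real breed structure, so many genes carry
signal). Both scans select 2 windows each — the two 50-kb windows covering
the planted sweep footprint — and the MI ∩ scan intersections each contain
2 genes. All per-stage tables land in `demo_out/` with a `report.json`
index; rerunning with the same config and seed reproduces every file byte
for byte. The same workflow runs from the shell via `breedsig run`,
`breedsig simulate`, `breedsig wmi`, `breedsig xpehh`, etc. — see
`breedsig --help`.

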