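# Methods

This note records the models, estimators, numerical conventions and design
choices behind `breedsig`, and what the synthetic panels its tests run on
do and do not emulate.

## Data model and encodings

The unit of analysis is a phased biallelic panel: two haplotypes per
diploid sample, one breed label per sample, sites sorted and unique by
(chromosome, position). Internally all coordinates are 0-based half-open;
VCF's 1-based positions are converted only at the I/O boundary, and BED
(0-based) or GFF3 (1-based, converted on read) supply gene intervals.

Each site is recoded against the most frequent allele over *all*
haplotypes of *all* samples: major → 0 ("conserved"), minor → 1
("mutated"). An exact 50/50 tie keeps the REF allele major, which makes
the recode deterministic under any sample ordering and idempotent;
monomorphic sites become all-0 and flow through every downstream stage as
degenerate-but-valid input. The ternary genotype code is the sum of a
sample's two binary allele codes (0 major-hom, 1 het, 2 alt-hom), so per
site the haplotype count of minor alleles always equals
#het + 2·#alt-hom — an identity under test. Multi-allelic records are
dropped rather than decomposed, because the binary encoding is defined for
one major/minor pair; missing or unphased genotypes are rejected by
default (an `allow_unphased` escape hatch degrades the panel to
genotype-level use only).

## Information-theoretic estimators

All entropies and mutual informations are plug-in (maximum-likelihood)
estimates in **nats**. Natural log matters: the largest MI a single
marker can attain against a 10-vs-9 two-breed split is the class-label
entropy H(C) = 0.6918 nats, and the acceptance suite pins a perfect
separator to exactly that value. No small-sample bias correction is
applied; significance is instead assessed by permutation (below).

MI is computed in the joint-sum form Σ p(x,c) ln[p(x,c)/(p(x)p(c))] and,
vectorized across sites, as H(X) + H(C) − H(X,C); the two routes agree to
1e-12 and both are exercised by tests. Conditional MI I(C; S1 | S2) uses
the triple-sum form; the two-locus estimator MIE = I(C; S1, S2) is the MI
of the joint pair symbol and satisfies the chain rule
I(C; S1, S2) = I(C; S1 | S2) + I(C; S2) to 1e-12 on random tables.
Floating-point negatives above −1e-9 are clamped to zero; anything lower
raises, as it would indicate a genuine bug.

MI is evaluated at **haplotype level** by default — 2N observations per
site, each haplotype carrying its sample's breed label — because the
selection statistic is defined over adjacent-locus *haplotypes*; a
genotype-level option exists. Discriminative pair selection evaluates the
MIE on every consecutive same-chromosome site pair (the adjacent-pair
rule keeps the scan linear in the number of sites rather than quadratic
over all pairs) and keeps pairs with MIE > θ (default 0.5 nats) and a
permutation p below the cutoff (default 1e-3). The selected SNP set is
the union of member sites.

Permutation significance everywhere uses the add-one estimator
p = (1 + #{permuted ≥ observed}) / (B + 1), permuting **sample** labels
(both haplotypes of a sample travel together, preserving within-sample
phase and diploidy). B defaults to 1999, making the smallest attainable p
0.0005 — below the 1e-3 selection cutoffs. KL divergence between binned
score distributions is computed after add-ε smoothing (ε = 1e-10) and
renormalization on shared bin edges, and both directions are always
reported since KL is asymmetric.

## Gene-level scores

Per-site MI aggregates to genes through the SNP→gene map (a site may hit
several overlapping genes; genes may be empty). The weighted MI of gene
*i* is the convex interpolation

    wMI_i = α · Ī(g_i; C) + (1 − α) · |g_i| / max_g |g|,

α = 0.5 by default — the value is a free constant of the method and 0.5
weighs discriminativeness and SNP density equally; it is exposed in every
config. wMI is monotone in each factor at the other fixed (tested). The
permutation null of wMI recomputes per-site MI for every label
permutation; only the mean-MI term varies (the count term is label-free),
so the null preserves allele frequencies and gene sizes exactly.
Zero-SNP genes get p = 1 by convention. Per-gene mean/max MI ratios
between two breed-pair analyses use a pseudocount (default 1e-6) to keep
zero-MI genes finite; distribution comparisons across breed pairs use
50 shared histogram bins spanning the pooled range.

## Selection scans

**XP-EHH.** EHH from a core site is the probability that two random
haplotypes of a population are identical at every site from the core out
to a given distance: Σ_h C(e_h, 2)/C(n, 2) over extended-haplotype
groups. The curve starts at (0, 1) — the core's own alleles are not part
of the extension, so the statistic conditions on nothing — is
non-increasing, and is truncated once it falls below 0.05. iHH is the
trapezoidal integral of EHH against physical distance, both directions
summed. Physical distance stands in for genetic distance throughout: the
synthetic panels have no recombination map, and none is assumed; a map
could be substituted by transforming positions before the scan. Raw
XP-EHH per site is ln(iHH_A/iHH_B) (positive = selection in A); sites
with zero iHH on either side are skipped and logged. Scores are
normalized to genome-wide mean 0, sd 1 (exact by construction, tested to
1e-9). The genome is tiled into non-overlapping 50-kb windows; a window's
statistic is the maximum *normalized* score of its SNPs (a config flag
switches to raw). Windows are binned by SNP count in increments of 500
(bin = ⌊n/500⌋) and, within a bin, a window's empirical p is the fraction
of windows with a *strictly greater* statistic — so tied windows all get
p = 0, exactly as the definition reads. The selection set is windows with
a positive statistic and empirical p < 0.01.

**XP-CLR-style scan.** The full sweep-trajectory composite likelihood of
the original XP-CLR program is out of scope; the implemented scan keeps
the windowing conventions (50-kb windows, at most 600 SNPs per window,
SNPs whose genotype-code correlation with an already-kept SNP exceeds
0.95 contributing weight 0, top-1% rule) around a simpler drift-inflation
likelihood: with ω the genome-wide drift variance of population A's
frequencies around B's (method-of-moments median of
(p_A − p_B)²/(p_B(1 − p_B)), a median so planted windows do not inflate
their own null), each window's statistic is the composite log-likelihood
ratio of p_A ~ Normal(p_B, c·ω·p_B(1−p_B) + sampling) maximized over
c ∈ {1, 2, 5, 10, 20, 50, 100} against c = 1. Under the 600-SNP cap,
"most informative" means largest |p_A − p_B| (a deterministic rule; the
choice is not otherwise constrained). B's frequencies are shrunk away
from 0/1 by half a haplotype count for numerical stability. An external
XP-CLR or xpehh score file (whitespace-delimited position + score) can be
dropped in via `scans.read_external_scores`.

Candidate genes are all genes whose interval intersects a selected window
extended by ±25 kb — partial overlap with the flank suffices. Gene-list
intersections (MI ∩ XP-CLR, MI ∩ XP-EHH) are plain set intersections
ordered by gene id.

## Association tests

Per-chromosome enrichment of selected SNPs uses the two-sided Fisher
exact test (scipy's point-probability convention, verified against full
hypergeometric enumeration) on the 2×2 table (on-chromosome?) ×
(selected?), plus the per-chromosome −log10(selected/total) ratio.
Case-control genotype tests collapse the ternary codes per genetic model:
dominant {1,2} vs {0} and recessive {2} vs {0,1} go to two-sided Fisher;
the co-dominant 2×3 table goes to the Cochran-Armitage trend test with
equally spaced scores (0, 1, 2) and no continuity correction —
hand-implemented (no installed package provides it) and verified against
the N·r² identity. All three models are always available because which
one generated a given published p-value is generally not recoverable.
Monomorphic sites get p = 1 and a flag. Multiple testing uses Bonferroni
only (min(1, m·p)); FDR alternatives are deliberately out of scope.

## Zygosity networks

A selected gene's variation profile is, per sample, the mean ternary code
over the gene's SNPs: 0 = reference-like, larger = more heterozygous or
alternative-homozygous. Profiles are computed jointly over both breeds'
samples (the plausible per-breed-then-concatenate alternative changes
little and is not implemented). Pearson correlations of profiles connect
genes; thresholds are strict inequalities (r > pos_cut or r < neg_cut),
matching "larger than / smaller than" semantics, with presets
(0.45, −0.25), (0.8, −0.3), (0.9, −0.4), (0.97, −0.5), (0.9, −0.5).
Zero-variance profiles are excluded and logged rather than assigned
r = 0 — Pearson is undefined for them. Hubs are ranked by degree with
positive/negative breakdowns, ties broken by gene id; the top
negative-edge hub is the gene whose zygosity opposes most of the network.

## The synthetic panel generator

The generator emulates the scale of a two-breed contrast from a
multi-breed resequencing panel: 10 vs 9 diploid samples, 20,000 SNPs on a
10-Mb chromosome, 200 genes of 20 kb tiling it, and moderate
differentiation. Breed structure comes from the Balding–Nichols model:
ancestral frequencies p ~ Beta(0.8, 0.8) (a mildly U-shaped folded
spectrum), per-breed frequencies ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with
F = 0.1 — a between-breed F_ST in the range typical of differentiated
livestock breeds — and haplotype alleles drawn independently per site.

Planted truth:

* **Signature genes** (10 by default): a breed-private fixed difference —
  the target breed alternative-homozygous at every gene SNP, the other
  breeds monomorphic major. Per-site MI at these SNPs equals H(C) exactly.
* **An opposite-zygosity gene** (1 by default): one breed uniformly
  heterozygous across the gene, everyone else major-homozygous. Which
  breed is heterozygous is chosen so the profile anticorrelates (r = −1)
  with the signature profiles: under global major/minor recoding a fixed
  difference leaves the *larger* breed at code 0 (its allele is the
  global major), so with a 10-vs-9 split the signature profiles are high
  in the contrast breed and the heterozygous gene must sit in the target
  breed. An exact "2 − profile" gene is unreachable by fixed differences
  under this recoding; the heterozygous construction achieves the same
  r = −1 and the same top-negative-hub behavior.
* **Hard sweeps**: a fraction (default 0.9) of one breed's haplotypes are
  replaced by copies of a core haplotype over a footprint (default
  150 kb), with copy fidelity decaying linearly from 1 at the core to 0
  at the edges — the simplest monotone footprint; no test asserts the
  decay's shape.

What the generator does **not** emulate: recombination and linkage
outside sweep footprints (sites are independent, so background EHH decays
faster than in real genomes and the XP-EHH contrast is, if anything,
easier than in real data), demography, mutation-rate heterogeneity,
genotyping error, and missing data. Passing recovery tests therefore
demonstrates correctness of the statistics and of the pipeline's
plumbing, not calibrated power on real resequencing panels.

Everything is drawn from one `numpy` Generator seeded from the config:
identical config + seed reproduce panels, fixture files and full pipeline
outputs byte for byte (floats are written with a fixed `%.10g` format and
the report's config hash excludes the output path).

## Calibration and null conventions

Null-calibration runs use panels with **no breed structure** — F_ST
lowered to 0.001 so breeds are exchangeable — because at F_ST 0.1 the
breeds are genuinely differentiated by drift and the label-permutation
null correctly flags that structure (most genes of a drifted panel *are*
breed-informative; the corresponding real-data analysis likewise selects
thousands of genes). On structure-free panels the wMI selection at
p < 1e-3 covers ≲0.1% of genes and the trend test's type-I error at
α = 0.05 sits near 0.047 (slightly conservative from genotype
discreteness at n = 19); both are under test.

## Problem sizes

Test and acceptance runs use the generator's default scale (20k SNPs, 200
genes, 19–20 samples) or a 2k-SNP miniature for unit tests; sweep
detection is measured over 10 seeded replicates, calibrations over 5.
These sizes are where the method's behavior is already unambiguous while
a full run stays in the minutes range on one core.

## Known limitations

* The adjacent-pair MIE scan ignores longer-range haplotype structure by
  construction.
* The XP-CLR-style statistic is a differentiation scan, not a sweep-model
  likelihood; its absolute values are not comparable to the original
  program's (use the external-score reader for that).
* Plug-in MI is upward-biased at small n; the permutation null absorbs
  the bias for selection decisions, but raw MI values should not be
  compared across very different sample sizes.
* With one simulated chromosome the per-chromosome enrichment test is
  exercised only degenerately in the default pipeline; it is fully tested
  on multi-chromosome inputs at unit level.
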