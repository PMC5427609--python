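"""Gene-level aggregation of per-SNP mutual information and wMI ranking.

The weighted MI of gene *i* interpolates its mean per-SNP MI and its
normalized SNP count:

    wMI_i = alpha * mean_MI(g_i) + (1 - alpha) * |g_i| / max_g |g|

so a gene scores highly when it is both SNP-dense and, on average,
breed-discriminative. Significance is assessed against a label-permutation
null of the wMI (add-one p-values); only the mean-MI term varies under
permutation, the count term being label-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mi as _mi
from .io import GeneSNPMap, HaplotypePanel

logger = logging.getLogger(__name__)


@dataclass
class WMIConfig:
    alpha: float = 0.5
    p_cutoff: float = 1e-3
    n_permutations: int = 1999
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")


def aggregate_gene_mi(per_site_mi: np.ndarray, gene_map: GeneSNPMap) -> pd.DataFrame:
    """Per-gene n_snps, mean, max and sum of per-site MI values.

    Genes with zero SNPs get NaN statistics and n_snps = 0.
    """
    per_site_mi = np.asarray(per_site_mi, dtype=float)
    rows = []
    for gene_id, idx in gene_map.assignments.items():
        if len(idx) == 0:
            rows.append((gene_id, 0, np.nan, np.nan, np.nan))
        else:
            v = per_site_mi[idx]
            rows.append((gene_id, len(idx), v.mean(), v.max(), v.sum()))
    return pd.DataFrame(
        rows, columns=["gene_id", "n_snps", "mi_mean", "mi_max", "mi_sum"]
    )


def weighted_mi(stats: pd.DataFrame, alpha: float = 0.5) -> pd.DataFrame:
    """Attach the wMI column: alpha * mean MI + (1 - alpha) * |g| / max |g|."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    max_n = stats["n_snps"].max()
    if not max_n > 0:
        raise ValueError("wMI undefined: no gene contains any SNP")
    out = stats.copy()
    mean_term = out["mi_mean"].fillna(0.0)
    out["wmi"] = alpha * mean_term + (1 - alpha) * out["n_snps"] / max_n
    return out


def wmi_significance(
    panel: HaplotypePanel, gene_map: GeneSNPMap, config: WMIConfig | None = None
) -> pd.DataFrame:
    """wMI per gene with an add-one label-permutation p-value.

    Breed labels are permuted at the sample level (both haplotypes of a
    sample travel together); per-site MI is recomputed for every
    permutation, so the null preserves the panel's allele frequencies and
    the genes' SNP counts. Zero-SNP genes get p = 1.
    """
    config = config or WMIConfig()
    if config.n_permutations < 1:
        raise ValueError("permutation count must be >= 1")
    hap = panel.haplotypes
    labels = panel.samples.breed_labels

    lens = np.array([len(idx) for idx in gene_map.assignments.values()], dtype=np.int64)
    n_genes = len(lens)
    flat_sites = (
        np.concatenate([idx for idx in gene_map.assignments.values() if len(idx)])
        if lens.sum()
        else np.array([], dtype=np.int64)
    )
    flat_gene = np.repeat(np.arange(n_genes), lens)

    def gene_means(site_mi: np.ndarray) -> np.ndarray:
        sums = np.bincount(flat_gene, weights=site_mi[flat_sites], minlength=n_genes)
        return sums / np.maximum(lens, 1)

    observed_site_mi = _mi.per_site_mi(hap, np.repeat(labels, 2))
    stats = aggregate_gene_mi(observed_site_mi, gene_map)
    stats = weighted_mi(stats, config.alpha)
    max_n = stats["n_snps"].max()
    count_term = (1 - config.alpha) * stats["n_snps"].to_numpy() / max_n
    observed_wmi = config.alpha * gene_means(observed_site_mi) + count_term

    rng = np.random.default_rng(config.seed)
    hits = np.zeros(len(observed_wmi), dtype=np.int64)
    for _ in range(config.n_permutations):
        perm = np.repeat(rng.permutation(labels), 2)
        null_wmi = config.alpha * gene_means(_mi.per_site_mi(hap, perm)) + count_term
        hits += null_wmi >= observed_wmi
    p = (1 + hits) / (config.n_permutations + 1)
    p[stats["n_snps"].to_numpy() == 0] = 1.0
    stats["p_value"] = p
    stats["selected"] = (stats["p_value"] < config.p_cutoff) & (stats["n_snps"] > 0)
    return stats


def select_genes(stats: pd.DataFrame, p_cutoff: float = 1e-3) -> list:
    """Gene ids passing the wMI permutation cutoff, sorted by id."""
    sel = stats.loc[(stats["p_value"] < p_cutoff) & (stats["n_snps"] > 0), "gene_id"]
    return sorted(sel.tolist())


def mi_ratio_profiles(
    stats_a: pd.DataFrame, stats_b: pd.DataFrame, pseudocount: float = 1e-6
) -> pd.DataFrame:
    """Per-gene ratios of mean and max MI between two breed-pair analyses.

    Genes present on only one side are excluded (and logged); zero-SNP
    genes on either side are likewise dropped.
    """
    a = stats_a.set_index("gene_id")
    b = stats_b.set_index("gene_id")
    shared = a.index.intersection(b.index)
    missing = len(a.index.symmetric_difference(b.index))
    if missing:
        logger.info("mi_ratio_profiles: %d genes present on one side only", missing)
    a, b = a.loc[shared], b.loc[shared]
    ok = (a["n_snps"] > 0) & (b["n_snps"] > 0)
    eps = pseudocount
    return pd.DataFrame(
        {
            "gene_id": shared[ok.to_numpy()],
            "ratio_mean": (a.loc[ok, "mi_mean"] + eps).to_numpy()
            / (b.loc[ok, "mi_mean"] + eps).to_numpy(),
            "ratio_max": (a.loc[ok, "mi_max"] + eps).to_numpy()
            / (b.loc[ok, "mi_max"] + eps).to_numpy(),
        }
    ).reset_index(drop=True)


def compare_pair_analyses_kl(
    stats_a: pd.DataFrame, stats_b: pd.DataFrame, n_bins: int = 50
) -> dict:
    """KL divergence between two analyses' per-gene MI distributions.

    Histograms of the mean-MI and max-MI summaries are formed on shared
    edges spanning the pooled range; both divergence directions are
    reported (KL is not symmetric).
    """
    if n_bins < 2:
        raise ValueError("need at least two histogram bins")
    out = {}
    for col in ("mi_mean", "mi_max"):
        va = stats_a.loc[stats_a["n_snps"] > 0, col].to_numpy(dtype=float)
        vb = stats_b.loc[stats_b["n_snps"] > 0, col].to_numpy(dtype=float)
        pooled = np.concatenate([va, vb])
        edges = np.histogram_bin_edges(pooled, bins=n_bins)
        ha, _ = np.histogram(va, bins=edges)
        hb, _ = np.histogram(vb, bins=edges)
        out[col] = {
            "kl_ab": _mi.kl_divergence(ha, hb),
            "kl_ba": _mi.kl_divergence(hb, ha),
        }
    return out
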