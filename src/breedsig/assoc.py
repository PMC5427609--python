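"""Contingency-table tests: chromosome enrichment and case-control models.

* ``chromosome_enrichment`` — per chromosome, a two-sided Fisher exact test
  of the 2x2 table (SNP on this chromosome?) x (SNP selected?), plus the
  negative-log ratio of selected to total SNPs per chromosome.
* ``case_control_test`` — per site, the dominant ({1,2} vs {0}) and
  recessive ({2} vs {0,1}) collapses tested by two-sided Fisher exact on
  2x2 tables, and the co-dominant 2x3 table tested by the Cochran-Armitage
  trend test with equally spaced scores (0, 1, 2), no continuity
  correction. Bonferroni correction over tested sites.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2, fisher_exact
from statsmodels.stats.multitest import multipletests

MODELS = ("dominant", "recessive", "codominant")


def cochran_armitage(table_2x3: np.ndarray, scores=(0.0, 1.0, 2.0)) -> tuple:
    """Cochran-Armitage trend chi-square and two-sided p for a 2x3 table.

    Rows are the two groups, columns the genotype codes. Returns
    ``(statistic, p)``; a table with no genotype spread (or an empty group)
    yields statistic 0 and p = 1.
    """
    t = np.asarray(table_2x3, dtype=float)
    if t.shape != (2, 3):
        raise ValueError("expected a 2x3 table")
    s = np.asarray(scores, dtype=float)
    n_cols = t.sum(axis=0)  # genotype margins
    r = t[0]  # group-1 counts per genotype
    n = t.sum()
    big_r = r.sum()
    if n == 0 or big_r == 0 or big_r == n:
        return 0.0, 1.0
    num = n * (s * r).sum() - big_r * (s * n_cols).sum()
    den = big_r * (n - big_r) * (n * (s**2 * n_cols).sum() - ((s * n_cols).sum()) ** 2)
    if den <= 0:
        return 0.0, 1.0
    stat = num**2 * n / den
    return float(stat), float(chi2.sf(stat, df=1))


def genotype_table(codes: np.ndarray, group_mask: np.ndarray) -> np.ndarray:
    """2x3 genotype count table for one site: rows (group, rest)."""
    t = np.zeros((2, 3))
    for g in (0, 1, 2):
        t[0, g] = int(((codes == g) & group_mask).sum())
        t[1, g] = int(((codes == g) & ~group_mask).sum())
    return t


def case_control_test(
    ternary_codes: np.ndarray,
    labels: np.ndarray,
    case_label,
    model: str,
    sites: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-site genotype association tests under one genetic model.

    Monomorphic sites get p = 1 and are flagged. Bonferroni multiplies each
    p by the number of tested sites, capped at 1.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    labels = np.asarray(labels)
    group = labels == case_label
    if group.all() or not group.any():
        raise ValueError("both groups must be non-empty")
    n_sites = ternary_codes.shape[1]
    pvals = np.ones(n_sites)
    stats = np.zeros(n_sites)
    direction = np.zeros(n_sites)
    mono = np.zeros(n_sites, dtype=bool)
    for j in range(n_sites):
        codes = ternary_codes[:, j]
        if (codes == codes[0]).all():
            mono[j] = True
            continue
        t = genotype_table(codes, group)
        if model == "codominant":
            stats[j], pvals[j] = cochran_armitage(t)
            mean_case = codes[group].mean()
            mean_ctrl = codes[~group].mean()
            direction[j] = np.sign(mean_case - mean_ctrl)
        else:
            if model == "dominant":
                a, b = t[0, 1] + t[0, 2], t[0, 0]
                c, d = t[1, 1] + t[1, 2], t[1, 0]
            else:  # recessive
                a, b = t[0, 2], t[0, 0] + t[0, 1]
                c, d = t[1, 2], t[1, 0] + t[1, 1]
            stats[j], pvals[j] = fisher_exact([[a, b], [c, d]], alternative="two-sided")
            n1, n2 = a + b, c + d
            direction[j] = np.sign(a / n1 - c / n2) if n1 and n2 else 0.0
    out = pd.DataFrame(
        {
            "model": model,
            "stat": stats,
            "p": pvals,
            "bonferroni_p": bonferroni(pvals),
            "direction": direction,
            "monomorphic": mono,
        }
    )
    if sites is not None:
        out.insert(0, "pos", sites["pos"].to_numpy())
        out.insert(0, "chrom", sites["chrom"].to_numpy())
    return out


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni-corrected p-values: min(1, m * p), order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="bonferroni")[1]


def chromosome_enrichment(
    selected_flags: np.ndarray, chromosome_of_snp: np.ndarray
) -> pd.DataFrame:
    """Per-chromosome Fisher enrichment of selected SNPs.

    For each chromosome the 2x2 table is (on-chrom vs off-chrom) x
    (selected vs not), tested two-sided. Also reports the per-chromosome
    selected/total ratio on a negative-log10 scale (lower = more enriched;
    infinite when no SNP on the chromosome is selected).
    """
    sel = np.asarray(selected_flags, dtype=bool)
    chrom = np.asarray(chromosome_of_snp)
    rows = []
    total_sel = int(sel.sum())
    total = len(sel)
    for c in pd.unique(chrom):
        on = chrom == c
        n_on = int(on.sum())
        if n_on == 0:
            continue
        a = int((sel & on).sum())
        b = n_on - a
        cc = total_sel - a
        d = (total - n_on) - cc
        _, p = fisher_exact([[a, b], [cc, d]], alternative="two-sided")
        ratio = a / n_on
        rows.append(
            (c, n_on, a, p, ratio, -np.log10(ratio) if ratio > 0 else np.inf)
        )
    out = pd.DataFrame(
        rows, columns=["chrom", "n_snps", "n_selected", "p", "ratio", "neg_log10_ratio"]
    )
    out["bonferroni_p"] = bonferroni(out["p"].to_numpy())
    return out
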