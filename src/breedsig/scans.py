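"""Cross-population selection scans: XP-EHH and a simplified XP-CLR.

XP-EHH follows the standard construction: per core site, extended
haplotype homozygosity (EHH) is the probability that two random haplotypes
of a population are identical over all sites from the core out to a given
distance; its integral over physical distance (iHH, trapezoidal, both
directions) is compared between two populations as raw = ln(iHH_A/iHH_B),
normalized genome-wide to mean 0 / sd 1. Positive normalized scores point
to selection in population A. The genome is tiled into non-overlapping
50-kb windows; each window's statistic is the maximum normalized score of
its SNPs; windows are binned by SNP count in increments of 500 and, within
a bin, a window's empirical p-value is the fraction of windows with a
strictly greater statistic. Windows with a positive statistic and
empirical p < 0.01 form the selection set.

The XP-CLR-style scan is a deliberately simplified drift-inflation
composite likelihood on windowed allele frequencies (not the full
sweep-trajectory model): within each 50-kb window (at most 600
most-differentiated SNPs, SNPs correlated > 0.95 with an already kept SNP
contributing weight 0), the log-likelihood of population A's frequencies
around population B's under an inflated drift variance c * omega
(maximized over a grid of c) is compared with the genome-wide neutral
variance omega. Physical distance substitutes for genetic distance
throughout (no recombination map).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)


@dataclass
class EHHCurve:
    """EHH decay from a core outward: (distance bp, EHH) pairs, EHH(0) = 1."""

    core_index: int
    direction: str  # "left" | "right"
    distances: np.ndarray
    values: np.ndarray


@dataclass
class XPCLRConfig:
    window_bp: int = 50_000
    max_snps_per_window: int = 600
    redundancy_r: float = 0.95
    drift_grid: tuple = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0)
    top_fraction: float = 0.01
    omega: float | None = None  # genome-wide drift variance; estimated if None

    def __post_init__(self) -> None:
        if not (0.0 < self.redundancy_r <= 1.0):
            raise ValueError("redundancy cutoff must be in (0, 1]")
        if len(self.drift_grid) == 0:
            raise ValueError("drift grid must be nonempty")


def ehh(
    haplotypes: np.ndarray,
    core_index: int,
    direction: str,
    positions: np.ndarray,
    truncation: float = 0.05,
) -> EHHCurve:
    """EHH curve from a core site outward over one set of haplotypes.

    At each successive site the haplotypes are partitioned by their alleles
    over all sites traversed so far; EHH is sum_h C(e_h, 2) / C(n, 2) over
    group sizes e_h. The curve starts at (0, 1) and stops once EHH falls
    below ``truncation`` (the crossing point is kept).
    """
    h = np.asarray(haplotypes)
    n = h.shape[0]
    if n < 2:
        raise ValueError("EHH requires at least two haplotypes")
    if direction == "right":
        idx = range(core_index + 1, h.shape[1])
    elif direction == "left":
        idx = range(core_index - 1, -1, -1)
    else:
        raise ValueError(f"direction must be 'left' or 'right', got {direction!r}")
    positions = np.asarray(positions)
    denom = n * (n - 1) / 2.0
    groups = np.zeros(n, dtype=np.int64)
    dists, vals = [0.0], [1.0]
    for j in idx:
        _, groups = np.unique(groups * 2 + h[:, j], return_inverse=True)
        counts = np.bincount(groups)
        e = float((counts * (counts - 1) / 2.0).sum() / denom)
        dists.append(abs(float(positions[j] - positions[core_index])))
        vals.append(e)
        if e < truncation:
            break
    return EHHCurve(core_index, direction, np.asarray(dists), np.asarray(vals))


def ihh(curve_left: EHHCurve, curve_right: EHHCurve) -> float:
    """Integrated EHH: trapezoidal area under both directional curves, in bp."""
    total = 0.0
    for c in (curve_left, curve_right):
        if len(c.distances) < 2:
            logger.warning("empty EHH curve at core %d; contributes 0", c.core_index)
            continue
        total += float(np.trapezoid(c.values, c.distances))
    return total


def site_ihh(haplotypes: np.ndarray, positions: np.ndarray, core: int, truncation: float = 0.05) -> float:
    left = ehh(haplotypes, core, "left", positions, truncation)
    right = ehh(haplotypes, core, "right", positions, truncation)
    return ihh(left, right)


def tile_windows(sites: pd.DataFrame, window_bp: int = 50_000) -> pd.DataFrame:
    """Non-overlapping window tiling; every SNP falls in exactly one window."""
    frames = []
    for chrom, grp in sites.groupby("chrom", sort=True):
        pos0 = grp["pos"].to_numpy() - 1
        w = pos0 // window_bp
        for wi in np.unique(w):
            frames.append(
                (chrom, int(wi) * window_bp, (int(wi) + 1) * window_bp, int((w == wi).sum()))
            )
    return pd.DataFrame(frames, columns=["chrom", "start", "end", "n_snps"])


def xpehh_scan(
    panel_a_hap: np.ndarray,
    panel_b_hap: np.ndarray,
    sites: pd.DataFrame,
    window_bp: int = 50_000,
    truncation: float = 0.05,
    use_normalized: bool = True,
):
    """Per-site XP-EHH scores and per-window maxima.

    Returns ``(site_scores, window_scores)`` frames. Sites where either
    population's iHH is 0 are skipped (and logged). Raw scores are
    antisymmetric under swapping the populations; normalized scores have
    genome-wide mean 0 and sd 1 by construction.
    """
    if panel_a_hap.shape[1] != panel_b_hap.shape[1] or panel_a_hap.shape[1] != len(sites):
        raise ValueError("both populations must cover the same sites")
    positions = sites["pos"].to_numpy()
    chrom_arr = sites["chrom"].to_numpy()
    n_sites = len(sites)
    raw = np.full(n_sites, np.nan)
    n_skipped = 0
    for chrom in pd.unique(chrom_arr):
        cidx = np.flatnonzero(chrom_arr == chrom)
        pos_c = positions[cidx]
        ha = panel_a_hap[:, cidx]
        hb = panel_b_hap[:, cidx]
        for k in range(len(cidx)):
            ia = site_ihh(ha, pos_c, k, truncation)
            ib = site_ihh(hb, pos_c, k, truncation)
            if ia <= 0 or ib <= 0:
                n_skipped += 1
                continue
            raw[cidx[k]] = np.log(ia / ib)
    if n_skipped:
        logger.info("xpehh: skipped %d sites with zero iHH", n_skipped)
    ok = ~np.isnan(raw)
    mu = raw[ok].mean()
    sd = raw[ok].std()
    norm_scores = np.full(n_sites, np.nan)
    norm_scores[ok] = (raw[ok] - mu) / sd if sd > 0 else 0.0

    site_scores = pd.DataFrame(
        {
            "chrom": chrom_arr,
            "pos": positions,
            "xpehh_raw": raw,
            "xpehh_norm": norm_scores,
        }
    )
    windows = tile_windows(sites, window_bp)
    stat_col = "xpehh_norm" if use_normalized else "xpehh_raw"
    stats = []
    for w in windows.itertuples(index=False):
        mask = (
            (chrom_arr == w.chrom)
            & (positions - 1 >= w.start)
            & (positions - 1 < w.end)
            & ok
        )
        stats.append(np.nanmax(site_scores.loc[mask, stat_col]) if mask.any() else np.nan)
    windows = windows.copy()
    windows["stat"] = stats
    return site_scores, windows


def bin_and_empirical_p(
    windows: pd.DataFrame, bin_increment: int = 500, p_cutoff: float = 0.01
) -> pd.DataFrame:
    """SNP-count binning and within-bin empirical p-values.

    bin = floor(n_snps / increment); empirical_p(i) = #{j in bin :
    stat_j > stat_i} / (bin size) — strict inequality, so tied windows all
    receive p = 0 within a bin of ties. The selection flag requires a
    positive statistic and empirical_p < ``p_cutoff``. Windows with an
    undefined statistic are excluded from their bin's denominator.
    """
    out = windows.copy()
    out["bin"] = out["n_snps"] // bin_increment
    emp = np.full(len(out), np.nan)
    stat = out["stat"].to_numpy(dtype=float)
    for b in out["bin"].unique():
        idx = np.flatnonzero((out["bin"].to_numpy() == b) & ~np.isnan(stat))
        if len(idx) == 0:
            continue
        vals = stat[idx]
        # fraction strictly greater, computed by rank: count of larger values
        order = np.argsort(vals, kind="stable")
        greater = len(vals) - np.searchsorted(np.sort(vals), vals, side="right")
        emp[idx] = greater / len(vals)
    out["empirical_p"] = emp
    out["selected"] = (out["stat"] > 0) & (out["empirical_p"] < p_cutoff)
    return out


def estimate_drift_variance(freq_a: np.ndarray, freq_b: np.ndarray) -> float:
    """Genome-wide neutral drift variance omega of A's frequencies around B's.

    Method of moments on (pA - pB)^2 / (pB (1 - pB)) over sites polymorphic
    in B; robust to planted outlier windows via the median (scaled to the
    mean of a half-normal-ish spread would over-fit — the median of the
    per-site ratios is used directly as a conservative scale).
    """
    ok = (freq_b > 0.0) & (freq_b < 1.0)
    if not ok.any():
        raise ValueError("population B is monomorphic everywhere")
    ratio = (freq_a[ok] - freq_b[ok]) ** 2 / (freq_b[ok] * (1 - freq_b[ok]))
    return float(max(np.median(ratio), 1e-6))


def _window_xpclr_stat(
    pa: np.ndarray,
    pb: np.ndarray,
    codes_window: np.ndarray,
    omega: float,
    config: XPCLRConfig,
    n_hap_a: int,
) -> float:
    """Composite LR of inflated drift vs neutral for one window's SNPs."""
    poly = ((pa > 0) & (pa < 1)) | ((pb > 0) & (pb < 1))
    idx = np.flatnonzero(poly)
    if len(idx) == 0:
        return 0.0
    order = idx[np.argsort(-np.abs(pa[idx] - pb[idx]), kind="stable")]
    sub = codes_window[:, order].astype(float)
    sd = sub.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub.T) if sub.shape[1] > 1 else np.ones((1, 1))
    kept: list[int] = []  # positions within `order`
    for t in range(len(order)):
        if len(kept) >= config.max_snps_per_window:
            break
        if sd[t] > 0 and any(
            sd[k] > 0 and abs(corr[t, k]) > config.redundancy_r for k in kept
        ):
            continue  # weight 0: redundant with an already-kept SNP
        kept.append(t)
    kept = [int(order[t]) for t in kept]
    if not kept:
        return 0.0
    kept_arr = np.asarray(kept)
    pb_s = np.clip(pb[kept_arr], 1.0 / (2 * n_hap_a), 1 - 1.0 / (2 * n_hap_a))
    pa_s = pa[kept_arr]
    base_var = pb_s * (1 - pb_s)
    sampling = base_var / n_hap_a

    def loglik(c: float) -> float:
        var = c * omega * base_var + sampling
        return float(norm.logpdf(pa_s, loc=pb_s, scale=np.sqrt(var)).sum())

    ll_neutral = loglik(1.0)
    ll_best = max(loglik(c) for c in config.drift_grid)
    return max(ll_best - ll_neutral, 0.0)


def xpclr_lite(
    codes_a: np.ndarray,
    codes_b: np.ndarray,
    sites: pd.DataFrame,
    config: XPCLRConfig | None = None,
) -> pd.DataFrame:
    """Windowed drift-inflation composite-likelihood scan.

    ``codes_a`` / ``codes_b`` are ternary genotype matrices (samples x
    sites) of the two populations on shared sites. Returns the window frame
    with the LR statistic and a top-fraction selection flag.
    """
    config = config or XPCLRConfig()
    if codes_a.shape[1] != codes_b.shape[1] or codes_a.shape[1] != len(sites):
        raise ValueError("populations must share the site set")
    n_hap_a = 2 * codes_a.shape[0]
    pa = codes_a.sum(axis=0) / n_hap_a
    pb = codes_b.sum(axis=0) / (2 * codes_b.shape[0])
    omega = config.omega if config.omega is not None else estimate_drift_variance(pa, pb)

    codes_all = np.vstack([codes_a, codes_b])
    positions = sites["pos"].to_numpy()
    chrom_arr = sites["chrom"].to_numpy()
    windows = tile_windows(sites, config.window_bp)
    stats = []
    for w in windows.itertuples(index=False):
        mask = (chrom_arr == w.chrom) & (positions - 1 >= w.start) & (positions - 1 < w.end)
        widx = np.flatnonzero(mask)
        stats.append(
            _window_xpclr_stat(
                pa[widx], pb[widx], codes_all[:, widx], omega, config, n_hap_a
            )
        )
    windows = windows.copy()
    windows["stat"] = stats
    n_top = max(int(np.ceil(config.top_fraction * len(windows))), 1)
    cutoff = np.sort(windows["stat"].to_numpy())[-n_top]
    windows["selected"] = (windows["stat"] >= cutoff) & (windows["stat"] > 0)
    return windows


def assign_candidate_genes(
    selected_windows: pd.DataFrame, genes: pd.DataFrame, flank: int = 25_000
) -> list:
    """Genes intersecting any selected window extended by +-flank bp."""
    out = set()
    for w in selected_windows.itertuples(index=False):
        lo, hi = w.start - flank, w.end + flank
        hit = genes[
            (genes["chrom"] == w.chrom) & (genes["start"] < hi) & (genes["end"] > lo)
        ]
        out.update(hit["gene_id"].tolist())
    return sorted(out)


def intersect_gene_lists(list_a, list_b) -> list:
    """Set intersection of two gene-id lists, ordered by gene id."""
    return sorted(set(list_a) & set(list_b))


def read_external_scores(path, sites: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a whitespace-delimited external score file (position, score).

    Accepts optional leading chrom column; used to drop in scores from the
    published XP-CLR / xpehh programs in place of the internal scans.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    if df.shape[1] >= 3:
        df = df.iloc[:, :3]
        df.columns = ["chrom", "pos", "score"]
    else:
        df.columns = ["pos", "score"]
        df.insert(0, "chrom", sites["chrom"].iat[0] if sites is not None else "chr1")
    df["pos"] = df["pos"].astype(int)
    df["score"] = df["score"].astype(float)
    return df
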