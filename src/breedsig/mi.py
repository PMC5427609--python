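"""Information-theoretic estimators for SNP-breed association.

All quantities are in nats (natural log) and use plug-in (maximum
likelihood) probability estimates: with a 10-vs-9 two-breed split the
class-label entropy — and hence the largest attainable single-marker MI —
is H = 0.6918 nats, the ceiling a perfectly breed-separating marker hits.

Estimators:

* ``entropy`` / ``mutual_information`` — H(X) and I(SNP; C).
* ``conditional_mi`` — I(C; SNP1 | SNP2), the triple-sum form.
* ``mie_two_locus`` — the two-locus estimator I(C; SNP1, SNP2) via the
  joint (adjacent-pair haplotype) variable; equals the chain-rule sum.
* ``select_discriminative_pairs`` — scans consecutive same-chromosome site
  pairs at haplotype level and keeps those with MIE above a threshold theta
  and a permutation p-value below a cutoff.
* ``permutation_pvalue`` — add-one label-permutation significance.
* ``kl_divergence`` — smoothed Kullback-Leibler divergence on shared bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_NEG_TOL = 1e-9  # floating-point guard: tiny negative MI is clamped to 0


@dataclass
class MIEstimate:
    """An MI (or MIE) value with optional permutation significance."""

    value: float
    p_value: float | None = None
    n_permutations: int = 0
    seed: int | None = None


@dataclass
class MIEConfig:
    """Configuration for adjacent-pair discriminative SNP selection."""

    theta: float = 0.5
    p_cutoff: float = 1e-3
    n_permutations: int = 1999
    seed: int = 0
    level: str = "haplotype"  # or "genotype"


def _as_codes(x) -> np.ndarray:
    """Map an arbitrary discrete vector to contiguous integer codes."""
    _, codes = np.unique(np.asarray(x), return_inverse=True)
    return codes


def entropy(counts) -> float:
    """Plug-in entropy -sum p ln p of a count vector, with 0 ln 0 := 0."""
    c = np.asarray(counts, dtype=float).ravel()
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    total = c.sum()
    if total <= 0:
        raise ValueError("entropy of an all-zero count vector is undefined")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def _mi_from_joint(joint: np.ndarray) -> float:
    """MI from a joint count table: sum p(x,y) ln[p(x,y)/(p(x)p(y))]."""
    joint = np.asarray(joint, dtype=float)
    total = joint.sum()
    if total <= 0:
        raise ValueError("empty joint table")
    p = joint / total
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    val = float((p[nz] * np.log(p[nz] / (px * py)[nz])).sum())
    if val < -_NEG_TOL:
        raise FloatingPointError(f"MI evaluated to {val}")
    return max(val, 0.0)


def joint_counts(x, y) -> np.ndarray:
    """Joint count table of two equal-length discrete vectors."""
    xc, yc = _as_codes(x), _as_codes(y)
    if len(xc) != len(yc):
        raise ValueError("vectors must have equal length")
    nx, ny = xc.max() + 1, yc.max() + 1
    return np.bincount(xc * ny + yc, minlength=nx * ny).reshape(nx, ny)


def mutual_information(snp_values, class_labels) -> float:
    """I(SNP; C) in nats between a marker vector and class labels."""
    labels = np.asarray(class_labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("mutual information requires at least two classes")
    return _mi_from_joint(joint_counts(snp_values, labels))


def mi_with_significance(
    snp_values, class_labels, n_permutations: int = 999, seed: int = 0
) -> MIEstimate:
    """MI plus an add-one label-permutation p-value."""
    value = mutual_information(snp_values, class_labels)
    p = permutation_pvalue(
        mutual_information, snp_values, class_labels, n_permutations, seed
    )
    return MIEstimate(value=value, p_value=p, n_permutations=n_permutations, seed=seed)


def conditional_mi(s1, s2, labels) -> float:
    """I(C; SNP1 | SNP2): triple sum over (c, s1, s2), clamped at 0."""
    c = _as_codes(labels)
    a = _as_codes(s1)
    b = _as_codes(s2)
    if not (len(a) == len(b) == len(c)):
        raise ValueError("vectors must have equal length")
    if c.max() == 0:
        raise ValueError("conditional MI requires at least two classes")
    nc, na, nb = c.max() + 1, a.max() + 1, b.max() + 1
    joint = np.bincount(
        (c * na + a) * nb + b, minlength=nc * na * nb
    ).reshape(nc, na, nb).astype(float)
    total = joint.sum()
    p = joint / total
    p_b = p.sum(axis=(0, 1))  # p(s2)
    p_cb = p.sum(axis=1)  # p(c, s2)
    p_ab = p.sum(axis=0)  # p(s1, s2)
    nz = p > 0
    num = p_b[None, None, :] * p
    den = p_cb[:, None, :] * p_ab[None, :, :]
    val = float((p[nz] * np.log(num[nz] / den[nz])).sum())
    if val < -_NEG_TOL:
        raise FloatingPointError(f"conditional MI evaluated to {val}")
    return max(val, 0.0)


def mie_two_locus(s1, s2, labels) -> float:
    """I(C; SNP1, SNP2): MI between labels and the joint two-locus symbol.

    By the chain rule this equals I(C; SNP1 | SNP2) + I(C; SNP2); the two
    routes agree to numerical precision and the identity is under test.
    """
    a = _as_codes(s1)
    b = _as_codes(s2)
    if len(a) != len(b):
        raise ValueError("vectors must have equal length")
    joint_symbol = a * (b.max() + 1) + b
    return mutual_information(joint_symbol, labels)


def permutation_pvalue(stat_fn, values, labels, n_perm: int, seed: int = 0) -> float:
    """Add-one permutation p: (1 + #{permuted >= observed}) / (n_perm + 1)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    observed = stat_fn(values, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        hits += stat_fn(values, rng.permutation(labels)) >= observed
    return (1 + hits) / (n_perm + 1)


def columnwise_mi(values: np.ndarray, labels) -> np.ndarray:
    """Vectorized I(X_j; C) for every column of a small-alphabet matrix.

    ``values`` is (n_obs, n_cols) of small nonnegative integers (alleles,
    ternary codes, or joint pair symbols); ``labels`` is one class label per
    observation. Computed as H(X) + H(C) - H(X, C) from the per-column
    count tables, exact for plug-in estimates.
    """
    v = np.asarray(values)
    labels = _as_codes(labels)
    n_classes = labels.max() + 1
    if n_classes < 2:
        raise ValueError("at least two classes required")
    n_obs = v.shape[0]
    n_values = int(v.max()) + 1 if v.size else 1
    onehot = np.zeros((n_classes, n_obs))
    onehot[labels, np.arange(n_obs)] = 1.0

    def _plug_h(counts):  # plug-in entropy of each column of a count stack
        p = counts / n_obs
        return -np.where(p > 0, p * np.log(np.maximum(p, 1e-300)), 0.0).sum(axis=0)

    joint = np.empty((n_classes * n_values, v.shape[1]))
    for sym in range(n_values):
        joint[sym * n_classes : (sym + 1) * n_classes] = onehot @ (v == sym)
    marg = joint.reshape(n_values, n_classes, -1).sum(axis=1)
    mi = _plug_h(marg) + entropy(onehot.sum(axis=1)) - _plug_h(joint)
    return np.clip(mi, 0.0, None)


def per_site_mi(haplotypes: np.ndarray, hap_labels) -> np.ndarray:
    """Vectorized I(SNP; C) for every column of a binary haplotype matrix.

    Each haplotype is one observation carrying its sample's breed label.
    """
    return columnwise_mi(haplotypes, hap_labels)


def adjacent_pair_mie(panel, labels=None, level: str = "haplotype") -> "np.ndarray":
    """MIE for each consecutive same-chromosome site pair of a panel.

    Returns a structured record array with fields (i, j, mie). At haplotype
    level the joint symbol is the two-site haplotype of each of the 2N
    haplotypes; at genotype level it is the pair of ternary codes.
    """
    from . import io as _io

    if level == "haplotype":
        mat = panel.haplotypes
        labs = panel.hap_breeds if labels is None else np.repeat(labels, 2)
    elif level == "genotype":
        tern = _io.ternary_encode(panel)
        mat = tern.codes
        labs = panel.samples.breed_labels if labels is None else np.asarray(labels)
    else:
        raise ValueError(f"unknown level {level!r}")
    chrom = panel.sites["chrom"].to_numpy()
    if panel.n_sites < 2:
        return np.array([], dtype=[("i", np.int64), ("j", np.int64), ("mie", float)])
    left = np.flatnonzero(chrom[:-1] == chrom[1:])
    if len(left) == 0:
        return np.array([], dtype=[("i", np.int64), ("j", np.int64), ("mie", float)])
    n_sym = int(mat.max()) + 1
    symbols = mat[:, left].astype(np.int64) * n_sym + mat[:, left + 1]
    mie = columnwise_mi(symbols, labs)
    out = np.empty(len(left), dtype=[("i", np.int64), ("j", np.int64), ("mie", float)])
    out["i"], out["j"], out["mie"] = left, left + 1, mie
    return out


def select_discriminative_pairs(panel, labels=None, config: MIEConfig | None = None):
    """Adjacent-pair MIE selection F(X; y): keep pairs with MIE > theta.

    Pairs passing theta are additionally screened by an add-one label
    permutation p-value (permutation of sample labels, carried to both
    haplotypes of a sample). Returns a list of (i, j, mie, p) tuples; the
    selected SNP set is the union of the member sites.
    """
    config = config or MIEConfig()
    pairs = adjacent_pair_mie(panel, labels, level=config.level)
    if len(pairs) == 0:
        logger.warning("no adjacent same-chromosome site pairs; empty selection")
        return []
    candidates = pairs[pairs["mie"] > config.theta]
    if len(candidates) == 0:
        return []

    sample_labels = panel.samples.breed_labels if labels is None else np.asarray(labels)
    rng = np.random.default_rng(config.seed)
    if config.level == "haplotype":
        mat = panel.haplotypes
    else:
        from . import io as _io

        mat = _io.ternary_encode(panel).codes
    n_sym = int(mat.max()) + 1
    # joint pair symbol per observation, one column per candidate pair
    ci = candidates["i"].astype(np.int64)
    cj = candidates["j"].astype(np.int64)
    symbols = mat[:, ci].astype(np.int64) * n_sym + mat[:, cj]
    observed = candidates["mie"]

    # label permutations at sample level (both haplotypes travel together)
    hits = np.zeros(len(candidates), dtype=np.int64)
    for _ in range(config.n_permutations):
        perm = rng.permutation(sample_labels)
        labs = np.repeat(perm, 2) if config.level == "haplotype" else perm
        hits += columnwise_mi(symbols, labs) >= observed
    p = (1 + hits) / (config.n_permutations + 1)
    keep = p < config.p_cutoff
    return [
        (int(i), int(j), float(v), float(pp))
        for i, j, v, pp in zip(ci[keep], cj[keep], observed[keep], p[keep])
    ]


def selected_site_union(pairs) -> np.ndarray:
    """Union of member site indices over selected pairs (the set X*)."""
    idx = set()
    for i, j, *_ in pairs:
        idx.add(int(i))
        idx.add(int(j))
    return np.asarray(sorted(idx), dtype=np.int64)


def kl_divergence(hist_p, hist_q, eps: float = 1e-10) -> float:
    """KL(P || Q) between two histograms on shared bin edges.

    Both histograms are add-eps smoothed and renormalized, so the result is
    finite and nonnegative; it is not symmetric in its arguments.
    """
    p = np.asarray(hist_p, dtype=float).ravel()
    q = np.asarray(hist_q, dtype=float).ravel()
    if p.shape != q.shape:
        raise ValueError("histograms must share bin edges")
    if p.sum() <= 0 or q.sum() <= 0:
        raise ValueError("empty histogram")
    p = (p + eps) / (p + eps).sum()
    q = (q + eps) / (q + eps).sum()
    return float(max((p * np.log(p / q)).sum(), 0.0))
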