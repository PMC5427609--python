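"""Gene-gene correlation networks from zygosity profiles.

Each selected gene's "variation" is, per sample, the mean of the sample's
ternary genotype codes over the gene's SNPs — 0 means the sample is
major-homozygous (reference-like) across the gene, values toward 2 mean
heterozygous or alternative-homozygous. Pearson correlations of these
per-sample profiles connect gene pairs whose zygosity rises and falls
together (r near +1) or in opposition (r near -1); edges are kept by
strict thresholds (r > pos_cut or r < neg_cut). Hub genes — and in
particular negative-edge hubs whose zygosity opposes most of the network —
are ranked by degree.

Threshold presets used in practice: (0.45, -0.25), (0.8, -0.3),
(0.9, -0.4), (0.97, -0.5), (0.9, -0.5).
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import GeneSNPMap, TernaryGenotypeMatrix

logger = logging.getLogger(__name__)

THRESHOLD_PRESETS = {
    "loose": (0.45, -0.25),
    "medium": (0.8, -0.3),
    "tight": (0.9, -0.4),
    "strict": (0.97, -0.5),
    "tight_negative": (0.9, -0.5),
}


def gene_variation(
    matrix: TernaryGenotypeMatrix, gene_map: GeneSNPMap, selected_genes
) -> pd.DataFrame:
    """Per-gene, per-sample mean ternary code (genes x samples frame)."""
    rows = {}
    for g in selected_genes:
        idx = gene_map.sites_for(g)
        if len(idx) == 0:
            raise ValueError(f"gene {g!r} has no SNPs; cannot compute its variation")
        rows[g] = matrix.codes[:, idx].mean(axis=1)
    return pd.DataFrame.from_dict(rows, orient="index", columns=matrix.samples.sample_ids)


def correlation_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between gene variation profiles.

    Zero-variance profiles are excluded (Pearson is undefined for them) and
    logged. Requires at least 3 samples and 2 genes with variance.
    """
    if profiles.shape[1] < 3:
        raise ValueError("correlation requires at least 3 samples")
    var = profiles.var(axis=1, ddof=0)
    keep = var > 0
    if (~keep).any():
        logger.info(
            "excluding %d zero-variance gene profiles: %s",
            int((~keep).sum()),
            list(profiles.index[~keep])[:10],
        )
    kept = profiles.loc[keep]
    if len(kept) < 2:
        raise ValueError("fewer than 2 genes with non-constant profiles")
    r = np.corrcoef(kept.to_numpy(dtype=float))
    return pd.DataFrame(r, index=kept.index, columns=kept.index)


def build_network(corr: pd.DataFrame, pos_cut: float, neg_cut: float) -> nx.Graph:
    """Thresholded signed correlation graph: edge iff r > pos_cut or r < neg_cut."""
    if not neg_cut < pos_cut:
        raise ValueError("need neg_cut < pos_cut")
    g = nx.Graph(pos_cut=pos_cut, neg_cut=neg_cut)
    genes = list(corr.index)
    g.add_nodes_from(genes)
    r = corr.to_numpy()
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            rij = float(r[i, j])
            if rij > pos_cut or rij < neg_cut:
                g.add_edge(genes[i], genes[j], r=rij, sign="+" if rij > 0 else "-")
    return g


def hub_genes(network: nx.Graph, top_k: int | None = None) -> pd.DataFrame:
    """Genes ranked by degree with positive/negative edge breakdowns.

    Ties break by gene id. ``degree = pos_degree + neg_degree``.
    """
    rows = []
    for node in network.nodes:
        pos = sum(1 for _, _, d in network.edges(node, data=True) if d["sign"] == "+")
        neg = network.degree(node) - pos
        rows.append((node, network.degree(node), pos, neg))
    out = pd.DataFrame(rows, columns=["gene_id", "degree", "pos_degree", "neg_degree"])
    out = out.sort_values(["degree", "gene_id"], ascending=[False, True], kind="stable")
    out = out.reset_index(drop=True)
    return out.head(top_k) if top_k is not None else out


def top_negative_hub(network: nx.Graph) -> str | None:
    """Gene with the most negative edges (ties by gene id); None if no edges."""
    hubs = hub_genes(network)
    if hubs.empty or hubs["neg_degree"].max() == 0:
        return None
    hubs = hubs.sort_values(["neg_degree", "gene_id"], ascending=[False, True], kind="stable")
    return str(hubs["gene_id"].iloc[0])


def export_network(network: nx.Graph, path, fmt: str = "tsv") -> Path:
    """Write the network as an edge-list TSV or GraphML."""
    path = Path(path)
    if fmt == "tsv":
        rows = [
            (min(u, v), max(u, v), d["r"], d["sign"])
            for u, v, d in network.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["gene_i", "gene_j", "r", "sign"]).sort_values(
            ["gene_i", "gene_j"]
        ).to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        nx.write_graphml(network, path)
    else:
        raise ValueError(f"unknown network format {fmt!r}")
    return path


def import_network(path, fmt: str = "tsv") -> nx.Graph:
    """Inverse of :func:`export_network` (node set = edge endpoints for TSV)."""
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for row in df.itertuples(index=False):
            g.add_edge(row.gene_i, row.gene_j, r=float(row.r), sign=row.sign)
        return g
    if fmt == "graphml":
        return nx.read_graphml(path)
    raise ValueError(f"unknown network format {fmt!r}")
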