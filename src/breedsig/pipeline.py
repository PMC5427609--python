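"""End-to-end orchestration of the signature-discovery workflow.

Stages, in order: obtain a panel (simulate or ingest VCF + labels + genes),
restrict to the target/contrast breed pair, recode to major/minor, per-site
MI, adjacent-pair MIE selection, gene mapping and wMI ranking with
permutation significance, XP-EHH and XP-CLR-style window scans with
candidate-gene assignment, MI-scan gene intersections, per-chromosome
enrichment, case-control genotype tests, and the zygosity correlation
network over the wMI-selected genes. Every stage writes a TSV under the
output directory; a rerun with the same config and seed reproduces the
files byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, assoc, genes as gene_stats, mi as mi_core, network as net, scans
from .io import (
    HaplotypePanel,
    SamplePanel,
    map_snps_to_genes,
    read_genes,
    read_labels,
    read_vcf,
    recode_major_minor,
    ternary_encode,
)
from .simulate import SimConfig, simulate_panel

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Inputs, breed pair, per-stage knobs, output directory and seed.

    Exactly one of ``sim`` or (``vcf``, ``labels``, ``genes``) supplies the
    data. Default cutoffs: MIE theta 0.5 nats with pair p < 1e-3, wMI gene
    selection p < 1e-3, scan empirical p < 0.01, candidate-gene flank 25 kb,
    network thresholds (0.45, -0.25).
    """

    sim: SimConfig | None = None
    vcf: str | None = None
    labels: str | None = None
    genes: str | None = None
    target_breed: str = "breed0"
    contrast_breed: str = "breed1"
    theta: float = 0.5
    pair_p_cutoff: float = 1e-3
    mie_permutations: int = 1999
    alpha: float = 0.5
    wmi_p_cutoff: float = 1e-3
    wmi_permutations: int = 1999
    window_bp: int = 50_000
    scan_p_cutoff: float = 0.01
    bin_increment: int = 500
    gene_flank: int = 25_000
    pos_cut: float = 0.45
    neg_cut: float = -0.25
    out_dir: str = "breedsig_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_breed == self.contrast_breed:
            raise ValueError("target and contrast breed must differ")
        if self.sim is None and not (self.vcf and self.labels and self.genes):
            raise ValueError("provide either a SimConfig or vcf+labels+genes paths")

    def config_hash(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return {k: default(v) if hasattr(v, "__dict__") else v for k, v in vars(o).items()}
            return str(o)

        fields = asdict(self)
        fields.pop("out_dir", None)  # hash the analysis, not the output location
        blob = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All pipeline outputs plus a provenance block."""

    site_mi: pd.DataFrame
    selected_pairs: pd.DataFrame
    mi_gene_list: list
    wmi_table: pd.DataFrame
    wmi_gene_list: list
    xpehh_windows: pd.DataFrame
    xpehh_gene_list: list
    xpclr_windows: pd.DataFrame
    xpclr_gene_list: list
    intersection_mi_xpclr: list
    intersection_mi_xpehh: list
    enrichment: pd.DataFrame
    case_control: pd.DataFrame
    hub_report: pd.DataFrame
    provenance: dict
    paths: dict = field(default_factory=dict)


def _subset_breed_pair(panel: HaplotypePanel, target: str, contrast: str) -> HaplotypePanel:
    mask = panel.breed_mask(target) | panel.breed_mask(contrast)
    if not panel.breed_mask(target).any() or not panel.breed_mask(contrast).any():
        raise ValueError(f"panel lacks samples for {target!r} or {contrast!r}")
    rows = np.repeat(mask, 2)
    return HaplotypePanel(
        samples=SamplePanel(panel.samples.sample_ids[mask], panel.samples.breed_labels[mask]),
        sites=panel.sites,
        haplotypes=panel.haplotypes[rows],
        encoding=panel.encoding,
    )


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def run_full_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage and write the machine-readable report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    timings: dict[str, float] = {}
    stage = "ingest"
    try:
        t0 = time.perf_counter()
        if config.sim is not None:
            panel, genes_df, truth = simulate_panel(config.sim)
        else:
            panel = read_vcf(config.vcf, read_labels(config.labels))
            genes_df = read_genes(config.genes)
            truth = None
        panel = _subset_breed_pair(panel, config.target_breed, config.contrast_breed)
        timings[stage] = time.perf_counter() - t0

        stage = "recode"
        t0 = time.perf_counter()
        panel = recode_major_minor(panel)
        tern = ternary_encode(panel)
        timings[stage] = time.perf_counter() - t0

        stage = "mi"
        t0 = time.perf_counter()
        site_mi_values = mi_core.per_site_mi(panel.haplotypes, panel.hap_breeds)
        site_mi = panel.sites[["chrom", "pos"]].copy()
        site_mi["mi_nats"] = site_mi_values
        paths["site_mi"] = _write(site_mi, out / "site_mi.tsv")

        mie_cfg = mi_core.MIEConfig(
            theta=config.theta,
            p_cutoff=config.pair_p_cutoff,
            n_permutations=config.mie_permutations,
            seed=config.seed,
        )
        pairs = mi_core.select_discriminative_pairs(panel, config=mie_cfg)
        pair_rows = [
            (
                panel.sites["chrom"].iat[i],
                panel.sites["pos"].iat[i],
                panel.sites["pos"].iat[j],
                v,
                p,
            )
            for i, j, v, p in pairs
        ]
        selected_pairs = pd.DataFrame(
            pair_rows, columns=["chrom", "pos", "pos2", "mie_nats", "p_value"]
        )
        paths["selected_pairs"] = _write(selected_pairs, out / "selected_pairs.tsv")
        selected_sites = mi_core.selected_site_union(pairs)
        timings[stage] = time.perf_counter() - t0

        stage = "genes"
        t0 = time.perf_counter()
        gene_map = map_snps_to_genes(panel.sites, genes_df)
        sel_flags = np.zeros(panel.n_sites, dtype=bool)
        sel_flags[selected_sites] = True
        mi_gene_list = sorted(
            g for g, idx in gene_map.assignments.items() if len(idx) and sel_flags[idx].any()
        )
        wmi_cfg = gene_stats.WMIConfig(
            alpha=config.alpha,
            p_cutoff=config.wmi_p_cutoff,
            n_permutations=config.wmi_permutations,
            seed=config.seed + 1,
        )
        wmi_table = gene_stats.wmi_significance(panel, gene_map, wmi_cfg)
        wmi_gene_list = gene_stats.select_genes(wmi_table, config.wmi_p_cutoff)
        paths["wmi"] = _write(wmi_table, out / "gene_wmi.tsv")
        timings[stage] = time.perf_counter() - t0

        stage = "xpehh"
        t0 = time.perf_counter()
        hap_a = panel.haplotypes[panel.hap_mask(config.target_breed)]
        hap_b = panel.haplotypes[panel.hap_mask(config.contrast_breed)]
        site_scores, xpehh_windows = scans.xpehh_scan(
            hap_a, hap_b, panel.sites, window_bp=config.window_bp
        )
        xpehh_windows = scans.bin_and_empirical_p(
            xpehh_windows, config.bin_increment, config.scan_p_cutoff
        )
        xpehh_gene_list = scans.assign_candidate_genes(
            xpehh_windows[xpehh_windows["selected"]], genes_df, config.gene_flank
        )
        paths["xpehh_sites"] = _write(site_scores, out / "xpehh_sites.tsv")
        paths["xpehh_windows"] = _write(xpehh_windows, out / "xpehh_windows.tsv")
        timings[stage] = time.perf_counter() - t0

        stage = "xpclr"
        t0 = time.perf_counter()
        codes_a = tern.codes[panel.breed_mask(config.target_breed)]
        codes_b = tern.codes[panel.breed_mask(config.contrast_breed)]
        xpclr_windows = scans.xpclr_lite(codes_a, codes_b, panel.sites)
        xpclr_gene_list = scans.assign_candidate_genes(
            xpclr_windows[xpclr_windows["selected"]], genes_df, config.gene_flank
        )
        paths["xpclr_windows"] = _write(xpclr_windows, out / "xpclr_windows.tsv")
        timings[stage] = time.perf_counter() - t0

        stage = "intersections"
        t0 = time.perf_counter()
        inter_clr = scans.intersect_gene_lists(mi_gene_list, xpclr_gene_list)
        inter_ehh = scans.intersect_gene_lists(mi_gene_list, xpehh_gene_list)
        timings[stage] = time.perf_counter() - t0

        stage = "enrichment"
        t0 = time.perf_counter()
        enrichment = assoc.chromosome_enrichment(sel_flags, panel.sites["chrom"].to_numpy())
        paths["enrichment"] = _write(enrichment, out / "chromosome_enrichment.tsv")
        timings[stage] = time.perf_counter() - t0

        stage = "case_control"
        t0 = time.perf_counter()
        cc_frames = [
            assoc.case_control_test(
                tern.codes, tern.samples.breed_labels, config.target_breed, m, panel.sites
            )
            for m in assoc.MODELS
        ]
        case_control = pd.concat(cc_frames, ignore_index=True)
        paths["case_control"] = _write(case_control, out / "case_control.tsv")
        timings[stage] = time.perf_counter() - t0

        stage = "network"
        t0 = time.perf_counter()
        net_genes = [g for g in wmi_gene_list if len(gene_map.sites_for(g))]
        if len(net_genes) >= 2:
            profiles = net.gene_variation(tern, gene_map, net_genes)
            try:
                corr = net.correlation_matrix(profiles)
                graph = net.build_network(corr, config.pos_cut, config.neg_cut)
            except ValueError:
                graph = None
        else:
            graph = None
        if graph is not None:
            hub_report = net.hub_genes(graph)
            paths["network"] = net.export_network(graph, out / "network_edges.tsv")
            paths["network_graphml"] = net.export_network(
                graph, out / "network.graphml", fmt="graphml"
            )
            paths["profiles"] = _write(
                profiles.rename_axis("gene_id").reset_index(), out / "gene_profiles.tsv"
            )
        else:
            hub_report = pd.DataFrame(
                columns=["gene_id", "degree", "pos_degree", "neg_degree"]
            )
        paths["hubs"] = _write(hub_report, out / "hub_genes.tsv")
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    provenance = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "target_breed": config.target_breed,
        "contrast_breed": config.contrast_breed,
        "n_samples": int(panel.n_samples),
        "n_sites": int(panel.n_sites),
        "n_genes": int(len(genes_df)),
        "planted": None if truth is None else truth.planted_gene_ids,
        "stage_counts": {
            "selected_pairs": int(len(selected_pairs)),
            "mi_genes": len(mi_gene_list),
            "wmi_genes": len(wmi_gene_list),
            "xpehh_selected_windows": int(xpehh_windows["selected"].sum()),
            "xpclr_selected_windows": int(xpclr_windows["selected"].sum()),
            "mi_and_xpclr": len(inter_clr),
            "mi_and_xpehh": len(inter_ehh),
        },
    }
    logger.info("stage timings: %s", {k: round(v, 2) for k, v in timings.items()})

    index = {
        "provenance": provenance,
        "gene_lists": {
            "mi": mi_gene_list,
            "wmi": wmi_gene_list,
            "xpehh": xpehh_gene_list,
            "xpclr": xpclr_gene_list,
            "mi_and_xpclr": inter_clr,
            "mi_and_xpehh": inter_ehh,
        },
        "files": {k: Path(v).name for k, v in paths.items()},
    }
    (out / "report.json").write_text(json.dumps(index, indent=2, sort_keys=True))
    paths["report"] = out / "report.json"

    return ReportBundle(
        site_mi=site_mi,
        selected_pairs=selected_pairs,
        mi_gene_list=mi_gene_list,
        wmi_table=wmi_table,
        wmi_gene_list=wmi_gene_list,
        xpehh_windows=xpehh_windows,
        xpehh_gene_list=xpehh_gene_list,
        xpclr_windows=xpclr_windows,
        xpclr_gene_list=xpclr_gene_list,
        intersection_mi_xpclr=inter_clr,
        intersection_mi_xpehh=inter_ehh,
        enrichment=enrichment,
        case_control=case_control,
        hub_report=hub_report,
        provenance=provenance,
        paths=paths,
    )


def intersect_and_summarize(report: ReportBundle) -> pd.DataFrame:
    """Per-measure and per-intersection gene counts as one summary table."""
    rows = [
        ("mi", len(report.mi_gene_list)),
        ("wmi", len(report.wmi_gene_list)),
        ("xpehh", len(report.xpehh_gene_list)),
        ("xpclr", len(report.xpclr_gene_list)),
        ("mi_and_xpclr", len(report.intersection_mi_xpclr)),
        ("mi_and_xpehh", len(report.intersection_mi_xpehh)),
    ]
    return pd.DataFrame(rows, columns=["measure", "n_genes"])
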