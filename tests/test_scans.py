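"""Selection-scan machinery against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from breedsig import mi
from breedsig.io import recode_major_minor, ternary_encode
from breedsig.mi import MIEConfig, select_discriminative_pairs, selected_site_union
from breedsig.scans import (
    EHHCurve,
    XPCLRConfig,
    assign_candidate_genes,
    bin_and_empirical_p,
    ehh,
    ihh,
    intersect_gene_lists,
    tile_windows,
    xpclr_lite,
    xpehh_scan,
)
from breedsig.simulate import SimConfig, SweepSpec, plant_sweep, simulate_panel

from conftest import SMALL_SIM


def ehh_pairwise_oracle(h, core, direction, positions):
    """O(n^2) oracle: fraction of haplotype pairs identical over the prefix."""
    n = h.shape[0]
    idx = (
        list(range(core + 1, h.shape[1]))
        if direction == "right"
        else list(range(core - 1, -1, -1))
    )
    out = [(0.0, 1.0)]
    prefix = []
    for j in idx:
        prefix.append(j)
        same = sum(
            (h[a, prefix] == h[b, prefix]).all()
            for a in range(n)
            for b in range(a + 1, n)
        )
        out.append((abs(positions[j] - positions[core]), same / (n * (n - 1) / 2)))
    return out


class TestEHH:
    def test_distance_zero_is_one(self):
        h = np.random.default_rng(0).integers(0, 2, size=(6, 10))
        c = ehh(h, 4, "right", np.arange(10) * 100)
        assert c.values[0] == 1.0 and c.distances[0] == 0.0

    def test_all_singletons_at_first_flank(self):
        # 4 haplotypes all distinct at the first flanking site pair-coverage 0
        h = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])[:, :1]
        h = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        # use a 4-valued first flank by combining two sites? single site is binary;
        # 2 groups of 2 -> EHH = 2/6. For EHH 0 use 2 haplotypes differing.
        h2 = np.array([[0, 0], [0, 1]])
        c = ehh(h2, 0, "right", np.array([0, 50]))
        assert c.values[-1] == 0.0

    def test_matches_pairwise_identity_oracle(self):
        rng = np.random.default_rng(4)
        h = rng.integers(0, 2, size=(8, 20))
        positions = np.sort(rng.choice(5000, size=20, replace=False))
        for core in (0, 7, 19):
            for direction in ("left", "right"):
                curve = ehh(h, core, direction, positions, truncation=0.0)
                oracle = ehh_pairwise_oracle(h, core, direction, positions)
                np.testing.assert_allclose(
                    curve.values, [v for _, v in oracle], atol=1e-12
                )
                np.testing.assert_allclose(
                    curve.distances, [d for d, _ in oracle], atol=0
                )

    def test_non_increasing(self):
        rng = np.random.default_rng(5)
        h = rng.integers(0, 2, size=(10, 30))
        c = ehh(h, 15, "right", np.arange(30) * 10, truncation=0.0)
        assert (np.diff(c.values) <= 1e-12).all()

    def test_fewer_than_two_haplotypes_rejected(self):
        with pytest.raises(ValueError):
            ehh(np.zeros((1, 5), dtype=int), 2, "left", np.arange(5))


class TestIHH:
    def test_rectangle(self):
        left = EHHCurve(0, "left", np.array([0.0, 100.0]), np.array([1.0, 1.0]))
        right = EHHCurve(0, "right", np.array([0.0, 100.0]), np.array([1.0, 1.0]))
        assert ihh(left, right) == pytest.approx(200.0)

    def test_empty_curves_contribute_zero(self):
        empty = EHHCurve(0, "left", np.array([0.0]), np.array([1.0]))
        assert ihh(empty, empty) == 0.0

    def test_trapezoid_matches_refined_interpolation(self):
        rng = np.random.default_rng(6)
        d = np.concatenate([[0.0], np.sort(rng.uniform(10, 1000, size=15))])
        v = np.concatenate([[1.0], np.sort(rng.uniform(0, 1, size=15))[::-1]])
        curve = EHHCurve(0, "right", d, v)
        coarse = ihh(curve, EHHCurve(0, "left", np.array([0.0]), np.array([1.0])))
        fine_d = np.linspace(d[0], d[-1], 10 * len(d))
        fine_v = np.interp(fine_d, d, v)
        fine = np.trapezoid(fine_v, fine_d)
        assert coarse == pytest.approx(fine, rel=0.005)


@pytest.fixture(scope="module")
def swept_fixture():
    panel, genes, truth = simulate_panel(SimConfig(**SMALL_SIM))
    rec = recode_major_minor(panel)
    return rec, genes, truth


class TestXPEHH:
    def test_identical_panels_score_zero(self):
        rng = np.random.default_rng(7)
        hap = rng.integers(0, 2, size=(10, 200))
        sites = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.sort(rng.choice(100_000, 200, replace=False)) + 1,
                "ref": "A",
                "alt": "T",
            }
        )
        scores, _ = xpehh_scan(hap, hap, sites)
        ok = ~scores["xpehh_raw"].isna()
        assert ok.any()
        np.testing.assert_allclose(scores.loc[ok, "xpehh_raw"], 0.0, atol=1e-12)

    def test_population_swap_negates_raw_scores(self, swept_fixture):
        rec, _, _ = swept_fixture
        sub = rec.sites.index[:400]
        sites = rec.sites.loc[sub].reset_index(drop=True)
        ha = rec.haplotypes[rec.hap_mask("breed0")][:, sub]
        hb = rec.haplotypes[rec.hap_mask("breed1")][:, sub]
        ab, _ = xpehh_scan(ha, hb, sites)
        ba, _ = xpehh_scan(hb, ha, sites)
        np.testing.assert_allclose(
            ab["xpehh_raw"], -ba["xpehh_raw"], atol=1e-12, equal_nan=True
        )

    def test_normalized_scores_standardized(self, swept_fixture):
        rec, _, _ = swept_fixture
        ha = rec.haplotypes[rec.hap_mask("breed0")]
        hb = rec.haplotypes[rec.hap_mask("breed1")]
        scores, windows = xpehh_scan(ha, hb, rec.sites)
        z = scores["xpehh_norm"].dropna()
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-9)
        # tiling is a partition of the SNPs
        assert windows["n_snps"].sum() == len(rec.sites)

    def test_planted_sweep_window_attains_genomewide_maximum(self, swept_fixture):
        rec, _, truth = swept_fixture
        ha = rec.haplotypes[rec.hap_mask("breed0")]
        hb = rec.haplotypes[rec.hap_mask("breed1")]
        _, windows = xpehh_scan(ha, hb, rec.sites)
        windows = bin_and_empirical_p(windows)
        best = windows.loc[windows["stat"].idxmax()]
        chrom, lo, hi = truth.sweep_windows[0]
        assert best["start"] < hi and best["end"] > lo  # overlaps the true footprint
        assert best["empirical_p"] < 0.01 and best["selected"]


class TestEmpiricalP:
    def test_top_window_of_bin_gets_zero(self):
        w = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(5) * 100,
                "end": (np.arange(5) + 1) * 100,
                "n_snps": [10, 10, 10, 10, 10],
                "stat": [1.0, 5.0, 3.0, 2.0, 4.0],
            }
        )
        out = bin_and_empirical_p(w)
        assert out.loc[out["stat"].idxmax(), "empirical_p"] == 0.0

    def test_all_tied_all_zero(self):
        w = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": [0, 100],
                "end": [100, 200],
                "n_snps": [3, 3],
                "stat": [2.0, 2.0],
            }
        )
        out = bin_and_empirical_p(w)
        assert (out["empirical_p"] == 0.0).all()

    def test_matches_quadratic_brute_force(self):
        rng = np.random.default_rng(8)
        n = 200
        w = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(n) * 100,
                "end": (np.arange(n) + 1) * 100,
                "n_snps": rng.integers(0, 1600, size=n),
                "stat": rng.normal(size=n),
            }
        )
        out = bin_and_empirical_p(w)
        bins = w["n_snps"] // 500
        for i in range(n):
            members = np.flatnonzero(bins == bins[i])
            expected = (w["stat"].to_numpy()[members] > w["stat"][i]).sum() / len(members)
            assert out["empirical_p"][i] == pytest.approx(expected, abs=1e-12)


class TestXPCLR:
    def _panels(self, seed=13, planted=True):
        cfg = SimConfig(
            **{
                **SMALL_SIM,
                "sweep_specs": (),
                "signature_genes": 3 if planted else 0,
                "opposite_genes": 0,
                "seed": seed,
            }
        )
        panel, genes, truth = simulate_panel(cfg)
        rec = recode_major_minor(panel)
        tern = ternary_encode(rec)
        a = tern.codes[rec.breed_mask("breed0")]
        b = tern.codes[rec.breed_mask("breed1")]
        return a, b, rec.sites, genes, truth

    def test_identical_matrices_never_beat_planted_differentiation(self):
        for seed in range(1, 6):
            a, b, sites, _, _ = self._panels(seed=seed, planted=True)
            planted_best = xpclr_lite(a, b, sites)["stat"].max()
            null = xpclr_lite(a, a, sites, XPCLRConfig(omega=0.05))
            assert null["stat"].max() < planted_best

    def test_near_fixed_differentiated_window_in_top_percent(self):
        rng = np.random.default_rng(9)
        n_sites = 1000
        pos = np.sort(rng.choice(500_000, n_sites, replace=False)) + 1
        sites = pd.DataFrame({"chrom": "chr1", "pos": pos, "ref": "A", "alt": "T"})
        # background: both populations share moderate frequencies
        freq = rng.uniform(0.2, 0.8, size=n_sites)
        a = (rng.random((10, n_sites)) < freq) * 1 + (rng.random((10, n_sites)) < freq)
        b = (rng.random((9, n_sites)) < freq) * 1 + (rng.random((9, n_sites)) < freq)
        # one window: 10 sites near-fixed in A, ~0.5 in B
        target = np.flatnonzero((pos - 1 >= 250_000) & (pos - 1 < 300_000))[:10]
        a[:, target] = 2
        b[:, target] = (rng.random((9, len(target))) < 0.5) * 2
        windows = xpclr_lite(a.astype(np.uint8), b.astype(np.uint8), sites)
        hot = windows[(windows["start"] == 250_000)]
        assert hot["selected"].all()

    def test_duplicated_column_leaves_statistic_unchanged(self):
        a, b, sites, _, _ = self._panels(seed=21)
        w0 = xpclr_lite(a, b, sites)
        # duplicate the most differentiated column within its window (r = 1 > 0.95)
        pa = a.mean(axis=0) / 2
        pb = b.mean(axis=0) / 2
        j = int(np.argmax(np.abs(pa - pb)))
        pos_j = sites["pos"].iat[j]
        new_pos = pos_j + 1 if pos_j % 2 == 0 else pos_j - 1
        sites2 = pd.concat(
            [
                sites,
                pd.DataFrame(
                    {"chrom": ["chr1"], "pos": [new_pos], "ref": "A", "alt": "T"}
                ),
            ]
        ).sort_values("pos", kind="stable").reset_index(drop=True)
        insert_at = int(np.searchsorted(sites["pos"].to_numpy(), new_pos))
        a2 = np.insert(a, insert_at, a[:, j], axis=1)
        b2 = np.insert(b, insert_at, b[:, j], axis=1)
        w1 = xpclr_lite(a2, b2, sites2, XPCLRConfig(omega=0.05))
        w0 = xpclr_lite(a, b, sites, XPCLRConfig(omega=0.05))
        merged = w0.merge(w1, on=["chrom", "start", "end"], suffixes=("_0", "_1"))
        np.testing.assert_allclose(merged["stat_0"], merged["stat_1"], atol=1e-9)


class TestCandidateGenes:
    GENES = pd.DataFrame(
        {
            "gene_id": ["inside", "flank_only", "outside"],
            "chrom": "chr1",
            "start": [110_000, 70_000, 10_000],
            "end": [140_000, 76_000, 74_999],
        }
    )
    WINDOW = pd.DataFrame(
        {"chrom": ["chr1"], "start": [100_000], "end": [150_000], "stat": [5.0]}
    )

    def test_boundary_semantics(self):
        got = assign_candidate_genes(self.WINDOW, self.GENES, flank=25_000)
        # flank reaches down to 75,000: 'outside' ends at 74,999 -> excluded
        assert got == ["flank_only", "inside"]

    def test_intersection(self):
        assert intersect_gene_lists(["b", "a"], ["c", "a", "b"]) == ["a", "b"]
        assert intersect_gene_lists(["a"], ["b"]) == []
        assert intersect_gene_lists(["a", "b"], ["a", "b", "c"]) == ["a", "b"]


class TestSweepSignatureIntersection:
    def test_gene_planted_as_both_signature_and_sweep_is_in_both_lists(self):
        # plant the sweep on top of a signature gene, then check that the
        # MI-selected genes and the XP-EHH candidate genes share it
        cfg = SimConfig(**{**SMALL_SIM, "sweep_specs": (), "seed": 31})
        panel, genes, truth = simulate_panel(cfg)
        target = genes[genes["gene_id"] == truth.planted_gene_ids[0]].iloc[0]
        core = int((target["start"] + target["end"]) // 2)
        plant_sweep(
            panel,
            SweepSpec(0, core, 0.95, 100_000),
            np.random.default_rng(2),
        )
        rec = recode_major_minor(panel)
        pairs = select_discriminative_pairs(
            rec,
            config=MIEConfig(theta=0.5, p_cutoff=0.05, n_permutations=199, seed=0),
        )
        sel = selected_site_union(pairs)
        pos0 = rec.sites["pos"].to_numpy() - 1
        mi_genes = [
            g.gene_id
            for g in genes.itertuples(index=False)
            if ((pos0[sel] >= g.start) & (pos0[sel] < g.end)).any()
        ]
        ha = rec.haplotypes[rec.hap_mask("breed0")]
        hb = rec.haplotypes[rec.hap_mask("breed1")]
        _, windows = xpehh_scan(ha, hb, rec.sites)
        windows = bin_and_empirical_p(windows)
        scan_genes = assign_candidate_genes(windows[windows["selected"]], genes)
        common = intersect_gene_lists(mi_genes, scan_genes)
        assert target["gene_id"] in common
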