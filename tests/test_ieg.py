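import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from epidiff.genome import GeneModel, GenomeLayout, Interval
from epidiff.ieg import (
    CellTypeWeights,
    RegionMatrix,
    build_gene_regions,
    celltype_logfc,
    combined_level,
    gene_mark_logfc,
    ieg_summary,
    region_matrix,
    region_ttest,
    tile_region,
)

from oracles import pooled_ttest


def gene(start, end, strand, chrom="chr1", gid="g"):
    return GeneModel(gid, Interval(chrom, start, end, strand))


class TestGeneRegions:
    def test_plus_strand_windows(self):
        body, prom = build_gene_regions(gene(5000, 7000, "+"))
        assert (body.start, body.end) == (4000, 8000)
        assert (prom.start, prom.end) == (2000, 6000)

    def test_minus_strand_promoter_flips(self):
        body, prom = build_gene_regions(gene(5000, 7000, "-"))
        assert (body.start, body.end) == (4000, 8000)
        assert (prom.start, prom.end) == (6000, 10_000)

    def test_clipping_at_chromosome_edge(self):
        layout = GenomeLayout(("chr1",), (100_000,))
        body, prom = build_gene_regions(gene(500, 900, "+"), layout)
        assert prom.start == 0 and prom.end == 1500  # TSS + 1000
        assert body.start == 0

    @given(start=st.integers(3000, 50_000), length=st.integers(1000, 30_000),
           strand=st.sampled_from(["+", "-"]))
    def test_window_lengths(self, start, length, strand):
        body, prom = build_gene_regions(gene(start, start + length, strand))
        assert body.width == length + 2000
        assert prom.width == 4000


class TestTileRegion:
    @pytest.mark.parametrize("length,n_tiles", [(1500, 3), (1600, 3), (499, 0), (500, 1)])
    def test_tile_counts(self, length, n_tiles):
        tiles = tile_region(Interval("chr1", 1000, 1000 + length))
        assert len(tiles) == n_tiles
        assert all(t.width == 500 for t in tiles)

    def test_keep_partial_appends_clipped_tile(self):
        tiles = tile_region(Interval("chr1", 0, 1600), keep_partial=True)
        assert len(tiles) == 4 and tiles[-1].width == 100


class TestRegionMatrix:
    def _reads(self, positions, chrom="chr1"):
        return [Interval(chrom, max(0, p - 50), p + 50) for p in positions]

    def test_no_reads_gives_zero_matrix(self):
        rm = region_matrix(Interval("chr1", 0, 500), {}, {"treated": 1e6, "mock": 1e6})
        assert rm.counts.shape == (2, 10)
        assert rm.counts.sum() == 0

    def test_one_read_per_sub_bin_gives_uniform_row(self):
        reads = {"treated": self._reads([25 + 50 * k for k in range(10)])}
        rm = region_matrix(Interval("chr1", 0, 500), reads,
                          {"treated": 1e6, "mock": 1e6})
        assert np.allclose(rm.counts[0], rm.counts[0][0])
        assert rm.counts[0][0] == pytest.approx(1.0)  # 1 read CPM of 1e6

    def test_wrong_tile_width_rejected(self):
        with pytest.raises(ValueError):
            region_matrix(Interval("chr1", 0, 400), {}, {"treated": 1, "mock": 1})


class TestRegionTTest:
    def test_identical_rows_give_t_zero_p_one(self):
        rm = RegionMatrix(Interval("chr1", 0, 500), np.ones((2, 10)) * 3)
        t, p = region_ttest(rm)
        assert t == 0.0 and p == 1.0

    def test_textbook_example_frozen_value(self):
        """Rows (1..10) vs (2..11): pooled-variance t = -0.73855, p = 0.46973."""
        rm = RegionMatrix(
            Interval("chr1", 0, 500),
            np.array([np.arange(1.0, 11.0), np.arange(2.0, 12.0)]),
        )
        t, p = region_ttest(rm)
        t_exp, p_exp = pooled_ttest(list(np.arange(1.0, 11.0)), list(np.arange(2.0, 12.0)))
        assert t == pytest.approx(t_exp, abs=1e-12)
        assert p == pytest.approx(p_exp, abs=1e-12)
        assert t == pytest.approx(-0.7385489458759964, abs=1e-9)
        assert p == pytest.approx(0.46973, abs=1e-4)

    def test_swapping_rows_negates_t(self):
        rng = np.random.default_rng(1)
        c = rng.uniform(size=(2, 10))
        rm1 = RegionMatrix(Interval("chr1", 0, 500), c)
        rm2 = RegionMatrix(Interval("chr1", 0, 500), c[::-1].copy())
        t1, p1 = region_ttest(rm1)
        t2, p2 = region_ttest(rm2)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)


class TestCombinedLevel:
    def test_unit_basis_vectors(self):
        assert combined_level(1.0, 0.0) == 0.28
        assert combined_level(0.0, 1.0) == 0.72

    @given(x=st.floats(0, 100, allow_nan=False))
    def test_identical_levels_pass_through(self, x):
        assert combined_level(x, x) == pytest.approx(x)

    @given(a=st.floats(0, 10), b=st.floats(0, 10))
    def test_bounded_by_inputs(self, a, b):
        v = combined_level(a, b)
        assert min(a, b) - 1e-12 <= v <= max(a, b) + 1e-12

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            combined_level(-0.1, 0.5)

    def test_weights_must_sum_to_one(self):
        w = CellTypeWeights(0.4)
        assert w.f_non_neuron == pytest.approx(0.6)
        with pytest.raises(ValueError):
            CellTypeWeights(1.2)


class TestCelltypeLogfc:
    def _means(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "cluster", "group", "mean_expr"])

    def test_equal_means_give_zero(self):
        rows = [("g", c, g, 5.0) for c in ("Ex1", "Astro") for g in ("mock", "treated")]
        out = celltype_logfc(self._means(rows), {"Ex1"})
        assert out["log2fc_neuronal"][0] == pytest.approx(0.0)
        assert out["log2fc_non_neuronal"][0] == pytest.approx(0.0)

    def test_doubled_treated_means_give_one(self):
        rows = []
        for c in ("Ex1", "In1", "Astro"):
            rows += [("g", c, "mock", 4.0), ("g", c, "treated", 8.0)]
        out = celltype_logfc(self._means(rows), {"Ex1", "In1"})
        assert out["log2fc_neuronal"][0] == pytest.approx(1.0, abs=0.01)

    def test_single_cluster_compartment_equals_cluster_logfc(self):
        rows = [("g", "Ex1", "mock", 2.0), ("g", "Ex1", "treated", 6.0),
                ("g", "Astro", "mock", 1.0), ("g", "Astro", "treated", 1.0)]
        out = celltype_logfc(self._means(rows), {"Ex1"})
        expected = np.log2(6.01 / 2.01)
        assert out["log2fc_neuronal"][0] == pytest.approx(expected)

    def test_empty_compartment_rejected(self):
        rows = [("g", "Ex1", "mock", 2.0), ("g", "Ex1", "treated", 2.0)]
        with pytest.raises(ValueError):
            celltype_logfc(self._means(rows), {"Ex1"})


class TestIegSummary:
    def test_exact_monotone_relation_gives_unit_spearman(self):
        n = 10
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "is_ieg": [True] * n,
                "expr_log2fc": np.arange(n, dtype=float),
                "hmc_log2fc": np.arange(n, dtype=float) * 0.5,
                "mc_log2fc": -np.arange(n, dtype=float) * 0.3,
            }
        )
        out = ieg_summary(df)
        assert out["ieg"]["spearman_hmc"] == pytest.approx(1.0)
        assert out["ieg"]["spearman_mc"] == pytest.approx(-1.0)

    def test_shuffled_labels_break_correlation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        ok = 0
        for _ in range(100):
            y = rng.permutation(x)
            df = pd.DataFrame(
                {"gene_id": range(200), "is_ieg": [True] * 200,
                 "expr_log2fc": x, "hmc_log2fc": y, "mc_log2fc": y}
            )
            r = ieg_summary(df)["ieg"]["pearson_hmc"]
            ok += abs(r) < 0.3
        assert ok >= 95

    def test_recovers_planted_ieg_concordance(self, default_truth):
        """Per-gene 5hmC log2FC measured from simulated gene-body reads
        correlates positively with planted expression change."""
        from epidiff.simulate import simulate_expression, simulate_region_reads

        reads, sheet = simulate_region_reads(default_truth, "hmc")
        by_group: dict[str, list] = {"mock": [], "treated": []}
        for sid, grp in zip(sheet["sample_id"], sheet["group"]):
            by_group[grp].extend(reads[sid])
        libs = {"mock": 3e6, "treated": 3e6}
        expr = simulate_expression(default_truth).set_index("gene_id")
        genes = {g.gene_id: g for g in default_truth.genes}
        rows = []
        for gid in sorted(default_truth.ieg_effects):
            df = gene_mark_logfc(genes[gid], "body", by_group, libs,
                                 default_truth.layout)
            rows.append(
                {"gene_id": gid, "is_ieg": genes[gid].is_ieg,
                 "expr_log2fc": float(expr.loc[gid, "log2_fc"]),
                 "hmc_log2fc": df.attrs["log2_fc"],
                 "mc_log2fc": 0.0}
            )
        out = ieg_summary(pd.DataFrame(rows))
        assert out["ieg"]["pearson_hmc"] > 0.5
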