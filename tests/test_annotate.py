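import numpy as np
import pandas as pd
import pytest

from epidiff.annotate import (
    annotate_regions,
    crosstab_repeat_expression,
    repeat_gain_fraction,
    state_enrichment,
)
from epidiff.genome import GeneModel, Interval, RegionCall

from oracles import fisher_twosided


@pytest.fixture
def gene_plus():
    # first exon placed beyond the promoter window (TSS-2000..TSS+500) so
    # exon/UTR precedence is observable
    chrom = "chr1"
    exons = [Interval(chrom, 10_600, 11_100, "+"), Interval(chrom, 14_000, 14_400, "+")]
    return GeneModel(
        "gA", Interval(chrom, 10_000, 15_000, "+"), False, exons,
        utr5=Interval(chrom, 10_600, 10_750, "+"),
        utr3=Interval(chrom, 14_100, 14_400, "+"),
    )


class TestAnnotateRegions:
    def test_midpoint_in_exon(self, gene_plus):
        (fa,) = annotate_regions([Interval("chr1", 10_800, 11_000)], [gene_plus])
        assert fa.feature == "exon"
        assert fa.gene_id == "gA"

    def test_promoter_shadows_early_exon(self, gene_plus):
        """Precedence: a midpoint within TSS+500 is promoter even inside the
        gene body."""
        (fa,) = annotate_regions([Interval("chr1", 10_100, 10_300)], [gene_plus])
        assert fa.feature == "promoter"

    def test_midpoint_1kb_upstream_is_promoter(self, gene_plus):
        (fa,) = annotate_regions([Interval("chr1", 8_900, 9_100)], [gene_plus])
        assert fa.feature == "promoter"

    def test_intergenic_with_repeat_flag(self, gene_plus):
        sine = Interval("chr1", 50_000, 50_300, label="SINE")
        (fa,) = annotate_regions(
            [Interval("chr1", 50_100, 50_200)], [gene_plus], repeats=[sine]
        )
        assert fa.feature == "intergenic"
        assert fa.repeat_class == "SINE"

    def test_utr5_beats_exon(self, gene_plus):
        (fa,) = annotate_regions([Interval("chr1", 10_620, 10_700)], [gene_plus])
        assert fa.feature == "5'UTR"

    def test_intron_between_exons(self, gene_plus):
        (fa,) = annotate_regions([Interval("chr1", 12_000, 12_100)], [gene_plus])
        assert fa.feature == "intron"

    def test_tts_downstream_of_tes(self, gene_plus):
        (fa,) = annotate_regions([Interval("chr1", 15_100, 15_300)], [gene_plus])
        assert fa.feature == "TTS"

    def test_annotation_is_total(self, default_truth):
        regions = [p.interval for p in default_truth.planted_dhmrs]
        fas = annotate_regions(
            regions, default_truth.genes, default_truth.cgi, default_truth.repeats
        )
        assert len(fas) == len(regions)
        valid = {"promoter", "5'UTR", "exon", "3'UTR", "TTS", "intron", "intergenic"}
        assert all(fa.feature in valid for fa in fas)


class TestStateEnrichment:
    def _states(self):
        return [Interval("chr1", i * 1000, i * 1000 + 500, label="S") for i in range(20)]

    def test_query_equals_background_gives_or_one_p_one(self):
        q = [Interval("chr1", 100, 200), Interval("chr1", 600, 700)]  # one in, one out
        df = state_enrichment(q, list(q), self._states())
        assert np.allclose(df["odds_ratio"], 1.0)
        assert np.allclose(df["p_value"], 1.0)

    def test_fisher_p_matches_hypergeometric_oracle(self):
        # query: 8 of 10 overlap; background: 2 of 10 overlap
        states = self._states()
        q = [Interval("chr1", i * 1000 + 100, i * 1000 + 200) for i in range(8)]
        q += [Interval("chr1", i * 1000 + 700, i * 1000 + 800) for i in range(2)]
        b = [Interval("chr1", i * 1000 + 100, i * 1000 + 200) for i in range(2)]
        b += [Interval("chr1", i * 1000 + 700, i * 1000 + 800) for i in range(8)]
        df = state_enrichment(q, b, states)
        assert df["p_value"][0] == pytest.approx(fisher_twosided(8, 2, 2, 8), abs=1e-12)
        assert df["p_value"][0] == pytest.approx(0.023, abs=5e-4)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            state_enrichment([], [Interval("chr1", 0, 10)], self._states())

    def test_swapping_query_background_inverts_odds(self):
        states = self._states()
        q = [Interval("chr1", i * 1000 + 100, i * 1000 + 200) for i in range(6)]
        q += [Interval("chr1", i * 1000 + 700, i * 1000 + 800) for i in range(4)]
        b = [Interval("chr1", i * 1000 + 100, i * 1000 + 200) for i in range(3)]
        b += [Interval("chr1", i * 1000 + 700, i * 1000 + 800) for i in range(7)]
        d1 = state_enrichment(q, b, states)
        d2 = state_enrichment(b, q, states)
        assert d1["odds_ratio"][0] == pytest.approx(1 / d2["odds_ratio"][0], abs=1e-9)


class TestRepeatGainFraction:
    def _call(self, chrom, start, end, direction):
        lfc = 1.0 if direction == "gain" else -1.0
        return RegionCall(Interval(chrom, start, end), direction, lfc, 1e-4, 1e-3)

    def test_all_gain_gives_fraction_one(self):
        reps = [Interval("chr1", 100, 300, label="SINE")]
        calls = [self._call("chr1", 0, 500, "gain")]
        assert repeat_gain_fraction(calls, reps)["overall"] == 1.0

    def test_one_gain_one_loss_gives_half(self):
        reps = [
            Interval("chr1", 100, 300, label="SINE"),
            Interval("chr1", 1100, 1300, label="LINE"),
        ]
        calls = [self._call("chr1", 0, 500, "gain"), self._call("chr1", 1000, 1500, "loss")]
        out = repeat_gain_fraction(calls, reps)
        assert out["overall"] == 0.5
        assert out["per_class"]["SINE"]["fraction_gain"] == 1.0
        assert out["per_class"]["LINE"]["fraction_gain"] == 0.0

    def test_majority_overlap_decides_mixed_elements(self):
        reps = [Interval("chr1", 0, 1000, label="LTR")]
        calls = [self._call("chr1", 0, 700, "gain"), self._call("chr1", 700, 1000, "loss")]
        assert repeat_gain_fraction(calls, reps)["overall"] == 1.0

    def test_recovers_planted_gain_bias_in_repeats(self):
        """End-to-end: plant gain DhMRs preferentially in repeats, call them
        from simulated counts, and recover the planted repeat gain bias."""
        from epidiff.dhmr import bin_exact_test, call_dhmrs, estimate_common_dispersion
        from epidiff.simulate import SimulationConfig, simulate_5hmc_counts, simulate_truth

        cfg = SimulationConfig(
            chrom_lengths=(2_000_000, 2_000_000), n_genes=100,
            frac_gain_repeat=0.6, frac_loss_repeat=0.0, frac_genic=0.2,
        )
        truth = simulate_truth(cfg, seed=9)
        # planted expectation measured from the truth itself
        planted_calls = [
            RegionCall(p.interval, p.direction,
                       1.0 if p.direction == "gain" else -1.0, 1e-6, 1e-6)
            for p in truth.planted_dhmrs
        ]
        expected = repeat_gain_fraction(planted_calls, truth.repeats)["overall"]
        m = simulate_5hmc_counts(truth)
        res = bin_exact_test(m, estimate_common_dispersion(m))
        calls = call_dhmrs(res)
        got = repeat_gain_fraction(calls, truth.repeats)["overall"]
        assert got == pytest.approx(expected, abs=0.05)


class TestCrosstab:
    def test_categories_and_fractions(self):
        calls = pd.DataFrame(
            {"element_id": ["r1", "r2", "r3", "r4"], "direction": ["gain"] * 4}
        )
        expr = pd.DataFrame(
            {"element_id": ["r1", "r2", "r3"], "log2_fc": [1.0, -1.0, 0.0]}
        )
        out = crosstab_repeat_expression(calls, expr).set_index("category")
        assert out.loc["up", "count"] == 1
        assert out.loc["down", "count"] == 1
        assert out.loc["unchanged", "count"] == 1
        assert out.loc["unmeasured", "count"] == 1
        assert out["fraction"].sum() == pytest.approx(1.0)

    def test_all_zero_lfc_all_unchanged(self):
        calls = pd.DataFrame({"element_id": ["r1", "r2"], "direction": ["gain"] * 2})
        expr = pd.DataFrame({"element_id": ["r1", "r2"], "log2_fc": [0.0, 0.1]})
        out = crosstab_repeat_expression(calls, expr).set_index("category")
        assert out.loc["unchanged", "count"] == 2
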