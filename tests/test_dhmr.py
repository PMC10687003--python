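import numpy as np
import pytest

from epidiff.dhmr import (
    BinTestResult,
    DispersionEstimate,
    bin_exact_test,
    call_dhmrs,
    estimate_common_dispersion,
    global_regression,
    meta_profile,
    normalize_cpm,
)
from epidiff.genome import BinCountMatrix, GenomeLayout, Interval, make_genome_bins
from epidiff.simulate import SimulationConfig, simulate_5hmc_counts, simulate_truth
from epidiff.stats import bh_adjust

from oracles import conditional_binomial_twosided


def matrix(counts, libs=None, groups=("mock", "mock", "treated", "treated")):
    counts = np.asarray(counts)
    n_bins, n_samp = counts.shape
    layout = GenomeLayout(("c",), (500 * n_bins,))
    bins = make_genome_bins(layout, 500)
    libs = np.asarray(libs) if libs is not None else np.maximum(counts.sum(axis=0), 1)
    return BinCountMatrix(
        bins, counts, [f"s{i}" for i in range(n_samp)],
        np.asarray(groups, dtype=object), libs, 500,
    )


class TestNormalizeCpm:
    def test_cpm_formula(self):
        m = matrix([[10, 10, 10, 10]], libs=[10**6, 2 * 10**6, 10**6, 10**6])
        nd = normalize_cpm(m)
        assert nd.cpm[0, 0] == pytest.approx(10.0)
        assert nd.cpm[0, 1] == pytest.approx(5.0)

    def test_zero_library_rejected(self):
        m = matrix([[0, 0, 0, 0]], libs=[1, 1, 1, 1])
        m.library_sizes = np.array([0, 1, 1, 1])
        with pytest.raises(ValueError):
            normalize_cpm(m)

    def test_sample_density_sums_to_one_million(self, hmc_counts):
        nd = normalize_cpm(hmc_counts)
        assert np.allclose(nd.cpm.sum(axis=0), 1e6)


class TestDispersion:
    def test_poisson_data_estimates_near_zero(self):
        cfg = SimulationConfig(chrom_lengths=(500_000, 500_000), n_genes=30,
                               n_cgi=20, n_repeats=20, n_gain=0, n_loss=0,
                               n_hyper=0, n_hypo=0, n_background_sites=50)
        t = simulate_truth(cfg, seed=7)
        m = simulate_5hmc_counts(t, dispersion=0.0)
        est = estimate_common_dispersion(m)
        assert est.common_dispersion <= 0.01

    def test_nb_dispersion_recovered(self):
        cfg = SimulationConfig(chrom_lengths=(500_000, 500_000), n_genes=30,
                               n_cgi=20, n_repeats=20, n_gain=0, n_loss=0,
                               n_hyper=0, n_hypo=0, n_background_sites=50)
        t = simulate_truth(cfg, seed=8)
        m = simulate_5hmc_counts(t, dispersion=0.2)
        est = estimate_common_dispersion(m)
        assert 0.1 <= est.common_dispersion <= 0.3

    def test_duplicated_samples_give_zero_dispersion(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(50, size=200)
        counts = np.stack([col, col, col, col], axis=1)
        m = matrix(counts)
        est = estimate_common_dispersion(m)
        assert est.common_dispersion <= 1e-4

    def test_all_zero_matrix_returns_zero_with_warning(self, caplog):
        m = matrix(np.zeros((10, 4), dtype=int), libs=[1, 1, 1, 1])
        est = estimate_common_dispersion(m)
        assert est.common_dispersion == 0.0


class TestExactTest:
    def test_identical_group_sums_give_p_one(self):
        m = matrix([[5, 5, 5, 5], [3, 7, 4, 6]])
        res = bin_exact_test(m, DispersionEstimate(0.0, 1.0))
        assert res.p_value[0] == pytest.approx(1.0)
        assert res.p_value[1] == pytest.approx(1.0)

    def test_extreme_split_matches_closed_form(self):
        """Group sums 0 vs 20 of total 20 with equal libraries: doubled
        binomial tail = 2 * (1/2)**20."""
        counts = np.array([[0, 0, 0, 10, 5, 5]] + [[5, 5, 5, 5, 5, 5]] * 50)
        m = matrix(counts, groups=["mock"] * 3 + ["treated"] * 3,
                   libs=[counts.sum(axis=0).max()] * 6)
        res = bin_exact_test(m, DispersionEstimate(0.0, 1.0))
        assert res.p_value[0] == pytest.approx(2 * 0.5**20, rel=1e-9)

    def test_matches_enumeration_oracle_at_zero_dispersion(self):
        rng = np.random.default_rng(42)
        counts = rng.integers(0, 6, size=(40, 6))
        libs = [max(counts.sum(axis=0).max(), 1)] * 6
        m = matrix(counts, groups=["mock"] * 3 + ["treated"] * 3, libs=libs)
        res = bin_exact_test(m, DispersionEstimate(0.0, 1.0))
        for i in range(40):
            s_trt = counts[i, 3:].sum()
            t = counts[i].sum()
            if t == 0:
                assert res.p_value[i] == 1.0
                continue
            expected = conditional_binomial_twosided(int(s_trt), int(t), 3, 3)
            assert res.p_value[i] == pytest.approx(expected, abs=1e-12)

    def test_label_swap_flips_logfc_and_keeps_p(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(20, size=(30, 6))
        libs = [counts.sum(axis=0).max()] * 6
        g1 = ["mock"] * 3 + ["treated"] * 3
        g2 = ["treated"] * 3 + ["mock"] * 3
        r1 = bin_exact_test(matrix(counts, groups=g1, libs=libs),
                            DispersionEstimate(0.05, 1.0))
        r2 = bin_exact_test(matrix(counts, groups=g2, libs=libs),
                            DispersionEstimate(0.05, 1.0))
        assert np.allclose(r1.p_value, r2.p_value, atol=1e-12)
        assert np.allclose(r1.log_fc, -r2.log_fc, atol=1e-12)

    def test_zero_total_bin_gives_p_one_logfc_zero(self):
        m = matrix([[0, 0, 0, 0], [1, 2, 3, 4]])
        res = bin_exact_test(m, DispersionEstimate(0.0, 1.0))
        assert res.p_value[0] == 1.0 and res.log_fc[0] == 0.0


class TestCallDhmrs:
    def _result(self, pvals, lfc):
        n = len(pvals)
        layout = GenomeLayout(("c",), (500 * n,))
        bins = make_genome_bins(layout, 500)
        return BinTestResult(bins, np.asarray(pvals, float),
                             np.asarray(lfc, float), np.ones(n, bool))

    def test_no_significant_bins_gives_empty_list(self):
        res = self._result([0.5, 0.8, 0.9], [1, -1, 1])
        assert call_dhmrs(res) == []

    def test_adjacent_same_direction_bins_merge(self):
        res = self._result([1e-6, 1e-6, 0.9, 1e-6], [2.0, 1.5, 0.1, -2.0])
        calls = call_dhmrs(res)
        assert len(calls) == 2
        assert calls[0].interval == Interval("c", 0, 1000)
        assert calls[0].direction == "gain"
        assert calls[1].direction == "loss"

    def test_opposite_direction_bins_do_not_merge(self):
        res = self._result([1e-6, 1e-6], [2.0, -2.0])
        assert len(call_dhmrs(res)) == 2

    def test_merge_flag_reports_bins_individually(self):
        res = self._result([1e-6, 1e-6], [2.0, 1.0])
        assert len(call_dhmrs(res, merge_adjacent=False)) == 2


class TestBH:
    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=100)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.01]))[0] == pytest.approx(0.01)

    def test_ties_share_adjusted_value(self):
        adj = bh_adjust(np.array([0.05] * 7))
        assert np.allclose(adj, 0.05)


class TestGlobalRegression:
    def test_identity_gives_unit_slope(self):
        counts = np.repeat(np.arange(1, 21)[:, None], 4, axis=1) * 10
        nd = normalize_cpm(matrix(counts))
        res = global_regression(nd)
        assert res["slope"] == pytest.approx(1.0)
        assert res["pearson_r"] == pytest.approx(1.0)

    def test_global_loss_gives_slope_below_one(self):
        cfg = SimulationConfig(chrom_lengths=(500_000, 500_000), n_genes=30,
                               n_cgi=20, n_repeats=20, n_gain=0, n_loss=0,
                               n_hyper=0, n_hypo=0, n_background_sites=50,
                               treated_global_scale=0.8)
        t = simulate_truth(cfg, seed=5)
        m = simulate_5hmc_counts(t)
        nd = normalize_cpm(m)
        res = global_regression(nd)
        assert res["slope"] < 0.95

    def test_constant_mock_rejected(self):
        counts = np.ones((5, 4), dtype=int)
        with pytest.raises(ValueError):
            global_regression(normalize_cpm(matrix(counts)))


class TestMetaProfile:
    def test_uniform_density_gives_flat_profile(self):
        counts = np.full((10, 4), 50)
        nd = normalize_cpm(matrix(counts))
        prof = meta_profile(nd, [Interval("c", 0, 5000)], n_points=20)
        for g in ("mock", "treated"):
            assert np.allclose(prof.profile[g], prof.profile[g][0])

    def test_minus_strand_region_is_flipped(self):
        counts = (np.arange(1, 11)[:, None] * np.ones((1, 4))).astype(int) * 10
        nd = normalize_cpm(matrix(counts))
        fwd = meta_profile(nd, [Interval("c", 0, 5000, "+")], n_points=10)
        rev = meta_profile(nd, [Interval("c", 0, 5000, "-")], n_points=10)
        assert np.allclose(fwd.profile["mock"], rev.profile["mock"][::-1])

    def test_identical_groups_give_fold_one(self):
        counts = np.tile(np.arange(1, 11)[:, None], (1, 4)) * 10
        nd = normalize_cpm(matrix(counts))
        prof = meta_profile(nd, [Interval("c", 0, 2500), Interval("c", 2500, 5000)])
        assert prof.fold_change == pytest.approx(1.0)

    def test_empty_region_set_rejected(self, hmc_counts):
        with pytest.raises(ValueError):
            meta_profile(normalize_cpm(hmc_counts), [])
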