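"""Site filters, selection-coefficient estimation, windows, gamma p, peaks."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from paleotwas import estimate_selection, filter_sites, gamma_pvalues, merge_peaks, window_scan
from paleotwas.gwss import GenomeWideScan, binned_allele_counts, peaks_to_table

from .conftest import make_dataset, make_samples


class TestSiteFilters:
    def test_stated_rules(self):
        # 4 samples: first two ancient, last two modern
        doses = np.array(
            [
                # snp0: common everywhere -> kept
                [1.0, 1.0, 1.0, 1.0],
                # snp1: fixed in ancients, polymorphic in moderns -> dropped
                [0.0, 0.0, 1.0, 2.0],
                # snp2: overall MAF < 0.1 -> dropped
                [0.0, 0.0, 0.0, 1.0],
            ]
        ).T
        ds = make_dataset(doses)
        samples = make_samples([3000.0, 2000.0, 0.0, 0.0])
        keep = filter_sites(ds, samples)
        np.testing.assert_array_equal(keep, [True, False, False])

    def test_maf_boundary_exactly_point_one_retained(self):
        # 5 samples, alt count 1 -> freq 0.1 exactly
        doses = np.array([[1.0], [0.0], [0.0], [0.0], [0.0]])
        ds = make_dataset(doses)
        samples = make_samples([3000.0, 2000.0, 1000.0, 500.0, 0.0])
        assert filter_sites(ds, samples)[0]

    def test_missingness_rule(self):
        doses = np.full((10, 1), np.nan)
        doses[0, 0] = 1.0  # 90% missing: retained (rule is strictly greater)
        ds = make_dataset(doses)
        samples = make_samples([3000.0] + [1000.0] * 8 + [0.0])
        assert filter_sites(ds, samples)[0]
        doses2 = np.full((11, 1), np.nan)
        doses2[0, 0] = 1.0
        ds2 = make_dataset(doses2)
        samples2 = make_samples([3000.0] + [1000.0] * 9 + [0.0])
        assert not filter_sites(ds2, samples2)[0]

    def test_retained_count_matches_bookkeeping(self, rng):
        n_snps = 200
        freq = rng.uniform(0.0, 1.0, n_snps)
        doses = rng.binomial(2, freq, size=(100, n_snps)).astype(float)
        ds = make_dataset(doses)
        dates = np.concatenate([rng.uniform(500, 4500, 80), np.zeros(20)])
        samples = make_samples(dates)
        keep = filter_sites(ds, samples)
        f = doses.mean(axis=0) / 2
        fa = doses[:80].mean(axis=0) / 2
        expected = (np.minimum(f, 1 - f) >= 0.1) & (np.minimum(fa, 1 - fa) > 0)
        np.testing.assert_array_equal(keep, expected)


class TestEstimator:
    def logistic_counts(self, s, a=-1.0, n_per_bin=200_000, n_bins=40):
        g = np.linspace(-160.0, 0.0, n_bins)
        p = special.expit(a + s * g)
        n = np.full(n_bins, float(n_per_bin))
        return np.round(p * n), n, g

    @pytest.mark.parametrize("s_true", [0.0, 0.005, 0.01, 0.02])
    def test_recovers_s_on_noiseless_logistic_input(self, s_true):
        d, n, g = self.logistic_counts(s_true)
        est = estimate_selection(d, n, g)
        assert est.converged
        assert est.s_hat == pytest.approx(s_true, abs=1e-3)
        assert est.rms_s == pytest.approx(abs(est.s_hat))

    def test_constant_frequency_gives_zero(self):
        g = np.linspace(-160.0, 0.0, 20)
        n = np.full(20, 1e6)
        d = np.full(20, 3e5)
        est = estimate_selection(d, n, g)
        assert abs(est.s_hat) < 1e-6

    def test_antisymmetric_under_allele_relabeling(self):
        d, n, g = self.logistic_counts(0.015)
        e1 = estimate_selection(d, n, g)
        e2 = estimate_selection(n - d, n, g)
        assert e2.s_hat == pytest.approx(-e1.s_hat, rel=1e-4)

    def test_monomorphic_series_flagged(self):
        g = np.linspace(-160.0, 0.0, 10)
        n = np.full(10, 100.0)
        est = estimate_selection(np.zeros(10), n, g)
        assert not est.converged

    def test_blocks_mode_collapses_to_scalar_at_large_smoothing(self):
        d, n, g = self.logistic_counts(0.012, n_bins=30)
        scalar = estimate_selection(d, n, g, mode="scalar")
        blocks = estimate_selection(d, n, g, mode="blocks", smoothing=1e12, n_blocks=4)
        np.testing.assert_allclose(blocks.s_hat, scalar.s_hat, atol=2e-4)
        assert blocks.rms_s == pytest.approx(scalar.rms_s, abs=2e-4)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            estimate_selection([1.0], [10.0], [0.0])

    def test_binned_counts_bookkeeping(self):
        doses = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0], [1.0, 2.0]])
        ds = make_dataset(doses)
        samples = make_samples([250.0, 220.0, 150.0, 0.0])
        D, N, g = binned_allele_counts(ds, samples, bin_years=100.0, generation_time=28.0)
        assert D.shape == (2, 3)
        # oldest bin (dates 250,220): derived = 0+1, total = 4
        np.testing.assert_array_equal(D[0], [1.0, 2.0, 1.0])
        np.testing.assert_array_equal(N[0], [4.0, 2.0, 2.0])
        assert g[0] < g[1] < g[2] <= 0


class TestWindows:
    def est_frame(self, rms, chrom="1", spacing=1000):
        n = len(rms)
        return pd.DataFrame(
            {
                "snp_id": [f"s{i}" for i in range(n)],
                "chrom": chrom,
                "pos": [(i + 1) * spacing for i in range(n)],
                "rms_s": rms,
                "converged": True,
            }
        )

    def test_forty_snps_give_three_full_windows(self):
        w = window_scan(self.est_frame(np.ones(40)))
        assert len(w) == 3
        assert not w["partial"].any()
        np.testing.assert_array_equal(w["start"], [1000, 11000, 21000])
        np.testing.assert_array_equal(w["end"], [20000, 30000, 40000])

    def test_constant_rms_gives_constant_statistic(self):
        w = window_scan(self.est_frame(np.full(40, 0.7)))
        np.testing.assert_allclose(w["stat"], 0.7)

    def test_statistics_match_brute_force(self, rng):
        rms = rng.uniform(0, 0.05, 55)
        w = window_scan(self.est_frame(rms))
        starts = [0, 10, 20, 30]
        for row, s0 in zip(w.itertuples(), starts):
            assert row.stat == pytest.approx(rms[s0 : s0 + 20].mean())
        # trailing partial window (SNPs 40-54, 15 SNPs) flagged
        assert w.iloc[-1]["partial"]
        assert w.iloc[-1]["n_snps"] == 15
        assert w.iloc[-1]["stat"] == pytest.approx(rms[40:].mean())

    def test_short_chromosome_skipped(self, caplog):
        w = window_scan(self.est_frame(np.ones(7)))
        assert len(w) == 0

    def test_windows_do_not_cross_chromosomes(self, rng):
        f1 = self.est_frame(rng.uniform(0, 0.1, 20), chrom="1")
        f2 = self.est_frame(rng.uniform(0, 0.1, 20), chrom="2")
        w = window_scan(pd.concat([f1, f2], ignore_index=True))
        assert len(w) == 2
        assert set(w["chrom"]) == {"1", "2"}

    def test_statistic_permutation_invariant_within_window(self, rng):
        rms = rng.uniform(0, 0.05, 20)
        w1 = window_scan(self.est_frame(rms))
        w2 = window_scan(self.est_frame(rng.permutation(rms)))
        assert w1["stat"].iloc[0] == pytest.approx(w2["stat"].iloc[0])


class TestGamma:
    def test_parameter_recovery_and_uniform_p(self, rng):
        stats_vec = rng.gamma(2.0, 0.01, size=10_000)
        windows = pd.DataFrame({"chrom": "1", "start": 1, "end": 2, "stat": stats_vec})
        out, (shape, scale) = gamma_pvalues(windows)
        assert shape == pytest.approx(2.0, abs=0.05)
        assert scale == pytest.approx(0.01, rel=0.05)
        ks = stats.kstest(out["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_maximum_statistic_has_minimum_p(self, rng):
        windows = pd.DataFrame(
            {"chrom": "1", "start": 1, "end": 2, "stat": rng.gamma(2.0, 0.01, 200)}
        )
        out, _ = gamma_pvalues(windows)
        assert out["p"].idxmin() == out["stat"].idxmax()

    def test_duplicating_windows_preserves_fit(self, rng):
        stats_vec = rng.gamma(3.0, 0.02, size=500)
        w1 = pd.DataFrame({"chrom": "1", "start": 1, "end": 2, "stat": stats_vec})
        w2 = pd.DataFrame(
            {"chrom": "1", "start": 1, "end": 2, "stat": np.tile(stats_vec, 2)}
        )
        _, p1 = gamma_pvalues(w1)
        _, p2 = gamma_pvalues(w2)
        assert p1 == pytest.approx(p2, rel=1e-6)

    def test_zero_statistics_replaced(self, rng):
        stats_vec = rng.gamma(2.0, 0.01, size=100)
        stats_vec[:3] = 0.0
        windows = pd.DataFrame({"chrom": "1", "start": 1, "end": 2, "stat": stats_vec})
        out, _ = gamma_pvalues(windows)
        assert np.isfinite(out["p"]).all() and (out["p"] < 1).all()

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            gamma_pvalues(pd.DataFrame({"stat": np.ones(10)}))


class TestPeaks:
    def windows(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "stat", "p"])

    def test_merge_rule_five_mb(self):
        w49 = self.windows(
            [("1", 1_000_000, 1_050_000, 0.1, 1e-6), ("1", 5_950_000, 6_000_000, 0.1, 1e-6)]
        )
        assert len(merge_peaks(w49, p_threshold=1e-4)) == 1  # 4.9 Mb apart
        w51 = self.windows(
            [("1", 1_000_000, 1_050_000, 0.1, 1e-6), ("1", 6_150_000, 6_200_000, 0.1, 1e-6)]
        )
        assert len(merge_peaks(w51, p_threshold=1e-4)) == 2  # 5.1 Mb apart

    def test_buffer_arithmetic(self):
        w = self.windows([("1", 1_000_000, 1_050_000, 0.1, 1e-6)])
        pk = merge_peaks(w, p_threshold=1e-4)[0]
        assert (pk.start, pk.end) == (900_000, 1_150_000)

    def test_gene_overlap_counts_match_brute_force(self, rng):
        w = self.windows([("1", 2_000_000, 2_500_000, 0.1, 1e-6)])
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(100)],
                "chrom": "1",
                "start": rng.integers(1, 5_000_000, 100),
            }
        )
        genes["end"] = genes["start"] + rng.integers(1000, 200_000, 100)
        modeled = {f"g{i}" for i in range(0, 100, 2)}
        signif = {"g0", "g3"}
        pk = merge_peaks(
            w, p_threshold=1e-4, gene_table=genes, modeled_genes=modeled,
            significant_genes=signif,
        )[0]
        lo, hi = 1_900_000, 2_600_000
        overlap = genes[(genes["start"] <= hi) & (genes["end"] >= lo)]
        assert pk.n_all_genes == len(overlap)
        assert pk.n_modeled_genes == sum(g in modeled for g in overlap["gene_id"])
        assert pk.n_significant_genes == sum(g in signif for g in overlap["gene_id"])
        assert len(peaks_to_table([pk])) == 1

    def test_different_chromosomes_never_merge(self):
        w = self.windows(
            [("1", 1_000_000, 1_050_000, 0.1, 1e-6), ("2", 1_100_000, 1_150_000, 0.1, 1e-6)]
        )
        assert len(merge_peaks(w, p_threshold=1e-4)) == 2


class TestScanFacade:
    def test_selection_raises_window_statistic(self, rng):
        # monotone response of the window statistic to true s at a locus
        from paleotwas.simulate import SimConfig, simulate_cohort, simulate_trajectories

        stats_at_s = []
        for s_true in (0.0, 0.01, 0.03):
            n_snps = 60
            config = SimConfig(seed=3, imputation_quality_range=(1.0, 1.0))
            p0 = np.full(n_snps, 0.4)
            s_vec = np.zeros(n_snps)
            s_vec[20:40] = s_true
            paths = simulate_trajectories(
                p0, s_vec, config.n_generations, 10_000, np.random.default_rng(5)
            )
            trajs = {f"snp_{i}": paths[i] for i in range(n_snps)}
            dataset, samples = simulate_cohort(config, trajs)
            scan = GenomeWideScan(dataset, samples)
            D, N, g = binned_allele_counts(dataset, samples)
            from paleotwas.gwss import estimate_selection_table

            est = estimate_selection_table(dataset, samples)
            w = window_scan(est)
            sel = w[(w["start"] >= 20 * 20_000) & (w["end"] <= 41 * 20_000)]
            stats_at_s.append(sel["stat"].mean())
        assert stats_at_s[0] < stats_at_s[1] < stats_at_s[2]

    def test_fit_produces_schema_valid_windows(self):
        from paleotwas import simulate_study

        study = simulate_study(n_snps=1200, n_genes=5, seed=31)
        res = GenomeWideScan(study.dataset, study.samples).fit()
        w = res.windows
        assert {"chrom", "start", "end", "n_snps", "stat", "p"} <= set(w.columns)
        assert (w["stat"] >= 0).all()
        assert ((w["p"] > 0) & (w["p"] <= 1)).all()
        assert "gamma" in res.summary()
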