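"""Insertion-site characterization: feature/state classification with
baselines, signal profiles, metagene positions, orientation, TSD logos,
hotspot clustering (with exhaustive oracle) and expression tests."""

from __future__ import annotations

import numpy as np
import pytest
import pandas as pd
from scipy import stats

from temkit import simulate, sites
from temkit.insertions import InsertionCall


@pytest.fixture(scope="module")
def sim():
    cfg = simulate.SimulationConfig(seed=61, min_insertion_spacing=100)
    return simulate.simulate_genome(cfg)


def brute_force_clusters(positions, window):
    out = []
    by = {}
    for c, p in positions:
        by.setdefault(c, []).append(p)
    for c in sorted(by):
        ps = sorted(by[c])
        i = 0
        while i < len(ps):
            j = i
            while j + 1 < len(ps) and ps[j + 1] - ps[i] <= window:
                j += 1
            if j - i + 1 >= 2:
                out.append((c, ps[i], ps[j], j - i + 1))
            i = j + 1
    return out


class TestClassifySites:
    def test_fractions_and_baselines_sum_to_one(self, sim):
        rng = np.random.default_rng(62)
        cfg = simulate.SimulationConfig(seed=61, min_insertion_spacing=100)
        pts = simulate.sample_insertion_sites(sim, 100, cfg, rng)
        rep = sites.classify_sites(pts, sim.annotation, sim.states)
        assert sum(f for _, f, _ in rep.feature_freq.values()) == pytest.approx(1.0)
        assert sum(g for _, _, g in rep.feature_freq.values()) == pytest.approx(1.0)
        assert sum(f for _, f, _ in rep.state_freq.values()) == pytest.approx(1.0)
        assert sum(g for _, _, g in rep.state_freq.values()) == pytest.approx(1.0)
        assert 0.0 <= rep.genic_fraction() <= 1.0

    def test_intergenic_only_sites_have_zero_genic_fraction(self, sim):
        # pick positions known to be intergenic
        arrays = sites.feature_class_arrays(sim.annotation, sim.states.chrom_sizes())
        chrom = "chr1"
        code = sites.FEATURE_CLASSES.index("intergenic")
        inter = np.flatnonzero(arrays[chrom] == code)[:50]
        pts = [(chrom, int(q) + 1) for q in inter]
        rep = sites.classify_sites(pts, sim.annotation, sim.states)
        assert rep.genic_fraction() == 0.0

    def test_state_frequencies_match_truth_sampling(self, sim):
        cfg = simulate.SimulationConfig(
            seed=61,
            min_insertion_spacing=100,
            preference_weights={s: (10.0 if s == 5 else 1.0) for s in range(1, 10)},
        )
        rng = np.random.default_rng(63)
        pts = simulate.sample_insertion_sites(sim, 300, cfg, rng)
        rep = sites.classify_sites(pts, sim.annotation, sim.states)
        truth = sum(1 for c, p in pts if sim.states.state_at(c, p - 1) == 5)
        assert rep.state_freq[5][0] == truth


class TestSignalProfile:
    def test_constant_track(self, sim):
        track = {c: np.full(n, 3.0) for c, n in sim.chrom_sizes().items()}
        prof = sites.signal_profile([("chr1", 50_000)], track)
        assert prof.shape == (40,)
        np.testing.assert_allclose(prof, 3.0)

    def test_delta_peak_maximal_in_central_bins(self, sim):
        calls = [("chr1", 20_000), ("chr1", 60_000), ("chr2", 30_000)]
        track = {c: np.zeros(n) for c, n in sim.chrom_sizes().items()}
        for c, p in calls:
            track[c][p - 3 : p + 2] = 100.0
        prof = sites.signal_profile(calls, track)
        central = {19, 20}
        assert set(np.argsort(prof)[-2:]) == central

    def test_linearity(self, sim):
        rng = np.random.default_rng(64)
        track = {c: rng.random(n) for c, n in sim.chrom_sizes().items()}
        calls = [("chr1", 30_000), ("chr2", 90_000)]
        p1 = sites.signal_profile(calls, track)
        p3 = sites.signal_profile(calls, {c: 3.0 * a for c, a in track.items()})
        np.testing.assert_allclose(p3, 3.0 * p1)

    def test_contig_end_bins_excluded(self, sim):
        track = {c: np.full(n, 2.0) for c, n in sim.chrom_sizes().items()}
        prof = sites.signal_profile([("chr1", 500)], track)
        assert np.isnan(prof[0])  # upstream bins fall off the contig
        assert prof[-1] == pytest.approx(2.0)


class TestMetagene:
    def test_midpoint_of_plus_gene(self):
        feat = simulate.Feature("g", "chr1", 1000, 2000, "+", "gene")
        rel, hist = sites.metagene_positions([("chr1", 1501)], [feat])
        assert rel[0] == pytest.approx(50.0)
        assert hist.sum() == 1

    def test_strand_correction_on_minus_gene(self):
        feat = simulate.Feature("g", "chr1", 1000, 2000, "-", "gene")
        rel, _ = sites.metagene_positions([("chr1", 1101)], [feat])
        assert rel[0] == pytest.approx(90.0)

    def test_uniform_positions_give_flat_histogram(self):
        feat = simulate.Feature("g", "chr1", 0, 100_000, "+", "gene")
        rng = np.random.default_rng(65)
        calls = [("chr1", int(p) + 1) for p in rng.integers(0, 100_000, size=2000)]
        rel, hist = sites.metagene_positions(calls, [feat])
        chi = stats.chisquare(hist)
        assert chi.pvalue > 0.01

class TestOrientation:
    def test_all_same_orientation(self):
        feat = simulate.Feature("g", "chr1", 0, 1000, "+", "gene")
        calls = [InsertionCall("chr1", 500, "ACGTA", "+", 1, 1)]
        assert sites.orientation_concordance(calls, [feat]) == (1, 0)

    def test_single_opposite(self):
        feat = simulate.Feature("g", "chr1", 0, 1000, "+", "gene")
        calls = [InsertionCall("chr1", 500, "ACGTA", "-", 1, 1)]
        assert sites.orientation_concordance(calls, [feat]) == (0, 1)

    def test_balanced_orientations_not_significant(self):
        rng = np.random.default_rng(66)
        feat = simulate.Feature("g", "chr1", 0, 100_000, "+", "gene")
        calls = [
            InsertionCall("chr1", int(rng.integers(1, 100_000)), "",
                          "+" if rng.random() < 0.5 else "-", 1, 1)
            for _ in range(400)
        ]
        same, opp = sites.orientation_concordance(calls, [feat])
        assert same + opp == 400
        res = stats.binomtest(same, same + opp, 0.5)
        assert res.pvalue > 0.001


class TestTsdLogo:
    def test_identical_tsds_reach_two_bits(self):
        _, ic = sites.tsd_logo(["ACGTA"] * 25)
        np.testing.assert_allclose(ic, 2.0)

    def test_uniform_random_tsds_near_zero_bits(self):
        rng = np.random.default_rng(67)
        tsds = ["".join(rng.choice(list("ACGT"), 5)) for _ in range(10_000)]
        _, ic = sites.tsd_logo(tsds)
        assert (ic < 0.01).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no TSD"):
            sites.tsd_logo([])

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            sites.tsd_logo(["ACGTA", "ACGT"])


class TestHotspots:
    def test_sparse_insertions_have_no_clusters(self):
        pos = [("chr1", p) for p in range(10_000, 200_000, 20_000)]
        tally = sites.find_hotspots({"a": pos}, {"chr1": 500_000}, window=10_000)
        assert tally.clusters == []
        assert tally.size_histogram == {}

    def test_worked_example_cluster_of_three(self):
        pos = [("chr1", p) for p in (100, 5000, 9900, 30000)]
        tally = sites.find_hotspots({"a": pos}, {"chr1": 100_000}, window=10_000)
        assert tally.clusters == [("chr1", 100, 9900, 3)]
        assert tally.size_histogram == {3: 1}

    def test_equals_exhaustive_oracle_on_random_lists(self):
        rng = np.random.default_rng(68)
        sizes = {"chr1": 300_000, "chr2": 200_000}
        for _ in range(250):
            n = int(rng.integers(2, 60))
            pos = [
                (("chr1", "chr2")[int(rng.integers(2))], int(rng.integers(1, 200_000)))
                for _ in range(n)
            ]
            tally = sites.find_hotspots({"a": pos}, sizes, window=10_000)
            assert tally.clusters == brute_force_clusters(pos, 10_000)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            sites.find_hotspots({"a": [("chr1", 5)]}, {"chr1": 100}, window=0)

    def test_chi2_null_is_calibrated(self):
        rng = np.random.default_rng(69)
        ps = []
        for _ in range(100):
            pos = [("chr1", int(rng.integers(1, 2_000_000))) for _ in range(300)]
            tally = sites.find_hotspots({"a": pos}, {"chr1": 2_000_000}, window=10_000)
            ps.append(tally.chi2_p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_clustered_insertions_reject_the_null(self):
        rng = np.random.default_rng(70)
        centers = rng.integers(1, 2_000_000, size=30)
        pos = [
            ("chr1", int(c + rng.integers(0, 2000)))
            for c in centers
            for _ in range(10)
        ]
        tally = sites.find_hotspots({"a": pos}, {"chr1": 2_000_000}, window=10_000)
        assert tally.chi2_p < 1e-10


class TestExpression:
    def _table(self, rng, n=3000):
        genes = [f"G{i}" for i in range(n)]
        return pd.Series(rng.lognormal(2.0, 1.0, size=n), index=genes)

    def test_null_calibration(self):
        rng = np.random.default_rng(71)
        ps = []
        for rep in range(60):
            expr = self._table(rng)
            targets = list(rng.choice(expr.index, size=200, replace=False))
            res = sites.target_expression_test(targets, expr, seed=int(rng.integers(2**31)))
            ps.append(res.pvalue)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_downshifted_targets_detected_with_direction(self):
        rng = np.random.default_rng(72)
        expr = self._table(rng)
        targets = list(rng.choice(expr.index, size=200, replace=False))
        expr.loc[targets] = expr.loc[targets] / 2.0
        res = sites.target_expression_test(targets, expr, seed=73)
        assert res.pvalue < 0.01
        assert res.direction == "lower"
        assert (res.pairwise["p_bonferroni"] < 0.05).all()

    def test_identical_values_give_null_result(self):
        expr = pd.Series(1.0, index=[f"G{i}" for i in range(100)])
        res = sites.target_expression_test(["G0", "G1"], expr, seed=74)
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_too_small_table_rejected(self):
        expr = pd.Series(1.0, index=[f"G{i}" for i in range(10)])
        with pytest.raises(ValueError, match="too small"):
            sites.target_expression_test(["G0", "G1", "G2"], expr, seed=75)
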