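"""Bin statistics, data-derived thresholds and fixed-region calls."""

import numpy as np
import pytest

from divscan import fixation_scan as fx
from divscan import windowed_diversity as wd
from divscan.io_formats import PopulationMap


def _bins(het_dom, ratio, contig="c", width=300_000):
    n = len(het_dom)
    return fx.BinStats(
        contigs=np.array([contig] * n, dtype=object),
        starts=np.arange(n) * width, ends=(np.arange(n) + 1) * width,
        het_dom=np.array(het_dom, dtype=float),
        homnr_dom=np.full(n, 1e-4), homnr_wild=np.full(n, 2e-4),
        diff_norm=np.zeros(n), ratio=np.array(ratio, dtype=float))


def _profile_from_counts(samples, homnr_counts, het_counts, covered):
    n = homnr_counts.shape[0]
    return wd.WindowProfile(
        samples=samples, contigs=np.array(["c"] * n, dtype=object),
        starts=np.arange(n) * 300_000, ends=(np.arange(n) + 1) * 300_000,
        het=het_counts, homnr=homnr_counts, covered=covered)


class TestBinStats:
    def test_hand_built_ratio(self):
        # wild homnr density 4e-4, each domesticated population 2e-4
        pm = PopulationMap({"d1": "D1", "d2": "D2", "w": "W"},
                           frozenset({"W"}))
        covered = np.full((1, 3), 100_000)
        homnr = np.array([[20, 20, 40]])
        het = np.zeros((1, 3), dtype=int)
        prof = _profile_from_counts(["d1", "d2", "w"], homnr, het, covered)
        bins = fx.bin_stats(prof, pm)
        assert bins.homnr_wild[0] == pytest.approx(4e-4)
        assert bins.homnr_dom[0] == pytest.approx(2e-4)
        assert bins.ratio[0] == pytest.approx(2.0)
        # diff normaliser is the all-population mean: (2+2+4)/3 e-4
        assert bins.diff_norm[0] == pytest.approx((4e-4 - 2e-4)
                                                  / (8e-4 / 3))

    def test_zero_everywhere_is_undefined(self):
        pm = PopulationMap({"d": "D", "w": "W"}, frozenset({"W"}))
        prof = _profile_from_counts(["d", "w"], np.zeros((1, 2), int),
                                    np.zeros((1, 2), int),
                                    np.full((1, 2), 100_000))
        bins = fx.bin_stats(prof, pm)
        assert bins.het_dom[0] == 0
        assert np.isnan(bins.ratio[0])

    def test_wild_signal_over_zero_domesticated_is_infinite(self):
        pm = PopulationMap({"d": "D", "w": "W"}, frozenset({"W"}))
        prof = _profile_from_counts(["d", "w"], np.array([[0, 10]]),
                                    np.zeros((1, 2), int),
                                    np.full((1, 2), 100_000))
        bins = fx.bin_stats(prof, pm)
        assert np.isinf(bins.ratio[0])

    def test_populations_weighted_equally_not_individuals(self):
        # population D1 has two members; its density is averaged first
        pm = PopulationMap({"a": "D1", "b": "D1", "c": "D2", "w": "W"},
                           frozenset({"W"}))
        homnr = np.array([[10, 30, 10, 10]])
        prof = _profile_from_counts(["a", "b", "c", "w"], homnr,
                                    np.zeros((1, 4), int),
                                    np.full((1, 4), 100_000))
        bins = fx.bin_stats(prof, pm)
        # D1 mean = 2e-4, D2 = 1e-4 -> domesticated mean 1.5e-4
        assert bins.homnr_dom[0] == pytest.approx(1.5e-4)

    def test_invariant_to_uniform_coverage_rescaling(self):
        pm = PopulationMap({"d": "D", "w": "W"}, frozenset({"W"}))
        homnr = np.array([[7, 13]])
        het = np.array([[3, 5]])
        a = fx.bin_stats(_profile_from_counts(
            ["d", "w"], homnr, het, np.full((1, 2), 100_000)), pm)
        b = fx.bin_stats(_profile_from_counts(
            ["d", "w"], homnr * 2, het * 2, np.full((1, 2), 200_000)), pm)
        assert a.ratio[0] == pytest.approx(b.ratio[0])
        assert a.diff_norm[0] == pytest.approx(b.diff_norm[0])


class TestThresholds:
    def test_lower_tail_order_statistic(self):
        het = (np.arange(1, 101)) * 1e-5
        bins = _bins(het, np.ones(100))
        het_thr, _ = fx.derive_thresholds(bins)
        assert het_thr == pytest.approx(5e-5)
        # exactly 5% of bins are at or below the threshold
        assert np.mean(het <= het_thr) == 0.05

    def test_upper_tail_order_statistic(self):
        ratio = np.linspace(1.0, 3.0, 200)
        bins = _bins(np.full(200, 1e-4), ratio)
        _, ratio_thr = fx.derive_thresholds(bins)
        assert np.mean(ratio >= ratio_thr) >= 0.05
        above = ratio[ratio > ratio_thr]
        assert np.mean(ratio >= above.min()) < 0.05 if above.size else True

    def test_identical_bins_collapse_to_that_value(self):
        bins = _bins(np.full(50, 2e-4), np.full(50, 1.5))
        het_thr, ratio_thr = fx.derive_thresholds(bins)
        assert het_thr == 2e-4 and ratio_thr == 1.5


class TestCalls:
    def test_inclusive_boundaries(self):
        bins = _bins([2e-4, 2e-4], [1.73, 1.72])
        calls = fx.call_fixed_regions(bins, 2e-4, 1.73, merge=False)
        assert len(calls) == 1 and calls[0].start == 0

    def test_adjacent_bins_merged(self):
        bins = _bins([1e-5] * 3 + [1e-3] + [1e-5], [2.0] * 5)
        calls = fx.call_fixed_regions(bins)
        assert [(c.start, c.end, c.n_bins) for c in calls] == [
            (0, 900_000, 3), (1_200_000, 1_500_000, 1)]

    def test_infinite_ratio_passes(self):
        bins = _bins([1e-5], [np.inf])
        assert len(fx.call_fixed_regions(bins)) == 1

    def test_monotone_in_both_thresholds(self, small_sim):
        table, _, tracks, pm = small_sim
        prof = wd.window_profile(table, tracks)
        bins = fx.bin_stats(prof, pm)
        n_calls = []
        for het_thr, ratio_thr in [(5e-4, 1.2), (2e-4, 1.73), (1e-4, 2.5)]:
            calls = fx.call_fixed_regions(bins, het_thr, ratio_thr,
                                          merge=False)
            n_calls.append(len(calls))
        assert n_calls == sorted(n_calls, reverse=True)

    def test_planted_sweep_recovered_on_simulation(self, small_sim):
        table, truth, tracks, pm = small_sim
        prof = wd.window_profile(table, tracks)
        bins = fx.bin_stats(prof, pm)
        calls = fx.call_fixed_regions(bins)
        def overlaps(call, region):
            c, s, e = region
            return call.contig == c and call.start < e and call.end > s
        assert any(overlaps(c, truth.sweep_regions[0]) for c in calls)

    def test_bin_stats_match_brute_force_from_genotypes(self, small_sim):
        from divscan.variant_filtering import passing_mask
        from divscan.io_formats import HOM_NONREF, depth_at

        table, _, tracks, pm = small_sim
        prof = wd.window_profile(table, tracks)
        bins = fx.bin_stats(prof, pm)
        widx = 3
        contig, start, end = (bins.contigs[widx], bins.starts[widx],
                              bins.ends[widx])
        ok = passing_mask(table, 20, 3, 15)
        wild_members = pm.samples_in("SM")
        dens = []
        for s in wild_members:
            j = table.sample_index(s)
            in_win = ((table.contigs == contig) & (table.pos - 1 >= start)
                      & (table.pos - 1 < end))
            n = np.sum(in_win & ok[:, j] & (table.gt[:, j] == HOM_NONREF))
            d = depth_at(tracks[s], contig, np.arange(start, end))
            dens.append(n / np.sum((d >= 3) & (d <= 15)))
        assert bins.homnr_wild[widx] == pytest.approx(np.mean(dens))
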