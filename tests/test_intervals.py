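"""Interval arithmetic vs. brute-force oracles; profiles and densities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spikecal import intervals as iv
from spikecal import simulate as sim

from conftest import (brute_force_counts, brute_force_merge,
                      brute_force_overlaps, random_interval_set)


class TestMakeWindows:
    def test_truncated_final_window(self):
        w = iv.make_windows({"chrA": 250}, 100)
        assert w[["start", "end"]].values.tolist() == [[0, 100], [100, 200],
                                                       [200, 250]]

    def test_exact_fit_single_window(self):
        w = iv.make_windows({"chrA": 100}, 100)
        assert len(w) == 1 and w.at[0, "end"] == 100

    @given(st.dictionaries(st.sampled_from(["c1", "c2", "c3"]),
                           st.integers(1, 10_000), min_size=1),
           st.integers(1, 3_000))
    def test_count_and_coverage_identities(self, sizes, width):
        w = iv.make_windows(sizes, width)
        assert len(w) == sum(-(-L // width) for L in sizes.values())
        assert (w["end"] - w["start"]).sum() == sum(sizes.values())
        for chrom, sub in w.groupby("chrom"):
            sub = sub.sort_values("start")
            assert sub["start"].iloc[0] == 0
            assert sub["end"].iloc[-1] == sizes[chrom]
            assert (sub["start"].to_numpy()[1:]
                    == sub["end"].to_numpy()[:-1]).all()

    def test_empty_and_invalid_inputs(self):
        with pytest.raises(ValueError):
            iv.make_windows({}, 100)
        with pytest.raises(ValueError):
            iv.make_windows({"c": 10}, 0)


class TestCountInIntervals:
    def test_midpoint_containment(self):
        frags = pd.DataFrame({"chrom": ["c", "c"], "pos": [5, 15]})
        win = pd.DataFrame({"chrom": ["c", "c"], "start": [0, 10],
                            "end": [10, 20]})
        np.testing.assert_array_equal(iv.count_in_intervals(frags, win),
                                      [1, 1])

    def test_boundary_belongs_to_right_interval(self):
        frags = pd.DataFrame({"chrom": ["c"], "pos": [10]})
        win = pd.DataFrame({"chrom": ["c", "c"], "start": [0, 10],
                            "end": [10, 20]})
        np.testing.assert_array_equal(iv.count_in_intervals(frags, win),
                                      [0, 1])

    def test_unknown_chromosome_warns_and_counts_unassigned(self):
        frags = pd.DataFrame({"chrom": ["nope"], "pos": [5]})
        win = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [10]})
        with pytest.warns(UserWarning, match="unknown chromosome"):
            counts, un = iv.count_in_intervals(frags, win,
                                               return_unassigned=True)
        assert counts.sum() == 0 and un == 1

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            win = iv.make_windows({"chrA": 5_000, "chrB": 3_000},
                                  int(rng.integers(100, 900)))
            frags = pd.DataFrame({
                "chrom": rng.choice(["chrA", "chrB"], 300),
                "pos": rng.integers(0, 3_000, 300)})
            np.testing.assert_array_equal(
                iv.count_in_intervals(frags, win),
                brute_force_counts(frags, win))

    def test_partition_conserves_total(self, null_chip):
        frags = sim.fragment_midpoints(null_chip.counts,
                                       null_chip.sample_ids[0], seed=0)
        win = iv.make_windows(null_chip.config.target_chrom_sizes, 250_000)
        assert iv.count_in_intervals(frags, win).sum() == len(frags)


class TestMergeAndOverlap:
    @given(st.integers(0, 2**31 - 1))
    def test_merge_matches_fixpoint_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s = random_interval_set(rng, int(rng.integers(1, 30)), size=10_000)
        pd.testing.assert_frame_equal(
            iv.merge_intervals(s).reset_index(drop=True),
            brute_force_merge(s), check_dtype=False)

    @given(st.integers(0, 2**31 - 1))
    def test_overlap_mask_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        q = random_interval_set(rng, 40, size=20_000)
        s = random_interval_set(rng, 40, size=20_000)
        np.testing.assert_array_equal(iv.overlaps_any(q, s),
                                      brute_force_overlaps(q, s))


class TestConsensus:
    def test_identical_sets_return_that_set(self):
        peaks = pd.DataFrame({"chrom": ["c"] * 2, "start": [0, 100],
                              "end": [50, 200]})
        out = iv.consensus_peaks([peaks, peaks.copy(), peaks.copy()])
        pd.testing.assert_frame_equal(out, peaks, check_dtype=False)

    def test_peak_in_two_of_three_sets_dropped(self):
        a = pd.DataFrame({"chrom": ["c", "c"], "start": [0, 100],
                          "end": [50, 150]})
        b = a.copy()
        c = a.iloc[:1].copy()
        out = iv.consensus_peaks([a, b, c])
        assert out[["start", "end"]].values.tolist() == [[0, 50]]

    def test_single_set_is_identity_after_merge(self):
        peaks = pd.DataFrame({"chrom": ["c"], "start": [5], "end": [9]})
        pd.testing.assert_frame_equal(iv.consensus_peaks([peaks]), peaks,
                                      check_dtype=False)

    def test_disjoint_false_peaks_removed_by_triple_consensus(self,
                                                              chip_config):
        truth = sim.build_intervals(chip_config)
        truth = truth[truth["is_peak"]][["chrom", "start", "end"]]
        reps = sim.simulate_peak_calls(truth, 3, jitter_bp=50,
                                       fdr_extra_peaks=5,
                                       chrom_sizes=chip_config.target_chrom_sizes,
                                       seed=9)
        out = iv.consensus_peaks(reps)
        # every consensus region overlaps a true peak, and every true peak
        # is recovered (checked against the all-pairs oracle)
        assert brute_force_overlaps(out, truth).all()
        assert brute_force_overlaps(truth, out).all()

    def test_consensus_monotone_in_added_sets(self):
        rng = np.random.default_rng(5)
        sets = [random_interval_set(rng, 15, size=20_000) for _ in range(3)]
        base = iv.consensus_peaks(sets[:2])
        more = iv.consensus_peaks(sets)
        # adding an input set never adds a consensus region
        assert brute_force_overlaps(more, base).all()


class TestFilters:
    def test_empty_blacklist_is_identity(self):
        peaks = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [10]})
        out = iv.subtract_blacklist(
            peaks, pd.DataFrame(columns=["chrom", "start", "end"]))
        pd.testing.assert_frame_equal(out, peaks)

    def test_single_bp_overlap_removes_whole_peak(self):
        peaks = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [10]})
        bl = pd.DataFrame({"chrom": ["c"], "start": [9], "end": [20]})
        assert len(iv.subtract_blacklist(peaks, bl)) == 0

    def test_retained_artifact_peaks_are_exactly_those_removed(self):
        rng = np.random.default_rng(11)
        real = random_interval_set(rng, 20, genome=("chrA",), size=200_000)
        real = iv.merge_intervals(real)
        artifacts = real.iloc[::3].copy()  # every third peak is an artifact
        peaks = real
        ko_calls = artifacts.assign(start=artifacts["start"] - 5,
                                    end=artifacts["end"] + 5)
        kept = iv.remove_retained_peaks(peaks, ko_calls)
        expect = peaks[~brute_force_overlaps(peaks, ko_calls)]
        pd.testing.assert_frame_equal(kept.reset_index(drop=True),
                                      expect.reset_index(drop=True))


class TestProfiles:
    def _uniform_fragments(self, rng, n, length):
        return pd.DataFrame({"chrom": "c",
                             "pos": rng.integers(0, length, size=n)})

    def test_uniform_track_gives_flat_unit_profile(self):
        rng = np.random.default_rng(0)
        frags = self._uniform_fragments(rng, 200_000, 1_000_000)
        centers = pd.DataFrame({"chrom": ["c"] * 20,
                                "center": np.linspace(50_000, 950_000, 20,
                                                      dtype=int)})
        prof = iv.metaprofile({"unt": frags}, centers, {"c": 1_000_000},
                              {"unt": 1.0}, untreated="unt")
        assert prof["unt"].to_numpy() == pytest.approx(1.0, rel=0.15)

    def test_halved_treated_track_scales_to_half(self):
        rng = np.random.default_rng(1)
        frags = self._uniform_fragments(rng, 100_000, 500_000)
        half = frags.iloc[::2]
        centers = pd.DataFrame({"chrom": ["c"] * 10,
                                "center": np.linspace(30_000, 470_000, 10,
                                                      dtype=int)})
        prof = iv.metaprofile({"unt": frags, "trt": half}, centers,
                              {"c": 500_000}, {"unt": 1.0, "trt": 1.0},
                              untreated="unt")
        center = prof.iloc[len(prof) // 2]
        assert center["unt"] == pytest.approx(1.0, rel=0.1)
        assert center["trt"] == pytest.approx(0.5, rel=0.15)

    def test_peak_centers_peak_at_center_bin(self, null_chip):
        frags = sim.fragment_midpoints(null_chip.counts,
                                       null_chip.sample_ids[0], seed=1)
        peaks = null_chip.counts[null_chip.counts["is_peak"]]
        centers = pd.DataFrame({
            "chrom": peaks["chrom"],
            "center": (peaks["start"] + peaks["end"]) // 2})
        prof = iv.metaprofile({"unt": frags}, centers,
                              null_chip.config.target_chrom_sizes,
                              {"unt": 1.0}, untreated="unt")
        mid = len(prof) // 2
        assert prof["unt"].iloc[mid] >= prof["unt"].max() * 0.9
        assert prof["unt"].iloc[0] < 0.5  # flank blanket well below apex

    def test_edge_centers_excluded(self):
        rng = np.random.default_rng(3)
        frags = pd.DataFrame({"chrom": "c",
                              "pos": rng.integers(0, 50_000, 5_000)})
        centers = pd.DataFrame({"chrom": ["c", "c"],
                                "center": [5_000, 40_000]})  # first too close
        prof = iv.metaprofile({"u": frags}, centers, {"c": 50_000},
                              {"u": 1.0}, untreated="u")
        assert prof.attrs["n_excluded"] == 1

    def test_flank_must_align_with_bins(self):
        with pytest.raises(ValueError):
            iv.profile_matrix(pd.DataFrame({"chrom": [], "pos": []}),
                              pd.DataFrame({"chrom": [], "center": []}),
                              {}, flank=10_000, bin_width=3_000)


class TestChromosomeDensity:
    def test_composition_matches_manual_pipeline(self, null_chip):
        sid = null_chip.sample_ids[0]
        frags = sim.fragment_midpoints(null_chip.counts, sid, seed=2)
        sizes = null_chip.config.target_chrom_sizes
        out = iv.chromosome_density({sid: frags}, sizes, {sid: 0.5},
                                    bin_width=250_000)
        win = iv.make_windows(sizes, 250_000)
        manual = iv.count_in_intervals(frags, win) * 0.5 \
            / ((win["end"] - win["start"]) / 1000.0)
        np.testing.assert_allclose(out.column(sid), manual)
        assert out.normalization == "per_kb"

    def test_chromosome_with_no_fragments_is_zero(self):
        frags = pd.DataFrame({"chrom": ["c1"], "pos": [100]})
        out = iv.chromosome_density({"s": frags}, {"c1": 1_000, "c2": 1_000},
                                    {"s": 1.0}, bin_width=500)
        vals = out.to_frame()
        assert (vals.loc[vals["chrom"] == "c2", "s"] == 0).all()


def test_sum_into_windows_conserves_totals(null_chip):
    sids = null_chip.sample_ids[:2]
    win = iv.make_windows(null_chip.config.target_chrom_sizes, 100_000)
    sm = iv.sum_into_windows(null_chip.counts, sids, win)
    for j, s in enumerate(sids):
        assert sm.values[:, j].sum() == pytest.approx(
            null_chip.counts[s].sum())


def test_signal_matrix_shape_and_provenance_guard():
    with pytest.raises(ValueError, match="inconsistent"):
        iv.SignalMatrix(pd.DataFrame({"chrom": ["c"], "start": [0],
                                      "end": [10]}),
                        ["a", "b"], np.zeros((2, 2)))
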