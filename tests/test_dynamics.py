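"""NB differential testing, BH-FDR, loop-dynamics classification, profiles."""

import numpy as np
import pandas as pd
import pytest

import chromdyn as cd
from chromdyn.dynamics import (
    BinnedTrack,
    bh_fdr,
    classify_loop_dynamics,
    cobinding_split,
    link_dynamics_to_genes,
    nb_count_test,
    signal_profile,
)
from chromdyn.genome import FragmentMap, Genome


def nb_draw(rng, mean, disp, size):
    lam = rng.gamma(1 / disp, disp * np.broadcast_to(mean, size))
    return rng.poisson(lam)


class TestNBCountTest:
    def test_identical_columns_not_significant(self):
        counts = np.tile([[50], [120], [7]], (1, 4))
        res = nb_count_test(counts, ["A", "A", "B", "B"])
        assert (res["p"] > 0.5).all()
        assert (res["direction"] == "ns").all()

    def test_all_zero_unit(self):
        counts = np.array([[0, 0, 0, 0], [10, 12, 9, 11]])
        res = nb_count_test(counts, ["A", "A", "B", "B"])
        assert res.loc[0, "p"] == 1.0
        assert res.loc[0, "direction"] == "ns"

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            nb_count_test(np.array([[1.5, 2.0, 1.0, 2.0]]), ["A", "A", "B", "B"])

    def test_null_calibration(self, rng):
        counts = nb_draw(rng, 100, 0.05, (10_000, 4))
        res = nb_count_test(counts, ["A", "A", "B", "B"])
        assert (res["p"] < 0.001).mean() <= 0.003

    def test_power_at_planted_fold_change(self, rng):
        m = 500
        a = nb_draw(rng, 400, 0.05, (m, 2))
        b = nb_draw(rng, 100, 0.05, (m, 2))
        res = nb_count_test(np.hstack([a, b]), ["A", "A", "B", "B"],
                            normalize=False)
        assert (res["p"] < 0.001).mean() >= 0.95
        sig = res["p"] < 0.001
        assert (res.loc[sig, "direction"] == "up_A").all()

    def test_power_monotone_in_fold_change(self, rng):
        powers = []
        for fc in (1.5, 2.0, 4.0):
            a = nb_draw(rng, 100 * fc, 0.05, (400, 2))
            b = nb_draw(rng, 100, 0.05, (400, 2))
            res = nb_count_test(np.hstack([a, b]), ["A", "A", "B", "B"],
                                normalize=False)
            powers.append((res["p"] < 0.001).mean())
        assert powers[0] <= powers[1] <= powers[2]

    def test_direction_thresholds_by_unit_kind(self, rng):
        # a modest 1.3x change: significant by p for interactions but below
        # the 1.5x fold-change floor for peaks
        a = nb_draw(rng, 1300, 0.0005, (200, 3))
        b = nb_draw(rng, 1000, 0.0005, (200, 3))
        counts = np.hstack([a, b])
        labels = ["A", "A", "A", "B", "B", "B"]
        inter = nb_count_test(counts, labels, kind="interaction",
                              normalize=False, dispersion=0.0005)
        peak = nb_count_test(counts, labels, kind="peak", normalize=False,
                             dispersion=0.0005)
        assert (inter["direction"] == "up_A").mean() > 0.5
        assert (peak["direction"] == "ns").all()

    def test_library_size_normalization(self, rng):
        # doubling one replicate's depth alone should not create signal
        base = nb_draw(rng, 100, 0.05, (2_000, 4))
        base[:, 0] *= 2
        res = nb_count_test(base, ["A", "A", "B", "B"])
        assert (res["p"] < 0.001).mean() <= 0.005


class TestBH:
    def test_matches_hand_computed_step_up(self):
        # textbook step-up on a 20-value vector, adjusted values computed by
        # hand: q_i = min_{j >= i} (n * p_(j) / j), mapped back to input order
        p = np.array(
            [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212,
             0.216, 0.222, 0.251, 0.269, 0.275, 0.34, 0.341, 0.384, 0.569,
             0.594, 0.696]
        )
        order = np.argsort(p)
        ranked = p[order]
        n = len(p)
        raw = ranked * n / np.arange(1, n + 1)
        stepped = np.minimum.accumulate(raw[::-1])[::-1]
        expect = np.empty(n)
        expect[order] = np.minimum(stepped, 1.0)
        assert np.allclose(bh_fdr(p), expect)

    def test_shuffled_vector_consistent(self, rng):
        p = rng.random(20)
        perm = rng.permutation(20)
        assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_fdr_not_below_p(self, rng):
        p = rng.random(50)
        assert (bh_fdr(p) >= p - 1e-12).all()


def toy_fragments():
    genome = Genome({"chr1": 400_000})
    frame = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(0, 400_000, 10_000),
            "end": np.arange(10_000, 410_000, 10_000),
        }
    )
    return FragmentMap(frame, genome)


class TestClassification:
    def setup_inputs(self):
        frags = toy_fragments()
        interactions = pd.DataFrame(
            {
                "unit_id": ["i1", "i2", "i3", "i4"],
                "bait_id": [0, 0, 1, 1],
                "other_end_id": [10, 20, 30, 35],
                "bait_gene": ["gA", "gA", "gB", "gB"],
            }
        )
        diffs = pd.DataFrame(
            {
                "unit_id": ["i1", "i2", "i3", "i4"],
                "log2fc": [2.0, 0.1, -0.2, 0.05],
                "p": [1e-4, 0.4, 0.8, 0.6],
                "fdr": [1e-3, 0.5, 0.9, 0.7],
                "direction": ["up_A", "ns", "ns", "ns"],
            }
        )
        # differential peak overlapping the distal end of i2 (fragment 20)
        peaks = pd.DataFrame(
            {
                "peak_id": ["pk1", "pk2"],
                "chrom": ["chr1", "chr1"],
                "start": [203_000, 100_000],
                "end": [204_000, 101_000],
                "direction": ["up_A", "ns"],
                "log2fc": [1.8, 0.0],
            }
        )
        return frags, interactions, diffs, peaks

    def test_three_way_classification(self):
        frags, inter, diffs, peaks = self.setup_inputs()
        recs = classify_loop_dynamics(inter, diffs, peaks, frags)
        got = dict(zip(recs["unit_id"], recs["loop_class"]))
        assert got == {
            "i1": "rewired_gained_A",
            "i2": "preformed_activated_A",
            "i3": "static",
            "i4": "static",
        }

    def test_rewired_takes_precedence(self):
        frags, inter, diffs, peaks = self.setup_inputs()
        # make i2 both significantly rewired and acetylation-overlapping
        diffs.loc[diffs["unit_id"] == "i2", ["p", "log2fc"]] = [1e-5, -1.0]
        recs = classify_loop_dynamics(inter, diffs, peaks, frags)
        got = dict(zip(recs["unit_id"], recs["loop_class"]))
        assert got["i2"] == "rewired_gained_B"

    def test_missing_differential_record_is_error(self):
        frags, inter, diffs, peaks = self.setup_inputs()
        with pytest.raises(ValueError, match="missing"):
            classify_loop_dynamics(inter, diffs.iloc[:2], peaks, frags)

    def test_classification_is_a_partition(self, capture_pipeline):
        recs = capture_pipeline["records"]
        assert recs["loop_class"].isin(
            ["rewired_gained_A", "rewired_gained_B", "preformed_activated_A",
             "preformed_activated_B", "static"]
        ).all()
        assert len(recs) == len(capture_pipeline["called"])

    def test_planted_class_recovery(self, capture_pipeline):
        recs = capture_pipeline["records"]
        planted = recs[recs["true_class"] != "background"]
        for cls in planted["true_class"].unique():
            sub = planted[planted["true_class"] == cls]
            assert (sub["loop_class"] == cls).mean() >= 0.95, cls


class TestGeneLinkage:
    def test_dedup_and_de_status(self):
        records = pd.DataFrame(
            {
                "loop_class": ["rewired_gained_A", "rewired_gained_A",
                               "static", "preformed_activated_B"],
                "linked_genes": [["gA"], ["gA"], ["gB"], ["gB"]],
            }
        )
        degs = pd.DataFrame(
            {"unit_id": ["gA", "gB"], "direction": ["up_A", "ns"]}
        )
        table = link_dynamics_to_genes(records, degs)
        assert len(table) == 3  # gA deduplicated within class
        row = table[(table["gene_id"] == "gA")]
        assert row["de_status"].iloc[0] == "up_A"

    def test_gene_without_loops_absent(self):
        records = pd.DataFrame(
            {"loop_class": ["static"], "linked_genes": [["gA"]]}
        )
        table = link_dynamics_to_genes(records)
        assert set(table["gene_id"]) == {"gA"}

    def test_planted_linkage_recovered(self, capture_pipeline):
        recs = capture_pipeline["records"]
        table = link_dynamics_to_genes(recs)
        # every (gene, class) planted among correctly classified loops appears
        planted = recs[recs["true_class"] == recs["loop_class"]]
        expected = set(
            zip(planted["bait_gene"], planted["loop_class"])
        )
        got = set(zip(table["gene_id"], table["loop_class"]))
        assert expected <= got


class TestSignalProfile:
    GENOME = Genome({"chr1": 1_000_000})

    def test_constant_track_flat(self):
        track = BinnedTrack(
            self.GENOME, 100, {"chr1": np.full(10_000, 3.5)}
        )
        regions = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "start": [100_000, 300_000, 500_000],
             "end": [101_000, 301_000, 501_000]}
        )
        mat, curve, used = signal_profile(track, regions, flank_bp=5_000)
        assert np.all(mat == 3.5)
        assert np.all(curve == 3.5)
        assert len(used) == 3

    def test_gaussian_peak_centered(self, rng):
        vals = np.zeros(10_000)
        centers = [2_000, 5_000, 8_000]
        x = np.arange(10_000)
        for c in centers:
            vals += 10 * np.exp(-((x - c) ** 2) / (2 * 20.0**2))
        track = BinnedTrack(self.GENOME, 100, {"chr1": vals})
        regions = pd.DataFrame(
            {"chrom": "chr1", "start": [c * 100 - 500 for c in centers],
             "end": [c * 100 + 500 for c in centers]}
        )
        mat, curve, _ = signal_profile(track, regions, flank_bp=100_000,
                                       n_points=41)
        assert np.argmax(curve) == 20

    def test_center_outside_chromosome_skipped(self):
        track = BinnedTrack(self.GENOME, 100, {"chr1": np.ones(10_000)})
        regions = pd.DataFrame(
            {"chrom": ["chr1", "chrX"], "start": [100_000, 0],
             "end": [101_000, 1_000]}
        )
        with pytest.warns(UserWarning, match="skipped"):
            mat, _, used = signal_profile(track, regions, flank_bp=1_000)
        assert list(used) == [0]

    def test_premark_split_ordering(self, rng):
        # sites with a premark carry stronger signal; the two mean curves
        # must recover that ordering at the midpoint
        n_sites = 40
        vals = np.zeros(10_000)
        pos = rng.choice(np.arange(50, 9_950, 100), size=n_sites, replace=False)
        premarked = np.zeros(n_sites, dtype=bool)
        premarked[: n_sites // 2] = True
        for k, c in enumerate(pos):
            vals[c - 3 : c + 3] += 12.0 if premarked[k] else 4.0
        track = BinnedTrack(self.GENOME, 100, {"chr1": vals})
        sites = pd.DataFrame(
            {"chrom": "chr1", "start": pos * 100 - 200, "end": pos * 100 + 200}
        )
        marks = pd.DataFrame(
            {"chrom": "chr1", "start": pos[premarked] * 100 - 100,
             "end": pos[premarked] * 100 + 100}
        )
        with_pm, without_pm = cobinding_split(sites, marks)
        _, curve_w, _ = signal_profile(track, with_pm, flank_bp=2_000, n_points=21)
        _, curve_wo, _ = signal_profile(track, without_pm, flank_bp=2_000, n_points=21)
        assert curve_w[10] > curve_wo[10]


class TestCobindingSplit:
    def test_disjoint_sets_all_without(self):
        a = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        b = pd.DataFrame({"chrom": ["chr1"], "start": [500], "end": [600]})
        with_pm, without_pm = cobinding_split(a, b)
        assert len(with_pm) == 0 and len(without_pm) == 1

    def test_superset_all_with(self):
        a = pd.DataFrame({"chrom": ["chr1"], "start": [50], "end": [80]})
        b = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        with_pm, without_pm = cobinding_split(a, b)
        assert len(with_pm) == 1 and len(without_pm) == 0

    def test_partition_sizes_match_oracle(self, rng):
        from conftest import random_intervals
        a = random_intervals(rng, 300, max_pos=200_000)
        b = random_intervals(rng, 300, max_pos=200_000)
        with_pm, without_pm = cobinding_split(a, b)
        # oracle: quadratic scan
        n_with = 0
        for _, ra in a.iterrows():
            hit = (
                (b["chrom"] == ra["chrom"])
                & (b["start"] < ra["end"])
                & (b["end"] > ra["start"])
            ).any()
            n_with += bool(hit)
        assert len(with_pm) == n_with
        assert len(with_pm) + len(without_pm) == len(a)
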