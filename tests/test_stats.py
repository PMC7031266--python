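"""Association statistics, shuffle overlap tests, and the calorimetry formula."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import chromdyn as cd
from chromdyn.stats import (
    ShuffleConfig,
    _Universe,
    energy_expenditure,
    expression_by_loop_count,
    expression_by_strata,
    gene_loop_strata,
    mann_whitney,
    matched_control_annotation_overlap,
    nearest_tss_assignment,
    shuffle_intervals,
    shuffle_overlap_test,
    tpm_bin,
)


def exact_mw_p(x, y):
    """Independent oracle: full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = scipy.stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
    us = np.asarray(us)
    lo = np.mean(us <= u_obs + 1e-9)
    hi = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


class TestMannWhitney:
    def test_identical_multisets(self):
        u, p = mann_whitney([1, 2, 2, 3], [1, 2, 2, 3])
        assert p == 1.0

    def test_complete_separation_exact(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)  # 2/20 orderings

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(1, 5))
        n2 = int(rng.integers(1, 8 - n1 + 1))
        # integer draws so ties occur
        x = rng.integers(0, 5, n1).astype(float)
        y = rng.integers(0, 5, n2).astype(float)
        if np.ptp(np.concatenate([x, y])) == 0:
            x[0] += 1
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(exact_mw_p(x, y))

    @pytest.mark.parametrize("seed", range(4))
    def test_u_matches_brute_force_pair_count(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=int(rng.integers(3, 20)))
        y = rng.normal(size=int(rng.integers(3, 20)))
        u, _ = mann_whitney(x, y)
        brute = sum(
            (xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y
        )
        assert u == pytest.approx(brute)

    def test_large_sample_agrees_with_scipy(self, rng):
        x = rng.normal(0, 1, 60)
        y = rng.normal(0.5, 1, 50)
        u, p = mann_whitney(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=0.05)


class TestTpmBins:
    def test_edges(self):
        tpm = [0.0, 0.5, 1.0, 1.0001, 10.0, 10.5, 200.0]
        labels = tpm_bin(tpm)
        assert list(labels) == ["0", "(0,1]", "(0,1]", "(1,10]", "(1,10]",
                                ">10", ">10"]

    def test_partition(self, rng):
        tpm = rng.exponential(5, 500)
        tpm[:50] = 0
        labels = tpm_bin(tpm)
        assert (labels != None).all()  # noqa: E711
        assert set(labels) <= {"0", "(0,1]", "(1,10]", ">10"}

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            tpm_bin([-1.0])


class TestExpressionByLoopCount:
    def planted(self, rng, n_per_bin=250):
        """Clean monotone map: expression bin -> Poisson mean loops."""
        tpm_vals = {"0": 0.0, "(0,1]": 0.5, "(1,10]": 5.0, ">10": 50.0}
        loop_means = {"0": 0.6, "(0,1]": 2.0, "(1,10]": 4.5, ">10": 8.0}
        genes, inter_rows = [], []
        k = 0
        for lab, tpm in tpm_vals.items():
            for _ in range(n_per_bin):
                g = f"g{k:05d}"
                genes.append({"gene_id": g, "tpm": tpm})
                for _ in range(rng.poisson(loop_means[lab])):
                    inter_rows.append({"bait_gene": g})
                k += 1
        return pd.DataFrame(genes), pd.DataFrame(inter_rows)

    def test_monotone_association_recovered(self, rng):
        expr, inter = self.planted(rng)
        res = expression_by_loop_count(expr, inter, "tpm")
        meds = [res["medians"][b] for b in ("0", "(0,1]", "(1,10]", ">10")]
        assert all(a < b for a, b in zip(meds, meds[1:]))
        assert all(p < 0.01 for p in res["pairwise_p"].values())

    def test_counts_match_oracle_recount(self, rng):
        expr, inter = self.planted(rng, n_per_bin=50)
        res = expression_by_loop_count(expr, inter, "tpm")
        total = sum(len(v) for v in res["loop_counts"].values())
        assert total == len(expr)
        recount = inter.groupby("bait_gene").size()
        assert sum(v.sum() for v in res["loop_counts"].values()) == len(inter)

    def test_identical_genes_all_p_one(self):
        expr = pd.DataFrame({"gene_id": [f"g{i}" for i in range(40)],
                             "tpm": [0.5] * 20 + [5.0] * 20})
        inter = pd.DataFrame({"bait_gene": ["g0"]})
        with pytest.warns(UserWarning):
            res = expression_by_loop_count(expr, inter, "tpm")
        for p in res["pairwise_p"].values():
            assert p > 0.3


class TestStrata:
    def test_strata_partition_and_sizes(self, rng):
        expr = pd.DataFrame({"gene_id": [f"g{i}" for i in range(100)],
                             "tpm": rng.exponential(5, 100)})
        inter = pd.DataFrame(
            {
                "bait_gene": rng.choice(expr["gene_id"], 300),
                "acetylated": rng.random(300) < 0.5,
            }
        )
        strata = gene_loop_strata(expr, inter)
        assert len(strata) == len(expr)
        res = expression_by_strata(expr, strata, "tpm")
        assert sum(res["sizes"].values()) == len(expr)

    def test_planted_acetylation_effect(self, capture_pipeline):
        truth = capture_pipeline["truth"]
        cap = capture_pipeline["capture"]
        inter = cap[cap["true_class"] != "background"].copy()
        inter["acetylated"] = inter["true_class"].str.startswith("preformed")
        strata = gene_loop_strata(truth.expression, inter)
        res = expression_by_strata(truth.expression, strata, "tpm_A")
        for band in ("1", "2-5", ">5"):
            w = res["medians"].get(f"{band}_with")
            wo = res["medians"].get(f"{band}_without")
            assert w > wo, band
        assert res["tests"]["2-5"] < 0.01


class TestNearestTSS:
    EXPR = pd.DataFrame(
        {
            "gene_id": ["gB", "gA"],
            "chrom": ["chr1", "chr1"],
            "tss": [100_000, 200_000],
        }
    )

    def test_within_window_assigned(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "start": [130_000],
                              "end": [131_000]})
        res = nearest_tss_assignment(sites, self.EXPR, window_bp=50_000)
        assert res.loc[0, "gene_id"] == "gB"

    def test_outside_window_unassigned(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "start": [290_000],
                              "end": [291_000]})
        res = nearest_tss_assignment(sites, self.EXPR, window_bp=50_000)
        assert res.loc[0, "gene_id"] is None

    def test_equidistant_tie_lower_gene_id(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "start": [149_800],
                              "end": [150_201]})
        res = nearest_tss_assignment(sites, self.EXPR, window_bp=50_000)
        assert res.loc[0, "gene_id"] == "gA"  # lexicographically smaller

    def test_tss_inside_site_distance_zero(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "start": [99_000],
                              "end": [101_000]})
        res = nearest_tss_assignment(sites, self.EXPR)
        assert res.loc[0, "distance"] == 0


def make_universe(n=800, length=1_000, spacing=10_000, chrom="chr1"):
    starts = np.arange(n) * spacing
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + length}
    )


class TestShuffle:
    def test_lengths_and_count_preserved(self, rng):
        uni = _Universe(make_universe())
        lengths = np.array([100, 250, 500, 100, 900])
        s, e = shuffle_intervals(lengths, uni, rng)
        assert np.array_equal(np.sort(e - s), np.sort(lengths))
        # placed inside universe intervals
        for a, b in zip(s, e):
            inside = (uni.start_lin <= a) & (b <= uni.start_lin + uni.lengths)
            assert inside.any()

    def test_no_self_overlap(self, rng):
        uni = _Universe(make_universe(n=100))
        lengths = np.full(60, 800)
        s, e = shuffle_intervals(lengths, uni, rng)
        order = np.argsort(s)
        assert np.all(s[order][1:] >= e[order][:-1])

    def test_query_inside_sparse_reference_min_p(self):
        # query identical to reference; reference covers ~1% of the universe:
        # no shuffle can reach full overlap, so p attains its minimum
        universe = make_universe(n=1_000)
        reference = universe.iloc[:10][["chrom", "start", "end"]]
        query = reference.copy()
        cfg = ShuffleConfig(n_iter=500, seed=0)
        res = shuffle_overlap_test(query, reference, universe, cfg)
        assert res.observed == len(query)
        assert res.p == pytest.approx(1 / 501)

    def test_null_p_usually_insignificant(self):
        universe = make_universe(n=500)
        reference = universe.iloc[::10][["chrom", "start", "end"]]
        n_sig = 0
        runs = 30
        for k in range(runs):
            rng = np.random.default_rng(1000 + k)
            uni = _Universe(universe)
            s, e = shuffle_intervals(np.full(50, 500), uni, rng)
            query = pd.DataFrame(
                {"chrom": "chr1", "start": s, "end": e}
            )
            res = shuffle_overlap_test(
                query, reference, universe, ShuffleConfig(n_iter=99, seed=k)
            )
            n_sig += res.p <= 0.05
        assert n_sig <= runs * 0.10 + 1

    def test_universe_too_small_is_error(self):
        universe = make_universe(n=2)
        query = pd.DataFrame(
            {"chrom": "chr1", "start": [0, 100, 200], "end": [900, 1_000, 1_100]}
        )
        with pytest.raises(ValueError, match="universe too small"):
            shuffle_overlap_test(query, query, universe, ShuffleConfig(n_iter=5))

    def test_empirical_p_near_uniform_under_null(self):
        # KS distance of the null p distribution from uniform over 200 runs;
        # the query set is large enough that the overlap count has fine
        # resolution (coarse counts leave atoms in the p distribution)
        starts = np.arange(3_000) * 5_000
        universe = pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + 1_000}
        )
        reference = universe.iloc[::3][["chrom", "start", "end"]]
        ps = []
        for k in range(200):
            rng = np.random.default_rng(9_000 + k)
            uni = _Universe(universe)
            s, e = shuffle_intervals(np.full(250, 300), uni, rng)
            query = pd.DataFrame({"chrom": "chr1", "start": s, "end": e})
            res = shuffle_overlap_test(
                query, reference, universe, ShuffleConfig(n_iter=99, seed=k)
            )
            ps.append(res.p)
        ks = scipy.stats.kstest(ps, "uniform").statistic
        assert ks < 0.1


class TestMatchedControls:
    def test_annotation_equal_to_universe_all_hit(self, rng):
        universe = make_universe(n=300)
        uni = _Universe(universe)
        s, e = shuffle_intervals(np.full(40, 400), uni, rng)
        query = pd.DataFrame({"chrom": "chr1", "start": s, "end": e})
        res = matched_control_annotation_overlap(
            query, {"everything": universe}, universe, n_controls=10, seed=1
        )
        assert res.loc[0, "query_pct"] == 100.0
        assert res.loc[0, "control_mean"] == 100.0

    def test_planted_enrichment_detected(self, rng):
        universe = make_universe(n=1_000)
        annot = universe.iloc[:100][["chrom", "start", "end"]]
        # queries seeded inside the annotated subset of the universe
        starts = annot["start"].to_numpy()[:60] + 100
        query = pd.DataFrame(
            {"chrom": "chr1", "start": starts, "end": starts + 400}
        )
        res = matched_control_annotation_overlap(
            query, {"annot": annot}, universe, n_controls=40, seed=2
        )
        row = res.iloc[0]
        assert row["query_pct"] > row["control_mean"] + 3 * row["control_sd"]

    def test_control_pct_stable_across_seeds(self, rng):
        universe = make_universe(n=500)
        annot = universe.iloc[::5][["chrom", "start", "end"]]
        uni = _Universe(universe)
        s, e = shuffle_intervals(np.full(50, 400), uni, rng)
        query = pd.DataFrame({"chrom": "chr1", "start": s, "end": e})
        r1 = matched_control_annotation_overlap(
            query, {"a": annot}, universe, n_controls=40, seed=10
        ).iloc[0]
        r2 = matched_control_annotation_overlap(
            query, {"a": annot}, universe, n_controls=40, seed=20
        ).iloc[0]
        sd = max(r1["control_sd"], r2["control_sd"]) / np.sqrt(40)
        assert abs(r1["control_mean"] - r2["control_mean"]) < 2 * sd * 3


class TestEnergyExpenditure:
    def test_formula_coefficients(self):
        assert energy_expenditure(1.0, 0.0) == pytest.approx(3.941)
        assert energy_expenditure(0.0, 1.0) == pytest.approx(1.106)
        assert energy_expenditure(0.0, 0.0) == 0.0
        assert energy_expenditure(0.5, 0.5) == pytest.approx(2.5235)

    def test_vectorised(self):
        out = energy_expenditure([1.0, 0.0], [0.0, 1.0])
        assert np.allclose(out, [3.941, 1.106])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            energy_expenditure(-0.1, 0.2)
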