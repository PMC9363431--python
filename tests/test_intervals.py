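"""HDR calling, sharing classification, permutation nulls, jackknife."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from parallelpeaks import intervals
from parallelpeaks.genome import Genome, IntervalSet, merge_intervals, overlaps_any

GEN = Genome({"chr1": 2_000_000, "chr2": 2_000_000})


def iset(pairs, chrom="chr1", genome=GEN):
    if not pairs:
        return IntervalSet(genome, np.array([], dtype=object),
                           np.array([], dtype=np.int64),
                           np.array([], dtype=np.int64))
    return IntervalSet(genome, np.array([chrom] * len(pairs), dtype=object),
                       np.array([a for a, _ in pairs]),
                       np.array([b for _, b in pairs]))


def track_with_z(z_by_centre: dict[int, float]) -> pd.DataFrame:
    centres = sorted(z_by_centre)
    return pd.DataFrame({
        "chrom": "chr1",
        "start": [c - 2500 for c in centres],
        "end": [c + 2500 for c in centres],
        "centre": centres,
        "z": [z_by_centre[c] for c in centres],
    })


class TestCallOutliers:
    def test_no_window_above_threshold(self):
        out = intervals.call_outliers(track_with_z({10_000: 3.0, 20_000: 4.0}))
        assert len(out) == 0

    def test_strict_inequality_at_boundary(self):
        out = intervals.call_outliers(
            track_with_z({10_000: 3.9, 20_000: 4.0, 30_000: 4.1}))
        assert list(out["centre"]) == [30_000]

    def test_null_windows_excluded(self):
        out = intervals.call_outliers(track_with_z({10_000: np.nan, 20_000: 5.0}))
        assert list(out["centre"]) == [20_000]


class TestBuildHdrs:
    def test_single_outlier_buffered(self):
        hdrs = intervals.build_hdrs(GEN, track_with_z({100_000: 5.0}))
        df = hdrs.to_frame()
        assert (df.loc[0, "start"], df.loc[0, "end"]) == (50_000, 150_000)

    def test_nearby_outliers_merge(self):
        hdrs = intervals.build_hdrs(GEN, track_with_z({100_000: 5.0, 130_000: 6.0}))
        df = hdrs.to_frame()
        assert len(df) == 1
        assert (df.loc[0, "start"], df.loc[0, "end"]) == (50_000, 180_000)
        assert df.loc[0, "max_z"] == 6.0

    def test_clipping_at_chromosome_start(self):
        hdrs = intervals.build_hdrs(GEN, track_with_z({10_000: 5.0}))
        df = hdrs.to_frame()
        assert (df.loc[0, "start"], df.loc[0, "end"]) == (0, 60_000)

    def test_empty_outlier_list(self):
        hdrs = intervals.build_hdrs(GEN, track_with_z({}).iloc[:0])
        assert len(hdrs) == 0


LAYOUT = {"a": "west", "b": "west", "c": "east", "d": "east"}


class TestClassifySharing:
    def test_identical_sets_are_fully_allopatric(self):
        sets = {t: iset([(0, 100_000), (500_000, 600_000)]) for t in LAYOUT}
        res = intervals.classify_sharing(sets, LAYOUT)
        for t in LAYOUT:
            assert (res[t]["sharing_class"] == "shdr_allopatric").all()

    def test_disjoint_sets_are_private(self):
        sets = {t: iset([(i * 200_000, i * 200_000 + 50_000)])
                for i, t in enumerate(LAYOUT)}
        res = intervals.classify_sharing(sets, LAYOUT)
        for t in LAYOUT:
            assert (res[t]["sharing_class"] == "private").all()

    def test_within_side_but_not_allopatric(self):
        sets = {"a": iset([(0, 100_000)]), "b": iset([(90_000, 200_000)]),
                "c": iset([]), "d": iset([])}
        res = intervals.classify_sharing(sets, LAYOUT)
        assert res["a"]["sharing_class"].iloc[0] == "shdr_within_side"

    def test_allopatric_requires_both_opposite_transects(self):
        sets = {"a": iset([(0, 100_000)]), "b": iset([(50_000, 150_000)]),
                "c": iset([(0, 100_000)]), "d": iset([])}
        res = intervals.classify_sharing(sets, LAYOUT)
        # overlaps replicate and one (not both) opposite transects
        assert res["a"]["sharing_class"].iloc[0] == "shdr_within_side"

    def test_class_ordering_invariant(self, small_dataset):
        rng = np.random.default_rng(8)
        sets = {}
        for t in LAYOUT:
            start = rng.integers(0, 1_800_000, 6)
            sets[t] = iset(sorted((int(s), int(s) + 100_000) for s in start))
        res = intervals.classify_sharing(sets, LAYOUT)
        for t, df in res.items():
            n = len(sets[t].merged())
            allo = (df["sharing_class"] == "shdr_allopatric").sum()
            within = (df["sharing_class"] != "private").sum()
            assert allo <= within <= n

    def test_single_transect_is_an_error(self):
        with pytest.raises(ValueError):
            intervals.classify_sharing({"a": iset([(0, 10)])}, LAYOUT)


class TestPermutationNull:
    def test_saturated_genome_gives_p_near_one(self):
        full = iset([(0, 2_000_000)]) if False else IntervalSet(
            GEN, np.array(["chr1", "chr2"], dtype=object),
            np.array([0, 0]), np.array([2_000_000, 2_000_000]))
        res = intervals.overlap_permutation_null(GEN, full, [full],
                                                 n_perm=50, seed=0)
        assert res["observed"] == 1.0
        assert res["p"] == pytest.approx(1.0, abs=0.05)

    def test_tiny_identical_hdrs_are_significant(self):
        a = iset([(1_000_000, 1_002_000)])
        res = intervals.overlap_permutation_null(GEN, a, [a], n_perm=10_000,
                                                 seed=1)
        assert res["observed"] == 1.0
        # collision chance of a 2 kb interval with a 2 kb target on 4 Mb
        assert res["p"] <= 0.01

    def test_zero_permutations_is_an_error(self):
        a = iset([(0, 1000)])
        with pytest.raises(ValueError):
            intervals.overlap_permutation_null(GEN, a, [a], n_perm=0)

    def test_null_p_values_are_valid(self):
        """Exchangeability: random focal sets against a fixed partner set
        give valid (super-uniform) empirical p-values — the sharing
        proportion is discrete, so ties make p conservative rather than
        exactly uniform; rejection at any level must not exceed it."""
        partner = iset([(200_000, 400_000), (900_000, 1_100_000)])
        rng = np.random.default_rng(9)
        pvals = []
        for _ in range(200):
            # focal intervals drawn from the same uniform-genome process
            # the null re-places them by (both chromosomes, equal lengths)
            chroms = rng.choice(["chr1", "chr2"], 3)
            starts = rng.integers(0, 1_920_000, 3)
            focal = IntervalSet(GEN, chroms.astype(object),
                                starts, starts + 80_000)
            res = intervals.overlap_permutation_null(
                GEN, focal, [partner], n_perm=99, seed=int(rng.integers(2**31)))
            pvals.append(res["p"])
        pvals = np.array(pvals)
        for alpha in (0.05, 0.10, 0.25, 0.50):
            slack = 3 * np.sqrt(alpha * (1 - alpha) / 200)
            assert np.mean(pvals <= alpha) <= alpha + slack


class TestJackknife:
    def make_sets(self, seed=0, n=50):
        rng = np.random.default_rng(seed)
        focal = []
        for _ in range(n):
            c = rng.choice(["chr1", "chr2"])
            s = int(rng.integers(0, 1_900_000))
            focal.append((c, s, s + int(rng.integers(20_000, 80_000))))
        focal.sort()
        fs = IntervalSet(GEN, np.array([c for c, _, _ in focal], dtype=object),
                         np.array([s for _, s, _ in focal]),
                         np.array([e for _, _, e in focal]))
        partner = iset([(0, 500_000)], chrom="chr1")
        return fs.merged(), partner

    def test_ci_contains_point_estimate(self):
        focal, partner = self.make_sets()
        res = intervals.jackknife_ci(GEN, focal, [partner], block_size=200_000)
        assert res["ci"][0] <= res["observed"] <= res["ci"][1]

    def test_identical_replicates_give_zero_width(self):
        # partner covers everything: every leave-one-out proportion is 1
        focal, _ = self.make_sets()
        full = IntervalSet(GEN, np.array(["chr1", "chr2"], dtype=object),
                           np.array([0, 0]), np.array([2_000_000, 2_000_000]))
        res = intervals.jackknife_ci(GEN, focal, [full], block_size=200_000)
        assert res["se"] == 0.0
        assert res["ci"][0] == res["ci"][1] == res["observed"]

    def test_se_matches_brute_force_recomputation(self):
        focal, partner = self.make_sets(seed=2)
        block = 200_000
        res = intervals.jackknife_ci(GEN, focal, [partner], block_size=block)
        # independent recomputation with explicit interval filtering
        mids = (focal.lin_start + focal.lin_end) // 2
        pm = partner.merged()
        reps = []
        n_blocks = int(np.ceil((GEN.linearise(["chr2"], [2_000_000])[0]) / block))
        for b in range(n_blocks):
            keep = mids // block != b
            hits = overlaps_any(focal.lin_start[keep], focal.lin_end[keep],
                                pm.lin_start, pm.lin_end)
            reps.append(hits.mean() if keep.any() else np.nan)
        reps = np.array(reps)
        ok = np.isfinite(reps)
        g = ok.sum()
        se = np.sqrt((g - 1) / g * np.sum((reps[ok] - reps[ok].mean()) ** 2))
        assert res["se"] == pytest.approx(se, abs=1e-12)

    def test_too_few_blocks_is_an_error(self):
        focal, partner = self.make_sets()
        with pytest.raises(ValueError):
            intervals.jackknife_ci(GEN, focal, [partner], block_size=1_000_000)


class TestRecombComparison:
    def rho_track(self, values):
        n = len(values)
        return pd.DataFrame({"chrom": "chr1",
                             "start": np.arange(n) * 50_000,
                             "end": (np.arange(n) + 1) * 50_000,
                             "centre": np.arange(n) * 50_000 + 25_000,
                             "rho": values})

    def test_constant_rho_gives_zero_ks(self):
        hdrs = iset([(100_000, 300_000)])
        res = intervals.recomb_comparison(GEN, hdrs, self.rho_track([1.0] * 40))
        assert res["ks_d"] == 0.0

    def test_hdrs_in_low_rho_regions_detected(self):
        rho = np.linspace(0.1, 5.0, 40)  # increasing along the chromosome
        hdrs = iset([(0, 400_000)])  # the lowest-rho windows only
        res = intervals.recomb_comparison(GEN, hdrs, self.rho_track(rho))
        assert res["ks_p"] < 0.05

    def test_empty_hdr_set_is_an_error(self):
        with pytest.raises(ValueError):
            intervals.recomb_comparison(GEN, iset([]), self.rho_track([1.0] * 10))


class TestCandidateOverlap:
    def test_candidates_identical_to_hdrs(self):
        hdrs = iset([(0, 100_000), (500_000, 600_000)])
        res = intervals.candidate_overlap_test(GEN, hdrs, hdrs, n_perm=50, seed=0)
        assert res["observed"] == 2

    def test_candidates_on_hdr_free_chromosome(self):
        hdrs = iset([(0, 100_000)], chrom="chr1")
        cands = iset([(0, 100_000), (300_000, 400_000)], chrom="chr2")
        res = intervals.candidate_overlap_test(GEN, hdrs, cands, n_perm=50, seed=0)
        assert res["observed"] == 0

    def test_enriched_overlap_is_reproducibly_significant(self):
        hdrs = iset([(100_000, 140_000), (800_000, 840_000)])
        cands = iset([(110_000, 120_000), (810_000, 820_000),
                      (1_500_000, 1_510_000)])
        r1 = intervals.candidate_overlap_test(GEN, hdrs, cands, n_perm=2000, seed=5)
        r2 = intervals.candidate_overlap_test(GEN, hdrs, cands, n_perm=2000, seed=5)
        assert r1["observed"] == 2
        assert r1["p"] < 0.1
        assert r1["p"] == r2["p"]
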