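"""Windowed statistics against closed-form values and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parallelpeaks import windows
from parallelpeaks.genome import Genome
from parallelpeaks.windows import (
    AlleleCounts,
    delta_pi,
    dxy_window,
    hudson_fst_site,
    make_grid,
    pbs_from_fst,
    pi_window,
    tajimas_d_window,
    window_fst,
    zscore,
)

GEN = Genome({"chr1": 10_000})
GRID = make_grid(GEN, 10_000, 10_000)  # one whole-chromosome window


def counts_from_haplotypes(hap_a: np.ndarray, hap_b: np.ndarray | None = None,
                           positions=None) -> AlleleCounts:
    """Build an AlleleCounts from explicit haplotype matrices
    (haplotypes x sites, 0/1)."""
    n_sites = hap_a.shape[1]
    pos = (np.asarray(positions, dtype=np.int64) if positions is not None
           else np.arange(n_sites, dtype=np.int64))
    chrom = np.full(n_sites, "chr1", dtype=object)
    ac = {"A": hap_a.sum(axis=0).astype(np.int64)}
    an = {"A": np.full(n_sites, hap_a.shape[0], dtype=np.int64)}
    if hap_b is not None:
        ac["B"] = hap_b.sum(axis=0).astype(np.int64)
        an["B"] = np.full(n_sites, hap_b.shape[0], dtype=np.int64)
    return AlleleCounts(chrom=chrom, pos=pos, ac=ac, an=an)


class TestHudsonFst:
    def test_fixed_difference_gives_unit_fst(self):
        a, b = hudson_fst_site(1.0, 10, 0.0, 10)
        assert a == pytest.approx(1.0) and b == pytest.approx(1.0)

    def test_equal_intermediate_frequencies(self):
        a, b = hudson_fst_site(0.5, 10, 0.5, 10)
        assert a == pytest.approx(-0.05556, abs=1e-5)
        assert b == pytest.approx(0.5)

    def test_monomorphic_site_contributes_nothing(self):
        a, b = hudson_fst_site(0.0, 10, 0.0, 10)
        assert a == 0.0 and b == 0.0

    def test_single_haplotype_population_is_skipped(self):
        a, b = hudson_fst_site(np.array([0.5]), np.array([1]),
                               np.array([0.5]), np.array([10]))
        assert np.isnan(a[0]) and np.isnan(b[0])

    def test_windowed_fst_is_symmetric(self, small_dataset):
        c = small_dataset["counts"]
        a1, b1 = hudson_fst_site(c.freq("t1_high"), c.an["t1_high"],
                                 c.freq("t1_low"), c.an["t1_low"])
        a2, b2 = hudson_fst_site(c.freq("t1_low"), c.an["t1_low"],
                                 c.freq("t1_high"), c.an["t1_high"])
        g = small_dataset["genome"]
        grid = make_grid(g, 5000, 1000)
        f1 = window_fst(g, c.chrom, c.pos, a1, b1, grid)["fst"]
        f2 = window_fst(g, c.chrom, c.pos, a2, b2, grid)["fst"]
        assert np.allclose(f1, f2, equal_nan=True)

    def test_window_fst_worked_cases(self):
        chrom = np.array(["chr1"], dtype=object)
        pos = np.array([100])
        # one fixed-difference site
        a, b = hudson_fst_site(np.array([1.0]), np.array([10]),
                               np.array([0.0]), np.array([10]))
        out = window_fst(GEN, chrom, pos, a, b, GRID, min_sites=1)
        assert out["fst"].iloc[0] == pytest.approx(1.0)
        # zero denominator -> null
        out = window_fst(GEN, chrom, pos, np.array([0.0]), np.array([0.0]),
                         GRID, min_sites=1)
        assert np.isnan(out["fst"].iloc[0])

    def test_equal_frequency_windows_are_nonpositive(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.95, 200)
        a, b = hudson_fst_site(p, np.full(200, 20), p, np.full(200, 20))
        out = window_fst(GEN, np.full(200, "chr1", dtype=object),
                         np.arange(200) * 50, a, b, GRID, min_sites=1)
        assert out["fst"].iloc[0] <= 0


class TestPbs:
    def test_zero_fst_gives_zero_branches(self):
        assert pbs_from_fst(np.array([0.0]), np.array([0.0]),
                            np.array([0.0]))[0][0] == 0.0

    def test_symmetric_fst_triple(self):
        h, l, d = pbs_from_fst(np.array([0.1]), np.array([0.1]), np.array([0.1]))
        assert h[0] == pytest.approx(0.052680, abs=1e-6)
        assert l[0] == pytest.approx(h[0]) and d[0] == pytest.approx(h[0])

    def test_highland_specific_divergence_maps_to_high_branch(self):
        h, l, d = pbs_from_fst(np.array([0.5]), np.array([0.5]), np.array([0.0]))
        assert h[0] == pytest.approx(np.log(2), abs=1e-6)
        assert l[0] == pytest.approx(0.0, abs=1e-12)
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_null_input_nulls_all_branches(self):
        h, l, d = pbs_from_fst(np.array([np.nan]), np.array([0.1]), np.array([0.1]))
        assert np.isnan(h[0]) and np.isnan(l[0]) and np.isnan(d[0])

    @settings(max_examples=200, derandomize=True)
    @given(st.tuples(*[st.floats(0.0, 0.99) for _ in range(3)]))
    def test_branch_sum_identity(self, fsts):
        """The three PBS branches sum to (T_hl + T_hd + T_ld)/2."""
        f = [np.array([x]) for x in fsts]
        h, l, d = pbs_from_fst(*f)
        t = [-np.log(1 - np.clip(x, 0, 1 - 1e-9)) for x in fsts]
        assert abs(h[0] + l[0] + d[0] - sum(t) / 2) < 1e-12


class TestZscore:
    def test_constant_track_maps_to_zero(self):
        assert np.allclose(zscore(np.full(10, 3.3)), 0.0)

    def test_population_sd_convention(self):
        z = zscore(np.array([0.0, 0.0, 0.0, 10.0]))
        assert z[3] == pytest.approx(np.sqrt(3), abs=1e-3)  # 1.732

    def test_mean_z_is_zero(self, small_dataset):
        rng = np.random.default_rng(1)
        x = rng.normal(size=500)
        x[::7] = np.nan
        z = zscore(x)
        assert abs(np.nanmean(z)) < 1e-9

    def test_too_few_windows_is_an_error(self):
        with pytest.raises(ValueError):
            zscore(np.array([1.0, np.nan]))


class TestPi:
    def test_single_heterozygous_pair_contributes_one(self):
        # two haplotypes differing at one site: exactly one pairwise diff
        hap = np.array([[0], [1]])
        c = counts_from_haplotypes(hap, positions=[100])
        pi = pi_window(GEN, c, "A", GRID)
        assert pi[0] * 10_000 == pytest.approx(1.0)

    def test_monomorphic_window_has_zero_pi(self):
        hap = np.zeros((4, 5), dtype=int)
        c = counts_from_haplotypes(hap)
        assert pi_window(GEN, c, "A", GRID)[0] == 0.0

    def test_pi_matches_mean_pairwise_hamming_oracle(self):
        rng = np.random.default_rng(4)
        hap = (rng.random((6, 50)) < 0.3).astype(int)
        c = counts_from_haplotypes(hap, positions=rng.choice(10_000, 50, replace=False))
        pi = pi_window(GEN, c, "A", GRID)[0]
        # brute force over all 15 haplotype pairs
        diffs = [np.sum(hap[i] != hap[j])
                 for i in range(6) for j in range(i + 1, 6)]
        assert pi == pytest.approx(np.mean(diffs) / 10_000, abs=1e-12)

    def test_pi_invariant_to_allele_label_swap(self):
        rng = np.random.default_rng(5)
        hap = (rng.random((8, 30)) < 0.4).astype(int)
        c1 = counts_from_haplotypes(hap)
        c2 = counts_from_haplotypes(1 - hap)
        assert pi_window(GEN, c1, "A", GRID)[0] == pytest.approx(
            pi_window(GEN, c2, "A", GRID)[0], abs=1e-12)


def tajima_d_oracle(hap: np.ndarray) -> float:
    """Straight-from-the-textbook Tajima's D for a haplotype matrix."""
    n, _ = hap.shape
    freqs = hap.mean(axis=0)
    seg = (freqs > 0) & (freqs < 1)
    s = int(seg.sum())
    if s == 0:
        return np.nan
    # mean pairwise differences, counted explicitly
    pi = np.mean([np.sum(hap[i] != hap[j])
                  for i in range(n) for j in range(i + 1, n)])
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))


class TestTajimasD:
    def test_no_segregating_sites_is_null(self):
        hap = np.zeros((6, 10), dtype=int)
        c = counts_from_haplotypes(hap)
        assert np.isnan(tajimas_d_window(GEN, c, "A", GRID)[0])

    def test_singleton_excess_is_negative(self):
        hap = np.zeros((4, 1), dtype=int)
        hap[0, 0] = 1  # one derived singleton among 4 haplotypes
        c = counts_from_haplotypes(hap)
        d = tajimas_d_window(GEN, c, "A", GRID)[0]
        assert d < 0
        assert d == pytest.approx(tajima_d_oracle(hap), abs=1e-10)

    def test_matches_independent_oracle_to_1e10(self):
        rng = np.random.default_rng(6)
        hap = (rng.random((10, 40)) < 0.25).astype(int)
        c = counts_from_haplotypes(hap, positions=rng.choice(10_000, 40, replace=False))
        d = tajimas_d_window(GEN, c, "A", GRID)[0]
        assert d == pytest.approx(tajima_d_oracle(hap), abs=1e-10)


def dxy_oracle(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """Mean per-pair between-population difference count."""
    diffs = [np.sum(a != b) for a in hap_a for b in hap_b]
    return np.mean(diffs)


class TestDxy:
    def test_reciprocally_fixed_site(self):
        c = counts_from_haplotypes(np.array([[0], [0]]), np.array([[1], [1]]),
                                   positions=[0])
        assert dxy_window(GEN, c, "A", "B", GRID)[0] * 10_000 == pytest.approx(1.0)

    def test_shared_polymorphism(self):
        c = counts_from_haplotypes(np.array([[0], [1]]), np.array([[0], [1]]),
                                   positions=[0])
        assert dxy_window(GEN, c, "A", "B", GRID)[0] * 10_000 == pytest.approx(0.5)

    def test_identical_monomorphic_populations(self):
        c = counts_from_haplotypes(np.zeros((4, 3), dtype=int),
                                   np.zeros((4, 3), dtype=int))
        assert dxy_window(GEN, c, "A", "B", GRID)[0] == 0.0

    @pytest.mark.parametrize("na,nb", [(2, 2), (4, 6), (8, 8), (3, 8)])
    def test_matches_brute_force_pair_oracle(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        hap_a = (rng.random((na, 40)) < 0.4).astype(int)
        hap_b = (rng.random((nb, 40)) < 0.2).astype(int)
        c = counts_from_haplotypes(hap_a, hap_b,
                                   positions=rng.choice(10_000, 40, replace=False))
        dxy = dxy_window(GEN, c, "A", "B", GRID)[0]
        assert dxy * 10_000 == pytest.approx(dxy_oracle(hap_a, hap_b), abs=1e-10)


class TestDeltaPi:
    def test_equal_tracks_give_zero(self):
        x = np.array([0.1, 0.2])
        assert np.allclose(delta_pi(x, x), 0.0)

    def test_sweep_consistent_sign_and_null_propagation(self):
        d = delta_pi(np.array([0.002, np.nan]), np.array([0.005, 0.001]))
        assert d[0] == pytest.approx(-0.003)
        assert np.isnan(d[1])


class TestTransectScan:
    def test_outputs_on_fixed_grid_with_nulls_below_min_sites(self, small_dataset):
        g = small_dataset["genome"]
        tr = windows.transect_scan(
            g, small_dataset["counts"],
            windows.TransectTrio("t1_high", "t1_low", "t1_low_distant"))
        grid = make_grid(g, 5000, 1000)
        assert len(tr) == len(grid)
        sparse = tr["n_sites"] < windows.DEFAULT_MIN_SITES
        assert tr.loc[sparse, "fst_high_low"].isna().all()

    def test_fst_only_mode_uses_fst_z(self, small_dataset):
        tr = windows.transect_scan(
            small_dataset["genome"], small_dataset["counts"],
            windows.TransectTrio("t1_high", "t1_low"))
        assert "pbs_high" not in tr.columns
        assert np.isfinite(tr["z"]).any()

    def test_heavy_tail_bound_without_signal(self, small_dataset):
        tr = windows.transect_scan(
            small_dataset["genome"], small_dataset["counts"],
            windows.TransectTrio("t1_high", "t1_low", "t1_low_distant"))
        frac = np.mean(tr["z"].to_numpy() > 4)
        assert frac < 0.01
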