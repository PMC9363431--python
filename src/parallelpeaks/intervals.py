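"""High Differentiation Regions: calling, sharing, and permutation nulls.

Outlier windows (z above a threshold, default 4) are expanded by a +/-50 kb
buffer around the window centre and overlapping or book-ended intervals are
merged into discrete HDRs. An HDR shared with the replicate transect on the
same side of the barrier is a within-side SHDR; one additionally shared
with at least one HDR in each transect on the opposite side is an
allopatric SHDR. Significance of sharing comes from permutation nulls that
re-place interval sets of the same number and sizes uniformly across the
genome (placed intervals may collide and are merged afterwards, mirroring
how observed HDRs arise from merged buffers), and from delete-one-block
jackknife confidence intervals for the observed sharing proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import Genome, IntervalSet, merge_intervals, overlaps_any, place_random_intervals

__all__ = [
    "call_outliers",
    "build_hdrs",
    "classify_sharing",
    "overlap_permutation_null",
    "jackknife_ci",
    "recomb_comparison",
    "candidate_overlap_test",
]

DEFAULT_Z_THRESHOLD = 4.0
DEFAULT_BUFFER = 50_000


def call_outliers(track: pd.DataFrame, threshold: float = DEFAULT_Z_THRESHOLD,
                  z_column: str = "z") -> pd.DataFrame:
    """Windows with z strictly above the threshold; null windows excluded."""
    z = track[z_column]
    return track[np.isfinite(z) & (z > threshold)].reset_index(drop=True)


def build_hdrs(genome: Genome, outliers: pd.DataFrame,
               buffer: int = DEFAULT_BUFFER,
               source_transect: str | None = None,
               z_column: str = "z") -> IntervalSet:
    """Merge +/-buffer intervals around outlier window centres into HDRs.

    Intervals are clipped to chromosome bounds before merging. The merged
    set carries per-HDR provenance: member window centres and the maximum
    z among members.
    """
    if len(outliers) == 0:
        return IntervalSet(genome, np.array([], dtype=object),
                           np.array([], dtype=np.int64), np.array([], dtype=np.int64),
                           meta=pd.DataFrame({"source_transect": [], "max_z": [],
                                              "member_centres": []}))
    chrom = outliers["chrom"].to_numpy()
    centre = outliers["centre"].to_numpy(dtype=np.int64)
    lengths = np.array([genome.chrom_lengths[c] for c in chrom], dtype=np.int64)
    start = np.clip(centre - buffer, 0, None)
    end = np.minimum(centre + buffer, lengths)
    lin_s = genome.linearise(chrom, start)
    lin_e = genome.linearise(chrom, end)
    ms, me = merge_intervals(lin_s, lin_e)
    # assign members to merged intervals
    lin_c = genome.linearise(chrom, centre)
    idx = np.searchsorted(ms, genome.linearise(chrom, start), side="right") - 1
    z = (outliers[z_column].to_numpy(dtype=float)
         if z_column in outliers else np.full(len(outliers), np.nan))
    max_z = np.full(ms.size, -np.inf)
    members: list[list[int]] = [[] for _ in range(ms.size)]
    for k, m in enumerate(idx):
        max_z[m] = max(max_z[m], z[k])
        members[m].append(int(lin_c[k]))
    meta = pd.DataFrame(
        {
            "source_transect": source_transect,
            "max_z": max_z,
            "member_centres": [",".join(map(str, m)) for m in members],
        }
    )
    return IntervalSet.from_linear(genome, ms, me, meta=meta)


def _side_partners(layout: dict[str, str], focal: str) -> tuple[list[str], list[str]]:
    """(same-side replicates, opposite-side transects) for a focal transect."""
    side = layout[focal]
    same = [t for t, s in layout.items() if s == side and t != focal]
    other = [t for t, s in layout.items() if s != side]
    return same, other


def classify_sharing(hdr_sets: dict[str, IntervalSet],
                     layout: dict[str, str]) -> dict[str, pd.DataFrame]:
    """Classify every HDR of every transect as private / within-side SHDR /
    allopatric SHDR.

    ``layout`` maps transect -> side. A within-side SHDR overlaps at least
    one HDR of a same-side replicate transect; an allopatric SHDR overlaps
    the replicate AND at least one HDR in EACH opposite-side transect.
    """
    if len(hdr_sets) < 2:
        raise ValueError("sharing needs at least 2 transects")
    for t in hdr_sets:
        if t not in layout:
            raise ValueError(f"transect {t!r} missing from layout")
    out = {}
    for focal, hdrs in hdr_sets.items():
        same, other = _side_partners(layout, focal)
        n = len(hdrs)
        within = np.zeros(n, dtype=bool)
        for t in same:
            within |= hdrs.overlaps(hdr_sets[t])
        allo = within.copy()
        for t in other:
            allo &= hdrs.overlaps(hdr_sets[t])
        if not other:
            allo[:] = False
        cls = np.where(allo, "shdr_allopatric",
                       np.where(within, "shdr_within_side", "private"))
        df = hdrs.to_frame()
        df["sharing_class"] = cls
        out[focal] = df
    return out


def sharing_proportion(focal: IntervalSet, partner_sets: list[IntervalSet],
                       mode: str = "any") -> float:
    """Proportion of focal intervals overlapping the partners.

    mode='any': overlap with at least one partner set (within-side when a
    single replicate is passed); mode='all': overlap with every partner
    set (allopatric-style sharing).
    """
    n = len(focal)
    if n == 0:
        return float("nan")
    if mode == "any":
        hit = np.zeros(n, dtype=bool)
        for p in partner_sets:
            hit |= focal.overlaps(p)
    elif mode == "all":
        hit = np.ones(n, dtype=bool)
        for p in partner_sets:
            hit &= focal.overlaps(p)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(hit.mean())


def overlap_permutation_null(
    genome: Genome,
    focal: IntervalSet,
    partner_sets: list[IntervalSet],
    n_perm: int = 10_000,
    seed: int = 0,
    mode: str = "any",
) -> dict:
    """Permutation null for the sharing proportion of one transect.

    Each permutation re-places the focal transect's intervals (same number,
    same sizes, before merging) uniformly at random — the chromosome chosen
    proportional to its length, the start uniform over valid positions —
    merges collisions, and recomputes the sharing proportion against the
    OBSERVED partner sets. Empirical one-sided
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    observed = sharing_proportion(focal, partner_sets, mode)
    sizes = focal.sizes()
    rng = np.random.default_rng(seed)
    # pre-merge partner sets once
    merged_partners = [p.merged() for p in partner_sets]
    null = np.empty(n_perm)
    for b in range(n_perm):
        s, e = place_random_intervals(genome, sizes, rng)
        ms, me = merge_intervals(s, e)
        if mode == "any":
            hit = np.zeros(ms.size, dtype=bool)
            for p in merged_partners:
                hit |= overlaps_any(ms, me, p.lin_start, p.lin_end)
        else:
            hit = np.ones(ms.size, dtype=bool)
            for p in merged_partners:
                hit &= overlaps_any(ms, me, p.lin_start, p.lin_end)
        null[b] = hit.mean() if ms.size else np.nan
    valid = null[np.isfinite(null)]
    if np.isnan(observed):
        p = float("nan")
    else:
        p = (1.0 + np.sum(valid >= observed)) / (valid.size + 1.0)
    return {"observed": observed, "null": null, "p": p,
            "null_mean": float(np.nanmean(null)) if null.size else float("nan")}


def jackknife_ci(
    genome: Genome,
    focal: IntervalSet,
    partner_sets: list[IntervalSet],
    block_size: int = 1_000_000,
    confidence: float = 0.95,
    mode: str = "any",
) -> dict:
    """Delete-one-block jackknife CI for the observed sharing proportion.

    The genome is cut into contiguous ``block_size`` blocks (in linearised
    coordinates); each replicate recomputes the sharing proportion without
    the focal HDRs whose midpoint falls in the deleted block. CI is
    estimate +/- z * jackknife SE.
    """
    total_lin = genome.linearise([genome.chroms[-1]],
                                 [genome.chrom_lengths[genome.chroms[-1]]])[0]
    n_blocks = int(np.ceil(total_lin / block_size))
    if n_blocks < 10:
        raise ValueError("need >= 10 jackknife blocks; reduce block_size")
    observed = sharing_proportion(focal, partner_sets, mode)
    mid = (focal.lin_start + focal.lin_end) // 2
    block_of = mid // block_size
    if len(focal) and np.unique(block_of).size == 1:
        return {"observed": observed, "se": float("nan"),
                "ci": (float("nan"), float("nan")), "degenerate": True}
    reps = np.empty(n_blocks)
    for b in range(n_blocks):
        keep = block_of != b
        sub = IntervalSet.from_linear(genome, focal.lin_start[keep], focal.lin_end[keep])
        reps[b] = sharing_proportion(sub, partner_sets, mode)
    ok = np.isfinite(reps)
    m = reps[ok].mean()
    g = ok.sum()
    se = float(np.sqrt((g - 1) / g * np.sum((reps[ok] - m) ** 2)))
    zq = stats.norm.ppf(0.5 + confidence / 2.0)
    return {"observed": observed, "se": se,
            "ci": (observed - zq * se, observed + zq * se),
            "replicates": reps, "degenerate": False}


def recomb_comparison(genome: Genome, hdrs: IntervalSet, rho_track: pd.DataFrame,
                      value_column: str = "rho") -> dict:
    """Compare recombination-rate values inside vs outside HDRs.

    ``rho_track`` needs chrom/centre/value columns on its own (e.g. 50 kb)
    grid. Returns the two distributions and a two-sample KS test.
    """
    if len(hdrs) == 0:
        raise ValueError("no inside windows: HDR set is empty")
    lin_c = genome.linearise(rho_track["chrom"].to_numpy(),
                             rho_track["centre"].to_numpy(dtype=np.int64))
    merged = hdrs.merged()
    inside = overlaps_any(lin_c, lin_c + 1, merged.lin_start, merged.lin_end)
    vals = rho_track[value_column].to_numpy(dtype=float)
    ok = np.isfinite(vals)
    inside_vals = vals[inside & ok]
    outside_vals = vals[~inside & ok]
    if inside_vals.size == 0:
        raise ValueError("no inside windows overlap the rho track")
    if inside_vals.size and outside_vals.size:
        ks = stats.ks_2samp(inside_vals, outside_vals)
        d, p = float(ks.statistic), float(ks.pvalue)
    else:
        d, p = 0.0, 1.0
    return {"inside": inside_vals, "outside": outside_vals, "ks_d": d, "ks_p": p}


def candidate_overlap_test(
    genome: Genome,
    hdrs: IntervalSet,
    candidates: IntervalSet,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """How many candidate loci overlap an HDR, against a placement null.

    The null re-places the HDR set (same number/sizes, merged after
    placement) and counts candidates overlapping each permuted set;
    empirical p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    merged = hdrs.merged()
    observed = int(np.sum(overlaps_any(candidates.lin_start, candidates.lin_end,
                                       merged.lin_start, merged.lin_end)))
    sizes = hdrs.sizes()
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=np.int64)
    for b in range(n_perm):
        s, e = place_random_intervals(genome, sizes, rng)
        ms, me = merge_intervals(s, e)
        null[b] = np.sum(overlaps_any(candidates.lin_start, candidates.lin_end, ms, me))
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return {"observed": observed, "null": null, "p": float(p),
            "null_quantiles": {q: float(np.quantile(null, q))
                               for q in (0.05, 0.5, 0.9, 0.95)}}
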