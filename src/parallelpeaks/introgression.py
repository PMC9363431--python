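"""Excess allele sharing: windowed f_dM scans and SHDR-level tests.

On a four-population tree (((P1, P2), P3), O) — lowland P1, highland P2,
putative donor P3 (an allopatric conspecific highland population or a
sympatric highland-specialist species) and outgroup O — the per-site
ABBA-BABA difference on derived-allele frequencies is

    num = (1 - p1) p2 p3 (1 - pO)  -  p1 (1 - p2) p3 (1 - pO).

f_dM normalises the summed numerator by a dynamic denominator: at sites
with p2 >= p1 the donor-like frequency pD = max(p2, p3) is substituted for
both P2 and P3; at sites with p2 < p1, pD = max(p1, p3) is substituted for
both P1 and P3 and the contribution is negated. f_dM lies in [-1, 1] and
is antisymmetric under swapping P1 and P2: positive values mean excess
sharing between the donor and the highland population, negative between
the donor and the lowland population.

Sites are polarised on the outgroup major allele (ancestral); sites where
the outgroup is polymorphic above 20% minor frequency are dropped. Windows
are non-overlapping (default 50 kb) and need a minimum number of
informative sites (default 20) to be non-null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import Genome, IntervalSet, merge_intervals, overlaps_any, place_random_intervals
from .windows import make_grid

__all__ = [
    "QuartetConfig",
    "fdm_track",
    "pattersons_d",
    "shdr_fdm_outliers",
    "fdm_enrichment_test",
    "background_fdm",
]

DEFAULT_FDM_WINDOW = 50_000
DEFAULT_MIN_INFORMATIVE = 20
OUTGROUP_MAX_MINOR = 0.2


@dataclass(frozen=True)
class QuartetConfig:
    """(((P1, P2), P3), O): P1 lowland, P2 highland, P3 putative donor."""

    p1: str
    p2: str
    p3: str
    outgroup: str

    def __post_init__(self):
        names = [self.p1, self.p2, self.p3, self.outgroup]
        if len(set(names)) != 4:
            raise ValueError("quartet populations must be distinct")


def _polarise(p1, p2, p3, po):
    """Polarise on the outgroup major allele; returns derived frequencies
    and a mask of usable (polarizable) sites."""
    p1, p2, p3, po = (np.asarray(x, dtype=float) for x in (p1, p2, p3, po))
    ok = np.isfinite(p1) & np.isfinite(p2) & np.isfinite(p3) & np.isfinite(po)
    minor = np.minimum(po, 1 - po)
    ok &= minor <= OUTGROUP_MAX_MINOR
    flip = po > 0.5
    d1 = np.where(flip, 1 - p1, p1)
    d2 = np.where(flip, 1 - p2, p2)
    d3 = np.where(flip, 1 - p3, p3)
    do = np.where(flip, 1 - po, po)
    return d1, d2, d3, do, ok


def _fdm_site_terms(p1, p2, p3, po):
    """Per-site f_dM numerator and denominator terms (already polarised)."""
    num = (1 - p1) * p2 * p3 * (1 - po) - p1 * (1 - p2) * p3 * (1 - po)
    hi = p2 >= p1  # ties on the P2 branch by convention
    pd23 = np.maximum(p2, p3)
    den_hi = (1 - p1) * pd23 * pd23 * (1 - po) - p1 * (1 - pd23) * pd23 * (1 - po)
    pd13 = np.maximum(p1, p3)
    den_lo = -((1 - pd13) * p2 * pd13 * (1 - po) - pd13 * (1 - p2) * pd13 * (1 - po))
    den = np.where(hi, den_hi, den_lo)
    return num, den


def fdm_track(
    genome: Genome,
    counts,
    quartet: QuartetConfig,
    window: int = DEFAULT_FDM_WINDOW,
    min_informative: int = DEFAULT_MIN_INFORMATIVE,
) -> pd.DataFrame:
    """Windowed f_dM on non-overlapping windows.

    Informative sites are polarizable sites carrying derived variation in
    at least one of P1/P2/P3; windows with fewer than ``min_informative``
    are null. f_dM = sum(num) / sum(den) per window.
    """
    grid = make_grid(genome, window, window)
    d1, d2, d3, do, ok = _polarise(
        counts.freq(quartet.p1), counts.freq(quartet.p2),
        counts.freq(quartet.p3), counts.freq(quartet.outgroup),
    )
    num, den = _fdm_site_terms(d1, d2, d3, do)
    informative = ok & ((d1 > 0) | (d2 > 0) | (d3 > 0))
    num = np.where(informative, num, 0.0)
    den = np.where(informative, den, 0.0)
    lin = genome.linearise(counts.chrom, counts.pos)
    order = np.argsort(lin, kind="stable")
    lin_s = lin[order]
    cs_num = np.concatenate([[0.0], np.cumsum(num[order])])
    cs_den = np.concatenate([[0.0], np.cumsum(den[order])])
    cs_inf = np.concatenate([[0], np.cumsum(informative[order])])
    ws = genome.linearise(grid["chrom"].to_numpy(), grid["start"].to_numpy())
    we = genome.linearise(grid["chrom"].to_numpy(), grid["end"].to_numpy())
    i = np.searchsorted(lin_s, ws, side="left")
    j = np.searchsorted(lin_s, we, side="left")
    snum = cs_num[j] - cs_num[i]
    sden = cs_den[j] - cs_den[i]
    ninf = cs_inf[j] - cs_inf[i]
    with np.errstate(invalid="ignore", divide="ignore"):
        fdm = np.where((ninf >= min_informative) & (sden != 0), snum / np.where(sden != 0, sden, 1.0), np.nan)
    out = grid.copy()
    out["n_informative"] = ninf
    out["fdm"] = fdm
    return out


def pattersons_d(counts, quartet: QuartetConfig) -> float:
    """Genome-wide Patterson's D: same numerator summed over all
    informative sites, over sum of (ABBA + BABA)."""
    d1, d2, d3, do, ok = _polarise(
        counts.freq(quartet.p1), counts.freq(quartet.p2),
        counts.freq(quartet.p3), counts.freq(quartet.outgroup),
    )
    abba = (1 - d1) * d2 * d3 * (1 - do)
    baba = d1 * (1 - d2) * d3 * (1 - do)
    num = np.sum((abba - baba)[ok])
    den = np.sum((abba + baba)[ok])
    return float(num / den) if den > 0 else float("nan")


def shdr_fdm_outliers(genome: Genome, track: pd.DataFrame,
                      shdrs: IntervalSet) -> dict:
    """Per-SHDR f_dM extrema and the relative outlier rule.

    For each SHDR, record the maximum and minimum f_dM over overlapping
    windows; the outlier threshold is the 90th percentile of |min f_dM|
    across all SHDRs (SHDRs whose minimum is positive contribute |min| as
    well), and an SHDR is flagged when its maximum exceeds that threshold.
    """
    merged = shdrs.merged()
    if len(merged) == 0:
        raise ValueError("empty SHDR set")
    vals = track["fdm"].to_numpy(dtype=float)
    rows = []
    ws = genome.linearise(track["chrom"].to_numpy(),
                          track["start"].to_numpy(dtype=np.int64))
    we = genome.linearise(track["chrom"].to_numpy(),
                          track["end"].to_numpy(dtype=np.int64))
    for i in range(len(merged)):
        overlap = (ws < merged.lin_end[i]) & (we > merged.lin_start[i])
        v = vals[overlap]
        v = v[np.isfinite(v)]
        rows.append({"shdr": i,
                     "max_fdm": v.max() if v.size else np.nan,
                     "min_fdm": v.min() if v.size else np.nan,
                     "n_windows": int(v.size)})
    df = pd.DataFrame(rows)
    chrom, start = genome.delinearise(merged.lin_start)
    _, end = genome.delinearise(merged.lin_end)
    df.insert(1, "chrom", chrom)
    df.insert(2, "start", start)
    df.insert(3, "end", end)
    usable = df[np.isfinite(df["max_fdm"])]
    low_power = len(usable) < 10
    absmin = np.abs(usable["min_fdm"].to_numpy(dtype=float))
    if len(usable):
        thr = float(np.percentile(absmin, 90))
        flagged = np.isfinite(df["max_fdm"]) & (df["max_fdm"] > thr)
    else:
        thr = np.nan
        flagged = pd.Series(False, index=df.index)
    df["fdm_outlier"] = flagged
    pct = 100.0 * flagged.sum() / len(usable) if len(usable) else float("nan")
    return {"table": df, "threshold": thr, "percent_flagged": pct,
            "low_power": low_power}


def fdm_enrichment_test(max_fdm: np.ndarray, absmin_fdm: np.ndarray) -> dict:
    """One-sided two-sample KS test: are the per-SHDR maxima (sharing with
    the highlands) stochastically larger than the |minima| (sharing with
    the lowlands)?"""
    a = np.asarray(max_fdm, dtype=float)
    b = np.asarray(absmin_fdm, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 5 or b.size < 5:
        raise ValueError("insufficient SHDRs for the KS enrichment test")
    # alternative='less': CDF of maxima lies below that of |minima|,
    # i.e. maxima stochastically larger
    res = stats.ks_2samp(a, b, alternative="less")
    return {"ks_d": float(res.statistic), "p": float(res.pvalue)}


def background_fdm(
    genome: Genome,
    track: pd.DataFrame,
    sizes: np.ndarray,
    n_perm: int = 1_000,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of the mean per-interval maximum f_dM.

    Each permutation places SHDR-sized intervals uniformly across the
    genome (merged after placement), takes the maximum f_dM of windows
    overlapping each interval, and records the mean of those maxima.
    """
    sizes = np.asarray(sizes, dtype=np.int64)
    rng = np.random.default_rng(seed)
    ws = genome.linearise(track["chrom"].to_numpy(),
                          track["start"].to_numpy(dtype=np.int64))
    we = genome.linearise(track["chrom"].to_numpy(),
                          track["end"].to_numpy(dtype=np.int64))
    vals = track["fdm"].to_numpy(dtype=float)
    out = np.empty(n_perm)
    for b in range(n_perm):
        s_, e_ = place_random_intervals(genome, sizes, rng)
        ms, me = merge_intervals(s_, e_)
        maxima = []
        for k in range(ms.size):
            sel = (ws < me[k]) & (we > ms[k])
            v = vals[sel]
            v = v[np.isfinite(v)]
            if v.size:
                maxima.append(v.max())
        out[b] = np.mean(maxima) if maxima else np.nan
    return out
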