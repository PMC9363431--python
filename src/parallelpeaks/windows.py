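"""Per-site and windowed population-genetic statistics.

Selection statistics (Hudson Fst, PBS, pi, Tajima's D, delta-pi, Dxy) are
computed on a fixed sliding-window grid (default 5 kb windows, 1 kb steps);
windowed Fst is the ratio of sums ("weighted") estimator. PBS transforms
pairwise Fst into relative divergence times T = -log(1 - Fst) and assigns
the branch lengths

    PBS_high = (T_high,low + T_high,dist - T_low,dist) / 2

(and symmetrically for the other two branches); large PBS_high marks
highland-specific allele-frequency change. Window tracks are z-normalised
genome-wide per transect so differentiation is comparable across transects.

Coordinates are 0-based half-open throughout; VCF input is converted on
read. Windows with fewer than ``min_sites`` usable variant sites are null
(NaN) and excluded from z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Genome

__all__ = [
    "TransectTrio",
    "make_grid",
    "allele_counts",
    "hudson_fst_site",
    "window_fst",
    "pbs_from_fst",
    "zscore",
    "pi_window",
    "tajimas_d_window",
    "dxy_window",
    "delta_pi",
    "transect_scan",
]

DEFAULT_WINDOW = 5_000
DEFAULT_STEP = 1_000
DEFAULT_MIN_SITES = 10


@dataclass(frozen=True)
class TransectTrio:
    """High / low / distant-low populations of one transect.

    ``low_distant`` may be None, flagging a degenerate two-population
    transect analysed in Fst-only mode.
    """

    high: str
    low: str
    low_distant: str | None = None

    def __post_init__(self):
        names = [self.high, self.low] + ([self.low_distant] if self.low_distant else [])
        if len(set(names)) != len(names):
            raise ValueError("trio populations must be distinct")

    @property
    def fst_only(self) -> bool:
        return self.low_distant is None


def make_grid(genome: Genome, size: int = DEFAULT_WINDOW, step: int | None = None) -> pd.DataFrame:
    """Fixed window grid: per chromosome, starts 0, step, ... while the
    window fits fully on the chromosome. centre = start + size // 2."""
    step = size if step is None else step
    frames = []
    for chrom, length in genome.chrom_lengths.items():
        if length < size:
            continue
        starts = np.arange(0, length - size + 1, step, dtype=np.int64)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + size,
                    "centre": starts + size // 2,
                }
            )
        )
    if not frames:
        raise ValueError("no chromosome can hold a full window")
    return pd.concat(frames, ignore_index=True)


@dataclass
class AlleleCounts:
    """Per-site derived-allele counts and called haplotype totals per
    population (derived = ALT = non-ancestral by the simulator's
    polarisation)."""

    chrom: np.ndarray
    pos: np.ndarray
    ac: dict[str, np.ndarray]  # population -> derived allele count
    an: dict[str, np.ndarray]  # population -> called haplotypes

    def freq(self, pop: str) -> np.ndarray:
        an = self.an[pop]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(an > 0, self.ac[pop] / np.maximum(an, 1), np.nan)


def allele_counts(chrom, pos, genotypes, sample_ids, popmap: pd.DataFrame) -> AlleleCounts:
    """Tabulate per-population derived counts from a dosage matrix
    (sites x samples; -1 = missing)."""
    geno = np.asarray(genotypes)
    sample_to_pop = dict(zip(popmap["sample"], popmap["population"]))
    cols_by_pop: dict[str, list[int]] = {}
    for j, s in enumerate(sample_ids):
        if s in sample_to_pop:
            cols_by_pop.setdefault(sample_to_pop[s], []).append(j)
    ac, an = {}, {}
    for pop, cols in cols_by_pop.items():
        sub = geno[:, cols]
        called = sub >= 0
        ac[pop] = np.where(called, sub, 0).sum(axis=1).astype(np.int64)
        an[pop] = 2 * called.sum(axis=1).astype(np.int64)
    return AlleleCounts(chrom=np.asarray(chrom, dtype=object),
                        pos=np.asarray(pos, dtype=np.int64), ac=ac, an=an)


def hudson_fst_site(p1, n1, p2, n2) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Hudson Fst components (Bhatia's estimator).

    alpha (numerator) and beta (denominator) per site; windowed Fst is
    sum(alpha)/sum(beta). Sites where either population has fewer than 2
    called haplotypes yield NaN components (skipped downstream).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        beta = p1 * (1 - p2) + p2 * (1 - p1)
    alpha = np.where(ok, alpha, np.nan)
    beta = np.where(ok, beta, np.nan)
    return alpha, beta


def _window_slices(genome: Genome, chrom, pos, grid: pd.DataFrame):
    """searchsorted index pairs (i, j) of sites inside each grid window."""
    lin = genome.linearise(chrom, pos)
    order = np.argsort(lin, kind="stable")
    lin_sorted = lin[order]
    wstart = genome.linearise(grid["chrom"].to_numpy(), grid["start"].to_numpy())
    wend = genome.linearise(grid["chrom"].to_numpy(), grid["end"].to_numpy())
    i = np.searchsorted(lin_sorted, wstart, side="left")
    j = np.searchsorted(lin_sorted, wend, side="left")
    return order, i, j


def _window_sum(values: np.ndarray, order, i, j) -> tuple[np.ndarray, np.ndarray]:
    """Sum of (possibly NaN) per-site values per window, plus the count of
    finite sites, via cumulative sums."""
    v = values[order]
    finite = np.isfinite(v)
    cs = np.concatenate([[0.0], np.cumsum(np.where(finite, v, 0.0))])
    cn = np.concatenate([[0], np.cumsum(finite)])
    return cs[j] - cs[i], cn[j] - cn[i]


def window_fst(genome, chrom, pos, alpha, beta, grid: pd.DataFrame,
               min_sites: int = DEFAULT_MIN_SITES) -> pd.DataFrame:
    """Windowed ratio-of-sums Hudson Fst on the grid; NaN where the
    denominator is zero or fewer than ``min_sites`` sites contribute."""
    order, i, j = _window_slices(genome, chrom, pos, grid)
    sa, na = _window_sum(np.asarray(alpha, dtype=float), order, i, j)
    sb, _ = _window_sum(np.asarray(beta, dtype=float), order, i, j)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where((sb > 0) & (na >= min_sites), sa / np.where(sb > 0, sb, 1.0), np.nan)
    out = grid.copy()
    out["n_sites"] = na
    out["fst"] = fst
    return out


def pbs_from_fst(fst_high_low, fst_high_dist, fst_low_dist):
    """Population branch statistics from the three pairwise windowed Fst.

    Fst estimates are clamped to [0, 1-1e-9] before T = -log(1-Fst); any
    NaN input nulls all three outputs for that window.
    """
    def t(f):
        f = np.clip(np.asarray(f, dtype=float), 0.0, 1.0 - 1e-9)
        return -np.log(1.0 - f)

    t_hl, t_hd, t_ld = t(fst_high_low), t(fst_high_dist), t(fst_low_dist)
    bad = ~(np.isfinite(np.asarray(fst_high_low, dtype=float))
            & np.isfinite(np.asarray(fst_high_dist, dtype=float))
            & np.isfinite(np.asarray(fst_low_dist, dtype=float)))
    pbs_high = (t_hl + t_hd - t_ld) / 2.0
    pbs_low = (t_hl + t_ld - t_hd) / 2.0
    pbs_dist = (t_hd + t_ld - t_hl) / 2.0
    for arr in (pbs_high, pbs_low, pbs_dist):
        arr[bad] = np.nan
    return pbs_high, pbs_low, pbs_dist


def zscore(values) -> np.ndarray:
    """Genome-wide z-normalisation over non-null windows (population sd,
    ddof=0); a zero sd maps everything to 0."""
    x = np.asarray(values, dtype=float)
    ok = np.isfinite(x)
    if ok.sum() < 2:
        raise ValueError("need at least 2 non-null windows to z-normalise")
    mu = x[ok].mean()
    sd = x[ok].std(ddof=0)
    z = np.full_like(x, np.nan)
    z[ok] = 0.0 if sd == 0 else (x[ok] - mu) / sd
    return z


def _pi_site(p: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Unbiased per-site mean pairwise difference: 2p(1-p) n/(n-1)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    return np.where(n >= 2, pi, np.nan)


def pi_window(genome, counts: AlleleCounts, pop: str, grid: pd.DataFrame,
              denominator: str = "window_length",
              accessible: np.ndarray | None = None) -> np.ndarray:
    """Windowed nucleotide diversity for one population.

    The numerator sums per-site unbiased pairwise diversity over variant
    sites; the denominator is the full window length by default (all
    unlisted sites count as monomorphic), or an accessible-site count per
    window when a mask total is supplied.
    """
    p = counts.freq(pop)
    n = counts.an[pop].astype(float)
    site_pi = _pi_site(p, n)
    order, i, j = _window_slices(genome, counts.chrom, counts.pos, grid)
    s, _ = _window_sum(site_pi, order, i, j)
    if denominator == "window_length":
        denom = (grid["end"] - grid["start"]).to_numpy(dtype=float)
    elif denominator == "accessible":
        if accessible is None:
            raise ValueError("accessible denominator requires per-window counts")
        denom = np.asarray(accessible, dtype=float)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, s / np.where(denom > 0, denom, 1.0), np.nan)


def _tajima_constants(n: int) -> dict[str, float]:
    """Classical constants for n haplotypes."""
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "e1": e1, "e2": e2}


def tajimas_d_window(genome, counts: AlleleCounts, pop: str, grid: pd.DataFrame,
                     n_haplotypes: int | None = None) -> np.ndarray:
    """Windowed Tajima's D for one population.

    Uses only sites where all of the population's haplotypes were called,
    so the classical constant-n formulation applies; windows with zero
    segregating sites are null.
    """
    n = n_haplotypes if n_haplotypes is not None else int(counts.an[pop].max(initial=0))
    if n < 3:
        raise ValueError("Tajima's D needs >= 3 haplotypes")
    full = counts.an[pop] == n
    p = counts.freq(pop)
    seg = full & (counts.ac[pop] > 0) & (counts.ac[pop] < n)
    site_pi = np.where(seg, _pi_site(p, float(n)), np.nan)
    order, i, j = _window_slices(genome, counts.chrom, counts.pos, grid)
    pi_sum, s_count = _window_sum(site_pi, order, i, j)
    k = _tajima_constants(n)
    s = s_count.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = k["e1"] * s + k["e2"] * s * (s - 1.0)
        d = (pi_sum - s / k["a1"]) / np.sqrt(var)
    d[s_count == 0] = np.nan
    return d


def dxy_window(genome, counts: AlleleCounts, pop_a: str, pop_b: str,
               grid: pd.DataFrame, denominator: str = "window_length",
               accessible: np.ndarray | None = None) -> np.ndarray:
    """Windowed absolute divergence between two populations.

    Per site, with haplotype counts nA, nB, nAB = nA + nB and theta the
    unbiased mean pairwise difference within a (pooled) group,

        Dxy = [theta_AB*C(nAB,2) - theta_A*C(nA,2) - theta_B*C(nB,2)]
              / (nA * nB)

    which reduces exactly to the mean pairwise difference between one
    haplotype from each population. Window value = sum over variant sites
    over the same denominator convention as pi.
    """
    na = counts.an[pop_a].astype(float)
    nb = counts.an[pop_b].astype(float)
    pa, pb = counts.freq(pop_a), counts.freq(pop_b)
    nab = na + nb
    with np.errstate(invalid="ignore", divide="ignore"):
        pab = (counts.ac[pop_a] + counts.ac[pop_b]) / np.where(nab > 0, nab, 1.0)
    th_a = _pi_site(pa, na)
    th_b = _pi_site(pb, nb)
    th_ab = _pi_site(pab, nab)

    def c2(n):
        return n * (n - 1) / 2.0

    with np.errstate(invalid="ignore", divide="ignore"):
        site = (th_ab * c2(nab) - th_a * c2(na) - th_b * c2(nb)) / (na * nb)
    site = np.where((na >= 2) & (nb >= 2), site, np.nan)
    order, i, j = _window_slices(genome, counts.chrom, counts.pos, grid)
    s, _ = _window_sum(site, order, i, j)
    if denominator == "window_length":
        denom = (grid["end"] - grid["start"]).to_numpy(dtype=float)
    elif denominator == "accessible":
        if accessible is None:
            raise ValueError("accessible denominator requires per-window counts")
        denom = np.asarray(accessible, dtype=float)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, s / np.where(denom > 0, denom, 1.0), np.nan)


def delta_pi(pi_high, pi_ref) -> np.ndarray:
    """Elementwise pi_high - pi_ref; NaN propagates."""
    return np.asarray(pi_high, dtype=float) - np.asarray(pi_ref, dtype=float)


def transect_scan(
    genome: Genome,
    counts: AlleleCounts,
    trio: TransectTrio,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_sites: int = DEFAULT_MIN_SITES,
) -> pd.DataFrame:
    """Full selection-statistic track for one transect.

    Returns one row per grid window with pairwise Fst, PBS branches (or
    Fst only for degenerate trios), the transect's genome-wide z track
    (zPBS_high, or zFst in Fst-only mode), per-population pi, highland
    Tajima's D, delta-pi (high minus distant low, or low when no distant
    population exists) and Dxy(high, reference lowland).
    """
    grid = make_grid(genome, window, step)
    hi, lo, di = trio.high, trio.low, trio.low_distant

    def pair_fst(a, b):
        alpha, beta = hudson_fst_site(counts.freq(a), counts.an[a],
                                      counts.freq(b), counts.an[b])
        return window_fst(genome, counts.chrom, counts.pos, alpha, beta,
                          grid, min_sites)

    out = grid.copy()
    f_hl = pair_fst(hi, lo)
    out["n_sites"] = f_hl["n_sites"]
    out["fst_high_low"] = f_hl["fst"]
    if not trio.fst_only:
        out["fst_high_dist"] = pair_fst(hi, di)["fst"]
        out["fst_low_dist"] = pair_fst(lo, di)["fst"]
        pbs_h, pbs_l, pbs_d = pbs_from_fst(
            out["fst_high_low"], out["fst_high_dist"], out["fst_low_dist"]
        )
        out["pbs_high"], out["pbs_low"], out["pbs_dist"] = pbs_h, pbs_l, pbs_d
        out["z"] = zscore(pbs_h)
    else:
        out["z"] = zscore(out["fst_high_low"].to_numpy())

    out[f"pi_{hi}"] = pi_window(genome, counts, hi, grid)
    out[f"pi_{lo}"] = pi_window(genome, counts, lo, grid)
    ref = lo if trio.fst_only else di
    if not trio.fst_only:
        out[f"pi_{di}"] = pi_window(genome, counts, di, grid)
    out["tajimas_d_high"] = tajimas_d_window(genome, counts, hi, grid)
    out["delta_pi"] = delta_pi(out[f"pi_{hi}"], out[f"pi_{ref}"])
    out["dxy"] = dxy_window(genome, counts, hi, ref, grid)
    return out
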