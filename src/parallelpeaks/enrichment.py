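"""Corroborating selection signatures inside shared HDRs.

For each SHDR we record the extrema of the sweep-sensitive statistics over
its member windows — minimum highland Tajima's D, minimum delta-pi, and
maximum Dxy — and compare them against null extrema distributions obtained
by randomly placing interval sets of the same number and sizes across the
genome. A statistic flags an SHDR when its observed extremum falls in the
selection-consistent tail of the null: sweeps depress Tajima's D and
delta-pi (observed minimum below the null-min 10th percentile) and elevate
Dxy (observed maximum above the null-max 90th percentile). The alternative
tail pairing (minima judged against the upper tail and vice versa) is
available behind a switch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import Genome, IntervalSet, merge_intervals, overlaps_any, place_random_intervals

__all__ = ["shdr_extrema", "permuted_extrema_null", "classify_outliers"]

STATS = ("tajimas_d", "delta_pi", "dxy")
# which extremum is recorded per statistic, and which null tail flags it
EXTREMUM = {"tajimas_d": "min", "delta_pi": "min", "dxy": "max"}


def _window_assignment(genome: Genome, track: pd.DataFrame, intervals_s, intervals_e):
    """Index of the (merged, sorted) interval containing each window
    centre, or -1."""
    lin_c = genome.linearise(track["chrom"].to_numpy(),
                             track["centre"].to_numpy(dtype=np.int64))
    idx = np.searchsorted(intervals_s, lin_c, side="right") - 1
    inside = (idx >= 0) & (lin_c < intervals_e[np.clip(idx, 0, None)])
    return np.where(inside, idx, -1)


def shdr_extrema(genome: Genome, shdrs: IntervalSet, track: pd.DataFrame,
                 columns: dict[str, str] | None = None) -> pd.DataFrame:
    """Observed per-SHDR extrema over member windows.

    ``columns`` maps statistic name -> track column (defaults:
    tajimas_d -> 'tajimas_d_high', delta_pi -> 'delta_pi', dxy -> 'dxy').
    SHDRs containing no non-null window for a statistic get NaN and are
    flagged ``eligible=False``.
    """
    columns = columns or {"tajimas_d": "tajimas_d_high",
                          "delta_pi": "delta_pi", "dxy": "dxy"}
    merged = shdrs.merged()
    assign = _window_assignment(genome, track, merged.lin_start, merged.lin_end)
    rows = []
    for i in range(len(merged)):
        in_i = assign == i
        row = {"shdr": i}
        eligible = False
        for stat, col in columns.items():
            v = track.loc[in_i, col].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if v.size:
                eligible = True
                row[stat] = v.min() if EXTREMUM[stat] == "min" else v.max()
            else:
                row[stat] = np.nan
        row["eligible"] = eligible
        rows.append(row)
    out = pd.DataFrame(rows)
    chrom, start = genome.delinearise(merged.lin_start)
    _, end = genome.delinearise(merged.lin_end)
    out.insert(1, "chrom", chrom)
    out.insert(2, "start", start)
    out.insert(3, "end", end)
    return out


def permuted_extrema_null(
    genome: Genome,
    track: pd.DataFrame,
    sizes: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    columns: dict[str, str] | None = None,
    stratify_by_size: bool = False,
) -> dict[str, np.ndarray]:
    """Null extrema from randomly placed interval sets.

    Per permutation, intervals of the observed sizes are placed uniformly
    (merged after placement) and each placed interval contributes one
    extremum per statistic. Extrema are pooled across intervals by default;
    ``stratify_by_size`` instead returns, per statistic, a dict keyed by
    the original interval size.
    """
    columns = columns or {"tajimas_d": "tajimas_d_high",
                          "delta_pi": "delta_pi", "dxy": "dxy"}
    sizes = np.asarray(sizes, dtype=np.int64)
    rng = np.random.default_rng(seed)
    lin_c = genome.linearise(track["chrom"].to_numpy(),
                             track["centre"].to_numpy(dtype=np.int64))
    order = np.argsort(lin_c, kind="stable")
    lin_sorted = lin_c[order]
    vals = {s: track[c].to_numpy(dtype=float)[order] for s, c in columns.items()}
    pooled: dict[str, list] = {s: [] for s in columns}
    strat: dict[str, dict[int, list]] = {s: {} for s in columns}
    for _ in range(n_perm):
        s_, e_ = place_random_intervals(genome, sizes, rng)
        i = np.searchsorted(lin_sorted, s_, side="left")
        j = np.searchsorted(lin_sorted, e_, side="left")
        for k in range(sizes.size):
            if j[k] <= i[k]:
                continue
            for stat in columns:
                v = vals[stat][i[k]:j[k]]
                v = v[np.isfinite(v)]
                if not v.size:
                    continue
                x = v.min() if EXTREMUM[stat] == "min" else v.max()
                pooled[stat].append(x)
                if stratify_by_size:
                    strat[stat].setdefault(int(sizes[k]), []).append(x)
    if stratify_by_size:
        return {s: {k: np.array(v) for k, v in strat[s].items()} for s in columns}
    return {s: np.array(v) for s, v in pooled.items()}


def classify_outliers(observed: pd.DataFrame, nulls: dict[str, np.ndarray],
                      percentile: float = 10.0,
                      sweep_tails: bool = True) -> pd.DataFrame:
    """Flag SHDRs whose extrema fall in the selection-consistent null tail.

    Default (``sweep_tails=True``): Tajima's D and delta-pi minima below
    the null 10th percentile; Dxy maxima above the null 90th percentile.
    ``sweep_tails=False`` applies the opposite tail to each statistic.
    ``n_outlier_stats`` counts flags among the three statistics;
    ``n_outlier_stats_total`` adds 1 for the defining zPBS/zFst outlier.
    """
    out = observed.copy()
    for stat in STATS:
        null = np.asarray(nulls.get(stat, []), dtype=float)
        null = null[np.isfinite(null)]
        col = f"{stat}_outlier"
        if null.size == 0:
            out[col] = False
            out[f"{stat}_threshold"] = np.nan
            continue
        lower_tail = (EXTREMUM[stat] == "min") == sweep_tails
        if lower_tail:
            thr = np.percentile(null, percentile)
            out[col] = out[stat] < thr
        else:
            thr = np.percentile(null, 100.0 - percentile)
            out[col] = out[stat] > thr
        out[f"{stat}_threshold"] = thr
        out.loc[~np.isfinite(out[stat]), col] = False
    flags = [f"{s}_outlier" for s in STATS]
    out["n_outlier_stats"] = out[flags].sum(axis=1).astype(int)
    out["n_outlier_stats_total"] = out["n_outlier_stats"] + 1
    return out
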