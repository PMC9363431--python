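"""Genome coordinate bookkeeping and interval arithmetic.

All intervals are 0-based half-open. Internally, multi-chromosome interval
sets are mapped onto a single linearised coordinate axis (chromosomes laid
end to end with a 1 bp spacer so that book-ended intervals on different
chromosomes never merge). Every public result is reported back in
per-chromosome coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Genome", "merge_intervals", "overlaps_any", "IntervalSet"]


@dataclass(frozen=True)
class Genome:
    """Ordered chromosome names and lengths, with linearisation helpers."""

    chrom_lengths: dict[str, int]
    _offsets: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        off, cum = {}, 0
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            off[name] = cum
            cum += int(length) + 1  # 1 bp spacer: no cross-chromosome merging
        object.__setattr__(self, "_offsets", off)

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def offset(self, chrom: str) -> int:
        return self._offsets[chrom]

    def linearise(self, chrom, pos) -> np.ndarray:
        """Map (chrom, pos) pairs to linear coordinates."""
        chrom = np.asarray(chrom)
        pos = np.asarray(pos, dtype=np.int64)
        out = np.empty(pos.shape, dtype=np.int64)
        for name, off in self._offsets.items():
            mask = chrom == name
            out[mask] = pos[mask] + off
        return out

    def delinearise(self, lin) -> tuple[np.ndarray, np.ndarray]:
        """Inverse of :meth:`linearise`."""
        lin = np.asarray(lin, dtype=np.int64)
        chrom = np.empty(lin.shape, dtype=object)
        pos = np.empty(lin.shape, dtype=np.int64)
        for name, off in self._offsets.items():
            hi = off + self.chrom_lengths[name]
            mask = (lin >= off) & (lin <= hi)
            chrom[mask] = name
            pos[mask] = lin[mask] - off
        return chrom, pos


def merge_intervals(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping or book-ended half-open intervals on one axis.

    Book-ended intervals (end == next start) merge, matching the half-open
    convention used throughout. Idempotent.
    """
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts.copy(), ends.copy()
    if np.any(ends <= starts):
        raise ValueError("empty or inverted interval")
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    run_end = np.maximum.accumulate(e)
    # a new merged run starts where the current start exceeds the running end
    new_run = np.ones(s.size, dtype=bool)
    new_run[1:] = s[1:] > run_end[:-1]
    idx = np.flatnonzero(new_run)
    out_s = s[idx]
    out_e = np.append(run_end[idx[1:] - 1], run_end[-1])
    return out_s, out_e


def overlaps_any(qs, qe, starts, ends) -> np.ndarray:
    """For each query [qs, qe), does it overlap any interval in the
    merged, sorted reference set (starts, ends)? Vectorised over queries."""
    qs = np.atleast_1d(np.asarray(qs, dtype=np.int64))
    qe = np.atleast_1d(np.asarray(qe, dtype=np.int64))
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return np.zeros(qs.shape, dtype=bool)
    # reference interval starting at or before the query start
    j = np.searchsorted(starts, qs, side="right") - 1
    hit_left = (j >= 0) & (ends[np.clip(j, 0, None)] > qs)
    # next reference interval beginning inside the query
    k = j + 1
    hit_right = (k < starts.size) & (starts[np.clip(k, None, starts.size - 1)] < qe)
    return hit_left | hit_right


class IntervalSet:
    """A set of genomic intervals held in linearised coordinates.

    Construction merges nothing; call :meth:`merged` for the merged set.
    """

    def __init__(self, genome: Genome, chrom, start, end, meta: pd.DataFrame | None = None):
        self.genome = genome
        chrom = np.asarray(chrom, dtype=object)
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        if not (start.shape == end.shape == chrom.shape):
            raise ValueError("chrom/start/end shape mismatch")
        if np.any(end <= start):
            raise ValueError("empty or inverted interval")
        for c in set(chrom.tolist()):
            if c not in genome.chrom_lengths:
                raise KeyError(f"unknown chromosome {c!r}")
        self.lin_start = genome.linearise(chrom, start)
        self.lin_end = genome.linearise(chrom, end)
        order = np.argsort(self.lin_start, kind="stable")
        self.lin_start = self.lin_start[order]
        self.lin_end = self.lin_end[order]
        self.meta = meta.iloc[order].reset_index(drop=True) if meta is not None else None

    @classmethod
    def from_linear(cls, genome: Genome, lin_start, lin_end, meta=None) -> "IntervalSet":
        chrom, start = genome.delinearise(lin_start)
        _, end = genome.delinearise(lin_end)
        return cls(genome, chrom, start, end, meta)

    def __len__(self) -> int:
        return self.lin_start.size

    def merged(self) -> "IntervalSet":
        s, e = merge_intervals(self.lin_start, self.lin_end)
        return IntervalSet.from_linear(self.genome, s, e)

    def overlaps(self, other: "IntervalSet") -> np.ndarray:
        ref = other.merged()
        return overlaps_any(self.lin_start, self.lin_end, ref.lin_start, ref.lin_end)

    def total_bases(self) -> int:
        m = self.merged()
        return int(np.sum(m.lin_end - m.lin_start))

    def genome_fraction(self) -> float:
        return self.total_bases() / self.genome.total_length

    def to_frame(self) -> pd.DataFrame:
        chrom, start = self.genome.delinearise(self.lin_start)
        _, end = self.genome.delinearise(self.lin_end)
        df = pd.DataFrame({"chrom": chrom, "start": start, "end": end})
        if self.meta is not None:
            df = pd.concat([df, self.meta.reset_index(drop=True)], axis=1)
        return df

    def sizes(self) -> np.ndarray:
        return self.lin_end - self.lin_start


def place_random_intervals(
    genome: Genome, sizes: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Place intervals of the given sizes uniformly at random on the genome.

    The chromosome is chosen with probability proportional to its length
    among chromosomes the interval fits on; the start is uniform over the
    valid start positions. Returns linearised (start, end) arrays; placed
    intervals may overlap each other.
    """
    sizes = np.asarray(sizes, dtype=np.int64)
    names = list(genome.chrom_lengths)
    lengths = np.array([genome.chrom_lengths[c] for c in names], dtype=np.int64)
    offsets = np.array([genome.offset(c) for c in names], dtype=np.int64)
    out_s = np.empty(sizes.size, dtype=np.int64)
    for i, size in enumerate(sizes):
        fits = lengths >= size
        if not np.any(fits):
            raise ValueError(f"interval of size {size} exceeds every chromosome")
        p = np.where(fits, lengths, 0).astype(float)
        c = rng.choice(len(names), p=p / p.sum())
        start = rng.integers(0, lengths[c] - size + 1)
        out_s[i] = offsets[c] + start
    return out_s, out_s + sizes
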