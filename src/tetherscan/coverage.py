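"""Fragment-overlap coverage tracks, cluster/summit calling, consensus peaks.

The ChIP signal model here is fragment-centric: each sequenced read pair is
converted back to the sheared chromatin fragment it came from, and the track
value at a position is the number of fragments overlapping that position.
Enriched regions are maximal runs where at least ``min_cluster_fragments``
fragments stack up (default 5) and the mean signal clears a fold threshold
over the input control (default 2-fold).  Peaks called independently by
several callers are combined by requiring a mutual overlap chain that
touches every caller's set; combined boundaries are the outermost
boundaries of the contributing member peaks and the summit is the center of
the deepest fragment-overlap run.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io import GenomicInterval, PairedRecord


class NoCoverageError(ValueError):
    """Raised when a summit is requested in a region with zero coverage."""


@dataclasses.dataclass(frozen=True)
class FragmentInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty fragment [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class FragmentCoverageTrack:
    """Sparse per-position fragment-overlap counts on one chromosome.

    Stored as sorted, non-overlapping runs (start, end, count) with count>0.
    """

    chrom: str
    starts: np.ndarray  # int64
    ends: np.ndarray
    counts: np.ndarray

    @classmethod
    def empty(cls, chrom: str) -> "FragmentCoverageTrack":
        z = np.empty(0, dtype=np.int64)
        return cls(chrom, z.copy(), z.copy(), z.copy())

    @property
    def runs(self) -> list[tuple[int, int, int]]:
        return list(zip(self.starts.tolist(), self.ends.tolist(), self.counts.tolist()))

    @property
    def total_bp_count(self) -> int:
        """Sum of per-position counts (= sum of fragment lengths)."""
        return int(np.sum((self.ends - self.starts) * self.counts))

    @property
    def max_count(self) -> int:
        return int(self.counts.max()) if self.counts.size else 0

    def to_array(self, start: int, end: int) -> np.ndarray:
        """Dense count vector over [start, end); positions outside any run
        (or outside the track) are zero."""
        out = np.zeros(end - start, dtype=np.int64)
        if self.starts.size == 0 or end <= start:
            return out
        lo = np.searchsorted(self.ends, start, side="right")
        hi = np.searchsorted(self.starts, end, side="left")
        for s, e, c in zip(self.starts[lo:hi], self.ends[lo:hi], self.counts[lo:hi]):
            out[max(s, start) - start : max(min(e, end) - start, 0)] = c
        return out

    def count_at(self, pos: int) -> int:
        i = np.searchsorted(self.starts, pos, side="right") - 1
        if i >= 0 and self.ends[i] > pos:
            return int(self.counts[i])
        return 0

    def mean_over(self, start: int, end: int) -> float:
        if end <= start:
            raise ValueError("empty region")
        return float(self.to_array(start, end).mean())


@dataclasses.dataclass(frozen=True)
class CoverageConfig:
    min_cluster_fragments: int = 5
    min_fold_vs_input: float = 2.0
    min_cluster_span: int = 1
    input_pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.min_cluster_fragments < 1:
            raise ValueError("min_cluster_fragments must be >= 1")
        if self.min_fold_vs_input < 1:
            raise ValueError("min_fold_vs_input must be >= 1")


@dataclasses.dataclass
class Peak:
    id: str
    chrom: str
    start: int
    end: int
    summit: int
    source_callers: frozenset[str] = frozenset()
    categories: set[str] = dataclasses.field(default_factory=set)

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside peak [{self.start}, {self.end})"
            )

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, name=self.id)


def pairs_to_fragments(
    pairs: Iterable[PairedRecord],
) -> tuple[list[FragmentInterval], int]:
    """Reconstruct sheared-chromatin fragments from proper read pairs.

    The fragment spans from the leftmost mate start to the rightmost mate
    end.  Pairs with mates on different chromosomes or the same strand are
    rejected (improper) and counted, not fatal.  Returns (sorted fragments,
    rejected-pair tally).
    """
    fragments: list[FragmentInterval] = []
    rejects = 0
    for p in pairs:
        if p.chrom1 != p.chrom2 or p.strand1 == p.strand2:
            rejects += 1
            continue
        fragments.append(
            FragmentInterval(p.chrom1, min(p.start1, p.start2), max(p.end1, p.end2))
        )
    fragments.sort(key=lambda f: (f.chrom, f.start, f.end))
    return fragments, rejects


def overlap_track(
    fragments: Sequence[FragmentInterval], chrom: str
) -> FragmentCoverageTrack:
    """Exact per-position fragment-overlap counts for one chromosome."""
    starts = np.array(
        [f.start for f in fragments if f.chrom == chrom], dtype=np.int64
    )
    ends = np.array([f.end for f in fragments if f.chrom == chrom], dtype=np.int64)
    if starts.size == 0:
        return FragmentCoverageTrack.empty(chrom)
    # classic sweep: +1 at fragment starts, -1 at ends, prefix-sum over
    # the distinct breakpoints
    bounds = np.concatenate([starts, ends])
    deltas = np.concatenate(
        [np.ones_like(starts), -np.ones_like(ends)]
    )
    order = np.argsort(bounds, kind="stable")
    bounds, deltas = bounds[order], deltas[order]
    uniq, first = np.unique(bounds, return_index=True)
    per_bound = np.add.reduceat(deltas, first)
    depth = np.cumsum(per_bound)
    run_starts, run_ends, run_counts = [], [], []
    for i in range(len(uniq) - 1):
        if depth[i] > 0:
            # keep runs canonical: maximal spans of constant count
            if (
                run_counts
                and run_counts[-1] == depth[i]
                and run_ends[-1] == uniq[i]
            ):
                run_ends[-1] = uniq[i + 1]
            else:
                run_starts.append(uniq[i])
                run_ends.append(uniq[i + 1])
                run_counts.append(depth[i])
    return FragmentCoverageTrack(
        chrom,
        np.array(run_starts, dtype=np.int64),
        np.array(run_ends, dtype=np.int64),
        np.array(run_counts, dtype=np.int64),
    )


def find_summit(track: FragmentCoverageTrack, start: int, end: int) -> int:
    """Center of the deepest fragment-overlap run within [start, end).

    Among several runs at the maximal count, the leftmost is used; its
    center is the floor midpoint of the run's positions.  Zero coverage in
    the region is an error.
    """
    arr = track.to_array(start, end)
    if arr.size == 0 or arr.max() == 0:
        raise NoCoverageError(
            f"no coverage in region {track.chrom}:[{start}, {end})"
        )
    peak = arr.max()
    at_max = np.flatnonzero(arr == peak)
    run_start = int(at_max[0])
    run_end = run_start
    while run_end + 1 < arr.size and arr[run_end + 1] == peak:
        run_end += 1
    return start + (run_start + run_end) // 2


def call_clusters(
    track: FragmentCoverageTrack,
    input_track: FragmentCoverageTrack | None,
    config: CoverageConfig = CoverageConfig(),
) -> list[Peak]:
    """Maximal runs of >= min_cluster_fragments overlapping fragments,
    fold-filtered against the input control.

    The input mean over a candidate run is floored at ``input_pseudocount``
    so that zero-coverage input never divides by zero (and sparse input is
    not over-penalised).
    """
    peaks: list[Peak] = []
    thr = config.min_cluster_fragments
    qual = track.counts >= thr
    if not qual.any():
        return peaks
    # merge adjacent/contiguous qualifying runs into maximal regions
    regions: list[tuple[int, int]] = []
    cur: tuple[int, int] | None = None
    for s, e, q in zip(track.starts, track.ends, qual):
        if not q:
            continue
        if cur is not None and s == cur[1]:
            cur = (cur[0], int(e))
        else:
            if cur is not None:
                regions.append(cur)
            cur = (int(s), int(e))
    if cur is not None:
        regions.append(cur)
    idx = 0
    for s, e in regions:
        if e - s < config.min_cluster_span:
            continue
        mean_signal = track.mean_over(s, e)
        mean_input = (
            input_track.mean_over(s, e) if input_track is not None else 0.0
        )
        mean_input = max(mean_input, config.input_pseudocount)
        if mean_signal < config.min_fold_vs_input * mean_input:
            continue
        summit = find_summit(track, s, e)
        peaks.append(
            Peak(f"{track.chrom}_cluster_{idx}", track.chrom, s, e, summit)
        )
        idx += 1
    return peaks


def consensus_intersect(
    peak_sets: dict[str, Sequence[GenomicInterval]],
    tracks: dict[str, FragmentCoverageTrack] | None = None,
) -> list[Peak]:
    """Combined peaks: regions supported by every input peak set.

    A combined peak is emitted for each maximal chain of mutually
    overlapping intervals (transitive, >=1 bp) that touches all input sets;
    its boundaries are the outermost boundaries of the contributing
    intervals and its summit comes from the deepest fragment-overlap run
    (falling back to the region midpoint when no track coverage exists).
    """
    if len(peak_sets) < 2:
        raise ValueError("consensus requires at least 2 peak sets")
    names = list(peak_sets)
    tagged: list[tuple[str, int, int, int]] = []
    for si, name in enumerate(names):
        for iv in peak_sets[name]:
            tagged.append((iv.chrom, iv.start, iv.end, si))
    tagged.sort()
    combined: list[Peak] = []
    i, idx = 0, 0
    while i < len(tagged):
        chrom, start, end, si = tagged[i]
        members = {si}
        max_end = end
        j = i + 1
        while j < len(tagged) and tagged[j][0] == chrom and tagged[j][1] < max_end:
            members.add(tagged[j][3])
            max_end = max(max_end, tagged[j][2])
            j += 1
        if members == set(range(len(names))):
            track = (tracks or {}).get(chrom)
            try:
                summit = (
                    find_summit(track, start, max_end)
                    if track is not None
                    else (start + max_end - 1) // 2
                )
            except NoCoverageError:
                summit = (start + max_end - 1) // 2
            combined.append(
                Peak(
                    f"combined_{idx}", chrom, start, max_end, summit,
                    source_callers=frozenset(names),
                )
            )
            idx += 1
        i = j
    return combined


def write_track(track: FragmentCoverageTrack, path: str | Path) -> None:
    """Write the track as fixedStep wiggle (1-based, per the wiggle spec)."""
    with open(path, "w") as fh:
        fh.write("track type=wiggle_0\n")
        for s, e, c in track.runs:
            fh.write(f"fixedStep chrom={track.chrom} start={s + 1} step=1 span=1\n")
            for _ in range(e - s):
                fh.write(f"{c}\n")


def read_track(path: str | Path) -> FragmentCoverageTrack:
    """Read a fixedStep wiggle written by :func:`write_track` (lossless
    round trip; adjacent equal-count positions re-coalesce into runs)."""
    chrom: str | None = None
    positions: list[int] = []
    values: list[int] = []
    pos = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("fixedStep"):
                kv = dict(part.split("=") for part in line.split()[1:])
                chrom = kv["chrom"]
                pos = int(kv["start"]) - 1
                continue
            positions.append(pos)
            values.append(int(float(line)))
            pos += 1
    if chrom is None:
        raise ValueError("no fixedStep declaration found")
    if not positions:
        return FragmentCoverageTrack.empty(chrom)
    starts, ends, counts = [], [], []
    run_start, run_val = positions[0], values[0]
    prev = positions[0]
    for p, v in zip(positions[1:], values[1:]):
        if p == prev + 1 and v == run_val:
            prev = p
            continue
        starts.append(run_start)
        ends.append(prev + 1)
        counts.append(run_val)
        run_start, run_val, prev = p, v, p
    starts.append(run_start)
    ends.append(prev + 1)
    counts.append(run_val)
    return FragmentCoverageTrack(
        chrom,
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        np.array(counts, dtype=np.int64),
    )
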