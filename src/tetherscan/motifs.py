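"""IUPAC consensus motif scanning, summit-window assignment, motif profiles.

Three consensus patterns drive the peak categorisation: the AP-1 binding
TRE element TGANTCA, the TEAD1 site [AT]GGAAT[GT] (WGGAATK), and the CTCF
site CCA[CG][CT]AG[AG][GT]GGC (CCASYAGRKGGC).  Matching is exact IUPAC
consensus matching on both strands — no position-weight scoring — because
the categories are defined by consensus strings, not matrices.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np

from .coverage import FragmentCoverageTrack, Peak
from .elements import RepeatElement
from .io import GenomicInterval
from .sequence import IUPAC, iupac_match, revcomp, validate_iupac

BUILTIN_PATTERNS = {
    "TRE": "TGANTCA",
    "TEAD1": "WGGAATK",
    "CTCF": "CCASYAGRKGGC",
}


@dataclasses.dataclass(frozen=True)
class MotifPattern:
    name: str
    iupac_string: str

    def __post_init__(self) -> None:
        validate_iupac(self.iupac_string)
        if len(self.iupac_string) < 4:
            raise ValueError("pattern length must be >= 4")

    @classmethod
    def builtin(cls, name: str) -> "MotifPattern":
        return cls(name, BUILTIN_PATTERNS[name])


@dataclasses.dataclass(frozen=True)
class MotifOccurrence:
    chrom: str
    start: int
    end: int
    strand: str
    pattern: str
    peak_id: str | None = None

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def _matches_at(seq: str, pattern: str, i: int) -> bool:
    return all(iupac_match(seq[i + j], pattern[j]) for j in range(len(pattern)))


def scan_iupac(
    seq: str,
    pattern: MotifPattern | str,
    chrom: str = "chr1",
    offset: int = 0,
    both_strands: bool = True,
) -> list[MotifOccurrence]:
    """All exact IUPAC matches of the pattern in ``seq``.

    Minus-strand matches (the reverse complement of the pattern on the
    forward sequence) are reported in plus-strand coordinates with strand
    '-'.  A palindromic pattern that matches both strands at one position is
    reported once per strand.  ``offset`` shifts reported coordinates so a
    subsequence can be scanned in chromosome coordinates.
    """
    if isinstance(pattern, str):
        pattern = MotifPattern("pattern", pattern)
    seq = seq.upper()
    pat = pattern.iupac_string.upper()
    rc_pat = revcomp(pat)
    L = len(pat)
    hits: list[MotifOccurrence] = []
    for i in range(len(seq) - L + 1):
        if _matches_at(seq, pat, i):
            hits.append(
                MotifOccurrence(chrom, offset + i, offset + i + L, "+", pattern.name)
            )
        if both_strands and _matches_at(seq, rc_pat, i):
            hits.append(
                MotifOccurrence(chrom, offset + i, offset + i + L, "-", pattern.name)
            )
    return hits


def summit_windows(
    peaks: Sequence[Peak],
    flank: int = 50,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[tuple[GenomicInterval, bool]]:
    """The ``2*flank``-bp window around each peak summit.

    Window = [summit - flank, summit + flank), clipped at chromosome ends;
    each entry is (window, clipped_flag).  ``flank=0`` degenerates to the
    1-bp window at the summit.
    """
    out: list[tuple[GenomicInterval, bool]] = []
    for p in peaks:
        lo = p.summit - flank
        hi = p.summit + flank
        if hi <= lo:
            lo, hi = p.summit, p.summit + 1
        clipped = False
        if lo < 0:
            lo, clipped = 0, True
        if chrom_lengths is not None and p.chrom in chrom_lengths:
            L = chrom_lengths[p.chrom]
            if hi > L:
                hi, clipped = L, True
        out.append((GenomicInterval(p.chrom, lo, hi, name=p.id), clipped))
    return out


def categorize_peaks(
    peaks: Sequence[Peak],
    elements: Sequence[RepeatElement],
    occurrences: Sequence[MotifOccurrence],
    flank: int = 50,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[Peak]:
    """Assign each peak to element/motif categories.

    A peak overlapping a repeat element (>=1 bp) is labelled with that
    element's kind (MER85/PGBD3) and nothing else — element identity takes
    precedence, mirroring the removal of element peaks before motif
    discovery.  Otherwise the peak gets one label per pattern with at least
    one occurrence fully contained in its summit window (multi-label, e.g.
    TRE+TEAD1 peaks count in both sets), or 'none'.  Motif occurrences in
    windows are annotated with the peak id regardless of precedence, for
    audit.
    """
    windows = {p.id: w for p, (w, _) in zip(peaks, summit_windows(peaks, flank, chrom_lengths))}
    by_chrom_elem: dict[str, list[RepeatElement]] = {}
    for el in elements:
        by_chrom_elem.setdefault(el.chrom, []).append(el)
    occ_by_chrom: dict[str, list[MotifOccurrence]] = {}
    for occ in occurrences:
        occ_by_chrom.setdefault(occ.chrom, []).append(occ)
    for p in peaks:
        p.categories = set()
        for el in by_chrom_elem.get(p.chrom, ()):
            if el.start < p.end and p.start < el.end:
                p.categories.add(el.kind)
        if p.categories:
            continue
        w = windows[p.id]
        for occ in occ_by_chrom.get(p.chrom, ()):
            if occ.start >= w.start and occ.end <= w.end:
                p.categories.add(occ.pattern)
        if not p.categories:
            p.categories.add("none")
    return list(peaks)


def assign_occurrences_to_windows(
    occurrences: Sequence[MotifOccurrence],
    peaks: Sequence[Peak],
    flank: int = 50,
) -> list[MotifOccurrence]:
    """Tag each occurrence with the id of a peak whose summit window fully
    contains it (first peak in coordinate order wins)."""
    tagged: list[MotifOccurrence] = []
    wins = summit_windows(peaks, flank)
    for occ in occurrences:
        peak_id = None
        for w, _ in wins:
            if w.chrom == occ.chrom and occ.start >= w.start and occ.end <= w.end:
                peak_id = w.name
                break
        tagged.append(dataclasses.replace(occ, peak_id=peak_id))
    return tagged


def motif_profile(
    tracks: Mapping[str, FragmentCoverageTrack],
    occurrences: Sequence[MotifOccurrence],
    window: tuple[int, int] = (-200, 200),
) -> np.ndarray:
    """Average fragment-overlap vector centered on motif midpoints.

    Windows are extracted strand-oriented (minus-strand windows mirrored)
    and zero-padded at chromosome edges; the result is the mean across
    occurrences.  Empty occurrence lists are an error.
    """
    occurrences = list(occurrences)
    if not occurrences:
        raise ValueError("no motif occurrences to profile")
    lo, hi = window
    width = hi - lo
    total = np.zeros(width, dtype=float)
    for occ in occurrences:
        track = tracks.get(occ.chrom)
        mid = occ.midpoint
        if occ.strand == "+":
            gstart, gend = mid + lo, mid + hi
        else:
            gstart, gend = mid - hi + 1, mid - lo + 1
        arr = np.zeros(width, dtype=float)
        if track is not None:
            s = max(gstart, 0)
            arr[s - gstart : gend - gstart] = track.to_array(s, gend)
        if occ.strand == "-":
            arr = arr[::-1]
        total += arr
    return total / len(occurrences)
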