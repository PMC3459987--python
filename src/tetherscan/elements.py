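"""Annotation of piggyBac-derived repeat elements.

The nonautonomous MER85 family modelled here is a 140-bp internal deletion
derivative of a 2.5-kb piggyBac-family transposon.  An intact element, read
in the orientation of the parental transposase ORF, is laid out as

    TSD(4: TTAA) + 5'TIR(13) + spacer(3) + palindrome(16) + internal(91) + 3'TIR(13)

where the imperfect 16-bp palindrome (consensus GTTCCATTATTGGAAC, whose
distance to its own reverse complement is exactly 2) sits 3 bp internal to
the 5' TIR and is the essential binding determinant of the transposase
fusion protein.  This module locates those landmarks in candidate element
sequence, classifies completeness (intact / incomplete ends / expanded /
deleted / no TIRs), flags elements overlapped by ChIP peaks as bound, and
builds orientation-corrected cumulative binding profiles anchored at the
5' TSD.

The 13-bp TIR consensus used by the default model is the Trichoplusia ni
piggyBac TIR, a synthetic stand-in: the human family's TIR sequence is a
curated annotation, not something this package derives.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np

from .coverage import FragmentCoverageTrack, Peak
from .io import GenomicInterval
from .sequence import hamming, revcomp

PALINDROME_CONSENSUS = "GTTCCATTATTGGAAC"
TIR_CONSENSUS = "CCCTAGAAAGATA"  # synthetic stand-in, 13 bp
TSD_SEQ = "TTAA"


@dataclasses.dataclass(frozen=True)
class ElementModel:
    """Sequence landmarks of the modelled element family."""

    tsd_seq: str = TSD_SEQ
    tir_length: int = 13
    tir_consensus: str = TIR_CONSENSUS
    palindrome_consensus: str = PALINDROME_CONSENSUS
    spacer_5prime: int = 3
    mer85_length: int = 140
    expansion_slack: int = 20  # bp over reference length before "expanded"

    def __post_init__(self) -> None:
        if len(self.palindrome_consensus) != 16:
            raise ValueError("palindrome consensus must be 16 bp")
        if len(self.tir_consensus) != self.tir_length:
            raise ValueError("TIR consensus length must equal tir_length")
        if self.palindrome_consensus[:6] != revcomp(self.palindrome_consensus[-6:]):
            raise ValueError("palindrome arms must be mutual reverse complements")

    # fixed offsets of an intact element, in element orientation
    @property
    def tsd_offset(self) -> tuple[int, int]:
        return 0, len(self.tsd_seq)

    @property
    def tir5_offset(self) -> tuple[int, int]:
        s = len(self.tsd_seq)
        return s, s + self.tir_length

    @property
    def palindrome_offset(self) -> tuple[int, int]:
        s = len(self.tsd_seq) + self.tir_length + self.spacer_5prime
        return s, s + len(self.palindrome_consensus)

    @property
    def tir3_offset(self) -> tuple[int, int]:
        return self.mer85_length - self.tir_length, self.mer85_length


@dataclasses.dataclass(frozen=True)
class PalindromeHit:
    position: int
    arm_length: int
    loop_length: int
    arm_mismatches: int
    full_self_revcomp_mismatches: int

    @property
    def span(self) -> int:
        return 2 * self.arm_length + self.loop_length


@dataclasses.dataclass
class RepeatElement:
    """An oriented repeat element with landmark annotations.

    ``strand`` is the element's orientation = the parental transposase ORF
    orientation, which may differ from the strand of genomic placement.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    kind: str = "MER85"
    tir5: GenomicInterval | None = None
    tir3: GenomicInterval | None = None
    palindrome: GenomicInterval | None = None
    palindrome_mismatches: int | None = None
    palindrome_flags: dict | None = None
    completeness: str = "intact"
    bound: bool = False
    bound_peak_id: str | None = None

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end,
                               name=self.id, strand=self.strand)

    @property
    def anchor5(self) -> int:
        """Genomic position of the 5' TSD start in element orientation."""
        return self.start if self.strand == "+" else self.end - 1


def match_palindrome(
    seq: str,
    consensus: str = PALINDROME_CONSENSUS,
    max_mismatch: int = 0,
    both_strands: bool = True,
) -> list[tuple[int, int]]:
    """All offsets where the consensus matches within ``max_mismatch``.

    Both strands are scanned; a minus-strand hit is reported at its
    plus-strand coordinate, and at any offset the smaller of the two strand
    distances is reported.  Ambiguous bases count as mismatches.
    """
    if len(consensus) > len(seq):
        return []
    seq = seq.upper()
    consensus = consensus.upper()
    rc = revcomp(consensus)
    hits: list[tuple[int, int]] = []
    for i in range(len(seq) - len(consensus) + 1):
        window = seq[i : i + len(consensus)]
        mm = hamming(window, consensus)
        if both_strands:
            mm = min(mm, hamming(window, rc))
        if mm <= max_mismatch:
            hits.append((i, mm))
    return hits


def detect_palindrome_variant(pal: str, consensus: str = PALINDROME_CONSENSUS) -> dict:
    """Flag known variants of a 16-bp palindrome sequence.

    The main flag is the C>T substitution in the 3' arm that turns the
    consensus TGGAAC arm into TGGAAT (which, with its downstream base, reads
    as the TGGAATG variant motif).  Other deviations are listed as generic
    substitutions by position.  Non-ACGT input is an error.
    """
    pal = pal.upper()
    if len(pal) != 16:
        raise ValueError(f"palindrome must be 16 bp, got {len(pal)}")
    if any(b not in "ACGT" for b in pal):
        raise ValueError("palindrome contains ambiguous bases")
    arm3 = pal[10:16]
    c_to_t = arm3 == "TGGAAT"
    substitutions = [
        (i, consensus[i], pal[i]) for i in range(16) if pal[i] != consensus[i]
    ]
    return {
        "c_to_t_arm": c_to_t,
        "arm3": arm3,
        "substitutions": substitutions,
        "n_mismatches": len(substitutions),
        "perfect": not substitutions,
    }


def find_imperfect_palindromes(
    seq: str,
    arm_length: int,
    loop_range: tuple[int, int],
    max_arm_mismatch: int = 0,
) -> list[PalindromeHit]:
    """Scan for inverted-repeat structures: left arm ~ revcomp(right arm).

    ``loop_range`` is an inclusive (min, max) range of loop lengths.  For
    each hit the full-span distance of the hit sequence to its own reverse
    complement is also reported (0 = perfect palindrome).
    """
    if arm_length < 3:
        raise ValueError("arm_length must be >= 3")
    seq = seq.upper()
    lo, hi = loop_range
    hits: list[PalindromeHit] = []
    for loop in range(lo, hi + 1):
        span = 2 * arm_length + loop
        for p in range(len(seq) - span + 1):
            left = seq[p : p + arm_length]
            right = seq[p + arm_length + loop : p + span]
            mm = hamming(left, revcomp(right))
            if mm <= max_arm_mismatch:
                full = seq[p : p + span]
                hits.append(
                    PalindromeHit(
                        p, arm_length, loop, mm, hamming(full, revcomp(full))
                    )
                )
    hits.sort(key=lambda h: (h.position, h.loop_length))
    return hits


def _best_tir_offset(seq: str, consensus: str, window: range) -> tuple[int, int]:
    """(offset, mismatches) of the best consensus placement among offsets."""
    best = (-1, len(consensus) + 1)
    for off in window:
        if off < 0 or off + len(consensus) > len(seq):
            continue
        mm = hamming(seq[off : off + len(consensus)], consensus)
        if mm < best[1]:
            best = (off, mm)
    return best


def annotate_element(
    chrom_seq: str,
    start: int,
    end: int,
    chrom: str = "chr1",
    strand: str = "+",
    model: ElementModel = ElementModel(),
    element_id: str = "element",
    kind: str = "MER85",
    max_tir_mismatch: int = 2,
    max_palindrome_mismatch: int = 4,
) -> RepeatElement:
    """Locate TSD, TIRs and the internal palindrome of a candidate element.

    The candidate interval [start, end) on ``chrom_seq`` is read in element
    orientation (``strand``).  TIRs are located by matching the model TIR
    consensus (5' end) and its reverse complement (3' end) within a short
    edge window, each tolerating ``max_tir_mismatch`` mismatches;
    completeness is classified from which TIRs are present and how the
    element length compares with the family reference length.
    """
    length = end - start
    elem = chrom_seq[start:end].upper()
    if strand == "-":
        elem = revcomp(elem)

    def oriented_to_genomic(off: int, span: int) -> GenomicInterval:
        if strand == "+":
            return GenomicInterval(chrom, start + off, start + off + span)
        return GenomicInterval(chrom, end - off - span, end - off)

    element = RepeatElement(element_id, chrom, start, end, strand, kind=kind)
    tirlen = model.tir_length
    if length < 2 * tirlen:
        element.completeness = "no_tirs"
        return element

    tsd_present = elem.startswith(model.tsd_seq)
    edge = len(model.tsd_seq) + 4
    off5, mm5 = _best_tir_offset(elem, model.tir_consensus, range(0, edge + 1))
    tir5_ok = mm5 <= max_tir_mismatch
    rc_tir = revcomp(model.tir_consensus)
    off3_lo = max(0, length - tirlen - edge)
    off3, mm3 = _best_tir_offset(elem, rc_tir, range(off3_lo, length - tirlen + 1))
    tir3_ok = mm3 <= max_tir_mismatch

    if tir5_ok:
        element.tir5 = oriented_to_genomic(off5, tirlen)
    if tir3_ok:
        element.tir3 = oriented_to_genomic(off3, tirlen)

    ref = model.mer85_length
    if tir5_ok and tir3_ok:
        if length > ref + model.expansion_slack:
            element.completeness = "expanded"
        elif length < ref:
            element.completeness = "deleted"
        else:
            element.completeness = "intact"
    elif tir5_ok:
        element.completeness = "incomplete_3p"
    elif tir3_ok:
        element.completeness = "incomplete_5p"
    else:
        element.completeness = "no_tirs"

    # palindrome lives in the 5' region, 3 bp inside the 5' TIR when intact
    search_end = min(len(elem), 60)
    hits = match_palindrome(
        elem[:search_end], model.palindrome_consensus, max_palindrome_mismatch
    )
    if hits:
        pos, mm = min(hits, key=lambda h: (h[1], h[0]))
        element.palindrome = oriented_to_genomic(pos, 16)
        element.palindrome_mismatches = mm
        pal_seq = elem[pos : pos + 16]
        try:
            element.palindrome_flags = detect_palindrome_variant(
                pal_seq, model.palindrome_consensus
            )
        except ValueError:
            element.palindrome_flags = None
    if not tsd_present and element.completeness == "intact":
        # intact TIRs but no leading TTAA: keep the class, note via flags
        pass
    return element


def classify_bound(
    elements: Iterable[RepeatElement], peaks: Sequence[Peak]
) -> list[RepeatElement]:
    """Flag elements overlapped (>=1 bp) by any combined peak.

    ``bound_peak_id`` records the leftmost overlapping peak.  Returns the
    same element objects, mutated, for chaining.
    """
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for plist in by_chrom.values():
        plist.sort(key=lambda p: p.start)
    out = []
    for el in elements:
        el.bound = False
        el.bound_peak_id = None
        for p in by_chrom.get(el.chrom, ()):
            if p.start >= el.end:
                break
            if p.end > el.start:
                el.bound = True
                el.bound_peak_id = p.id
                break
        out.append(el)
    return out


@dataclasses.dataclass
class ElementProfile:
    """Cumulative and mean fragment-overlap profile over oriented elements,
    anchored at each element's 5' TSD."""

    offsets: np.ndarray
    cumulative: np.ndarray
    n_elements: int
    n_clipped: int

    @property
    def mean(self) -> np.ndarray:
        return self.cumulative / max(self.n_elements, 1)

    @property
    def argmax_offset(self) -> int:
        """Offset of the profile maximum, using the same deepest-run-center
        rule as summit calling: the floor midpoint of the leftmost run of
        positions attaining the maximal count."""
        arr = self.cumulative
        peak = arr.max()
        at_max = np.flatnonzero(arr == peak)
        run_start = int(at_max[0])
        run_end = run_start
        while run_end + 1 < arr.size and arr[run_end + 1] == peak:
            run_end += 1
        return int(self.offsets[(run_start + run_end) // 2])


def cumulative_element_profile(
    tracks: Mapping[str, FragmentCoverageTrack],
    elements: Sequence[RepeatElement],
    window: tuple[int, int] = (-100, 240),
    chrom_lengths: Mapping[str, int] | None = None,
) -> ElementProfile:
    """Sum fragment overlaps position-wise across elements, in element
    orientation relative to each 5' TSD.

    ``window`` is (min_offset, max_offset) half-open in oriented element
    coordinates; offset 0 is the first base of the 5' TSD.  Minus-strand
    windows are extracted mirrored so that profiles align.  Windows running
    past a chromosome end are zero-padded and counted in ``n_clipped``.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must be non-empty")
    width = hi - lo
    total = np.zeros(width, dtype=np.int64)
    n_clipped = 0
    n = 0
    for el in elements:
        track = tracks.get(el.chrom)
        anchor = el.anchor5
        if el.strand == "+":
            gstart, gend = anchor + lo, anchor + hi
        else:
            gstart, gend = anchor - hi + 1, anchor - lo + 1
        clipped = gstart < 0
        if chrom_lengths is not None and el.chrom in chrom_lengths:
            clipped = clipped or gend > chrom_lengths[el.chrom]
        if clipped:
            n_clipped += 1
        if track is not None:
            arr = np.zeros(width, dtype=np.int64)
            s = max(gstart, 0)
            arr[s - gstart : gend - gstart] = track.to_array(s, gend)
            if el.strand == "-":
                arr = arr[::-1]
        else:
            arr = np.zeros(width, dtype=np.int64)
        total += arr
        n += 1
    return ElementProfile(np.arange(lo, hi), total, n, n_clipped)


def emsa_normalize(
    seq_pair: tuple[float, float],
    scrambled_pair: tuple[float, float],
    consensus_pair: tuple[float, float],
) -> float:
    """Percent binding affinity from shifted-band intensities.

    Each pair is (intensity with protein, intensity without protein); the
    per-sequence signal is the with-minus-without difference, rescaled so
    the scrambled control reads 0% and the family consensus reads 100%.
    """
    d_seq = seq_pair[0] - seq_pair[1]
    d_scr = scrambled_pair[0] - scrambled_pair[1]
    d_con = consensus_pair[0] - consensus_pair[1]
    if d_con == d_scr:
        raise ValueError("degenerate controls: consensus and scrambled deltas equal")
    return 100.0 * (d_seq - d_scr) / (d_con - d_scr)
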