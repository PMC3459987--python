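"""Shared genomic-interval container and text-format readers/writers.

Every coordinate inside the package is 0-based, half-open.  Conversion to
1-based conventions happens only at format boundaries (wiggle, SAM).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class BedFormatError(ValueError):
    """Malformed BED/BEDPE record; message carries the 1-based line number."""


@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional BED6 metadata."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float = 0.0
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end - 1) // 2


@dataclasses.dataclass(frozen=True)
class PairedRecord:
    """One proper read pair: two mates on a shared chromosome.

    Mate intervals are the aligned read spans; strands must differ for a
    proper pair.
    """

    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    strand1: str = "+"
    strand2: str = "-"
    name: str = "."


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6.  Track/browser/comment headers are skipped; strand
    '.' is stored as None.  A malformed line raises with its line number."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(
                    f"line {lineno}: expected >=3 tab-separated fields"
                )
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(f"line {lineno}: {exc}") from exc
            name = fields[3] if len(fields) > 3 else None
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else None
            if strand == ".":
                strand = None
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name, score, strand)
                )
            except ValueError as exc:
                raise BedFormatError(f"line {lineno}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand is not None:
                fields += [
                    iv.name if iv.name is not None else ".",
                    format(iv.score, "g"),
                    iv.strand if iv.strand is not None else ".",
                ]
            fh.write("\t".join(fields) + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {name: uppercase sequence}."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_bedpe(path: str | Path) -> list[PairedRecord]:
    """Read BEDPE (chrom1 start1 end1 chrom2 start2 end2 [name score strand1 strand2])."""
    pairs: list[PairedRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise BedFormatError(
                    f"line {lineno}: BEDPE needs >=6 fields, got {len(f)}"
                )
            try:
                pairs.append(
                    PairedRecord(
                        f[0], int(f[1]), int(f[2]),
                        f[3], int(f[4]), int(f[5]),
                        strand1=f[8] if len(f) > 8 else "+",
                        strand2=f[9] if len(f) > 9 else "-",
                        name=f[6] if len(f) > 6 else ".",
                    )
                )
            except ValueError as exc:
                raise BedFormatError(f"line {lineno}: {exc}") from exc
    return pairs


def write_bedpe(pairs: Iterable[PairedRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(
                "\t".join(
                    [
                        p.chrom1, str(p.start1), str(p.end1),
                        p.chrom2, str(p.start2), str(p.end2),
                        p.name, "0", p.strand1, p.strand2,
                    ]
                )
                + "\n"
            )


def read_pairs(path: str | Path) -> list[PairedRecord]:
    """Read paired-end alignments from BEDPE or minimal text SAM.

    SAM is parsed with pysam; only proper pairs are returned, and a pair
    whose mates name different reference sequences (RNEXT mismatch) is an
    error, matching the proper-pair contract.
    """
    path = Path(path)
    if path.suffix.lower() == ".sam":
        return _read_sam_pairs(path)
    return read_bedpe(path)


def _read_sam_pairs(path: Path) -> list[PairedRecord]:
    import pysam

    by_name: dict[str, list] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or not aln.is_paired:
                continue
            by_name.setdefault(aln.query_name, []).append(
                (
                    aln.reference_name,
                    aln.reference_start,
                    aln.reference_end,
                    "-" if aln.is_reverse else "+",
                    aln.next_reference_name,
                )
            )
    pairs: list[PairedRecord] = []
    for name, mates in sorted(by_name.items()):
        if len(mates) != 2:
            continue
        (c1, s1, e1, st1, rn1), (c2, s2, e2, st2, rn2) = mates
        if rn1 != c2 or rn2 != c1:
            raise ValueError(
                f"pair {name}: RNEXT does not match the mate's reference"
            )
        pairs.append(PairedRecord(c1, s1, e1, c2, s2, e2, st1, st2, name))
    return pairs


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated table with a header row ('#' comments skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(df: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> None:
    """Write a TSV with an optional '#key=value' metadata header block."""
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"#{key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)
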