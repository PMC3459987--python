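"""Synthetic genomes with planted repeat elements, motifs, genes and reads.

This module generates the study conditions every downstream stage is
exercised on: a multi-chromosome toy genome of i.i.d. uniform ACGT
background carrying

* 140-bp MER85-like elements (TTAA TSD, 13-bp TIRs, the imperfect 16-bp
  palindrome 3 bp inside the 5' TIR), some flagged *bound* — fragment
  coverage is enriched over their 5' palindromic region;
* one 2.5-kb PGBD3-like parental transposon carrying three palindrome
  copies (near the 5' TIR, 59 bp upstream of the transposase ORF, and 75 bp
  downstream of the ORF stop / 114 bp upstream of the 3' TIR);
* concrete TRE / TEAD1 / CTCF motif instances, some bound;
* gene models (TSSs) whose expression responds to nearby bound TRE sites
  but not to nearby MER85s.

Paired-end ChIP fragments are simulated with centers Normal around each
bound site's anchor and lengths uniform in the size-selection window
(default 300-600 bp); the input control is uniform single-end background.
Everything is deterministic under the spec seed, and truth tables are
emitted alongside so recovery is checkable without re-deriving ground
truth.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .elements import ElementModel
from .io import GenomicInterval, PairedRecord
from .sequence import IUPAC, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# PGBD3-like parental element layout (element-oriented offsets, synthetic)
PGBD3_LENGTH = 2500
PGBD3_ORF = (500, 2282)
# palindrome copies: near the 5' TIR; ORF start - 59 - 16; ORF stop + 75
# (= 114 + 16 bp upstream of the 3' TIR which starts at 2487)
PGBD3_PALINDROME_OFFSETS = (20, 425, 2357)


@dataclasses.dataclass(frozen=True)
class PlantedElement:
    kind: str  # "MER85" or "PGBD3"
    chrom: str
    start: int
    strand: str = "+"
    palindrome_mismatches: int = 0
    tir5_intact: bool = True
    tir3_intact: bool = True
    bound: bool = False
    insertion_length: int = 0  # internal insertion (-> "expanded" when >20)
    deletion_5p: int = 0  # bp removed from the 5' end
    deletion_3p: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("MER85", "PGBD3"):
            raise ValueError(f"unknown element kind {self.kind!r}")


@dataclasses.dataclass(frozen=True)
class MotifSite:
    chrom: str
    pos: int
    pattern: str  # TRE / TEAD1 / CTCF
    strand: str = "+"
    bound: bool = False


@dataclasses.dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"


@dataclasses.dataclass(frozen=True)
class SyntheticGenomeSpec:
    chrom_lengths: dict[str, int]
    element_layouts: tuple[PlantedElement, ...] = ()
    motif_sites: tuple[MotifSite, ...] = ()
    gene_models: tuple[GeneModel, ...] = ()
    seed: int = 0


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    n_fragments_signal: int = 12_000
    n_fragments_background: int = 30_000
    n_input_reads: int = 30_000
    fragment_length_range: tuple[int, int] = (300, 600)
    read_length: int = 36
    binding_offset: int = 25  # bp from the 5' TSD; middle of the palindrome
    enrichment_sd: float = 60.0
    up_slr: float = 2.0
    down_slr: float = 2.0
    expression_sigma: float = 0.3
    regulatory_distance: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.fragment_length_range
        if lo < 2 * self.read_length:
            raise ValueError(
                "fragment length minimum must be >= 2 x read length"
            )
        if hi < lo:
            raise ValueError("invalid fragment length range")
        for v in (self.up_slr, self.down_slr, self.expression_sigma):
            if not np.isfinite(v):
                raise ValueError("expression effects must be finite")


# ---------------------------------------------------------------------------
# sequence construction

_MOTIF_INSTANCES = {"TRE": "TGACTCA", "TEAD1": "TGGAATG", "CTCF": "CCACCAGAGGGC"}


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _mutate(seq: str, n_mut: int, rng: np.random.Generator) -> str:
    """Substitute n_mut distinct positions with a different base."""
    if n_mut == 0:
        return seq
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def build_mer85(
    element: PlantedElement,
    model: ElementModel = ElementModel(),
    rng: np.random.Generator | None = None,
) -> str:
    """Element-oriented MER85 sequence for one planted element.

    Intact layout: TSD(4) + TIR(13) + spacer(3) + palindrome(16) +
    internal(91) + TIR(13) = 140 bp.  TIRs flagged non-intact are replaced
    by random sequence; 5'/3' deletions and internal insertions adjust the
    length for the incomplete/expanded completeness classes.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    tir5 = model.tir_consensus
    tir3 = revcomp(model.tir_consensus)
    if not element.tir5_intact:
        tir5 = _random_dna(model.tir_length, rng)
    if not element.tir3_intact:
        tir3 = _random_dna(model.tir_length, rng)
    palindrome = _mutate(
        model.palindrome_consensus, element.palindrome_mismatches, rng
    )
    internal = _random_dna(
        model.mer85_length
        - len(model.tsd_seq)
        - 2 * model.tir_length
        - model.spacer_5prime
        - 16
        + element.insertion_length,
        rng,
    )
    spacer = _random_dna(model.spacer_5prime, rng)
    seq = model.tsd_seq + tir5 + spacer + palindrome + internal + tir3
    if element.deletion_5p:
        seq = seq[element.deletion_5p :]
    if element.deletion_3p:
        seq = seq[: len(seq) - element.deletion_3p]
    return seq


def build_pgbd3(
    model: ElementModel = ElementModel(),
    rng: np.random.Generator | None = None,
) -> str:
    """Element-oriented 2.5-kb PGBD3-like sequence with three palindromes."""
    rng = rng if rng is not None else np.random.default_rng(0)
    seq = list(model.tsd_seq + _random_dna(PGBD3_LENGTH - len(model.tsd_seq), rng))
    tirlen = model.tir_length
    seq[4 : 4 + tirlen] = model.tir_consensus
    seq[PGBD3_LENGTH - tirlen :] = revcomp(model.tir_consensus)
    for off in PGBD3_PALINDROME_OFFSETS:
        seq[off : off + 16] = model.palindrome_consensus
    return "".join(seq)


def element_length(element: PlantedElement, model: ElementModel) -> int:
    if element.kind == "PGBD3":
        return PGBD3_LENGTH
    return (
        model.mer85_length
        + element.insertion_length
        - element.deletion_5p
        - element.deletion_3p
    )


def _concrete_motif(pattern: str, rng: np.random.Generator) -> str:
    """A concrete instance of a built-in IUPAC pattern (fixed canonical
    instance; the pattern name selects it)."""
    if pattern in _MOTIF_INSTANCES:
        return _MOTIF_INSTANCES[pattern]
    raise ValueError(f"unknown motif pattern {pattern!r}")


def generate_genome(
    spec: SyntheticGenomeSpec, model: ElementModel = ElementModel()
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate genome sequences plus element/motif/gene truth tables.

    Background bases are i.i.d. uniform ACGT from the spec seed; planted
    sequences are written at their declared positions on their declared
    strands (minus-strand plants are written as the reverse complement of
    the element-oriented sequence).  Overlapping planted elements or
    out-of-range coordinates are errors naming the offender.
    """
    rng = np.random.default_rng(spec.seed)
    genome_arr: dict[str, np.ndarray] = {}
    for chrom, length in spec.chrom_lengths.items():
        genome_arr[chrom] = _BASES[rng.integers(0, 4, size=length)].copy()

    # validate plant coordinates and pairwise element overlap
    placed: list[tuple[str, int, int, str]] = []
    elem_rows = []
    for i, el in enumerate(spec.element_layouts):
        if el.chrom not in spec.chrom_lengths:
            raise ValueError(f"element {i}: unknown chromosome {el.chrom!r}")
        length = element_length(el, model)
        end = el.start + length
        if el.start < 0 or end > spec.chrom_lengths[el.chrom]:
            raise ValueError(
                f"element {i} ({el.kind} at {el.chrom}:{el.start}) out of range"
            )
        for (pchrom, ps, pe, pname) in placed:
            if pchrom == el.chrom and el.start < pe and ps < end:
                raise ValueError(
                    f"planted elements overlap: {pname} and "
                    f"{el.kind}_{i} at {el.chrom}:{el.start}-{end}"
                )
        placed.append((el.chrom, el.start, end, f"{el.kind}_{i}"))

        if el.kind == "PGBD3":
            seq = build_pgbd3(model, rng)
        else:
            seq = build_mer85(el, model, rng)
        oriented = seq if el.strand == "+" else revcomp(seq)
        genome_arr[el.chrom][el.start : end] = np.frombuffer(
            oriented.encode(), dtype=np.uint8
        )

        # truth landmark coordinates (genomic) for intact layout pieces
        def g(off: int, span: int) -> tuple[int, int]:
            if el.strand == "+":
                return el.start + off, el.start + off + span
            return end - off - span, end - off

        pal_off = model.palindrome_offset[0]
        pal = g(pal_off, 16) if not el.deletion_5p else (None, None)
        elem_rows.append(
            {
                "id": f"{el.kind}_{i}",
                "kind": el.kind,
                "chrom": el.chrom,
                "start": el.start,
                "end": end,
                "strand": el.strand,
                "bound": el.bound,
                "palindrome_mismatches": el.palindrome_mismatches,
                "tir5_intact": el.tir5_intact,
                "tir3_intact": el.tir3_intact,
                "palindrome_start": pal[0],
                "palindrome_end": pal[1],
            }
        )

    motif_rows = []
    for i, site in enumerate(spec.motif_sites):
        inst = _concrete_motif(site.pattern, rng)
        end = site.pos + len(inst)
        if site.chrom not in spec.chrom_lengths:
            raise ValueError(f"motif {i}: unknown chromosome {site.chrom!r}")
        if site.pos < 0 or end > spec.chrom_lengths[site.chrom]:
            raise ValueError(f"motif {i} at {site.chrom}:{site.pos} out of range")
        oriented = inst if site.strand == "+" else revcomp(inst)
        genome_arr[site.chrom][site.pos : end] = np.frombuffer(
            oriented.encode(), dtype=np.uint8
        )
        motif_rows.append(
            {
                "id": f"{site.pattern}_{i}",
                "pattern": site.pattern,
                "chrom": site.chrom,
                "start": site.pos,
                "end": end,
                "strand": site.strand,
                "bound": site.bound,
            }
        )

    gene_rows = []
    for gm in spec.gene_models:
        if gm.chrom not in spec.chrom_lengths:
            raise ValueError(f"gene {gm.gene_id}: unknown chromosome {gm.chrom!r}")
        if not 0 <= gm.tss < spec.chrom_lengths[gm.chrom]:
            raise ValueError(f"gene {gm.gene_id} TSS out of range")
        gene_rows.append(
            {
                "gene_id": gm.gene_id,
                "chrom": gm.chrom,
                "tss": gm.tss,
                "strand": gm.strand,
            }
        )

    genome = {c: a.tobytes().decode() for c, a in genome_arr.items()}
    columns = [
        "id", "kind", "chrom", "start", "end", "strand", "bound",
        "palindrome_mismatches", "tir5_intact", "tir3_intact",
        "palindrome_start", "palindrome_end",
    ]
    elements = pd.DataFrame(elem_rows, columns=columns)
    motifs = pd.DataFrame(
        motif_rows,
        columns=["id", "pattern", "chrom", "start", "end", "strand", "bound"],
    )
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "tss", "strand"])
    return genome, elements, motifs, genes


# ---------------------------------------------------------------------------
# fragment simulation


def binding_anchors(
    spec: SyntheticGenomeSpec,
    config: SimulationConfig,
    model: ElementModel = ElementModel(),
) -> list[tuple[str, int]]:
    """Genomic positions where signal fragments center.

    Bound elements anchor ``binding_offset`` bp inside their 5' TSD in
    element orientation (the middle of the palindromic region); bound motif
    sites anchor at the motif midpoint.
    """
    anchors: list[tuple[str, int]] = []
    for el in spec.element_layouts:
        if not el.bound:
            continue
        length = element_length(el, model)
        if el.strand == "+":
            anchors.append((el.chrom, el.start + config.binding_offset))
        else:
            anchors.append((el.chrom, el.start + length - 1 - config.binding_offset))
    for site in spec.motif_sites:
        if site.bound:
            inst_len = len(_MOTIF_INSTANCES[site.pattern])
            anchors.append((site.chrom, site.pos + inst_len // 2))
    return anchors


def simulate_fragments(
    spec: SyntheticGenomeSpec,
    config: SimulationConfig,
    model: ElementModel = ElementModel(),
) -> tuple[list[PairedRecord], list[GenomicInterval]]:
    """Simulate ChIP read pairs and input-control single-end reads.

    Signal fragments center Normal(anchor, enrichment_sd) (truncated so the
    fragment fits the chromosome), conditioned on the fragment containing
    the anchor — an immunoprecipitated fragment must carry the bound site,
    which is what gives the fragment-overlap profile its sharp apex over
    the binding position.  Lengths are uniform over the size-selection
    window; background fragments and input reads are uniform over the
    genome with the chromosome chosen proportional to length.  Each
    fragment is emitted as two ``read_length`` mates at its ends on
    opposite strands.
    """
    if not spec.chrom_lengths:
        raise ValueError("empty genome")
    anchors = binding_anchors(spec, config, model)
    if config.n_fragments_signal > 0 and not anchors:
        raise ValueError("signal fragments requested but nothing is bound")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.fragment_length_range
    chroms = list(spec.chrom_lengths)
    lengths = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()

    pairs: list[PairedRecord] = []

    def emit(chrom: str, start: int, end: int, idx: int, tag: str) -> None:
        rl = config.read_length
        pairs.append(
            PairedRecord(
                chrom, start, start + rl, chrom, end - rl, end,
                "+", "-", name=f"{tag}_{idx}",
            )
        )

    for i in range(config.n_fragments_signal):
        chrom, anchor = anchors[rng.integers(0, len(anchors))]
        chrom_len = spec.chrom_lengths[chrom]
        frag_len = int(rng.integers(lo, hi + 1))
        start = None
        for _ in range(100):  # condition on the fragment covering its anchor
            center = int(round(rng.normal(anchor, config.enrichment_sd)))
            cand = min(max(center - frag_len // 2, 0), chrom_len - frag_len)
            if cand <= anchor < cand + frag_len:
                start = cand
                break
        if start is None:
            start = min(max(anchor - frag_len // 2, 0), chrom_len - frag_len)
        emit(chrom, start, start + frag_len, i, "signal")

    for i in range(config.n_fragments_background):
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        chrom_len = spec.chrom_lengths[chrom]
        frag_len = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, max(chrom_len - frag_len, 1)))
        emit(chrom, start, start + frag_len, i, "background")

    input_reads: list[GenomicInterval] = []
    rl = config.read_length
    for i in range(config.n_input_reads):
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        chrom_len = spec.chrom_lengths[chrom]
        start = int(rng.integers(0, max(chrom_len - rl, 1)))
        input_reads.append(
            GenomicInterval(chrom, start, start + rl, name=f"input_{i}")
        )
    return pairs, input_reads


# ---------------------------------------------------------------------------
# expression simulation


def simulate_expression(
    spec: SyntheticGenomeSpec,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Expression table with planted regulation near bound TRE sites.

    Genes within ``regulatory_distance`` of a bound TRE site are regulated:
    each is assigned up or down with equal probability and draws its SLR
    from Normal(+-effect, sigma).  All other genes — including genes whose
    only nearby planted feature is a MER85 — draw from Normal(0, sigma) and
    carry the truth label 'null'.
    """
    if not spec.gene_models:
        raise ValueError("no gene models in spec")
    rng = np.random.default_rng(config.seed + 1)
    tre_sites = [
        (s.chrom, s.pos) for s in spec.motif_sites
        if s.pattern == "TRE" and s.bound
    ]
    rows = []
    for i, gm in enumerate(spec.gene_models):
        near_tre = any(
            c == gm.chrom and abs(p - gm.tss) <= config.regulatory_distance
            for c, p in tre_sites
        )
        if near_tre:
            direction = "up" if rng.random() < 0.5 else "down"
            effect = config.up_slr if direction == "up" else -config.down_slr
        else:
            direction = "null"
            effect = 0.0
        slr = float(rng.normal(effect, config.expression_sigma))
        rows.append(
            {
                "probe_id": f"probe_{i}",
                "gene_id": gm.gene_id,
                "chrom": gm.chrom,
                "tss": gm.tss,
                "strand": gm.strand,
                "slr": slr,
                "truth": direction,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the default study layout


def default_study_spec(
    seed: int = 0,
    n_chroms: int = 8,
    chrom_length: int = 10_000_000,
    n_bound_mer85: int = 50,
    n_unbound_mer85: int = 40,
    n_regulated_genes: int = 20,
    n_null_genes: int = 40,
    tre_per_regulated_gene: int = 2,
    n_extra_tre: int = 10,
    n_tead1: int = 10,
    n_ctcf: int = 6,
    frac_bound_perfect_palindrome: float = 0.801,
    frac_unbound_perfect_palindrome: float = 0.091,
) -> SyntheticGenomeSpec:
    """The standard synthetic study layout.

    Bound MER85s mostly carry a perfect palindrome (80.1%) while unbound
    ones rarely do (9.1%); regulated genes each get bound TRE sites planted
    10-30 kb from their TSS; bound MER85s are placed away from regulated
    genes so element binding carries no expression signal.  Placement is by
    rejection sampling with a minimum 5-kb separation between plants.
    """
    rng = np.random.default_rng(seed)
    chrom_lengths = {f"chr{i + 1}": chrom_length for i in range(n_chroms)}
    chroms = list(chrom_lengths)

    taken: list[tuple[str, int, int]] = []

    def place(span: int, chrom: str | None = None, near: tuple[str, int] | None = None,
              lo_off: int = 10_000, hi_off: int = 30_000,
              min_sep: int = 5_000, max_tries: int = 1000) -> tuple[str, int]:
        for _ in range(max_tries):
            if near is not None:
                c = near[0]
                off = int(rng.integers(lo_off, hi_off)) * (1 if rng.random() < 0.5 else -1)
                pos = near[1] + off
            else:
                c = chrom if chrom is not None else chroms[int(rng.integers(0, len(chroms)))]
                pos = int(rng.integers(50_000, chrom_lengths[c] - 50_000))
            if pos < 1_000 or pos + span > chrom_lengths[c] - 1_000:
                continue
            if all(
                not (c == tc and pos < te + min_sep and ts - min_sep < pos + span)
                for tc, ts, te in taken
            ):
                taken.append((c, pos, pos + span))
                return c, pos
        raise RuntimeError("could not place a planted feature; genome too crowded")

    elements: list[PlantedElement] = []
    motifs: list[MotifSite] = []
    genes: list[GeneModel] = []

    # regulated genes with bound TRE sites nearby; null genes elsewhere
    for g in range(n_regulated_genes):
        chrom, tss = place(1)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"gene_reg_{g}", chrom, tss, strand))
        for _ in range(tre_per_regulated_gene):
            c, pos = place(7, near=(chrom, tss))
            motifs.append(MotifSite(c, pos, "TRE",
                                    "+" if rng.random() < 0.5 else "-", bound=True))
    for g in range(n_null_genes):
        chrom, tss = place(1)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"gene_null_{g}", chrom, tss, strand))

    for _ in range(n_extra_tre):
        c, pos = place(7)
        motifs.append(MotifSite(c, pos, "TRE",
                                "+" if rng.random() < 0.5 else "-", bound=True))
    for _ in range(n_tead1):
        c, pos = place(7)
        motifs.append(MotifSite(c, pos, "TEAD1",
                                "+" if rng.random() < 0.5 else "-", bound=True))
    for _ in range(n_ctcf):
        c, pos = place(12)
        motifs.append(MotifSite(c, pos, "CTCF",
                                "+" if rng.random() < 0.5 else "-", bound=True))

    # bound MER85s: away from genes (independent uniform placement), mostly
    # perfect palindromes; unbound: mostly mismatched palindromes
    for b in range(n_bound_mer85):
        c, pos = place(140)
        perfect = rng.random() < frac_bound_perfect_palindrome
        elements.append(
            PlantedElement(
                "MER85", c, pos, "+" if rng.random() < 0.5 else "-",
                palindrome_mismatches=0 if perfect else int(rng.integers(1, 3)),
                bound=True,
            )
        )
    for b in range(n_unbound_mer85):
        c, pos = place(140)
        perfect = rng.random() < frac_unbound_perfect_palindrome
        elements.append(
            PlantedElement(
                "MER85", c, pos, "+" if rng.random() < 0.5 else "-",
                palindrome_mismatches=0 if perfect else int(rng.integers(2, 5)),
                bound=False,
            )
        )
    c, pos = place(PGBD3_LENGTH)
    elements.append(PlantedElement("PGBD3", c, pos, "+", bound=True))

    return SyntheticGenomeSpec(
        chrom_lengths=chrom_lengths,
        element_layouts=tuple(elements),
        motif_sites=tuple(motifs),
        gene_models=tuple(genes),
        seed=seed,
    )


def proximity_study_spec(
    seed: int = 0,
    n_bound: int = 20,
    n_unbound: int = 20,
    chrom_length: int = 10_000_000,
    tre_offset_range: tuple[int, int] = (10_000, 50_000),
) -> SyntheticGenomeSpec:
    """A layout for the element-proximity contrast: every bound MER85 has
    one bound TRE site planted 10-50 kb away, while unbound MER85s have
    none nearby, so TRE binding sites are enriched within 100 kb of bound
    anchors only."""
    rng = np.random.default_rng(seed)
    chrom_lengths = {"chr1": chrom_length, "chr2": chrom_length}
    taken: list[tuple[str, int]] = []

    def place(chrom=None, near=None):
        while True:
            if near is not None:
                c = near[0]
                off = int(rng.integers(*tre_offset_range))
                pos = near[1] + (off if rng.random() < 0.5 else -off)
            else:
                c = "chr1" if rng.random() < 0.5 else "chr2"
                pos = int(rng.integers(200_000, chrom_length - 200_000))
            if pos < 1_000 or pos > chrom_length - 5_000:
                continue
            if all(cc != c or abs(pos - pp) > 2_000 for cc, pp in taken):
                taken.append((c, pos))
                return c, pos

    elements: list[PlantedElement] = []
    motifs: list[MotifSite] = []
    for _ in range(n_bound):
        c, pos = place()
        elements.append(PlantedElement("MER85", c, pos, "+", bound=True))
        mc, mpos = place(near=(c, pos))
        motifs.append(MotifSite(mc, mpos, "TRE", "+", bound=True))
    for _ in range(n_unbound):
        c, pos = place()
        elements.append(PlantedElement("MER85", c, pos, "+", bound=False))
    return SyntheticGenomeSpec(
        chrom_lengths=chrom_lengths,
        element_layouts=tuple(elements),
        motif_sites=tuple(motifs),
        seed=seed,
    )
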