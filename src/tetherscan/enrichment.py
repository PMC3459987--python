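"""GREAT-style regulatory-domain association statistics.

Each gene (or microarray probe set) anchors a "regulatory domain" around
its start site; a peak set is called enriched near a gene set when the
number of peak summits falling inside the union of the gene set's domains
is binomially improbable given the fraction of the genome the union
covers:

    P = P(X >= k),  X ~ Binomial(n, p)

with n test summits, k of them inside the union, and p the union's genome
fraction.  Statistical significance is assessed by an empirical false
discovery rate: R sets of n summits are drawn uniformly over the genome
(chromosome chosen proportional to length), the binomial P-value is
recomputed for each, and the FDR is the fraction of random sets whose
P-value is at least as small as the observed one.

Two domain constructions are provided because the choice is a modelling
decision: the GREAT-like default gives every start site a strand-oriented
basal region (5 kb upstream / 1 kb downstream) then extends up to the
maximum extension but not into a neighbour's basal region; pure-extension
mode extends symmetrically and truncates at the midpoint to the
neighbouring start site.  The mode used is recorded in the result.
"""

from __future__ import annotations

import dataclasses
import zlib
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coverage import Peak
from .io import GenomicInterval


@dataclasses.dataclass(frozen=True)
class RegulatoryDomain:
    gene_id: str
    chrom: str
    start: int
    end: int
    tss: int
    max_extension: int

    def __post_init__(self) -> None:
        if not (self.start <= self.tss <= self.end):
            raise ValueError("TSS must lie inside its regulatory domain")


@dataclasses.dataclass
class EnrichmentTest:
    name: str
    n: int
    k: int
    p: float
    p_value: float
    empirical_fdr: float | None = None
    fdr_label: str | None = None
    degenerate: bool = False
    mode: str | None = None

    @property
    def significant(self) -> bool:
        return self.empirical_fdr is not None and self.empirical_fdr < 0.01


@dataclasses.dataclass(frozen=True)
class EnrichmentConfig:
    n_random_sets: int = 100
    fdr_threshold: float = 0.01
    basal_up: int = 5_000
    basal_down: int = 1_000
    mode: str = "basal"  # "basal" or "extension"

    def __post_init__(self) -> None:
        if self.n_random_sets < 1:
            raise ValueError("n_random_sets must be >= 1")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.mode not in ("basal", "extension"):
            raise ValueError(f"unknown domain mode {self.mode!r}")


def probe_start_sites(probes: pd.DataFrame) -> pd.DataFrame:
    """5' start-site positions of stranded probe/gene intervals.

    Expects columns chrom/start/end/strand (plus any id columns, which are
    preserved); the start site is the interval start on '+' and end-1 on
    '-'.  Input row order is preserved.  Missing strand is an error.
    """
    required = {"chrom", "start", "end", "strand"}
    missing = required - set(probes.columns)
    if missing:
        raise ValueError(f"probe table missing columns: {sorted(missing)}")
    if probes["strand"].isna().any() or (~probes["strand"].isin(["+", "-"])).any():
        raise ValueError("every probe needs strand '+' or '-'")
    out = probes.copy()
    out["tss"] = np.where(out["strand"] == "+", out["start"], out["end"] - 1)
    return out


def make_regulatory_domains(
    sites: pd.DataFrame,
    max_extension: int,
    genome: Mapping[str, int],
    config: EnrichmentConfig = EnrichmentConfig(),
) -> list[RegulatoryDomain]:
    """Build one regulatory domain per start site.

    ``sites`` needs columns gene_id/chrom/tss/strand (strand used only in
    basal mode).  Basal mode: strand-oriented basal region
    [tss - basal_up, tss + basal_down) extended each way up to
    ``max_extension`` but stopping at the neighbouring site's basal region.
    Extension mode: [tss - d, tss + d) truncated at the midpoint to the
    neighbouring TSS.  All domains are clipped to chromosome bounds.
    """
    domains: list[RegulatoryDomain] = []
    for chrom, group in sites.groupby("chrom", sort=False):
        chrom_len = genome[chrom]
        g = group.sort_values("tss").reset_index(drop=True)
        tss = g["tss"].to_numpy()
        if config.mode == "basal":
            strands = g["strand"].to_numpy()
            basal_lo = np.where(
                strands == "+", tss - config.basal_up, tss - config.basal_down + 1
            )
            basal_hi = np.where(
                strands == "+", tss + config.basal_down, tss + config.basal_up + 1
            )
            basal_lo = np.clip(basal_lo, 0, chrom_len)
            basal_hi = np.clip(basal_hi, 0, chrom_len)
            for i in range(len(g)):
                lo = max(tss[i] - max_extension, 0)
                hi = min(tss[i] + max_extension, chrom_len)
                if i > 0:
                    lo = max(lo, int(basal_hi[i - 1]))
                if i + 1 < len(g):
                    hi = min(hi, int(basal_lo[i + 1]))
                # the basal region always belongs to its own gene
                lo = min(lo, int(basal_lo[i]))
                hi = max(hi, int(basal_hi[i]))
                lo, hi = max(lo, 0), min(hi, chrom_len)
                domains.append(
                    RegulatoryDomain(
                        str(g.loc[i, "gene_id"]), chrom, int(lo), int(hi),
                        int(tss[i]), max_extension,
                    )
                )
        else:
            for i in range(len(g)):
                lo = max(tss[i] - max_extension, 0)
                hi = min(tss[i] + max_extension, chrom_len)
                if i > 0:
                    lo = max(lo, (int(tss[i - 1]) + int(tss[i])) // 2)
                if i + 1 < len(g):
                    hi = min(hi, (int(tss[i]) + int(tss[i + 1])) // 2 + 1)
                domains.append(
                    RegulatoryDomain(
                        str(g.loc[i, "gene_id"]), chrom, int(lo), int(hi),
                        int(tss[i]), max_extension,
                    )
                )
    return domains


def _merged_intervals(
    intervals: Iterable[tuple[str, int, int]]
) -> dict[str, np.ndarray]:
    """Merge (chrom, start, end) triples into disjoint sorted intervals,
    returned as {chrom: array of (start, end) rows}."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        if e > s:
            by_chrom.setdefault(chrom, []).append((s, e))
    merged: dict[str, np.ndarray] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out: list[list[int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.array(out, dtype=np.int64)
    return merged


def merge_domains(domains: Sequence[RegulatoryDomain]) -> dict[str, np.ndarray]:
    return _merged_intervals((d.chrom, d.start, d.end) for d in domains)


def domain_union_fraction(
    domains: Sequence[RegulatoryDomain] | dict[str, np.ndarray],
    genome: Mapping[str, int],
) -> float:
    """Fraction of the genome covered by the union of the domains."""
    total_genome = sum(genome.values())
    if total_genome <= 0:
        raise ValueError("empty genome")
    merged = domains if isinstance(domains, dict) else merge_domains(domains)
    covered = sum(
        int(np.sum(arr[:, 1] - arr[:, 0])) for arr in merged.values()
    )
    return covered / total_genome


def _count_in_union(
    summits: Sequence[tuple[str, int]], merged: dict[str, np.ndarray]
) -> int:
    k = 0
    for chrom, pos in summits:
        arr = merged.get(chrom)
        if arr is None or arr.size == 0:
            continue
        i = int(np.searchsorted(arr[:, 0], pos, side="right")) - 1
        if i >= 0 and arr[i, 1] > pos:
            k += 1
    return k


def binomial_tail(k: int, n: int, p: float) -> float:
    """Upper-tail P(X >= k) for X ~ Binomial(n, p), log-space stable."""
    if k <= 0:
        return 1.0
    if p >= 1.0:
        return 1.0
    if p <= 0.0:
        return 0.0
    return float(stats.binom.sf(k - 1, n, p))


def binomial_enrichment(
    summits: Sequence[tuple[str, int]],
    domains: Sequence[RegulatoryDomain] | dict[str, np.ndarray],
    genome: Mapping[str, int],
    name: str = "test",
) -> EnrichmentTest:
    """Binomial enrichment of summit positions in a domain union.

    ``summits`` are (chrom, position) pairs; containment is half-open.
    """
    n = len(summits)
    if n < 1:
        raise ValueError("need at least one summit")
    merged = domains if isinstance(domains, dict) else merge_domains(domains)
    p = domain_union_fraction(merged, genome)
    k = _count_in_union(summits, merged)
    degenerate = p == 0.0 and k > 0
    return EnrichmentTest(name, n, k, p, binomial_tail(k, n, p), degenerate=degenerate)


def draw_random_summits(
    n: int, genome: Mapping[str, int], rng: np.random.Generator
) -> list[tuple[str, int]]:
    """n positions uniform over the genome: chromosome chosen proportional
    to its length, then a uniform position."""
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    idx = rng.choice(len(chroms), size=n, p=probs)
    return [
        (chroms[i], int(rng.integers(0, genome[chroms[i]]))) for i in idx
    ]


def empirical_fdr(
    tests: Sequence[EnrichmentTest],
    domain_sets: Mapping[str, Sequence[RegulatoryDomain] | dict[str, np.ndarray]],
    genome: Mapping[str, int],
    config: EnrichmentConfig = EnrichmentConfig(),
    seed: int = 0,
) -> list[EnrichmentTest]:
    """Attach an empirical FDR to each observed test.

    For each test, R = ``config.n_random_sets`` random summit sets of the
    same size are drawn uniformly over the genome and scored against the
    same domain union; the FDR is the fraction of random sets achieving a
    P-value <= the observed one.  A count of zero is reported as '<1/R'.
    Fully seeded and independent of test ordering (each test gets its own
    child seed keyed by its name).
    """
    ss = np.random.SeedSequence(seed)
    out: list[EnrichmentTest] = []
    for test in tests:
        domains = domain_sets[test.name]
        merged = domains if isinstance(domains, dict) else merge_domains(domains)
        p = domain_union_fraction(merged, genome)
        # per-test stream so that adding/removing tests never shifts others
        child = np.random.SeedSequence(
            entropy=ss.entropy,
            spawn_key=(zlib.crc32(test.name.encode()) % (2**31),),
        )
        rng = np.random.default_rng(child)
        hits = 0
        for _ in range(config.n_random_sets):
            rand = draw_random_summits(test.n, genome, rng)
            k_r = _count_in_union(rand, merged)
            if binomial_tail(k_r, test.n, p) <= test.p_value:
                hits += 1
        fdr = hits / config.n_random_sets
        label = f"<{1 / config.n_random_sets:g}" if hits == 0 else f"{fdr:g}"
        out.append(
            dataclasses.replace(
                test, empirical_fdr=fdr, fdr_label=label, mode=config.mode
            )
        )
    return out


def proximity_enrichment(
    anchors: Sequence[GenomicInterval],
    peaks: Sequence[Peak],
    genome: Mapping[str, int],
    window: int = 100_000,
    name: str = "proximity",
) -> EnrichmentTest:
    """Are peak summits enriched within ``window`` bp of anchor elements?

    Builds merged +-window regions around anchor midpoints (merging avoids
    double-counting summits under overlapping windows) and computes the
    binomial enrichment of the peak summits in that union.
    """
    anchors = list(anchors)
    if not anchors:
        raise ValueError("no anchor elements")
    merged = _merged_intervals(
        (
            a.chrom,
            max(a.midpoint - window, 0),
            min(a.midpoint + window, genome[a.chrom]),
        )
        for a in anchors
    )
    summits = [(p.chrom, p.summit) for p in peaks]
    return binomial_enrichment(summits, merged, genome, name=name)


def count_multi_support(
    query: Sequence[Peak],
    reference_sets: Mapping[str, Sequence[GenomicInterval]],
    min_support: int = 10,
    slop: int = 50,
) -> tuple[list[Peak], pd.DataFrame]:
    """Count, per query peak, how many reference peak sets it overlaps.

    Each query is padded by ``slop`` bp on both sides (regions within 50 bp
    count as overlapping); support is the number of reference sets with at
    least one >=1 bp overlap.  Returns (queries with support >= min_support,
    full 0/1 support matrix indexed by query peak id).
    """
    if not reference_sets:
        raise ValueError("need at least one reference set")
    names = list(reference_sets)
    refs_by_chrom: dict[str, dict[str, np.ndarray]] = {}
    for rname, ivs in reference_sets.items():
        d: dict[str, list[tuple[int, int]]] = {}
        for iv in ivs:
            d.setdefault(iv.chrom, []).append((iv.start, iv.end))
        refs_by_chrom[rname] = {
            c: np.array(sorted(v), dtype=np.int64) for c, v in d.items()
        }
    rows = []
    for q in query:
        qs, qe = q.start - slop, q.end + slop
        row = {}
        for rname in names:
            arr = refs_by_chrom[rname].get(q.chrom)
            hit = 0
            if arr is not None and arr.size:
                i = int(np.searchsorted(arr[:, 0], qe, side="left"))
                if np.any(arr[:i, 1] > qs):
                    hit = 1
            row[rname] = hit
        rows.append(row)
    matrix = pd.DataFrame(rows, index=[q.id for q in query]).astype(int)
    support = matrix.sum(axis=1)
    retained = [q for q in query if support[q.id] >= min_support]
    matrix.insert(0, "support", support)
    return retained, matrix


def genes_near_peaks(
    domains: Sequence[RegulatoryDomain],
    summits: Sequence[tuple[str, int]],
) -> dict[str, list[tuple[str, int]]]:
    """Map each domain's gene id to the summits it contains.

    A summit inside the (possibly overlapping) domains of several genes is
    attributed to each of them.
    """
    out: dict[str, list[tuple[str, int]]] = {}
    for d in domains:
        contained = [
            s for s in summits if s[0] == d.chrom and d.start <= s[1] < d.end
        ]
        if contained:
            out.setdefault(d.gene_id, []).extend(contained)
    return out
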