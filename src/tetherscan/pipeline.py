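"""End-to-end orchestration of the synthetic study.

`run_study` wires every stage together: generate the planted genome,
simulate ChIP read pairs and input, build fragment-overlap tracks, call
clusters under three caller-like configurations and intersect them into
combined peaks, annotate and bound-classify the repeat elements, scan the
summit windows for TRE/TEAD1/CTCF motifs, categorize peaks, and simulate
expression.  The pieces are all importable individually; this module only
sequences them.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import pandas as pd

from . import coverage, elements, motifs, synthetic
from .io import GenomicInterval


@dataclasses.dataclass
class StudyResult:
    spec: synthetic.SyntheticGenomeSpec
    config: synthetic.SimulationConfig
    genome: dict[str, str]
    element_truth: pd.DataFrame
    motif_truth: pd.DataFrame
    gene_table: pd.DataFrame
    tracks: dict[str, coverage.FragmentCoverageTrack]
    input_tracks: dict[str, coverage.FragmentCoverageTrack]
    caller_sets: dict[str, list[GenomicInterval]]
    combined_peaks: list[coverage.Peak]
    annotated_elements: list[elements.RepeatElement]
    occurrences: list[motifs.MotifOccurrence]
    expression: pd.DataFrame
    rejected_pairs: int

    def peaks_in_category(self, label: str) -> list[coverage.Peak]:
        return [p for p in self.combined_peaks if label in p.categories]

    @property
    def bound_elements(self) -> list[elements.RepeatElement]:
        return [e for e in self.annotated_elements if e.bound]

    @property
    def unbound_elements(self) -> list[elements.RepeatElement]:
        return [e for e in self.annotated_elements if not e.bound]


# three caller-like parameterisations whose consensus defines combined peaks
CALLER_CONFIGS = {
    "callerA": coverage.CoverageConfig(min_cluster_fragments=4, min_fold_vs_input=1.5),
    "callerB": coverage.CoverageConfig(min_cluster_fragments=5, min_fold_vs_input=2.0),
    "callerC": coverage.CoverageConfig(min_cluster_fragments=6, min_fold_vs_input=2.0),
}


def run_study(
    spec: synthetic.SyntheticGenomeSpec | None = None,
    config: synthetic.SimulationConfig | None = None,
    seed: int = 0,
    model: elements.ElementModel = elements.ElementModel(),
) -> StudyResult:
    """Run the whole analysis on a synthetic study and return every stage's
    output.  When ``spec``/``config`` are omitted the default study layout
    and simulation conditions are used with ``seed``."""
    if spec is None:
        spec = synthetic.default_study_spec(seed=seed)
    if config is None:
        config = synthetic.SimulationConfig(seed=seed)

    genome, element_truth, motif_truth, gene_table = synthetic.generate_genome(
        spec, model
    )
    pairs, input_reads = synthetic.simulate_fragments(spec, config, model)
    fragments, rejected = coverage.pairs_to_fragments(pairs)
    input_fragments = [
        coverage.FragmentInterval(iv.chrom, iv.start, iv.end) for iv in input_reads
    ]
    tracks = {
        chrom: coverage.overlap_track(fragments, chrom) for chrom in spec.chrom_lengths
    }
    input_tracks = {
        chrom: coverage.overlap_track(input_fragments, chrom)
        for chrom in spec.chrom_lengths
    }

    caller_sets: dict[str, list[GenomicInterval]] = {}
    for name, cfg in CALLER_CONFIGS.items():
        ivs: list[GenomicInterval] = []
        for chrom in spec.chrom_lengths:
            for p in coverage.call_clusters(tracks[chrom], input_tracks[chrom], cfg):
                ivs.append(p.interval)
        caller_sets[name] = ivs
    combined = coverage.consensus_intersect(caller_sets, tracks)

    annotated: list[elements.RepeatElement] = []
    for row in element_truth.itertuples():
        annotated.append(
            elements.annotate_element(
                genome[row.chrom], row.start, row.end,
                chrom=row.chrom, strand=row.strand, model=model,
                element_id=row.id, kind=row.kind,
            )
        )
    elements.classify_bound(annotated, combined)

    occurrences: list[motifs.MotifOccurrence] = []
    windows = motifs.summit_windows(combined, chrom_lengths=spec.chrom_lengths)
    for (w, _), peak in zip(windows, combined):
        seq = genome[w.chrom][w.start : w.end]
        for pattern_name in motifs.BUILTIN_PATTERNS:
            occurrences.extend(
                motifs.scan_iupac(
                    seq, motifs.MotifPattern.builtin(pattern_name),
                    chrom=w.chrom, offset=w.start,
                )
            )
    # deduplicate hits found via overlapping windows
    occurrences = sorted(
        {(o.chrom, o.start, o.end, o.strand, o.pattern) for o in occurrences}
    )
    occurrences = [motifs.MotifOccurrence(*o) for o in occurrences]
    motifs.categorize_peaks(
        combined, annotated, occurrences, chrom_lengths=spec.chrom_lengths
    )

    expression = synthetic.simulate_expression(spec, config)
    return StudyResult(
        spec, config, genome, element_truth, motif_truth, gene_table,
        tracks, input_tracks, caller_sets, combined, annotated, occurrences,
        expression, rejected,
    )
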