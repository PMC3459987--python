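"""Signal-log-ratio expression classification and QPCR arithmetic.

Regulation calls use the 2-fold convention on log2 signal log ratios
(SLR): up means SLR > 1, down means SLR < -1, and anything in the closed
interval [-1, 1] is unchanged.  QPCR fold changes come from the delta-delta
Ct method assuming perfect per-cycle doubling.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import pandas as pd


@dataclasses.dataclass
class RegulatedGeneSet:
    condition: str
    direction: str  # up / down / unchanged
    gene_ids: list[str]

    def __len__(self) -> int:
        return len(self.gene_ids)


def classify_regulated(
    records: pd.DataFrame,
    up_threshold: float = 1.0,
    down_threshold: float = -1.0,
    condition: str = "condition",
) -> tuple[dict[str, RegulatedGeneSet], int]:
    """Partition genes by SLR into up / down / unchanged sets.

    ``records`` needs columns gene_id and slr.  Inequalities are strict, so
    a boundary SLR of exactly 1 (or -1) is "unchanged".  Records with
    non-finite SLR are rejected and tallied, not fatal.  Returns
    ({direction: RegulatedGeneSet}, n_rejected).
    """
    if down_threshold >= up_threshold:
        raise ValueError("down_threshold must be < up_threshold")
    finite = records["slr"].apply(lambda x: isinstance(x, (int, float)) and math.isfinite(x))
    rejected = int((~finite).sum())
    ok = records[finite]
    up = ok.loc[ok["slr"] > up_threshold, "gene_id"].tolist()
    down = ok.loc[ok["slr"] < down_threshold, "gene_id"].tolist()
    unchanged = ok.loc[
        (ok["slr"] <= up_threshold) & (ok["slr"] >= down_threshold), "gene_id"
    ].tolist()
    sets = {
        d: RegulatedGeneSet(condition, d, ids)
        for d, ids in (("up", up), ("down", down), ("unchanged", unchanged))
    }
    return sets, rejected


def qpcr_slr(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Delta-delta Ct signal log ratio assuming amplification efficiency 2.

    SLR = (Ct_target,control - Ct_ref,control) - (Ct_target,sample -
    Ct_ref,sample); under perfect doubling this equals the log2 fold change
    of the target in sample vs control.
    """
    for ct in (ct_target_sample, ct_ref_sample, ct_target_control, ct_ref_control):
        if ct <= 0:
            raise ValueError("Ct values must be positive")
    return (ct_target_control - ct_ref_control) - (ct_target_sample - ct_ref_sample)


def gene_set_overlap(
    set_a: Iterable[str],
    set_b: Iterable[str],
    peaks_near_gene: Mapping[str, Sequence] | None = None,
) -> dict:
    """Exact id intersection of two gene sets.

    When a gene -> nearby-peaks map (e.g. from
    :func:`tetherscan.enrichment.genes_near_peaks`) is supplied, the shared
    genes that have at least one peak nearby are also reported.
    """
    a, b = set(set_a), set(set_b)
    shared = sorted(a & b)
    result = {"shared": shared, "count": len(shared)}
    if peaks_near_gene is not None:
        with_peaks = [g for g in shared if peaks_near_gene.get(g)]
        result["with_nearby_peaks"] = with_peaks
        result["n_with_nearby_peaks"] = len(with_peaks)
    return result
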