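"""Simulate a synthetic ChIP study and call consensus peaks.

Builds the default planted genome (MER85-like elements, TRE/TEAD1/CTCF
motif sites, gene models), simulates paired-end fragments enriched at bound
sites, converts pairs back to fragments, computes fragment-overlap tracks,
calls clusters under three caller-like configurations and intersects them
into combined peaks with summits.
"""

from tetherscan import pipeline

res = pipeline.run_study(seed=1)

print(f"chromosomes: {len(res.spec.chrom_lengths)} "
      f"x {next(iter(res.spec.chrom_lengths.values())):,} bp")
print(f"planted elements: {len(res.element_truth)} "
      f"({int(res.element_truth.bound.sum())} bound)")
print(f"simulated pairs rejected as improper: {res.rejected_pairs}")
for name, ivs in res.caller_sets.items():
    print(f"{name}: {len(ivs)} cluster peaks")
print(f"combined peaks (consensus of all callers): {len(res.combined_peaks)}")
p = res.combined_peaks[0]
print(f"example peak {p.id}: {p.chrom}:{p.start}-{p.end} summit {p.summit}")

# The combined-peak count is at most the smallest caller set because a
# combined peak needs support from every caller; each summit marks the
# center of the deepest fragment-overlap run inside its peak.
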