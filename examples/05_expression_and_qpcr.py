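"""Classify regulated genes from signal log ratios and check QPCR math.

SLR > 1 is up (>2-fold), SLR < -1 is down, the closed interval between is
unchanged.  QPCR fold changes use delta-delta Ct with assumed perfect
doubling per cycle.
"""

from tetherscan import expression, pipeline

res = pipeline.run_study(seed=1)
sets, rejected = expression.classify_regulated(res.expression)
print(
    " ".join(f"{d}={len(s)}" for d, s in sets.items())
    + f" (rejected {rejected})"
)

truth_up = set(res.expression.loc[res.expression.truth == "up", "gene_id"])
overlap = expression.gene_set_overlap(sets["up"].gene_ids, sorted(truth_up))
print(f"planted up-genes recovered: {overlap['count']}/{len(truth_up)}")

# target amplifies 2 cycles earlier in the sample, reference unchanged:
slr = expression.qpcr_slr(
    ct_target_sample=18.0, ct_ref_sample=20.0,
    ct_target_control=20.0, ct_ref_control=20.0,
)
print(f"QPCR delta-delta Ct example: SLR = {slr} (4-fold up)")
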