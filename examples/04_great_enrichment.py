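"""GREAT-style binomial enrichment of peak sets near regulated genes.

Builds regulatory domains around regulated-gene start sites at three
maximum extensions, counts peak summits in the domain union, computes the
binomial upper-tail P-value, and attaches an empirical FDR from 100 random
summit sets.  Regulation was planted near bound TRE sites only, so TRE
peaks are enriched and MER85 peaks are not.
"""

from tetherscan import enrichment, expression, pipeline

res = pipeline.run_study(seed=1)
genome = res.spec.chrom_lengths
sets, _ = expression.classify_regulated(res.expression)
config = enrichment.EnrichmentConfig(n_random_sets=100)

up = res.expression[res.expression.gene_id.isin(sets["up"].gene_ids)]
sites = up[["gene_id", "chrom", "tss", "strand"]]
print(f"{len(sites)} upregulated genes (SLR > 1)")
for ext in (100_000, 250_000, 1_000_000):
    domains = enrichment.make_regulatory_domains(sites, ext, genome, config)
    for label in ("TRE", "MER85"):
        summits = [(p.chrom, p.summit) for p in res.peaks_in_category(label)]
        name = f"{label}@{ext // 1000}kb"
        t = enrichment.binomial_enrichment(summits, domains, genome, name)
        [t] = enrichment.empirical_fdr([t], {name: domains}, genome, config, seed=1)
        print(f"{name:12s} n={t.n:3d} k={t.k:3d} p={t.p:.4f} "
              f"P={t.p_value:9.3g} FDR={t.fdr_label}")

# TRE peak sets reach empirical FDR < 1% at every domain size; MER85 peaks,
# though just as strongly bound, show no association with regulated genes.
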