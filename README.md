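# tetherscan

Fragment-coverage ChIP-seq analysis for a domesticated transposase fusion
protein that binds its ancestral transposon family directly and is
*tethered* to transcription-factor motifs indirectly.

## The problem

The human piggyBac-derived protein studied here (a CSB–PGBD3-type fusion)
binds two very different classes of genomic site:

* **MER85-family elements** — 140-bp nonautonomous DNA transposons
  (TTAA target-site duplication, 13-bp terminal inverted repeats, and an
  imperfect 16-bp internal palindrome `GTTCCATTATTGGAAC` located 3 bp
  inside the 5′ TIR) that are bound directly through the transposase
  domain; and
* **transcription-factor motifs** — the AP-1 binding TRE element
  `TGANTCA`, the TEAD1 site `[AT]GGAAT[GT]` and the CTCF site
  `CCA[CG][CT]AG[AG][GT]GGC` — reached through protein–protein tethering.

The analytical question is which class of binding matters for gene
regulation.  tetherscan implements the full computational chain needed to
answer it, and a synthetic-data generator so every stage is testable
without any external downloads:

1. **Coverage** (`tetherscan.coverage`) — paired-end reads → fragment
   intervals → per-base fragment-overlap tracks; cluster calling (runs of
   ≥ 5 overlapping fragments, ≥ 2-fold over the input control); summit =
   center of the deepest overlap run; consensus ("combined") peaks
   supported by every caller, with boundaries from the outermost
   overlapping members.
2. **Elements** (`tetherscan.elements`) — TSD/TIR/palindrome annotation,
   completeness classes (intact / incomplete ends / expanded / deleted /
   no TIRs), bound/unbound classification against combined peaks,
   orientation-corrected cumulative binding profiles anchored at the 5′
   TSD, imperfect-palindrome search, and EMSA band normalization.
3. **Motifs** (`tetherscan.motifs`) — exact IUPAC consensus scanning on
   both strands, 100-bp summit windows (summit − 50 to summit + 49), peak
   categorisation with element precedence and TRE+TEAD1 multi-labelling,
   motif-centered average profiles.
4. **Enrichment** (`tetherscan.enrichment`) — GREAT-style regulatory
   domains (basal + extension, or pure extension; 100 kb / 250 kb / 1 Mb
   maximum extensions), the binomial test
   `P = P(X ≥ k), X ~ Binomial(n, p)` with `n` summits, `k` of them in the
   domain union covering genome fraction `p`, empirical FDR from 100
   random summit sets, element-proximity enrichment, and multi-dataset
   overlap support counting.
5. **Expression** (`tetherscan.expression`) — signal-log-ratio
   classification (up: SLR > 1; down: SLR < −1), ΔΔCt QPCR arithmetic,
   gene-set intersections with nearby-peak reporting.
6. **Synthetic data** (`tetherscan.synthetic`) — multi-chromosome toy
   genomes with planted elements, motif sites and gene models; paired-end
   fragment simulation (300–600 bp size selection, 36-bp reads) with
   signal enriched over bound sites; expression tables in which genes near
   bound TRE sites — but not genes near MER85s — are regulated.

`tetherscan.pipeline.run_study` wires the stages together;
`tetherscan.io` holds the BED/BEDPE/SAM/FASTA/wiggle readers and writers.
A thin CLI (`tetherscan simulate|coverage|consensus|motifs|great|proximity|expr`)
wraps the same functions.

## Worked example

`examples/04_great_enrichment.py` runs the whole synthetic study and asks
whether TRE-motif peaks or element peaks sit near upregulated genes:

```
11 upregulated genes (SLR > 1)
TRE@100kb    n= 49 k= 20 p=0.0250 P= 1.31e-19 FDR=<0.01
MER85@100kb  n= 50 k=  1 p=0.0250 P=    0.718 FDR=0.73
TRE@250kb    n= 49 k= 22 p=0.0607 P= 1.66e-14 FDR=<0.01
MER85@250kb  n= 50 k=  3 p=0.0607 P=    0.591 FDR=0.62
TRE@1000kb   n= 49 k= 27 p=0.2331 P= 1.58e-06 FDR=<0.01
MER85@1000kb n= 50 k=  8 p=0.2331 P=    0.923 FDR=0.89
```

Of `n` peak summits in each category, `k` fall inside the union of
regulatory domains around upregulated genes (fraction `p` of the genome).
TRE peaks are enormously enriched at every domain size (empirical FDR
below 1%), while the equally strongly bound MER85 peaks track the null —
the planted contrast between tethered-motif binding and direct element
binding, recovered end to end from simulated reads.  The other examples
show peak calling (`01`), the element meta-profile whose apex sits over
the internal palindrome just inside the 5′ TIR (`02`), motif
categorisation with multi-labelling (`03`), and expression classification
plus QPCR arithmetic (`05`).

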