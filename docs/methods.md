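# Methods

## Coordinates and formats

All internal coordinates are 0-based, half-open; strand `.` means absent.
Conversion to 1-based conventions happens only at format boundaries
(wiggle, SAM).  BED/BEDPE parsing reports the offending line number on
malformed input; chromosome names are matched by exact string equality.

## Fragment-overlap model

Each proper read pair is collapsed to the sheared chromatin fragment it
came from: `[min(mate starts), max(mate ends))` on the shared chromosome.
Pairs with mates on different chromosomes or the same strand are rejected
and tallied, never fatal.  The coverage track stores maximal constant-count
runs; by construction the sum of per-position counts equals the sum of
fragment lengths, an invariant the tests enforce on arbitrary inputs.

Cluster calling takes maximal runs with at least `min_cluster_fragments`
(default 5) overlapping fragments and keeps those whose mean count is at
least `min_fold_vs_input` (default 2.0) times the mean input-control count
over the run.  The input mean is floored at a one-fragment pseudocount so
zero-coverage input neither divides by zero nor inflates enrichment.
Summits are the floor midpoint of the leftmost maximal-count run — a
deterministic, order-independent tie-break chosen because nothing in the
underlying procedure distinguishes tied runs.

Consensus ("combined") peaks are computed over ≥ 2 named peak sets: any
maximal transitive chain of ≥ 1-bp overlaps that touches every set becomes
one combined peak spanning the outermost boundaries of its members, with
the summit recomputed from the fragment track (region midpoint when no
track is supplied).  Chain-based union was chosen over pairwise anchoring
because interval-join semantics merge overlapping features transitively;
the count of combined peaks can therefore never exceed the smallest input
set.

## Element model

The modelled 140-bp element family, read in the orientation of the
parental transposase ORF, is laid out as

    TSD(4: TTAA) + 5'TIR(13) + spacer(3) + palindrome(16) + internal(91) + 3'TIR(13)

with the imperfect internal palindrome `GTTCCATTATTGGAAC` 3 bp inside the
5′ TIR.  The palindrome's 6-bp arms are perfect mutual reverse
complements; the full 16-mer sits at Hamming distance exactly 2 from its
own reverse complement, which is what "imperfect" means here.  The
parental 2.5-kb element carries three palindrome copies (near the 5′ TIR,
59 bp upstream of the ORF, and 75 bp downstream of the ORF stop, 114 bp
upstream of the 3′ TIR).  The 13-bp TIR consensus used by the synthetic
model (`CCCTAGAAAGATA`, the *Trichoplusia ni* piggyBac TIR) is a synthetic
stand-in: the human family's TIR is a curated annotation this package does
not derive.

Annotation locates each TIR by matching the model TIR consensus (5′ end)
and its reverse complement (3′ end) within a short edge window, tolerating
2 mismatches by default.  Consensus-anchored matching was chosen over pure
mutual inverted-repeat alignment of the element's two ends because the
mutual test cannot tell *which* end is damaged, and the completeness
classes distinguish `incomplete_5p` from `incomplete_3p`.  With both TIRs
present, an element more than 20 bp over the 140-bp reference is
`expanded`, shorter than the reference is `deleted`, otherwise `intact`.
Ambiguity codes count as mismatches everywhere so degenerate sequence can
never satisfy a consensus silently.

Bound/unbound classification uses any ≥ 1-bp overlap between the element
and a combined peak (not summit containment), recording the leftmost
overlapping peak.  Cumulative binding profiles anchor at each element's 5′
TSD in element orientation, mirror minus-strand windows, zero-pad and flag
windows running off a chromosome, and report both the cumulative and the
per-element mean profile.  The profile apex is located with the same
deepest-run-center rule as summit calling, because plain argmax is biased
left by tie-breaking on plateaus.

EMSA normalization is linear rescaling of with-minus-without band
intensity differences between a scrambled control (0%) and the family
consensus (100%); equal control deltas are a hard error.

## Motif scanning and peak categories

Motif matching is exact IUPAC consensus matching on both strands (the
category definitions are consensus strings, not matrices; no PWM scores).
Minus-strand hits are reported in plus-strand coordinates; the TRE pattern
is its own reverse complement, so a TRE instance matches once per strand
at the same position.  Summit windows are `[summit − 50, summit + 50)`
clipped at chromosome ends; a motif counts for a peak only when fully
contained in the window.  Peaks overlapping an annotated element take the
element's category exclusively — element peaks are set aside before motif
assignment — while motif categories are multi-label (a peak with both TRE
and TEAD1 matches belongs to both peak sets).  Motif midpoints for
profiles are `floor((start + end)/2)`.

## Enrichment statistics

Regulatory domains are built per start site in one of two modes, recorded
in the output because the choice is a genuine modelling decision:

* **basal** (default): a strand-oriented basal region (5 kb upstream,
  1 kb downstream) extended up to the maximum extension (100 kb, 250 kb
  or 1 Mb) but stopping at a neighbour's basal region;
* **extension**: symmetric `[TSS − d, TSS + d)` truncated at the midpoint
  to the neighbouring start site.

The enrichment P-value is the binomial upper tail `P(X ≥ k)` for `n` test
summits of which `k` fall in the merged domain union covering fraction `p`
of the genome, computed with the stable survival function.  The empirical
FDR draws `R = 100` random summit sets of size `n` uniformly over the
genome (chromosome proportional to length), recomputes the P-value for
each, and reports the fraction at or below the observed one ("< 1/R" when
none reach it).  Each named test gets its own CRC-keyed random stream, so
results are reproducible under a fixed seed and invariant to test
ordering.  Ties with the observed P-value count against significance,
which makes the procedure conservative: on null simulations well under 1%
of comparisons reach FDR < 1%.

Proximity enrichment merges ± window regions (default 100 kb) around
anchor-element midpoints before counting, so summits under overlapping
windows are not double-counted.  Multi-dataset support pads each query
peak by 50 bp ("within 50 bp" counts as overlap) and tallies the number
of reference sets with ≥ 1-bp overlap.

## Expression

Regulation thresholds are strict: up is SLR > 1, down is SLR < −1, and
the closed interval [−1, 1] — including the boundaries — is unchanged.
Non-finite SLRs are rejected and tallied.  QPCR fold change uses ΔΔCt
with an assumed amplification efficiency of exactly 2 and no
standard-curve correction; the choice is recorded in output metadata.

## The synthetic-data generator

The generator emulates the study conditions end to end: uniform i.i.d.
ACGT background on a multi-chromosome genome, planted elements written at
declared coordinates (minus-strand plants reverse-complemented), concrete
motif instances, and gene models.  Paired-end fragments use the 300–600 bp
size-selection window with 36-bp reads.  Signal fragment centers are
Normal(anchor, `enrichment_sd` = 60 bp) *conditioned on the fragment
containing its anchor*: an immunoprecipitated fragment must carry the
bound site.  The conditioning matters — without it, fragments at least
300 bp long with tightly clustered centers produce a ~±150 bp flat-topped
coverage dome whose maximum is numerically ill-localized, whereas the
containment constraint makes coverage exactly maximal at the anchor with
a sharp linear falloff (apex jitter ~±5 bp across seeds), matching the
sharply peaked meta-profiles the analysis is designed to detect.  Bound
elements anchor 25 bp from the 5′ TSD (within the palindromic region);
bound motif sites anchor at the motif midpoint.  Background fragments and
single-end input reads are uniform over the genome with the chromosome
chosen proportional to length.

The default study layout plants 50 bound and 40 unbound MER85s plus one
parental element on 8 × 10 Mb chromosomes — large enough that 1 Mb
regulatory domains do not saturate the genome; 80.1% of bound and 9.1% of
unbound elements carry a perfect palindrome (the observed in-vivo rates
for this family); each of 20 regulated genes gets two bound TRE sites
10–30 kb from its TSS, and 40 null genes plus the bound elements are
placed independently, so element binding carries no expression signal.
Expression effects are ±2 SLR with Normal(0, 0.3) noise; genes within
100 kb of a bound TRE site are regulated (up or down with equal
probability), everything else — including genes near elements — is null.
A separate proximity layout plants one bound TRE site 10–50 kb from each
bound element and none near unbound elements, for the anchored-proximity
contrast.  Everything is deterministic under the spec/config seeds, and
truth tables are emitted alongside the data.

What the generator does **not** model: base qualities, sequencing error,
PCR duplicates, GC or mappability bias, chromatin accessibility, diploid
genomes, or assembly gaps.  Passing tests therefore demonstrate the
statistical machinery — coverage arithmetic, consensus logic, the
binomial/FDR procedure, profile orientation — under clean conditions,
not robustness to real-data artefacts such as duplicated reads or
blacklist regions.

## Problem sizes

The shared test study uses the default layout above with 12,000 signal
and 30,000 background fragments (~7 s end to end); null-FDR calibration
uses 300 replicate comparisons of 20 summits each against a fixed
30-gene domain set on an 8 Mb genome; binding-site localization uses 50
bound elements and 5,000 signal fragments on 2 × 2 Mb chromosomes.  These
sizes keep every stochastic check comfortably reproducible while the
planted effects remain far from the decision thresholds (the weakest
planted enrichment sits at P ≈ 10⁻⁶ against an FDR cutoff whose null
rate is below 1%).

## Known limitations

* MER85 and parental-element identity is taken from the element table
  (as with a curated repeat annotation); the package does not do de novo
  repeat discovery.
* Consensus matching has no mismatch tolerance for motifs; a single
  substitution outside a degenerate position hides a site, exactly as
  with consensus-string scanning generally.
* The empirical FDR is a per-comparison plug-in estimate (fraction of
  random sets at or below the observed P-value), with resolution 1/R.
* Peak callers themselves are not re-implemented; the consensus stage
  consumes any BED-formatted peak sets, and the built-in cluster caller
  is deliberately simple.
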