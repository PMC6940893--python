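# Methods

This note documents the models and procedures behind each stage, the
parameters that matter, the synthetic-data generator's scope, and the
numerical and design choices that were genuinely open.

## Quadripartite structure

A plastome is treated as a circular uppercase A/C/G/T/N string with a flat
list of gene features (symbol, category, strand, 1-based inclusive exon
intervals, copy index; trans-spliced loci are separate features sharing a
symbol). The LSC/IRa/SSC/IRb partition is defined as the longest exact
reverse-complement repeat pair that leaves two non-empty single-copy gaps
on the circle; the shorter gap is labelled SSC. Detection anchors 24-mers
of the sequence against an index of its reverse complement (doubled, so
matches cross the sequence origin), extends each anchor maximally, and
keeps candidates whose arms are disjoint on the circle. Exact matching is
deliberate: biological IR copies are near-identical, and the approximate
case is out of scope. Ties on arm length break toward the candidate with
the smallest |LSC − SSC| asymmetry, then the lowest start coordinate.
`min_ir_len` defaults to 1000 bp; genomes with no reverse-complement pair
that long raise a "no IR detected" error that callers may treat as an
IR-less genome.

%GC is (G+C)/(A+C+G+T) × 100, rounded half-up to one decimal for report
parity with how plastome surveys print it. Region fractions are of total
genome length, with each IR reported separately, so the four fractions sum
to 1. Coordinates are 1-based inclusive everywhere in I/O and reports;
intervals that wrap the origin are written start > end.

## Repeat censuses

SSRs are maximal perfect tandem runs of a primitive unit (1–6 bp; a unit
is primitive if it is not a whole-number repetition of a shorter one),
reported at the unit length of that primitive motif and truncated to whole
copies. The run boundary is chain-maximal: a run starting at s cannot be
extended by one character on either side. Minimum copy numbers default to
7, 4, 4, 3, 3, 3 for mono- through hexanucleotides, the MISA settings used
for plastid surveys. Compound (interruption-merged) SSRs are not merged —
each perfect run is one record — because only per-unit-length counts are
compared downstream. N matches nothing.

Long repeats of four kinds (forward, reverse, complement, palindromic) are
maximal pairs with equal-length arms ≥ 30 bp and Hamming distance ≤ 3.
The finder is seed-and-extend: by pigeonhole, any qualifying pair contains
an exact seed of length `min_len // (max_hamming + 1)` (7 at the default
settings, which is why `min_len` below 8 is refused), and every seed hit is
extended to all maximal windows containing it. A window is maximal when
extending either end would exceed the mismatch budget or leave the
sequence; pairs whose arms are both strictly contained in another reported
pair of the same kind are dropped. Note a consequence of budgeted
maximality: a planted exact 40-mer copy is typically reported inside a
longer maximal window carrying up to 3 flanking mismatches, and several
co-maximal windows with different mismatch splits can coexist; tests
therefore check containment of planted arms, and the test suite verifies
the finder against a full per-diagonal enumeration on ≤ 2 kb instances.
Both censuses run on the IR-reduced sequence (LSC + IRa + SSC) by default
so IR-internal repeats are counted once; full-genome mode is a flag.

## Nucleotide diversity and identity

π per window is the mean over unordered row pairs of (differing sites /
compared sites), where a site is compared for a pair only when both rows
carry A/C/G/T (pairwise deletion; gaps and N never compare). No
multiple-hit correction is applied — the value is the raw mean pairwise
difference proportion, matching how windowed plastome scans are usually
reported. Windows tile the alignment (step = window = 500 bp by default;
both configurable); a window with no comparable site for any pair reports
NaN with `n_sites_used = 0`. Hotspots are windows or features with π
strictly above 0.02, returned sorted by value. Windowed identity between
two rows is matches / comparable sites × 100 under the same comparability
rule. Pairwise deletion was chosen over complete deletion to retain signal
in indel-rich spacers; `n_sites_used` flags windows where few sites
supported the value.

## Structural comparison

Signed gene orders are derived from annotations by ascending start
coordinate, entries keyed by (symbol, copy index). After setting aside
symbols private to one genome (reported as presence/absence), every
maximal contiguous run where the two orders disagree is classified: an
inversion if the run in one genome equals the other's run reversed with
flipped strands, otherwise translocation-or-other. Only single-block
reversals are classified as inversions; no sorting-by-reversals distance
is computed, since the target phenomenon is a single inverted block.
Presence/absence defaults to the 11 ndh chlororespiratory genes
(ndhA–ndhK), counting a gene present only when a non-partial copy is
annotated. Junction reports give, for each of the four region boundaries,
the nearest feature on each side with signed distances, and overlap
lengths for straddling genes.

## C-to-U editing calling

Input is a per-replicate pileup table of plus-strand base counts from
uniquely mapped reads (a SAM front-end with NH-tag/mapping-quality
filtering is provided, but read mapping itself is upstream of this
package). A site is called when

1. the reference base is C on the strand of an overlapping CDS (C on the
   plus strand for + genes, G for − genes);
2. the edited base (T on +, A on −) is observed with level > 0 in at least
   `min_replicates` (default 2) replicates, each with coverage ≥
   `min_coverage` (default 10×);
3. the editing level per replicate is edited/(edited + reference) × 100 —
   reads supporting neither base are sequencing error and are excluded
   from the denominator, which is why fully edited sites saturate at 100.

Levels are reported for all replicates including zeros; a replicate at
level 0 does not disqualify a site that two other replicates support.
Sites outside any CDS, or at a non-C reference on the gene strand, are
skipped with a log entry. Codon annotation splices the CDS (multi-exon and
trans-spliced loci included), replaces the edited C with U, and translates
both codons under the plant-plastid (bacterial, table 11) genetic code;
the effect is synonymous, nonsynonymous, or stop-gained. Trans-spliced
assembly orders same-strand loci by genomic position and collapses IR
duplicates to the copy matching the query locus; assemblies with mixed
strands are reported with effect "unresolved" rather than guessed.

The physicochemical table follows the enumeration used in plastid editing
surveys verbatim: S→L, S→F and R→C are hydrophilic→hydrophobic changes;
A→V, H→Y, L→F, P→F, P→L, P→S, R→W, T→I and T→M are listed as no-change.
The enumeration is internally inconsistent with a strict
hydrophilicity-scale rule (R→W would cross it), so pairs outside the table
are deliberately not extrapolated — they return unchanged with category
"unlisted", and stop transitions are flagged separately. The bundled
published 16-site table carries one row (ndhB) whose printed amino acids
(H→Y) contradict its own codons (CCA→CUA encodes P→L); the classifier
reports codon-derived amino acids and flags the discrepancy.

Known limitation: without a DNA-Seq input, reverse-transcription artifacts
and genuine SNPs are not masked; on real data the caller's output is a
candidate list conditioned on the genome assembly being the DNA truth.

## Expression

Size factors are median-of-ratios: per-gene references are geometric means
across samples over genes with all-positive counts; each sample's factor
is the median of its count/reference ratios; normalized counts are raw /
factor. Genes with a zero anywhere are excluded from the reference but
kept in outputs; no gene positive in all samples is an error. The
implementation is a direct transcription of this definition and is
cross-checked in the tests against DESeq2's implementation (pydeseq2) to
1e-10. Note the standard identifiability caveat: size factors are defined
up to one global constant, so scaling one sample rescales all normalized
values by c^(1/m); tests compare factor ratios, not absolute values.
Display values are log2(normalized + 1). Sample profiles are clustered
with average linkage on 1 − Pearson correlation (the distance matrix is
symmetrized and clipped at 0 before linkage); leaf order is deterministic
with ties broken by input column order, and a Newick string is emitted
with branch lengths of half the merge distance. Duplicated IR genes are
separate rows suffixed _1/_2; the trans-spliced gene's three parts are
rows name, name_2, name_3. Differential-expression testing is out of
scope.

## Synthetic-data generator

The generator emulates the study design at reduced scale: three haplotypes
(7,500 bp LSC, 1,300 bp IRs, 1,400 bp SSC; ~11.5 kb total, roughly 1/13th
of a real plastome), 28 gene models including all 11 ndh genes, IR-
duplicated genes, two intron-bearing genes, a trans-spliced two-locus gene
and a partial pseudogene; an adjacent petN/psbM pair inverted in the third
haplotype; five planted SSRs (one per unit length 1–5) and two planted
40-bp long repeats in dedicated LSC zones; divergence as i.i.d.
substitutions at 0.002/site with three 500-bp hotspot intervals at
0.05/site; five planted C-to-U edits in single-copy genes observed over
three pileup replicates at 30× with levels patterned on the published
table (including zero-level replicates); and a 3/3/2-replicate
negative-binomial count design (dispersion 0.05, per-gene group effects
lognormal with σ = 0.4, library multipliers uniform on [0.7, 1.4], psbA
and rbcL set high in line with observed chloroplast expression). Genome
sizes were scaled down so that a 100-seed recovery experiment runs in
seconds; all structural properties exercised by the pipeline are preserved
at this scale.

Planted truth is exact by construction, which drives several repair steps:
background sequence is i.i.d. uniform and then scanned and repaired until
it contains no SSR or long repeat above the reporting thresholds; planted
SSR runs get breaking flank bases so they are maximal; junction bases are
fixed so the IR pair cannot extend by chance; substitutions are mirrored
from IRa into IRb to preserve exact IR symmetry, never land on planted
intervals, start/stop codons, planted edit codons or junction bases, and
any substitution that completes a new SSR run is reverted. Planted
edited-read counts are the deterministic rounding of coverage × level/100
(a binomial mode exists for stochastic experiments); this makes the
100%-recall property hold for every seed rather than almost every seed.

What the generator does not emulate — hence what passing tests do not
show about real data: no indels (alignments are trivially gap-free), no
rearrangements beyond the single inverted block, no read-level error
structure beyond uniform per-base miscalls, no RT artifacts or SNP
contamination of pileups, no GC-dependent coverage bias, and no polyA-
selection depletion of organelle transcripts. Tests on this generator
validate the algorithms' correctness contracts, not robustness to real
library artifacts.

## Problem sizes and tolerances

The default test suite and the acceptance script use: 100 seeded
simulations for partition and inversion recovery; 20 for SSR and hotspot
recovery; 10 for editing recall and RLE recovery; 60 sub-seeded pileup
sets for the sequencing-error false-positive experiment (2 replicates,
10× coverage, 1% error over one small gene — conditions chosen so the
replicate filter's theoretical block rate is ≈ 97%); brute-force oracle
comparisons at ≤ 2 kb. Hand-value π checks are asserted to 1e-12;
size-factor cross-checks to 1e-10; planted editing levels to the rounding
granularity 100/(2 × coverage) percentage points.
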