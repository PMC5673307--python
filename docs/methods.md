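# Methods

This note documents the models, conventions and numerical choices behind
`cracsplice`, the assumptions of the synthetic-data generator, and what
passing the test suite does and does not establish about real data.

## Coordinate model

All internal coordinates are 0-based half-open intervals; GFF3/GTF (1-based
inclusive) are converted only at the I/O boundary, and writing + reloading an
annotation is an exact identity. A gene is one transcript model: an ordered
exon chain in transcription orientation with derived introns; `tss` and
`pa_site` are the genomic coordinates of the first and last transcribed base
(so `tss > pa_site` on the minus strand). Overlapping isoforms are out of
scope — metagene feature sets assume one model per gene. "Exon 2" is the exon
immediately downstream of the *first* intron; in budding-yeast-style
annotations nearly every spliced gene has a single intron, so this matches
common usage while remaining defined for multi-intron genes. The 600 nt
long/short exon-2 stratification places exact ties in the short stratum.

## Preprocessing chain

1. **Adapter trimming** removes the longest read suffix matching an adapter
   prefix with ≤ 1 mismatch and ≥ 4 nt overlap — a plain suffix/prefix scan,
   not a full aligner. Reads without an adapter hit are discarded: an insert
   sequenced through its 3' adapter is fully observed, which is what
   crosslink mapping needs.
2. **Low-complexity filter** drops reads in which any single nucleotide makes
   up strictly more than 80 % of the insert.
3. **Sequence-level duplicate collapse** merges reads identical in (insert,
   6 nt in-line barcode); the barcode length is configurable.
4. **Alignment** places each read at its unique exact match, allowing at most
   one single-nucleotide deletion (the crosslink signature). Reads with zero
   or multiple candidate placements are dropped and counted. Deleting any
   base of a homopolymer run yields the same read, so deletions are
   canonicalised to the leftmost base of their run — the simulator truth uses
   the same convention, which is what makes exact truth recovery a meaningful
   test. This aligner is intended for synthetic genomes (generated with
   unique 25-mers); real data should be aligned externally and imported via
   SAM.
5. **Aligned-stage duplicate collapse** merges reads sharing (chromosome,
   strand, 5' terminus, barcode), keeping the longest representative. This is
   a *fallback* for duplicates that escaped step 3 through sequencing errors
   or differential 3' trimming. On error-free data step 3 is already
   complete, and because 6 nt barcodes collide between distinct co-starting
   molecules at a rate of ~1e-4, enabling the fallback there can only merge
   false positives; the oracle-equivalence checks therefore run without it.
6. **Crosslink-site calling** uses reads with exactly one deletion (more are
   too ambiguous to pinpoint a base); the site is the deleted base and the
   count is the number of deduplicated molecules, not their PCR multiplicity.
   An annotation-driven gene-class filter (protein-coding, non-mitochondrial
   by default) stands in for blacklist-based exclusion of RNAPI/RNAPIII
   transcripts.
7. **Cluster assembly** transitively merges strictly overlapping same-strand
   read spans; the cluster sequence is the genome sequence of the merged span
   in transcript orientation. The result is independent of read order.

Read conservation (`reads_in == kept + Σ drops`) is asserted in every run
report.

## Junction classification and splicing statistics

A read is **EE** if it is contiguous in mature-mRNA space across an exon–exon
junction — genomically, two blocks whose gap is exactly an intron — with at
least `min_overhang` aligned nt on each side; **EI**/**IE** if a contiguous
block straddles the 5'/3' intron boundary (transcript orientation) with the
same overhang; otherwise exonic/intronic by majority base overlap. The
default overhang is 5 nt; no standard value exists, so it is configurable and
recorded in every report. EI is tested before IE for every intron, in
transcript order, so a read spanning an entire short intron is EI.

For the intron/exon coverage counts, a read increments **I** if any aligned
base is intronic and **E** otherwise: a single intronic base evidences an
unspliced molecule (an EE read has no intronic bases and increments E).
Counting is per read, not per base; a base-level variant was considered and
rejected as harder to interpret under variable read lengths.

Statistics per transcript:

* spliced ratio `2·EE/(EI+IE)`, NA when no unspliced junction reads exist;
* unspliced ratio `(EI+IE)/(2·EE)`, NA when EE = 0 (the two are exact
  reciprocals wherever both are defined);
* intron/exon ratio `(I+1)/(E+1)` — the pseudocount keeps the ratio finite
  and strictly positive at zero coverage.

Genotype comparisons compute the statistic per replicate, average within
genotype, then take `log2(mutant/wild-type)`; genes with NA terms are flagged
(`defined == False`), never silently dropped. Coverage filtering offers
`above_mean_both` (strictly above the mean `I+E` in every genotype) and
`top_n` (ties broken by gene id). Transcriptome-level spliced ratios are
reported both as the unweighted mean of per-gene ratios and as the pooled
count ratio `2ΣEE/Σ(EI+IE)`; the two diverge when junction coverage is
uneven across genes, and both are printed because the choice is a genuine
modelling decision.

RNA-seq reads are aligned by exact lookup against every read-length window
of each gene's pre-mRNA and mature mRNA (`TranscriptIndex`) — junction-
spanning spliced reads are contiguous only in mature-mRNA space, so the
genomic 1-deletion aligner cannot place them. When a read matches both forms
of the same gene the placements are genomically identical for purely exonic
reads; the pre-mRNA interpretation is preferred. Cross-gene collisions are
dropped as ambiguous.

## Metagene profiles

Signal (default: read 5' ends, the natural proxy for polymerase position in
CRAC; coverage and crosslink-site modes available) is accumulated per
chromosome and strand with PCR multiplicity weights, then mapped to offsets
relative to per-gene anchors in transcript orientation (minus-strand genes
flipped) and summed over genes. Values are divided by (total mapped reads /
10⁶) — RPM over everything mapped, not only profiled genes; per-gene mean
weighting is available but off by default, matching the convention of
summing RPM across genes. Default windows are TSS [−100, +1000],
pA [−1000, +200], 3'SS [−200, +600]; windows are free parameters recorded in
every output header.

Replicate averaging is a pointwise mean with sample standard deviation
(ddof = 1); a single replicate reports sd 0 with `n_replicates = 1` marking
the spread as undefined. Modified-vs-total comparisons are per-offset ratios
`(num + pc)/(den + pc)` of two RPM profiles with pseudocount `pc > 0`
(default 0.1 RPM). Peak calling smooths with an 11 nt edge-corrected moving
average (raw profiles are never modified); ties in the smoothed profile
break first on the raw signal, then toward the smallest offset, so a single
delta peak is reported at its own position while a flat profile reports the
window start and is flagged by inspection of the value.

No statistical testing of profile differences is implemented; the profiles
are descriptive.

## Motif scan

Motif discovery is exhaustive k-mer enumeration (default k = 4) rather than
PWM/EM search: the binding motif of interest is a plain tetramer, and exact
counting is fully reproducible. Sequences are held in DNA alphabet (U ≡ T)
and reported as RNA. Scores are `log2((obs+0.5)/(exp+0.5))` with expected
counts from the mean of dinucleotide-preserving shuffles (Altschul–Erickson
Euler-path construction; default 10 shuffles) or from the uniform analytic
expectation. Surprise is a one-sided pooled binomial tail with a Bonferroni
threshold of 0.01 over the 4^k k-mers, stated in the output. Ranking is
deterministic (score, then lexicographic). Sequence sets for scanning follow
the two-disjoint-sets-of-500 convention, sampled randomly by default
(top-by-support available); the prevalence statistic is the fraction of
input sequences containing ≥ 1 exact occurrence of the top motif.

## The synthetic-data generator

The generator defines the package's study conditions; its defaults are fixed
and documented here, not tuned per analysis.

* **Genome**: one chromosome of random sequence, non-overlapping genes with
  300 nt intergenic gaps; exon 1 lengths uniform in [300, 1500] nt, introns
  in [80, 400] nt, exon 2 in [100, 1200] nt (spanning the 600 nt
  stratification threshold); half of genes intron-containing by default.
  Genomes are rejected and regenerated if any 25-mer repeats, which
  guarantees unique naive alignment.
* **Occupancy**: `(1 − depletion(x)) · (1 + Σ bumps)` over the gene body,
  with a promoter-proximal depletion step (width 150 nt, depth 0.8) and
  Gaussian pause bumps; defaults place bumps 200 nt upstream of the poly(A)
  site and 20 nt into exon 2 (width 30 nt, amplitude 2). No quantitative
  amplitude for splicing-linked pausing exists to calibrate against; these
  are synthetic choices made for testability, and the `ub_pol` sample
  multiplies bump amplitudes by 3 so the modified-vs-total enrichment has an
  analytic expected shape.
* **Crosslinks**: each gene carries ~8 hotspot positions (spacing > two
  insert lengths); a read is crosslinked with probability 0.2, anchored so
  the hotspot lies ≥ 10 nt inside the insert, and carries the corresponding
  single-nucleotide deletion. Hotspots avoid long homopolymer contexts and
  intron boundaries so the deleted base is identifiable from the read — an
  explicit identifiability constraint, without which no aligner could place
  ~1e-4 of deletions unambiguously and exact truth recovery would be
  impossible by construction.
* **Motif planting**: the configured motif (default UUUG) is written into
  the genome at each hotspot with probability 0.7, on the gene's strand.
  When a motif is configured the background genome is scrubbed of chance
  occurrences in both orientations, so the prevalence of the motif among
  cluster sequences is a clean binomial draw of the plant rate. Real genomes
  obviously contain background occurrences; this is a deliberate
  idealisation that makes the recovery tests sharp, and it is the main
  reason motif-test results should not be read as sensitivity estimates for
  real CRAC libraries.
* **Library artefacts**: 6 nt random in-line barcodes; PCR duplicate counts
  `1 + Poisson(mean − 1)` (mean 2.5, degenerating to exactly one copy at
  mean 1) with duplicates sharing barcode and sequence; the 3' adapter
  appended where the insert (24–40 nt) is shorter than the 50 nt read;
  low-complexity junk reads injected at 1 %; optional uniform substitution
  errors (off by default). Intron boundary bases are forced to differ from
  their exon partner bases so junction reads with 1 nt overhangs are never
  sequence-identical between spliced and unspliced molecule forms (a second
  identifiability constraint).
* **RNA-seq**: each molecule is spliced with the genotype's splicing
  efficiency (defaults: wild type 0.9, mutant 0.7); poly(A)+ libraries draw
  full-length molecules only, ribominus libraries additionally draw 30 %
  unspliced nascent molecules truncated uniformly between TSS and poly(A)
  site (the simplest model of nascent-transcript recovery). Reads sample
  uniformly along the molecule; no paired ends, no quality modelling beyond
  a constant score, no sequence-specific biases.

All randomness flows from a single seed through named substreams (stage,
sample, replicate), so every output byte is reproducible and stages are
individually re-runnable.

**What the simulator does not emulate**: expression-level variation between
genes, alternative isoforms, mismatch-tolerant alignment, ligation and PCR
sequence biases, crosslinking sequence preferences beyond the planted motif,
and background motif occurrences. Passing the oracle-equivalence and
recovery tests demonstrates that the implementation computes its statistics
correctly and recovers planted signal under the stated model — not that the
pipeline is robust to every artefact of real libraries.

## Numerical and degenerate-input conventions

NA propagates explicitly: undefined ratios are excluded from aggregates with
their count reported; genes with NA in a comparison are flagged. Empty read
sets produce zero profiles with a warning; an empty 3'SS anchor set (no
introns) warns rather than fails. Reads tied between two genes are dropped
with a warning. Coverage-filter ties break on gene id; k-mer ranking ties
break lexicographically; peak ties break on raw signal then smallest offset.
The analysis problem sizes used by the recovery checks (20–50 genes,
50k–200k reads, ten replicate simulations for the splicing comparison) were
chosen so each check completes in seconds to a couple of minutes while
leaving the binomial error of every estimated quantity well inside its
asserted tolerance.

## Known limitations

The naive aligner requires genome-wide k-mer uniqueness and tolerates no
substitutions, so reads carrying sequencing errors are dropped rather than
rescued — on error-containing simulations the recovered molecule count is
bounded by the fraction of lineages with at least one clean copy. Barcode
collisions make the aligned-stage duplicate collapse slightly lossy on deep
libraries (see above). The splicing statistics are directional descriptions,
not inferential tests; no p-values are attached to genotype comparisons.
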