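# Methods

This note records the models, conventions, and design choices behind
`seqexpress`, and what the synthetic-data tests do and do not demonstrate.

## Coordinates and annotation

All internal coordinates are 0-based half-open; SAM input (1-based) is
converted at the parser boundary and every emitted TSV carries a header
comment stating the convention.  Transcripts are grouped into genes
strictly by the annotation's `gene_id` — no overlap-based re-clustering —
so the gene "model" is exactly the merged exon union of all transcripts
sharing an id, and the RPKM length is the union length.  Known splice
sites are collected from internal exon boundaries of every member
transcript ("half-junctions") and are the only anchors used anywhere:
junction enumeration, skip-read evidence, and junction-aware liftover all
refuse coordinates that are not annotated sites.

Junctions are stored genomically, `donor_end < acceptor_start` on either
strand; on the minus strand the biological donor sits at
`acceptor_start`.  This makes enumeration strand-symmetric: pairing every
genomic-left intron edge with every genomic-right edge to its right
realizes donor-before-acceptor in transcription direction on both
strands, and gives E(E−1)/2 junctions for a single transcript with E
exons.

## Junction library and liftover

Contig flanks default to `read_len − 1` nt so a full-length read aligned
anywhere on a contig must cross the splice point; flanks are truncated
(never padded) where the containing exon-union block or chromosome is
shorter, and the actual flank lengths are encoded in the contig name
(`JUNC|chrom|donor_end|acceptor_start|strand|gene|lf|rf`).  Liftover maps
contig position c to `donor_end − L_left + c` (left flank) or
`acceptor_start + c − L_left` (right flank); a hit confined to one flank
is reclassified as a plain genomic candidate.  Liftover precedes
unique-best selection, and candidates with identical genome-space blocks
are collapsed first, so a genome hit and a junction hit of the same locus
can never produce a spurious "Mult" call.

## Unique-best selection

The best-score metric is the mismatch count alone (no gap or quality
scoring) — the intended aligner regime is ungapped short reads, and the
selection semantics need only "unique best".  Duplicate-position reads
are not collapsed; no deduplication step is part of the model.  For
paired-end data, pairs with exactly one unique end keep it as a rescued
single read; rescue re-screens the existing candidate sets rather than
realigning with different parameters.

## Event evidence

Cassette events are built per internal exon-union block, for *all* known
exons whether or not any transcript skips them.  Inclusion evidence is
junction-only (junctions into and out of the block from known sites);
skip evidence is junctions spanning the block anchored at known sites on
both sides.  Exon-body reads are deliberately excluded from inclusion
evidence so both contingency sides are junction-count-scaled and the
cross-sample statistic carries no length bias; the cost is fewer
inclusion counts than a body-inclusive rule would give.

Retained-intron events exist for every union gap whose flanks are locally
constitutive — every transcript spanning the gap has an exon ending
exactly at the gap start and one starting exactly at the gap end;
transcripts that do not span the gap do not vote.  Retention evidence is
full containment in the intron; splicing evidence is full containment in
either flanking block with no junction crossed.  A read straddling the
exon/intron boundary counts for neither side: containment (not overlap)
keeps the two sides mutually exclusive.

Alternative-terminal events are created per distinct TSS (and PACS)
except the 5′-most TSS and 3′-most PACS, strand-aware.  Their evidence is
purely interval-based: candidate terminal exons minus the exonic regions
of transcripts with a more-extreme site, versus exon-union regions distal
to the candidate site; overlaps are resolved by subtraction and events
with an empty side are dropped.

Event counting requires `min_anchor` (default 1 nt) aligned on both sides
of a junction; the library's `read_len − 1` flanks already guarantee
1-nt anchors, and the knob exists for imported spliced BAMs.  A read
matching several evidence items of one side increments that side once; a
read crossing an unannotated gap contributes to no event evidence but
still counts for genes when exon-contained.

## Statistics

**Binomial change test.**  With per-gene counts g₁, g₂ and effective
totals n₁, n₂, g₂ ~ Binomial(g, q₂), q₂ = n₂/(n₁+n₂).  The two-tailed
P-value sums all outcomes whose probability is ≤ the observed one, with
relative tolerance 1 + 10⁻⁷ for pmf ties — the convention of the R
function the original procedure calls, so published outputs reproduce.
The implementation enumerates the pmf directly; the suite cross-checks it
against an independently coded test and against exact comb-based
enumeration to 10⁻¹².

**MSC normalization.**  Genes with g ≥ 1 contribute their Wilson interval
(chosen for coverage at extreme proportions, where the optimizer
operates) for g₂/g; genes with g = 0 carry the uninformative [0, 1] and
cannot move the argmax, so they are excluded.  Window width is 10⁻⁴,
overlap counting is done with a difference array (O(genes + windows)),
and ties take the arithmetic mean of the tied midpoints.  On 2000-gene
Poisson simulations at a mean depth of ~30 reads/gene with ≤5% genes
changed 8-fold, the estimator recovers the true read fraction with
sampling SD ≈ 0.004; precision tightens with depth (≈ 10⁻⁴ at mean depth
5000).  The voted window itself is *not* stable to one window across
confidence levels 0.90/0.95/0.99: widening every interval moves the
argmax of the vote surface by tens of windows (a few 10⁻³) at any
realistic gene count — robustness to the cutoff is real but of that
order, not of window order.

**Event tests.**  Expected values e_ij = row_i·col_j/total decide the
branch: chi-squared when all four exceed 5, with the capped continuity
correction min(0.5, |O−E|) so a perfectly balanced table scores 0 (this
matches the R 2×2 default; an uncapped correction would not), otherwise
two-sided Fisher under the same minimum-likelihood convention as the
binomial test.  Fisher is conservative in this regime; the suite measures
an empirical type-I error ≈ 1.4% at nominal 5% on null tables with
12-read margins.

**Fold and ratio changes.**  Gene fold change is (g₂/n₂)/(g₁/n₁) on the
effective totals; zero denominators yield explicit 0/∞ markers rather
than pseudocounts, because the zero-skip-read regimes are biologically
meaningful and must survive into downstream scatter quadrants (infinite
values participate in significance calls by sign but are excluded from
fold correlations).  P-values are unadjusted by default;
Benjamini–Hochberg is flag-enabled.

**Other computations.**  Expression-profile correlation is Pearson on
log2(RPKM + 1) with average-linkage ordering on 1 − r (the exact metric
is not pinned by the original interface description; this is the
package's choice).  Group-vs-group comparisons pool member-lane counts by
summation.  Background sets match each changed gene greedily (descending
count) to the unused unchanged gene minimizing |log((c+1)/(t+1))|, ties
to the lexicographically smaller id; raw read counts are the recommended
matching metric to avoid transcript-length bias.  Microarray gene levels
are the median over probes positive in every array; genes with no such
probe are reported missing rather than zero.

## Synthetic data

The generator emulates the data regimes the pipeline is built for: toy
multi-chromosome genomes; genes with cassette, retainable-intron, and
multi-TSS/PACS structures; per-sample depth factors (hence a known
effective read fraction), per-gene fold changes, per-event isoform
fractions; single- or paired-end reads with Normal outer-distance
geometry.  Reads are emitted pre-aligned (genome-space SAM with N-gap
CIGARs) so the full pipeline runs without an external aligner; a FASTQ
emitter exists for integration against real aligners.  Each
(seed, sample) pair owns an independent random stream, so adding a sample
never perturbs another's reads, and identical seeds give byte-identical
outputs.

Deliberately not modelled: sequencing errors and base qualities, PCR
duplicates, multi-mapping reads (every simulated read has one true
placement, so "Mult"/"Nonmatch" paths are exercised by constructed unit
fixtures rather than the simulation), positional coverage bias, and
biological replicate variance — counts are Poisson around fixed
expectations, i.e. technical noise only, which is exactly the regime the
binomial test models.  Passing end-to-end tests therefore demonstrate
correctness of the counting and inference machinery under the stated
model, not calibration on biologically replicated data (the original
workflow delegates that case to a negative-binomial model, out of scope
here).

Test problem sizes: the end-to-end suite uses 2000 three-exon genes
(mean ~30 reads/gene, two samples at a 0.4 read fraction) plus one
deep-coverage cassette gene, about 115k reads in total; unit fixtures are
a few genes each.

## Known limitations

* Gene assignment is containment-based and unstranded; antisense overlap
  double-counts by design ("any gene that contains the aligned
  positions").
* Cassette inclusion excludes exon-body reads (see above); the isoform
  ratio is junction-scaled, not an exon-inclusion PSI.
* The MSC estimate is a point estimate without an uncertainty; its
  sampling SD at low depth (above) should be kept in mind when comparing
  shallow lanes.
* Fisher's exact P-values are conservative; chi-squared takes over only
  when all expected values exceed 5.
* Alternative splice sites and sequence-variant events are not modelled.
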