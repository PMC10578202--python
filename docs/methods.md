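# Methods

## The merging model

`annotweave` treats an annotation as a set of stranded, exon-structured
transcript models on 1-based inclusive coordinates (the GTF convention;
BED and PSL inputs are converted at the reading boundary). The identity
used throughout is the **intron chain**: the ordered intron intervals of
a spliced transcript, keyed by chromosome and strand. Two spliced
transcripts may be collapsed into one if and only if their chains are
identical, which restricts any modification to extending the first or
last exonic position — a deliberately conservative rule that cannot
create chimeric models that no input sample contained. The collapsed
model takes the minimum first-exon start and maximum last-exon end over
its members, the union of their source transcriptomes (the detection
count used by the consistency filter), and per-sample TPM maxima.

The published collapse rule is silent on monoexonic transcripts; we
collapse them by stranded transitive interval union and record the rule
per transcript, so it can be disabled (`MergeConfig.monoexonic_collapse`).

**Containment.** A transcript strictly included in another carries no
information and is discarded — but inclusion requires intron-chain
compatibility, not merely extent: a spliced transcript is removed only
when some other model is an *extension* of it (same strand, ≥ 1 bp
overlap, its chain a contiguous sub-chain of the other's, with at least
one extra intron 5′-ward and/or 3′-ward) and its extent lies inside the
other's; a monoexonic transcript only when its interval lies within a
single exon. A transcript whose extent lies inside an incompatible model
(e.g. a monoexonic model spanning an intron) is kept: it documents a
genuinely different structure.

**Reference integration.** Every reference transcript appears in the
output exactly once. A reference transcript whose chain equals a novel
transcript's chain with shorter terminal exon(s) is replaced by the
longer isoform, which keeps the reference transcript ID and biotype; all
other reference models are reported verbatim. For monoexonic reference
transcripts — a case the chain rule cannot express — the analog is
interval containment: a novel monoexonic model strictly containing the
reference interval on the same strand replaces it; when one novel model
overlaps several monoexonic references it is assigned to the
largest-overlap one only, so reference uniqueness is preserved. Novel
transcripts strictly included in reference models are discarded.
Surviving novel transcripts get deterministic IDs (`TAGT%06d`, genes
`TAGG%06d`) in (chromosome, start) order, so re-running is reproducible
and re-merging the output with the reference is a no-op (tested).

**Gene building.** Genes are the connected components of the graph
joining transcripts with ≥ 1 bp of same-strand exonic overlap (a sweep
plus union-find; validated against networkx connected components).
Components containing reference transcripts keep the lexicographically
first reference gene ID.

## Filters

Novel transcripts survive iff `detection_count >= min_transcriptomes`
(default 2) and `max sample TPM >= min_tpm` (default 0.1) — both
inclusive, reading "detected in less than N are discarded" and "does not
reach T" as strict failures below the bound. Each input assembly file
counts as one transcriptome. Reference models are never filtered. The
two filters commute (tested by property).

## Classification

The five positional classes are evaluated in priority order; the first
predicate that holds wins. `Extension` means the candidate adds introns
to a reference chain, `Inclusion` that a reference transcript is an
extension of the candidate, `Overlapping` any remaining same-strand
extent overlap — extent rather than exonic overlap, with exonic overlap
available behind a flag, since the published class list does not
distinguish the two. Monoexonic transcripts are classified separately.

"Known" means exact structural correspondence with a reference model:
chain identity for spliced transcripts; for monoexonic transcripts we
take the strictest reading — coordinate identity of (chromosome, strand,
start, end). Gene novelty is known/unknown when all members are, else
enriched.

Unified biotypes give priority to mRNA/protein_coding from either source
(reference `transcript_biotype` or `feelnc_biotype`), then lncRNA, then
FEELnc's TUCp/noORF, else uncharacterized. A gene is mRNA if any member
transcript is, else lncRNA if any is, else uncharacterized.

lncRNA positional classes use the closest mRNA within a 100 kb window
(the window size is our choice; the class names do not fix one):
overlapping an mRNA extent ⇒ genic (exonic on ≥ 1 bp exon overlap, else
intronic); otherwise upstream/downstream is read relative to the mRNA's
own orientation, and antisense-upstream/downstream are additionally
labelled divergent/convergent. Nearest-mRNA ties break by smaller
distance then lexicographic ID.

## QC metrics

All four metrics are ratios of de-duplicated counts, reported with their
numerators and denominators. Intron canonicity checks the donor/acceptor
dinucleotide pair against {(GT,AG), (GC,AG), (AT,AC)}; on the minus
strand the dinucleotides are reverse-complemented from the forward
sequence. Introns shorter than 4 bp are rejected at validation (the two
dinucleotides would overlap). 3′ completion is the share of distinct
(chromosome, strand, TTS) triples with a same-strand AATAAA/ATTAAA
occurrence at distance < 50 bp, distance being the minimum absolute
difference between the TTS and any motif base; an alternative span mode
(motif start within the transcript's last 30 bp) is provided because
both definitions are in circulation, and neither is presumed canonical.
Peak overlap for 5′ completion is strandless (open-chromatin peaks carry
no strand) and inclusive after BED → 1-based conversion.

## Expression statistics

tau is computed over per-tissue mean TPMs, needs N ≥ 2 tissues and a
positive maximum, and is scale invariant (tested by property). The
specificity call is strict (tau > 0.9), with argmax-tissue assignment
and lexicographic tie-break. Note the deliberate asymmetry, which
follows the respective wordings of the rules: expressed-feature calls
use TPM ≥ 0.1 ("expressed at TPM ≥ 0.1 in ≥ 2 samples"), while
expression breadth uses TPM > 0.1 ("above 0.1 in at least 4 of the 12
samples of a tissue").

Sample similarity is the Pearson correlation of log10(TPM + 0.1) over
all features; a zero-variance sample vector is an error naming the
sample. Clustering is agglomerative with complete linkage on
d = 1 − r (the distance transform is our choice; it is the standard one
for correlation clustering). We implement the agglomeration explicitly
(O(n³), fine for sample-scale inputs) with ties broken by the smallest
participating sample index, making the merge sequence fully
deterministic; scipy's complete linkage serves as an independent oracle
in the tests on tie-free matrices.

## Orthology

PSL alignments are scored `matches + repMatches − misMatches −
qNumInsert − tNumInsert`; the per-query best hit maximizes the score,
then the block count, then file order. A best hit is assigned to the
target transcript with the longest same-strand overlap, computed by
summing block-by-exon bp intersections (PSL blocks do not preserve the
query's exon boundaries after chain mapping, so the per-block sum is the
faithful quantity); ties go to the lexicographically smallest target ID.
Evaluation percentages are rounded half-up to one decimal, the
convention used when reporting such rates, and are always recomputable
from the stored integer counts.

Synteny triplets are (coding, lnc, coding) runs of consecutive genes
ordered by (chromosome, start) irrespective of strand. Triplet matching
treats the orthology-mapped flanking pair as unordered by default —
robust to local inversions — with a strict ordered mode behind a flag,
since consecutive gene order has no canonical reading direction.

## Synthetic data: what it emulates, and what it does not

The generator lays out non-overlapping single-transcript gene loci with
interleaved protein-coding/lncRNA biotypes (so synteny triplets exist by
construction), writes a random genome, then *plants* the sequence
features the QC metrics measure: splice-site dinucleotides with an exact
canonical share, polyA hexamers within 50 bp of a designated share of
TTSs, and peaks over a designated share of TSSs. Accidental polyA
hexamers are scrubbed from the random sequence first (the motifs are
A/T-only, so a planted C cannot recreate one), which is what makes the
planted QC fractions exact rather than approximate. Per-sample
assemblies contain chain-preserving jittered copies of reference models,
K novel isoforms (first-intron donor shifted 12 bp inward — a chain that
neither matches nor is contained in the reference) placed in ≥ 2 samples
at TPM ≥ 0.5, terminal extensions in ≥ 2 samples, and intergenic noise
placed in exactly 1 sample or at TPM 0.05. The expression design is 7
tissues × 3 stages × 4 replicates (84 samples), log-normal TPMs
(log-mean 1, log-sd 1, multiplicative noise log-sd 0.5), with planted
tissue-specific genes at a 50× effect — scales chosen so the whole suite
runs in seconds while every planted quantity is still recovered exactly.

Every random draw derives from the master seed through a stable
per-artifact label, so changing one fixture never perturbs another and
all emitted files are byte-identical across runs (tested).

What passing these tests does **not** show: real assemblies have
coverage-dependent fragmentations, soft-clipped terminal exons beyond
our jitter model, shared exons between overlapping genes, multi-isoform
reference loci, and splice-site sequence context beyond the planted
dinucleotides. The synthetic study demonstrates algorithmic correctness
against recorded ground truth, not robustness to every artifact of real
RNA-seq data.

## Numerical and degenerate-input choices

* Inclusive filter thresholds; strict tau threshold; strict < 50 bp
  polyA distance — each following the wording of its rule.
* A novel transcript with an empty TPM map fails the expression filter
  (max of nothing is 0).
* Unstranded transcripts are dropped at GTF ingestion with a counted
  warning (every downstream rule is strand-aware); a flag turns this
  into a hard error. Exon rows of one transcript on two chromosomes or
  strands are a hard error (no trans-splicing).
* Duplicate reference chains: reference-ID inheritance picks the
  lexicographically smallest transcript ID.
* Percentages are Decimal-rounded half-up to one decimal, avoiding
  binary-float round-to-even surprises at the reporting precision.
* Empty peak sets give 0 completion with a warning rather than an error.

## Known limitations

Single-transcript genes in the generator; no fuzzy splice-site
tolerance (a 1 bp splice shift is a different chain, by design); no
coverage-guided merging; FEELnc's coding-potential classifier is out of
scope (its labels are inputs; only candidate eligibility and positional
classes are implemented); GTF2.2 only, no GFF3.
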