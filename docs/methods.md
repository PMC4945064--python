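# Methods

This note documents the models and procedures implemented in `refusion`,
the defaults and why they were chosen, what the synthetic data does and
does not emulate, and the numerical conventions.

## Coordinates and annotation model

All internal coordinates are 0-based half-open. RepeatMasker `.out`
(1-based inclusive) and GFF3 (1-based inclusive) are converted at the
parsing boundary; BED is native. Repeat classes are normalized to a closed
vocabulary {SINE, LINE, LTR, DNA, SSR, Low_complexity, Satellite}
(`Simple_repeat` → SSR; the class is the part of `class/family` before the
slash). Unknown classes are retained with a flag and a warning and are
excluded from class-frequency denominators unless mapped through a
user-supplied table.

"Within an exon" and "within a repeat" mean **full containment** of the
aligned interval, not mere overlap; the repeat label additionally requires
zero exon overlap, so a repeat copy inside an exon can never be the repeat
side of a fusion. Containment is stricter than overlap and avoids
ambiguous half-in intervals; an overlap mode exists as a switch.
Interval queries go through per-chromosome interval trees and are tested
for exact equality against linear scans.

Nearest-repeat queries anchor on the exon and measure the distance to
either the repeat's start or its end (both anchorings are computed and
reported side by side; on symmetric data they agree). Ties are broken
toward the transcription-sense upstream repeat, then by (start, name) for
determinism. The nearest repeat's region is *intronic* when it lies inside
the exon's gene body, else *intergenic*.

## Mapping model

The mapper is a k-mer seed index (default k = 12) with pigeonhole search:
a query is cut into `max_mismatches + 1` disjoint chunks, so any placement
within the mismatch budget matches at least one chunk exactly; candidates
are verified by full ungapped comparison on both strands. It is exhaustive
up to a hit cap (default 100,000) and `N` never matches anything. This is
deliberately a toy-scale, alignment-free-of-gaps model: the pipeline's
junction logic needs exact ungapped segment placement, not spliced
alignment, and the unit tests hold the mapper to exact hit-set equality
with a brute-force full scan. Performance targets are genomes of a few
hundred kb.

Split-alignment enumeration tries every split position leaving at least
`min_anchor` (25) bases on each side and emits every same-strand segment
pair within the total mismatch budget (1), flagging non-unique sides.
Co-linear contiguous pairs are skipped — a read that reconstructs
contiguously is not a chimera. When one read admits several equal-scoring
splits (the classic shift ambiguity when the junction's flanking bases
repeat), the per-read representative is chosen by minimal mismatches, then
presence of a canonical splice motif at the implied junction, then lowest
junction coordinate — i.e. motif-guided junction placement.

## Event calling and qualifying

Events are keyed by the exact junction coordinate pair; junctions one base
apart are distinct events. The raw aggregated event list is retained in
full for reporting (annotations are refreshed from the union of
supporting alignments after aggregation); `read_filter_ok` marks events
with ≥ `min_reads` (2) reads in at least one sample, and the authoritative
per-sample read filter is applied at the qualifying stage. This keeps one
filter point while preserving the two-pass character of annotate →
aggregate → re-annotate → filter.

Splice-motif checking reads the two bases just inside each end of the
junction gap on the transcribed strand (the fused gene's strand; minus
junctions are checked on the reverse complement). The donor set is
{GT, GC} — the canonical and minor-canonical donors — with a strict
GT-only mode available; the acceptor is AG. A junction at a contig edge is
motif-failed with an explicit flag.

Qualifying rule per group: ≥ 2 samples of the group with ≥ `min_reads`
junction reads. The optional `strict_one_read_rule` additionally requires,
for events where some sample has exactly 1 read, that the remaining
samples all have > `min_reads` reads; with the rule off, counts like
(1,2,2) qualify under the base 2-of-3 reading. Both behaviours are tested
against a fixed decision table, and qualifying is monotone: raising
`min_reads` or enabling the strict rule never enlarges the qualifying set.
Orientation (`RE5p_exon3p` vs `exon5p_RE3p`) is derived from the fused
gene's strand, which makes it independent of the sequenced strand of the
read. No distance cap between repeat and exon is imposed by default.

## Hard-clip estimator

The permissive companion maps the terminal 25-mers of every
not-full-length-mappable read independently. Classification buckets are
mutually exclusive and conserve the candidate count (checked by
assertion): mitochondrial hits exclude the read first (an intron-less,
polycistronic genome yields chimera-like reads that are not splice
fusions); both ends repeat-like is a repeat–repeat discard; a repeat end
with an exon-mapping opposite end is a fusion only when the exon end has
exactly one genomic hit, otherwise an `exon_multimap` discard; the rest is
unassigned (including reads of 25–49 nt, which pass QC but cannot yield
two clips). The repeat end may multi-map freely; when it does, the
representative repeat locus for event grouping is the minimum by
(chromosome, start) over hit loci — deterministic and identical across
reads of the same fusion. Event granularity for the ≥ 2-read rule is the
(gene, representative repeat locus) pair, collapsible to gene level. A
gene enters a group's set when one of its events has ≥ `min_reads` reads
in **every** replicate of that group (the stricter reading of "present in
all samples"; a switch relaxes it).

## Statistics

*log₂ fold change* is `log2(mean(group2) / mean(group1))` on raw junction
counts. The pseudo-count wording for zeros is ambiguous, so the default
(`any_zero`) adds 1 to every sample of an event whenever any of its
samples is 0 — symmetric and always defined — while `both_groups_zero`
implements the literal reading (bump only when the event is all-zero) and
`raw` reports signed infinities. Events without zeros are bit-identical
across modes.

*Empirical p* for event *i* is the fraction of events with fold change
≥ that of *i* (a population-relative, one-directional rule; the strictly
largest of N events gets 1/N, the smallest gets 1). Because down-regulated
events are of equal interest, a `signed` mode reverses the tail for
negative fold changes.

*Wilcoxon rank-sum*: W is the midrank sum of group 1. For per-group n ≤ 10
the two-sided p is exact — all C(n, n₁) rank assignments are enumerated
and compared by |W − E[W]| — which handles ties correctly; larger samples
use the tie-corrected normal approximation. All-identical data returns
p = 1.

*Bootstrap* (B = 10,000 default): each replicate redraws both groups with
replacement from their own observed counts and recomputes the rank-sum
statistic centred at its null mean (centring makes "positive/negative
observed" well defined). p = n/B where n counts resampled statistics
strictly greater than a positive observed statistic or strictly smaller
than a negative one; an observed statistic of exactly 0 counts resamples
≥ 0, so identical-constant groups give p ≈ 1, the natural null limit. At
n = 3 per group the resample space is finite (3³ × 3³ ordered draws) and
an exhaustive enumerator provides the exact value; the estimator is held
within 0.02 of it. One seeded generator drives all resampling; B, seed
and mode are recorded in output headers. No multiple-testing correction is
applied by default (Benjamini–Hochberg is a flag).

*Observed vs expected classes*: the expectation is the class × region
tally of every exon's nearest repeat (both anchorings); each class's
observed event count is tested against its expected fraction with a
two-sided binomial test at α = 0.05. A plus-strand-only restriction of the
repeat set is available as a flag. Classes absent from the expectation are
flagged untestable rather than dropped silently.

## Isoform usage and protein consequences

Junction-read counting for usage comparison requires ≥ 15 aligned bases on
**each** side of the junction by default; the literal "at least 15 bp from
one side" reading is a mode flag. The symmetric default reflects that a
1|75 split cannot support a junction assignment. CPM is
count × 10⁶ / total aligned reads of the sample. Per tissue/stage label
the comparison reports mean ± SD (SE for n = 2) of fusion and non-fusion
CPM and a presence flag (FT-only / non-fusion-only / both / neither). The
"corresponding" exon–exon junction is the annotated junction involving the
fused exon on the side the repeat replaces (upstream for `RE5p_exon3p`),
falling back to the opposite side for terminal exons.

Reconstruction joins the repeat-derived segment to the annotated exon
chain of the transcript containing the fused exon with the longest CDS
(reported in output); `RE5p` models keep the chain from the fused exon
onward, `exon5p` models end in the repeat segment. Consequence rules:

- start codon inside the retained chain of an `RE5p` fusion →
  **alternative promoter**, full-length protein (the retained suffix
  necessarily contains the remaining CDS);
- start codon upstream of the fused exon → **truncation**: the reading
  frame of the first retained coding exon is inherited from the annotated
  CDS phase and scanned codon-by-codon for the first in-frame ATG; Δaa is
  its codon index in the annotated protein, and the predicted protein is
  the annotated suffix from that methionine. An in-frame stop before any
  ATG is reported as `frame_disrupted`. ATGs inside the repeat-derived
  segment are ignored by default (switchable), since recruitment of
  downstream exonic starts is the modelled mechanism;
- `exon5p` fusions retaining the start codon are **exonization** (a 3'
  alteration; residue-level effects of running into the repeat are not
  modelled), and ones losing it are non-coding.

Predictions are validated against an independent oracle that translates
the reconstructed fusion mRNA directly from the reported ATG.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the target study design: 2 groups × 3 replicates,
76-nt single-end reads, six repeat classes, fusions of all three
architectures with canonical GT/GC–AG motifs written into the sequence,
non-canonical (TT–AG) negative controls, a ≥ 3-copy near-identical repeat
family as a multi-mapping stressor, and contaminating unspliced pre-mRNA,
exon–exon splice reads and repeat–repeat chimeras. Each gene cassette is
built in transcript sense and placed forward or reverse-complemented, so
both strands are exercised while planted motifs remain correct by
construction. Coding genes carry a 199-residue ORF starting in exon 2;
truncation genes plant an extra in-frame ATG at codon 120 (inside exon 4),
so the expected Δaa is 120.

Depths are fixed counts per event and sample by default, so read
bookkeeping is exactly conserved and recovery guarantees are
deterministic; a Poisson mode exists for stochastic tests. Junction-read
breakpoints are drawn uniformly over offsets leaving ≥ 25 bases on each
side (`offset_margin`), i.e. every emitted junction read is informative
for a 25-base-anchor caller; set the margin to 1 to emulate raw physical
spanning, at the cost of the deterministic recovery guarantees.
`repeats_per_class` is a per-class minimum: structural loci placed by the
cassettes are topped up with decoy loci in the intergenic tail. Quality
strings are constant; QC trimming is represented by a pass-through length
filter.

Not emulated: indels and gapped alignment, PCR duplicates, paired-end
insert geometry (mates are treated as independent single-end reads,
matching the junction logic), sequencing-quality structure, genome-scale
repeat density, and read-through (contiguous, unspliced) fusions — the
splice-motif requirement excludes those by design, and the caller makes no
attempt to recover them. Passing tests therefore demonstrate the
correctness of the filtering logic and statistics under clean, known-truth
conditions, not recall on real multi-mapping-heavy mammalian data.

## Problem sizes and defaults

Default simulated genomes are 150 kb with 12 genes (one fusion each, three
negative controls, 150 noise reads per sample at depth 4); the acceptance
script uses depth 3 and 20% unspliced contamination. These sizes keep the
full pipeline — including the exhaustive mapper and B = 10,000 bootstrap —
to a few seconds while exercising every filter with non-trivial
multiplicity. The mm9-scale gene denominator (29,922) used for
genome-wide percentage reporting is a configurable constant
(`total_genes`); toy runs default to the simulated gene count.

## Known limitations

- The mapper is exhaustive-ungapped only and quadratic in the worst case;
  it is not a replacement for a production aligner on real genomes.
- Two-hop chimeras (repeat → repeat → exon) are reported as separate
  events when both junctions are called; chained reconstruction into one
  model is not attempted.
- Junction counts are sparse evidence, not expression estimates; no
  size-factor normalization or count-model (negative binomial) machinery
  is provided, by design.
- Hard-clip fusion identity is locus-pair-based; exact junctions are not
  reconstructed from clipped pairs.
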