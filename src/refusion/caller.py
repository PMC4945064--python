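"""Repeat<->exon fusion-event calling from split-read junction candidates.

Implements the filter cascade of the splice-aware pipeline: each side of a
chimeric split alignment is classified against the annotation (one side
must lie in a repeat locus and overlap no exon, the other must be contained
in an annotated exon of exactly one gene), the junction must be flanked by
canonical GT/GC-AG dinucleotides on the transcribed strand, candidates are
aggregated into events keyed by the exact junction coordinate pair, and an
event qualifies when >=2 supporting reads are seen in >=2 of the replicates
of one experimental group (with an optional stricter handling of
single-read samples).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

from .annotation import Exon, GenomeBundle, RepeatLocus, revcomp
from .mapping import JunctionCandidate

DONORS_CANONICAL = ("GT", "GC")
ACCEPTOR = "AG"


@dataclass
class SideCall:
    """Result of classifying one candidate: repeat side + exon side."""
    repeat_locus: RepeatLocus
    repeat_interval: tuple[int, int]
    exon: Exon
    exon_interval: tuple[int, int]
    gene_id: str
    orientation: str          # RE5p_exon3p | exon5p_RE3p
    repeat_is_left: bool


@dataclass
class Rejection:
    reason: str               # exon_exon | repeat_repeat | ambiguous_gene | unclassified


@dataclass
class FusionEvent:
    event_id: str
    chrom: str
    junction: tuple[int, int]
    repeat_locus: RepeatLocus
    repeat_interval: tuple[int, int]
    exon: Exon
    exon_interval: tuple[int, int]
    gene_id: str
    orientation: str
    donor: str = ""
    acceptor: str = ""
    motif_ok: bool = False
    edge_flag: bool = False
    counts: dict[str, int] = field(default_factory=dict)
    read_filter_ok: bool = False   # >= min_reads in at least one sample
    section_ok: bool = True        # both aligned sections >= min_section
    unique_ok: bool = True         # both sides uniquely mapped
    qualifying_groups: list[str] = field(default_factory=list)

    @property
    def qualifying(self) -> bool:
        return bool(self.qualifying_groups)

    @property
    def re_class(self) -> str:
        return self.repeat_locus.re_class


@dataclass
class FusionGene:
    gene_id: str
    events: list[FusionEvent]

    @property
    def qualifying(self) -> bool:
        return any(e.qualifying for e in self.events)


# ---------------------------------------------------------------------------
# Side classification
# ---------------------------------------------------------------------------

def _side_label(bundle: GenomeBundle, chrom, start, end):
    """(kind, payload): exon hits (contained, unique-gene logic applied by
    caller), repeat containment with the no-exon-overlap requirement."""
    exon_hits = bundle.exons_overlapping(chrom, start, end)
    contained_exons = [e for e in exon_hits if e.start <= start and end <= e.end]
    if contained_exons:
        return "exon", contained_exons
    reps = [r for r in bundle.repeats_overlapping(chrom, start, end)
            if r.start <= start and end <= r.end]
    if reps and not exon_hits:
        return "repeat", reps
    return "other", []


def classify_sides(cand: JunctionCandidate, bundle: GenomeBundle):
    """Classify the two sides of a candidate as repeat + exon, or reject.

    Repeat-repeat and exon-exon chimeras are rejected (they are data, not
    errors); the exon side must identify exactly one gene. Orientation is
    taken from the fused gene's strand: on '+' the genome-left side is the
    transcript 5' side, on '-' the genome-right side is.
    """
    lc, ls, le, _ = cand.left_segment
    rc, rs, re_, _ = cand.right_segment
    lkind, lhits = _side_label(bundle, lc, ls, le)
    rkind, rhits = _side_label(bundle, rc, rs, re_)

    if lkind == "exon" and rkind == "exon":
        return Rejection("exon_exon")
    if lkind == "repeat" and rkind == "repeat":
        return Rejection("repeat_repeat")
    if {lkind, rkind} != {"repeat", "exon"}:
        return Rejection("unclassified")

    if lkind == "repeat":
        rep_hits, rep_iv = lhits, (ls, le)
        exon_hits, exon_iv = rhits, (rs, re_)
        repeat_is_left = True
    else:
        rep_hits, rep_iv = rhits, (rs, re_)
        exon_hits, exon_iv = lhits, (ls, le)
        repeat_is_left = False

    genes = sorted({e.gene_id for e in exon_hits})
    if len(genes) != 1:
        return Rejection("ambiguous_gene")
    gene_id = genes[0]
    # prefer the transcript-exon with the longest CDS transcript, stable order
    gene = bundle.genes[gene_id]
    exon = max(exon_hits,
               key=lambda e: (gene.transcript_cds_length(e.transcript_id),
                              -e.exon_index, e.transcript_id))
    strand = gene.strand
    if strand == "+":
        orientation = "RE5p_exon3p" if repeat_is_left else "exon5p_RE3p"
    else:
        orientation = "exon5p_RE3p" if repeat_is_left else "RE5p_exon3p"
    return SideCall(rep_hits[0], rep_iv, exon, exon_iv, gene_id,
                    orientation, repeat_is_left)


# ---------------------------------------------------------------------------
# Splice motif
# ---------------------------------------------------------------------------

def splice_motif_check(
    chrom: str,
    junction: tuple[int, int],
    strand: str,
    sequences: dict[str, str],
    strict_gt_only: bool = False,
) -> tuple[str, str, bool, bool]:
    """Read donor/acceptor dinucleotides inside the junction gap.

    On the transcribed ('+') strand the two bases after the left coordinate
    must be a donor (GT, or GC unless ``strict_gt_only``) and the two bases
    before the right coordinate must be AG; minus-strand junctions are
    checked on the reverse complement. Returns (donor, acceptor, motif_ok,
    edge_flag); a junction at a contig edge is motif_ok=False with the flag
    set.
    """
    left_end, right_start = junction
    seq = sequences[chrom]
    if left_end + 2 > len(seq) or right_start - 2 < 0 or right_start > len(seq):
        return "", "", False, True
    if strand == "+":
        donor = seq[left_end : left_end + 2]
        acceptor = seq[right_start - 2 : right_start]
    else:
        donor = revcomp(seq[right_start - 2 : right_start])
        acceptor = revcomp(seq[left_end : left_end + 2])
    donors = ("GT",) if strict_gt_only else DONORS_CANONICAL
    return donor, acceptor, donor in donors and acceptor == ACCEPTOR, False


# ---------------------------------------------------------------------------
# Candidate selection + event aggregation
# ---------------------------------------------------------------------------

def select_best_candidates(
    candidates: list[JunctionCandidate],
    bundle: GenomeBundle,
    strict_gt_only: bool = False,
) -> list[JunctionCandidate]:
    """Pick one candidate per read: minimal mismatches, canonical motif
    preferred (splice-motif-guided placement resolves the shift ambiguity
    when the same read admits several equal-scoring splits), then lowest
    junction coordinates for determinism."""
    by_read: dict[tuple[str, str], list[JunctionCandidate]] = defaultdict(list)
    for c in candidates:
        by_read[(c.sample_id, c.read_id)].append(c)
    out = []
    for key in sorted(by_read):
        group = by_read[key]

        def rank(c: JunctionCandidate):
            side = classify_sides(c, bundle)
            if isinstance(side, SideCall):
                strand = bundle.genes[side.gene_id].strand
                *_, ok, _ = splice_motif_check(c.chrom, c.junction, strand,
                                               bundle.sequences, strict_gt_only)
            else:
                ok = False
            return (c.mismatches, 0 if ok else 1, c.junction)

        out.append(min(group, key=rank))
    return out


def call_events(
    candidates: list[JunctionCandidate],
    bundle: GenomeBundle,
    samples: list[str] | None = None,
    min_reads: int = 2,
    min_section: int = 25,
    strict_gt_only: bool = False,
    require_unique: bool = True,
) -> tuple[list[FusionEvent], Counter]:
    """Aggregate side-classified candidates into fusion events.

    Candidates are grouped by their exact junction coordinate pair (two
    junctions one base apart are distinct events); per-sample supporting
    read counts are tallied; annotations are (re)derived from the
    aggregated interval union, refreshing repeat/exon identity after
    aggregation. The raw event list retains everything; ``read_filter_ok``
    flags events with >= min_reads reads in at least one sample, and
    ``section_ok`` flags events whose aligned sections are both
    >= min_section. The authoritative per-sample >=2 filter is applied by
    :func:`qualifying_events`. Returns (events, rejection counter).
    """
    rejections: Counter = Counter()
    grouped: dict[tuple, list[tuple[JunctionCandidate, SideCall]]] = defaultdict(list)
    for cand in candidates:
        if require_unique and not (cand.left_unique and cand.right_unique):
            rejections["non_unique"] += cand.support
            continue
        side = classify_sides(cand, bundle)
        if isinstance(side, Rejection):
            rejections[side.reason] += cand.support
            continue
        grouped[(cand.chrom, cand.junction)].append((cand, side))

    events: list[FusionEvent] = []
    sample_list = samples or sorted({c.sample_id for c in candidates})
    for i, key in enumerate(sorted(grouped), 1):
        chrom, junction = key
        members = grouped[key]
        # refresh annotation from the union of supporting alignments
        rep_iv = (min(s.repeat_interval[0] for _, s in members),
                  max(s.repeat_interval[1] for _, s in members))
        exon_iv = (min(s.exon_interval[0] for _, s in members),
                   max(s.exon_interval[1] for _, s in members))
        side = members[0][1]
        counts = {s: 0 for s in sample_list}
        for cand, _ in members:
            counts[cand.sample_id] = counts.get(cand.sample_id, 0) + cand.support
        strand = bundle.genes[side.gene_id].strand
        donor, acceptor, motif_ok, edge = splice_motif_check(
            chrom, junction, strand, bundle.sequences, strict_gt_only)
        events.append(FusionEvent(
            event_id=f"E{i:04d}", chrom=chrom, junction=junction,
            repeat_locus=side.repeat_locus, repeat_interval=rep_iv,
            exon=side.exon, exon_interval=exon_iv, gene_id=side.gene_id,
            orientation=side.orientation, donor=donor, acceptor=acceptor,
            motif_ok=motif_ok, edge_flag=edge, counts=counts,
            read_filter_ok=max(counts.values(), default=0) >= min_reads,
            section_ok=(rep_iv[1] - rep_iv[0] >= min_section
                        and exon_iv[1] - exon_iv[0] >= min_section),
        ))
    return events, rejections


def event_qualifies_in_group(
    counts: list[int],
    min_reads: int = 2,
    strict_one_read_rule: bool = False,
) -> bool:
    """Per-group qualifying rule on replicate junction-read counts.

    Base rule: >= min_reads supporting reads in >= 2 replicates of the
    group. Strict addition: when some replicate has exactly 1 read, the
    other replicates must all have > min_reads reads.
    """
    if sum(1 for c in counts if c >= min_reads) < 2:
        return False
    if strict_one_read_rule and any(c == 1 for c in counts):
        others = [c for c in counts if c != 1]
        if not others or not all(c > min_reads for c in others):
            return False
    return True


def qualifying_events(
    events: list[FusionEvent],
    design: dict[str, str],
    min_reads: int = 2,
    strict_one_read_rule: bool = False,
    require_motif: bool = True,
) -> tuple[list[FusionEvent], list[FusionGene]]:
    """Apply the per-group qualifying rule; group events into genes.

    An event qualifies when it passes the read-count rule in at least one
    group (and, by default, carries a canonical splice motif and passes the
    section/uniqueness filters). A gene qualifies when >= 1 of its events
    qualifies.
    """
    groups: dict[str, list[str]] = defaultdict(list)
    for sample, grp in design.items():
        groups[grp].append(sample)
    for e in events:
        missing = [s for s in e.counts if s not in design]
        if missing:
            raise ValueError(f"samples {missing} missing from design")
        e.qualifying_groups = []
        if require_motif and not e.motif_ok:
            continue
        if not (e.section_ok and e.unique_ok):
            continue
        for grp, samps in groups.items():
            if event_qualifies_in_group([e.counts.get(s, 0) for s in samps],
                                        min_reads, strict_one_read_rule):
                e.qualifying_groups.append(grp)
        e.qualifying_groups.sort()
    qualified = [e for e in events if e.qualifying]
    by_gene: dict[str, list[FusionEvent]] = defaultdict(list)
    for e in events:
        by_gene[e.gene_id].append(e)
    fusion_genes = [FusionGene(g, evs) for g, evs in sorted(by_gene.items())]
    return qualified, fusion_genes


def class_frequencies(events: list[FusionEvent]) -> dict[str, dict]:
    """Per-repeat-class event counts and fractions over classified events.

    Events whose repeat class is outside the closed vocabulary are excluded
    from the denominator (they are retained upstream with a flag).
    """
    counted = [e for e in events if e.repeat_locus.known_class]
    total = len(counted)
    tally = Counter(e.re_class for e in counted)
    return {
        cls: {"count": n, "fraction": n / total if total else 0.0}
        for cls, n in sorted(tally.items())
    }
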