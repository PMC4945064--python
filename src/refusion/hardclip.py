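"""Broad estimation of fusion-expressing genes by terminal hard clipping.

A deliberately permissive companion to the splice-aware caller: reads that
fail to map full length are truncated to their terminal 25-mers, each end
is mapped independently (multi-hits tolerated up to a large cap), and a
read is a fusion candidate when one end lies within a repeat locus (not
inside an exon) while the other maps uniquely inside an annotated exon,
identifying the gene. No splice motif, anchor or replicate rule is
imposed, so on clean data the resulting gene set is a superset of the
caller's. Mitochondrial hits are excluded (an intron-less polycistronic
genome produces chimera-like reads that are not fusions).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .annotation import GenomeBundle
from .mapping import MappingResult, SeedIndex, map_read_full, map_segment

CLIP_LENGTH = 25


@dataclass
class ClippedPair:
    read_id: str
    sample_id: str
    end5: MappingResult | None
    end3: MappingResult | None
    classification: str = "unassigned"
    # fusion | repeat_repeat | unassigned | mito_excluded | exon_multimap
    orientation: str = ""      # RE5p_exon3p | exon5p_RE3p when fusion
    gene_id: str = ""
    repeat_id: str = ""        # representative repeat locus when fusion


def select_chimera_candidates(
    reads: list[tuple[str, str]],
    index: SeedIndex,
    max_mismatches: int = 1,
    cap: int = 100_000,
) -> list[tuple[str, str]]:
    """Reads (id, seq) with no full-length ungapped hit at <= max_mismatches."""
    return [(rid, seq) for rid, seq in reads
            if not map_read_full(index, seq, max_mismatches, cap).mapped]


def clip_and_map(
    read_id: str,
    seq: str,
    index: SeedIndex,
    sample_id: str = "",
    clip_length: int = CLIP_LENGTH,
    max_mismatches: int = 1,
    cap: int = 100_000,
) -> ClippedPair:
    """Map the first and last ``clip_length`` bases independently.

    Reads shorter than two clips cannot be classified and stay unassigned
    with unmapped ends.
    """
    if len(seq) < 2 * clip_length:
        return ClippedPair(read_id, sample_id, None, None)
    end5 = map_segment(index, seq[:clip_length], max_mismatches, cap)
    end3 = map_segment(index, seq[-clip_length:], max_mismatches, cap)
    return ClippedPair(read_id, sample_id, end5, end3)


def _end_status(bundle: GenomeBundle, res: MappingResult, clip_length: int):
    """Summarize one clipped end against the annotation.

    in_repeat: any hit contained in a repeat locus and overlapping no exon;
    exon_unique: the end has exactly one genomic hit and it lies in an exon.
    """
    in_repeat = False
    repeat_ids = []
    exon_gene = None
    mito = False
    for h in res.hits:
        if h.chrom == bundle.mito_chrom:
            mito = True
            continue
        s, e = h.pos, h.pos + clip_length
        exon_hits = bundle.exons_overlapping(h.chrom, s, e)
        contained = [x for x in exon_hits if x.start <= s and e <= x.end]
        if contained:
            exon_gene = sorted({x.gene_id for x in contained})[0]
            continue
        if exon_hits:
            continue
        reps = [r for r in bundle.repeats_overlapping(h.chrom, s, e)
                if r.start <= s and e <= r.end]
        if reps:
            in_repeat = True
            repeat_ids.extend(r.locus_id for r in reps)
    exon_unique = res.unique and exon_gene is not None
    multimapped = len(res.hits) > 1 or res.capped
    return {"in_repeat": in_repeat, "repeat_ids": sorted(set(repeat_ids)),
            "exon_gene": exon_gene, "exon_unique": exon_unique,
            "multimapped": multimapped, "mito": mito}


def classify_pair(pair: ClippedPair, bundle: GenomeBundle,
                  clip_length: int = CLIP_LENGTH) -> ClippedPair:
    """Assign one classification bucket to a mapped pair (funnel step).

    Order: mitochondrial hits exclude the read; both ends repeat-like is a
    repeat-repeat discard; a repeat end plus an exon-mapping opposite end
    is a fusion only when the exon end maps exactly once genome-wide,
    otherwise it is an exon_multimap discard; everything else is
    unassigned.
    """
    if pair.end5 is None or pair.end3 is None:
        pair.classification = "unassigned"
        return pair
    s5 = _end_status(bundle, pair.end5, clip_length)
    s3 = _end_status(bundle, pair.end3, clip_length)
    if s5["mito"] or s3["mito"]:
        pair.classification = "mito_excluded"
        return pair
    if s5["in_repeat"] and s3["in_repeat"]:
        pair.classification = "repeat_repeat"
        return pair
    for rep_end, exon_end, orientation in ((s5, s3, "RE5p_exon3p"),
                                           (s3, s5, "exon5p_RE3p")):
        if rep_end["in_repeat"] and exon_end["exon_gene"] is not None:
            if exon_end["exon_unique"]:
                pair.classification = "fusion"
                pair.orientation = orientation
                pair.gene_id = exon_end["exon_gene"]
                pair.repeat_id = rep_end["repeat_ids"][0]
                return pair
            if exon_end["multimapped"]:
                pair.classification = "exon_multimap"
                return pair
    pair.classification = "unassigned"
    return pair


def run_hardclip(
    reads_by_sample: dict[str, list[tuple[str, str]]],
    index: SeedIndex,
    bundle: GenomeBundle,
    clip_length: int = CLIP_LENGTH,
    max_mismatches: int = 1,
    cap: int = 100_000,
) -> tuple[list[ClippedPair], dict[str, Counter]]:
    """Full funnel: candidate selection, clipping, classification.

    Returns classified pairs plus a per-sample funnel table whose buckets
    sum to the candidate count (conservation is asserted).
    """
    pairs: list[ClippedPair] = []
    funnel: dict[str, Counter] = {}
    for sample in sorted(reads_by_sample):
        reads = reads_by_sample[sample]
        cands = select_chimera_candidates(reads, index, max_mismatches, cap)
        buckets: Counter = Counter()
        buckets["total_reads"] = len(reads)
        buckets["not_full_length_mapped"] = len(cands)
        for rid, seq in cands:
            pair = clip_and_map(rid, seq, index, sample, clip_length,
                                max_mismatches, cap)
            classify_pair(pair, bundle, clip_length)
            buckets[pair.classification] += 1
            pairs.append(pair)
        assert sum(buckets[k] for k in
                   ("fusion", "repeat_repeat", "exon_multimap",
                    "mito_excluded", "unassigned")) == buckets["not_full_length_mapped"]
        funnel[sample] = buckets
    return pairs, funnel


def estimate_fusion_genes(
    pairs: list[ClippedPair],
    design: dict[str, str],
    min_reads: int = 2,
    total_genes: int | None = None,
    granularity: str = "gene_repeat",
) -> dict:
    """Per-group fusion gene sets from classified pairs.

    An event is a (gene, representative repeat locus) pair (``gene``
    granularity collapses to the gene). Per group, an event is kept when it
    has >= min_reads reads in every sample of the group; a gene enters the
    group set through any kept event. Reported: per-group gene sets, their
    union, and union/total_genes as a percentage.
    """
    if total_genes is not None and total_genes <= 0:
        raise ValueError("total_genes must be positive")
    groups: dict[str, list[str]] = defaultdict(list)
    for s, g in design.items():
        groups[g].append(s)
    counts: dict[tuple, Counter] = defaultdict(Counter)
    for p in pairs:
        if p.classification != "fusion":
            continue
        key = (p.gene_id, p.repeat_id) if granularity == "gene_repeat" else (p.gene_id,)
        counts[key][p.sample_id] += 1
    group_genes: dict[str, set[str]] = {}
    group_events: dict[str, set[tuple]] = {}
    for grp, samps in sorted(groups.items()):
        kept = {k for k, c in counts.items()
                if all(c.get(s, 0) >= min_reads for s in samps)}
        group_events[grp] = kept
        group_genes[grp] = {k[0] for k in kept}
    union = set().union(*group_genes.values()) if group_genes else set()
    out = {
        "group_genes": group_genes,
        "group_events": group_events,
        "union_genes": union,
        "n_union": len(union),
    }
    if total_genes:
        out["percent_of_genes"] = 100.0 * len(union) / total_genes
    return out


def overlap_with_caller(hardclip_genes: set[str], caller_genes: set[str]) -> dict:
    """Intersection size and the fraction of caller genes also found by
    hard clipping; the fraction is None when the caller set is empty."""
    inter = hardclip_genes & caller_genes
    return {
        "n_overlap": len(inter),
        "fraction_of_caller": (len(inter) / len(caller_genes)
                               if caller_genes else None),
        "overlap_genes": sorted(inter),
    }
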