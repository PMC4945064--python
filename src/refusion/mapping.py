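"""Toy-genome read and segment mapping.

A k-mer seed index supports exhaustive ungapped alignment of short
segments with a bounded mismatch budget on both strands, mirroring a
Bowtie ``-v 1 -m100K`` style search, plus the split-alignment enumeration
that produces chimeric junction candidates. The search is pigeonhole-based
(a query is cut into ``max_mismatches + 1`` disjoint chunks; at least one
chunk must match exactly) and is verified against a naive full scan in the
test suite. Performance targets are toy genomes, not real assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotation import revcomp

_VALID = set("ACGTN")


@dataclass(frozen=True)
class SegmentHit:
    chrom: str
    pos: int  # 0-based leftmost on the forward strand
    strand: str
    mismatches: int


@dataclass
class MappingResult:
    hits: list[SegmentHit] = field(default_factory=list)
    capped: bool = False

    @property
    def unique(self) -> bool:
        return len(self.hits) == 1 and not self.capped

    @property
    def mapped(self) -> bool:
        return bool(self.hits)


@dataclass(frozen=True)
class JunctionCandidate:
    """One read's split alignment: two mapped segments and the junction.

    ``left_segment``/``right_segment`` are (chrom, start, end, strand)
    ordered by genomic position; ``junction`` is (left_end, right_start),
    the exclusive end of the genome-left segment and the start of the
    genome-right one. ``read_5p_is_left`` records whether the read's 5'
    anchor is the genome-left segment (used downstream only as metadata;
    event orientation is derived from the fused gene's strand).
    """

    read_id: str
    sample_id: str
    left_segment: tuple[str, int, int, str]
    right_segment: tuple[str, int, int, str]
    junction: tuple[int, int]
    mismatches: int
    left_unique: bool
    right_unique: bool
    read_5p_is_left: bool = True
    support: int = 1

    @property
    def chrom(self) -> str:
        return self.left_segment[0]


class SeedIndex:
    """Exact k-mer lookup table over the forward strand of every chromosome."""

    def __init__(self, sequences: dict[str, str], k: int = 12):
        if k > 25:
            raise ValueError("seed length k must be <= 25")
        shortest = min(len(s) for s in sequences.values())
        if k > shortest:
            raise ValueError(f"k={k} larger than shortest chromosome ({shortest})")
        self.k = k
        self.sequences = sequences
        self._table: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in sequences.items():
            for i in range(len(seq) - k + 1):
                self._table.setdefault(seq[i : i + k], []).append((chrom, i))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._table.get(kmer, [])


def build_index(sequences: dict[str, str], k: int = 12) -> SeedIndex:
    return SeedIndex(sequences, k)


def _count_mismatches(a: str, b: str, limit: int) -> int:
    """Mismatches between equal-length strings, early-exit past limit.
    N never matches anything (treated as a mismatch everywhere)."""
    n = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            n += 1
            if n > limit:
                return n
    return n


def _scan_one_strand(index: SeedIndex, query: str, strand: str,
                     max_mismatches: int) -> set[tuple[str, int, str, int]]:
    k = index.k
    L = len(query)
    # disjoint chunks: a read with <= max_mismatches errors matches at least
    # one chunk exactly (pigeonhole)
    n_chunks = max_mismatches + 1
    offsets = [i * (L // n_chunks) for i in range(n_chunks)]
    hits: set[tuple[str, int, str, int]] = set()
    seen_pos: set[tuple[str, int]] = set()
    for off in offsets:
        if off + k > L:
            off = L - k
        for chrom, pos in index.lookup(query[off : off + k]):
            start = pos - off
            if start < 0 or start + L > len(index.sequences[chrom]):
                continue
            if (chrom, start) in seen_pos:
                continue
            seen_pos.add((chrom, start))
            mm = _count_mismatches(query, index.sequences[chrom][start : start + L],
                                   max_mismatches)
            if mm <= max_mismatches:
                hits.add((chrom, start, strand, mm))
    return hits


def map_segment(index: SeedIndex, seq: str, max_mismatches: int = 1,
                cap: int = 100_000) -> MappingResult:
    """All ungapped alignments of ``seq`` with <= max_mismatches, both strands.

    Exhaustive up to ``cap`` hits; ``capped`` is set when the cap truncates
    the list (a capped result is never treated as unique downstream).
    """
    seq = seq.upper()
    if set(seq) - _VALID:
        raise ValueError(f"sequence contains non-ACGTN characters: {set(seq) - _VALID}")
    if len(seq) < index.k:
        raise ValueError(f"query shorter than seed length {index.k}")
    raw = _scan_one_strand(index, seq, "+", max_mismatches)
    raw |= _scan_one_strand(index, revcomp(seq), "-", max_mismatches)
    ordered = sorted(raw)
    capped = len(ordered) > cap
    hits = [SegmentHit(c, p, s, m) for c, p, s, m in ordered[:cap]]
    return MappingResult(hits=hits, capped=capped)


def map_read_full(index: SeedIndex, seq: str, max_mismatches: int = 1,
                  cap: int = 100_000) -> MappingResult:
    """Full-length ungapped mapping; an empty result marks a chimera candidate."""
    return map_segment(index, seq, max_mismatches=max_mismatches, cap=cap)


def find_split_alignments(
    index: SeedIndex,
    read_id: str,
    seq: str,
    sample_id: str = "",
    min_anchor: int = 25,
    total_mismatch_budget: int = 1,
    cap: int = 100_000,
) -> list[JunctionCandidate]:
    """Enumerate chimeric split alignments of one read.

    Every split position leaving >= min_anchor bases on each side is tried;
    every (prefix hit, suffix hit) pair on the same strand with combined
    mismatches within the budget yields a candidate. Non-unique sides are
    flagged, not dropped — uniqueness is a downstream filter. Same-strand
    co-linear pairs with no gap (a contiguously mappable read) are skipped:
    such reads are not chimeras.

    Reads shorter than ``2 * min_anchor`` yield no candidates.
    """
    seq = seq.upper()
    if len(seq) < 2 * min_anchor:
        return []
    out: list[JunctionCandidate] = []
    for split in range(min_anchor, len(seq) - min_anchor + 1):
        pre, suf = seq[:split], seq[split:]
        rp = map_segment(index, pre, total_mismatch_budget, cap)
        if not rp.mapped:
            continue
        rs = map_segment(index, suf, total_mismatch_budget, cap)
        if not rs.mapped:
            continue
        for hp in rp.hits:
            for hs in rs.hits:
                if hp.mismatches + hs.mismatches > total_mismatch_budget:
                    continue
                if hp.strand != hs.strand:
                    continue
                # genomic intervals of the two read parts
                pre_iv = (hp.chrom, hp.pos, hp.pos + len(pre), hp.strand)
                suf_iv = (hs.chrom, hs.pos, hs.pos + len(suf), hs.strand)
                if hp.strand == "+":
                    first, second = pre_iv, suf_iv  # transcript order = genome order
                    five_prime_iv = pre_iv
                else:
                    first, second = suf_iv, pre_iv
                    five_prime_iv = pre_iv
                if first[0] == second[0] and first[2] == second[1]:
                    continue  # contiguous, not a chimera
                if (first[0], first[1]) <= (second[0], second[1]):
                    left, right = first, second
                else:
                    left, right = second, first
                out.append(JunctionCandidate(
                    read_id=read_id,
                    sample_id=sample_id,
                    left_segment=left,
                    right_segment=right,
                    junction=(left[2], right[1]),
                    mismatches=hp.mismatches + hs.mismatches,
                    left_unique=(rp if left is pre_iv else rs).unique,
                    right_unique=(rs if left is pre_iv else rp).unique,
                    read_5p_is_left=(five_prime_iv == left),
                ))
    for cand in out:
        assert cand.left_segment[2] - cand.left_segment[1] >= min_anchor
        assert cand.right_segment[2] - cand.right_segment[1] >= min_anchor
    return out


def naive_scan(sequences: dict[str, str], seq: str,
               max_mismatches: int = 1) -> set[tuple[str, int, str, int]]:
    """Brute-force O(L*G) oracle for map_segment (test use)."""
    seq = seq.upper()
    out = set()
    for strand, q in (("+", seq), ("-", revcomp(seq))):
        for chrom, ref in sequences.items():
            for i in range(len(ref) - len(q) + 1):
                mm = _count_mismatches(q, ref[i : i + len(q)], max_mismatches)
                if mm <= max_mismatches:
                    out.add((chrom, i, strand, mm))
    return out
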