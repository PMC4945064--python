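"""Fusion-isoform usage comparison and protein-consequence prediction.

Two analyses live here. The first compares, per tissue/stage label, the
junction-read support of a fusion transcript against the corresponding
exon-exon junction of the same exon in the non-fusion isoform, on a
counts-per-million scale. The second reconstructs the fusion transcript
model (repeat-derived segment joined to the annotated exon chain at the
called junction) and predicts the protein consequence: a repeat acting as
an alternative promoter upstream of an intact ORF, an exonization, or an
N-terminal truncation in which translation must recruit the first
downstream in-frame ATG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .annotation import Exon, GeneModel, revcomp
from .caller import FusionEvent
from .mapping import JunctionCandidate


# ---------------------------------------------------------------------------
# Junction usage
# ---------------------------------------------------------------------------

def count_junction_reads(
    candidates: list[JunctionCandidate],
    chrom: str,
    junction: tuple[int, int],
    min_side: int = 15,
    mode: str = "both",
) -> int:
    """Count reads spanning an exact junction with sufficient overhang.

    ``both`` (default): >= min_side aligned bases required on each side of
    the junction. ``one``: the literal reading — at least one side must
    reach min_side (so a 10|66 split still counts).
    """
    n = 0
    for c in candidates:
        if c.chrom != chrom or c.junction != junction:
            continue
        left = c.left_segment[2] - c.left_segment[1]
        right = c.right_segment[2] - c.right_segment[1]
        ok = (left >= min_side and right >= min_side) if mode == "both" else \
             (left >= min_side or right >= min_side)
        n += c.support if ok else 0
    return n


def normalize_cpm(count: float, total_aligned_reads: int) -> float:
    if total_aligned_reads <= 0:
        raise ValueError("total_aligned_reads must be positive")
    return count * 1e6 / total_aligned_reads


@dataclass(frozen=True)
class JunctionUsage:
    gene_id: str
    event_id: str
    label: str                # tissue / stage / sample label
    ft_count: int
    nonfusion_count: int
    cpm_ft: float
    cpm_nonfusion: float


def compare_isoforms(records: list[JunctionUsage]) -> pd.DataFrame:
    """Per label: mean +/- dispersion of FT and non-fusion CPM.

    Dispersion is the sample SD (ddof=1); for n=2 the SE (SD/sqrt 2) is
    reported instead, and 0 for a single record. The ``expression`` flag
    marks labels as FT-only / non-fusion-only / both / neither.
    """
    if not records:
        raise ValueError("need at least one usage record")
    df = pd.DataFrame([r.__dict__ for r in records])
    rows = []
    for label, sub in df.groupby("label", sort=True):
        n = len(sub)
        row = {"label": label, "n": n}
        for col, name in (("cpm_ft", "ft"), ("cpm_nonfusion", "nonfusion")):
            mean = sub[col].mean()
            sd = sub[col].std(ddof=1) if n > 1 else 0.0
            disp = sd / math.sqrt(n) if n == 2 else sd
            row[f"{name}_mean"] = mean
            row[f"{name}_disp"] = disp
        ft_on = (sub["cpm_ft"] > 0).any()
        nf_on = (sub["cpm_nonfusion"] > 0).any()
        row["expression"] = ("both" if ft_on and nf_on else
                             "FT-only" if ft_on else
                             "non-fusion-only" if nf_on else "neither")
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Transcript reconstruction
# ---------------------------------------------------------------------------

@dataclass
class FtModel:
    """Reconstructed fusion transcript: ordered transcript-sense segments."""
    event_id: str
    gene_id: str
    transcript_id: str
    orientation: str
    strand: str
    segments: list[tuple[str, str, int, int]]   # (kind, chrom, start, end)
    mrna: str                                    # spliced transcript-sense sequence
    junction_pos: int                            # RE/exon boundary within mrna
    fused_exon_index: int


def _seg_seq(sequences, chrom, start, end, strand) -> str:
    s = sequences[chrom][start:end]
    return s if strand == "+" else revcomp(s)


def reconstruct_transcript(
    event: FusionEvent,
    gene: GeneModel,
    sequences: dict[str, str],
) -> FtModel:
    """Join the repeat-derived segment to the annotated exon chain.

    The transcript used is the one containing the fused exon with the
    longest CDS. RE5p events keep the exon chain from the fused exon
    onward; exon5p events keep it up to the fused exon and end in the
    repeat segment. Honors annotated splicing and gene strand.
    """
    candidates = [
        tid for tid, exons in gene.transcripts.items()
        if any(e.start == event.exon.start and e.end == event.exon.end
               for e in exons)
    ]
    if not candidates:
        raise ValueError(
            f"fused exon {event.exon.exon_id} absent from transcripts of "
            f"{gene.gene_id}: {sorted(gene.transcripts)}")
    tid = max(candidates, key=lambda t: (gene.transcript_cds_length(t), t))
    exons = gene.transcripts[tid]
    fused_idx = next(e.exon_index for e in exons
                     if e.start == event.exon.start and e.end == event.exon.end)
    rep_iv = event.repeat_interval
    strand = gene.strand
    rep_seg = ("repeat", event.chrom, rep_iv[0], rep_iv[1])
    rep_seq = _seg_seq(sequences, event.chrom, rep_iv[0], rep_iv[1], strand)
    if event.orientation == "RE5p_exon3p":
        kept = [e for e in exons if e.exon_index >= fused_idx]
        segs = [rep_seg] + [("exon", e.chrom, e.start, e.end) for e in kept]
        mrna = rep_seq + "".join(
            _seg_seq(sequences, e.chrom, e.start, e.end, strand) for e in kept)
        jpos = len(rep_seq)
    else:
        kept = [e for e in exons if e.exon_index <= fused_idx]
        segs = [("exon", e.chrom, e.start, e.end) for e in kept] + [rep_seg]
        exon_part = "".join(
            _seg_seq(sequences, e.chrom, e.start, e.end, strand) for e in kept)
        mrna = exon_part + rep_seq
        jpos = len(exon_part)
    return FtModel(event.event_id, gene.gene_id, tid, event.orientation,
                   strand, segs, mrna, jpos, fused_idx)


# ---------------------------------------------------------------------------
# Protein consequence
# ---------------------------------------------------------------------------

@dataclass
class ConsequenceCall:
    event_id: str
    category: str               # alternative_promoter | exonization | truncation | non_coding
    protein_effect: str         # full_length | n_truncated | frame_disrupted | none
    delta_aa: int | None = None
    recruited_atg: int | None = None   # genomic coord of the recruited A
    transcript_id: str = ""
    annotated_protein_len: int | None = None
    predicted_protein_len: int | None = None
    predicted_protein: str = ""


def _chain_maps(exons: list[Exon]):
    """Transcript-sense coordinate maps over an exon chain."""
    offsets = []
    off = 0
    for e in exons:
        offsets.append(off)
        off += e.end - e.start
    total = off

    def g2t(gpos: int) -> int | None:
        for e, o in zip(exons, offsets):
            if e.start <= gpos < e.end:
                return o + (gpos - e.start if e.strand == "+" else e.end - 1 - gpos)
        return None

    def t2g(tpos: int) -> int:
        for e, o in zip(exons, offsets):
            size = e.end - e.start
            if o <= tpos < o + size:
                d = tpos - o
                return e.start + d if e.strand == "+" else e.end - 1 - d
        raise IndexError(tpos)

    return g2t, t2g, total


def _translate(seq: str) -> str:
    from Bio.Seq import Seq
    aa = str(Seq(seq[: len(seq) - len(seq) % 3]).translate(to_stop=True))
    return aa


def classify_consequence(
    ft: FtModel,
    gene: GeneModel,
    sequences: dict[str, str],
    allow_re_atg: bool = False,
) -> ConsequenceCall:
    """Predict the protein consequence of a reconstructed fusion transcript.

    RE5p fusions retaining the annotated start codon (with the whole CDS
    downstream intact by construction of the retained suffix) are
    alternative promoters expressing the full-length protein. RE5p fusions
    that skip the start codon are truncations: the annotated reading frame
    of the first retained coding exon is inherited and scanned for the
    first in-frame ATG; the truncated protein is the annotated protein
    minus its first delta_aa residues. ATGs inside the repeat-derived
    segment are ignored unless ``allow_re_atg``. exon5p fusions with the
    start codon retained are exonizations (3' alterations are reported but
    not modelled at residue level); ones losing it are non-coding.
    """
    tid = ft.transcript_id
    cds = gene.cds.get(tid, [])
    if not cds:
        return ConsequenceCall(ft.event_id, "non_coding", "none", transcript_id=tid)

    exons = gene.transcripts[tid]
    g2t, t2g, _ = _chain_maps(exons)
    strand = gene.strand
    atg_genomic = cds[0][0] if strand == "+" else cds[-1][1] - 1
    cds_len = sum(e - s for s, e in cds)
    cds_start_t = g2t(atg_genomic)
    annotated_mrna = "".join(
        _seg_seq(sequences, e.chrom, e.start, e.end, strand) for e in exons)
    annotated_protein = _translate(annotated_mrna[cds_start_t : cds_start_t + cds_len])
    ann_len = len(annotated_protein)

    kept = [e for e in exons
            if (e.exon_index >= ft.fused_exon_index
                if ft.orientation == "RE5p_exon3p"
                else e.exon_index <= ft.fused_exon_index)]
    atg_retained = any(
        (e.start <= atg_genomic < e.end) for e in kept)

    if ft.orientation == "exon5p_RE3p":
        if not atg_retained:
            return ConsequenceCall(ft.event_id, "non_coding", "none",
                                   transcript_id=tid,
                                   annotated_protein_len=ann_len)
        cds_end_t = cds_start_t + cds_len
        kept_len = sum(e.end - e.start for e in kept)
        if cds_end_t <= kept_len:
            effect, pred = "full_length", annotated_protein
        else:
            effect, pred = "none", ""
        return ConsequenceCall(ft.event_id, "exonization", effect,
                               transcript_id=tid,
                               annotated_protein_len=ann_len,
                               predicted_protein_len=len(pred) or None,
                               predicted_protein=pred)

    # RE5p_exon3p -----------------------------------------------------------
    if atg_retained:
        return ConsequenceCall(ft.event_id, "alternative_promoter", "full_length",
                               delta_aa=0, recruited_atg=atg_genomic,
                               transcript_id=tid,
                               annotated_protein_len=ann_len,
                               predicted_protein_len=ann_len,
                               predicted_protein=annotated_protein)

    # truncation: inherit the CDS frame of the first retained coding exon
    first_kept = kept[0]
    chain_start_g = first_kept.start if strand == "+" else first_kept.end - 1
    chain_start_t = g2t(chain_start_g)
    offset_in_cds = chain_start_t - cds_start_t
    if offset_in_cds < 0 or offset_in_cds >= cds_len:
        return ConsequenceCall(ft.event_id, "non_coding", "none",
                               transcript_id=tid, annotated_protein_len=ann_len)
    phase = offset_in_cds % 3
    # position in the FT mRNA of the first complete inherited codon
    first_codon_q = ft.junction_pos + ((3 - phase) % 3)
    # with allow_re_atg the same frame lattice is scanned from the start of
    # the repeat-derived segment as well
    q = first_codon_q % 3 if allow_re_atg else first_codon_q
    cds_end_q = ft.junction_pos + (cds_len - offset_in_cds)
    recruited_q = None
    while q + 3 <= len(ft.mrna) and q < cds_end_q:
        codon = ft.mrna[q : q + 3]
        if codon == "ATG":
            recruited_q = q
            break
        if codon in ("TAA", "TAG", "TGA") and q >= first_codon_q:
            break
        q += 3
    if recruited_q is None:
        return ConsequenceCall(ft.event_id, "truncation", "frame_disrupted",
                               transcript_id=tid, annotated_protein_len=ann_len)
    if recruited_q >= ft.junction_pos:
        # codon index within the annotated protein
        delta = (offset_in_cds + (recruited_q - ft.junction_pos)) // 3
        pred = annotated_protein[delta:]
        # genomic coordinate of the recruited A within the retained chain
        chain_pos = recruited_q - ft.junction_pos
        kept_g2t, kept_t2g, _ = _chain_maps(kept)
        atg_g = kept_t2g(chain_pos)
    else:
        pred = _translate(ft.mrna[recruited_q:])
        delta = ann_len - len(pred)
        atg_g = None
    return ConsequenceCall(ft.event_id, "truncation", "n_truncated",
                           delta_aa=int(delta), recruited_atg=atg_g,
                           transcript_id=tid,
                           annotated_protein_len=ann_len,
                           predicted_protein_len=len(pred),
                           predicted_protein=pred)
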