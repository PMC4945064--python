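"""Synthetic genomes with planted repeat->exon fusion transcripts.

The generator emulates the study design the pipeline targets: a small
genome carrying multi-exon coding genes and annotated repeat loci of six
classes (SINE, LINE, LTR, DNA, SSR, Low_complexity), 2 experimental
groups x 3 replicates of RNA-seq reads, and a known-truth set of planted
fusion transcripts (FTs) whose splice junctions carry canonical GT/GC-AG
dinucleotides written into the sequence. Contaminating read classes —
contiguous unspliced pre-mRNA, ordinary exon-exon splice reads and
repeat-repeat chimeras — plus deliberate non-canonical-motif negative
controls exercise every filter of the caller.

Each gene cassette is assembled in transcript sense and then placed on
the chromosome either forward or reverse-complemented, so both strands
are exercised while the planted motifs stay correct on the transcribed
strand by construction.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .annotation import (Exon, GeneModel, GenomeBundle, RepeatLocus, revcomp,
                         write_fasta, write_genes_gff3, write_repeats_bed,
                         write_repeats_out)

#: the six repeat classes cycled over planted loci (Satellite is valid in the
#: annotation vocabulary but not planted, matching the six classes analysed)
SIM_CLASSES = ("SINE", "LINE", "LTR", "DNA", "SSR", "Low_complexity")

_SAFE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("ATG", "TAA", "TAG", "TGA")
]

_STOP = "TAA"

# cassette geometry (transcript-sense local coordinates)
_GAP = 1000            # intergenic gap ahead of each gene
_REP_LOCAL = (200, 400)    # upstream intergenic repeat locus
_SEG_LEN = 80          # fused repeat segment length
_NEG_SEG_END = 340     # negative-control segment end inside the same locus
_CORE_LOCAL = (600, 680)   # multi-copy repeat core position (when assigned)
_UTR5, _UTR3 = 180, 150
_N_CODONS = 200        # annotated protein: 199 aa + stop
_TRUNC_CODON = 120     # recruited in-frame ATG for truncation genes
_EXON_CUTS = (150, 330, 510, 690, 870)  # mRNA split points -> 6 exons
_INTRON_LEN = 400
_PAD = 300             # pad after each gene cassette


@dataclass
class SimConfig:
    seed: int = 0
    genome_length: int = 150_000
    n_genes: int = 12
    repeats_per_class: int = 4
    read_length: int = 76
    error_rate: float = 0.0
    replicates_per_group: int = 3
    groups: int = 2
    junction_depth: int = 4
    group_effect: float = 1.0
    n_fusions: int = 12
    n_negative_controls: int = 3
    n_noise_reads: int = 150
    noise_fractions: dict[str, float] = field(default_factory=lambda: {
        "unspliced_premrna": 0.25,
        "exon_exon": 0.5,
        "repeat_repeat_chimera": 0.25,
    })
    offset_margin: int = 25   # min bases each side of the junction in a read
    poisson_depth: bool = False
    mito_length: int = 2000

    def validate(self) -> None:
        if self.read_length < 50:
            raise ValueError("read_length must be >= 50 (two 25-base anchors)")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be in [0,1]")
        for k, v in self.noise_fractions.items():
            if not 0 <= v <= 1:
                raise ValueError(f"noise fraction {k}={v} outside [0,1]")
        if sum(self.noise_fractions.values()) > 1 + 1e-9:
            raise ValueError("noise fractions must sum to <= 1")
        if self.repeats_per_class < 0:
            raise ValueError("repeats_per_class must be >= 0")
        if self.n_genes < 3:
            raise ValueError("need at least 3 genes")
        if self.n_fusions > self.n_genes:
            raise ValueError("at most one planted fusion per gene")
        if self.n_negative_controls > self.n_genes:
            raise ValueError("at most one negative control per gene")
        if not 1 <= self.offset_margin <= self.read_length // 2:
            raise ValueError("offset_margin must be in [1, read_length/2]")

    @property
    def samples(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.groups * self.replicates_per_group)]

    def design(self) -> dict[str, str]:
        """sample -> group label, replicates_per_group consecutive samples per group."""
        out = {}
        for i, s in enumerate(self.samples):
            out[s] = f"group{i // self.replicates_per_group + 1}"
        return out


@dataclass
class TruthRecord:
    event_id: str
    gene_id: str
    re_id: str
    exon_id: str
    re_class: str
    orientation: str                  # RE5p_exon3p | exon5p_RE3p
    donor: str
    acceptor: str
    canonical: bool
    junction: tuple[int, int]         # genomic (left_end, right_start)
    chrom: str
    consequence_truth: str            # alternative_promoter | truncation | exonization
    per_sample_depth: dict[str, int] = field(default_factory=dict)
    # transcript-sense sequences for read generation (not serialized)
    ft_mrna: str = ""
    junction_pos: int = 0             # junction offset within ft_mrna


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _mirror(iv: tuple[int, int], block_len: int, off: int, strand: str) -> tuple[int, int]:
    s, e = iv
    if strand == "+":
        return off + s, off + e
    return off + block_len - e, off + block_len - s


class _Block:
    """One gene cassette built in transcript sense, placed later."""

    def __init__(self, seq: list[str]):
        self.seq = seq  # mutable list of characters

    def write(self, pos: int, text: str) -> None:
        self.seq[pos : pos + len(text)] = list(text)

    def text(self) -> str:
        return "".join(self.seq)


def build_genome(cfg: SimConfig) -> tuple[GenomeBundle, list[TruthRecord]]:
    """Construct the toy genome, annotations and fusion truth records."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    cds_len = 3 * _N_CODONS
    mrna_len = _UTR5 + cds_len + _UTR3
    n_exons = len(_EXON_CUTS) + 1
    gene_len = mrna_len + (n_exons - 1) * _INTRON_LEN
    block_len = _GAP + gene_len + _PAD
    min_len = cfg.n_genes * block_len + 1000
    if cfg.genome_length < min_len:
        raise ValueError(
            f"genome_length {cfg.genome_length} too small for {cfg.n_genes} genes; "
            f"need at least {min_len}")

    multi_core = _rand_seq(rng, _CORE_LOCAL[1] - _CORE_LOCAL[0])

    chrom = "chr1"
    parts: list[str] = []
    cursor = 0
    repeats: list[RepeatLocus] = []
    genes: list[GeneModel] = []
    truth: list[TruthRecord] = []
    arch_cycle = ("alternative_promoter", "truncation", "exonization")

    for gi in range(cfg.n_genes):
        strand = "+" if gi % 2 == 0 else "-"
        gene_id = f"gene{gi + 1:02d}"
        arch = arch_cycle[gi % 3]
        planted = gi < cfg.n_fusions
        negative = gi < cfg.n_negative_controls

        block = _Block(list(_rand_seq(rng, block_len)))

        # ---- mRNA in transcript sense -----------------------------------
        codons = [
            "ATG",
            *(_SAFE_CODONS[i] for i in rng.integers(0, len(_SAFE_CODONS),
                                                    _N_CODONS - 2)),
            _STOP,
        ]
        if arch == "truncation":
            codons[_TRUNC_CODON] = "ATG"
        mrna = _rand_seq(rng, _UTR5) + "".join(codons) + _rand_seq(rng, _UTR3)

        # ---- lay exons and introns into the block -----------------------
        cuts = [0, *_EXON_CUTS, mrna_len]
        exon_local: list[tuple[int, int]] = []
        pos = _GAP
        for ei in range(n_exons):
            size = cuts[ei + 1] - cuts[ei]
            block.write(pos, mrna[cuts[ei] : cuts[ei + 1]])
            exon_local.append((pos, pos + size))
            pos += size
            if ei < n_exons - 1:
                intron = "GT" + _rand_seq(rng, _INTRON_LEN - 4) + "AG"
                block.write(pos, intron)
                pos += _INTRON_LEN
        gene_end_local = pos

        # ---- repeat loci: the fused repeat's class cycles through all six
        fused_class = SIM_CLASSES[gi % len(SIM_CLASSES)]
        other_class = SIM_CLASSES[(gi + 2) % len(SIM_CLASSES)]
        if arch == "alternative_promoter":
            up_class, in_class = fused_class, other_class
        else:
            up_class, in_class = other_class, fused_class
        intron2 = (exon_local[1][1], exon_local[2][0])
        in_rep_local = (intron2[0] + 50, intron2[0] + 250)
        if gi < 3:  # multi-copy family stressor with unique flanks
            block.write(_CORE_LOCAL[0], multi_core)

        # ---- plant the fusion -------------------------------------------
        rec = None
        if planted:
            if arch == "alternative_promoter":
                seg = (_REP_LOCAL[0], _REP_LOCAL[0] + _SEG_LEN)
                fused_exon = 1
                block.write(seg[1], "GT")                      # donor after RE segment
                block.write(exon_local[0][0] - 2, "AG")        # acceptor before exon 1
                jpos_local = (seg[1], exon_local[0][0])
                re_class, re_local = up_class, _REP_LOCAL
                orientation = "RE5p_exon3p"
                ft_mrna = (block.text()[seg[0]:seg[1]]
                           + mrna[cuts[0]:])                   # all exons retained
                jpos = _SEG_LEN
            elif arch == "truncation":
                seg = (in_rep_local[0], in_rep_local[0] + _SEG_LEN)
                fused_exon = 3
                block.write(seg[1], "GT")
                # acceptor: intron 2 already ends with AG before exon 3
                jpos_local = (seg[1], exon_local[2][0])
                re_class, re_local = in_class, in_rep_local
                orientation = "RE5p_exon3p"
                ft_mrna = block.text()[seg[0]:seg[1]] + mrna[cuts[2]:]
                jpos = _SEG_LEN
            else:  # exonization: exons 1-2 splice onto the intronic RE
                seg = (in_rep_local[0], in_rep_local[0] + _SEG_LEN)
                fused_exon = 2
                # donor: intron 2 already starts with GT after exon 2
                block.write(seg[0] - 2, "AG")                  # acceptor before RE segment
                jpos_local = (exon_local[1][1], seg[0])
                re_class, re_local = in_class, in_rep_local
                orientation = "exon5p_RE3p"
                ft_mrna = mrna[: cuts[2]] + block.text()[seg[0]:seg[1]]
                jpos = cuts[2]
            rec = (arch, seg, fused_exon, jpos_local, re_class, re_local,
                   orientation, ft_mrna, jpos)

        neg = None
        if negative:
            seg = (_REP_LOCAL[0], _NEG_SEG_END)
            block.write(seg[1], "TT")                          # non-canonical donor
            # acceptor: intron 1 already ends with AG before exon 2
            jpos_local = (seg[1], exon_local[1][0])
            ft_mrna = block.text()[seg[0]:seg[1]] + mrna[cuts[1]:]
            neg = (seg, jpos_local, up_class, ft_mrna, seg[1] - seg[0])

        # ---- place the block --------------------------------------------
        text = block.text()
        if strand == "-":
            text = revcomp(text)
        off = cursor
        parts.append(text)
        cursor += block_len

        def g(iv):  # local transcript-sense interval -> genomic
            return _mirror(iv, block_len, off, strand)

        # annotations
        up_iv = g(_REP_LOCAL)
        repeats.append(RepeatLocus(chrom, up_iv[0], up_iv[1], strand,
                                   f"rep_up_{gene_id}", up_class, up_class))
        in_iv = g(in_rep_local)
        repeats.append(RepeatLocus(chrom, in_iv[0], in_iv[1], strand,
                                   f"rep_in_{gene_id}", in_class, in_class))
        if gi < 3:
            core_iv = g(_CORE_LOCAL)
            repeats.append(RepeatLocus(chrom, core_iv[0], core_iv[1], strand,
                                       "multiCore", "LINE", "multiCore", True))

        tid = f"{gene_id}.t1"
        # transcript order is preserved under mirroring; only coordinates flip
        exons = [Exon(chrom, s, e, strand, gene_id, tid, i + 1,
                      coding=(cuts[i] < _UTR5 + cds_len and cuts[i + 1] > _UTR5))
                 for i, (s, e) in enumerate(g(iv) for iv in exon_local)]
        # genomic CDS intervals: intersect mRNA CDS range with each exon
        cds_ivs = []
        for i in range(n_exons):
            lo = max(cuts[i], _UTR5)
            hi = min(cuts[i + 1], _UTR5 + cds_len)
            if lo < hi:
                local_iv = (exon_local[i][0] + (lo - cuts[i]),
                            exon_local[i][0] + (hi - cuts[i]))
                cds_ivs.append(g(local_iv))
        model = GeneModel(gene_id, chrom, strand, {tid: exons},
                          cds={tid: sorted(cds_ivs)})
        first = exons[0]
        model.tss = first.start if strand == "+" else first.end - 1
        sc = sorted(cds_ivs)
        model.start_codon = sc[0][0] if strand == "+" else sc[-1][1] - 1
        genes.append(model)

        if rec is not None:
            arch_, seg, fused_exon, jl, re_class, re_local, orientation, ftm, jp = rec
            a, b = jl
            jgen = (off + a, off + b) if strand == "+" else (off + block_len - b,
                                                            off + block_len - a)
            rep_name = ("rep_up_" if re_local == _REP_LOCAL else "rep_in_") + gene_id
            re_locus = next(r for r in repeats if r.name == rep_name)
            truth.append(TruthRecord(
                event_id=f"FT{len(truth) + 1:03d}", gene_id=gene_id,
                re_id=re_locus.locus_id, exon_id=f"{tid}.e{fused_exon}",
                re_class=re_class, orientation=orientation,
                donor="GT", acceptor="AG", canonical=True, junction=jgen,
                chrom=chrom, consequence_truth=arch_,
                ft_mrna=ftm, junction_pos=jp))
        if neg is not None:
            seg, jl, re_class, ftm, jp = neg
            a, b = jl
            jgen = (off + a, off + b) if strand == "+" else (off + block_len - b,
                                                            off + block_len - a)
            neg_locus = next(r for r in repeats if r.name == f"rep_up_{gene_id}")
            truth.append(TruthRecord(
                event_id=f"NEG{len(truth) + 1:03d}", gene_id=gene_id,
                re_id=neg_locus.locus_id, exon_id=f"{tid}.e2",
                re_class=re_class, orientation="RE5p_exon3p",
                donor="TT", acceptor="AG", canonical=False, junction=jgen,
                chrom=chrom, consequence_truth="truncation",
                ft_mrna=ftm, junction_pos=jp))

    # top up each class to >= repeats_per_class with tail decoy loci
    tail_start = cursor
    tail = list(_rand_seq(rng, cfg.genome_length - cursor))
    per_class = {c: sum(1 for r in repeats if r.re_class == c) for c in SIM_CLASSES}
    pos = 200
    for c in SIM_CLASSES:
        while per_class[c] < cfg.repeats_per_class:
            if pos + 250 > len(tail):
                raise ValueError("genome_length too small for requested decoy repeats")
            repeats.append(RepeatLocus(chrom, tail_start + pos, tail_start + pos + 150,
                                       "+", f"decoy_{c}_{per_class[c]}", c, c))
            per_class[c] += 1
            pos += 400
    parts.append("".join(tail))

    sequences = {chrom: "".join(parts),
                 "chrM": _rand_seq(rng, cfg.mito_length)}
    bundle = GenomeBundle(sequences, repeats, genes)
    return bundle, truth


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    seq: str
    qual: str
    sample_id: str
    truth_class: str   # ft | negft | unspliced_premrna | exon_exon | repeat_repeat_chimera
    event_id: str = ""


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = "ACGT"[(("ACGT".index(chars[i]) + rng.integers(1, 4)) % 4)]
    return "".join(chars)


def simulate_reads(
    bundle: GenomeBundle,
    truth: list[TruthRecord],
    cfg: SimConfig,
) -> dict[str, list[ReadRecord]]:
    """Emit per-sample reads; updates each truth record's per_sample_depth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    L = cfg.read_length
    qual = "I" * L
    design = cfg.design()
    reads: dict[str, list[ReadRecord]] = {s: [] for s in cfg.samples}
    noise_classes = list(cfg.noise_fractions)
    noise_p = np.array([cfg.noise_fractions[c] for c in noise_classes], float)
    if noise_p.sum() < 1:
        noise_classes.append("unspliced_premrna")
        noise_p = np.append(noise_p, 1 - noise_p.sum())
    noise_p = noise_p / noise_p.sum()

    coding_genes = list(bundle.genes.values())
    repeats = bundle.repeats

    for sample in cfg.samples:
        group = design[sample]
        serial = 0
        for rec in truth:
            base = cfg.junction_depth
            if group != "group1":
                base = cfg.junction_depth * cfg.group_effect
            depth = int(rng.poisson(base)) if cfg.poisson_depth else int(round(base))
            emitted = 0
            for _ in range(depth):
                o = int(rng.integers(cfg.offset_margin, L - cfg.offset_margin + 1))
                start = rec.junction_pos - o
                if start < 0 or start + L > len(rec.ft_mrna):
                    continue  # cannot fit; geometry guarantees this never fires
                seq = _mutate(rng, rec.ft_mrna[start : start + L], cfg.error_rate)
                if rng.random() < 0.5:
                    seq = revcomp(seq)
                cls = "ft" if rec.canonical else "negft"
                serial += 1
                reads[sample].append(ReadRecord(
                    f"{cls}|{rec.event_id}|{sample}|{serial}", seq, qual,
                    sample, cls, rec.event_id))
                emitted += 1
            rec.per_sample_depth[sample] = emitted

        for _ in range(cfg.n_noise_reads):
            cls = noise_classes[int(rng.choice(len(noise_classes), p=noise_p))]
            serial += 1
            rid = f"{cls}|.|{sample}|{serial}"
            if cls == "unspliced_premrna":
                g = coding_genes[int(rng.integers(len(coding_genes)))]
                exons = next(iter(g.transcripts.values()))
                e = exons[int(rng.integers(1, len(exons)))]
                bnd = e.start if g.strand == "+" else e.end  # an exon/intron boundary
                o = int(rng.integers(1, L))
                seq = bundle.slice(g.chrom, bnd - o, bnd - o + L)
            elif cls == "exon_exon":
                g = coding_genes[int(rng.integers(len(coding_genes)))]
                exons = next(iter(g.transcripts.values()))
                k = int(rng.integers(0, len(exons) - 1))
                e1, e2 = exons[k], exons[k + 1]
                if g.strand == "+":
                    up, down = (bundle.slice(g.chrom, e1.start, e1.end),
                                bundle.slice(g.chrom, e2.start, e2.end))
                else:
                    up = revcomp(bundle.slice(g.chrom, e1.start, e1.end))
                    down = revcomp(bundle.slice(g.chrom, e2.start, e2.end))
                o = int(rng.integers(cfg.offset_margin, L - cfg.offset_margin + 1))
                seq = (up + down)[len(up) - o : len(up) - o + L]
            else:  # repeat_repeat_chimera
                i, j = rng.choice(len(repeats), 2, replace=False)
                r1, r2 = repeats[int(i)], repeats[int(j)]
                s1 = bundle.slice(r1.chrom, r1.start, r1.end)
                s2 = bundle.slice(r2.chrom, r2.start, r2.end)
                o = int(rng.integers(cfg.offset_margin, L - cfg.offset_margin + 1))
                seq = s1[-o:] + s2[: L - o]
                if len(seq) < L:
                    seq = (s1 + s2)[:L]
            seq = _mutate(rng, seq, cfg.error_rate)
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads[sample].append(ReadRecord(rid, seq, qual, sample, cls))
    return reads


def write_fastq(reads: list[ReadRecord], path) -> None:
    path = str(path)
    op = gzip.open if path.endswith(".gz") else open
    with op(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")


def read_fastq(path) -> list[tuple[str, str, str]]:
    path = str(path)
    op = gzip.open if path.endswith(".gz") else open
    out = []
    with op(path, "rt") as fh:
        while True:
            h = fh.readline().strip()
            if not h:
                break
            seq = fh.readline().strip()
            fh.readline()
            q = fh.readline().strip()
            out.append((h[1:], seq, q))
    return out


# ---------------------------------------------------------------------------
# Truth TSV
# ---------------------------------------------------------------------------

_TRUTH_COLS = ["event_id", "gene_id", "re_id", "exon_id", "re_class",
               "orientation", "donor", "acceptor", "canonical", "chrom",
               "junction_left", "junction_right", "consequence_truth",
               "per_sample_depth"]


def write_truth(truth: list[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TRUTH_COLS) + "\n")
        for t in truth:
            fh.write("\t".join([
                t.event_id, t.gene_id, t.re_id, t.exon_id, t.re_class,
                t.orientation, t.donor, t.acceptor, str(int(t.canonical)),
                t.chrom, str(t.junction[0]), str(t.junction[1]),
                t.consequence_truth, json.dumps(t.per_sample_depth, sort_keys=True),
            ]) + "\n")


def read_truth(path) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        assert header == _TRUTH_COLS, f"unexpected truth columns {header}"
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(TruthRecord(
                event_id=f[0], gene_id=f[1], re_id=f[2], exon_id=f[3],
                re_class=f[4], orientation=f[5], donor=f[6], acceptor=f[7],
                canonical=bool(int(f[8])), chrom=f[9],
                junction=(int(f[10]), int(f[11])), consequence_truth=f[12],
                per_sample_depth=json.loads(f[13])))
    return out


def simulate_to_dir(cfg: SimConfig, out_dir) -> dict:
    """Run the full generator and write FASTA/GFF3/BED/.out/FASTQ/truth files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle, truth = build_genome(cfg)
    reads = simulate_reads(bundle, truth, cfg)
    write_fasta(bundle.sequences, out / "genome.fa")
    write_genes_gff3(bundle.genes.values(), out / "genes.gff3")
    write_repeats_bed(bundle.repeats, out / "repeats.bed")
    write_repeats_out(bundle.repeats, out / "repeats.out")
    paths = {}
    for sample, recs in reads.items():
        p = out / f"{sample}.fq.gz"
        write_fastq(recs, p)
        paths[sample] = p
    write_truth(truth, out / "truth.tsv")
    with open(out / "design.tsv", "w") as fh:
        fh.write("sample\tgroup\tfastq\n")
        for s, g in cfg.design().items():
            fh.write(f"{s}\t{g}\t{paths[s]}\n")
    return {"bundle": bundle, "truth": truth, "reads": reads, "dir": out}
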