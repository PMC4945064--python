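"""Genome, repeat and gene-model annotation layer.

Loads a genome FASTA, RepeatMasker/BED repeat annotations and GFF3 or
knownGene-style gene models into a :class:`GenomeBundle` with interval
indexes, and answers the overlap / nearest / classification queries the
fusion pipeline relies on.

Coordinate convention: everything internal is 0-based half-open.
RepeatMasker ``.out`` (1-based inclusive) and GFF3 (1-based inclusive) are
converted at the parsing boundary; BED is taken as-is.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: Closed vocabulary of repeat classes used throughout the pipeline.
RE_CLASSES = ("SINE", "LINE", "LTR", "DNA", "SSR", "Low_complexity", "Satellite")

#: RepeatMasker spellings mapped onto the closed vocabulary.
_CLASS_ALIASES = {
    "Simple_repeat": "SSR",
    "Simple": "SSR",
    "Low_complexity": "Low_complexity",
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def normalize_re_class(raw: str) -> tuple[str, bool]:
    """Map a raw repeat class/family string to the closed vocabulary.

    RepeatMasker writes ``class/family`` (e.g. ``SINE/Alu``); the class is
    the part before the slash. Returns ``(class, known)`` where ``known``
    is False for classes outside the vocabulary (kept verbatim, flagged).
    """
    cls = raw.split("/", 1)[0]
    cls = _CLASS_ALIASES.get(cls, cls)
    if cls in RE_CLASSES:
        return cls, True
    return raw, False


@dataclass(frozen=True)
class RepeatLocus:
    chrom: str
    start: int
    end: int
    strand: str
    name: str
    re_class: str
    family: str = ""
    known_class: bool = True

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad repeat interval {self.start}-{self.end}")

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}/{self.name}"


@dataclass(frozen=True)
class Exon:
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_id: str
    exon_index: int  # 1-based ordinal in transcription order
    coding: bool = False

    @property
    def exon_id(self) -> str:
        return f"{self.transcript_id}.e{self.exon_index}"


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, list[Exon]]  # exons in transcription order
    cds: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    tss: int | None = None
    start_codon: int | None = None  # genomic coord of transcription-sense first CDS base

    @property
    def start(self) -> int:
        return min(e.start for exons in self.transcripts.values() for e in exons)

    @property
    def end(self) -> int:
        return max(e.end for exons in self.transcripts.values() for e in exons)

    @property
    def coding(self) -> bool:
        return any(self.cds.get(t) for t in self.transcripts)

    def transcript_cds_length(self, tid: str) -> int:
        return sum(e - s for s, e in self.cds.get(tid, []))


class GenomeBundle:
    """Sequences + repeats + gene models with interval indexes.

    ``total_gene_count`` is the denominator used for genome-wide "fraction
    of genes" statistics; it defaults to the number of loaded genes but can
    be set to an external annotation total.
    """

    def __init__(
        self,
        sequences: dict[str, str],
        repeats: Iterable[RepeatLocus] = (),
        genes: Iterable[GeneModel] = (),
        total_gene_count: int | None = None,
        mito_chrom: str = "chrM",
    ):
        self.sequences = dict(sequences)
        self.repeats: list[RepeatLocus] = list(repeats)
        self.genes: dict[str, GeneModel] = {g.gene_id: g for g in genes}
        self.mito_chrom = mito_chrom
        for r in self.repeats:
            self._check_bounds(r.chrom, r.start, r.end, f"repeat {r.name}")
        for g in self.genes.values():
            self._check_bounds(g.chrom, g.start, g.end, f"gene {g.gene_id}")
        self.total_gene_count = (
            total_gene_count if total_gene_count is not None else len(self.genes)
        )
        self._repeat_tree: dict[str, IntervalTree] = {}
        self._exon_tree: dict[str, IntervalTree] = {}
        self._gene_tree: dict[str, IntervalTree] = {}
        for r in self.repeats:
            self._repeat_tree.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)
        for g in self.genes.values():
            self._gene_tree.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)
            for exons in g.transcripts.values():
                for e in exons:
                    self._exon_tree.setdefault(e.chrom, IntervalTree()).addi(e.start, e.end, e)

    def _check_bounds(self, chrom, start, end, what):
        if chrom not in self.sequences:
            raise ValueError(f"{what}: unknown chromosome {chrom}")
        if not (0 <= start < end <= len(self.sequences[chrom])):
            raise ValueError(f"{what}: interval {start}-{end} outside {chrom}")

    # -- overlap queries -------------------------------------------------
    def repeats_overlapping(self, chrom, start, end) -> list[RepeatLocus]:
        tree = self._repeat_tree.get(chrom)
        return sorted((iv.data for iv in tree.overlap(start, end)),
                      key=lambda r: (r.start, r.end, r.name)) if tree else []

    def exons_overlapping(self, chrom, start, end) -> list[Exon]:
        tree = self._exon_tree.get(chrom)
        return sorted((iv.data for iv in tree.overlap(start, end)),
                      key=lambda e: (e.start, e.end, e.transcript_id, e.exon_index)) if tree else []

    def genes_overlapping(self, chrom, start, end) -> list[str]:
        tree = self._gene_tree.get(chrom)
        return sorted(iv.data for iv in tree.overlap(start, end)) if tree else []

    def slice(self, chrom, start, end) -> str:
        return self.sequences[chrom][start:end]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def load_fasta(path) -> dict[str, str]:
    """Read a (optionally gzipped) FASTA into a chrom -> sequence dict."""
    from Bio import SeqIO

    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Repeats
# ---------------------------------------------------------------------------

def load_repeats(
    path,
    dialect: Literal["repeatmasker_out", "bed"],
    class_map: dict[str, str] | None = None,
) -> list[RepeatLocus]:
    """Parse repeat annotations.

    ``repeatmasker_out``: standard RepeatMasker ``.out`` table, 1-based
    inclusive begin/end converted to 0-based half-open; strand ``C`` means
    minus. ``bed``: BED6 with the repeat name in column 4; the class is
    resolved through ``class_map`` (name -> class) when given, else the
    name itself is tried against the vocabulary.
    """
    repeats: list[RepeatLocus] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            try:
                if dialect == "repeatmasker_out":
                    f = line.split()
                    if f[0] in ("SW", "score") or f[0].startswith("#"):
                        continue
                    chrom, begin, end = f[4], int(f[5]), int(f[6])
                    strand = "+" if f[8] == "+" else "-"
                    name, classfam = f[9], f[10]
                    cls, known = normalize_re_class(classfam)
                    family = classfam.split("/", 1)[1] if "/" in classfam else classfam
                    loc = RepeatLocus(chrom, begin - 1, end, strand, name, cls, family, known)
                elif dialect == "bed":
                    if line.startswith(("#", "track", "browser")):
                        continue
                    f = line.split("\t") if "\t" in line else line.split()
                    chrom, start, end = f[0], int(f[1]), int(f[2])
                    name = f[3] if len(f) > 3 else "."
                    strand = f[5] if len(f) > 5 else "+"
                    raw = class_map.get(name, name) if class_map else name
                    cls, known = normalize_re_class(raw)
                    loc = RepeatLocus(chrom, start, end, strand, name, cls, name, known)
                else:
                    raise ValueError(f"unknown repeat dialect {dialect!r}")
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed {dialect} line {lineno}: {exc}") from exc
            if not loc.known_class:
                logger.warning("repeat %s line %d: unknown class %r retained",
                               loc.name, lineno, loc.re_class)
            repeats.append(loc)
    return repeats


def write_repeats_bed(repeats: Iterable[RepeatLocus], path) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t0\t{r.strand}\n")


def write_repeats_out(repeats: Iterable[RepeatLocus], path) -> None:
    """Write a minimal RepeatMasker-style .out (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("   SW  perc perc perc  query      position in query           matching"
                 "       repeat              position in  repeat\n"
                 "score  div. del. ins.  sequence    begin     end    (left)    repeat"
                 "         class/family         begin  end (left)   ID\n\n")
        for i, r in enumerate(repeats, 1):
            strand = "+" if r.strand == "+" else "C"
            classfam = r.re_class if r.family in ("", r.re_class) else f"{r.re_class}/{r.family}"
            fh.write(f"  100  0.0  0.0  0.0  {r.chrom}  {r.start + 1}  {r.end}  (0)  "
                     f"{strand}  {r.name}  {classfam}  1  {r.end - r.start}  (0)  {i}\n")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def _finish_gene(gene_id, chrom, strand, tx_exons, tx_cds) -> GeneModel:
    transcripts: dict[str, list[Exon]] = {}
    for tid, exon_ivs in tx_exons.items():
        if not exon_ivs:
            raise ValueError(f"transcript {tid} of {gene_id} has zero exons")
        ivs = sorted(exon_ivs)
        order = ivs if strand == "+" else ivs[::-1]
        cds_ivs = tx_cds.get(tid, [])
        for cs, ce in cds_ivs:
            if not any(s <= cs and ce <= e for s, e in ivs):
                raise ValueError(f"CDS {cs}-{ce} outside exons of {tid}")
        transcripts[tid] = [
            Exon(chrom, s, e, strand, gene_id, tid, i + 1,
                 coding=any(cs < e and s < ce for cs, ce in cds_ivs))
            for i, (s, e) in enumerate(order)
        ]
    model = GeneModel(gene_id, chrom, strand, transcripts,
                      cds={t: sorted(c) for t, c in tx_cds.items() if c})
    # primary transcript: longest CDS, then longest span, then id
    def _key(tid):
        exons = transcripts[tid]
        return (model.transcript_cds_length(tid),
                sum(e.end - e.start for e in exons), tid)
    primary = max(transcripts, key=_key)
    first = transcripts[primary][0]
    model.tss = first.start if strand == "+" else first.end - 1
    cds_ivs = model.cds.get(primary)
    if cds_ivs:
        model.start_codon = cds_ivs[0][0] if strand == "+" else cds_ivs[-1][1] - 1
    return model


def load_genes(path, dialect: Literal["gff3", "knowngene_tsv"]) -> list[GeneModel]:
    if dialect == "gff3":
        return _load_genes_gff3(path)
    if dialect == "knowngene_tsv":
        return _load_genes_knowngene(path)
    raise ValueError(f"unknown gene dialect {dialect!r}")


def _load_genes_gff3(path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    models = []
    for gene in db.features_of_type("gene"):
        tx_exons: dict[str, list[tuple[int, int]]] = {}
        tx_cds: dict[str, list[tuple[int, int]]] = {}
        for tx in db.children(gene, featuretype=("mRNA", "transcript"), level=1):
            tid = tx.id
            tx_exons[tid] = [(e.start - 1, e.end) for e in db.children(tx, featuretype="exon")]
            tx_cds[tid] = [(c.start - 1, c.end) for c in db.children(tx, featuretype="CDS")]
        if not tx_exons:  # gene with exons as direct children
            tx_exons[gene.id] = [(e.start - 1, e.end) for e in db.children(gene, featuretype="exon")]
            tx_cds[gene.id] = [(c.start - 1, c.end) for c in db.children(gene, featuretype="CDS")]
        models.append(_finish_gene(gene.id, gene.seqid, gene.strand, tx_exons, tx_cds))
    return models


def _load_genes_knowngene(path) -> list[GeneModel]:
    """knownGene-style TSV: name chrom strand txStart txEnd cdsStart cdsEnd
    exonCount exonStarts exonEnds [gene_id] — coordinates 0-based half-open."""
    by_gene: dict[str, dict] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            try:
                tid, chrom, strand = f[0], f[1], f[2]
                cds_s, cds_e = int(f[5]), int(f[6])
                starts = [int(x) for x in f[8].rstrip(",").split(",")]
                ends = [int(x) for x in f[9].rstrip(",").split(",")]
                gene_id = f[10] if len(f) > 10 and f[10] else tid
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed knownGene line {lineno}: {exc}") from exc
            rec = by_gene.setdefault(gene_id, {"chrom": chrom, "strand": strand,
                                               "tx_exons": {}, "tx_cds": {}})
            rec["tx_exons"][tid] = list(zip(starts, ends))
            if cds_e > cds_s:
                rec["tx_cds"][tid] = [
                    (max(s, cds_s), min(e, cds_e))
                    for s, e in zip(starts, ends) if max(s, cds_s) < min(e, cds_e)
                ]
    return [
        _finish_gene(gid, rec["chrom"], rec["strand"], rec["tx_exons"], rec["tx_cds"])
        for gid, rec in by_gene.items()
    ]


def write_genes_gff3(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(f"{g.chrom}\trefusion\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            for tid, exons in g.transcripts.items():
                ts = min(e.start for e in exons)
                te = max(e.end for e in exons)
                fh.write(f"{g.chrom}\trefusion\tmRNA\t{ts + 1}\t{te}\t.\t{g.strand}\t.\t"
                         f"ID={tid};Parent={g.gene_id}\n")
                for e in exons:
                    fh.write(f"{g.chrom}\trefusion\texon\t{e.start + 1}\t{e.end}\t.\t"
                             f"{g.strand}\t.\tParent={tid}\n")
                for cs, ce in g.cds.get(tid, []):
                    fh.write(f"{g.chrom}\trefusion\tCDS\t{cs + 1}\t{ce}\t.\t"
                             f"{g.strand}\t0\tParent={tid}\n")


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------

def classify_locus(
    bundle: GenomeBundle,
    chrom: str,
    start: int,
    end: int,
    containment: bool = True,
) -> tuple[str, list[str]]:
    """Classify an interval as exon / repeat / intron / intergenic.

    Precedence is exon > repeat > intron: the repeat label requires the
    interval to overlap no exon at all, mirroring a fusion pipeline in
    which the repeat side must not map within a defined exon. With
    ``containment`` (default) "within" an exon or repeat means fully
    contained; the looser overlap mode is a config switch.
    """
    if chrom not in bundle.sequences:
        raise ValueError(f"unknown chromosome {chrom}")
    if not (0 <= start < end <= len(bundle.sequences[chrom])):
        raise ValueError(f"interval {start}-{end} outside {chrom}")

    exon_hits = bundle.exons_overlapping(chrom, start, end)
    if containment:
        contained = [e for e in exon_hits if e.start <= start and end <= e.end]
    else:
        contained = exon_hits
    if contained:
        return "exon", sorted({e.exon_id for e in contained})

    rep_hits = bundle.repeats_overlapping(chrom, start, end)
    if containment:
        rep_contained = [r for r in rep_hits if r.start <= start and end <= r.end]
    else:
        rep_contained = rep_hits
    if rep_contained and not exon_hits:
        return "repeat", [r.locus_id for r in rep_contained]

    gene_hits = bundle.genes_overlapping(chrom, start, end)
    if gene_hits:
        return "intron", gene_hits
    return "intergenic", []


def nearest_repeat(
    bundle: GenomeBundle,
    exon: Exon,
    anchor: Literal["start", "end"] = "start",
) -> tuple[RepeatLocus, str] | None:
    """Nearest repeat to an exon, measured to the repeat's start or end.

    The exon acts as the anchor; distance is from the exon interval to the
    chosen repeat coordinate (0 when the coordinate falls inside the exon).
    Ties are broken toward the transcription-sense upstream repeat, then by
    (start, name). Returns ``(repeat, region)`` with region ``intronic``
    when the repeat lies within the exon's gene body, else ``intergenic``;
    None when the chromosome has no repeats.
    """
    tree = bundle._repeat_tree.get(exon.chrom)
    if not tree:
        return None
    best = None
    for iv in sorted(tree, key=lambda iv: (iv.begin, iv.end, iv.data.name)):
        r: RepeatLocus = iv.data
        c = r.start if anchor == "start" else r.end
        dist = max(exon.start - c, c - exon.end, 0)
        # upstream in transcription sense sorts first on ties
        if exon.strand == "+":
            upstream = 0 if c < exon.start else 1
        else:
            upstream = 0 if c >= exon.end else 1
        key = (dist, upstream, r.start, r.name)
        if best is None or key < best[0]:
            best = (key, r)
    r = best[1]
    gene = bundle.genes[exon.gene_id]
    region = "intronic" if (gene.start <= r.start and r.end <= gene.end) else "intergenic"
    return r, region
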