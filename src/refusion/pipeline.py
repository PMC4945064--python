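"""Pipeline orchestration, run configuration and bit-stable TSV I/O.

Ties the stages together in method order — map reads, call and qualify
fusion events, run the hard-clip estimator, differential statistics,
isoform usage and protein-consequence prediction — with every stage's
output written as a tab-separated file that can be reloaded independently.
Output headers embed the tool version, a config hash and the seed, so a
rerun with the same inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import GenomeBundle, load_fasta, load_genes, load_repeats
from .caller import (FusionEvent, call_events, class_frequencies,
                     qualifying_events, select_best_candidates)
from .consequence import (JunctionUsage, classify_consequence,
                          count_junction_reads, normalize_cpm,
                          reconstruct_transcript)
from .hardclip import estimate_fusion_genes, overlap_with_caller, run_hardclip
from .mapping import JunctionCandidate, build_index, find_split_alignments, map_read_full
from .simulate import read_fastq
from .stats import CountMatrix, differential_stats, enumerate_expected, observed_vs_expected

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters, defaulting to the reference protocol
    (25-base anchors and clips, one mismatch, 100K multimap cap, >=2
    junction reads, 15-base junction overhang, B=10,000 bootstrap,
    alpha=0.05)."""
    min_anchor: int = 25
    clip_length: int = 25
    max_mismatches: int = 1
    multimap_cap: int = 100_000
    min_reads: int = 2
    min_section: int = 25
    min_side: int = 15
    B: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    strict_one_read_rule: bool = False
    motif_mode: str = "gt_gc"          # or gt_only
    pseudocount_mode: str = "any_zero"
    empirical_mode: str = "literal"
    total_genes: int | None = None     # genome-wide denominator (e.g. 29922 for mm9)
    seed_k: int = 12
    min_read_length: int = 25          # QC stub: survivors must be >= this long

    def __post_init__(self):
        if self.motif_mode not in ("gt_gc", "gt_only"):
            raise ValueError(f"unknown motif_mode {self.motif_mode!r}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """TOML, or plain key=value lines; unknown keys are rejected."""
        path = Path(path)
        fields = {f.name: f for f in dataclasses.fields(cls)}
        raw: dict = {}
        if path.suffix == ".toml":
            import tomllib
            raw = tomllib.loads(path.read_text())
        else:
            for line in path.read_text().splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, _, v = line.partition("=")
                raw[k.strip()] = v.strip()
        kwargs = {}
        for k, v in raw.items():
            if k not in fields:
                raise ValueError(f"unknown config key {k!r}")
            typ = fields[k].type
            if isinstance(v, str):
                if typ in ("int", "int | None"):
                    v = int(v)
                elif typ == "float":
                    v = float(v)
                elif typ == "bool":
                    v = v.lower() in ("1", "true", "yes", "on")
            kwargs[k] = v
        return cls(**kwargs)

    def config_hash(self) -> str:
        body = ";".join(f"{k}={v}" for k, v in
                        sorted(dataclasses.asdict(self).items()))
        return hashlib.sha1(body.encode()).hexdigest()[:12]


@dataclass
class DesignTable:
    group_of: dict[str, str]
    fastq_of: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "DesignTable":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"design file not found: {path}")
        group_of, fastq_of = {}, {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                f = dict(zip(header, line.rstrip("\n").split("\t")))
                group_of[f["sample"]] = f["group"]
                if f.get("fastq"):
                    fastq_of[f["sample"]] = f["fastq"]
        return cls(group_of, fastq_of)

    @property
    def samples(self) -> list[str]:
        return sorted(self.group_of)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def _header_lines(cfg: RunConfig) -> str:
    return (f"# refusion_version={__version__}\n"
            f"# config_hash={cfg.config_hash()}\n"
            f"# seed={cfg.seed}\n")


_CAND_COLS = ["read_id", "sample_id", "l_chrom", "l_start", "l_end", "l_strand",
              "r_chrom", "r_start", "r_end", "r_strand", "j_left", "j_right",
              "mismatches", "left_unique", "right_unique", "read_5p_is_left",
              "support"]


def write_candidates(cands: list[JunctionCandidate], path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(cfg))
        fh.write("\t".join(_CAND_COLS) + "\n")
        for c in cands:
            lc, ls, le, lst = c.left_segment
            rc, rs, re_, rst = c.right_segment
            fh.write("\t".join(map(str, [
                c.read_id, c.sample_id, lc, ls, le, lst, rc, rs, re_, rst,
                c.junction[0], c.junction[1], c.mismatches,
                int(c.left_unique), int(c.right_unique),
                int(c.read_5p_is_left), c.support])) + "\n")


def read_candidates(path) -> list[JunctionCandidate]:
    out = []
    with open(path) as fh:
        rows = [l.rstrip("\n") for l in fh if not l.startswith("#")]
    header = rows[0].split("\t")
    assert header == _CAND_COLS, f"unexpected candidate columns: {header}"
    for row in rows[1:]:
        f = row.split("\t")
        out.append(JunctionCandidate(
            read_id=f[0], sample_id=f[1],
            left_segment=(f[2], int(f[3]), int(f[4]), f[5]),
            right_segment=(f[6], int(f[7]), int(f[8]), f[9]),
            junction=(int(f[10]), int(f[11])), mismatches=int(f[12]),
            left_unique=bool(int(f[13])), right_unique=bool(int(f[14])),
            read_5p_is_left=bool(int(f[15])), support=int(f[16])))
    return out


def events_frame(events: list[FusionEvent], samples: list[str]) -> pd.DataFrame:
    rows = []
    for e in events:
        row = {
            "event_id": e.event_id, "gene": e.gene_id, "chrom": e.chrom,
            "junction_left": e.junction[0], "junction_right": e.junction[1],
            "orientation": e.orientation,
            "repeat_name": e.repeat_locus.name,
            "repeat_family": e.repeat_locus.family,
            "repeat_class": e.re_class,
            "repeat_strand": e.repeat_locus.strand,
            "repeat_start": e.repeat_interval[0],
            "repeat_end": e.repeat_interval[1],
            "exon_id": e.exon.exon_id, "exon_strand": e.exon.strand,
            "donor": e.donor, "acceptor": e.acceptor,
            "motif_ok": int(e.motif_ok),
            "read_filter_ok": int(e.read_filter_ok),
            "section_ok": int(e.section_ok),
            "qualifying": int(e.qualifying),
            "qualifying_groups": ",".join(e.qualifying_groups),
        }
        for s in samples:
            row[f"count_{s}"] = e.counts.get(s, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def read_events(path, bundle: GenomeBundle) -> list[FusionEvent]:
    """Rebuild FusionEvent objects from an events.tsv, resolving repeat and
    exon identity against the annotation bundle."""
    df = pd.read_csv(path, sep="\t", comment="#")
    by_name = {(r.name, r.chrom): r for r in bundle.repeats}
    events = []
    for _, row in df.iterrows():
        gene = bundle.genes[row["gene"]]
        tid, _, eidx = row["exon_id"].rpartition(".e")
        exon = next(e for e in gene.transcripts[tid] if e.exon_index == int(eidx))
        rep = by_name[(row["repeat_name"], row["chrom"])]
        counts = {c.removeprefix("count_"): int(row[c])
                  for c in df.columns if c.startswith("count_")}
        qg = row.get("qualifying_groups", "")
        events.append(FusionEvent(
            event_id=row["event_id"], chrom=row["chrom"],
            junction=(int(row["junction_left"]), int(row["junction_right"])),
            repeat_locus=rep,
            repeat_interval=(int(row["repeat_start"]), int(row["repeat_end"])),
            exon=exon, exon_interval=(exon.start, exon.end),
            gene_id=row["gene"], orientation=row["orientation"],
            donor=row["donor"], acceptor=row["acceptor"],
            motif_ok=bool(row["motif_ok"]),
            counts=counts, read_filter_ok=bool(row["read_filter_ok"]),
            section_ok=bool(row["section_ok"]),
            qualifying_groups=(str(qg).split(",") if isinstance(qg, str) and qg
                               else [])))
    return events


def write_tsv(df: pd.DataFrame, path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(cfg))
        df.to_csv(fh, sep="\t", index=False)


def parse_fusions_out(
    path,
    column_map: dict[str, int] | None = None,
) -> list[JunctionCandidate]:
    """Ingest pre-computed chimeric junction records (fusions.out dialect).

    Whitespace-separated; the default column layout is
    ``chrom1-chrom2 left right orientation support`` with ``orientation``
    two letters f/r giving each side's strand. ``column_map`` remaps
    field positions for dialect drift (keys: chrom_pair, left, right,
    orientation, support). One synthetic candidate per supporting read is
    produced, with 25-base segments abutting the junction coordinates.
    """
    cm = {"chrom_pair": 0, "left": 1, "right": 2, "orientation": 3, "support": 4}
    if column_map:
        cm.update(column_map)
    stem = Path(path).stem
    out: list[JunctionCandidate] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            try:
                pair = f[cm["chrom_pair"]]
                left = int(f[cm["left"]])
                right = int(f[cm["right"]])
                orient = f[cm["orientation"]]
                support = int(f[cm["support"]])
                chrom_l, chrom_r = pair.split("-", 1)
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: unparseable fusions line {lineno}: {exc}") from exc
            strands = {"f": "+", "r": "-"}
            sl = strands.get(orient[0], "+")
            sr = strands.get(orient[1] if len(orient) > 1 else orient[0], "+")
            for i in range(support):
                out.append(JunctionCandidate(
                    read_id=f"{stem}:L{lineno}:r{i + 1}",
                    sample_id="external",
                    left_segment=(chrom_l, left - 25, left, sl),
                    right_segment=(chrom_r, right, right + 25, sr),
                    junction=(left, right), mismatches=0,
                    left_unique=True, right_unique=True))
    return out


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------

def load_bundle(genome, genes, repeats, repeat_dialect=None,
                gene_dialect=None, total_genes=None) -> GenomeBundle:
    sequences = load_fasta(genome)
    rd = repeat_dialect or ("bed" if str(repeats).endswith(".bed") else "repeatmasker_out")
    gd = gene_dialect or ("gff3" if str(genes).endswith((".gff", ".gff3")) else "knowngene_tsv")
    return GenomeBundle(sequences, load_repeats(repeats, rd),
                        load_genes(genes, gd), total_gene_count=total_genes)


def map_sample(index, reads: list[tuple[str, str]], sample_id: str,
               cfg: RunConfig) -> tuple[list[JunctionCandidate], Counter]:
    """QC stub + full-length filter + split-alignment enumeration."""
    funnel: Counter = Counter()
    cands: list[JunctionCandidate] = []
    for rid, seq in reads:
        funnel["total"] += 1
        if len(seq) < cfg.min_read_length:
            funnel["qc_fail"] += 1
            continue
        if map_read_full(index, seq, cfg.max_mismatches, cfg.multimap_cap).mapped:
            funnel["full_length_mapped"] += 1
            continue
        funnel["not_full_length_mapped"] += 1
        if len(seq) < 2 * cfg.min_anchor:
            funnel["too_short_to_split"] += 1
            continue
        cc = find_split_alignments(index, rid, seq, sample_id,
                                   cfg.min_anchor, cfg.max_mismatches,
                                   cfg.multimap_cap)
        if cc:
            funnel["split_candidates"] += 1
        cands.extend(cc)
    return cands, funnel


def _nonfusion_junction(event: FusionEvent, bundle: GenomeBundle):
    """The annotated exon-exon junction involving the fused exon, preferring
    the side the repeat replaces (upstream for RE5p, downstream for exon5p)."""
    gene = bundle.genes[event.gene_id]
    exons = gene.transcripts[event.exon.transcript_id]
    k = event.exon.exon_index
    prefer_upstream = event.orientation == "RE5p_exon3p"
    neighbours = ([k - 1, k + 1] if prefer_upstream else [k + 1, k - 1])
    for nk in neighbours:
        if 1 <= nk <= len(exons):
            a = exons[min(k, nk) - 1]   # transcript-earlier exon
            b = exons[max(k, nk) - 1]
            if gene.strand == "+":
                return a.chrom, (a.end, b.start)
            return a.chrom, (b.end, a.start)
    return None


def run_pipeline(
    cfg: RunConfig,
    design: DesignTable,
    genome_path,
    genes_path,
    repeats_path,
    out_dir,
    bundle: GenomeBundle | None = None,
    reads_by_sample: dict[str, list[tuple[str, str]]] | None = None,
) -> dict:
    """Execute map -> call -> qualify -> hardclip -> stats -> compare ->
    consequence, writing each stage's TSV under ``out_dir``.

    ``bundle`` / ``reads_by_sample`` allow in-memory inputs (the simulator's
    output) to bypass file loading; otherwise paths are read.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if bundle is None:
        bundle = load_bundle(genome_path, genes_path, repeats_path,
                             total_genes=cfg.total_genes)
    if reads_by_sample is None:
        reads_by_sample = {}
        for sample in design.samples:
            path = design.fastq_of.get(sample)
            if not path or not Path(path).exists():
                raise FileNotFoundError(f"reads for sample {sample} not found: {path}")
            reads_by_sample[sample] = [(rid, seq) for rid, seq, _ in read_fastq(path)]

    index = build_index(bundle.sequences, cfg.seed_k)
    samples = design.samples

    # --- map ---------------------------------------------------------------
    all_cands: list[JunctionCandidate] = []
    for sample in samples:
        cands, funnel = map_sample(index, reads_by_sample[sample], sample, cfg)
        logger.info("map %s: %s", sample, dict(funnel))
        all_cands.extend(cands)
    best = select_best_candidates(all_cands, bundle,
                                  cfg.motif_mode == "gt_only")
    write_candidates(best, out / "candidates.tsv", cfg)

    # --- call + qualify ------------------------------------------------------
    events, rejections = call_events(best, bundle, samples,
                                     cfg.min_reads, cfg.min_section,
                                     cfg.motif_mode == "gt_only")
    logger.info("call: %d events, rejections %s", len(events), dict(rejections))
    qualified, fusion_genes = qualifying_events(
        events, design.group_of, cfg.min_reads, cfg.strict_one_read_rule)
    write_tsv(events_frame(events, samples), out / "events.tsv", cfg)
    caller_genes = {g.gene_id for g in fusion_genes if g.qualifying}
    freq = class_frequencies(qualified)
    write_tsv(pd.DataFrame([{"re_class": c, **v} for c, v in freq.items()]),
              out / "class_frequencies.tsv", cfg)

    # --- hardclip ------------------------------------------------------------
    pairs, hc_funnel = run_hardclip(reads_by_sample, index, bundle,
                                    cfg.clip_length, cfg.max_mismatches,
                                    cfg.multimap_cap)
    hc = estimate_fusion_genes(pairs, design.group_of, cfg.min_reads,
                               cfg.total_genes or bundle.total_gene_count)
    overlap = overlap_with_caller(hc["union_genes"], caller_genes)
    funnel_df = pd.DataFrame(hc_funnel).T.fillna(0).astype(int)
    funnel_df.index.name = "sample"
    write_tsv(funnel_df.reset_index(), out / "hardclip_funnel.tsv", cfg)
    write_tsv(pd.DataFrame({"gene": sorted(hc["union_genes"])}),
              out / "hardclip_genes.tsv", cfg)

    # --- stats ---------------------------------------------------------------
    stats_df = pd.DataFrame()
    if qualified:
        counts = pd.DataFrame(
            {s: [e.counts.get(s, 0) for e in qualified] for s in samples},
            index=[e.event_id for e in qualified])
        matrix = CountMatrix(counts, design.group_of)
        stats_df = differential_stats(matrix, B=cfg.B, seed=cfg.seed,
                                      alpha=cfg.alpha,
                                      pseudocount_rule=cfg.pseudocount_mode,
                                      empirical_mode=cfg.empirical_mode)
        write_tsv(stats_df.reset_index(names="event_id"), out / "stats.tsv", cfg)
    expected = enumerate_expected(bundle)
    write_tsv(expected.to_frame(), out / "expected_frequencies.tsv", cfg)
    if qualified:
        ove = observed_vs_expected([e.re_class for e in qualified], expected,
                                   alpha=cfg.alpha)
        write_tsv(ove, out / "observed_vs_expected.tsv", cfg)

    # --- compare (junction usage) -------------------------------------------
    totals = {
        s: sum(1 for rid, seq in reads_by_sample[s]
               if map_read_full(index, seq, cfg.max_mismatches,
                                cfg.multimap_cap).mapped) or 1
        for s in samples
    }
    by_sample_cands: dict[str, list[JunctionCandidate]] = {s: [] for s in samples}
    for c in best:
        by_sample_cands.setdefault(c.sample_id, []).append(c)
    usage_rows = []
    for e in qualified:
        nf = _nonfusion_junction(e, bundle)
        for s in samples:
            ft_n = count_junction_reads(by_sample_cands[s], e.chrom, e.junction,
                                        cfg.min_side)
            nf_n = (count_junction_reads(by_sample_cands[s], nf[0], nf[1],
                                         cfg.min_side) if nf else 0)
            usage_rows.append(JunctionUsage(
                e.gene_id, e.event_id, s, ft_n, nf_n,
                normalize_cpm(ft_n, totals[s]), normalize_cpm(nf_n, totals[s])))
    usage_df = pd.DataFrame([u.__dict__ for u in usage_rows])
    write_tsv(usage_df, out / "usage.tsv", cfg)

    # --- consequence ----------------------------------------------------------
    calls = []
    for e in qualified:
        model = reconstruct_transcript(e, bundle.genes[e.gene_id], bundle.sequences)
        call = classify_consequence(model, bundle.genes[e.gene_id], bundle.sequences)
        calls.append({
            "event_id": e.event_id, "gene": e.gene_id,
            "category": call.category, "protein_effect": call.protein_effect,
            "delta_aa": "" if call.delta_aa is None else call.delta_aa,
            "recruited_atg": "" if call.recruited_atg is None else call.recruited_atg,
            "transcript": call.transcript_id,
        })
    write_tsv(pd.DataFrame(calls), out / "consequence.tsv", cfg)

    return {
        "bundle": bundle, "candidates": best, "events": events,
        "qualified": qualified, "fusion_genes": fusion_genes,
        "caller_genes": caller_genes, "class_frequencies": freq,
        "hardclip": hc, "hardclip_funnel": hc_funnel, "overlap": overlap,
        "stats": stats_df, "usage": usage_df, "consequence": calls,
        "rejections": rejections, "out_dir": out,
    }
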