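"""Annotation layer: parsing dialects, coordinate conventions, interval queries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from refusion.annotation import (GenomeBundle, RepeatLocus, classify_locus,
                                 load_genes, load_repeats, nearest_repeat,
                                 normalize_re_class, revcomp,
                                 write_genes_gff3, write_repeats_bed,
                                 write_repeats_out)


# ---------------------------------------------------------------------------
# Repeat parsing
# ---------------------------------------------------------------------------

def test_repeatmasker_out_converts_one_based_inclusive(tmp_path):
    p = tmp_path / "r.out"
    p.write_text("  463 1.3 0.6 1.7  chr1  101  200  (0)  +  AluY  SINE/Alu  1  100  (0)  1\n")
    (r,) = load_repeats(p, "repeatmasker_out")
    assert (r.start, r.end) == (100, 200)
    assert r.re_class == "SINE" and r.family == "Alu" and r.known_class


def test_bed_taken_as_is_with_class_map(tmp_path):
    p = tmp_path / "r.bed"
    p.write_text("chr1\t100\t200\tAluY\t0\t+\n")
    (r,) = load_repeats(p, "bed", class_map={"AluY": "SINE"})
    assert (r.start, r.end, r.re_class, r.strand) == (100, 200, "SINE", "+")


def test_out_fixture_sequences_match_fasta_slices(tmp_path):
    """Loci parsed from a 3-line .out fixture point at the embedded repeat
    sequences of the accompanying genome."""
    rng = np.random.default_rng(5)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
    planted = {"repA": (100, 180), "repB": (500, 650), "repC": (1200, 1300)}
    lines = []
    for i, (name, (s, e)) in enumerate(planted.items(), 1):
        lines.append(f"100 0 0 0 chrT {s + 1} {e} (0) + {name} LINE/L1 1 {e - s} (0) {i}\n")
    p = tmp_path / "three.out"
    p.write_text("".join(lines))
    reps = load_repeats(p, "repeatmasker_out")
    assert len(reps) == 3
    for r in reps:
        s, e = planted[r.name]
        assert seq[r.start:r.end] == seq[s:e] and (r.start, r.end) == (s, e)


def test_malformed_line_names_line_number(tmp_path):
    p = tmp_path / "bad.out"
    p.write_text("100 0 0 0 chr1 10 20 (0) + ok SINE 1 10 (0) 1\nnot a line\n")
    with pytest.raises(ValueError, match="line 2"):
        load_repeats(p, "repeatmasker_out")


def test_unknown_class_retained_and_flagged(tmp_path):
    p = tmp_path / "r.out"
    p.write_text("100 0 0 0 chr1 10 20 (0) + weird Unknown/xx 1 10 (0) 1\n")
    (r,) = load_repeats(p, "repeatmasker_out")
    assert not r.known_class and r.re_class == "Unknown/xx"


@pytest.mark.parametrize("raw,expected", [
    ("SINE/Alu", ("SINE", True)),
    ("Simple_repeat", ("SSR", True)),
    ("Low_complexity", ("Low_complexity", True)),
    ("LTR/ERVK", ("LTR", True)),
    ("rRNA", ("rRNA", False)),
])
def test_class_normalization(raw, expected):
    assert normalize_re_class(raw) == expected


# ---------------------------------------------------------------------------
# Gene parsing
# ---------------------------------------------------------------------------

GFF = """##gff-version 3
chrT\tx\tgene\t1\t300\t.\t{strand}\t.\tID=g1
chrT\tx\tmRNA\t1\t300\t.\t{strand}\t.\tID=t1;Parent=g1
chrT\tx\texon\t1\t100\t.\t{strand}\t.\tParent=t1
chrT\tx\texon\t201\t300\t.\t{strand}\t.\tParent=t1
"""


def test_gff3_exon_indices_plus_strand(tmp_path):
    p = tmp_path / "g.gff3"
    p.write_text(GFF.format(strand="+"))
    (g,) = load_genes(p, "gff3")
    exons = g.transcripts["t1"]
    assert [(e.start, e.end, e.exon_index) for e in exons] == [(0, 100, 1), (200, 300, 2)]


def test_gff3_exon_indices_minus_strand(tmp_path):
    p = tmp_path / "g.gff3"
    p.write_text(GFF.format(strand="-"))
    (g,) = load_genes(p, "gff3")
    exons = g.transcripts["t1"]
    assert (exons[0].start, exons[0].end, exons[0].exon_index) == (200, 300, 1)


def test_knowngene_matches_equivalent_gff3(tmp_path):
    gff = tmp_path / "g.gff3"
    gff.write_text("##gff-version 3\n"
                   "chrT\tx\tgene\t1\t300\t.\t+\t.\tID=g1\n"
                   "chrT\tx\tmRNA\t1\t300\t.\t+\t.\tID=t1;Parent=g1\n"
                   "chrT\tx\texon\t1\t100\t.\t+\t.\tParent=t1\n"
                   "chrT\tx\texon\t201\t300\t.\t+\t.\tParent=t1\n"
                   "chrT\tx\tCDS\t51\t100\t.\t+\t0\tParent=t1\n"
                   "chrT\tx\tCDS\t201\t260\t.\t+\t0\tParent=t1\n")
    kg = tmp_path / "g.tsv"
    kg.write_text("t1\tchrT\t+\t0\t300\t50\t260\t2\t0,200,\t100,300,\tg1\n")
    (a,) = load_genes(gff, "gff3")
    (b,) = load_genes(kg, "knowngene_tsv")
    assert a.transcripts["t1"] == b.transcripts["t1"]
    assert a.cds == b.cds
    assert (a.tss, a.start_codon) == (b.tss, b.start_codon)


def test_zero_exon_transcript_rejected(tmp_path):
    p = tmp_path / "g.gff3"
    p.write_text("##gff-version 3\n"
                 "chrT\tx\tgene\t1\t300\t.\t+\t.\tID=g1\n"
                 "chrT\tx\tmRNA\t1\t300\t.\t+\t.\tID=t1;Parent=g1\n")
    with pytest.raises(ValueError, match="zero exons"):
        load_genes(p, "gff3")


def test_cds_outside_exons_rejected(tmp_path):
    p = tmp_path / "g.gff3"
    p.write_text(GFF.format(strand="+") + "chrT\tx\tCDS\t120\t180\t.\t+\t0\tParent=t1\n")
    with pytest.raises(ValueError, match="CDS"):
        load_genes(p, "gff3")


# ---------------------------------------------------------------------------
# Round trips
# ---------------------------------------------------------------------------

def test_gff3_round_trip_is_identity(sim, tmp_path):
    genes = list(sim["bundle"].genes.values())
    p = tmp_path / "rt.gff3"
    write_genes_gff3(genes, p)
    reloaded = {g.gene_id: g for g in load_genes(p, "gff3")}
    assert set(reloaded) == set(sim["bundle"].genes)
    for gid, g in sim["bundle"].genes.items():
        r = reloaded[gid]
        assert r.transcripts == g.transcripts
        assert r.cds == g.cds
        assert (r.tss, r.start_codon, r.strand) == (g.tss, g.start_codon, g.strand)


def test_repeat_round_trips(sim, tmp_path):
    reps = sim["bundle"].repeats
    out = tmp_path / "rt.out"
    write_repeats_out(reps, out)
    assert load_repeats(out, "repeatmasker_out") == reps
    bed = tmp_path / "rt.bed"
    write_repeats_bed(reps, bed)
    rb = load_repeats(bed, "bed", class_map={r.name: r.re_class for r in reps})
    assert [(r.chrom, r.start, r.end, r.strand, r.name, r.re_class) for r in rb] == \
           [(r.chrom, r.start, r.end, r.strand, r.name, r.re_class) for r in reps]


# ---------------------------------------------------------------------------
# classify_locus
# ---------------------------------------------------------------------------

def test_classify_precedence_and_labels(tiny_bundle):
    # interval inside the intronic LINE, overlapping no exon -> repeat
    kind, ids = classify_locus(tiny_bundle, "c", 1160, 1200)
    assert kind == "repeat" and ids == ["c:1150-1250/l1a"]
    # inside an exon (exon wins even where a repeat overlapped an exon)
    kind, _ = classify_locus(tiny_bundle, "c", 1010, 1040)
    assert kind == "exon"
    # in the gene body touching neither -> intron
    kind, ids = classify_locus(tiny_bundle, "c", 1500, 1550)
    assert kind == "intron" and ids == ["gA"]
    kind, _ = classify_locus(tiny_bundle, "c", 3000, 3100)
    assert kind == "intergenic"


def test_exon_precedence_over_repeat():
    """A repeat lying inside an exon never yields the repeat label."""
    bundle_seq = {"c": "A" * 1000}
    from refusion.annotation import Exon, GeneModel
    g = GeneModel("g", "c", "+",
                  {"t": [Exon("c", 100, 300, "+", "g", "t", 1)]})
    b = GenomeBundle(bundle_seq, [RepeatLocus("c", 150, 250, "+", "r", "SINE", "x")], [g])
    kind, _ = classify_locus(b, "c", 160, 240)
    assert kind == "exon"
    # partial exon overlap disqualifies the repeat label too
    kind, _ = classify_locus(b, "c", 90, 160)
    assert kind == "intron"


def test_classify_out_of_bounds_errors(tiny_bundle):
    with pytest.raises(ValueError):
        classify_locus(tiny_bundle, "c", 5900, 6100)
    with pytest.raises(ValueError):
        classify_locus(tiny_bundle, "nope", 0, 10)


from hypothesis import HealthCheck, settings as hsettings


@hsettings(suppress_health_check=[HealthCheck.function_scoped_fixture])
@given(st.integers(0, 5990), st.integers(1, 80))
def test_classify_is_total_with_exclusive_labels(tiny_bundle, start, width):
    kind, _ = classify_locus(tiny_bundle, "c", start, min(start + width, 6000))
    assert kind in ("exon", "repeat", "intron", "intergenic")


# ---------------------------------------------------------------------------
# nearest_repeat
# ---------------------------------------------------------------------------

def test_nearest_repeat_picks_closer(tiny_bundle):
    exon = tiny_bundle.genes["gA"].transcripts["gA.t1"][0]  # (1000,1100)
    rep, region = nearest_repeat(tiny_bundle, exon, anchor="end")
    assert rep.name == "l1a" and region == "intronic"


def test_nearest_repeat_tie_breaks_upstream():
    from refusion.annotation import Exon, GeneModel
    g = GeneModel("g", "c", "+",
                  {"t": [Exon("c", 1000, 1100, "+", "g", "t", 1)]})
    reps = [RepeatLocus("c", 880, 900, "+", "up", "SINE", "x"),
            RepeatLocus("c", 1200, 1300, "+", "down", "LINE", "y")]
    b = GenomeBundle({"c": "A" * 2000}, reps, [g])
    # distances: upstream end 900 -> 100; downstream start 1200 -> 100
    rep, region = nearest_repeat(b, g.transcripts["t"][0], anchor="start")
    # start anchor: up start=880 (d=120) vs down start=1200 (d=100) -> down
    assert rep.name == "down"
    rep, _ = nearest_repeat(b, g.transcripts["t"][0], anchor="end")
    # end anchor: up end=900 (d=100) vs down end=1300 (d=200) -> up
    assert rep.name == "up"
    # construct an exact tie: both at distance 100 under the end anchor
    reps2 = [RepeatLocus("c", 880, 900, "+", "up", "SINE", "x"),
             RepeatLocus("c", 1150, 1200, "+", "down", "LINE", "y")]
    b2 = GenomeBundle({"c": "A" * 2000}, reps2, [g])
    rep, _ = nearest_repeat(b2, g.transcripts["t"][0], anchor="end")
    assert rep.name == "up"  # upstream wins ties


def test_nearest_repeat_empty_chromosome():
    from refusion.annotation import Exon, GeneModel
    g = GeneModel("g", "c", "+", {"t": [Exon("c", 10, 20, "+", "g", "t", 1)]})
    b = GenomeBundle({"c": "A" * 100}, [], [g])
    assert nearest_repeat(b, g.transcripts["t"][0]) is None


# ---------------------------------------------------------------------------
# Index/scan equivalence
# ---------------------------------------------------------------------------

def test_interval_index_matches_linear_scan(tiny_bundle):
    rng = np.random.default_rng(3)
    exons = [e for g in tiny_bundle.genes.values()
             for ex in g.transcripts.values() for e in ex]
    for _ in range(1000):
        s = int(rng.integers(0, 5900))
        e = s + int(rng.integers(1, 100))
        got = tiny_bundle.repeats_overlapping("c", s, e)
        want = sorted([r for r in tiny_bundle.repeats if r.start < e and s < r.end],
                      key=lambda r: (r.start, r.end, r.name))
        assert got == want
        got_e = tiny_bundle.exons_overlapping("c", s, e)
        want_e = sorted([x for x in exons if x.start < e and s < x.end],
                        key=lambda x: (x.start, x.end, x.transcript_id, x.exon_index))
        assert got_e == want_e


def test_revcomp():
    assert revcomp("ACGTN") == "NACGT"
    assert revcomp(revcomp("GATTACA")) == "GATTACA"
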