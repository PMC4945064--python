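"""Isoform usage comparison and protein-consequence prediction."""

import pytest
from Bio.Seq import Seq

from refusion.caller import call_events, qualifying_events
from refusion.consequence import (JunctionUsage, classify_consequence,
                                  compare_isoforms, count_junction_reads,
                                  normalize_cpm, reconstruct_transcript)
from refusion.mapping import JunctionCandidate


def _cand(junction, left_len, right_len, chrom="c", read="r1"):
    l_end, r_start = junction
    return JunctionCandidate(read, "S1",
                             (chrom, l_end - left_len, l_end, "+"),
                             (chrom, r_start, r_start + right_len, "+"),
                             junction, 0, True, True)


# ---------------------------------------------------------------------------
# Junction counting and CPM
# ---------------------------------------------------------------------------

def test_count_junction_reads_overhang_rules():
    j = (100, 300)
    cands = [_cand(j, 20, 56), _cand(j, 10, 66, read="r2"),
             _cand((100, 301), 30, 30, read="r3")]
    assert count_junction_reads(cands, "c", j, min_side=15) == 1        # both sides
    assert count_junction_reads(cands, "c", j, min_side=15, mode="one") == 2
    assert count_junction_reads(cands, "c", (999, 1000), min_side=15) == 0


def test_count_junction_reads_matches_brute_force():
    import numpy as np
    rng = np.random.default_rng(12)
    junctions = [(100, 300), (100, 301), (500, 900)]
    cands = []
    for i in range(500):
        j = junctions[int(rng.integers(3))]
        cands.append(_cand(j, int(rng.integers(5, 40)), int(rng.integers(5, 40)),
                           read=f"r{i}"))
    for j in junctions:
        brute = sum(1 for c in cands if c.junction == j
                    and c.left_segment[2] - c.left_segment[1] >= 15
                    and c.right_segment[2] - c.right_segment[1] >= 15)
        assert count_junction_reads(cands, "c", j) == brute


def test_normalize_cpm():
    assert normalize_cpm(5, 1_000_000) == 5.0
    assert normalize_cpm(0, 10) == 0.0
    assert normalize_cpm(7, 2_000_000) == normalize_cpm(7, 1_000_000) / 2
    with pytest.raises(ValueError):
        normalize_cpm(1, 0)


def test_compare_isoforms_flags_and_dispersion():
    recs = []
    for label, ft, nf in [("brain", 40.0, 1.0), ("brain", 44.0, 1.0),
                          ("liver", 0.0, 5.0), ("liver", 0.0, 7.0),
                          ("skin", 0.0, 0.0)]:
        recs.append(JunctionUsage("g", "e", label, int(ft), int(nf), ft, nf))
    df = compare_isoforms(recs).set_index("label")
    assert df.loc["brain", "expression"] == "both"
    assert df.loc["liver", "expression"] == "non-fusion-only"
    assert df.loc["skin", "expression"] == "neither"
    assert df.loc["brain", "ft_mean"] == pytest.approx(42.0)
    # n=2 -> SE rather than SD
    sd = ((40 - 42) ** 2 + (44 - 42) ** 2) ** 0.5
    assert df.loc["brain", "ft_disp"] == pytest.approx(sd / 2 ** 0.5)


def test_compare_isoforms_recovers_planted_ratio():
    recs = [JunctionUsage("g", "e", "t", 40 * i, i, 40.0 * i, 1.0 * i)
            for i in (1, 2, 3)]
    df = compare_isoforms(recs)
    assert df["ft_mean"].iloc[0] / df["nonfusion_mean"].iloc[0] == pytest.approx(40.0)


# ---------------------------------------------------------------------------
# Reconstruction + consequence on simulated truth
# ---------------------------------------------------------------------------

def _genomic_to_ft_mrna(ft, gene, gpos):
    """Map a genomic coordinate inside a retained exon to FT mRNA position."""
    off = 0
    for kind, chrom, s, e in ft.segments:
        if kind == "exon" and s <= gpos < e:
            d = gpos - s if gene.strand == "+" else e - 1 - gpos
            return off + d
        off += e - s
    raise AssertionError(f"{gpos} not in retained exons")


@pytest.fixture(scope="module")
def called_events(request):
    sim = request.getfixturevalue("sim")
    pr = request.getfixturevalue("pipeline_result")
    by_junction = {t.junction: t for t in sim["truth"]}
    return [(e, by_junction[e.junction]) for e in pr["qualified"]]


def test_reconstruction_architecture(called_events, sim):
    bundle = sim["bundle"]
    for event, truth in called_events:
        gene = bundle.genes[event.gene_id]
        ft = reconstruct_transcript(event, gene, bundle.sequences)
        kinds = [s[0] for s in ft.segments]
        n_exons = len(gene.transcripts[ft.transcript_id])
        if truth.consequence_truth == "alternative_promoter":
            # RE + the full annotated exon chain
            assert kinds == ["repeat"] + ["exon"] * n_exons
        elif truth.consequence_truth == "truncation":
            # RE in intron 2 splicing to exon 3 onward
            assert kinds[0] == "repeat" and ft.fused_exon_index == 3
            assert len(kinds) == 1 + (n_exons - 2)
        else:  # exonization: exons 1-2 then the RE segment
            assert kinds == ["exon", "exon", "repeat"]
        # junction sequence agrees with the truth fusion mRNA around the join
        w = 30
        assert (ft.mrna[ft.junction_pos - w : ft.junction_pos + w]
                == truth.ft_mrna[truth.junction_pos - w : truth.junction_pos + w])


def test_reconstruction_errors_on_foreign_exon(called_events, sim):
    event, _ = called_events[0]
    other = next(g for g in sim["bundle"].genes.values()
                 if g.gene_id != event.gene_id)
    with pytest.raises(ValueError, match="absent from transcripts"):
        reconstruct_transcript(event, other, sim["bundle"].sequences)


def test_consequence_calls_match_truth_categories(called_events, sim):
    bundle = sim["bundle"]
    seen = set()
    for event, truth in called_events:
        gene = bundle.genes[event.gene_id]
        ft = reconstruct_transcript(event, gene, bundle.sequences)
        call = classify_consequence(ft, gene, bundle.sequences)
        assert call.category == truth.consequence_truth
        seen.add(call.category)
    assert seen == {"alternative_promoter", "truncation", "exonization"}


def test_alternative_promoter_protein_is_annotated_protein(called_events, sim):
    """Fusions retaining the start codon express a protein string-identical
    to the annotated one (checked against direct translation)."""
    bundle = sim["bundle"]
    n = 0
    for event, truth in called_events:
        if truth.consequence_truth != "alternative_promoter":
            continue
        gene = bundle.genes[event.gene_id]
        ft = reconstruct_transcript(event, gene, bundle.sequences)
        call = classify_consequence(ft, gene, bundle.sequences)
        assert call.protein_effect == "full_length"
        # independent oracle: translate the FT mRNA from the annotated ATG,
        # located by genomic coordinate
        atg_q = _genomic_to_ft_mrna(ft, gene, call.recruited_atg)
        assert ft.mrna[atg_q : atg_q + 3] == "ATG"
        tail = ft.mrna[atg_q : atg_q + 3 * ((len(ft.mrna) - atg_q) // 3)]
        oracle = str(Seq(tail).translate(to_stop=True))
        assert call.predicted_protein == oracle
        n += 1
    assert n >= 2


def test_truncation_delta_aa_matches_translation_oracle(called_events, sim):
    """Predicted truncations: translating the reconstructed FT mRNA from the
    reported recruited ATG yields a peptide of annotated length - delta_aa."""
    bundle = sim["bundle"]
    n = 0
    for event, truth in called_events:
        if truth.consequence_truth != "truncation":
            continue
        gene = bundle.genes[event.gene_id]
        ft = reconstruct_transcript(event, gene, bundle.sequences)
        call = classify_consequence(ft, gene, bundle.sequences)
        assert call.protein_effect == "n_truncated"
        assert call.recruited_atg is not None
        # locate the recruited ATG inside the FT mRNA via its genomic coord
        atg_q = _genomic_to_ft_mrna(ft, gene, call.recruited_atg)
        assert ft.mrna[atg_q : atg_q + 3] == "ATG"
        tail = ft.mrna[atg_q : atg_q + 3 * ((len(ft.mrna) - atg_q) // 3)]
        oracle = str(Seq(tail).translate(to_stop=True))
        assert len(oracle) == call.annotated_protein_len - call.delta_aa
        assert call.predicted_protein == oracle
        n += 1
    assert n >= 2


def test_exonization_keeps_start_codon(called_events, sim):
    bundle = sim["bundle"]
    for event, truth in called_events:
        if truth.consequence_truth != "exonization":
            continue
        gene = bundle.genes[event.gene_id]
        ft = reconstruct_transcript(event, gene, bundle.sequences)
        call = classify_consequence(ft, gene, bundle.sequences)
        assert call.category == "exonization"
        # CDS continues past the retained exons -> residue-level effect not modelled
        assert call.protein_effect == "none"


def test_non_coding_gene_yields_non_coding_call(sim):
    from refusion.annotation import GeneModel
    bundle = sim["bundle"]
    event = next(iter([e for e in _qualified(sim)]), None)
    gene = bundle.genes[event.gene_id]
    stripped = GeneModel(gene.gene_id, gene.chrom, gene.strand,
                         gene.transcripts, cds={}, tss=gene.tss)
    ft = reconstruct_transcript(event, stripped, bundle.sequences)
    call = classify_consequence(ft, stripped, bundle.sequences)
    assert call.category == "non_coding" and call.protein_effect == "none"


def _qualified(sim):
    from refusion.caller import select_best_candidates
    from refusion.mapping import build_index, find_split_alignments
    bundle = sim["bundle"]
    idx = build_index(bundle.sequences, 12)
    cands = []
    rec = next(t for t in sim["truth"] if t.canonical)
    for i, r in enumerate(sim["reads"]["S1"]):
        if r.event_id == rec.event_id:
            cands += find_split_alignments(idx, r.read_id, r.seq, "S1")
    best = select_best_candidates(cands, bundle)
    events, _ = call_events(best, bundle, ["S1"])
    return events
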