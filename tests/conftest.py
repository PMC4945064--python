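import numpy as np
import pytest
from hypothesis import settings

from refusion.annotation import Exon, GeneModel, GenomeBundle, RepeatLocus
from refusion.pipeline import DesignTable, RunConfig, run_pipeline
from refusion.simulate import SimConfig, build_genome, simulate_reads

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def rand_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def sim():
    """Default synthetic dataset: genome, truth and per-sample reads."""
    cfg = SimConfig(seed=11)
    bundle, truth = build_genome(cfg)
    reads = simulate_reads(bundle, truth, cfg)
    return {"cfg": cfg, "bundle": bundle, "truth": truth, "reads": reads}


@pytest.fixture(scope="session")
def pipeline_result(sim, tmp_path_factory):
    """Full pipeline run on the default synthetic dataset (small bootstrap)."""
    cfg = RunConfig(seed=11, B=300)
    design = DesignTable(sim["cfg"].design())
    reads = {s: [(r.read_id, r.seq) for r in v] for s, v in sim["reads"].items()}
    out = tmp_path_factory.mktemp("pipeline")
    res = run_pipeline(cfg, design, None, None, None, out,
                       bundle=sim["bundle"], reads_by_sample=reads)
    res["run_config"] = cfg
    res["design"] = design
    return res


@pytest.fixture()
def tiny_bundle():
    """Hand-built two-gene bundle for annotation query tests."""
    rng = np.random.default_rng(7)
    seq = rand_seq(rng, 6000)
    ga = GeneModel(
        "gA", "c", "+",
        {"gA.t1": [Exon("c", 1000, 1100, "+", "gA", "gA.t1", 1, True),
                   Exon("c", 1300, 1400, "+", "gA", "gA.t1", 2, True),
                   Exon("c", 1600, 1700, "+", "gA", "gA.t1", 3, False)]},
        cds={"gA.t1": [(1050, 1100), (1300, 1360)]}, tss=1000, start_codon=1050)
    gb = GeneModel(
        "gB", "c", "-",
        {"gB.t1": [Exon("c", 4300, 4400, "-", "gB", "gB.t1", 1, False),
                   Exon("c", 4000, 4100, "-", "gB", "gB.t1", 2, False)]},
        tss=4399)
    reps = [
        RepeatLocus("c", 200, 380, "+", "alu1", "SINE", "Alu"),
        RepeatLocus("c", 1150, 1250, "+", "l1a", "LINE", "L1"),   # intronic in gA
        RepeatLocus("c", 2000, 2150, "-", "mir1", "SINE", "MIR"),
        RepeatLocus("c", 5000, 5100, "+", "ssr1", "SSR", "(CA)n"),
    ]
    return GenomeBundle({"c": seq}, reps, [ga, gb])
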