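"""Differential-expression statistics on junction counts, and the
observed-versus-expected repeat-class frequency analysis.

The differential tests operate on raw junction-spanning read counts (no
size-factor normalization — the counts are sparse junction evidence, not
expression estimates): a log2 fold change of group means with a
pseudo-count rule for zeros, an empirical fold-change p-value over the
event population, a Wilcoxon rank-sum test (exact by enumeration at small
n, midranks for ties), and a within-group bootstrap (B resamples with
replacement, p = n/B counting resampled statistics beyond the observed
one). The expected-frequency analysis tallies each exon's nearest repeat
per class and genomic region, computed separately for repeat-start and
repeat-end anchoring, and compares observed event classes against it with
binomial tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import GenomeBundle, nearest_repeat
from .simulate import SIM_CLASSES  # canonical six analysed classes


@dataclass
class CountMatrix:
    """events x samples junction counts with a two-group design."""
    counts: pd.DataFrame               # index: event ids, columns: sample ids
    group_of: dict[str, str]

    def __post_init__(self):
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integers")
        missing = [s for s in self.counts.columns if s not in self.group_of]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        self.groups = sorted(set(self.group_of.values()))
        if len(self.groups) != 2:
            raise ValueError("exactly two groups required")

    def group_columns(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.group_of[s] == group]


def log2_fold_change(
    matrix: CountMatrix,
    pseudocount_rule: str = "any_zero",
) -> pd.Series:
    """Per-event log2(mean group2 / mean group1) with a pseudo-count rule.

    ``any_zero`` (default): when any sample of an event has count 0, add 1
    to every sample of that event before averaging, keeping the ratio
    defined and symmetric. ``both_groups_zero``: add 1 only to events whose
    samples are all zero in both groups (a literal reading of adding to
    "samples that contained 0 counts from both sample groups"). ``raw``:
    no pseudo-count; zero denominators give signed infinity.
    """
    g1 = matrix.counts[matrix.group_columns(matrix.groups[0])].to_numpy(float)
    g2 = matrix.counts[matrix.group_columns(matrix.groups[1])].to_numpy(float)
    if pseudocount_rule == "any_zero":
        bump = ((g1 == 0).any(axis=1) | (g2 == 0).any(axis=1))
    elif pseudocount_rule == "both_groups_zero":
        bump = (g1 == 0).all(axis=1) & (g2 == 0).all(axis=1)
    elif pseudocount_rule == "raw":
        bump = np.zeros(len(g1), dtype=bool)
    else:
        raise ValueError(f"unknown pseudocount rule {pseudocount_rule!r}")
    g1 = g1 + bump[:, None]
    g2 = g2 + bump[:, None]
    with np.errstate(divide="ignore"):
        fc = np.log2(g2.mean(axis=1)) - np.log2(g1.mean(axis=1))
    return pd.Series(fc, index=matrix.counts.index, name="log2fc")


def empirical_fc_pvalues(log2fc: pd.Series, mode: str = "literal") -> pd.Series:
    """Empirical p over the event population's fold changes.

    ``literal`` (default): p_i = #{j: fc_j >= fc_i} / N — the fraction of
    events with a fold change at least as large. ``signed``: for events
    with negative fc the tail is reversed (#{fc_j <= fc_i}/N), a two-tailed
    variant for down-regulated events.
    """
    if len(log2fc) < 2:
        raise ValueError("need at least 2 events")
    vals = log2fc.to_numpy()
    n = len(vals)
    ge = np.array([(vals >= v).sum() for v in vals]) / n
    if mode == "literal":
        p = ge
    elif mode == "signed":
        le = np.array([(vals <= v).sum() for v in vals]) / n
        p = np.where(vals < 0, le, ge)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.Series(p, index=log2fc.index, name="p_empirical")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def _ranksum_stat(values: np.ndarray, n1: int) -> float:
    """Midrank sum of the first group over pooled values."""
    ranks = sps.rankdata(values)
    return float(ranks[:n1].sum())


def wilcoxon_test(x: list[float], y: list[float]) -> tuple[float, float]:
    """Two-sided rank-sum test of group x vs group y.

    W is the midrank sum of x. For per-group sizes <= 10 the p-value is
    exact: all C(n, n1) assignments of the pooled midranks are enumerated
    and the two-sided tail is P(|W* - E[W]| >= |W - E[W]|), which handles
    ties correctly. Larger samples fall back to the tie-corrected normal
    approximation. All-identical data gives p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(x) + len(y)
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n1].sum())
    if np.all(pooled == pooled[0]):
        return w, 1.0
    mean_w = n1 * (n + 1) / 2.0
    if len(x) <= 10 and len(y) <= 10:
        obs_dev = abs(w - mean_w)
        hits = total = 0
        for combo in itertools.combinations(range(n), n1):
            ws = ranks[list(combo)].sum()
            total += 1
            if abs(ws - mean_w) >= obs_dev - 1e-9:
                hits += 1
        return w, hits / total
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return w, float(res.pvalue)


def wilcoxon_matrix(matrix: CountMatrix) -> pd.DataFrame:
    g1 = matrix.group_columns(matrix.groups[0])
    g2 = matrix.group_columns(matrix.groups[1])
    rows = []
    for ev in matrix.counts.index:
        w, p = wilcoxon_test(matrix.counts.loc[ev, g1].tolist(),
                             matrix.counts.loc[ev, g2].tolist())
        rows.append((w, p))
    return pd.DataFrame(rows, index=matrix.counts.index, columns=["W", "p_wilcoxon"])


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _centered_stat(x: np.ndarray, y: np.ndarray) -> float:
    """Rank-sum statistic of x centered at its null mean, so the sign of the
    observed statistic is well-defined for the directional counting rule."""
    n1, n = len(x), len(x) + len(y)
    return _ranksum_stat(np.concatenate([x, y]), n1) - n1 * (n + 1) / 2.0


def bootstrap_pvalue(
    x: list[float],
    y: list[float],
    B: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Within-group bootstrap p-value, p = n/B.

    Each of B resamples redraws both groups with replacement from their own
    observed counts and recomputes the centered rank-sum statistic; n
    counts resamples with a statistic > the observed one when the observed
    is positive, or < it when negative. An observed statistic of exactly 0
    (the null center) counts resamples >= 0, giving p near 1 under the
    null, which is the natural limit of the directional rule.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    t_obs = _centered_stat(x, y)
    xs = x[rng.integers(0, len(x), size=(B, len(x)))]
    ys = y[rng.integers(0, len(y), size=(B, len(y)))]
    pooled = np.concatenate([xs, ys], axis=1)
    n1, ntot = len(x), len(x) + len(y)
    ranks = sps.rankdata(pooled, axis=1)
    t = ranks[:, :n1].sum(axis=1) - n1 * (ntot + 1) / 2.0
    if t_obs > 0:
        n = int((t > t_obs).sum())
    elif t_obs < 0:
        n = int((t < t_obs).sum())
    else:
        n = int((t >= 0).sum())
    return n / B


def bootstrap_pvalue_exact(x: list[float], y: list[float]) -> float:
    """Exact value of the bootstrap p by exhaustive enumeration of the
    finite resample space (oracle for small groups; O(n1^n1 * n2^n2))."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    t_obs = _centered_stat(x, y)
    num = den = 0
    for xs in itertools.product(x, repeat=len(x)):
        for ys in itertools.product(y, repeat=len(y)):
            t = _centered_stat(np.array(xs), np.array(ys))
            den += 1
            if t_obs > 0:
                num += t > t_obs
            elif t_obs < 0:
                num += t < t_obs
            else:
                num += t >= 0
    return num / den


# ---------------------------------------------------------------------------
# Observed vs expected repeat classes
# ---------------------------------------------------------------------------

@dataclass
class ExpectedFrequencyTable:
    """Nearest-repeat class x region tallies, per anchoring."""
    # anchoring -> class -> {"intronic": n, "intergenic": n}
    tallies: dict[str, dict[str, dict[str, int]]] = field(default_factory=dict)

    def fractions(self, anchor: str) -> dict[str, float]:
        tally = self.tallies[anchor]
        totals = {c: sum(r.values()) for c, r in tally.items()}
        grand = sum(totals.values())
        return {c: (n / grand if grand else 0.0) for c, n in sorted(totals.items())}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for anchor, tally in self.tallies.items():
            for cls, regions in sorted(tally.items()):
                rows.append({"anchor": anchor, "re_class": cls,
                             "intronic": regions.get("intronic", 0),
                             "intergenic": regions.get("intergenic", 0),
                             "total": sum(regions.values())})
        return pd.DataFrame(rows)


def enumerate_expected(
    bundle: GenomeBundle,
    classes: tuple[str, ...] = SIM_CLASSES,
    plus_strand_only: bool = False,
) -> ExpectedFrequencyTable:
    """Expected fusion combinations: every exon's nearest repeat.

    For each annotated exon the nearest repeat is found twice — once
    anchoring on repeat starts, once on repeat ends (the two tallies
    confirm each other) — and tallied by class and by the repeat's genomic
    region (intronic when inside the gene body, else intergenic). With
    ``plus_strand_only`` only plus-strand repeats are considered.
    """
    table = ExpectedFrequencyTable({a: {} for a in ("start", "end")})
    restricted = None
    if plus_strand_only:
        restricted = GenomeBundle(
            bundle.sequences,
            [r for r in bundle.repeats if r.strand == "+"],
            bundle.genes.values(),
            total_gene_count=bundle.total_gene_count,
            mito_chrom=bundle.mito_chrom)
    src = restricted or bundle
    for anchor in ("start", "end"):
        tally = table.tallies[anchor]
        for gene in src.genes.values():
            for exons in gene.transcripts.values():
                for exon in exons:
                    hit = nearest_repeat(src, exon, anchor=anchor)
                    if hit is None:
                        continue
                    rep, region = hit
                    if rep.re_class not in classes:
                        continue
                    tally.setdefault(rep.re_class, {"intronic": 0, "intergenic": 0})
                    tally[rep.re_class][region] += 1
    return table


def observed_vs_expected(
    observed_classes: list[str],
    expected: ExpectedFrequencyTable,
    anchor: str = "start",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Binomial test of each class's observed event count vs its expected
    fraction; classes absent from the expected table are flagged and
    excluded from testing."""
    if not observed_classes:
        raise ValueError("need at least one observed event")
    frac = expected.fractions(anchor)
    n = len(observed_classes)
    rows = []
    from collections import Counter
    obs = Counter(observed_classes)
    for cls in sorted(set(obs) | set(frac)):
        k = obs.get(cls, 0)
        if cls not in frac or frac[cls] == 0:
            rows.append({"re_class": cls, "observed": k, "observed_fraction": k / n,
                         "expected_fraction": math.nan, "p": math.nan,
                         "direction": "untestable", "significant": False})
            continue
        p = sps.binomtest(k, n, frac[cls], alternative="two-sided").pvalue
        direction = ("depleted" if k / n < frac[cls]
                     else "enriched" if k / n > frac[cls] else "as_expected")
        rows.append({"re_class": cls, "observed": k, "observed_fraction": k / n,
                     "expected_fraction": frac[cls], "p": p,
                     "direction": direction, "significant": p <= alpha})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Combined per-event table
# ---------------------------------------------------------------------------

def differential_stats(
    matrix: CountMatrix,
    B: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    pseudocount_rule: str = "any_zero",
    empirical_mode: str = "literal",
    bh_correct: bool = False,
) -> pd.DataFrame:
    """One row per event: log2fc, empirical p, Wilcoxon W/p, bootstrap p.

    A single seeded generator drives all bootstrap resampling; optional
    Benjamini-Hochberg correction adds q-value columns (raw p at alpha is
    the default decision rule).
    """
    fc = log2_fold_change(matrix, pseudocount_rule)
    emp = empirical_fc_pvalues(fc, empirical_mode)
    wx = wilcoxon_matrix(matrix)
    rng = np.random.default_rng(seed)
    g1 = matrix.group_columns(matrix.groups[0])
    g2 = matrix.group_columns(matrix.groups[1])
    boot = pd.Series(
        [bootstrap_pvalue(matrix.counts.loc[ev, g1].tolist(),
                          matrix.counts.loc[ev, g2].tolist(), B=B, seed=rng)
         for ev in matrix.counts.index],
        index=matrix.counts.index, name="p_bootstrap")
    out = pd.concat([fc, emp, wx, boot], axis=1)
    out["significant"] = (out[["p_empirical", "p_wilcoxon", "p_bootstrap"]]
                          .min(axis=1) <= alpha)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests
        for col in ("p_empirical", "p_wilcoxon", "p_bootstrap"):
            out[f"q_{col[2:]}"] = multipletests(out[col], method="fdr_bh")[1]
    return out
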