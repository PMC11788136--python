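"""Repertoire statistics: diversity, clonality, overlap, lengths, usage.

Clonality measures (inverse Simpson, top/rare/clonal proportions,
rarefaction) operate on total clone counts; length distributions and gene
usage are computed over unique clones — the same split the underlying
study protocol prescribes. Percentages follow the printed-table rounding
convention (half-up; two decimals for alignment rate, one for the
unique/total ratio).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import hypergeom

from .model import RepertoireSample

DEFAULT_RARE_BIN_EDGES = (1, 3, 10, 30, 100, 1000)


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SampleSummary:
    """The per-sample accounting row of a sequencing summary table."""

    total_reads: int
    aligned_reads: int
    aligned_pct: float  # 100 * aligned/total, half-up, 2 decimals
    clonotype_count: int
    unique_clones: int
    unique_over_total_pct: float  # 100 * unique/clonotypes, half-up, 1 decimal


def summarize_counts(
    total_reads: int, aligned_reads: int, clonotype_count: int, unique_clones: int
) -> SampleSummary:
    if clonotype_count <= 0:
        raise ValueError("clonotype_count must be positive")
    return SampleSummary(
        total_reads=total_reads,
        aligned_reads=aligned_reads,
        aligned_pct=_round_half_up(100.0 * aligned_reads / total_reads, 2),
        clonotype_count=clonotype_count,
        unique_clones=unique_clones,
        unique_over_total_pct=_round_half_up(
            100.0 * unique_clones / clonotype_count, 1
        ),
    )


def summarize_sample(sample: RepertoireSample) -> SampleSummary:
    return summarize_counts(
        sample.total_reads,
        sample.aligned_reads,
        sample.clonotype_count,
        sample.unique_clones,
    )


# ------------------------------------------------------------------ diversity

def inverse_simpson(counts) -> float:
    """1 / sum(p_i^2); 1 for a monoclonal sample, the number of clonotypes
    for a perfectly even one."""
    c = np.asarray(list(counts), dtype=float)
    if c.size == 0:
        raise ValueError("empty count vector")
    if np.any(c <= 0):
        raise ValueError("counts must be positive")
    p = c / c.sum()
    return float(1.0 / np.sum(p**2))


def rarefaction(counts, depths) -> list[float]:
    """Analytic (hypergeometric) expected number of distinct clonotypes in
    a random subsample of each depth: E[S(d)] = sum_i (1 - C(N-c_i, d)/C(N, d)).
    """
    c = np.asarray(list(counts), dtype=int)
    if c.size == 0 or np.any(c <= 0):
        raise ValueError("counts must be positive and non-empty")
    n_total = int(c.sum())
    out = []
    for d in depths:
        if not 0 < d <= n_total:
            raise ValueError(f"depth {d} outside (0, {n_total}]")
        # P(clone i absent from the subsample) = hypergeom pmf of drawing 0
        p_absent = hypergeom.pmf(0, n_total, c, d)
        out.append(float(np.sum(1.0 - p_absent)))
    return out


def top_proportion(counts, k: int) -> float:
    """Fraction of reads held by the k most abundant clonotypes."""
    if k < 1:
        raise ValueError("k must be >= 1")
    c = sorted(counts, reverse=True)
    if not c:
        raise ValueError("empty count vector")
    return sum(c[:k]) / sum(c)


def rare_proportion(counts, bin_edges=DEFAULT_RARE_BIN_EDGES) -> dict[str, float]:
    """Fraction of reads in each clone-abundance class; classes are
    [1,1], [2,3], ..., (last edge, inf) for the default edges."""
    edges = list(bin_edges)
    if any(b >= a for a, b in zip(edges[1:], edges)):
        raise ValueError("bin edges must be strictly increasing")
    c = list(counts)
    total = sum(c)
    labels, bounds = [], []
    lo = 1
    for e in edges:
        labels.append(str(e) if lo == e else f"{lo}-{e}")
        bounds.append((lo, e))
        lo = e + 1
    labels.append(f">{edges[-1]}")
    bounds.append((lo, float("inf")))
    out = {}
    for label, (a, b) in zip(labels, bounds):
        out[label] = sum(x for x in c if a <= x <= b) / total
    return out


def clonal_proportion(counts, q: float = 0.31) -> int:
    """Minimal number of top clonotypes whose counts sum to at least a
    fraction q of all reads."""
    if not 0 < q <= 1:
        raise ValueError("q must lie in (0, 1]")
    c = sorted(counts, reverse=True)
    target = q * sum(c)
    acc = 0
    for m, x in enumerate(c, 1):
        acc += x
        if acc >= target - 1e-9:
            return m
    return len(c)


# -------------------------------------------------------------------- overlap

def _keys(sample: RepertoireSample, identity: str) -> set[str]:
    if identity == "cdr3_aa":
        return {c.cdr3_aa for c in sample.clonotypes}
    if identity == "cdr3_nt":
        return {c.cdr3_nt for c in sample.clonotypes}
    raise ValueError("identity must be 'cdr3_aa' or 'cdr3_nt'")


def overlap(
    sample_a: RepertoireSample,
    sample_b: RepertoireSample,
    identity: str = "cdr3_aa",
) -> int:
    """Number of distinct clonotype keys present in both samples."""
    return len(_keys(sample_a, identity) & _keys(sample_b, identity))


def shared_across(samples, identity: str = "cdr3_aa") -> set[str]:
    """Keys present in every sample (public clonotypes)."""
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    sets = [_keys(s, identity) for s in samples]
    return set.intersection(*sets)


def venn_counts(samples, identity: str = "cdr3_aa") -> dict[tuple[str, ...], int]:
    """Cardinality of every Venn region, keyed by the sorted tuple of
    sample_ids the region's keys occur in."""
    membership: dict[str, tuple[str, ...]] = {}
    key_sets = {s.sample_id: _keys(s, identity) for s in samples}
    all_keys = set().union(*key_sets.values())
    out: Counter = Counter()
    for k in all_keys:
        region = tuple(sorted(sid for sid, ks in key_sets.items() if k in ks))
        out[region] += 1
    return dict(out)


# ----------------------------------------------------------- lengths & usage

@dataclass
class LengthDistribution:
    histogram: dict[int, int]  # aa length -> number of unique clones
    ultralong_count: int
    max_length: int
    threshold: int


def length_distribution(
    sample: RepertoireSample, ultralong_threshold: int = 50
) -> LengthDistribution:
    """CDR3 amino-acid length histogram over unique clones, with the count
    of ultra-long clones (length strictly above the threshold)."""
    lengths = [len(c.cdr3_aa) for c in sample.clonotypes]
    if not lengths:
        raise ValueError("sample has no clonotypes")
    hist = dict(sorted(Counter(lengths).items()))
    return LengthDistribution(
        histogram=hist,
        ultralong_count=sum(1 for x in lengths if x > ultralong_threshold),
        max_length=max(lengths),
        threshold=ultralong_threshold,
    )


def gene_usage(sample: RepertoireSample, segment: str = "V") -> dict[str, float]:
    """Gene usage frequencies over unique clones (sums to 1). For D, the
    clones with no confident assignment appear under 'unassigned'."""
    attr = {"V": "v_gene", "D": "d_gene", "J": "j_gene"}[segment]
    n = len(sample.clonotypes)
    if n == 0:
        raise ValueError("sample has no clonotypes")
    tally: Counter = Counter()
    for c in sample.clonotypes:
        name = getattr(c, attr) or ("unassigned" if segment == "D" else "")
        tally[name] += 1
    return {name: cnt / n for name, cnt in sorted(tally.items())}


def junction_indel_profile(table) -> dict[str, dict[int, int]]:
    """Histograms of V deletions, J deletions and N insertions over unique
    clones, from a clonotype table carrying junction bookkeeping columns."""
    out = {}
    for column, key in (
        ("v_deletions", "v_deletions"),
        ("j_deletions", "j_deletions"),
        ("n_insertions", "n_insertions"),
    ):
        out[key] = dict(sorted(Counter(int(x) for x in table[column]).items()))
    return out
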