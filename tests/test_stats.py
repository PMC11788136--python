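"""Repertoire statistics against independent brute-force computations."""

import itertools
import random
from collections import Counter

import numpy as np
import pytest

from iglocus.model import Clonotype, RepertoireSample
from iglocus.seq import translate
from iglocus.stats import (
    clonal_proportion,
    gene_usage,
    inverse_simpson,
    length_distribution,
    overlap,
    rare_proportion,
    rarefaction,
    shared_across,
    summarize_counts,
    top_proportion,
    venn_counts,
)


def sample_from(counts, prefix="x", sample_id="s"):
    clons = []
    for i, c in enumerate(counts):
        nt = "TGT" + "".join(random.Random(i).choices("ACGT", k=18)) + f"{prefix}"
        nt = nt[:21]
        clons.append(Clonotype(nt, translate(nt), c, f"V{i%3}", f"J{i%2}"))
    total = sum(counts)
    return RepertoireSample(sample_id, clons, total, total)


# ------------------------------------------------------------- summary rows

@pytest.mark.parametrize(
    "total,aligned,clonotypes,unique,pct,upct",
    [
        (8046744, 1832517, 44716, 14464, 22.77, 32.3),
        (8014511, 2187835, 90705, 41620, 27.30, 45.9),
        (100, 100, 50, 50, 100.00, 100.0),
    ],
)
def test_summary_percentages(total, aligned, clonotypes, unique, pct, upct):
    s = summarize_counts(total, aligned, clonotypes, unique)
    assert s.aligned_pct == pct
    assert s.unique_over_total_pct == upct


def test_summary_rejects_empty():
    with pytest.raises(ValueError):
        summarize_counts(10, 5, 0, 0)


# ---------------------------------------------------------------- diversity

@pytest.mark.parametrize(
    "counts,expected",
    [([1] * 10, 10.0), ([7], 1.0), ([2, 1, 1], 8 / 3)],
)
def test_inverse_simpson_closed_forms(counts, expected):
    assert inverse_simpson(counts) == pytest.approx(expected)


def test_inverse_simpson_bounds_random():
    rng = random.Random(0)
    for _ in range(100):
        counts = [rng.randrange(1, 50) for _ in range(rng.randrange(1, 30))]
        d = inverse_simpson(counts)
        assert 1.0 - 1e-9 <= d <= len(counts) + 1e-9
        p = np.array(counts) / sum(counts)
        assert d == pytest.approx(1.0 / np.sum(p**2))


def exhaustive_rarefaction(counts, depth):
    """Mean distinct clones over all C(N, depth) subsamples (oracle)."""
    items = [i for i, c in enumerate(counts) for _ in range(c)]
    vals = [len(set(combo)) for combo in itertools.combinations(items, depth)]
    return sum(vals) / len(vals)


def test_rarefaction_identities():
    counts = [5, 3, 2]
    assert rarefaction(counts, [sum(counts)]) == [pytest.approx(3.0)]
    assert rarefaction(counts, [1]) == [pytest.approx(1.0)]


def test_rarefaction_matches_exhaustive_enumeration():
    rng = random.Random(4)
    for _ in range(15):
        k = rng.randrange(1, 5)
        counts = [rng.randrange(1, 5) for _ in range(k)]
        n = sum(counts)
        if n > 12:
            continue
        for depth in range(1, n + 1):
            assert rarefaction(counts, [depth])[0] == pytest.approx(
                exhaustive_rarefaction(counts, depth)
            )


def test_rarefaction_monotone_and_bounds():
    counts = [40, 10, 5, 3, 1, 1]
    depths = list(range(1, sum(counts) + 1, 5))
    vals = rarefaction(counts, depths)
    assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
    with pytest.raises(ValueError):
        rarefaction(counts, [sum(counts) + 1])


# ---------------------------------------------------------------- clonality

def test_top_proportion_examples_and_oracle():
    assert top_proportion([10] * 10, 10) == pytest.approx(1.0)
    assert top_proportion([90, 5, 5], 1) == pytest.approx(0.9)
    rng = random.Random(9)
    for _ in range(100):
        counts = [rng.randrange(1, 100) for _ in range(rng.randrange(1, 40))]
        k = rng.randrange(1, 15)
        expected = sum(sorted(counts, reverse=True)[:k]) / sum(counts)
        assert top_proportion(counts, k) == pytest.approx(expected)


def test_rare_proportion_classes():
    assert rare_proportion([1, 1, 1])["1"] == pytest.approx(1.0)
    r = rare_proportion([25, 500])
    assert r["11-30"] == pytest.approx(25 / 525)
    assert r["101-1000"] == pytest.approx(500 / 525)
    rng = random.Random(10)
    for _ in range(100):
        counts = [rng.randrange(1, 2000) for _ in range(rng.randrange(1, 50))]
        r = rare_proportion(counts)
        assert sum(r.values()) == pytest.approx(1.0)
        # direct binning oracle
        bounds = [(1, 1), (2, 3), (4, 10), (11, 30), (31, 100), (101, 1000),
                  (1001, float("inf"))]
        for (a, b), (label, frac) in zip(bounds, r.items()):
            assert frac == pytest.approx(
                sum(x for x in counts if a <= x <= b) / sum(counts)
            )


def test_clonal_proportion_examples():
    assert clonal_proportion([50, 30, 20], q=0.31) == 1
    assert clonal_proportion([10] * 10, q=0.31) == 4
    counts = [17, 9, 3, 3, 1]
    assert clonal_proportion(counts, q=1.0) == len(counts)


def test_clonal_proportion_concentration_monotonicity():
    rng = random.Random(2)
    for _ in range(50):
        counts = [rng.randrange(1, 30) for _ in range(10)]
        m1 = clonal_proportion(counts)
        counts2 = sorted(counts, reverse=True)
        counts2[0] += 100  # concentrate the repertoire
        m2 = clonal_proportion(counts2)
        assert m2 <= m1


# ------------------------------------------------------------------ overlap

def aa_sample(keys, sample_id):
    clons = [
        Clonotype("TGT" + "GCA" * 3, translate("TGT" + "GCA" * 3), 1, "V", "J")
    ]
    clons = []
    for k in keys:
        # build distinct nt per aa key deterministically
        nt = "".join({"A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
                      "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
                      "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
                      "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT"}[a]
                     for a in k)
        clons.append(Clonotype(nt, k, 1, "V", "J"))
    return RepertoireSample(sample_id, clons, len(clons), len(clons))


def test_overlap_examples():
    a = aa_sample(["CARW", "CATW", "CAGW"], "a")
    assert overlap(a, a) == 3
    b = aa_sample(["CDDW", "CEEW"], "b")
    assert overlap(a, b) == 0
    shared = [f"CA{x}W" for x in "ACDEFGH"]
    c = aa_sample(shared + ["CIIW"], "c")
    d = aa_sample(shared + ["CKKW", "CLLW"], "d")
    assert overlap(c, d) == 7
    assert overlap(c, d) == overlap(d, c) <= min(c.unique_clones, d.unique_clones)


def test_shared_across_and_venn():
    common = [f"CM{x}W" for x in "ACDEF"]
    privates = ["CPAW", "CPCW", "CPDW", "CPEW", "CPFW"]
    samples = [aa_sample(common + [privates[i]], f"s{i}") for i in range(5)]
    shared = shared_across(samples)
    assert shared == set(common)
    regions = venn_counts(samples)
    assert regions[tuple(sorted(s.sample_id for s in samples))] == len(common)
    disjoint = [aa_sample([k], f"t{i}") for i, k in enumerate(["CDDW", "CEEW", "CFFW"])]
    assert shared_across(disjoint) == set()


# ---------------------------------------------------------- lengths & usage

def test_length_distribution_and_ultralong():
    def aa_of(n):
        return "C" + "A" * (n - 2) + "W"

    keys = [aa_of(51), aa_of(55), aa_of(70), aa_of(30)]
    s = aa_sample(keys, "s")
    ld = length_distribution(s, ultralong_threshold=50)
    assert ld.ultralong_count == 3
    assert ld.max_length == 70
    single = aa_sample([aa_of(25)], "t")
    assert length_distribution(single).histogram == {25: 1}


def test_gene_usage_frequencies():
    nt = "TGTGCTTGG"
    clons = [
        Clonotype(nt, translate(nt), 1, "V-a", "J1"),
        Clonotype(nt + "GCT", translate(nt + "GCT"), 1, "V-a", "J1"),
        Clonotype(nt + "GCTGCA", translate(nt + "GCTGCA"), 1, "V-b", "J1"),
    ]
    s = RepertoireSample("s", clons, 3, 3)
    usage = gene_usage(s, "V")
    assert usage == {"V-a": pytest.approx(2 / 3), "V-b": pytest.approx(1 / 3)}
    d_usage = gene_usage(s, "D")
    assert d_usage == {"unassigned": pytest.approx(1.0)}
    assert sum(usage.values()) == pytest.approx(1.0)


def test_usage_bias_recovered_within_binomial_error(reference):
    from iglocus.simulate import RepertoireSpec, simulate_repertoire

    v_names = sorted({r.name for r in reference
                      if r.segment_type == "V" and r.productive})
    biased = v_names[0]
    weights = {n: (0.4 if n == biased else 0.6 / (len(v_names) - 1)) for n in v_names}
    n_reads = 4000
    sim = simulate_repertoire(
        RepertoireSpec(reference=reference, n_reads=n_reads, v_usage=weights, seed=5)
    )
    freq = (sim.read_truth["v_call"] == biased).mean()
    sigma = (0.4 * 0.6 / n_reads) ** 0.5
    assert abs(freq - 0.4) < 3 * sigma


def test_junction_indel_profile_matches_truth(small_sim):
    from iglocus.stats import junction_indel_profile

    prof = junction_indel_profile(small_sim.clonotypes)
    for col in ("v_deletions", "j_deletions", "n_insertions"):
        assert prof[col] == dict(sorted(Counter(small_sim.clonotypes[col]).items()))
    # geometric(0.5) trimming puts the mode at zero
    assert prof["v_deletions"][0] == max(prof["v_deletions"].values())
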