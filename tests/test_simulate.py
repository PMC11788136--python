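"""Generator properties: determinism, truth consistency, noise-free limits."""

import pandas as pd
import pytest

from iglocus.seq import reverse_complement, translate
from iglocus.simulate import (
    GenerationError,
    LocusSpec,
    RepertoireSpec,
    bovid_ultralong_spec,
    generate_locus,
    simulate_repertoire,
)


def test_same_seed_same_locus():
    a = generate_locus(LocusSpec(seed=42, n_v=8, clusters=((2, 2, 2),)))
    b = generate_locus(LocusSpec(seed=42, n_v=8, clusters=((2, 2, 2),)))
    assert a.genome == b.genome
    assert [(g.name, g.interval) for g in a.genes] == [
        (g.name, g.interval) for g in b.genes
    ]


def test_reversed_fraction_bookkeeping():
    spec = LocusSpec(seed=9, n_v=20, reversed_v_fraction=0.3)
    res = generate_locus(spec)
    minus = [g for g in res.genes if g.segment_type == "V" and g.interval.strand == "-"]
    assert len(minus) == round(0.3 * 20) == 6


def test_truth_intervals_slice_back_to_sequences(igh_locus):
    contig = next(iter(igh_locus.genome))
    seq = igh_locus.genome[contig]
    for g in igh_locus.genes:
        if g.segment_type == "C":
            raw = "".join(seq[e.start : e.end] for e in g.exons)
        else:
            raw = seq[g.interval.start : g.interval.end]
        expected = raw if g.interval.strand == "+" else reverse_complement(raw)
        assert g.nt_sequence == expected


def test_clean_locus_is_all_functional():
    spec = LocusSpec(seed=5, n_v=10, v_pseudo_fraction=0, v_orf_fraction=0,
                     j_pseudo_fraction=0, j_orf_fraction=0, c_pseudo_fraction=0)
    res = generate_locus(spec)
    assert all(g.functionality == "F" for g in res.genes)
    assert sum(g.segment_type == "V" for g in res.genes) == 10


def test_d_genes_rejected_for_light_chains():
    with pytest.raises(ValueError):
        LocusSpec(chain="IGK", clusters=((2, 3, 1),))


def test_same_seed_same_repertoire(reference):
    spec = RepertoireSpec(reference=reference, n_reads=50, seed=3)
    a = simulate_repertoire(spec)
    b = simulate_repertoire(RepertoireSpec(reference=reference, n_reads=50, seed=3))
    assert a.reads == b.reads
    assert a.clonotypes.equals(b.clonotypes)


def test_noise_free_limit_reproduces_germline_junction(reference):
    """With trimming and insertion switched off, every junction is the
    anchored germline V..J concatenation."""
    spec = RepertoireSpec(reference=reference, n_reads=40, trim_p=1.0,
                          insert_lambda=0.0, d_probability=0.0, seed=2)
    sim = simulate_repertoire(spec)
    v_by = {r.name: r for r in reference if r.segment_type == "V"}
    j_by = {r.name: r for r in reference if r.segment_type == "J"}
    for row in sim.read_truth.itertuples(index=False):
        v, j = v_by[row.v_call], j_by[row.j_call]
        expected = (
            v.nt_sequence[v.cdr3_anchor :] + j.nt_sequence[: j.cdr3_anchor + 3]
        )
        assert row.junction == expected
        assert (row.v_deletions, row.j_deletions, row.n_insertions) == (0, 0, 0)


def test_read_truth_consistent_with_read_sequences(small_sim, reference):
    """Each read contains its junction (in one orientation), inside the
    amplicon window."""
    lo, hi = small_sim.spec.amplicon_range
    truth = small_sim.read_truth.set_index("read_id")
    for name, seq, qual in small_sim.reads:
        assert len(seq) <= hi
        assert len(qual) == len(seq)
        junction = truth.loc[name, "junction"]
        assert junction in seq or junction in reverse_complement(seq)


def test_stop_planting_fraction_and_filter(reference):
    spec = RepertoireSpec(reference=reference, n_reads=400, force_in_frame=True,
                          stop_fraction=0.1, seed=13)
    sim = simulate_repertoire(spec)
    flagged = sim.read_truth[~sim.read_truth["productive"]]
    assert len(flagged) == pytest.approx(40, abs=3 * (400 * 0.1 * 0.9) ** 0.5)
    # every non-productive truth row carries a stop (frame is forced)
    assert all("*" in aa for aa in flagged["junction_aa"])
    assert all(len(j) % 3 == 0 for j in sim.read_truth["junction"])


def test_ultralong_preset_produces_ultralong_productive_clones(reference):
    spec = bovid_ultralong_spec(reference, seed=4, n_reads=150)
    sim = simulate_repertoire(spec)
    lengths = sim.clonotypes["junction_aa"].str.len()
    productive = sim.clonotypes["productive"]
    assert ((lengths > 50) & productive).sum() > 0
    # the planted core is stop-free in every frame
    core = spec.ultralong_core
    for f in range(3):
        assert "*" not in translate(core, f)
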