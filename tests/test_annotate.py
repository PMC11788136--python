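"""Candidate gene discovery on planted loci."""

import random

import pytest

from iglocus._templates import TEMPLATES
from iglocus.annotate import (
    AnnotationConfig,
    find_c_candidates,
    find_d_candidates,
    find_j_candidates,
    find_leader,
    find_v_candidates,
)
from iglocus.locus import annotate_locus
from iglocus.rss import HEPTAMER_CONSENSUS, NONAMER_CONSENSUS
from iglocus.seq import reverse_complement
from iglocus.simulate import LocusSpec, generate_locus

RC_H, RC_N = reverse_complement(HEPTAMER_CONSENSUS), reverse_complement(NONAMER_CONSENSUS)


def v_exon(chain="IGH"):
    t = TEMPLATES[chain]
    return t["v_leader_tail"] + t["v_mature_nt"] + t["v_stub"]


def rand(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


# ------------------------------------------------------------------ V genes

def test_planted_seed_copy_recovered_verbatim():
    rng = random.Random(0)
    exon = v_exon()
    genome = {"c": rand(rng, 300) + exon + rand(rng, 300)}
    cands = find_v_candidates(genome, {"s": exon})
    assert len(cands) == 1
    c = cands[0]
    assert c.identity_to_seed == 1.0
    assert (c.interval.start, c.interval.end) == (300, 300 + len(exon))
    assert c.exon_sequence == exon


def test_minus_strand_copy_gives_reading_sense_sequence():
    rng = random.Random(1)
    exon = v_exon()
    genome = {"c": rand(rng, 250) + reverse_complement(exon) + rand(rng, 250)}
    cands = find_v_candidates(genome, {"s": exon})
    assert len(cands) == 1
    assert cands[0].interval.strand == "-"
    assert cands[0].exon_sequence == exon


@pytest.mark.parametrize("rate,recovered", [(0.10, True), (0.30, False)])
def test_identity_threshold_governs_recovery(rate, recovered):
    rng = random.Random(7)
    exon = list(v_exon())
    for i in rng.sample(range(len(exon)), int(rate * len(exon))):
        exon[i] = rng.choice([b for b in "ACGT" if b != exon[i]])
    mutated = "".join(exon)
    genome = {"c": rand(rng, 200) + mutated + rand(rng, 200)}
    cands = find_v_candidates(genome, {"s": v_exon()}, AnnotationConfig(min_identity=0.75))
    assert bool(cands) == recovered


def test_leader_search_statuses():
    config = AnnotationConfig()
    rng = random.Random(3)
    leader = TEMPLATES["IGH"]["v_leader"]  # 45 nt, starts ATG, stop-free
    intron = "GT" + rand(rng, 86) + "AG"
    flank = rand(rng, 120).replace("ATG", "ACG")
    up = flank + leader + intron
    status, offset = find_leader(up, config)
    assert status == "ok"
    assert offset == len(leader) + len(intron)
    no_donor = flank + leader + "CA" + intron[2:]
    assert find_leader(no_donor.replace("ATG", "ACG", 0), config)[0] in ("ok", "no_donor")
    # destroy the ATG everywhere -> no init
    assert find_leader(up.replace("ATG", "ACG"), config)[0] == "no_init"


# ------------------------------------------------------------------ D genes

def d_block(core, rng):
    return RC_N + rand(rng, 12) + RC_H + core + HEPTAMER_CONSENSUS + rand(rng, 12) + NONAMER_CONSENSUS


def test_planted_d_core_boundaries():
    rng = random.Random(11)
    core = "GGTATAGGGGGTGGTTC"
    genome = {"c": rand(rng, 150) + d_block(core, rng) + rand(rng, 150)}
    genes = find_d_candidates(genome)
    plus = [g for g in genes if g.interval.strand == "+"]
    assert len(plus) == 1
    g = plus[0]
    assert g.nt_sequence == core
    assert (g.interval.start, g.interval.end) == (150 + 28, 150 + 28 + len(core))


def test_a_rich_core_rejected_by_g_fraction():
    rng = random.Random(12)
    core = "AATATAAAATATAATTC"
    genome = {"c": rand(rng, 150) + d_block(core, rng) + rand(rng, 150)}
    assert all(g.nt_sequence != core for g in find_d_candidates(genome))


def test_decoy_without_downstream_rss_not_reported():
    rng = random.Random(13)
    cores = ["GGTAGGGGTGGA", "GGGTTGGGGCGG", "GGAGGGGTTGGC"]
    seq = rand(rng, 120)
    planted = []
    for core in cores:
        planted.append(core)
        seq += d_block(core, rng) + rand(rng, 120)
    # decoy: upstream 12-RSS but no downstream signal
    decoy = "GGGGTTAGGGGG"
    seq += RC_N + rand(rng, 12) + RC_H + decoy + rand(rng, 140)
    genes = [g for g in find_d_candidates({"c": seq}) if g.interval.strand == "+"]
    assert sorted(g.nt_sequence for g in genes) == sorted(cores)


# ------------------------------------------------------------------ J genes

def j_block(coding, rng, spacer=23):
    return RC_N + rand(rng, spacer) + RC_H + coding + "GT"


def test_planted_j_with_motif_detected():
    rng = random.Random(21)
    coding = TEMPLATES["IGH"]["j_nt"]  # WGQG at codons 9-12
    flank = rand(rng, 200)
    genome = {"c": flank + j_block(coding, rng) + rand(rng, 200)}
    cands = [c for c in find_j_candidates(genome) if c.interval.strand == "+"]
    mine = [c for c in cands if c.coding_sequence == coding]
    assert len(mine) == 1
    c = mine[0]
    assert c.motif_found and c.donor_found and c.strict_rss
    assert (c.interval.start, c.interval.end) == (len(flank) + 39, len(flank) + 39 + 48)


def test_j_without_tryptophan_detected_with_motif_flag_false():
    rng = random.Random(22)
    coding = TEMPLATES["IGH"]["j_nt"]
    coding = coding[:24] + "TCG" + coding[27:]  # W -> S
    genome = {"c": rand(rng, 200) + j_block(coding, rng) + rand(rng, 200)}
    cands = [c for c in find_j_candidates(genome) if c.coding_sequence == coding]
    assert len(cands) == 1 and not cands[0].motif_found and cands[0].strict_rss


# ------------------------------------------------------------------ C genes

def test_multi_exon_c_gene_assembled():
    rng = random.Random(31)
    exons = TEMPLATES["IGH"]["c_exons"]
    seq = rand(rng, 200)
    for k, ex in enumerate(exons):
        if k:
            seq += "GT" + rand(rng, 120) + "AG"
        seq += ex
    seq += rand(rng, 200)
    seeds = {f"e{k}": ex for k, ex in enumerate(exons)}
    cands = [c for c in find_c_candidates({"c": seq}, seeds) if c.interval.strand == "+"]
    assert len(cands) == 1
    assert len(cands[0].exons) == 4
    assert all(ok == (True, True) for ok in cands[0].introns_ok)


def test_single_exon_and_distant_genes_not_merged():
    rng = random.Random(32)
    ex = TEMPLATES["IGK"]["c_exons"][0]
    seq = rand(rng, 100) + ex + rand(rng, 5000) + ex + rand(rng, 100)
    cands = [c for c in find_c_candidates({"c": seq}, {"e": ex}) if c.interval.strand == "+"]
    assert len(cands) == 2
    assert all(len(c.exons) == 1 for c in cands)


# ------------------------------------------------------- whole-locus checks

def test_strand_symmetry_of_locus_annotation(igh_locus):
    """Annotating the reverse-complemented genome yields mirror-image
    coordinates and identical gene sequences."""
    contig = next(iter(igh_locus.genome))
    seq = igh_locus.genome[contig]
    L = len(seq)
    fwd = annotate_locus(igh_locus.genome, igh_locus.v_seeds, igh_locus.c_seeds, "IGH")
    rev = annotate_locus({contig: reverse_complement(seq)}, igh_locus.v_seeds,
                         igh_locus.c_seeds, "IGH")

    def norm(genes, flip):
        out = set()
        for g in genes:
            iv = g.interval
            if flip:
                start, end = L - iv.end, L - iv.start
                strand = "+" if iv.strand == "-" else "-"
            else:
                start, end, strand = iv.start, iv.end, iv.strand
            out.add((g.segment_type, start, end, strand, g.nt_sequence,
                     g.functionality, tuple(sorted(g.defects))))
        return out

    assert norm(fwd.genes, False) == norm(rev.genes, True)


def test_zero_mutation_locus_recovered_exactly(igh_locus, annotated):
    truth = {
        (g.segment_type, g.interval.start, g.interval.end, g.interval.strand)
        for g in igh_locus.genes
    }
    pred = {
        (g.segment_type, g.interval.start, g.interval.end, g.interval.strand)
        for g in annotated.genes
    }
    assert truth == pred
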