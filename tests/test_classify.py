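"""F/ORF/P rule tables, V numbering, families and locus naming."""

import random

import pytest

from iglocus._templates import TEMPLATES
from iglocus.annotate import JCandidate, CCandidate, VCandidate
from iglocus.classify import (
    CHAIN_PREFIX,
    assign_families,
    classification_summary,
    classify_c,
    classify_j,
    classify_v,
    global_identity,
    name_genes,
    number_v,
)
from iglocus.model import (
    GenomicInterval,
    GermlineGene,
    MISSING_C23,
    NO_ACCEPTOR_SPLICE,
    NO_DONOR_SPLICE,
    NO_INIT_CODON,
    NO_J_HEPTAMER,
    NO_RSS,
    NO_WGXG,
    RssHit,
    STOP_CODON,
)
from iglocus.rss import HEPTAMER_CONSENSUS, NONAMER_CONSENSUS
from iglocus.seq import translate

TPL = TEMPLATES["IGH"]
TEMPLATE_AA = translate(TPL["v_mature_nt"])


# ---------------------------------------------------------------- numbering

def test_template_self_numbering_and_anchors():
    n = number_v(TEMPLATE_AA, "IGH")
    assert n is not None
    assert n.residue_at(23) == "C"
    assert n.residue_at(41) == "W"
    assert n.residue_at(89) == "L"
    assert n.residue_at(104) == "C"
    assert all(n.position_map[p] == p - 1 for p in range(1, 105))


def test_numbering_tracks_insertion_in_cdr1():
    # lengthen CDR1 (template positions 27-38) by two residues
    aa = TEMPLATE_AA[:32] + "GS" + TEMPLATE_AA[32:]
    n = number_v(aa, "IGH")
    assert n.residue_at(23) == "C"
    assert n.residue_at(41) == "W"
    assert n.residue_at(104) == "C"
    assert n.position_map[104] == 105  # shifted by the 2-residue insertion


def test_numbering_tracks_substitution():
    aa = TEMPLATE_AA[:103] + "R" + TEMPLATE_AA[104:]
    n = number_v(aa, "IGH")
    assert n.residue_at(104) == "R"


def test_short_sequence_unalignable():
    assert number_v(TEMPLATE_AA[:80], "IGH") is None


# ----------------------------------------------------------- V rule table

def make_v_candidate(defect=None):
    rng = random.Random(99)
    exon = list(TPL["v_leader_tail"] + TPL["v_mature_nt"] + TPL["v_stub"])
    tail = len(TPL["v_leader_tail"])
    if defect == STOP_CODON:
        exon[tail + 3 * 49 : tail + 3 * 50] = "TGA"
    if defect == MISSING_C23:
        exon[tail + 3 * 22 : tail + 3 * 23] = "CGT"
    exon = "".join(exon)
    leader = TPL["v_leader"] if defect != NO_INIT_CODON else "ACG" + TPL["v_leader"][3:]
    donor = "GT" if defect != NO_DONOR_SPLICE else "CA"
    acceptor = "AG" if defect != NO_ACCEPTOR_SPLICE else "CC"
    flank = "".join(rng.choice("ACGT") for _ in range(150)).replace("ATG", "ACG")
    intron = donor + "".join(rng.choice("CCA") for _ in range(86)) + acceptor
    hept = HEPTAMER_CONSENSUS if defect != NO_RSS else "CTCAGTG"
    rss = None
    if defect != NO_RSS:
        rss = RssHit(GenomicInterval("c", 1000, 1039, "+"), 23, hept,
                     NONAMER_CONSENSUS, 23, 7, 9)
    return VCandidate(
        interval=GenomicInterval("c", 500, 500 + len(exon), "+"),
        exon_sequence=exon,
        identity_to_seed=1.0,
        seed_name="s",
        chain="IGH",
        upstream=flank + leader + intron,
        downstream="",
        rss=rss,
    )


@pytest.mark.parametrize(
    "defect,functionality",
    [
        (None, "F"),
        (STOP_CODON, "P"),
        (MISSING_C23, "P"),
        (NO_INIT_CODON, "P"),
        (NO_DONOR_SPLICE, "P"),
        (NO_ACCEPTOR_SPLICE, "P"),
        (NO_RSS, "ORF"),
    ],
)
def test_classify_v_rule_table(defect, functionality):
    cls = classify_v(make_v_candidate(defect))
    assert cls.functionality == functionality
    if defect is None:
        assert cls.defects == []
    else:
        assert cls.defects == [defect]


def test_classify_v_is_deterministic():
    cand = make_v_candidate(STOP_CODON)
    first = classify_v(cand)
    second = classify_v(cand)
    assert (first.functionality, first.defects) == (second.functionality, second.defects)


# ----------------------------------------------------------- J rule table

def make_j_candidate(strict_rss=True, motif=True, donor=True):
    coding = TPL["j_nt"]
    return JCandidate(
        interval=GenomicInterval("c", 100, 148, "+"),
        coding_sequence=coding,
        chain="IGH",
        rss=RssHit(GenomicInterval("c", 61, 100, "+"), 23, HEPTAMER_CONSENSUS,
                   NONAMER_CONSENSUS, 23, 7, 9),
        strict_rss=strict_rss,
        motif_found=motif,
        donor_found=donor,
    )


@pytest.mark.parametrize(
    "kwargs,expected",
    [
        (dict(), ("F", [])),
        (dict(motif=False), ("ORF", [NO_WGXG])),
        (dict(donor=False), ("P", [NO_DONOR_SPLICE])),
        (dict(strict_rss=False), ("ORF", [NO_J_HEPTAMER])),
        (dict(motif=False, donor=False), ("P", [NO_DONOR_SPLICE, NO_WGXG])),
    ],
)
def test_classify_j_rule_table(kwargs, expected):
    functionality, defects = classify_j(make_j_candidate(**kwargs))
    assert (functionality, sorted(defects)) == (expected[0], sorted(expected[1]))


# ----------------------------------------------------------- C rule table

def make_c_candidate(n_exons=4, stop_in=None, bad_intron=None):
    exons = list(TPL["c_exons"][:n_exons])
    if stop_in is not None:
        ex = exons[stop_in]
        exons[stop_in] = ex[:30] + "TAA" + ex[33:]
    introns_ok = [(True, True)] * (n_exons - 1)
    if bad_intron is not None:
        introns_ok[bad_intron] = (True, False)
    return CCandidate(
        interval=GenomicInterval("c", 0, 1000 * n_exons, "+"),
        exons=[GenomicInterval("c", 100 * k, 100 * k + 96, "+") for k in range(n_exons)],
        exon_seqs=exons,
        introns_ok=introns_ok,
        chain="IGH",
        identity_to_seed=1.0,
        seed_name="e",
    )


def test_classify_c_rules():
    assert classify_c(make_c_candidate()) == ("F", [])
    functionality, defects = classify_c(make_c_candidate(stop_in=1))
    assert functionality == "P" and defects == [STOP_CODON]
    functionality, defects = classify_c(make_c_candidate(bad_intron=2))
    assert functionality == "P" and defects == [NO_ACCEPTOR_SPLICE]
    # a stop in the final exon does not demote a multi-exon gene
    assert classify_c(make_c_candidate(stop_in=3))[0] == "F"
    # ... but does in a single-exon gene
    assert classify_c(make_c_candidate(n_exons=1, stop_in=0))[0] == "P"


# ------------------------------------------------------------------ families

def mutate_fraction(seq, fraction, rng, block=0):
    """Scattered substitutions at a given fraction of positions; mutants
    built with different ``block`` values share no mutated site."""
    s = list(seq)
    n = len(s)
    order = list(range(n))
    random.Random(1234).shuffle(order)  # fixed site order, shared by blocks
    k = int(fraction * n)
    for i in order[block * k : (block + 1) * k]:
        s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
    return "".join(s)


def test_identical_sequences_share_family():
    base = TPL["v_mature_nt"]
    assert assign_families([base, base]) == ["1", "1"]


def test_low_identity_pair_split():
    rng = random.Random(0)
    base = TPL["v_mature_nt"]
    other = mutate_fraction(base, 0.30, rng)
    assert global_identity(base, other) < 0.75
    assert len(set(assign_families([base, other]))) == 2


def test_single_linkage_chains_families():
    rng = random.Random(0)
    b = TPL["v_mature_nt"]
    a = mutate_fraction(b, 0.18, rng, block=0)
    c = mutate_fraction(b, 0.18, rng, block=1)
    assert global_identity(a, b) >= 0.75
    assert global_identity(b, c) >= 0.75
    assert global_identity(a, c) < 0.75
    labels = assign_families([a, b, c])
    assert len(set(labels)) == 1


def test_family_assignment_order_invariant():
    rng = random.Random(1)
    base = TPL["v_mature_nt"]
    seqs = [mutate_fraction(base, 0.05, rng, block=i) for i in range(4)]
    seqs.append(mutate_fraction(base, 0.30, rng))
    fwd = assign_families(seqs)
    rev = assign_families(seqs[::-1])
    # same partition regardless of order
    def partition(labels):
        groups = {}
        for i, lab in enumerate(labels):
            groups.setdefault(lab, set()).add(i)
        return {frozenset(g) for g in groups.values()}
    n = len(seqs)
    rev_mapped = [rev[n - 1 - i] for i in range(n)]
    assert partition(fwd) == partition(rev_mapped)


# -------------------------------------------------------------------- names

def gene(seg, start, family="", chain="IGH"):
    return GermlineGene(
        name="?",
        segment_type=seg,
        chain=chain,
        interval=GenomicInterval("c", start, start + 50),
        functionality="F",
        nt_sequence="A" * 50,
        family=family,
    )


def test_two_cluster_j_naming():
    genes = (
        [gene("J", 100 + 60 * i) for i in range(3)]
        + [gene("C", 400)]
        + [gene("J", 600), gene("J", 700)]
        + [gene("C", 900)]
    )
    named = name_genes(genes, "IGH")
    j_names = [g.name for g in named if g.segment_type == "J"]
    assert j_names == ["IgHJ1-1", "IgHJ1-2", "IgHJ1-3", "IgHJ2-1", "IgHJ2-2"]


def test_single_c_gene_has_no_ordinal():
    named = name_genes([gene("C", 100, chain="IGK")], "IGK")
    assert named[0].name == f"{CHAIN_PREFIX['IGK']}C"


def test_v_ordinals_span_whole_locus():
    genes = [gene("V", 100 * i, family=f) for i, f in enumerate(["1", "2", "1", "2", "1"], 1)]
    named = name_genes(genes, "IGH")
    assert [g.name for g in named] == [
        "IgHV1-1", "IgHV2-2", "IgHV1-3", "IgHV2-4", "IgHV1-5"
    ]


def test_duplicate_coordinates_rejected():
    with pytest.raises(ValueError):
        name_genes([gene("V", 100), gene("V", 100)], "IGH")


def test_classification_summary_totals():
    counts = {
        "IgHV": {"F": 19, "P": 35, "ORF": 0},
        "IgλV": {"F": 31, "P": 35, "ORF": 5},
    }
    df = classification_summary(counts)
    assert df.loc["Total", "IgHV"] == 54
    assert df.loc["Total", "IgλV"] == 71


def test_every_pseudogene_has_a_defect(annotated):
    for g in annotated.genes:
        if g.functionality == "P":
            assert g.defects
        if g.functionality == "F":
            assert not g.defects
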