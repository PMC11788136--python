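"""Sequence utilities, domain types and file round-trips."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iglocus.io import (
    ParseError,
    read_airr,
    read_fasta,
    read_fastq,
    read_gff3,
    write_airr,
    write_fasta,
    write_fastq,
    write_gff3,
)
from iglocus.model import Clonotype, GenomicInterval, GermlineGene, RepertoireSample
from iglocus.seq import longest_common_substring, reverse_complement, translate

NT = st.text(alphabet="ACGT", min_size=0, max_size=60)


@pytest.mark.parametrize(
    "nt,frame,expected",
    [
        ("TGTGCT", 0, "CA"),
        ("TAA", 0, "*"),
        ("ATGTAA", 1, "C"),  # TGT then trailing AA truncated
        ("ATGAAA", 0, "MK"),
        ("NNNACG", 0, "XT"),
        ("AC", 0, ""),
    ],
)
def test_translate(nt, frame, expected):
    assert translate(nt, frame) == expected


def test_translate_rejects_bad_frame():
    with pytest.raises(ValueError):
        translate("ACGT", 3)


@given(NT)
@settings(max_examples=200, deadline=None)
def test_reverse_complement_involution(s):
    assert reverse_complement(reverse_complement(s)) == s


@given(st.text(alphabet="ACGT", min_size=3, max_size=90))
@settings(max_examples=200, deadline=None)
def test_translate_stop_free_without_stop_codons(s):
    aa = translate(s)
    has_stop_codon = any(
        s[i : i + 3] in ("TAA", "TAG", "TGA") for i in range(0, len(s) - 2, 3)
    )
    assert ("*" in aa) == has_stop_codon


@given(NT, NT)
@settings(max_examples=100, deadline=None)
def test_longest_common_substring_is_common_and_maximal(a, b):
    ln, ai, bi = longest_common_substring(a, b)
    assert a[ai : ai + ln] == b[bi : bi + ln]
    # no common substring of length ln+1 exists
    longer = {a[i : i + ln + 1] for i in range(len(a) - ln)}
    assert not any(w in b for w in longer)


def test_interval_validation():
    with pytest.raises(ValueError):
        GenomicInterval("c", 5, 5)
    with pytest.raises(ValueError):
        GenomicInterval("c", -1, 5)
    iv = GenomicInterval("c", 10, 20, "-")
    assert len(iv) == 10


def test_clonotype_invariants():
    c = Clonotype("TGTGCT", "CA", 5, "V1", "J1")
    assert c.productive
    with pytest.raises(ValueError):
        Clonotype("TGTGCT", "CC", 1, "V1", "J1")
    with pytest.raises(ValueError):
        Clonotype("TGTGCT", "CA", 0, "V1", "J1")


def test_sample_accounting_invariants():
    c = Clonotype("TGTGCT", "CA", 5, "V1", "J1")
    with pytest.raises(ValueError):
        RepertoireSample("s", [c], total_reads=10, aligned_reads=11)
    with pytest.raises(ValueError):
        RepertoireSample("s", [c], total_reads=10, aligned_reads=4)
    s = RepertoireSample("s", [c], total_reads=10, aligned_reads=6)
    assert s.clonotype_count == 5 and s.unique_clones == 1


def test_fasta_fastq_round_trip(tmp_path):
    records = {"geneA": "ACGTACGT", "geneB": "GGGTTTCC"}
    p = tmp_path / "x.fasta"
    write_fasta(p, records)
    assert read_fasta(p) == records
    reads = [("r1", "ACGT", "IIII"), ("r2", "GGTTA", "IIIII")]
    q = tmp_path / "x.fastq"
    write_fastq(q, reads)
    assert read_fastq(q) == reads


def test_gff3_round_trip_and_coordinates(tmp_path):
    gene = GermlineGene(
        name="IgHV1-1",
        segment_type="V",
        chain="IGH",
        interval=GenomicInterval("chr1", 10, 20, "+"),
        functionality="P",
        defects=["STOP_CODON"],
        nt_sequence="ACGTACGTAC",
        family="1",
    )
    p = tmp_path / "x.gff3"
    write_gff3(p, [gene])
    text = p.read_text()
    # 0-based [10, 20) becomes 1-based inclusive 11..20
    assert "\t11\t20\t" in text
    back = read_gff3(p, sequences={"chr1": "N" * 10 + "ACGTACGTAC" + "N" * 5})
    assert len(back) == 1
    g = back[0]
    assert g.interval == gene.interval
    assert g.functionality == "P" and g.defects == ["STOP_CODON"]
    assert g.nt_sequence == "ACGTACGTAC"


def test_gff3_parse_error_names_line(tmp_path):
    p = tmp_path / "bad.gff3"
    p.write_text("##gff-version 3\nchr1\tonly\tthree\n")
    with pytest.raises(ParseError, match="line 2"):
        read_gff3(p)


def test_airr_round_trip_and_field_mapping(tmp_path):
    c = Clonotype("TGTGCTTGG", "CAW", 5, "IgHV1-1", "IgHJ1-1", d_gene="IgHD1-1")
    sample = RepertoireSample("B1", [c], total_reads=5, aligned_reads=5)
    p = tmp_path / "x.tsv"
    write_airr(p, [sample])
    back = read_airr(p)
    assert len(back) == 1 and back[0].sample_id == "B1"
    rc = back[0].clonotypes[0]
    assert rc.count == 5 and rc.v_gene == "IgHV1-1" and rc.d_gene == "IgHD1-1"
    assert rc.cdr3_nt == "TGTGCTTGG" and rc.cdr3_aa == "CAW"
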