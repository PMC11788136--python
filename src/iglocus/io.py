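"""Readers and writers for FASTA, FASTQ, GFF3 and AIRR-style clonotype TSV.

FASTA/FASTQ go through Bio.SeqIO. The GFF3 writer emits 1-based inclusive
coordinates (internal intervals are 0-based half-open); functionality and
defect codes travel in the attribute column. The AIRR table is the
community-standard rearrangement schema restricted to the columns this
package produces.
"""

from __future__ import annotations

import os
from urllib.parse import quote, unquote

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import Clonotype, GenomicInterval, GermlineGene, RepertoireSample
from .seq import translate

AIRR_COLUMNS = [
    "sample_id",
    "v_call",
    "d_call",
    "j_call",
    "junction",
    "junction_aa",
    "duplicate_count",
]

_FEATURE_TYPES = {
    "V": "V_gene_segment",
    "D": "D_gene_segment",
    "J": "J_gene_segment",
    "C": "C_gene_segment",
}
_SEGMENT_OF = {v: k for k, v in _FEATURE_TYPES.items()}


class ParseError(ValueError):
    """Malformed record in an input file; message names the line."""


# ---------------------------------------------------------------- FASTA/FASTQ

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(path, records: dict[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s), id=n, description="") for n, s in records.items()),
        os.fspath(path),
        "fasta",
    )


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Read Sanger phred+33 FASTQ as ``(name, sequence, quality)`` tuples."""
    out = []
    for rec in SeqIO.parse(os.fspath(path), "fastq"):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        out.append((rec.id, str(rec.seq).upper(), qual))
    return out


def write_fastq(path, reads: list[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# --------------------------------------------------------------------- GFF3

def _attr_str(pairs: dict[str, str]) -> str:
    return ";".join(f"{k}={quote(str(v), safe=' ,')}" for k, v in pairs.items())


def write_gff3(path, genes: list[GermlineGene]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.interval.contig, g.interval.start)):
            iv = g.interval
            attrs = {"ID": g.name, "functionality": g.functionality}
            if g.family:
                attrs["family"] = g.family
            if g.defects:
                attrs["defects"] = ",".join(g.defects)
            attrs["chain"] = g.chain
            for key, val in g.attributes.items():
                attrs[str(key)] = str(val)
            fh.write(
                "\t".join(
                    [
                        iv.contig,
                        "iglocus",
                        _FEATURE_TYPES[g.segment_type],
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand,
                        ".",
                        _attr_str(attrs),
                    ]
                )
                + "\n"
            )
            for k, ex in enumerate(g.exons, 1):
                fh.write(
                    "\t".join(
                        [
                            ex.contig,
                            "iglocus",
                            "exon",
                            str(ex.start + 1),
                            str(ex.end),
                            ".",
                            ex.strand,
                            ".",
                            _attr_str({"ID": f"{g.name}.exon{k}", "Parent": g.name}),
                        ]
                    )
                    + "\n"
                )
            for which, hit in (("RSS3", g.rss), ("RSS5", g.rss_5p)):
                if hit is None:
                    continue
                fh.write(
                    "\t".join(
                        [
                            hit.interval.contig,
                            "iglocus",
                            "RSS",
                            str(hit.interval.start + 1),
                            str(hit.interval.end),
                            ".",
                            hit.interval.strand,
                            ".",
                            _attr_str(
                                {
                                    "ID": f"{g.name}.{which}",
                                    "Parent": g.name,
                                    "spacer_class": hit.spacer_class,
                                    "spacer_length": hit.spacer_length,
                                    "heptamer": hit.heptamer,
                                    "nonamer": hit.nonamer,
                                }
                            ),
                        ]
                    )
                    + "\n"
                )


def read_gff3(path, sequences: dict[str, str] | None = None) -> list[GermlineGene]:
    """Read gene-level features back from a GFF3 written by this package.

    Exon and RSS sub-features are re-attached to their parent gene. If
    ``sequences`` is given, reading-sense gene sequences are re-sliced from
    it; otherwise ``nt_sequence`` is left empty.
    """
    from .seq import reverse_complement

    genes: dict[str, GermlineGene] = {}
    order: list[str] = []
    sub_rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 columns")
            contig, _src, ftype, start, end, _score, strand, _frame, attrs = parts
            try:
                iv = GenomicInterval(contig, int(start) - 1, int(end), strand)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            attr = {
                k: unquote(v)
                for k, v, in (p.split("=", 1) for p in attrs.split(";") if p)
            }
            if ftype in _SEGMENT_OF:
                seq = ""
                if sequences is not None:
                    raw = sequences[contig][iv.start : iv.end]
                    seq = raw if strand == "+" else reverse_complement(raw)
                g = GermlineGene(
                    name=attr.get("ID", f"feature{lineno}"),
                    segment_type=_SEGMENT_OF[ftype],
                    chain=attr.get("chain", "IGH"),
                    interval=iv,
                    functionality=attr.get("functionality", "F"),
                    family=attr.get("family", ""),
                    defects=[d for d in attr.get("defects", "").split(",") if d],
                    nt_sequence=seq,
                    attributes={
                        k: v
                        for k, v in attr.items()
                        if k
                        not in {"ID", "functionality", "family", "defects", "chain"}
                    },
                )
                genes[g.name] = g
                order.append(g.name)
            elif ftype in ("exon", "RSS"):
                sub_rows.append((ftype, iv, attr))
    from .model import RssHit

    for ftype, iv, attr in sub_rows:
        parent = genes.get(attr.get("Parent", ""))
        if parent is None:
            continue
        if ftype == "exon":
            parent.exons.append(iv)
        else:
            hit = RssHit(
                interval=iv,
                spacer_class=int(attr["spacer_class"]),
                heptamer=attr["heptamer"],
                nonamer=attr["nonamer"],
                spacer_length=int(attr["spacer_length"]),
                heptamer_matches=sum(
                    a == b for a, b in zip(attr["heptamer"], "CACAGTG")
                ),
                nonamer_matches=sum(
                    a == b for a, b in zip(attr["nonamer"], "ACAAAAACC")
                ),
            )
            if attr["ID"].endswith("RSS5"):
                parent.rss_5p = hit
            else:
                parent.rss = hit
    for g in genes.values():
        g.exons.sort(key=lambda e: e.start)
    return [genes[n] for n in order]


# --------------------------------------------------------------------- AIRR

def write_airr(path, samples: list[RepertoireSample]) -> None:
    rows = []
    for s in samples:
        for c in s.clonotypes:
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "v_call": c.v_gene,
                    "d_call": c.d_gene,
                    "j_call": c.j_gene,
                    "junction": c.cdr3_nt,
                    "junction_aa": c.cdr3_aa,
                    "duplicate_count": c.count,
                }
            )
    pd.DataFrame(rows, columns=AIRR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_airr(path) -> list[RepertoireSample]:
    """Read an AIRR-style TSV into one RepertoireSample per sample_id.

    Read-level accounting (total/aligned reads) is not stored in the table;
    both fields are set to the sum of duplicate counts.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(AIRR_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: line 1: missing AIRR columns {sorted(missing)}")
    samples = []
    for sid, grp in df.groupby("sample_id", sort=False):
        clons = []
        for i, row in enumerate(grp.itertuples(index=False), 1):
            nt = row.junction.upper()
            aa = translate(nt)
            if row.junction_aa and row.junction_aa != aa:
                raise ParseError(
                    f"{path}: sample {sid} row {i}: junction_aa does not "
                    f"match translation of junction"
                )
            clons.append(
                Clonotype(
                    cdr3_nt=nt,
                    cdr3_aa=aa,
                    count=int(row.duplicate_count),
                    v_gene=row.v_call,
                    d_gene=row.d_call,
                    j_gene=row.j_call,
                )
            )
        total = sum(c.count for c in clons)
        samples.append(
            RepertoireSample(
                sample_id=str(sid),
                clonotypes=clons,
                total_reads=total,
                aligned_reads=total,
            )
        )
    return samples
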