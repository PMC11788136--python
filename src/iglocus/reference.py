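"""Segmented germline reference: FR/CDR boundaries and CDR3 anchors.

The CDR3 convention used throughout the package is anchor-INCLUSIVE: the
junction runs from the V gene's conserved cysteine codon (position 104)
through the J gene's W/F codon of the W/F-G-x-G motif, both codons
included. Reference serialization is a documented FASTA + TSV pair.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .classify import V_REGION_SPANS, number_v
from .io import read_fasta, write_fasta
from .model import GermlineGene
from .seq import translate

logger = logging.getLogger(__name__)

_J_MOTIF = {"IGH": re.compile("WG.G"), "IGK": re.compile("FG.G"), "IGL": re.compile("FG.G")}


@dataclass
class ReferenceRecord:
    """A germline gene ready for read alignment.

    ``segment_boundaries`` maps region names (FR1..FR3, CDR1, CDR2 for V;
    FR4 for J) to half-open nucleotide spans on ``nt_sequence``;
    ``cdr3_anchor`` is the nucleotide offset of the conserved C104 codon
    (V) or of the motif W/F codon (J)."""

    name: str
    segment_type: str
    chain: str
    functionality: str
    nt_sequence: str
    segment_boundaries: dict[str, tuple[int, int]] = field(default_factory=dict)
    cdr3_anchor: int | None = None

    @property
    def productive(self) -> bool:
        return self.functionality == "F"

    def anchor_residue(self) -> str | None:
        if self.cdr3_anchor is None:
            return None
        return translate(self.nt_sequence[self.cdr3_anchor : self.cdr3_anchor + 3])


def _build_v_record(gene: GermlineGene) -> ReferenceRecord | None:
    best = None
    for frame in range(3):
        numbered = number_v(translate(gene.nt_sequence, frame), gene.chain)
        if numbered is not None and (best is None or numbered.score > best[1].score):
            best = (frame, numbered)
    if best is None:
        logger.info("reference: %s excluded (unalignable)", gene.name)
        return None
    frame, numbered = best
    if 104 not in numbered.position_map:
        logger.info("reference: %s excluded (position 104 not mapped)", gene.name)
        return None
    if numbered.residue_at(104) != "C":
        logger.info("reference: %s excluded (no conserved cysteine at 104)", gene.name)
        return None
    boundaries = {}
    for region, lo, hi in V_REGION_SPANS:
        idxs = [numbered.position_map[p] for p in range(lo, hi + 1) if p in numbered.position_map]
        if not idxs:
            continue
        boundaries[region] = (frame + 3 * min(idxs), frame + 3 * (max(idxs) + 1))
    anchor = frame + 3 * numbered.position_map[104]
    return ReferenceRecord(
        name=gene.name,
        segment_type="V",
        chain=gene.chain,
        functionality=gene.functionality,
        nt_sequence=gene.nt_sequence,
        segment_boundaries=boundaries,
        cdr3_anchor=anchor,
    )


def _build_j_record(gene: GermlineGene) -> ReferenceRecord | None:
    aa = translate(gene.nt_sequence)
    m = _J_MOTIF[gene.chain].search(aa)
    if m is None:
        logger.info("reference: %s excluded (no W/F-G-x-G motif)", gene.name)
        return None
    anchor = 3 * m.start()
    return ReferenceRecord(
        name=gene.name,
        segment_type="J",
        chain=gene.chain,
        functionality=gene.functionality,
        nt_sequence=gene.nt_sequence,
        segment_boundaries={"FR4": (anchor, 3 * len(aa))},
        cdr3_anchor=anchor,
    )


def build_reference(genes: list[GermlineGene]) -> list[ReferenceRecord]:
    """Turn a classified locus into reference records.

    Every V or J gene whose anchor can be located yields a record
    (pseudogenes included, flagged by their functionality); D genes are
    carried as plain sequences for junction assignment. C genes are not
    part of the junction-alignment reference.
    """
    records: list[ReferenceRecord] = []
    for gene in genes:
        if gene.segment_type == "V":
            rec = _build_v_record(gene)
        elif gene.segment_type == "J":
            rec = _build_j_record(gene)
        elif gene.segment_type == "D":
            rec = ReferenceRecord(
                name=gene.name,
                segment_type="D",
                chain=gene.chain,
                functionality=gene.functionality,
                nt_sequence=gene.nt_sequence,
            )
        else:
            continue
        if rec is not None:
            records.append(rec)
    records.sort(key=lambda r: (r.segment_type, r.name))
    return records


def save_reference(prefix, records: list[ReferenceRecord]) -> None:
    """Serialize to ``<prefix>.fasta`` + ``<prefix>.segments.tsv``
    (deterministic: sorted by segment type then name)."""
    ordered = sorted(records, key=lambda r: (r.segment_type, r.name))
    write_fasta(f"{prefix}.fasta", {r.name: r.nt_sequence for r in ordered})
    rows = []
    for r in ordered:
        rows.append(
            {
                "name": r.name,
                "segment_type": r.segment_type,
                "chain": r.chain,
                "functionality": r.functionality,
                "cdr3_anchor": "" if r.cdr3_anchor is None else r.cdr3_anchor,
                "boundaries": ";".join(
                    f"{k}:{a}-{b}" for k, (a, b) in sorted(r.segment_boundaries.items())
                ),
            }
        )
    pd.DataFrame(rows).to_csv(f"{prefix}.segments.tsv", sep="\t", index=False)


def load_reference(prefix) -> list[ReferenceRecord]:
    seqs = read_fasta(f"{prefix}.fasta")
    df = pd.read_csv(f"{prefix}.segments.tsv", sep="\t", dtype=str, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        boundaries = {}
        if row.boundaries:
            for part in row.boundaries.split(";"):
                k, span = part.split(":")
                a, b = span.split("-")
                boundaries[k] = (int(a), int(b))
        records.append(
            ReferenceRecord(
                name=row.name,
                segment_type=row.segment_type,
                chain=row.chain,
                functionality=row.functionality,
                nt_sequence=seqs[row.name],
                segment_boundaries=boundaries,
                cdr3_anchor=None if row.cdr3_anchor == "" else int(row.cdr3_anchor),
            )
        )
    return records
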