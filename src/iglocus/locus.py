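"""End-to-end locus annotation: discovery -> classification -> naming.

Seed-based V and C discovery runs first; structural D and J discovery is
then restricted to regions not already claimed (a signal-like motif inside
a V exon or C intron is not a candidate gene). Every candidate is
classified rather than filtered, so defective genes appear in the output
with their defect codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .annotate import (
    AnnotationConfig,
    find_c_candidates,
    find_d_candidates,
    find_j_candidates,
    find_v_candidates,
)
from .classify import assign_families, classify_c, classify_j, classify_v, name_genes
from .model import GenomicInterval, GermlineGene

logger = logging.getLogger(__name__)

#: padding (bp) around claimed features when masking D/J structural search
V_PAD_5P = 360  # covers leader exon + intron + context
V_PAD_3P = 60  # covers the 3' RSS
C_PAD = 20
D_PAD = 40


@dataclass
class AnnotatedLocus:
    genes: list[GermlineGene] = field(default_factory=list)

    def of_type(self, segment_type: str) -> list[GermlineGene]:
        return [g for g in self.genes if g.segment_type == segment_type]


def _pad(iv: GenomicInterval, left: int, right: int) -> GenomicInterval:
    if iv.strand == "-":
        left, right = right, left
    return GenomicInterval(iv.contig, max(0, iv.start - left), iv.end + right, "+")


def build_exclusions(
    v_intervals: list[GenomicInterval],
    c_intervals: list[GenomicInterval],
    d_intervals: list[GenomicInterval],
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Masks applied to structural D and J discovery: regions claimed by
    seed-located V/C genes (plus leader/RSS margins), and additionally the
    D segments for the J search. Used identically by the annotation
    orchestrator and by the synthetic generator's ambiguity scrubber."""
    exclude = [_pad(iv, V_PAD_5P, V_PAD_3P) for iv in v_intervals]
    exclude += [_pad(iv, C_PAD, C_PAD) for iv in c_intervals]
    exclude_j = exclude + [_pad(iv, D_PAD, D_PAD) for iv in d_intervals]
    return exclude, exclude_j


def annotate_locus(
    genome: dict[str, str],
    v_seeds: dict[str, str],
    c_seeds: dict[str, str],
    chain: str = "IGH",
    config: AnnotationConfig | None = None,
    family_threshold: float = 0.75,
) -> AnnotatedLocus:
    config = config or AnnotationConfig()
    genes: list[GermlineGene] = []

    v_cands = find_v_candidates(genome, v_seeds, config, chain)
    c_cands = find_c_candidates(genome, c_seeds, config, chain) if c_seeds else []
    exclude, _ = build_exclusions(
        [c.interval for c in v_cands], [c.interval for c in c_cands], []
    )
    d_genes = find_d_candidates(genome, config, chain, exclude=exclude)
    _, exclude_j = build_exclusions(
        [c.interval for c in v_cands],
        [c.interval for c in c_cands],
        [g.interval for g in d_genes],
    )
    j_cands = find_j_candidates(genome, config, chain, exclude=exclude_j)

    for i, cand in enumerate(v_cands):
        cls = classify_v(cand, config=config)
        attrs = {
            "identity_to_seed": f"{cand.identity_to_seed:.4f}",
            "seed": cand.seed_name,
        }
        if cand.leader_start is not None:
            attrs["leader_start"] = cand.leader_start
        if cls.warnings:
            attrs["warnings"] = ",".join(cls.warnings)
        genes.append(
            GermlineGene(
                name=f"V.{i}",
                segment_type="V",
                chain=chain,
                interval=cand.interval,
                functionality=cls.functionality,
                defects=cls.defects,
                nt_sequence=cand.exon_sequence,
                rss=cand.rss,
                attributes=attrs,
            )
        )
        logger.debug("V candidate %s -> %s %s", cand.interval, cls.functionality, cls.defects)
    genes.extend(d_genes)
    for cand in j_cands:
        functionality, defects = classify_j(cand)
        genes.append(
            GermlineGene(
                name=f"J@{cand.interval.start}",
                segment_type="J",
                chain=chain,
                interval=cand.interval,
                functionality=functionality,
                defects=defects,
                nt_sequence=cand.coding_sequence,
                rss_5p=cand.rss,
            )
        )
    for cand in c_cands:
        functionality, defects = classify_c(cand)
        genes.append(
            GermlineGene(
                name=f"C@{cand.interval.start}",
                segment_type="C",
                chain=chain,
                interval=cand.interval,
                functionality=functionality,
                defects=defects,
                nt_sequence="".join(cand.exon_seqs),
                exons=cand.exons,
                attributes={"identity_to_seed": f"{cand.identity_to_seed:.4f}"},
            )
        )

    v_genes = sorted(
        (g for g in genes if g.segment_type == "V"),
        key=lambda g: (g.interval.contig, g.interval.start),
    )
    if v_genes:
        labels = assign_families(
            [g.nt_sequence for g in v_genes],
            threshold=family_threshold,
            seed_families=v_seeds,
        )
        for g, label in zip(v_genes, labels):
            g.family = label
    ordered = name_genes(genes, chain)
    return AnnotatedLocus(genes=ordered)
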