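"""Domain types for immunoglobulin locus annotation and repertoire analysis.

Coordinates are 0-based half-open on the plus strand of the contig; strand
is carried explicitly and ``nt_sequence`` always stores the gene's
reading-sense sequence. GFF3 emission converts to 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seq import translate

SEGMENT_TYPES = ("V", "D", "J", "C")
CHAINS = ("IGH", "IGK", "IGL")
FUNCTIONALITIES = ("F", "ORF", "P")

# Defect codes recorded during functional classification. Structural/coding
# defects force P; signal-only defects (RSS-related, missing J motif) yield
# ORF when the reading frame is otherwise intact.
STOP_CODON = "STOP_CODON"
MISSING_C23 = "MISSING_C23"
MISSING_W41 = "MISSING_W41"
MISSING_C104 = "MISSING_C104"
NO_INIT_CODON = "NO_INIT_CODON"
NO_DONOR_SPLICE = "NO_DONOR_SPLICE"
NO_ACCEPTOR_SPLICE = "NO_ACCEPTOR_SPLICE"
NO_RSS = "NO_RSS"
NO_WGXG = "NO_WGXG"
NO_FGXG = "NO_FGXG"
NO_J_HEPTAMER = "NO_J_HEPTAMER"
UNALIGNABLE = "UNALIGNABLE"

PSEUDOGENE_DEFECTS = frozenset(
    {
        STOP_CODON,
        MISSING_C23,
        MISSING_W41,
        MISSING_C104,
        NO_INIT_CODON,
        NO_DONOR_SPLICE,
        NO_ACCEPTOR_SPLICE,
        UNALIGNABLE,
    }
)
ORF_DEFECTS = frozenset({NO_RSS, NO_WGXG, NO_FGXG, NO_J_HEPTAMER})


@dataclass(frozen=True, order=True)
class GenomicInterval:
    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.strand == other.strand
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class RssHit:
    """A heptamer-spacer-nonamer recombination signal.

    ``heptamer`` and ``nonamer`` are reported in the canonical orientation
    (reading away from the gene), so they are directly comparable to the
    consensus CACAGTG / ACAAAAACC regardless of which side of the gene the
    signal sits on.
    """

    interval: GenomicInterval
    spacer_class: int  # 12 or 23
    heptamer: str
    nonamer: str
    spacer_length: int
    heptamer_matches: int
    nonamer_matches: int

    def __post_init__(self):
        if self.spacer_class not in (12, 23):
            raise ValueError("spacer_class must be 12 or 23")
        if abs(self.spacer_length - self.spacer_class) > 1:
            raise ValueError(
                f"spacer length {self.spacer_length} outside "
                f"{self.spacer_class}±1"
            )


@dataclass
class GermlineGene:
    name: str
    segment_type: str  # V, D, J, C
    chain: str  # IGH, IGK, IGL
    interval: GenomicInterval
    functionality: str  # F, ORF, P
    nt_sequence: str  # reading-sense sequence of the gene body
    family: str = ""
    defects: list[str] = field(default_factory=list)
    rss: RssHit | None = None
    rss_5p: RssHit | None = None  # upstream signal (J and D segments)
    exons: list[GenomicInterval] = field(default_factory=list)  # C genes
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.segment_type not in SEGMENT_TYPES:
            raise ValueError(f"bad segment_type {self.segment_type!r}")
        if self.functionality not in FUNCTIONALITIES:
            raise ValueError(f"bad functionality {self.functionality!r}")
        if self.functionality == "F" and self.defects:
            raise ValueError("functional gene must have no defects")
        if self.functionality == "P" and not (
            set(self.defects) & PSEUDOGENE_DEFECTS
        ):
            raise ValueError("pseudogene must carry a structural defect")


@dataclass(frozen=True)
class Clonotype:
    cdr3_nt: str
    cdr3_aa: str
    count: int
    v_gene: str
    j_gene: str
    d_gene: str = ""

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("count must be positive")
        if self.cdr3_aa != translate(self.cdr3_nt):
            raise ValueError("cdr3_aa is not the translation of cdr3_nt")

    @property
    def productive(self) -> bool:
        return len(self.cdr3_nt) % 3 == 0 and "*" not in self.cdr3_aa


@dataclass
class RepertoireSample:
    sample_id: str
    clonotypes: list[Clonotype]
    total_reads: int
    aligned_reads: int

    def __post_init__(self):
        if self.aligned_reads > self.total_reads:
            raise ValueError("aligned_reads exceeds total_reads")
        if sum(c.count for c in self.clonotypes) > self.aligned_reads:
            raise ValueError("clonotype counts exceed aligned reads")

    @property
    def clonotype_count(self) -> int:
        """Total retained reads (the 'clonotype count' of sequencing
        summary tables, as opposed to the number of unique clones)."""
        return sum(c.count for c in self.clonotypes)

    @property
    def unique_clones(self) -> int:
        return len(self.clonotypes)
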