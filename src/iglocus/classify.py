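"""Functional classification (F / ORF / P), family assignment and naming.

The rules mirror standard germline-gene curation practice: structural or
coding defects (in-frame stops, missing conserved C23/W41/C104 anchors,
missing initiation codon or splice sites) make a pseudogene (P); an intact
reading frame whose only defects are regulatory (degenerate RSS, missing
J motif) is an open reading frame (ORF); everything else is functional (F).
A conserved L89 is typical but not universal, so its absence is recorded
as a warning, never a defect.

V numbering is approximated by profile alignment of the translated exon to
one built-in template per chain; the template's residue index plays the
role of the standardized position, with the anchors at 23/41/89/104.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from . import _templates
from .annotate import AnnotationConfig, CCandidate, JCandidate, VCandidate, find_leader
from .model import (
    MISSING_C23,
    MISSING_C104,
    MISSING_W41,
    NO_ACCEPTOR_SPLICE,
    NO_DONOR_SPLICE,
    NO_FGXG,
    NO_INIT_CODON,
    NO_J_HEPTAMER,
    NO_RSS,
    NO_WGXG,
    STOP_CODON,
    UNALIGNABLE,
    GermlineGene,
)
from .seq import translate

CHAIN_PREFIX = {"IGH": "IgH", "IGK": "Igκ", "IGL": "Igλ"}

#: Anchor residues on the numbering template: (position, required residue).
V_ANCHORS = ((23, "C"), (41, "W"), (104, "C"))
V_L89 = 89

V_TEMPLATE_AA = {
    chain: translate(_templates.TEMPLATES[chain]["v_mature_nt"])
    for chain in _templates.TEMPLATES
}

# Framework/CDR spans on the numbering template, 1-based inclusive
# positions: FR1 1-26, CDR1 27-38, FR2 39-55, CDR2 56-65, FR3 66-104.
V_REGION_SPANS = (
    ("FR1", 1, 26),
    ("CDR1", 27, 38),
    ("FR2", 39, 55),
    ("CDR2", 56, 65),
    ("FR3", 66, 104),
)


def _aa_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11
    al.extend_gap_score = -1
    return al


_AA_ALIGNER = _aa_aligner()


@dataclass
class NumberedV:
    """A V amino-acid sequence aligned to the chain numbering template."""

    aa_sequence: str
    position_map: dict[int, int]  # template position (1-based) -> query index
    score: float

    def residue_at(self, position: int) -> str | None:
        idx = self.position_map.get(position)
        return None if idx is None else self.aa_sequence[idx]


def number_v(aa_sequence: str, chain: str = "IGH") -> NumberedV | None:
    """Align a translated V to the chain template; None if unalignable
    (shorter than 90 aa, or the alignment fails to cover the anchors'
    neighbourhood with a sensible score)."""
    if len(aa_sequence) < 90:
        return None
    template = V_TEMPLATE_AA[chain]
    alignments = _AA_ALIGNER.align(template, aa_sequence)
    if len(alignments) == 0:
        return None
    aln = alignments[0]
    # require at least half of the template aligned at a positive score
    covered = sum(te - ts for (ts, te) in aln.aligned[0])
    if covered < len(template) // 2 or aln.score <= 0:
        return None
    pos_map: dict[int, int] = {}
    for (ts, te), (qs, qe) in zip(aln.aligned[0], aln.aligned[1]):
        for k in range(te - ts):
            pos_map[ts + k + 1] = qs + k
    # assign terminal residues positionally: local alignment clips a
    # mismatched first/last residue, but numbering should still address it
    t, q = min(pos_map), pos_map[min(pos_map)]
    while t > 1 and q > 0:
        t -= 1
        q -= 1
        pos_map[t] = q
    t, q = max(pos_map), pos_map[max(pos_map)]
    while t < len(template) and q < len(aa_sequence) - 1:
        t += 1
        q += 1
        pos_map[t] = q
    return NumberedV(aa_sequence=aa_sequence, position_map=pos_map, score=aln.score)


@dataclass
class VClassification:
    functionality: str
    defects: list[str]
    warnings: list[str] = field(default_factory=list)
    numbered: NumberedV | None = None
    frame: int = 0

    def __iter__(self):  # allows (functionality, defects) unpacking
        return iter((self.functionality, self.defects))


def classify_v(
    candidate: VCandidate,
    numbered: NumberedV | None = None,
    config: AnnotationConfig | None = None,
) -> VClassification:
    """Apply the V-gene rule table to a candidate.

    P: stop codon, missing C23/W41/C104, no initiation codon, or missing
    donor/acceptor splice. ORF: intact frame but absent/degenerate 3' RSS
    (or ambiguous bases in the coding region). Otherwise F.
    """
    config = config or AnnotationConfig()
    exon = candidate.exon_sequence.upper()
    frame = 0
    if numbered is None:
        best = None
        for f in range(3):
            n = number_v(translate(exon, f), candidate.chain)
            if n is not None and (best is None or n.score > best[1].score):
                best = (f, n)
        if best is None:
            return VClassification("P", [UNALIGNABLE])
        frame, numbered = best
    defects: list[str] = []
    warnings: list[str] = []
    aa = translate(exon, frame)
    if "*" in aa:
        defects.append(STOP_CODON)
    for pos, residue in V_ANCHORS:
        if numbered.residue_at(pos) != residue:
            defects.append(f"MISSING_{residue}{pos}")
    status, _ = find_leader(candidate.upstream, config)
    if status == "no_init":
        defects.append(NO_INIT_CODON)
    elif status == "no_donor":
        defects.append(NO_DONOR_SPLICE)
    if candidate.upstream[-2:] != "AG":
        defects.append(NO_ACCEPTOR_SPLICE)
    if candidate.rss is None:
        defects.append(NO_RSS)
    if numbered.residue_at(V_L89) != "L":
        warnings.append("L89_ABSENT")
    ambiguous = "N" in exon
    if ambiguous:
        warnings.append("AMBIGUOUS_BASES")
    if set(defects) - {NO_RSS}:
        functionality = "P"
    elif defects or ambiguous:
        functionality = "ORF"
    else:
        functionality = "F"
    return VClassification(functionality, defects, warnings, numbered, frame)


def classify_j(candidate: JCandidate, chain: str | None = None) -> tuple[str, list[str]]:
    """J rule table: no donor splice -> P; missing W/F-G-x-G motif or a
    sub-threshold heptamer -> ORF; otherwise F."""
    chain = chain or candidate.chain
    defects: list[str] = []
    if not candidate.donor_found:
        defects.append(NO_DONOR_SPLICE)
    if not candidate.motif_found:
        defects.append(NO_WGXG if chain == "IGH" else NO_FGXG)
    if not candidate.strict_rss:
        defects.append(NO_J_HEPTAMER)
    if NO_DONOR_SPLICE in defects:
        return "P", defects
    if defects:
        return "ORF", defects
    return "F", defects


def classify_c(candidate: CCandidate) -> tuple[str, list[str]]:
    """C rule table: a stop codon before the final exon (or, in a
    single-exon gene, before its final codon), or an invalid splice
    junction, makes a pseudogene; otherwise functional."""
    defects: list[str] = []
    for donor_ok, acceptor_ok in candidate.introns_ok:
        if not donor_ok and NO_DONOR_SPLICE not in defects:
            defects.append(NO_DONOR_SPLICE)
        if not acceptor_ok and NO_ACCEPTOR_SPLICE not in defects:
            defects.append(NO_ACCEPTOR_SPLICE)
    spliced = "".join(candidate.exon_seqs)
    aa = translate(spliced)
    if len(candidate.exon_seqs) > 1:
        limit_nt = len(spliced) - len(candidate.exon_seqs[-1])
    else:
        limit_nt = len(spliced) - 3
    if any(ch == "*" and 3 * i < limit_nt for i, ch in enumerate(aa)):
        defects.append(STOP_CODON)
    return ("P" if defects else "F"), defects


# ------------------------------------------------------------------ families

def _nt_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -2
    al.extend_gap_score = -0.5
    return al


_NT_ALIGNER = _nt_aligner()


def global_identity(a: str, b: str) -> float:
    """Matches over alignment columns of a global alignment; gap columns
    count as mismatches."""
    aln = _NT_ALIGNER.align(a.upper(), b.upper())[0]
    counts = aln.counts()
    return counts.identities / aln.length


def assign_families(
    sequences: list[str],
    threshold: float = 0.75,
    seed_families: dict[str, str] | None = None,
) -> list[str]:
    """Single-linkage clustering on pairwise global nucleotide identity.

    Two genes share a family iff connected by a chain of pairs each at or
    above ``threshold``. Cluster labels are integers numbered by each
    cluster's first member in input order (callers pass genes 5'->3', so
    labels follow locus position); when ``seed_families`` maps label ->
    sequence and a cluster member matches a seed at or above threshold,
    that seed's label is reused instead.
    """
    n = len(sequences)
    if n == 0:
        raise ValueError("no sequences")
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if global_identity(sequences[i], sequences[j]) >= threshold:
                parent[find(i)] = find(j)
    roots: dict[int, list[int]] = {}
    for i in range(n):
        roots.setdefault(find(i), []).append(i)
    clusters = sorted(roots.values(), key=lambda mem: mem[0])
    labels = [""] * n
    next_label = 1
    for members in clusters:
        label = None
        if seed_families:
            best = None
            for seed_label, seed_seq in seed_families.items():
                ident = max(
                    global_identity(sequences[m], seed_seq) for m in members[:3]
                )
                if ident >= threshold and (best is None or ident > best[1]):
                    best = (seed_label, ident)
            if best is not None:
                label = best[0]
        if label is None:
            label = str(next_label)
        next_label += 1
        for m in members:
            labels[m] = label
    return labels


# -------------------------------------------------------------------- names

def name_genes(genes: list[GermlineGene], chain: str | None = None) -> list[GermlineGene]:
    """Assign locus names 5'->3'.

    V: <chain>V<family>-<ordinal over all V genes>. D/J: within the
    cluster structure (a new D-J-C cluster starts at the first D/J after a
    C gene); loci with a single cluster use a flat ordinal, clusters of
    single genes use the cluster index alone, otherwise
    <cluster>-<ordinal within cluster>. C: flat ordinal, omitted when the
    locus has only one C gene.
    """
    if not genes:
        return genes
    chain = chain or genes[0].chain
    prefix = CHAIN_PREFIX[chain]
    ordered = sorted(genes, key=lambda g: (g.interval.contig, g.interval.start))
    seen = set()
    for g in ordered:
        key = (g.interval.contig, g.interval.start, g.interval.end)
        if key in seen:
            raise ValueError(f"duplicate coordinates at {key}")
        seen.add(key)
    v_genes = [g for g in ordered if g.segment_type == "V"]
    for i, g in enumerate(v_genes, 1):
        fam = g.family or "1"
        g.name = f"{prefix}V{fam}-{i}"
    djc = [g for g in ordered if g.segment_type in ("D", "J", "C")]
    clusters: list[list[GermlineGene]] = []
    current: list[GermlineGene] = []
    saw_c = False
    for g in djc:
        if g.segment_type in ("D", "J") and saw_c:
            clusters.append(current)
            current, saw_c = [], False
        current.append(g)
        saw_c = saw_c or g.segment_type == "C"
    if current:
        clusters.append(current)
    n_c_total = sum(1 for g in djc if g.segment_type == "C")
    c_ordinal = 0
    for seg in ("D", "J"):
        per_cluster = [[g for g in cl if g.segment_type == seg] for cl in clusters]
        active = [cl for cl in per_cluster if cl]
        flat_ordinal = 0
        for ci, members in enumerate(per_cluster, 1):
            for k, g in enumerate(members, 1):
                if len(active) <= 1:
                    flat_ordinal += 1
                    g.name = f"{prefix}{seg}{flat_ordinal}"
                elif all(len(m) <= 1 for m in per_cluster):
                    g.name = f"{prefix}{seg}{ci}"
                else:
                    g.name = f"{prefix}{seg}{ci}-{k}"
    for g in djc:
        if g.segment_type == "C":
            c_ordinal += 1
            g.name = f"{prefix}C" if n_c_total == 1 else f"{prefix}C{c_ordinal}"
    return ordered


# ------------------------------------------------------------------ summary

def classification_summary(
    counts: dict[str, dict[str, int]] | list[GermlineGene],
) -> pd.DataFrame:
    """Per-segment F/P/ORF counts with a Total row, the layout used in
    locus-annotation summary tables.

    Accepts either a list of classified genes or a prepared mapping
    ``{column: {"F": n, "P": n, "ORF": n}}``.
    """
    if isinstance(counts, list):
        tally: dict[str, dict[str, int]] = {}
        for g in counts:
            col = f"{CHAIN_PREFIX[g.chain]}{g.segment_type}"
            tally.setdefault(col, {"F": 0, "P": 0, "ORF": 0})
            tally[col][g.functionality] += 1
        counts = tally
    df = pd.DataFrame(
        {col: {k: v.get(k, 0) for k in ("F", "P", "ORF")} for col, v in counts.items()}
    )
    df.loc["Total"] = df.loc[["F", "P", "ORF"]].sum()
    return df
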