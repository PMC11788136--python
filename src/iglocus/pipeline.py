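"""Read alignment, CDR3 extraction and clonotype assembly.

Each read is assigned the highest-scoring V by local alignment against
every V record (both orientations; a fast edit-distance prescreen narrows
the candidate list before scored alignment), then the best J on the read
suffix. The CDR3 spans the read from the position aligned to the V's
conserved-cysteine codon through the J's W/F codon, both included.
Junction bookkeeping: V/J deletions come from the alignment end points
against the germline anchors; the D segment is the reference D sharing the
longest exact substring (at least ``d_min_core`` bases) with the region
between the V and J alignments, and non-templated insertions are whatever
that region leaves unexplained.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import edlib
import pandas as pd
from Bio import Align

from .model import Clonotype, RepertoireSample
from .reference import ReferenceRecord
from .seq import longest_common_substring, reverse_complement, translate

NO_V = "NO_V"
NO_J = "NO_J"
LOW_SCORE = "LOW_SCORE"
ANCHOR_LOST = "ANCHOR_LOST"


@dataclass(frozen=True)
class AlignParams:
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    min_v_score: float = 50.0
    min_j_score: float = 20.0
    d_min_core: int = 7
    prescreen_core: int = 90  # bases of V upstream of the anchor screened
    prescreen_margin: int = 3  # keep V candidates within this edit distance
    prescreen_margin_j: int = 3
    prescreen_max_candidates: int = 4


@dataclass
class JunctionDetail:
    v_deletions: int
    j_deletions: int
    n_insertions: int
    d_gene: str = ""


@dataclass
class ReadAlignment:
    read_id: str
    sequence: str  # oriented read (V before J)
    orientation: str  # "+" as given, "-" reverse-complemented
    v_name: str
    v_score: float
    v_ref_end: int  # germline V coordinate where the alignment stops
    read_v_end: int
    read_v_anchor: int | None  # read position of the C104 codon start
    j_name: str
    j_score: float
    j_ref_start: int
    read_j_start: int
    read_j_anchor: int | None  # read position of the W/F codon start
    frame_ok: bool


@dataclass
class Rejection:
    read_id: str
    reason: str


@dataclass
class Extraction:
    read_id: str
    cdr3_nt: str
    cdr3_aa: str
    v_name: str
    j_name: str
    detail: JunctionDetail


def _map_through(blocks_ref, blocks_read, ref_pos: int) -> int | None:
    for (rs, re_), (qs, _qe) in zip(blocks_ref, blocks_read):
        if rs <= ref_pos < re_:
            return qs + (ref_pos - rs)
    return None


class RepertoireAligner:
    """Aligns reads against a segmented reference; reusable across reads."""

    def __init__(self, reference: list[ReferenceRecord], params: AlignParams | None = None):
        self.params = params or AlignParams()
        self.v_records = [r for r in reference if r.segment_type == "V" and r.cdr3_anchor is not None]
        self.j_records = [r for r in reference if r.segment_type == "J" and r.cdr3_anchor is not None]
        self.d_records = [r for r in reference if r.segment_type == "D"]
        if not self.v_records or not self.j_records:
            raise ValueError("reference must contain anchored V and J records")
        self._cores = []
        for r in self.v_records:
            a = r.cdr3_anchor
            self._cores.append(r.nt_sequence[max(0, a - self.params.prescreen_core) : a])
        self._v_by_name = {r.name: r for r in self.v_records}
        self._j_by_name = {r.name: r for r in self.j_records}
        self._d_kmers: dict[str, set[str]] = {
            r.name: {
                r.nt_sequence[i : i + self.params.d_min_core]
                for i in range(len(r.nt_sequence) - self.params.d_min_core + 1)
            }
            for r in self.d_records
        }
        al = Align.PairwiseAligner()
        al.mode = "local"
        al.match_score = self.params.match
        al.mismatch_score = self.params.mismatch
        al.open_gap_score = self.params.gap_open
        al.extend_gap_score = self.params.gap_extend
        self._aligner = al

    # ------------------------------------------------------------- V stage

    def _prescreen(self, oriented: str) -> list[int]:
        dists = []
        for core in self._cores:
            res = edlib.align(core, oriented, mode="HW", task="distance",
                              k=len(core) // 2)
            dists.append(res["editDistance"] if res["editDistance"] >= 0 else 1 << 30)
        best = min(dists)
        if best >= len(self._cores[0]) // 2:
            return []
        keep = [i for i, d in enumerate(dists) if d <= best + self.params.prescreen_margin]
        keep.sort(key=lambda i: dists[i])
        return keep[: self.params.prescreen_max_candidates]

    def _prescreen_dist(self, oriented: str) -> tuple[list[int], int]:
        idxs = self._prescreen(oriented)
        if not idxs:
            return [], 1 << 30
        core = self._cores[idxs[0]]
        res = edlib.align(core, oriented, mode="HW", task="distance", k=len(core) // 2)
        return idxs, res["editDistance"] if res["editDistance"] >= 0 else 1 << 30

    def align_read(self, read_id: str, seq: str) -> ReadAlignment | Rejection:
        seq = seq.upper()
        fwd, rev = seq, reverse_complement(seq)
        idx_f, dist_f = self._prescreen_dist(fwd)
        idx_r, dist_r = self._prescreen_dist(rev)
        # score only the better-screening orientation unless it is a near tie
        trials = []
        if idx_f and dist_f <= dist_r + 8:
            trials.append(("+", fwd, idx_f))
        if idx_r and dist_r <= dist_f + 8:
            trials.append(("-", rev, idx_r))
        if not trials:
            # heavily clipped or mutated V: fall back to scoring everything
            trials = [
                ("+", fwd, range(len(self.v_records))),
                ("-", rev, range(len(self.v_records))),
            ]
        best = None
        single = sum(len(list(idxs)) for _, _, idxs in trials) == 1
        for orientation, oriented, idxs in trials:
            for i in idxs:
                if single:
                    score = None  # scored by the full alignment below
                else:
                    score = self._aligner.score(self.v_records[i].nt_sequence, oriented)
                if best is None or (score is not None and score > best[0]):
                    best = (score, i, orientation)
        _, v_idx, orientation = best
        oriented = fwd if orientation == "+" else rev
        v_rec = self.v_records[v_idx]
        aln = self._aligner.align(v_rec.nt_sequence, oriented)[0]
        v_score = aln.score
        if v_score < self.params.min_v_score:
            return Rejection(read_id, NO_V)
        blocks_ref, blocks_read = aln.aligned
        v_ref_end = int(blocks_ref[-1][1])
        read_v_end = int(blocks_read[-1][1])
        read_v_anchor = _map_through(blocks_ref, blocks_read, v_rec.cdr3_anchor)

        suffix = oriented[read_v_end:]
        if not suffix:
            return Rejection(read_id, NO_J)
        j_dists = []
        for j_rec in self.j_records:
            res = edlib.align(j_rec.nt_sequence, suffix, mode="HW", task="distance")
            j_dists.append(res["editDistance"])
        j_best_d = min(j_dists)
        j_idxs = [
            i for i, d in enumerate(j_dists)
            if d <= j_best_d + self.params.prescreen_margin_j
        ]
        if len(j_idxs) > 1:
            j_idxs.sort(
                key=lambda i: -self._aligner.score(
                    self.j_records[i].nt_sequence, suffix
                )
            )
        j_idx = j_idxs[0]
        j_rec = self.j_records[j_idx]
        jaln = self._aligner.align(j_rec.nt_sequence, suffix)[0]
        j_score = jaln.score
        if j_score < self.params.min_j_score:
            return Rejection(read_id, NO_J)
        j_blocks_ref, j_blocks_read = jaln.aligned
        j_ref_start = int(j_blocks_ref[0][0])
        read_j_start = read_v_end + int(j_blocks_read[0][0])
        anchor_in_suffix = _map_through(j_blocks_ref, j_blocks_read, j_rec.cdr3_anchor)
        read_j_anchor = (
            None if anchor_in_suffix is None else read_v_end + anchor_in_suffix
        )
        frame_ok = (
            read_v_anchor is not None
            and read_j_anchor is not None
            and (read_j_anchor + 3 - read_v_anchor) % 3 == 0
        )
        return ReadAlignment(
            read_id=read_id,
            sequence=oriented,
            orientation=orientation,
            v_name=v_rec.name,
            v_score=v_score,
            v_ref_end=v_ref_end,
            read_v_end=read_v_end,
            read_v_anchor=read_v_anchor,
            j_name=j_rec.name,
            j_score=j_score,
            j_ref_start=j_ref_start,
            read_j_start=read_j_start,
            read_j_anchor=read_j_anchor,
            frame_ok=frame_ok,
        )

    # ------------------------------------------------------------ junction

    def extract_cdr3(self, alignment: ReadAlignment) -> Extraction | Rejection:
        if alignment.read_v_anchor is None or alignment.read_j_anchor is None:
            return Rejection(alignment.read_id, ANCHOR_LOST)
        if alignment.read_j_anchor < alignment.read_v_anchor:
            return Rejection(alignment.read_id, ANCHOR_LOST)
        v_rec = self._v_by_name[alignment.v_name]
        cdr3_nt = alignment.sequence[
            alignment.read_v_anchor : alignment.read_j_anchor + 3
        ]
        middle = alignment.sequence[alignment.read_v_end : alignment.read_j_start]
        d_gene, core_len = assign_d(
            middle, self.d_records, self.params.d_min_core, kmer_index=self._d_kmers
        )
        detail = JunctionDetail(
            v_deletions=len(v_rec.nt_sequence) - alignment.v_ref_end,
            j_deletions=alignment.j_ref_start,
            n_insertions=len(middle) - core_len,
            d_gene=d_gene,
        )
        return Extraction(
            read_id=alignment.read_id,
            cdr3_nt=cdr3_nt,
            cdr3_aa=translate(cdr3_nt),
            v_name=alignment.v_name,
            j_name=alignment.j_name,
            detail=detail,
        )


def assign_d(
    junction_nt: str,
    d_references: list[ReferenceRecord],
    min_core: int = 7,
    kmer_index: dict[str, set[str]] | None = None,
) -> tuple[str, int]:
    """The D gene whose longest exact substring match with the inter-anchor
    region reaches ``min_core`` and is maximal; ties break by locus order
    (reference order). Returns ``(name, matched_length)``; ("", 0) if none
    qualifies. ``kmer_index`` (name -> set of min_core-mers) is an exact
    prefilter: a common substring of length >= min_core implies a shared
    min_core-mer, so skipping records without one changes nothing."""
    best_name, best_len = "", 0
    junction_kmers = (
        {junction_nt[i : i + min_core] for i in range(len(junction_nt) - min_core + 1)}
        if kmer_index is not None
        else None
    )
    for rec in d_references:
        if junction_kmers is not None and not (junction_kmers & kmer_index[rec.name]):
            continue
        ln, _, _ = longest_common_substring(junction_nt, rec.nt_sequence)
        if ln >= min_core and ln > best_len:
            best_name, best_len = rec.name, ln
    return best_name, best_len


def assemble_clonotypes(
    extractions: list[Extraction],
    sample_id: str,
    total_reads: int,
) -> tuple[RepertoireSample, pd.DataFrame]:
    """Group extractions by exact (cdr3_nt, V, J); returns the sample plus
    a clonotype table carrying junction bookkeeping. Output is invariant
    to input order."""
    groups: dict[tuple[str, str, str], list[Extraction]] = {}
    for ex in extractions:
        groups.setdefault((ex.cdr3_nt, ex.v_name, ex.j_name), []).append(ex)
    rows = []
    for (nt, v, j), members in groups.items():
        d_counts = Counter(m.detail.d_gene for m in members)
        top = max(d_counts.values())
        d_gene = sorted(d for d, c in d_counts.items() if c == top)[0]
        detail = next(m.detail for m in members)
        rows.append(
            {
                "junction": nt,
                "junction_aa": translate(nt),
                "v_call": v,
                "d_call": d_gene,
                "j_call": j,
                "duplicate_count": len(members),
                "v_deletions": detail.v_deletions,
                "j_deletions": detail.j_deletions,
                "n_insertions": detail.n_insertions,
            }
        )
    table = (
        pd.DataFrame(
            rows,
            columns=[
                "junction",
                "junction_aa",
                "v_call",
                "d_call",
                "j_call",
                "duplicate_count",
                "v_deletions",
                "j_deletions",
                "n_insertions",
            ],
        )
        .sort_values(
            ["duplicate_count", "junction", "v_call", "j_call"],
            ascending=[False, True, True, True],
        )
        .reset_index(drop=True)
    )
    clonotypes = [
        Clonotype(
            cdr3_nt=r.junction,
            cdr3_aa=r.junction_aa,
            count=int(r.duplicate_count),
            v_gene=r.v_call,
            d_gene=r.d_call,
            j_gene=r.j_call,
        )
        for r in table.itertuples(index=False)
    ]
    sample = RepertoireSample(
        sample_id=sample_id,
        clonotypes=clonotypes,
        total_reads=total_reads,
        aligned_reads=len(extractions),
    )
    return sample, table


def filter_productive(
    sample: RepertoireSample,
) -> tuple[RepertoireSample, dict[str, int]]:
    """Drop clonotypes with a stop codon in the junction or an out-of-frame
    junction length; the removal tally is returned alongside."""
    kept, removed_stop, removed_frame = [], 0, 0
    for c in sample.clonotypes:
        if len(c.cdr3_nt) % 3 != 0:
            removed_frame += 1
        elif "*" in c.cdr3_aa:
            removed_stop += 1
        else:
            kept.append(c)
    filtered = RepertoireSample(
        sample_id=sample.sample_id,
        clonotypes=kept,
        total_reads=sample.total_reads,
        aligned_reads=sample.aligned_reads,
    )
    return filtered, {"stop_codon": removed_stop, "out_of_frame": removed_frame}


@dataclass
class PipelineResult:
    sample: RepertoireSample  # productive clonotypes
    raw_sample: RepertoireSample  # before the productivity filter
    table: pd.DataFrame  # raw clonotype table with junction bookkeeping
    rejections: dict[str, int]
    removed: dict[str, int]


def run_repertoire(
    reads: list[tuple[str, str, str]],
    reference: list[ReferenceRecord],
    sample_id: str = "sample",
    params: AlignParams | None = None,
) -> PipelineResult:
    """Full pipeline: align every read, extract CDR3s, assemble and filter
    clonotypes. ``reads`` are (name, sequence, quality) tuples."""
    aligner = RepertoireAligner(reference, params)
    extractions: list[Extraction] = []
    rejections: Counter = Counter()
    for name, seq, _qual in reads:
        res = aligner.align_read(name, seq)
        if isinstance(res, Rejection):
            rejections[res.reason] += 1
            continue
        ex = aligner.extract_cdr3(res)
        if isinstance(ex, Rejection):
            rejections[ex.reason] += 1
            continue
        extractions.append(ex)
    raw_sample, table = assemble_clonotypes(extractions, sample_id, len(reads))
    sample, removed = filter_productive(raw_sample)
    return PipelineResult(
        sample=sample,
        raw_sample=raw_sample,
        table=table,
        rejections=dict(rejections),
        removed=removed,
    )
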