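"""Candidate V/D/J/C gene detection in genomic sequence.

V and C segments are found by similarity to known germline seeds (edlib
infix alignment, iterated with masking so every occurrence above the
identity threshold is reported, on both strands). D and J segments are
found structurally: D by a G-rich core flanked by 12-class signals on both
sides, J by a correctly oriented 5' signal followed by a short open reading
stretch ending at a donor splice site. Discovery is deliberately more
permissive than functional classification: a candidate only needs enough
intact signals to be located, and every rule it fails is recorded later as
a defect rather than silently dropping the gene.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib

from .model import GenomicInterval, GermlineGene, RssHit
from .rss import CHAIN_RSS, RssConfig, best_hit, scan_rss
from .seq import g_fraction, reverse_complement, translate


@dataclass(frozen=True)
class AnnotationConfig:
    """Thresholds for candidate discovery; every value the source study
    left to external tools is surfaced here."""

    min_identity: float = 0.75  # seed mapping threshold (V)
    v_exon_range: tuple[int, int] = (240, 340)  # operationalizes ~290 bp
    leader_length_range: tuple[int, int] = (30, 60)  # leader exon, nt
    intron_range: tuple[int, int] = (60, 300)  # leader intron, nt
    upstream_window: int = 360  # bp of context kept 5' of a V exon
    rss_gap: int = 12  # max bp between coding end and heptamer
    d_min_g_fraction: float = 0.4
    d_core_range: tuple[int, int] = (5, 40)
    j_length_range: tuple[int, int] = (30, 70)
    j_default_length: int = 48  # used when no donor splice is found
    c_min_identity: float = 0.90
    c_max_intron: int = 800
    rss: RssConfig = field(default_factory=RssConfig)


@dataclass
class VCandidate:
    """A putative V gene: exon interval plus enough flanking context to
    classify it without going back to the genome."""

    interval: GenomicInterval
    exon_sequence: str  # reading-sense
    identity_to_seed: float
    seed_name: str
    chain: str
    upstream: str  # reading-sense context 5' of the exon
    downstream: str  # reading-sense context 3' of the exon
    rss: RssHit | None = None  # strict-threshold 3' signal, if any
    leader_start: int | None = None  # plus-strand coord of leader ATG span


@dataclass
class JCandidate:
    interval: GenomicInterval
    coding_sequence: str  # reading-sense
    chain: str
    rss: RssHit  # the located 5' signal (possibly below strict thresholds)
    strict_rss: bool
    motif_found: bool
    donor_found: bool


@dataclass
class CCandidate:
    interval: GenomicInterval
    exons: list[GenomicInterval]  # plus-strand coords, 5'->3' in gene sense
    exon_seqs: list[str]  # reading-sense
    introns_ok: list[tuple[bool, bool]]  # (donor GT, acceptor AG) per intron
    chain: str
    identity_to_seed: float
    seed_name: str


# ------------------------------------------------------------------ helpers

def _to_plus(start: int, end: int, length: int, strand: str) -> tuple[int, int]:
    if strand == "+":
        return start, end
    return length - end, length - start


def _seed_matches(seed: str, target: str, max_dist: int):
    """All non-overlapping infix matches of ``seed`` in ``target`` with edit
    distance <= max_dist, best-first via iterated masking."""
    work = target
    found = []
    while True:
        res = edlib.align(seed, work, mode="HW", task="locations", k=max_dist)
        if res["editDistance"] < 0:
            break
        s, e = res["locations"][0]
        e += 1
        found.append((s, e, res["editDistance"]))
        work = work[:s] + "\0" * (e - s) + work[e:]
    return found


def find_leader(upstream: str, config: AnnotationConfig) -> tuple[str, int | None]:
    """Search reading-sense context 5' of a V exon for a leader exon:
    ATG, a stop-free stretch, and a donor GT at a codon boundary, with a
    plausible intron back to the exon.

    Returns ``(status, offset)`` where status is "ok", "no_donor" or
    "no_init" and offset is the distance from the exon start back to the
    leader ATG (gene sense), or None.
    """
    lmin, lmax = config.leader_length_range
    imin, imax = config.intron_range
    n = len(upstream)
    saw_init = False
    # scan nearest-first so the reported leader is the closest plausible one
    for p in range(n - 3, -1, -1):
        if upstream[p : p + 3] != "ATG":
            continue
        for llen in range(lmin, lmax + 1, 3):
            if p + llen > n:
                continue
            intron_len = n - (p + llen)
            if not (imin <= intron_len <= imax):
                continue
            if "*" in translate(upstream[p : p + llen]):
                continue
            saw_init = True
            if upstream[p + llen : p + llen + 2] == "GT":
                return "ok", n - p
    return ("no_donor" if saw_init else "no_init"), None


# ------------------------------------------------------------------ V genes

def find_v_candidates(
    genome: dict[str, str],
    seeds: dict[str, str],
    config: AnnotationConfig | None = None,
    chain: str = "IGH",
) -> list[VCandidate]:
    """Locate V exons by similarity to seed sequences on both strands,
    attach the 3' RSS expected for the chain, and record leader context.
    Overlapping candidates from different seeds are merged keeping the
    higher identity."""
    config = config or AnnotationConfig()
    if not seeds:
        raise ValueError("seed set is empty")
    spacer = CHAIN_RSS[(chain, "V")]["3p"]
    out: list[VCandidate] = []
    for contig, seq in genome.items():
        length = len(seq)
        for strand, view in (("+", seq), ("-", reverse_complement(seq))):
            for seed_name, seed in seeds.items():
                max_dist = int((1 - config.min_identity) * len(seed))
                for s, e, dist in _seed_matches(seed, view, max_dist):
                    if not (config.v_exon_range[0] <= e - s <= config.v_exon_range[1]):
                        continue
                    ps, pe = _to_plus(s, e, length, strand)
                    up = view[max(0, s - config.upstream_window) : s]
                    down = view[e : e + 7 + spacer + 1 + 9 + config.rss_gap]
                    cand = VCandidate(
                        interval=GenomicInterval(contig, ps, pe, strand),
                        exon_sequence=view[s:e],
                        identity_to_seed=1 - dist / len(seed),
                        seed_name=seed_name,
                        chain=chain,
                        upstream=up,
                        downstream=down,
                    )
                    status, offset = find_leader(up, config)
                    if status == "ok":
                        if strand == "+":
                            cand.leader_start = ps - offset
                        else:
                            cand.leader_start = pe + offset - 3
                    hits = scan_rss(down, config.rss, spacer, "V-side", contig)
                    hits = [h for h in hits if h.interval.start <= config.rss_gap]
                    chosen = best_hit(hits, 0, "3p")
                    if chosen is not None:
                        hs, he = _to_plus(
                            e + chosen.interval.start,
                            e + chosen.interval.end,
                            length,
                            strand,
                        )
                        cand.rss = RssHit(
                            interval=GenomicInterval(contig, hs, he, strand),
                            spacer_class=chosen.spacer_class,
                            heptamer=chosen.heptamer,
                            nonamer=chosen.nonamer,
                            spacer_length=chosen.spacer_length,
                            heptamer_matches=chosen.heptamer_matches,
                            nonamer_matches=chosen.nonamer_matches,
                        )
                    out.append(cand)
    # merge same-strand overlaps, keeping the better seed identity
    out.sort(key=lambda c: (c.interval.contig, c.interval.start, -c.identity_to_seed))
    merged: list[VCandidate] = []
    for cand in out:
        if merged and merged[-1].interval.overlaps(cand.interval):
            if cand.identity_to_seed > merged[-1].identity_to_seed:
                merged[-1] = cand
            continue
        merged.append(cand)
    return merged


# ------------------------------------------------------------------ D genes

def _excluded(contig: str, ps: int, pe: int, exclude) -> bool:
    for iv in exclude:
        if iv.contig == contig and ps < iv.end and iv.start < pe:
            return True
    return False


def find_d_candidates(
    genome: dict[str, str],
    config: AnnotationConfig | None = None,
    chain: str = "IGH",
    exclude: list[GenomicInterval] = (),
) -> list[GermlineGene]:
    """Find G-rich cores flanked by a 12-class signal on both sides (the
    upstream one in J-side geometry, the downstream one in V-side
    geometry). ``exclude`` masks regions already claimed by V/C genes."""
    config = config or AnnotationConfig()
    if (chain, "D") not in CHAIN_RSS:
        return []
    cmin, cmax = config.d_core_range
    out = []
    for contig, seq in genome.items():
        length = len(seq)
        for strand, view in (("+", seq), ("-", reverse_complement(seq))):
            up_hits = scan_rss(view, config.rss, 12, "J-side", contig)
            down_hits = scan_rss(view, config.rss, 12, "V-side", contig)
            seen_cores = set()
            for u in up_hits:
                for v in down_hits:
                    core_len = v.interval.start - u.interval.end
                    if not (cmin <= core_len <= cmax):
                        continue
                    core_span = (u.interval.end, v.interval.start)
                    if core_span in seen_cores:
                        continue
                    core = view[core_span[0] : core_span[1]]
                    if g_fraction(core) < config.d_min_g_fraction:
                        continue
                    seen_cores.add(core_span)
                    ps, pe = _to_plus(*core_span, length, strand)
                    if _excluded(contig, ps, pe, exclude):
                        continue

                    def plus_hit(h: RssHit) -> RssHit:
                        hs, he = _to_plus(
                            h.interval.start, h.interval.end, length, strand
                        )
                        return RssHit(
                            GenomicInterval(contig, hs, he, strand),
                            h.spacer_class,
                            h.heptamer,
                            h.nonamer,
                            h.spacer_length,
                            h.heptamer_matches,
                            h.nonamer_matches,
                        )

                    out.append(
                        GermlineGene(
                            name=f"D@{contig}:{ps}",
                            segment_type="D",
                            chain=chain,
                            interval=GenomicInterval(contig, ps, pe, strand),
                            functionality="F",
                            nt_sequence=core,
                            rss_5p=plus_hit(u),
                            rss=plus_hit(v),
                        )
                    )
    out.sort(key=lambda g: (g.interval.contig, g.interval.start))
    return out


# ------------------------------------------------------------------ J genes

_MOTIF = {"IGH": re.compile("WG.G"), "IGK": re.compile("FG.G"), "IGL": re.compile("FG.G")}


def find_j_candidates(
    genome: dict[str, str],
    config: AnnotationConfig | None = None,
    chain: str = "IGH",
    exclude: list[GenomicInterval] = (),
) -> list[JCandidate]:
    """Locate J segments from their 5' signal. A candidate is kept when the
    signal passes strict thresholds, or when a relaxed signal is backed by
    an in-frame W/F-G-x-G motif — so a segment with any single defect
    (degenerate heptamer, missing motif, missing donor splice) is still
    found and can be classified rather than lost."""
    config = config or AnnotationConfig()
    spacer = CHAIN_RSS[(chain, "J")]["5p"]
    motif = _MOTIF[chain]
    jmin, jmax = config.j_length_range
    strict = config.rss
    out: list[JCandidate] = []
    for contig, seq in genome.items():
        length = len(seq)
        for strand, view in (("+", seq), ("-", reverse_complement(seq))):
            loose_hits = scan_rss(view, strict.relaxed(), spacer, "J-side", contig)
            by_start: dict[int, RssHit] = {}
            for h in loose_hits:
                cs = h.interval.end  # heptamer abuts the coding start
                prev = by_start.get(cs)
                if prev is None or (
                    h.heptamer_matches + h.nonamer_matches
                    > prev.heptamer_matches + prev.nonamer_matches
                ):
                    by_start[cs] = h
            for cs, h in sorted(by_start.items()):
                donor_found = False
                coding_len = config.j_default_length
                for d in range(jmin, jmax + 1, 3):
                    if view[cs + d : cs + d + 2] == "GT":
                        donor_found = True
                        coding_len = d
                        break
                coding = view[cs : cs + coding_len]
                if len(coding) < jmin:
                    continue
                motif_found = bool(motif.search(translate(coding)))
                is_strict = (
                    h.heptamer_matches >= 7 - strict.max_heptamer_mismatches
                    and h.nonamer_matches >= 9 - strict.max_nonamer_mismatches
                    and (not strict.require_first3 or h.heptamer[:3] == "CAC")
                )
                if not (is_strict or motif_found):
                    continue
                ps, pe = _to_plus(cs, cs + coding_len, length, strand)
                if _excluded(contig, ps, pe, exclude):
                    continue
                hs, he = _to_plus(h.interval.start, h.interval.end, length, strand)
                out.append(
                    JCandidate(
                        interval=GenomicInterval(contig, ps, pe, strand),
                        coding_sequence=coding,
                        chain=chain,
                        rss=RssHit(
                            GenomicInterval(contig, hs, he, strand),
                            h.spacer_class,
                            h.heptamer,
                            h.nonamer,
                            h.spacer_length,
                            h.heptamer_matches,
                            h.nonamer_matches,
                        ),
                        strict_rss=is_strict,
                        motif_found=motif_found,
                        donor_found=donor_found,
                    )
                )
    out.sort(key=lambda c: (c.interval.contig, c.interval.start))
    return out


# ------------------------------------------------------------------ C genes

def find_c_candidates(
    genome: dict[str, str],
    seeds: dict[str, str],
    config: AnnotationConfig | None = None,
    chain: str = "IGH",
) -> list[CCandidate]:
    """Assemble constant-gene exon chains from seed matches. Matches on the
    same strand closer than ``c_max_intron`` are chained into one gene;
    each intron is checked for GT...AG boundaries."""
    config = config or AnnotationConfig()
    if not seeds:
        raise ValueError("seed set is empty")
    out: list[CCandidate] = []
    for contig, seq in genome.items():
        length = len(seq)
        for strand, view in (("+", seq), ("-", reverse_complement(seq))):
            matches = []
            for seed_name, seed in seeds.items():
                max_dist = int((1 - config.c_min_identity) * len(seed))
                for s, e, dist in _seed_matches(seed, view, max_dist):
                    matches.append((s, e, seed_name, 1 - dist / len(seed)))
            matches.sort()
            group: list[tuple[int, int, str, float]] = []

            def flush():
                if not group:
                    return
                introns_ok = []
                for (s1, e1, *_), (s2, e2, *_) in zip(group, group[1:]):
                    introns_ok.append(
                        (view[e1 : e1 + 2] == "GT", view[s2 - 2 : s2] == "AG")
                    )
                exon_ivs = []
                for s, e, *_ in group:
                    ps, pe = _to_plus(s, e, length, strand)
                    exon_ivs.append(GenomicInterval(contig, ps, pe, strand))
                gs, ge = _to_plus(group[0][0], group[-1][1], length, strand)
                out.append(
                    CCandidate(
                        interval=GenomicInterval(contig, gs, ge, strand),
                        exons=exon_ivs,
                        exon_seqs=[view[s:e] for s, e, *_ in group],
                        introns_ok=introns_ok,
                        chain=chain,
                        identity_to_seed=max(m[3] for m in group),
                        seed_name=group[0][2],
                    )
                )

            for m in matches:
                if group and m[0] - group[-1][1] > config.c_max_intron:
                    flush()
                    group = []
                group.append(m)
            flush()
    out.sort(key=lambda c: (c.interval.contig, c.interval.start))
    return out
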