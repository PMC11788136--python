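"""Ground-truthed synthetic data: germline loci and V(D)J amplicon reads.

The locus generator plants structurally valid V/D/J/C genes (built from the
package's built-in templates) into random intergenic sequence, with a
configurable mix of surgically planted defects, and records exact truth:
intervals, strand, functionality class and defect codes. Because the
acceptance properties of the annotation pipeline are *exact recovery*,
the generator guarantees the truth labels are well-defined: after planting
it scrubs the random flanks of any spurious signal (leader-like patterns,
stray RSS placements) that would make an alternative annotation equally
valid. Likewise, the read simulator draws junctions whose non-templated
bases cannot extend a germline alignment, so trimming/insertion counts are
identifiable from the sequence alone.

None of this changes what the annotation or repertoire code sees — it only
makes the planted truth unambiguous, which is what "ground truth" means.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field, replace

import pandas as pd

from ._templates import TEMPLATES
from .annotate import AnnotationConfig, find_d_candidates, find_j_candidates
from .classify import name_genes
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
    GenomicInterval,
    GermlineGene,
    RssHit,
)
from .reference import ReferenceRecord
from .rss import CHAIN_RSS, HEPTAMER_CONSENSUS, NONAMER_CONSENSUS
from .seq import g_fraction, longest_common_substring, reverse_complement, translate

_RC_HEPT = reverse_complement(HEPTAMER_CONSENSUS)
_RC_NON = reverse_complement(NONAMER_CONSENSUS)

V_PSEUDO_CODES = (
    STOP_CODON,
    MISSING_C23,
    MISSING_W41,
    MISSING_C104,
    NO_INIT_CODON,
    NO_DONOR_SPLICE,
    NO_ACCEPTOR_SPLICE,
)
def _j_orf_codes(chain: str) -> tuple[str, str]:
    return ((NO_WGXG if chain == "IGH" else NO_FGXG), NO_J_HEPTAMER)
C_PSEUDO_CODES = (STOP_CODON, NO_DONOR_SPLICE)

_STOPS = {"TAA", "TAG", "TGA"}


class GenerationError(RuntimeError):
    pass


# =====================================================================
# Locus generation
# =====================================================================

@dataclass
class LocusSpec:
    """Study conditions for a synthetic germline locus.

    Defaults describe a heavy-chain locus with two D-J-C clusters
    (30 V, 5+5 D, 4+4 J, 4+5 C) and a 40% V pseudogene load spread over
    every plantable defect code, echoing the mixed F/ORF/P composition
    reported for real bovid loci.
    """

    chain: str = "IGH"
    n_v: int = 30
    clusters: tuple[tuple[int, int, int], ...] | None = None  # (nD, nJ, nC)
    n_families: int = 3
    v_pseudo_fraction: float = 0.4
    v_orf_fraction: float = 0.1
    j_pseudo_fraction: float = 0.25
    j_orf_fraction: float = 0.5
    c_pseudo_fraction: float = 0.22
    reversed_v_fraction: float = 0.0
    family_divergence: float = 0.16
    gene_divergence: float = 0.04
    rss_mutation_rate: float = 0.0
    sequence_mutation_rate: float = 0.0
    contig: str = "synthetic_locus"
    seed: int = 0

    def __post_init__(self):
        if self.clusters is None:
            default = {
                "IGH": ((5, 4, 4), (5, 4, 5)),
                "IGK": ((0, 5, 1),),
                "IGL": ((0, 1, 1), (0, 1, 1), (0, 1, 1)),
            }
            self.clusters = default[self.chain]
        if self.chain != "IGH" and any(c[0] > 0 for c in self.clusters):
            raise ValueError(f"{self.chain} locus cannot contain D genes")
        for f in (
            self.v_pseudo_fraction,
            self.v_orf_fraction,
            self.j_pseudo_fraction,
            self.j_orf_fraction,
            self.c_pseudo_fraction,
            self.reversed_v_fraction,
        ):
            if not 0 <= f <= 1:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class LocusResult:
    genome: dict[str, str]
    genes: list[GermlineGene]  # truth annotation, classified and named
    v_seeds: dict[str, str]  # family base sequences (annotation seeds)
    c_seeds: dict[str, str]  # C exon templates (annotation seeds)
    spec: LocusSpec


def _rand_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _mutate_coding(
    seq: str,
    rate: float,
    rng: random.Random,
    protect: set[int] = frozenset(),
    protect_ends: int = 3,
) -> str:
    """Random substitutions at ``rate``, skipping protected positions and
    reverting any change that creates an in-frame (frame 0) stop codon."""
    s = list(seq)
    n = len(s)
    k = max(0, round(rate * n))
    eligible = [
        i for i in range(protect_ends, n - protect_ends) if i not in protect
    ]
    for i in rng.sample(eligible, min(k, len(eligible))):
        old = s[i]
        s[i] = rng.choice([b for b in "ACGT" if b != old])
        c0 = 3 * (i // 3)
        if "".join(s[c0 : c0 + 3]) in _STOPS:
            s[i] = old
    return "".join(s)


def _v_anchor_positions(leader_tail_len: int) -> set[int]:
    """Exon nt positions of the C23/W41/L89/C104 codons (kept intact by
    diversification)."""
    out = set()
    for codon in (22, 40, 88, 103):
        start = leader_tail_len + 3 * codon
        out.update(range(start, start + 3))
    return out


@dataclass
class _Feature:
    kind: str  # V, D, J, C
    rel_spans: dict  # name -> (start, end) relative to block
    strand: str
    payload: dict


def _build_v_block(tpl: dict, exon: str, defect: str | None, spacer_class: int, rng):
    leader = tpl["v_leader"]
    if defect == NO_INIT_CODON:
        leader = "ACG" + leader[3:]
    ilen = rng.randrange(80, 151)
    intron = ("GT" if defect != NO_DONOR_SPLICE else "CA") + _rand_seq(rng, ilen - 4)
    intron += "AG" if defect != NO_ACCEPTOR_SPLICE else "CC"
    hept = HEPTAMER_CONSENSUS if defect != NO_RSS else "CTCAGTG"
    spacer = _rand_seq(rng, spacer_class)
    rss = hept + spacer + NONAMER_CONSENSUS
    block = leader + intron + exon + rss
    e0 = len(leader) + len(intron)
    spans = {
        "leader": (0, len(leader)),
        "exon": (e0, e0 + len(exon)),
        "rss": (e0 + len(exon), len(block)),
    }
    return block, spans


def _make_v_exon(base: str, defect: str | None, tail_len: int, rng) -> str:
    s = list(base)

    def set_codon(codon_idx: int, triplet: str):
        p = tail_len + 3 * codon_idx
        s[p : p + 3] = triplet

    if defect == STOP_CODON:
        set_codon(49, "TAA")
    elif defect == MISSING_C23:
        set_codon(22, "CGT")
    elif defect == MISSING_W41:
        set_codon(40, "CGG")
    elif defect == MISSING_C104:
        set_codon(103, "CGT")
    return "".join(s)


def _mutate_j(template: str, rng: random.Random, n_subs: int = 3) -> str:
    """Diversify a J coding region without touching the motif codons,
    creating stops, extra tryptophans, or codon-boundary GT dinucleotides
    in the donor search window."""
    s = list(template)
    protected = set(range(24, 36))
    tries = 0
    done = 0
    while done < n_subs and tries < 200:
        tries += 1
        i = rng.randrange(3, len(s) - 3)
        if i in protected:
            continue
        old = s[i]
        s[i] = rng.choice([b for b in "ACGT" if b != old])
        c0 = 3 * (i // 3)
        codon = "".join(s[c0 : c0 + 3])
        bad = codon in _STOPS or codon == "TGG"
        if not bad:
            for d in range(30, len(s), 3):
                if "".join(s[d : d + 2]) == "GT":
                    bad = True
                    break
        if bad:
            s[i] = old
        else:
            done += 1
    return "".join(s)


def _build_j_block(coding: str, defect: str | None, spacer_class: int, rng):
    if defect in (NO_WGXG, NO_FGXG):
        # destroy the motif tryptophan; diversification never adds a W,
        # so no alternative motif can exist
        coding = coding[:24] + "TCG" + coding[27:]
    hept = HEPTAMER_CONSENSUS if defect != NO_J_HEPTAMER else "CACAGAA"
    spacer = _rand_seq(rng, spacer_class)
    up = reverse_complement(NONAMER_CONSENSUS) + spacer + reverse_complement(hept)
    donor = "GT" if defect != NO_DONOR_SPLICE else "CA"
    # tail covers the donor search window; scrub codon-boundary GT in it
    tail = list(_rand_seq(rng, 26))
    block = up + coding + donor + "".join(tail)
    b = list(block)
    cs = len(up)
    for d in range(30, 71, 3):
        if defect != NO_DONOR_SPLICE and d == len(coding):
            continue
        if "".join(b[cs + d : cs + d + 2]) == "GT":
            b[cs + d + 1] = "C"
    block = "".join(b)
    spans = {"rss": (0, len(up)), "coding": (cs, cs + len(coding))}
    return block, spans


def _make_d_cores(rng: random.Random, n: int, length_range=(16, 28)) -> list[str]:
    """Distinct G-rich cores with pairwise longest common substrings short
    enough that junction D assignment is never ambiguous."""
    cores: list[str] = []
    guard = 0
    while len(cores) < n:
        guard += 1
        if guard > 5000:
            raise GenerationError("could not generate distinct D cores")
        length = rng.randrange(length_range[0], length_range[1] + 1)
        core = "".join(
            "G" if rng.random() < 0.55 else rng.choice("ACT") for _ in range(length)
        )
        if g_fraction(core) < 0.45 or core.count("C") / len(core) > 0.30:
            continue
        if any(longest_common_substring(core, c)[0] > 6 for c in cores):
            continue
        cores.append(core)
    return cores


def _build_d_block(core: str, rng: random.Random):
    up = _RC_NON + _rand_seq(rng, 12) + _RC_HEPT
    down = HEPTAMER_CONSENSUS + _rand_seq(rng, 12) + NONAMER_CONSENSUS
    block = up + core + down
    spans = {
        "rss5": (0, len(up)),
        "core": (len(up), len(up) + len(core)),
        "rss3": (len(up) + len(core), len(block)),
    }
    return block, spans


def _build_c_block(exons: list[str], defect: str | None, rng: random.Random):
    if defect == STOP_CODON:
        ex0 = exons[0]
        exons = [ex0[:30] + "TAA" + ex0[33:]] + exons[1:]
    parts = []
    spans = {}
    pos = 0
    for k, ex in enumerate(exons):
        if k > 0:
            ilen = rng.randrange(100, 251)
            donor = "GT" if not (defect == NO_DONOR_SPLICE and k == 1) else "GC"
            intron = donor + _rand_seq(rng, ilen - 4) + "AG"
            parts.append(intron)
            pos += len(intron)
        parts.append(ex)
        spans[f"exon{k}"] = (pos, pos + len(ex))
        pos += len(ex)
    return "".join(parts), spans, exons


# ----------------------------------------------------------------- assembly

def _assign_defects(rng, n, pseudo_frac, orf_frac, pseudo_codes, orf_codes):
    n_p = round(pseudo_frac * n)
    n_o = round(orf_frac * n)
    picked = rng.sample(range(n), min(n, n_p + n_o))
    defects: dict[int, str] = {}
    for k, idx in enumerate(picked):
        if k < n_p:
            defects[idx] = pseudo_codes[k % len(pseudo_codes)]
        else:
            defects[idx] = orf_codes[(k - n_p) % len(orf_codes)]
    return defects


def _leader_matches(upstream: str, config: AnnotationConfig):
    """All (atg_pos, leader_len, has_donor) placements the leader search
    would consider; mirrors annotate.find_leader."""
    lmin, lmax = config.leader_length_range
    imin, imax = config.intron_range
    n = len(upstream)
    out = []
    for p in range(n - 3, -1, -1):
        if upstream[p : p + 3] != "ATG":
            continue
        for llen in range(lmin, lmax + 1, 3):
            if p + llen > n:
                continue
            if not (imin <= n - (p + llen) <= imax):
                continue
            if "*" in translate(upstream[p : p + llen]):
                continue
            out.append((p, llen, upstream[p + llen : p + llen + 2] == "GT"))
    return out


def generate_locus(spec: LocusSpec) -> LocusResult:
    """Build a synthetic locus with exact, scrubbed ground truth.

    Deterministic given ``spec.seed``: the same spec always yields
    byte-identical sequence and truth.
    """
    last_err = None
    for attempt in range(6):
        rng = random.Random((spec.seed * 1000003 + attempt) % (2**31))
        try:
            return _generate_locus_once(spec, rng)
        except GenerationError as err:  # rare ambiguity; rebuild afresh
            last_err = err
    raise GenerationError(f"locus generation failed repeatedly: {last_err}")


def _generate_locus_once(spec: LocusSpec, rng: random.Random) -> LocusResult:
    chain = spec.chain
    tpl = TEMPLATES[chain]
    config = AnnotationConfig()
    tail_len = len(tpl["v_leader_tail"])
    v_spacer = CHAIN_RSS[(chain, "V")]["3p"]
    j_spacer = CHAIN_RSS[(chain, "J")]["5p"]

    exon_template = tpl["v_leader_tail"] + tpl["v_mature_nt"] + tpl["v_stub"]
    anchor_protect = _v_anchor_positions(tail_len)
    fam_bases = [
        _mutate_coding(exon_template, spec.family_divergence, rng, anchor_protect)
        for _ in range(spec.n_families)
    ]

    v_defects = _assign_defects(
        rng, spec.n_v, spec.v_pseudo_fraction, spec.v_orf_fraction,
        V_PSEUDO_CODES, (NO_RSS,),
    )
    n_rev = round(spec.reversed_v_fraction * spec.n_v)
    reversed_idx = set(rng.sample(range(spec.n_v), n_rev))

    n_j_total = sum(c[1] for c in spec.clusters)
    n_c_total = sum(c[2] for c in spec.clusters)
    j_defects = _assign_defects(
        rng, n_j_total, spec.j_pseudo_fraction, spec.j_orf_fraction,
        (NO_DONOR_SPLICE,), _j_orf_codes(chain),
    )
    c_defects = _assign_defects(
        rng, n_c_total, spec.c_pseudo_fraction, 0.0, C_PSEUDO_CODES, (),
    )
    d_cores = _make_d_cores(rng, sum(c[0] for c in spec.clusters))

    parts: list[str] = []
    pos = 0
    features: list[_Feature] = []

    def emit(seq: str):
        nonlocal pos
        parts.append(seq)
        pos += len(seq)

    def emit_block(block: str, spans: dict, kind: str, strand: str, payload: dict):
        nonlocal pos
        if strand == "-":
            L = len(block)
            block = reverse_complement(block)
            spans = {k: (L - e, L - s) for k, (s, e) in spans.items()}
        abs_spans = {k: (pos + s, pos + e) for k, (s, e) in spans.items()}
        features.append(_Feature(kind, abs_spans, strand, payload))
        emit(block)

    emit(_rand_seq(rng, 600))
    for i in range(spec.n_v):
        fam = i % spec.n_families
        exon = _mutate_coding(
            fam_bases[fam], spec.gene_divergence, rng, anchor_protect
        )
        defect = v_defects.get(i)
        exon = _make_v_exon(exon, defect, tail_len, rng)
        block, spans = _build_v_block(tpl, exon, defect, v_spacer, rng)
        strand = "-" if i in reversed_idx else "+"
        emit_block(block, spans, "V", strand, {"defect": defect, "family": fam})
        emit(_rand_seq(rng, rng.randrange(250, 551)))
    emit(_rand_seq(rng, 1200))

    d_iter = iter(d_cores)
    j_index = 0
    c_index = 0
    c_exon_counts = [4, 1, 2, 3]
    for n_d, n_j, n_c in spec.clusters:
        for _ in range(n_d):
            core = next(d_iter)
            block, spans = _build_d_block(core, rng)
            emit_block(block, spans, "D", "+", {"core": core})
            emit(_rand_seq(rng, rng.randrange(150, 251)))
        emit(_rand_seq(rng, 400))
        for _ in range(n_j):
            defect = j_defects.get(j_index)
            coding = _mutate_j(tpl["j_nt"], rng)
            block, spans = _build_j_block(coding, defect, j_spacer, rng)
            emit_block(block, spans, "J", "+", {"defect": defect})
            emit(_rand_seq(rng, rng.randrange(200, 301)))
            j_index += 1
        emit(_rand_seq(rng, 600))
        for _ in range(n_c):
            defect = c_defects.get(c_index)
            n_ex = c_exon_counts[c_index % len(c_exon_counts)]
            if defect == NO_DONOR_SPLICE and n_ex == 1:
                defect = STOP_CODON  # splice defect needs an intron
            exons = [
                _mutate_coding(tpl["c_exons"][k], 0.02, rng)
                for k in range(n_ex)
            ]
            block, spans, exons = _build_c_block(exons, defect, rng)
            emit_block(block, spans, "C", "+", {"defect": defect, "exons": exons})
            emit(_rand_seq(rng, rng.randrange(1600, 2001)))
            c_index += 1
    emit(_rand_seq(rng, 600))

    genome_list = list("".join(parts))
    protected = _protected_positions(features, len(genome_list))
    _scrub(genome_list, protected, features, spec, config)
    genome = {spec.contig: "".join(genome_list)}
    if spec.sequence_mutation_rate > 0 or spec.rss_mutation_rate > 0:
        genome = {
            spec.contig: _apply_noise(
                genome[spec.contig], features, spec, rng
            )
        }
    genes = _truth_genes(genome[spec.contig], features, spec)
    v_seeds = {str(k + 1): fam_bases[k] for k in range(spec.n_families)}
    c_seeds = {f"Cex{k + 1}": tpl["c_exons"][k] for k in range(4)}
    return LocusResult(genome=genome, genes=genes, v_seeds=v_seeds,
                       c_seeds=c_seeds, spec=spec)


def _protected_positions(features: list[_Feature], n: int) -> bytearray:
    """1 where the scrubber must not touch: exons, coding regions, RSS
    heptamer/nonamer elements, leader exons, splice dinucleotides."""
    prot = bytearray(n)

    def mark(s, e):
        for i in range(max(0, s), min(n, e)):
            prot[i] = 1

    for f in features:
        for name, (s, e) in f.rel_spans.items():
            if name in ("exon", "coding", "core", "leader") or name.startswith("exon"):
                mark(s, e)
                # splice dinucleotides flanking exons / leader
                mark(s - 2, s)
                mark(e, e + 2)
            else:
                # RSS span: protect the terminal heptamer/nonamer elements
                # (first and last 9 bp cover both), leave the spacer free
                mark(s, s + 9)
                mark(e - 9, e)
    return prot


def _scrub(genome: list, protected: bytearray, features: list[_Feature],
           spec: LocusSpec, config: AnnotationConfig) -> None:
    """Disrupt spurious signals until the planted truth is the unique
    annotation. Raises GenerationError if a spurious signal cannot be
    removed without touching planted sequence."""
    chain = spec.chain

    def disrupt(lo: int, hi: int) -> bool:
        for i in range(lo, hi):
            if 0 <= i < len(genome) and not protected[i]:
                genome[i] = "A" if genome[i] != "A" else "C"
                return True
        return False

    from .locus import build_exclusions

    v_feats = [f for f in features if f.kind == "V"]
    truth_d = {f.rel_spans["core"] for f in features if f.kind == "D"}
    truth_j = {f.rel_spans["coding"] for f in features if f.kind == "J"}
    v_ivs = [
        GenomicInterval(spec.contig, *f.rel_spans["exon"], f.strand)
        for f in v_feats
    ]
    c_ivs = [
        GenomicInterval(
            spec.contig,
            min(s for s, _ in f.rel_spans.values()),
            max(e for _, e in f.rel_spans.values()),
            f.strand,
        )
        for f in features
        if f.kind == "C"
    ]
    d_ivs = [
        GenomicInterval(spec.contig, *f.rel_spans["core"], f.strand)
        for f in features
        if f.kind == "D"
    ]
    exclude, exclude_j = build_exclusions(v_ivs, c_ivs, d_ivs)

    for _ in range(12):
        changed = False
        text = "".join(genome)

        # leader ambiguity for init/donor-defect V genes
        for f in v_feats:
            defect = f.payload["defect"]
            if defect not in (NO_INIT_CODON, NO_DONOR_SPLICE):
                continue
            es, ee = f.rel_spans["exon"]
            if f.strand == "+":
                up = text[max(0, es - config.upstream_window) : es]
                base = es - len(up)
                to_abs = lambda p: (base + p, base + p + 3)  # noqa: E731
            else:
                up = reverse_complement(text[ee : ee + config.upstream_window])
                base = ee + len(up)
                to_abs = lambda p: (base - p - 3, base - p)  # noqa: E731
            for p, llen, has_donor in _leader_matches(up, config):
                if defect == NO_INIT_CODON or has_donor:
                    lo, hi = to_abs(p)
                    if not disrupt(lo, hi):
                        raise GenerationError("cannot scrub leader signal")
                    changed = True
                    break  # re-extract text next iteration

        # spurious strict RSS downstream of RSS-defect V genes
        from .rss import scan_rss

        for f in v_feats:
            if f.payload["defect"] != NO_RSS:
                continue
            es, ee = f.rel_spans["exon"]
            spacer = CHAIN_RSS[(chain, "V")]["3p"]
            if f.strand == "+":
                down = text[ee : ee + 16 + spacer + 1 + config.rss_gap]
                hits = scan_rss(down, config.rss, spacer, "V-side")
                for h in hits:
                    if disrupt(ee + h.interval.start, ee + h.interval.end):
                        changed = True
                        break
                    raise GenerationError("cannot scrub V RSS")
            else:
                down = reverse_complement(
                    text[max(0, es - 16 - spacer - 1 - config.rss_gap) : es]
                )
                hits = scan_rss(down, config.rss, spacer, "V-side")
                for h in hits:
                    if disrupt(es - h.interval.end, es - h.interval.start):
                        changed = True
                        break
                    raise GenerationError("cannot scrub V RSS")

        # spurious structural D / J candidates
        gdict = {spec.contig: text}
        if any(f.kind == "D" for f in features) or chain == "IGH":
            for cand in find_d_candidates(gdict, config, chain, exclude=exclude):
                span = (cand.interval.start, cand.interval.end)
                if span in truth_d and cand.interval.strand == "+":
                    continue
                hit5, hit3 = cand.rss_5p, cand.rss
                if (
                    disrupt(hit5.interval.start, hit5.interval.end)
                    or disrupt(hit3.interval.start, hit3.interval.end)
                    or disrupt(cand.interval.start, cand.interval.end)
                ):
                    changed = True
                else:
                    raise GenerationError("cannot scrub spurious D")
        for cand in find_j_candidates(gdict, config, chain, exclude=exclude_j):
            span = (cand.interval.start, cand.interval.end)
            if span in truth_j and cand.interval.strand == "+":
                continue
            hit = cand.rss
            if disrupt(hit.interval.start, hit.interval.end):
                changed = True
            else:
                raise GenerationError("cannot scrub spurious J")

        if not changed:
            return
    raise GenerationError("scrubbing did not converge")


def _apply_noise(text: str, features: list[_Feature], spec: LocusSpec,
                 rng: random.Random) -> str:
    """Optional degradation used for non-exact experiments: point mutations
    inside gene bodies (sequence_mutation_rate) and RSS elements
    (rss_mutation_rate). Truth classes are NOT updated; callers using
    noise rates accept fuzzy truth."""
    s = list(text)
    for f in features:
        for name, (lo, hi) in f.rel_spans.items():
            rate = (
                spec.rss_mutation_rate
                if name.startswith("rss")
                else spec.sequence_mutation_rate
            )
            for i in range(lo, hi):
                if rng.random() < rate:
                    s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
    return "".join(s)


def _truth_genes(text: str, features: list[_Feature], spec: LocusSpec):
    chain = spec.chain
    genes: list[GermlineGene] = []
    contig = spec.contig

    def rss_hit(span, strand, side, spacer_class):
        s, e = span
        raw = text[s:e]
        sense = raw if strand == "+" else reverse_complement(raw)
        if side == "3p":  # heptamer first reading away from gene
            hept, non = sense[:7], sense[-9:]
        else:  # genome sense shows rc(non) ... rc(hept)
            hept = reverse_complement(sense[-7:])
            non = reverse_complement(sense[:9])
        return RssHit(
            interval=GenomicInterval(contig, s, e, strand),
            spacer_class=spacer_class,
            heptamer=hept,
            nonamer=non,
            spacer_length=(e - s) - 16,
            heptamer_matches=sum(a == b for a, b in zip(hept, HEPTAMER_CONSENSUS)),
            nonamer_matches=sum(a == b for a, b in zip(non, NONAMER_CONSENSUS)),
        )

    for f in features:
        if f.kind == "V":
            s, e = f.rel_spans["exon"]
            seq = text[s:e] if f.strand == "+" else reverse_complement(text[s:e])
            defect = f.payload["defect"]
            if defect is None:
                functionality, defects = "F", []
            elif defect == NO_RSS:
                functionality, defects = "ORF", [NO_RSS]
            else:
                functionality, defects = "P", [defect]
            genes.append(
                GermlineGene(
                    name="V?",
                    segment_type="V",
                    chain=chain,
                    interval=GenomicInterval(contig, s, e, f.strand),
                    functionality=functionality,
                    defects=defects,
                    nt_sequence=seq,
                    family=str(f.payload["family"] + 1),
                    rss=None if defect == NO_RSS else rss_hit(
                        f.rel_spans["rss"], f.strand, "3p",
                        CHAIN_RSS[(chain, "V")]["3p"],
                    ),
                )
            )
        elif f.kind == "D":
            s, e = f.rel_spans["core"]
            genes.append(
                GermlineGene(
                    name="D?",
                    segment_type="D",
                    chain=chain,
                    interval=GenomicInterval(contig, s, e, f.strand),
                    functionality="F",
                    nt_sequence=text[s:e],
                    rss_5p=rss_hit(f.rel_spans["rss5"], f.strand, "5p", 12),
                    rss=rss_hit(f.rel_spans["rss3"], f.strand, "3p", 12),
                )
            )
        elif f.kind == "J":
            s, e = f.rel_spans["coding"]
            defect = f.payload["defect"]
            if defect is None:
                functionality, defects = "F", []
            elif defect == NO_DONOR_SPLICE:
                functionality, defects = "P", [NO_DONOR_SPLICE]
            else:
                functionality, defects = "ORF", [defect]
            genes.append(
                GermlineGene(
                    name="J?",
                    segment_type="J",
                    chain=chain,
                    interval=GenomicInterval(contig, s, e, f.strand),
                    functionality=functionality,
                    defects=defects,
                    nt_sequence=text[s:e],
                    rss_5p=rss_hit(
                        f.rel_spans["rss"], f.strand, "5p",
                        CHAIN_RSS[(chain, "J")]["5p"],
                    ),
                )
            )
        elif f.kind == "C":
            exon_spans = sorted(
                (v for k, v in f.rel_spans.items() if k.startswith("exon")),
            )
            s = min(a for a, _ in exon_spans)
            e = max(b for _, b in exon_spans)
            defect = f.payload["defect"]
            genes.append(
                GermlineGene(
                    name="C?",
                    segment_type="C",
                    chain=chain,
                    interval=GenomicInterval(contig, s, e, f.strand),
                    functionality="F" if defect is None else "P",
                    defects=[] if defect is None else [defect],
                    nt_sequence="".join(text[a:b] for a, b in exon_spans),
                    exons=[
                        GenomicInterval(contig, a, b, f.strand)
                        for a, b in exon_spans
                    ],
                )
            )
    return name_genes(genes, chain)


# =====================================================================
# Repertoire simulation
# =====================================================================

@dataclass
class RepertoireSpec:
    """Study conditions for simulated V(D)J amplicon reads.

    The default junction model trims geometric(p=0.5) bases from the V 3'
    and J 5' ends, inserts Poisson(lambda=2) non-templated bases on each
    side of an optionally included, lightly trimmed D core, and clips the
    amplicon to the 200-300 bp window of the gel-purified PCR product it
    emulates. Amino-acid junction lengths then centre in the low 20s.
    """

    reference: list[ReferenceRecord]
    n_reads: int = 10000
    v_usage: dict[str, float] | None = None  # name -> weight; None = uniform
    j_usage: dict[str, float] | None = None
    trim_p: float = 0.5  # geometric success prob; mean (1-p)/p trims
    insert_lambda: float = 2.0  # per side of the D core
    d_probability: float = 0.85
    d_trim_max: int = 3
    mutation_rate: float = 0.0
    amplicon_range: tuple[int, int] = (200, 300)
    rc_fraction: float = 0.5
    force_in_frame: bool = False
    stop_fraction: float = 0.0
    d_min_core: int = 7  # below this a D remnant counts as insertions
    ultralong_core: str | None = None
    ultralong_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.amplicon_range
        if not (150 <= lo <= hi <= 400):
            raise ValueError("amplicon window must lie within [150, 400]")


def bovid_ultralong_spec(reference, seed: int = 0, **overrides) -> RepertoireSpec:
    """Preset planting extended D-like cores so a sizeable fraction of
    productive junctions exceed 50 aa, as bovid ultra-long heavy chains do.
    The core avoids TA/TG dinucleotides so it is stop-free in every frame."""
    rng = random.Random(seed + 991)
    core = []
    prev = ""
    while len(core) < 126:
        b = rng.choice("ACGG" if prev != "T" else "CT")
        core.append(b)
        prev = b
    defaults = dict(
        reference=reference,
        ultralong_core="".join(core),
        ultralong_fraction=0.35,
        amplicon_range=(280, 400),
        force_in_frame=True,
        seed=seed,
    )
    defaults.update(overrides)
    return RepertoireSpec(**defaults)


@dataclass
class SimulatedRepertoire:
    reads: list[tuple[str, str, str]]  # (name, sequence, quality)
    read_truth: pd.DataFrame
    clonotypes: pd.DataFrame  # truth clonotype table
    spec: RepertoireSpec


def _geom(rng: random.Random, p: float, cap: int) -> int:
    k = 0
    while k < cap and rng.random() > p:
        k += 1
    return k


def _poisson(rng: random.Random, lam: float) -> int:
    # Knuth; lam is small
    import math

    L = math.exp(-lam)
    k, prod = 0, rng.random()
    while prod > L:
        k += 1
        prod *= rng.random()
    return k


def _junction_aligner():
    from Bio import Align

    from .pipeline import AlignParams

    p = AlignParams()
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = p.match
    al.mismatch_score = p.mismatch
    al.open_gap_score = p.gap_open
    al.extend_gap_score = p.gap_extend
    return al


_JUNCTION_ALIGNER = _junction_aligner()


def _trim_identifiable(v_nt: str, vd: int, j_nt: str, jd: int,
                       v_kept: str, middle: str, j_kept: str) -> bool:
    """True iff scored local alignment recovers exactly the drawn trim
    points (no profitable, possibly gapped, extension into the junction).
    Verified with the same scoring the read pipeline uses, on a window
    around each junction boundary."""
    if vd:
        pad = min(24, len(v_kept))
        query = v_nt[len(v_nt) - vd - pad :]
        target = (v_kept[-pad:] + middle + j_kept)[: pad + vd + 12]
        aln = _JUNCTION_ALIGNER.align(query, target)[0]
        qb, tb = aln.aligned
        if len(qb) != 1 or tuple(qb[0]) != (0, pad) or tuple(tb[0]) != (0, pad):
            return False
    if jd:
        pad = min(24, len(j_kept))
        query = j_nt[: jd + pad]
        left = (v_kept + middle)[-(jd + 12) :]
        target = left + j_kept[:pad]
        aln = _JUNCTION_ALIGNER.align(query, target)[0]
        qb, tb = aln.aligned
        if (
            len(qb) != 1
            or tuple(qb[0]) != (jd, jd + pad)
            or tuple(tb[0]) != (len(target) - pad, len(target))
        ):
            return False
    return True


def _alignment_extends(read_cont: str, germ_cont: str) -> bool:
    """True if a scored extension (+2 match / -3 mismatch) of a germline
    alignment into ``read_cont`` could be profitable."""
    score = 0
    for a, b in zip(read_cont, germ_cont):
        score += 2 if a == b else -3
        if score > 0:
            return True
    return False


def _kmers(s: str, k: int) -> set[str]:
    return {s[i : i + k] for i in range(len(s) - k + 1)}


def simulate_repertoire(spec: RepertoireSpec) -> SimulatedRepertoire:
    """Simulate amplicon reads with exact junction truth.

    Insertions are drawn so that no germline alignment can extend into
    them (see module docstring); with ``mutation_rate`` 0 the pipeline can
    therefore recover the truth table exactly.
    """
    rng = random.Random(spec.seed)
    v_recs = [r for r in spec.reference if r.segment_type == "V" and r.productive
              and r.cdr3_anchor is not None]
    j_recs = [r for r in spec.reference if r.segment_type == "J" and r.productive
              and r.cdr3_anchor is not None]
    d_recs = [r for r in spec.reference if r.segment_type == "D"]
    if not v_recs or not j_recs:
        raise ValueError("reference must contain productive V and J records")
    d_order = {r.name: i for i, r in enumerate(d_recs)}
    d_kmer7 = {r.name: _kmers(r.nt_sequence, 7) for r in d_recs}

    def weights(recs, usage):
        if usage is None:
            return [1.0] * len(recs)
        return [usage.get(r.name, 0.0) for r in recs]

    v_w = weights(v_recs, spec.v_usage)
    j_w = weights(j_recs, spec.j_usage)

    reads = []
    rows = []
    for i in range(spec.n_reads):
        row = _draw_read(rng, spec, v_recs, v_w, j_recs, j_w, d_recs, d_kmer7, d_order)
        name = f"read{i}"
        seq = row.pop("read_seq")
        if rng.random() < spec.rc_fraction:
            seq = reverse_complement(seq)
        reads.append((name, seq, "I" * len(seq)))
        row["read_id"] = name
        rows.append(row)
    read_truth = pd.DataFrame(rows)
    clonotypes = (
        read_truth.groupby(["junction", "v_call", "j_call"], as_index=False)
        .agg(
            junction_aa=("junction_aa", "first"),
            d_call=("d_call", "first"),
            duplicate_count=("read_id", "size"),
            v_deletions=("v_deletions", "first"),
            j_deletions=("j_deletions", "first"),
            n_insertions=("n_insertions", "first"),
            productive=("productive", "first"),
        )
        .sort_values(
            ["duplicate_count", "junction", "v_call", "j_call"],
            ascending=[False, True, True, True],
        )
        .reset_index(drop=True)
    )
    return SimulatedRepertoire(reads=reads, read_truth=read_truth,
                               clonotypes=clonotypes, spec=spec)


def _draw_read(rng, spec, v_recs, v_w, j_recs, j_w, d_recs, d_kmer7, d_order):
    want_stop = spec.force_in_frame and rng.random() < spec.stop_fraction
    for _attempt in range(500):
        v = rng.choices(v_recs, weights=v_w)[0]
        j = rng.choices(j_recs, weights=j_w)[0]
        v_nt, j_nt = v.nt_sequence, j.nt_sequence
        v_anchor, j_anchor = v.cdr3_anchor, j.cdr3_anchor
        v_avail = len(v_nt) - v_anchor - 3  # never trim into the anchor codon
        vd = min(_geom(rng, spec.trim_p, 12), v_avail)
        jd = min(_geom(rng, spec.trim_p, 12), j_anchor)

        use_ultra = (
            spec.ultralong_core is not None
            and rng.random() < spec.ultralong_fraction
        )
        if use_ultra:
            d_name, d_seq = "", spec.ultralong_core
            ds, de = 0, len(d_seq)
        elif d_recs and rng.random() < spec.d_probability:
            d_rec = rng.choice(d_recs)
            d_name, d_seq = d_rec.name, d_rec.nt_sequence
            ds = min(_geom(rng, spec.trim_p, spec.d_trim_max), len(d_seq) // 3)
            de = len(d_seq) - min(
                _geom(rng, spec.trim_p, spec.d_trim_max), len(d_seq) // 3
            )
        else:
            d_name, d_seq, ds, de = "", "", 0, 0
        core = d_seq[ds:de]
        n1 = _poisson(rng, spec.insert_lambda)
        n2 = _poisson(rng, spec.insert_lambda)

        def draw_insert(n, avoid_first, avoid_last):
            s = [rng.choice("ACGT") for _ in range(n)]
            if n and avoid_first is not None and s[0] == avoid_first:
                s[0] = rng.choice([b for b in "ACGT" if b != avoid_first])
            if n and avoid_last is not None and s[-1] == avoid_last:
                alt = [b for b in "ACGT" if b != avoid_last]
                if n == 1 and avoid_first is not None:
                    alt = [b for b in alt if b != avoid_first] or alt
                s[-1] = rng.choice(alt)
            return "".join(s)

        v_next = v_nt[len(v_nt) - vd] if vd else None  # first trimmed base
        j_prev = j_nt[jd - 1] if jd else None
        d_first = core[0] if core else None
        d_left = d_seq[ds - 1] if ds else None
        d_right = d_seq[de] if de < len(d_seq) else None
        ins1 = draw_insert(n1, v_next, d_left if core else None)
        ins2 = draw_insert(n2, d_right, j_prev)
        if core:
            middle = ins1 + core + ins2
        else:
            middle = draw_insert(n1 + n2, v_next, j_prev)
        # identifiability checks -------------------------------------------
        if vd and not middle and j_nt[jd] == v_next:
            continue
        if jd and not middle and vd == 0 and v_nt[-1] == j_prev:
            continue
        if core and n1 == 0 and vd and d_first == v_next:
            continue
        v_kept = v_nt[: len(v_nt) - vd]
        j_kept = j_nt[jd:]
        if vd and _alignment_extends(middle + j_kept, v_nt[len(v_nt) - vd :]):
            continue
        if jd and _alignment_extends(
            (v_kept + middle)[::-1], j_nt[:jd][::-1]
        ):
            continue
        if not _trim_identifiable(v_nt, vd, j_nt, jd, v_kept, middle, j_kept):
            continue
        # D identifiability ------------------------------------------------
        kept_core = len(core)
        if core and not use_ultra:
            if kept_core < spec.d_min_core:
                d_name, kept_core_eff = "", 0
            else:
                kept_core_eff = kept_core
                # the kept core must be the unique maximal match
                longer = any(
                    w in d_seq
                    for w in (
                        middle[k : k + kept_core + 1]
                        for k in range(len(middle) - kept_core)
                    )
                )
                if longer:
                    continue
                bad = False
                for other in d_recs:
                    if other.name == d_name:
                        continue
                    if any(w in d_kmer7[other.name] for w in _kmers(middle, 7)):
                        ln, _, _ = longest_common_substring(middle, other.nt_sequence)
                        if ln >= kept_core or (
                            ln == kept_core
                            and d_order[other.name] < d_order.get(d_name, 1 << 30)
                        ):
                            bad = True
                            break
                if bad:
                    continue
        elif not use_ultra:
            kept_core_eff = 0
            if len(middle) >= spec.d_min_core and any(
                any(w in d_kmer7[r.name] for w in _kmers(middle, 7))
                for r in d_recs
            ):
                # an insertion-only junction must not fake a D core
                bad = False
                for r in d_recs:
                    ln, _, _ = longest_common_substring(middle, r.nt_sequence)
                    if ln >= spec.d_min_core:
                        bad = True
                        break
                if bad:
                    continue
        else:
            kept_core_eff = kept_core

        junction = v_nt[v_anchor : len(v_nt) - vd] + middle + j_kept[: j_anchor + 3 - jd]
        junction_aa = translate(junction)
        if spec.force_in_frame:
            if len(junction) % 3 != 0:
                continue
            if ("*" in junction_aa) != want_stop:
                continue
        if use_ultra and len(junction_aa) <= 50:
            continue

        full = v_kept + middle + j_kept
        target = rng.randrange(spec.amplicon_range[0], spec.amplicon_range[1] + 1)
        read_seq = full[-target:] if len(full) > target else full
        if spec.mutation_rate > 0:
            read_seq = "".join(
                rng.choice([b for b in "ACGT" if b != ch])
                if rng.random() < spec.mutation_rate
                else ch
                for ch in read_seq
            )
        n_ins = len(middle) - (kept_core_eff if d_name or spec.ultralong_core else 0)
        if use_ultra:
            n_ins = len(middle) - kept_core
        return {
            "read_seq": read_seq,
            "v_call": v.name,
            "d_call": d_name,
            "j_call": j.name,
            "junction": junction,
            "junction_aa": junction_aa,
            "v_deletions": vd,
            "j_deletions": jd,
            "n_insertions": n_ins,
            "productive": len(junction) % 3 == 0 and "*" not in junction_aa,
        }
    raise GenerationError("could not draw an identifiable junction")
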