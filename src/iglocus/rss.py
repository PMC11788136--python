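"""Recombination signal sequence (RSS) scanning and motif conservation.

An RSS is a conserved heptamer (consensus CACAGTG) and nonamer (consensus
ACAAAAACC) separated by a poorly conserved spacer of 12 +/- 1 or 23 +/- 1 bp.
The heptamer abuts the coding end of the gene segment and is read 5'->3'
away from it, so on the genome's plus strand a signal 3' of a V segment
reads heptamer-spacer-nonamer while a signal 5' of a J segment reads the
mirror image (reverse-complemented nonamer-spacer-heptamer).

The 12/23 geometry expected on each side of each segment type is fixed per
chain (``CHAIN_RSS``): IGH V 23 at 3', D 12 on both sides, J 23 at 5';
IGK V 12 at 3', J 23 at 5'; IGL V 23 at 3', J 12 at 5'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import GenomicInterval, RssHit
from .seq import reverse_complement

HEPTAMER_CONSENSUS = "CACAGTG"
NONAMER_CONSENSUS = "ACAAAAACC"

#: (chain, segment) -> {side: spacer class}; side "3p" = downstream of the
#: coding end (V-type geometry), "5p" = upstream (J-type geometry).
CHAIN_RSS: dict[tuple[str, str], dict[str, int]] = {
    ("IGH", "V"): {"3p": 23},
    ("IGH", "D"): {"5p": 12, "3p": 12},
    ("IGH", "J"): {"5p": 23},
    ("IGK", "V"): {"3p": 12},
    ("IGK", "J"): {"5p": 23},
    ("IGL", "V"): {"3p": 23},
    ("IGL", "J"): {"5p": 12},
}


@dataclass(frozen=True)
class RssConfig:
    """Mismatch tolerances for calling an RSS.

    The heptamer's first three bases (CAC) are the functionally critical
    cleavage motif and are required exactly by default; the nonamer is the
    degenerate element and tolerates more mismatches.
    """

    max_heptamer_mismatches: int = 1
    max_nonamer_mismatches: int = 3
    require_first3: bool = True

    def relaxed(self) -> "RssConfig":
        """Looser thresholds used only to *locate* candidate signals; the
        strict defaults remain the bar for functional classification."""
        return RssConfig(
            max_heptamer_mismatches=3,
            max_nonamer_mismatches=4,
            require_first3=self.require_first3,
        )


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _match_counts(arr: np.ndarray, offset: int, motif: str, n_pos: int) -> np.ndarray:
    """Matches to ``motif`` for windows starting at 0..n_pos-1 shifted by offset."""
    counts = np.zeros(n_pos, dtype=np.int16)
    for i, ch in enumerate(motif.encode("ascii")):
        counts += arr[offset + i : offset + i + n_pos] == ch
    return counts


def scan_rss(
    seq: str,
    config: RssConfig | None = None,
    spacer_class: int = 23,
    orientation: str = "V-side",
    contig: str = "",
) -> list[RssHit]:
    """Find all RSS placements in ``seq`` passing ``config`` thresholds.

    ``orientation`` is "V-side" (heptamer first, reading 5'->3') or
    "J-side" (the mirror arrangement). Spacer lengths of ``spacer_class``
    +/- 1 are accepted. Hits are returned sorted by position; overlapping
    placements with different spacer lengths are all reported.
    """
    if config is None:
        config = RssConfig()
    if spacer_class not in (12, 23):
        raise ValueError("spacer_class must be 12 or 23")
    if orientation not in ("V-side", "J-side"):
        raise ValueError("orientation must be 'V-side' or 'J-side'")
    arr = _encode(seq)
    rc_hept = reverse_complement(HEPTAMER_CONSENSUS)
    rc_non = reverse_complement(NONAMER_CONSENSUS)
    hits: list[RssHit] = []
    for sp in (spacer_class - 1, spacer_class, spacer_class + 1):
        window = 7 + sp + 9
        n_pos = len(arr) - window + 1
        if n_pos <= 0:
            continue
        if orientation == "V-side":
            hm = _match_counts(arr, 0, HEPTAMER_CONSENSUS, n_pos)
            nm = _match_counts(arr, 7 + sp, NONAMER_CONSENSUS, n_pos)
            first3 = _match_counts(arr, 0, "CAC", n_pos) == 3
        else:
            nm = _match_counts(arr, 0, rc_non, n_pos)
            hm = _match_counts(arr, 9 + sp, rc_hept, n_pos)
            first3 = _match_counts(arr, 9 + sp + 4, "GTG", n_pos) == 3
        ok = (hm >= 7 - config.max_heptamer_mismatches) & (
            nm >= 9 - config.max_nonamer_mismatches
        )
        if config.require_first3:
            ok &= first3
        for p in np.nonzero(ok)[0]:
            p = int(p)
            if orientation == "V-side":
                hept = seq[p : p + 7].upper()
                non = seq[p + 7 + sp : p + 16 + sp].upper()
            else:
                non = reverse_complement(seq[p : p + 9].upper())
                hept = reverse_complement(seq[p + 9 + sp : p + 16 + sp].upper())
            hits.append(
                RssHit(
                    interval=GenomicInterval(contig, p, p + window, "+"),
                    spacer_class=spacer_class,
                    heptamer=hept,
                    nonamer=non,
                    spacer_length=sp,
                    heptamer_matches=int(hm[p]),
                    nonamer_matches=int(nm[p]),
                )
            )
    hits.sort(key=lambda h: (h.interval.start, h.spacer_length))
    return hits


def best_hit(hits: list[RssHit], coding_pos: int, side: str) -> RssHit | None:
    """Pick one signal when several abut a gene end: highest total matches,
    ties broken by proximity of the heptamer to the coding end ``coding_pos``.
    ``side`` is "3p" (signal downstream, heptamer at hit start) or "5p"
    (signal upstream, heptamer ends at hit end)."""
    if not hits:
        return None

    def key(h: RssHit):
        hept_edge = h.interval.start if side == "3p" else h.interval.end
        return (
            -(h.heptamer_matches + h.nonamer_matches),
            abs(hept_edge - coding_pos),
            h.interval.start,
        )

    return min(hits, key=key)


@dataclass
class ConservationMatrix:
    """Per-position symbol frequencies of an equal-length alignment plus
    Shannon information content (2 - entropy, bits) per position."""

    frequencies: pd.DataFrame  # index: 0-based position; columns: symbols
    information: np.ndarray


def conservation_matrix(seqs: list[str]) -> ConservationMatrix:
    if not seqs:
        raise ValueError("no sequences")
    length = len(seqs[0])
    if length == 0 or any(len(s) != length for s in seqs):
        raise ValueError("sequences must be equal-length and non-empty")
    symbols = sorted({ch for s in seqs for ch in s.upper()})
    counts = pd.DataFrame(0, index=range(length), columns=symbols, dtype=float)
    for s in seqs:
        for i, ch in enumerate(s.upper()):
            counts.at[i, ch] += 1
    freqs = counts / len(seqs)
    p = freqs.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    return ConservationMatrix(frequencies=freqs, information=info)
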