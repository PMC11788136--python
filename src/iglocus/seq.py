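"""Low-level nucleotide utilities shared across the package."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Standard genetic code, indexed by codon. Codons with N translate to X.
CODON_TABLE = {}
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            CODON_TABLE[_b1 + _b2 + _b3] = _AA[16 * _i + 4 * _j + _k]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt: str, frame: int = 0) -> str:
    """Translate ``nt`` in the given frame with the standard code.

    Stop codons become ``*``; any codon containing a base other than
    A/C/G/T (e.g. N) becomes ``X``. A trailing partial codon is dropped.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    s = nt.upper()
    out = []
    for i in range(frame, len(s) - 2, 3):
        out.append(CODON_TABLE.get(s[i : i + 3], "X"))
    return "".join(out)


def g_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return s.count("G") / len(s)


def longest_common_substring(a: str, b: str) -> tuple[int, int, int]:
    """Length and start offsets (in ``a`` and ``b``) of the longest exact
    common substring. Ties resolve to the earliest position in ``a``, then
    in ``b``. O(len(a)*len(b)); both operands are short junction fragments.
    """
    best, best_ai, best_bi = 0, 0, 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        ca = a[i - 1]
        for j in range(1, len(b) + 1):
            if ca == b[j - 1]:
                v = prev[j - 1] + 1
                cur[j] = v
                if v > best:
                    best, best_ai, best_bi = v, i - v, j - v
        prev = cur
    return best, best_ai, best_bi
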