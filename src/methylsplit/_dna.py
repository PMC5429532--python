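"""Shared nucleotide coding helpers.

Bases are encoded as small integers (A=0, C=1, G=2, T=3, N=4) so that
collapsing into bisulfite three-letter space, reverse complementing and
mismatch counting are plain numpy array operations.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"
A, C, G, T, N = range(5)

_ENC = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_ENC[ord("U")] = T
_ENC[ord("u")] = T

_COMP = np.array([T, G, C, A, N], dtype=np.uint8)
_DEC = np.frombuffer(BASES.encode(), dtype=np.uint8)

_COMP_STR = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array."""
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode()


def complement_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_STR)[::-1]


def collapse_ct(codes: np.ndarray) -> np.ndarray:
    """C→T collapse (top-strand bisulfite space)."""
    out = codes.copy()
    out[out == C] = T
    return out


def collapse_ga(codes: np.ndarray) -> np.ndarray:
    """G→A collapse (bottom-strand bisulfite space)."""
    out = codes.copy()
    out[out == G] = A
    return out


# Cytosine context codes used throughout the package.
CTX_CG, CTX_CHG, CTX_CHH = 0, 1, 2
CONTEXT_NAMES = ("CG", "CHG", "CHH")


def context_codes_top(codes: np.ndarray) -> np.ndarray:
    """Per-position context class of top-strand cytosines.

    Returns an int8 array: CTX_* at positions holding a C whose context is
    decidable from the two downstream bases, -1 elsewhere (including Cs too
    close to the sequence end and contexts interrupted by N).
    """
    n = len(codes)
    ctx = np.full(n, -1, dtype=np.int8)
    if n < 2:
        return ctx
    is_c = codes == C
    nxt1 = np.full(n, N, dtype=np.uint8)
    nxt1[:-1] = codes[1:]
    nxt2 = np.full(n, N, dtype=np.uint8)
    if n >= 2:
        nxt2[:-2] = codes[2:]
    h1 = (nxt1 != G) & (nxt1 != N)
    h2 = (nxt2 != G) & (nxt2 != N)
    ctx[is_c & (nxt1 == G)] = CTX_CG
    ctx[is_c & h1 & (nxt2 == G)] = CTX_CHG
    ctx[is_c & h1 & h2] = CTX_CHH
    return ctx


def classify_strand_context(seq: str, pos: int, strand: str) -> str | None:
    """Context class (CG/CHG/CHH) of the cytosine at ``pos`` on ``strand``.

    ``seq`` is the top-strand sequence; for strand "-" the base at ``pos``
    must be G (a bottom-strand C) and the downstream bases run leftwards,
    complemented.  Returns None when the context is truncated by the
    sequence end or interrupted by N.
    """
    if strand == "+":
        if seq[pos] != "C":
            raise ValueError(f"base at position {pos} is {seq[pos]}, not C")
        if pos + 1 >= len(seq):
            return None
        n1 = seq[pos + 1]
        if n1 == "G":
            return "CG"
        if n1 == "N" or pos + 2 >= len(seq):
            return None
        n2 = seq[pos + 2]
        if n2 == "G":
            return "CHG"
        if n2 == "N":
            return None
        return "CHH"
    if strand == "-":
        if seq[pos] != "G":
            raise ValueError(
                f"base at position {pos} is {seq[pos]}, not G (bottom-strand C)"
            )
        if pos - 1 < 0:
            return None
        n1 = seq[pos - 1]
        if n1 == "C":
            return "CG"
        if n1 == "N" or pos - 2 < 0:
            return None
        n2 = seq[pos - 2]
        if n2 == "C":
            return "CHG"
        if n2 == "N":
            return None
        return "CHH"
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def context_codes_bottom(codes: np.ndarray) -> np.ndarray:
    """Per-position context class of bottom-strand cytosines.

    A bottom-strand cytosine sits opposite a top-strand G; its downstream
    bases run leftwards on the top strand, complemented.  Computed by
    classifying the reverse complement and mapping positions back.
    """
    return context_codes_top(revcomp_codes(codes))[::-1]
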