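"""Independent brute-force reference implementations used as test oracles.

Deliberately written without reusing the package's mapper internals: its own
base coding, its own collapse rules, and exhaustive scans of every genomic
offset in both bisulfite spaces.
"""

from __future__ import annotations

import numpy as np

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
STRANDS = ("top", "bottom")


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def _enc(seq: str, collapse: str) -> np.ndarray:
    if collapse == "ct":
        seq = seq.replace("C", "T")
    elif collapse == "ga":
        seq = seq.replace("G", "A")
    return np.array([_CODE[c] for c in seq], dtype=np.uint8)


def _profile(text: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Mismatch count of q at every offset of text."""
    n = len(text) - len(q) + 1
    if n <= 0:
        return np.empty(0, dtype=np.int32)
    mm = np.zeros(n, dtype=np.int32)
    for j in range(len(q)):
        mm += text[j : j + n] != q[j]
    return mm


def brute_map(seq: str, sequences: dict[str, str], max_mismatch: int):
    """All ungapped bisulfite-space alignments of seq, exhaustively.

    Returns a list of (mismatches, chrom, start, strand) sorted the way the
    package sorts its hits.
    """
    hits = []
    q_top = _enc(seq, "ct")
    q_bot = _enc(rc(seq), "ga")
    for chrom, text in sequences.items():
        mm = _profile(_enc(text, "ct"), q_top)
        for s in np.flatnonzero(mm <= max_mismatch):
            hits.append((int(mm[s]), chrom, int(s), "top"))
        mm = _profile(_enc(text, "ga"), q_bot)
        for s in np.flatnonzero(mm <= max_mismatch):
            hits.append((int(mm[s]), chrom, int(s), "bottom"))
    hits.sort(key=lambda h: (h[0], h[1], h[2], 0 if h[3] == "top" else 1))
    return hits


def brute_best_splits(
    read: str, sequences: dict[str, str], min_split: int, max_mismatch: int
):
    """Exhaustive breakpoint search: every split position, every locus pair.

    Returns the set of (b, left locus, right locus) tied at the minimal
    total mismatch count, excluding contiguous pairs (the two halves on one
    diagonal, which form a full-length alignment rather than a split).
    """
    L = len(read)
    best = None
    winners = set()
    for b in range(min_split, L - min_split + 1):
        lhits = brute_map(read[:b], sequences, max_mismatch)
        if not lhits:
            continue
        rhits = brute_map(read[b:], sequences, max_mismatch)
        for lm, lc, ls, lstr in lhits:
            for rm, rc_, rs, rstr in rhits:
                if lc == rc_ and lstr == rstr:
                    if lstr == "top" and rs == ls + b:
                        continue
                    if lstr == "bottom" and ls == rs + (L - b):
                        continue
                total = lm + rm
                if best is None or total < best:
                    best = total
                    winners = set()
                if total == best:
                    winners.add((b, lc, ls, lstr, rc_, rs, rstr, lm, rm))
    return best, winners
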