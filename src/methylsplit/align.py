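"""Bisulfite-space (three-letter) read and segment mapping.

Bisulfite conversion turns unmethylated C into T, so reads are compared to
the genome after collapsing the conversion-sensitive letter: reads from the
top genomic strand are matched C→T-collapsed against the C→T-collapsed
genome, reads from the bottom strand are reverse-complemented and matched
G→A-collapsed against the G→A-collapsed genome (directional protocol; only
the original top/bottom strands are sequenced).

The mapper is a deterministic ungapped seed-and-verify engine.  Seeds are
exact k-mers of the collapsed query looked up in a sorted k-mer index of the
collapsed genome; every candidate diagonal is then verified over the full
segment.  For a query of length L and mismatch allowance m, the engine uses
the largest stored seed length k with (m+1)·k ≤ L, so that m mismatches can
never destroy all of the m+1 disjoint seeds queried (pigeonhole): the search
is exhaustively sensitive, equivalent to scanning every genomic offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import _dna
from ._dna import classify_strand_context  # noqa: F401  (re-export site)
from .fileio import Genome, RawRead

TOP = "top"
BOTTOM = "bottom"

_STRAND_ORDER = {TOP: 0, BOTTOM: 1}


@dataclass(frozen=True)
class SegmentAlignment:
    """Ungapped alignment of a read (segment) to the reference.

    ``read_interval`` is given in original-read coordinates.  For
    bottom-strand alignments ``oriented_seq`` holds the reverse complement
    of the segment, i.e. the sequence as it matches the top-strand genome
    text left to right.
    """

    read_id: str
    read_interval: tuple[int, int]
    chrom: str
    ref_interval: tuple[int, int]
    genome_strand: str  # "top" | "bottom"
    mismatches: int
    n_hits: int
    oriented_seq: str = ""

    @property
    def ref_start(self) -> int:
        return self.ref_interval[0]

    @property
    def ref_end(self) -> int:
        return self.ref_interval[1]

    def __len__(self) -> int:
        return self.read_interval[1] - self.read_interval[0]


class BisulfiteIndex:
    """Sorted k-mer indices of the C→T- and G→A-collapsed genome.

    Chromosomes are concatenated with sentinel spacers (a code that matches
    nothing) so candidate windows crossing a boundary verify as garbage and
    are discarded automatically.
    """

    SENTINEL = 4  # the N code: mismatches every query letter

    def __init__(self, genome: Genome, k: int = 13, k_short: int = 8):
        if not genome.sequences:
            raise ValueError("cannot index an empty genome")
        if not 1 <= k_short <= k <= 31:
            raise ValueError("require 1 <= k_short <= k <= 31")
        self.k = k
        self.k_short = k_short
        self.chrom_names = list(genome.sequences)
        gap = k
        starts = []
        parts = []
        pos = 0
        for name in self.chrom_names:
            seq = genome.sequences[name]
            if len(seq) < k:
                warnings.warn(
                    f"chromosome {name} shorter than seed length {k}; "
                    "it contributes no long seeds"
                )
            starts.append(pos)
            parts.append(_dna.encode(seq))
            pos += len(seq)
            parts.append(np.full(gap, self.SENTINEL, dtype=np.uint8))
            pos += gap
        self._starts = np.array(starts, dtype=np.int64)
        self._lengths = np.array(
            [len(genome.sequences[n]) for n in self.chrom_names], dtype=np.int64
        )
        raw = np.concatenate(parts)
        self._codes = {
            TOP: _dna.collapse_ct(raw),
            BOTTOM: _dna.collapse_ga(raw),
        }
        self._tables: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}
        for space in (TOP, BOTTOM):
            for klen in sorted({k, k_short}):
                self._tables[(space, klen)] = self._build_table(
                    self._codes[space], klen
                )

    @staticmethod
    def _rolling_hash(codes: np.ndarray, klen: int) -> np.ndarray:
        n = len(codes) - klen + 1
        if n <= 0:
            return np.empty(0, dtype=np.int64)
        h = np.zeros(n, dtype=np.int64)
        for j in range(klen):
            h *= 5
            h += codes[j : j + n]
        return h

    def _build_table(self, codes, klen):
        h = self._rolling_hash(codes, klen)
        order = np.argsort(h, kind="stable")
        return h[order], order.astype(np.int64)

    # -- coordinate helpers -------------------------------------------------

    def codes(self, space: str) -> np.ndarray:
        return self._codes[space]

    def to_global(self, chrom: str, pos: int) -> int:
        i = self.chrom_names.index(chrom)
        return int(self._starts[i]) + pos

    def to_chrom(self, gpos: int) -> tuple[str, int] | None:
        i = int(np.searchsorted(self._starts, gpos, side="right")) - 1
        if i < 0:
            return None
        off = gpos - int(self._starts[i])
        if off >= int(self._lengths[i]):
            return None
        return self.chrom_names[i], int(off)

    def chrom_bounds(self, chrom: str) -> tuple[int, int]:
        i = self.chrom_names.index(chrom)
        return int(self._starts[i]), int(self._starts[i] + self._lengths[i])

    # -- seed lookup --------------------------------------------------------

    def _lookup(self, space: str, klen: int, qhash: int) -> np.ndarray:
        sh, pos = self._tables[(space, klen)]
        lo = np.searchsorted(sh, qhash, side="left")
        hi = np.searchsorted(sh, qhash, side="right")
        return pos[lo:hi]

    def candidate_starts(
        self, space: str, qcodes: np.ndarray, max_mismatch: int
    ) -> np.ndarray:
        """Candidate global start positions for a collapsed query."""
        L = len(qcodes)
        if (max_mismatch + 1) * self.k <= L:
            klen = self.k
        else:
            klen = self.k_short
        if L < klen:
            raise ValueError(
                f"query length {L} below minimum seed length {klen}"
            )
        m = max_mismatch + 1
        offsets = [i * klen for i in range(m) if (i + 1) * klen <= L]
        if L - klen not in offsets:
            offsets.append(L - klen)
        cands = []
        for off in offsets:
            qh = 0
            for j in range(off, off + klen):
                qh = qh * 5 + int(qcodes[j])
            hits = self._lookup(space, klen, qh)
            if len(hits):
                cands.append(hits - off)
        if not cands:
            return np.empty(0, dtype=np.int64)
        starts = np.unique(np.concatenate(cands))
        n = len(self._codes[space])
        return starts[(starts >= 0) & (starts + L <= n)]


def build_index(genome: Genome, k: int = 13, k_short: int = 8) -> BisulfiteIndex:
    """Construct the two collapsed-space seed indices for a genome."""
    return BisulfiteIndex(genome, k=k, k_short=k_short)


def _verify(
    codes: np.ndarray, starts: np.ndarray, qcodes: np.ndarray, max_mismatch: int
) -> list[tuple[int, int]]:
    if len(starts) == 0:
        return []
    L = len(qcodes)
    windows = codes[starts[:, None] + np.arange(L)[None, :]]
    mm = np.count_nonzero(windows != qcodes, axis=1)
    keep = mm <= max_mismatch
    return [(int(s), int(m)) for s, m in zip(starts[keep], mm[keep])]


def map_segment(
    seq: str,
    index: BisulfiteIndex,
    max_mismatch: int = 2,
    max_hits: int = 10,
    spaces: Sequence[str] = (TOP, BOTTOM),
    read_id: str = "",
    read_interval: tuple[int, int] | None = None,
) -> list[SegmentAlignment]:
    """Find all ungapped alignments of ``seq`` with ≤ max_mismatch
    collapsed-space mismatches; return the best ``max_hits`` sorted by
    (mismatches, chrom, position, strand).  ``n_hits`` on every returned
    alignment records the total number found.
    """
    L = len(seq)
    if read_interval is None:
        read_interval = (0, L)
    hits: list[tuple[int, int, str, str]] = []  # (mm, gstart, space, oriented)
    if TOP in spaces:
        q = _dna.collapse_ct(_dna.encode(seq))
        for s, mm in _verify(
            index.codes(TOP),
            index.candidate_starts(TOP, q, max_mismatch),
            q,
            max_mismatch,
        ):
            hits.append((mm, s, TOP, seq))
    if BOTTOM in spaces:
        rc = _dna.revcomp(seq)
        q = _dna.collapse_ga(_dna.encode(rc))
        for s, mm in _verify(
            index.codes(BOTTOM),
            index.candidate_starts(BOTTOM, q, max_mismatch),
            q,
            max_mismatch,
        ):
            hits.append((mm, s, BOTTOM, rc))
    alns = []
    for mm, gstart, space, oriented in hits:
        loc = index.to_chrom(gstart)
        if loc is None:
            continue
        chrom, pos = loc
        alns.append(
            SegmentAlignment(
                read_id=read_id,
                read_interval=read_interval,
                chrom=chrom,
                ref_interval=(pos, pos + L),
                genome_strand=space,
                mismatches=mm,
                n_hits=0,
                oriented_seq=oriented,
            )
        )
    alns.sort(
        key=lambda a: (
            a.mismatches,
            a.chrom,
            a.ref_interval[0],
            _STRAND_ORDER[a.genome_strand],
        )
    )
    n = len(alns)
    return [replace(a, n_hits=n) for a in alns[:max_hits]]


def map_full_read(
    read: RawRead, index: BisulfiteIndex, max_mismatch: int = 2
) -> tuple[str, SegmentAlignment | None]:
    """Map a whole read; returns (status, best alignment or None).

    status is "mapped" for a unique best full-length alignment,
    "multimapped" when the best alignment is tied, "unmapped" otherwise.
    Unmapped reads feed the split-read engine; uniquely mapped reads feed
    the un-split coverage track and the reference methylation pass.
    """
    hits = map_segment(
        read.seq, index, max_mismatch=max_mismatch, max_hits=2, read_id=read.read_id
    )
    if not hits:
        return "unmapped", None
    if len(hits) > 1 and hits[1].mismatches == hits[0].mismatches:
        return "multimapped", None
    return "mapped", hits[0]


def call_cytosines(
    aln: SegmentAlignment, read_seq: str, genome: Genome
) -> list[tuple[str, int, str, bool]]:
    """Per-cytosine methylation observations from one ungapped alignment.

    ``read_seq`` is the aligned sequence in genome (top-strand) orientation,
    i.e. ``aln.oriented_seq``.  Top-strand alignments interrogate reference
    Cs (read C = methylated, read T = unmethylated); bottom-strand
    alignments interrogate reference Gs (read G = methylated, read A =
    unmethylated).  Returns (chrom, 0-based ref position, context,
    methylated) tuples; positions with other read bases or an undecidable
    context yield no call.
    """
    s, e = aln.ref_interval
    ref = genome.fetch(aln.chrom, s, e)
    chrom_seq = genome.sequences[aln.chrom]
    out = []
    if aln.genome_strand == TOP:
        ref_base, meth_base, unmeth_base, strand = "C", "C", "T", "+"
    else:
        ref_base, meth_base, unmeth_base, strand = "G", "G", "A", "-"
    for i, rb in enumerate(ref):
        if rb != ref_base:
            continue
        b = read_seq[i]
        if b == meth_base:
            meth = True
        elif b == unmeth_base:
            meth = False
        else:
            continue
        ctx = classify_strand_context(chrom_seq, s + i, strand)
        if ctx is None:
            continue
        out.append((aln.chrom, s + i, ctx, meth))
    return out
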