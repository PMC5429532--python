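"""Cytosine methylation at new insertion alleles and windowed meta-profiles.

The same split reads that reveal an insertion carry the methylation state of
the new allele: the flank half reports the insertion site's flanking DNA,
the TE half reports the corresponding TE terminus.  Because the inserted
allele (flank + TSD + TE) does not exist in the reference, sequence contexts
near the junction are classified against the reconstructed allele — a CHH in
the empty reference can be a CHG or CG in the carrier chromosome.

With reads of length L and a minimal split length s, flank methylation is
resolved over L − s bases on either side of the insertion point (60 bp for
85-nt reads split at 25).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from . import _dna
from .align import BOTTOM, TOP, SegmentAlignment
from .caller import InsertionCall
from .fileio import Genome, TECopyAnnotation
from .splitread import FIVE, SplitJunctionRead

SIDES = ("flank5", "flank3", "te5", "te3")


def flank_resolution(read_len: int, min_split_len: int) -> int:
    """Bases of flank methylation resolved per side of the insertion point."""
    return read_len - min_split_len


def classify_context(seq: str, pos: int, strand: str = "+") -> str | None:
    """CG / CHG / CHH context of the cytosine at ``pos`` (H = A, C or T).

    ``strand`` "+" expects a C at ``pos`` and reads rightwards; "-" expects
    a G (a bottom-strand C) and reads leftwards, complemented.  Returns
    None when the context runs off the sequence or through an N.
    """
    return _dna.classify_strand_context(seq, pos, strand)


@dataclass(frozen=True)
class CytosineCall:
    """Aggregated methylation observations at one (side, offset, context)."""

    call_id: str
    side: str  # flank5 | flank3 | te5 | te3
    offset: int  # bp from the junction (0 = first base beyond it)
    context: str
    methylated: int
    total: int

    def __post_init__(self):
        if not 0 <= self.methylated <= self.total:
            raise ValueError("require 0 <= methylated <= total")


@dataclass(frozen=True)
class MetaProfile:
    side: str
    context: str
    window_start: int
    mean_level: float
    ci_low: float
    ci_high: float
    n_elements: int


def _allele_parts(
    call: InsertionCall,
    genome: Genome,
    te_sequences: dict[str, str],
    ref_copy: TECopyAnnotation,
    pad: int = 200,
):
    p2 = call.tsd_interval[0]
    p1 = call.tsd_interval[1] - 1 if call.tsd_seq else p2 - 1
    chrom_seq = genome.sequences[call.chrom]
    lstart = max(0, p2 - pad)
    left = chrom_seq[lstart : p1 + 1]
    right = chrom_seq[p2 : min(len(chrom_seq), p2 + pad)]
    copy_id = call.parental_copy if call.parental_copy in te_sequences else ref_copy.copy_id
    te_seq = te_sequences[copy_id]
    orient = call.te_orientation if call.te_orientation in "+-" else "+"
    if orient == "-":
        te_seq = _dna.revcomp(te_seq)
    return left + te_seq + right, lstart, len(left), len(left) + len(te_seq), p1, p2, orient


def methylation_at_insertion(
    call: InsertionCall,
    members: Sequence[SplitJunctionRead],
    genome: Genome,
    te_sequences: dict[str, str],
) -> list[CytosineCall]:
    """Per-cytosine methylation of the inserted allele from the call's own
    split reads, keyed by side and distance from the junction.

    Flank-half observations are keyed by the member's junction side; TE-half
    observations by the abutted TE terminus, with offsets measured inward
    from that terminus.  Counts are aggregated per (side, offset, context).
    """
    allele, lstart, te_lo, te_hi, p1, p2, orient = _allele_parts(
        call, genome, te_sequences, members[0].te_ref_copy
    )
    j5, j3 = te_lo - 1, te_hi
    acc: dict[tuple[str, int, str], list[int]] = {}

    def observe(side: str, offset: int, a: int, read_base: str, strand: str):
        ab = allele[a]
        if strand == TOP:
            if ab != "C" or read_base not in "CT":
                return
            meth = read_base == "C"
            ctx = _dna.classify_strand_context(allele, a, "+")
        else:
            if ab != "G" or read_base not in "GA":
                return
            meth = read_base == "G"
            ctx = _dna.classify_strand_context(allele, a, "-")
        if ctx is None:
            return
        key = (side, offset, ctx)
        cell = acc.setdefault(key, [0, 0])
        cell[1] += 1
        if meth:
            cell[0] += 1

    for m in members:
        # Flank half: allele coordinates follow the reference.
        fl = m.flank_aln
        s, e = fl.ref_interval
        for i, pos in enumerate(range(s, e)):
            if m.junction_side == FIVE:
                if pos > p1 or pos < lstart:
                    continue
                a = pos - lstart
                side, off = "flank5", j5 - a
            else:
                if pos < p2 or pos - p2 >= len(allele) - j3:
                    continue
                a = j3 + (pos - p2)
                side, off = "flank3", a - j3
            observe(side, off, a, fl.oriented_seq[i], fl.genome_strand)

        # TE half: anchor allele coordinates at the abutted terminus so the
        # mapping is robust to length differences between family copies.
        te = m.te_aln
        copy = m.te_ref_copy
        s, e = te.ref_interval
        terminus_left = (m.te_end == FIVE) == (orient == "+")
        flip = orient == "-"
        strand = te.genome_strand
        if flip:
            strand = TOP if strand == BOTTOM else BOTTOM
        side = "te5" if m.te_end == FIVE else "te3"
        for i, pos in enumerate(range(s, e)):
            if m.te_end == FIVE:
                local = pos - copy.start
            else:
                local = copy.end - 1 - pos
            if local < 0:
                continue
            a = te_lo + local if terminus_left else te_hi - 1 - local
            if not te_lo <= a < te_hi:
                continue
            base = te.oriented_seq[i]
            if flip:
                base = _dna.revcomp(base)
            observe(side, local, a, base, strand)

    return [
        CytosineCall(call.call_id, side, off, ctx, v[0], v[1])
        for (side, off, ctx), v in sorted(acc.items())
    ]


def metaprofile(
    calls: Iterable[CytosineCall], window: int = 10, ci: float = 0.95
) -> list[MetaProfile]:
    """Windowed meta-analysis across insertions.

    Within each (side, context, window) the per-element level is the pooled
    methylated/total fraction of one insertion call; the mean is taken
    across elements.  The interval is the envelope of two 95% intervals:
    the t interval on the across-element standard error (between-insertion
    variability) and the Wilson interval on the pooled counts.  The second
    component keeps the interval honestly calibrated where counts are
    sparse: with a handful of observations per element the empirical
    across-element variance can collapse to zero (e.g. every element
    unmethylated) even though the underlying rate is not.  Windows observed
    in fewer than two elements carry an undefined (NaN) interval.
    """
    cells: dict[tuple[str, str, int], dict[str, list[int]]] = {}
    for c in calls:
        if c.total == 0:
            continue
        key = (c.side, c.context, (c.offset // window) * window)
        per = cells.setdefault(key, {})
        m = per.setdefault(c.call_id, [0, 0])
        m[0] += c.methylated
        m[1] += c.total
    out = []
    for (side, ctx, wstart), per in sorted(cells.items()):
        levels = np.array([m / t for m, t in per.values() if t > 0])
        n = len(levels)
        mean = float(levels.mean())
        if n >= 2:
            se = levels.std(ddof=1) / np.sqrt(n)
            tcrit = stats.t.ppf(0.5 + ci / 2, n - 1)
            lo, hi = mean - tcrit * se, mean + tcrit * se
            pooled_m = sum(m for m, _ in per.values())
            pooled_t = sum(t for _, t in per.values())
            wlo, whi = stats.binomtest(pooled_m, pooled_t).proportion_ci(
                ci, method="wilson"
            )
            lo = max(0.0, min(lo, float(wlo)))
            hi = min(1.0, max(hi, float(whi)))
        else:
            lo = hi = float("nan")
        out.append(MetaProfile(side, ctx, wstart, mean, float(lo), float(hi), n))
    return out


# ---------------------------------------------------------------------------
# Genome-wide accumulator fed by uniquely mapped full-length reads.  Used for
# the companion views of an insertion: methylation of the same locus in the
# reference (pre-insertion) state and of the parental TE copy.


class MethylAccumulator:
    """Per-position methylated/total counts from full-length alignments,
    kept separately for top-strand Cs and bottom-strand Cs (reference Gs)."""

    def __init__(self, genome: Genome):
        self.genome = genome
        self._codes = {c: _dna.encode(s) for c, s in genome.sequences.items()}
        self.meth = {
            strand: {c: np.zeros(len(s), dtype=np.int32) for c, s in genome.sequences.items()}
            for strand in (TOP, BOTTOM)
        }
        self.total = {
            strand: {c: np.zeros(len(s), dtype=np.int32) for c, s in genome.sequences.items()}
            for strand in (TOP, BOTTOM)
        }

    def add(self, aln: SegmentAlignment) -> None:
        s, e = aln.ref_interval
        ref = self._codes[aln.chrom][s:e]
        read = _dna.encode(aln.oriented_seq)
        if aln.genome_strand == TOP:
            site = ref == _dna.C
            meth = site & (read == _dna.C)
            unmeth = site & (read == _dna.T)
        else:
            site = ref == _dna.G
            meth = site & (read == _dna.G)
            unmeth = site & (read == _dna.A)
        tot = self.total[aln.genome_strand][aln.chrom][s:e]
        mth = self.meth[aln.genome_strand][aln.chrom][s:e]
        tot[meth | unmeth] += 1
        mth[meth] += 1

    def site(self, chrom: str, pos: int) -> tuple[str | None, int, int]:
        """(context, methylated, total) at one reference position, reading
        the strand on which that base is a cytosine."""
        seq = self.genome.sequences[chrom]
        base = seq[pos]
        if base == "C":
            ctx = _dna.classify_strand_context(seq, pos, "+")
            strand = TOP
        elif base == "G":
            ctx = _dna.classify_strand_context(seq, pos, "-")
            strand = BOTTOM
        else:
            return None, 0, 0
        return (
            ctx,
            int(self.meth[strand][chrom][pos]),
            int(self.total[strand][chrom][pos]),
        )


def _region_calls(acc, chrom, positions_offsets, call_id, side):
    out = {}
    for pos, off in positions_offsets:
        ctx, m, t = acc.site(chrom, pos)
        if ctx is None or t == 0:
            continue
        cell = out.setdefault((side, off, ctx), [0, 0])
        cell[0] += m
        cell[1] += t
    return [
        CytosineCall(call_id, side, off, ctx, v[0], v[1])
        for (side, off, ctx), v in sorted(out.items())
    ]


def reference_flank_profile(
    acc: MethylAccumulator, calls: Sequence[InsertionCall], span: int = 60
) -> list[CytosineCall]:
    """Methylation of the insertion-site flanks in the reference (i.e.
    pre-insertion) state, from the un-split read pass."""
    out = []
    for call in calls:
        p2 = call.tsd_interval[0]
        p1 = call.tsd_interval[1] - 1 if call.tsd_seq else p2 - 1
        n = len(acc.genome.sequences[call.chrom])
        five = [(p1 - o, o) for o in range(span) if 0 <= p1 - o]
        three = [(p2 + o, o) for o in range(span) if p2 + o < n]
        out += _region_calls(acc, call.chrom, five, call.call_id, "flank5")
        out += _region_calls(acc, call.chrom, three, call.call_id, "flank3")
    return out


def parental_te_profile(
    acc: MethylAccumulator,
    calls: Sequence[InsertionCall],
    te_annot: Sequence[TECopyAnnotation],
    span: int = 60,
) -> list[CytosineCall]:
    """Methylation over the parental copy's terminal ``span`` bases and its
    flanks, for calls whose parental copy is resolved."""
    by_id = {a.copy_id: a for a in te_annot}
    out = []
    for call in calls:
        copy = by_id.get(call.parental_copy)
        if copy is None:
            continue
        n = len(acc.genome.sequences[copy.chrom])
        if copy.strand == "-":
            five_term = [(copy.end - 1 - o, o) for o in range(span)]
            three_term = [(copy.start + o, o) for o in range(span)]
            five_fl = [(copy.end + o, o) for o in range(span) if copy.end + o < n]
            three_fl = [(copy.start - 1 - o, o) for o in range(span) if copy.start - 1 - o >= 0]
        else:
            five_term = [(copy.start + o, o) for o in range(span)]
            three_term = [(copy.end - 1 - o, o) for o in range(span)]
            five_fl = [(copy.start - 1 - o, o) for o in range(span) if copy.start - 1 - o >= 0]
            three_fl = [(copy.end + o, o) for o in range(span) if copy.end + o < n]
        five_term = [(p, o) for p, o in five_term if 0 <= p < n]
        three_term = [(p, o) for p, o in three_term if 0 <= p < n]
        cid = call.call_id
        out += _region_calls(acc, copy.chrom, five_term, cid, "te5")
        out += _region_calls(acc, copy.chrom, three_term, cid, "te3")
        out += _region_calls(acc, copy.chrom, five_fl, cid, "flank5")
        out += _region_calls(acc, copy.chrom, three_fl, cid, "flank3")
    return out
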