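"""Call verification and benchmarking.

Two independent checks of a call set: (1) a true germinal insertion
depresses the coverage of full-length ("un-split") reads around the
insertion point, because carrier fragments spanning the junction contain TE
sequence and cannot map to the empty reference locus — quantified as a
standard score of site coverage against the flanking background; (2) on
simulated data, calls are matched one-to-one against the known insertion
truth to compute sensitivity TP/(TP+FN) and FDR FP/(TP+FP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .caller import InsertionCall


@dataclass(frozen=True)
class CoverageCheck:
    call_id: str
    site_cov: float
    bg_mean: float
    bg_sd: float
    z: float  # NaN when the background is degenerate
    supported: bool
    reason: str = ""


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def fdr(self) -> float:
        d = self.tp + self.fp
        return self.fp / d if d else 0.0


def coverage_track(
    genome_lengths: dict[str, int], alignments
) -> dict[str, np.ndarray]:
    """Per-base depth of uniquely mapped full-length reads."""
    track = {c: np.zeros(n, dtype=np.int32) for c, n in genome_lengths.items()}
    for aln in alignments:
        s, e = aln.ref_interval
        track[aln.chrom][s:e] += 1
    return track


def unsplit_coverage_check(
    call: InsertionCall,
    track: dict[str, np.ndarray],
    core: int = 5,
    flank: int = 80,
    inner: int = 30,
    z_cutoff: float = -1.0,
) -> CoverageCheck:
    """Standard score of un-split coverage at the insertion point.

    Site coverage is averaged over ±``core`` bp around the insertion point;
    the background is the ring [pos−flank, pos−inner] ∪ [pos+inner,
    pos+flank].  ``supported`` when z ≤ ``z_cutoff``.  Windows reaching
    beyond the chromosome are truncated with a warning.
    """
    cov = track[call.chrom]
    pos = call.position
    n = len(cov)
    lo, hi = pos - flank, pos + flank + 1
    if lo < 0 or hi > n:
        warnings.warn(
            f"coverage window around {call.chrom}:{pos} truncated at "
            "chromosome bounds"
        )
    site = cov[max(0, pos - core) : min(n, pos + core + 1)]
    bg = np.concatenate(
        [
            cov[max(0, pos - flank) : max(0, pos - inner + 1)],
            cov[min(n, pos + inner) : min(n, pos + flank + 1)],
        ]
    )
    site_cov = float(site.mean()) if len(site) else float("nan")
    bg_mean = float(bg.mean()) if len(bg) else float("nan")
    bg_sd = float(bg.std(ddof=1)) if len(bg) > 1 else 0.0
    if bg_sd > 0:
        z = (site_cov - bg_mean) / bg_sd
        return CoverageCheck(
            call.call_id, site_cov, bg_mean, bg_sd, z, z <= z_cutoff
        )
    return CoverageCheck(
        call.call_id,
        site_cov,
        bg_mean,
        bg_sd,
        float("nan"),
        False,
        reason="degenerate background (sd = 0)",
    )


def evaluate_calls(
    calls: Sequence[InsertionCall],
    truth,
    tolerance: int = 100,
    match_family: bool = True,
) -> EvalResult:
    """Greedy one-to-one matching of calls against truth insertions.

    A call matches an unmatched truth site on the same chromosome within
    ``tolerance`` bp (and of the same family when ``match_family``); pairs
    are taken closest-first, with coordinate order breaking ties so the
    result is invariant to the order of the input lists.  Unmatched calls
    are FP, unmatched truths FN.
    """
    pairs = []
    for i, c in enumerate(sorted(calls, key=lambda c: (c.chrom, c.position, c.family))):
        for j, t in enumerate(truth):
            if c.chrom != t.chrom:
                continue
            if match_family and c.family != t.family:
                continue
            d = abs(c.position - t.position)
            if d <= tolerance:
                pairs.append((d, c.position, t.position, i, j))
    pairs.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for _, _, _, i, j in pairs:
        if i in used_c or j in used_t:
            continue
        used_c.add(i)
        used_t.add(j)
        tp += 1
    return EvalResult(tp=tp, fp=len(calls) - tp, fn=len(truth) - tp)


def match_calls_to_truth(
    calls: Sequence[InsertionCall], truth, tolerance: int = 100,
    match_family: bool = True,
):
    """The greedy matching itself: list of (call, truth) TP pairs."""
    order = sorted(range(len(calls)), key=lambda i: (calls[i].chrom, calls[i].position))
    pairs = []
    for i in order:
        c = calls[i]
        for j, t in enumerate(truth):
            if c.chrom != t.chrom:
                continue
            if match_family and c.family != t.family:
                continue
            d = abs(c.position - t.position)
            if d <= tolerance:
                pairs.append((d, c.position, t.position, i, j))
    pairs.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    out = []
    for _, _, _, i, j in pairs:
        if i in used_c or j in used_t:
            continue
        used_c.add(i)
        used_t.add(j)
        out.append((calls[i], truth[j]))
    return out
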