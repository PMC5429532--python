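"""Cluster TE-junction reads and call insertion sites with their TSD.

A true germinal insertion leaves junction reads on both sides of the
integration point.  The 5′-side flank halves end at the last base of the
target-site duplication (TSD); the 3′-side flank halves begin at its first
base, because the TSD is present on both sides of the inserted element.
The overlap of the two read groups therefore *is* the TSD.

Three cluster filters gate every call: (1) more than ``min_support − 1``
supporting split reads, (2) both termini of one TE family represented, and
(3) a flank-half overlap no longer than the longest plausible TSD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .fileio import Genome
from .splitread import FIVE, THREE, SplitJunctionRead

AMBIGUOUS = "ambiguous"


@dataclass
class InsertionCluster:
    """Junction reads of one genomic neighbourhood (single linkage)."""

    chrom: str
    members: list[SplitJunctionRead]

    @property
    def side5(self) -> list[SplitJunctionRead]:
        return [m for m in self.members if m.junction_side == FIVE]

    @property
    def side3(self) -> list[SplitJunctionRead]:
        return [m for m in self.members if m.junction_side == THREE]

    def families(self) -> set[str]:
        return {m.family for m in self.members}


@dataclass(frozen=True)
class InsertionCall:
    chrom: str
    tsd_interval: tuple[int, int]  # 0-based half-open; empty when no TSD
    tsd_seq: str
    family: str
    superfamily: str
    parental_copy: str  # copy_id or "ambiguous"
    support_5: int
    support_3: int
    te_orientation: str  # "+", "-" or "unknown"

    @property
    def position(self) -> int:
        """0-based insertion point: first TSD base (or first base after the
        5′-side flank coverage when there is no TSD)."""
        return self.tsd_interval[0]

    @property
    def call_id(self) -> str:
        return f"{self.chrom}:{self.position + 1}:{self.family}"


@dataclass(frozen=True)
class Rejection:
    chrom: str
    position: int
    family: str
    reason: str  # "support" | "one_sided" | "te_ends" | "tsd" | "gap"
    support_5: int
    support_3: int


def cluster_junctions(
    splits: Sequence[SplitJunctionRead], cluster_window: int = 30
) -> list[InsertionCluster]:
    """Single-linkage clustering of junction positions: consecutive reads
    joined while their junction positions are within ``cluster_window``."""
    by_chrom: dict[str, list[SplitJunctionRead]] = {}
    for s in splits:
        by_chrom.setdefault(s.flank_aln.chrom, []).append(s)
    clusters = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda m: (m.junction_pos, m.read_id))
        current = [members[0]]
        for m in members[1:]:
            if m.junction_pos - current[-1].junction_pos <= cluster_window:
                current.append(m)
            else:
                clusters.append(InsertionCluster(chrom, current))
                current = [m]
        clusters.append(InsertionCluster(chrom, current))
    return clusters


def split_cluster_by_family(cluster: InsertionCluster) -> list[InsertionCluster]:
    """Clusters mixing TE families are split per family before filtering."""
    if len(cluster.families()) <= 1:
        return [cluster]
    out = []
    for fam in sorted(cluster.families()):
        out.append(
            InsertionCluster(
                cluster.chrom, [m for m in cluster.members if m.family == fam]
            )
        )
    return out


def _orientation(members: Sequence[SplitJunctionRead]) -> str:
    votes = set()
    for m in members:
        if m.junction_side == FIVE:
            votes.add("+" if m.te_end == FIVE else "-")
        else:
            votes.add("+" if m.te_end == THREE else "-")
    if votes == {"+"}:
        return "+"
    if votes == {"-"}:
        return "-"
    return "unknown"


def assign_parental_copy(members: Sequence[SplitJunctionRead]) -> str:
    """Parental copy: unanimous intersection wins, a strict majority of
    members otherwise, ``"ambiguous"`` when neither resolves a single copy."""
    sets = [set(m.te_copy_hits) for m in members if m.te_copy_hits]
    if not sets:
        return AMBIGUOUS
    inter = set.intersection(*sets)
    if len(inter) == 1:
        return inter.pop()
    if len(inter) > 1:
        return AMBIGUOUS
    votes: dict[str, int] = {}
    for s in sets:
        for c in s:
            votes[c] = votes.get(c, 0) + 1
    ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) == 1 or ranked[0][1] > ranked[1][1]:
        if ranked[0][1] > len(sets) / 2:
            return ranked[0][0]
    return AMBIGUOUS


def call_insertion(
    cluster: InsertionCluster,
    genome: Genome,
    min_support: int = 6,
    max_tsd: int = 20,
    max_gap: int = 10,
) -> InsertionCall | Rejection:
    """Apply the three cluster filters and derive the TSD.

    p1 = rightmost reference base covered by 5′-side flank halves,
    p2 = leftmost reference base covered by 3′-side flank halves;
    their overlap p1 − p2 + 1 is the TSD length.  A small negative overlap
    (gap up to ``max_gap``) is tolerated as a zero-length TSD; anything
    beyond ``max_tsd`` overlap is rejected as a spurious cluster.
    """
    members = cluster.members
    fams = cluster.families()
    if len(fams) != 1:
        raise ValueError("call_insertion requires a single-family cluster")
    family = fams.pop()
    side5, side3 = cluster.side5, cluster.side3
    approx = members[0].junction_pos

    def _reject(reason):
        return Rejection(
            cluster.chrom, approx, family, reason, len(side5), len(side3)
        )

    if len(members) < min_support:
        return _reject("support")
    if not side5 or not side3:
        return _reject("one_sided")
    te_ends = {m.te_end for m in members}
    if te_ends != {FIVE, THREE}:
        return _reject("te_ends")

    p1 = max(m.junction_pos for m in side5)
    p2 = min(m.junction_pos for m in side3)
    overlap = p1 - p2 + 1
    if overlap > max_tsd:
        return _reject("tsd")
    if overlap < 0 and -overlap - 1 > max_gap:
        return _reject("gap")
    if overlap > 0:
        tsd_interval = (p2, p1 + 1)
        tsd_seq = genome.fetch(cluster.chrom, p2, p1 + 1)
    else:
        tsd_interval = (p1 + 1, p1 + 1)
        tsd_seq = ""

    ref_copy = members[0].te_ref_copy
    return InsertionCall(
        chrom=cluster.chrom,
        tsd_interval=tsd_interval,
        tsd_seq=tsd_seq,
        family=family,
        superfamily=ref_copy.superfamily,
        parental_copy=assign_parental_copy(members),
        support_5=len(side5),
        support_3=len(side3),
        te_orientation=_orientation(members),
    )


def call_insertions(
    splits: Sequence[SplitJunctionRead],
    genome: Genome,
    cluster_window: int = 30,
    min_support: int = 6,
    max_tsd: int = 20,
    max_gap: int = 10,
) -> tuple[list[tuple[InsertionCall, list[SplitJunctionRead]]], list[Rejection]]:
    """Cluster, split by family, and call; returns accepted calls with their
    supporting reads, plus machine-readable rejections."""
    calls = []
    rejections = []
    for cluster in cluster_junctions(splits, cluster_window):
        for sub in split_cluster_by_family(cluster):
            res = call_insertion(
                sub, genome, min_support=min_support, max_tsd=max_tsd, max_gap=max_gap
            )
            if isinstance(res, Rejection):
                rejections.append(res)
            else:
                calls.append((res, sub.members))
    calls.sort(key=lambda cm: (cm[0].chrom, cm[0].position, cm[0].family))
    return calls, rejections
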