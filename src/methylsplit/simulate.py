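"""Simulation of TE insertions and directional bisulfite-converted reads.

The generator produces (1) a synthetic reference genome with annotated TE
copies and genes, (2) a mutant genome carrying known TE insertions with
family-specific target-site duplications, and (3) single-end reads drawn
from both strands of the mutant after in-silico bisulfite conversion, with
a truth table tying every read and insertion back to its origin.

Methylation is drawn independently per read and per cytosine at
context-specific rates; the defaults (20% CG, 3% CHG, 3% CHH) are typical
genome-wide plant averages.  Unmethylated cytosines are emitted as T on the
read's own strand (directional protocol: only the original top and bottom
strands are sequenced).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _dna
from .fileio import Genome, RawRead, TECopyAnnotation

CONTEXT_LABELS = ("genic", "intergenic", "TE")

#: Canonical target-site duplication lengths by superfamily.  LINEs have
#: variable TSDs in nature; a fixed 0 keeps the truth table deterministic.
DEFAULT_TSD_LEN = {
    "Copia": 5,
    "Gypsy": 5,
    "LTR": 5,
    "Mutator": 9,
    "MuDR": 9,
    "hAT": 8,
    "CACTA": 3,
    "EnSpm": 3,
    "LINE": 0,
    "Helitron": 0,
}


@dataclass(frozen=True)
class MethylationModel:
    """Per-context methylation probabilities."""

    p_mcg: float = 0.20
    p_mchg: float = 0.03
    p_mchh: float = 0.03

    def __post_init__(self):
        for p in (self.p_mcg, self.p_mchg, self.p_mchh):
            if not 0.0 <= p <= 1.0:
                raise ValueError("methylation probabilities must be in [0,1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_mcg, self.p_mchg, self.p_mchh])


@dataclass(frozen=True)
class InsertionTruth:
    chrom: str
    position: int  # 0-based point on the ORIGINAL reference
    copy_id: str
    family: str
    superfamily: str
    tsd_len: int
    tsd_seq: str
    context_label: str
    orientation: str = "+"


@dataclass(frozen=True)
class TEDonor:
    copy_id: str
    family: str
    superfamily: str
    seq: str


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def extract_te_donors(
    genome: Genome, te_annot: Sequence[TECopyAnnotation]
) -> list[TEDonor]:
    out = []
    for a in te_annot:
        seq = genome.fetch(a.chrom, a.start, a.end)
        if a.strand == "-":
            seq = _dna.revcomp(seq)
        out.append(TEDonor(a.copy_id, a.family, a.superfamily, seq))
    return out


# ---------------------------------------------------------------------------
# Site selection


def context_label_arrays(
    genome: Genome,
    te_annot: Sequence[TECopyAnnotation],
    gene_annot: Sequence[tuple[str, int, int]],
) -> dict[str, np.ndarray]:
    """Per-base context labels: 0 intergenic, 1 genic, 2 TE (TE wins)."""
    labels = {c: np.zeros(n, dtype=np.int8) for c, n in genome.lengths.items()}
    for chrom, start, end in gene_annot:
        labels[chrom][start:end] = 1
    for a in te_annot:
        labels[a.chrom][a.start : a.end] = 2
    return labels


def choose_insertion_sites(
    genome: Genome,
    te_annot: Sequence[TECopyAnnotation],
    gene_annot: Sequence[tuple[str, int, int]],
    n_per_context: int | dict[str, int],
    seed,
    end_margin: int = 150,
    min_gap: int = 300,
) -> list[tuple[str, int, str]]:
    """Random insertion sites, uniform over the eligible bases of each
    chromosomal context and reproducible under ``seed``.

    Sites keep ``end_margin`` bp clear of chromosome ends and ``min_gap``
    bp from each other so neighbouring insertions stay resolvable.
    """
    rng = _rng(seed)
    if isinstance(n_per_context, int):
        wanted = {lab: n_per_context for lab in CONTEXT_LABELS}
    else:
        wanted = dict(n_per_context)
    labels = context_label_arrays(genome, te_annot, gene_annot)
    chroms = list(genome.sequences)
    offsets = np.cumsum([0] + [genome.lengths[c] for c in chroms])
    flat = np.concatenate([labels[c] for c in chroms]) if chroms else np.empty(0)
    eligible_mask = np.ones(len(flat), dtype=bool)
    for ci, c in enumerate(chroms):
        n = genome.lengths[c]
        eligible_mask[offsets[ci] : offsets[ci] + min(end_margin, n)] = False
        eligible_mask[offsets[ci] + max(0, n - end_margin) : offsets[ci] + n] = False

    chosen: list[tuple[str, int, str]] = []
    chosen_flat: list[int] = []
    code = {"intergenic": 0, "genic": 1, "TE": 2}
    for lab in CONTEXT_LABELS:
        count = wanted.get(lab, 0)
        if count == 0:
            continue
        pool = np.flatnonzero((flat == code[lab]) & eligible_mask)
        if len(pool) == 0:
            raise ValueError(f"no eligible bases for context {lab!r}")
        perm = rng.permutation(pool)
        taken = 0
        for g in perm:
            if taken == count:
                break
            if all(abs(int(g) - f) >= min_gap for f in chosen_flat):
                ci = int(np.searchsorted(offsets, g, side="right")) - 1
                chosen.append((chroms[ci], int(g - offsets[ci]), lab))
                chosen_flat.append(int(g))
                taken += 1
        if taken < count:
            raise ValueError(
                f"could not place {count} sites in context {lab!r} with "
                f"min_gap={min_gap}"
            )
    return chosen


# ---------------------------------------------------------------------------
# Insertion


def tsd_length_for(superfamily: str, family: str, table=None) -> int:
    table = DEFAULT_TSD_LEN if table is None else table
    if superfamily in table:
        return table[superfamily]
    if family in table:
        return table[family]
    return 5


def insert_tes(
    genome: Genome,
    te_copies: Sequence[TEDonor],
    sites: Sequence[tuple[str, int, str]],
    tsd_len_by_superfamily: dict[str, int] | None = None,
    seed=0,
    orientation: str = "+",
    assignments: Sequence[int] | None = None,
) -> tuple[Genome, list[InsertionTruth]]:
    """Insert TE copies at the given sites, duplicating the ``tsd_len``
    bases immediately 5′ of each site on both sides of the element
    (flank…TSD + TE + TSD…flank).

    ``assignments`` fixes which donor goes to which site; otherwise donors
    are drawn at random.  ``orientation`` is "+", "-" or "random".
    """
    rng = _rng(seed)
    if not te_copies:
        raise ValueError("need at least one TE donor")
    if assignments is None:
        assignments = [int(i) for i in rng.integers(0, len(te_copies), len(sites))]
    orients = []
    for _ in sites:
        if orientation == "random":
            orients.append("+" if rng.random() < 0.5 else "-")
        else:
            orients.append(orientation)

    per_chrom: dict[str, list[tuple[int, TEDonor, int, str, str]]] = {}
    truths: list[InsertionTruth] = []
    for (chrom, pos, label), donor_i, orient in zip(sites, assignments, orients):
        donor = te_copies[donor_i]
        tsd_len = tsd_length_for(
            donor.superfamily, donor.family, tsd_len_by_superfamily
        )
        if pos - tsd_len < 0:
            raise ValueError(f"site {chrom}:{pos} too close to chromosome start")
        tsd_seq = genome.fetch(chrom, pos - tsd_len, pos)
        per_chrom.setdefault(chrom, []).append((pos, donor, tsd_len, orient, label))
        truths.append(
            InsertionTruth(
                chrom,
                pos,
                donor.copy_id,
                donor.family,
                donor.superfamily,
                tsd_len,
                tsd_seq,
                label,
                orient,
            )
        )

    sequences = dict(genome.sequences)
    for chrom, events in per_chrom.items():
        events.sort()
        for (p1, _, t1, _, _), (p2, _, _, _, _) in zip(events, events[1:]):
            if p2 - p1 <= t1:
                raise ValueError(
                    f"overlapping insertion sites at {chrom}:{p1} and {chrom}:{p2}"
                )
        ref = sequences[chrom]
        parts = []
        prev = 0
        for pos, donor, tsd_len, orient, _ in events:
            te = donor.seq if orient == "+" else _dna.revcomp(donor.seq)
            parts.append(ref[prev:pos])
            parts.append(te)
            parts.append(ref[pos - tsd_len : pos])
            prev = pos
        parts.append(ref[prev:])
        sequences[chrom] = "".join(parts)

    truths.sort(key=lambda t: (t.chrom, t.position))
    return Genome(sequences), truths


# ---------------------------------------------------------------------------
# Read simulation


def simulate_bisulfite_reads(
    genome: Genome,
    read_len: int,
    coverage: float,
    model: MethylationModel | None = None,
    n_snps_per_read: int = 0,
    error_rate: float = 0.0,
    seed=0,
    phred_quality: int = 40,
) -> tuple[list[RawRead], list[tuple[str, str, int, str]]]:
    """Directional bisulfite reads drawn uniformly from both strands.

    Every cytosine of a read (in read-strand orientation) is methylated
    independently with the context-specific probability and emitted as T
    otherwise.  ``n_snps_per_read`` substitutions are then placed at random
    positions, never as C→T (which would mimic conversion), keeping the
    SNP and conversion effects separable.  Returns the reads and a truth
    origin record (read_id, chrom, start, strand) per read.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if read_len < 1:
        raise ValueError("read_len must be at least 1")
    model = model or MethylationModel()
    rng = _rng(seed)
    p_by_ctx = model.as_array()
    qual = chr(33 + phred_quality) * read_len

    reads: list[RawRead] = []
    origins: list[tuple[str, str, int, str]] = []
    counter = 0
    for chrom, seq in genome.sequences.items():
        n = len(seq)
        if n < read_len:
            raise ValueError(f"read_len {read_len} exceeds chromosome {chrom}")
        codes = _dna.encode(seq)
        ctx_top = _dna.context_codes_top(codes)
        ctx_bot = _dna.context_codes_bottom(codes)
        is_c = codes == _dna.C
        is_g = codes == _dna.G
        # Cytosines whose context is truncated by the chromosome end are
        # treated as CHH for the conversion draw.
        p_top = np.where(
            is_c, p_by_ctx[np.where(ctx_top >= 0, ctx_top, _dna.CTX_CHH)], 0.0
        )
        p_bot = np.where(
            is_g, p_by_ctx[np.where(ctx_bot >= 0, ctx_bot, _dna.CTX_CHH)], 0.0
        )
        n_reads = int(round(coverage * n / read_len))
        starts = rng.integers(0, n - read_len + 1, n_reads)
        tops = rng.random(n_reads) < 0.5
        for s, top in zip(starts, tops):
            s = int(s)
            window = codes[s : s + read_len].copy()
            if top:
                idx = np.flatnonzero(is_c[s : s + read_len])
                if len(idx):
                    conv = rng.random(len(idx)) >= p_top[s + idx]
                    window[idx[conv]] = _dna.T
            else:
                idx = np.flatnonzero(is_g[s : s + read_len])
                if len(idx):
                    conv = rng.random(len(idx)) >= p_bot[s + idx]
                    window[idx[conv]] = _dna.A
                window = _dna.revcomp_codes(window)
            if error_rate > 0:
                errs = np.flatnonzero(rng.random(read_len) < error_rate)
                for e in errs:
                    window[e] = (window[e] + rng.integers(1, 4)) % 4
            if n_snps_per_read > 0:
                pos = rng.choice(read_len, size=n_snps_per_read, replace=False)
                for p in sorted(int(x) for x in pos):
                    old = int(window[p])
                    choices = [b for b in range(4) if b != old]
                    if old == _dna.C:
                        choices.remove(_dna.T)  # C→T mimics conversion
                    window[p] = choices[int(rng.integers(0, len(choices)))]
            read_id = f"r{counter:07d}"
            counter += 1
            reads.append(RawRead(read_id, _dna.decode(window), qual))
            origins.append((read_id, chrom, s, "top" if top else "bottom"))
    return reads, origins


# ---------------------------------------------------------------------------
# Synthetic reference genome


def make_reference(
    seed,
    length: int = 500_000,
    chrom: str = "chr1",
    n_single_copy_families: int = 12,
    multi_copy_counts: Sequence[int] = (2, 3, 3, 3, 3, 4),
    n_genes: int = 25,
) -> tuple[Genome, list[TECopyAnnotation], list[tuple[str, int, int]]]:
    """Build a synthetic annotated reference genome.

    Single-copy TE families are long (1.2–2 kb) and uniquely mappable;
    multi-copy families are shorter (300–600 bp) with identical copies, so
    reads inside them multimap — the repetitive fraction that makes TE
    detection hard in real genomes.  Genes are plain labelled intervals
    used only for context classification.  Base composition is AT-rich
    (64%), as in plant genomes.
    """
    rng = _rng(seed)
    superfams = ["Copia", "Gypsy", "Mutator", "hAT", "EnSpm", "LINE", "Helitron"]

    def random_seq(n):
        return _dna.decode(
            rng.choice(4, size=n, p=[0.32, 0.18, 0.18, 0.32]).astype(np.uint8)
        )

    families = []  # (family, superfamily, seq, n_copies)
    fam_i = 0
    for _ in range(n_single_copy_families):
        sf = superfams[fam_i % len(superfams)]
        families.append(
            (f"{sf}{fam_i}", sf, random_seq(int(rng.integers(1200, 2001))), 1)
        )
        fam_i += 1
    for count in multi_copy_counts:
        sf = superfams[fam_i % len(superfams)]
        families.append(
            (f"{sf}{fam_i}", sf, random_seq(int(rng.integers(300, 601))), count)
        )
        fam_i += 1

    elements: list[tuple[str, int]] = []  # ("te", family index) | ("gene", length)
    for i, (_, _, _, count) in enumerate(families):
        elements += [("te", i)] * count
    for _ in range(n_genes):
        elements.append(("gene", int(rng.integers(1000, 2501))))
    order = rng.permutation(len(elements))
    elements = [elements[i] for i in order]

    total_el = 0
    for kind, val in elements:
        total_el += len(families[val][2]) if kind == "te" else val
    per_gap = max(600, (length - total_el) // (len(elements) + 1))

    parts: list[str] = []
    te_annot: list[TECopyAnnotation] = []
    genes: list[tuple[str, int, int]] = []
    copy_counter: dict[int, int] = {}
    pos = 0
    for kind, val in elements:
        gap = int(per_gap + rng.integers(-per_gap // 3, per_gap // 3 + 1))
        parts.append(random_seq(gap))
        pos += gap
        if kind == "te":
            fam, sf, seq, _ = families[val]
            j = copy_counter.get(val, 0)
            copy_counter[val] = j + 1
            te_annot.append(
                TECopyAnnotation(
                    chrom, pos, pos + len(seq), "+", f"{fam}_c{j}", fam, sf
                )
            )
            parts.append(seq)
            pos += len(seq)
        else:
            g = random_seq(val)
            genes.append((chrom, pos, pos + val))
            parts.append(g)
            pos += val
    tail = int(per_gap + rng.integers(-per_gap // 3, per_gap // 3 + 1))
    parts.append(random_seq(tail))
    genome = Genome({chrom: "".join(parts)})
    return genome, te_annot, genes


# ---------------------------------------------------------------------------
# Whole-dataset orchestration


@dataclass
class SimulatedDataset:
    reference: Genome
    te_annot: list[TECopyAnnotation]
    gene_annot: list[tuple[str, int, int]]
    mutant: Genome
    truths: list[InsertionTruth]
    reads: list[RawRead]
    origins: list[tuple[str, str, int, str]]
    model: MethylationModel
    params: dict


def simulate_dataset(
    seed: int,
    genome_length: int = 500_000,
    n_per_context: dict[str, int] | int = None,
    read_len: int = 100,
    coverage: float = 20.0,
    model: MethylationModel | None = None,
    n_snps_per_read: int = 0,
    error_rate: float = 0.0,
    reference=None,
    orientation: str = "+",
    min_gap: int = 300,
) -> SimulatedDataset:
    """Full simulation: reference, insertions, bisulfite reads, truth.

    Child seeds for reference construction, site choice, donor pairing and
    read generation are derived from ``seed`` so replicates differ only
    where they should.  Donors for TE-context sites are drawn from families
    other than the host copy's: an insertion into its own family would be
    removed by the same-family filter by construction and is a known blind
    spot, not a benchmark case.
    """
    ss = np.random.SeedSequence(seed).spawn(4)
    model = model or MethylationModel()
    if n_per_context is None:
        n_per_context = {"genic": 7, "intergenic": 7, "TE": 6}
    if reference is None:
        genome, te_annot, gene_annot = make_reference(
            np.random.default_rng(ss[0]), length=genome_length
        )
    else:
        genome, te_annot, gene_annot = reference
    sites = choose_insertion_sites(
        genome,
        te_annot,
        gene_annot,
        n_per_context,
        np.random.default_rng(ss[1]),
        end_margin=max(150, read_len + 50),
        min_gap=min_gap,
    )
    donors = extract_te_donors(genome, te_annot)
    rng_pair = np.random.default_rng(ss[2])
    host_family: dict[tuple[str, int], str] = {}
    for chrom, pos, lab in sites:
        if lab == "TE":
            for a in te_annot:
                if a.chrom == chrom and a.start <= pos < a.end:
                    host_family[(chrom, pos)] = a.family
                    break
    assignments = []
    for chrom, pos, lab in sites:
        host = host_family.get((chrom, pos))
        pool = [
            i
            for i, d in enumerate(donors)
            if (host is None or d.family != host) and len(d.seq) >= read_len + 50
        ]
        assignments.append(pool[int(rng_pair.integers(0, len(pool)))])
    mutant, truths = insert_tes(
        genome, donors, sites, seed=rng_pair, orientation=orientation,
        assignments=assignments,
    )
    reads, origins = simulate_bisulfite_reads(
        mutant,
        read_len=read_len,
        coverage=coverage,
        model=model,
        n_snps_per_read=n_snps_per_read,
        error_rate=error_rate,
        seed=np.random.default_rng(ss[3]),
    )
    params = {
        "seed": seed,
        "genome_length": genome_length,
        "n_per_context": dict(n_per_context)
        if isinstance(n_per_context, dict)
        else n_per_context,
        "read_len": read_len,
        "coverage": coverage,
        "p_mcg": model.p_mcg,
        "p_mchg": model.p_mchg,
        "p_mchh": model.p_mchh,
        "n_snps_per_read": n_snps_per_read,
        "error_rate": error_rate,
        "orientation": orientation,
    }
    return SimulatedDataset(
        genome, te_annot, gene_annot, mutant, truths, reads, origins, model, params
    )


# ---------------------------------------------------------------------------
# Truth table / manifest I/O

TRUTH_COLUMNS = [
    "chrom",
    "position",
    "copy_id",
    "family",
    "superfamily",
    "tsd_len",
    "tsd_seq",
    "context_label",
    "orientation",
]


def write_truth_table(truths: Sequence[InsertionTruth], path) -> None:
    rows = [
        {
            "chrom": t.chrom,
            "position": t.position,
            "copy_id": t.copy_id,
            "family": t.family,
            "superfamily": t.superfamily,
            "tsd_len": t.tsd_len,
            "tsd_seq": t.tsd_seq if t.tsd_seq else ".",
            "context_label": t.context_label,
            "orientation": t.orientation,
        }
        for t in truths
    ]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def load_truth_table(path) -> list[InsertionTruth]:
    df = pd.read_csv(path, sep="\t", dtype={"tsd_seq": str})
    return [
        InsertionTruth(
            chrom=r.chrom,
            position=int(r.position),
            copy_id=r.copy_id,
            family=r.family,
            superfamily=r.superfamily,
            tsd_len=int(r.tsd_len),
            tsd_seq="" if r.tsd_seq == "." else r.tsd_seq,
            context_label=r.context_label,
            orientation=r.orientation,
        )
        for _, r in df.iterrows()
    ]


def write_manifest(params: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True)
        fh.write("\n")
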