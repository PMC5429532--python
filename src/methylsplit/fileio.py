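"""Standard-format input/output: genomes, annotations, reads and report files.

Internal coordinates are 0-based half-open everywhere.  The insertion report
TSV uses 1-based inclusive positions (the convention of published insertion
tables); the BED output stays 0-based half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_VALID = set("ACGTN")


@dataclass
class Genome:
    """Named chromosome sequences, uppercase, alphabet {A,C,G,T,N}."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass(frozen=True)
class TECopyAnnotation:
    """One annotated TE copy: the universe of known TE edges."""

    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    copy_id: str
    family: str
    superfamily: str = ""

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(
                f"TE copy {self.copy_id}: start must be < end "
                f"({self.start} >= {self.end})"
            )


@dataclass(frozen=True)
class RawRead:
    read_id: str
    seq: str
    qual: str  # Phred scores, ASCII encoded

    def __post_init__(self):
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.read_id}: sequence and quality lengths differ"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _clean_sequence(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    if not set(s) <= _VALID:
        # IUPAC ambiguity codes degrade to N rather than aborting a run.
        s = "".join(c if c in _VALID else "N" for c in s)
    return s


def load_genome(path: str | os.PathLike) -> Genome:
    """Load a FASTA reference; sequences are uppercased and U→T normalised."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate sequence name in FASTA: {rec.id}")
        sequences[rec.id] = _clean_sequence(str(rec.seq))
    if not sequences:
        raise ValueError(f"no sequences found in FASTA file {path}")
    return Genome(sequences)


def write_fasta(genome: Genome, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# TE / gene annotations


def _parse_gff_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().strip(";").split(";"):
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
        elif " " in part:
            k, v = part.split(" ", 1)
        else:
            continue
        out[k.strip()] = v.strip().strip('"')
    return out


def load_te_annotation(
    path: str | os.PathLike, genome: Genome
) -> list[TECopyAnnotation]:
    """Load TE copies from GFF3 (1-based inclusive) or BED (0-based half-open).

    GFF3 attribute fields must carry ``ID`` (copy id) and ``family``;
    ``superfamily`` is optional.  BED files carry the same information in the
    name field as ``copy_id:family[:superfamily]``.
    """
    path = str(path)
    is_bed = path.endswith(".bed")
    annos: list[TECopyAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if is_bed:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else ""
                strand = fields[5] if len(fields) > 5 else "+"
                parts = name.split(":")
                if len(parts) < 2 or not parts[1]:
                    raise ValueError(
                        f"{path}:{lineno}: BED name field must be "
                        "'copy_id:family[:superfamily]'"
                    )
                copy_id, family = parts[0], parts[1]
                superfamily = parts[2] if len(parts) > 2 else ""
            else:
                if len(fields) < 9:
                    raise ValueError(f"{path}:{lineno}: not a GFF3 line")
                chrom = fields[0]
                start, end = int(fields[3]) - 1, int(fields[4])  # → half-open
                strand = fields[6]
                attrs = _parse_gff_attributes(fields[8])
                copy_id = attrs.get("ID") or attrs.get("Name") or ""
                family = attrs.get("family") or attrs.get("Family") or ""
                superfamily = attrs.get("superfamily", attrs.get("Superfamily", ""))
                if not copy_id:
                    raise ValueError(f"{path}:{lineno}: missing ID attribute")
                if not family:
                    raise ValueError(f"{path}:{lineno}: missing family attribute")
            if chrom not in genome:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom}")
            if start < 0 or end > len(genome.sequences[chrom]):
                raise ValueError(
                    f"{path}:{lineno}: interval [{start},{end}) out of bounds "
                    f"for {chrom}"
                )
            if copy_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate copy_id {copy_id}")
            seen.add(copy_id)
            annos.append(
                TECopyAnnotation(chrom, start, end, strand, copy_id, family, superfamily)
            )
    return annos


def write_te_annotation(
    annos: Sequence[TECopyAnnotation], path: str | os.PathLike
) -> None:
    """Write TE copies as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annos:
            attrs = f"ID={a.copy_id};family={a.family}"
            if a.superfamily:
                attrs += f";superfamily={a.superfamily}"
            fh.write(
                f"{a.chrom}\tmethylsplit\ttransposable_element\t{a.start + 1}\t"
                f"{a.end}\t.\t{a.strand}\t.\t{attrs}\n"
            )


def load_intervals(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    """Load plain intervals (e.g. gene spans) from BED or GFF3."""
    path = str(path)
    is_bed = path.endswith(".bed")
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if is_bed:
                out.append((f[0], int(f[1]), int(f[2])))
            else:
                out.append((f[0], int(f[3]) - 1, int(f[4])))
    return out


def write_intervals(
    intervals: Sequence[tuple[str, int, int]], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Reads


def read_fastq(path: str | os.PathLike) -> Iterator[RawRead]:
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield RawRead(title.split()[0], seq.upper(), qual)


def write_fastq(reads: Iterable[RawRead], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")


def read_unmapped_from_bam(path: str | os.PathLike) -> Iterator[RawRead]:
    """Unmapped reads from a SAM/BAM produced by an external bisulfite
    mapper — the alternative entry point into the split-read engine for
    users who ran their own full-length alignment."""
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            if not rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            seq = rec.query_sequence
            if not seq:
                continue
            if rec.query_qualities is not None:
                qual = "".join(chr(33 + q) for q in rec.query_qualities)
            else:
                qual = "I" * len(seq)
            yield RawRead(rec.query_name, seq.upper(), qual)


def preprocess_reads(
    reads: Iterable[RawRead],
    qual_cutoff: int = 30,
    max_n: int = 0,
    min_len: int = 25,
    phred_offset: int = 33,
) -> Iterator[RawRead]:
    """Quality/N/length filtering of raw reads.

    3′ bases are trimmed while their quality is below ``qual_cutoff``;
    trimmed reads with more than ``max_n`` N bases or shorter than
    ``min_len`` are discarded.  Adapter removal proper is assumed to have
    been done upstream.  Order of surviving reads is preserved.
    """
    for r in reads:
        end = len(r.seq)
        while end > 0 and ord(r.qual[end - 1]) - phred_offset < qual_cutoff:
            end -= 1
        seq, qual = r.seq[:end], r.qual[:end]
        if len(seq) < min_len:
            continue
        if seq.count("N") > max_n:
            continue
        if end == len(r.seq):
            yield r
        else:
            yield RawRead(r.read_id, seq, qual)


# ---------------------------------------------------------------------------
# Reports

INSERTION_COLUMNS = [
    "chrom",
    "position",  # 1-based first TSD base
    "tsd_seq",
    "tsd_start",  # 1-based inclusive
    "tsd_end",
    "family",
    "superfamily",
    "parental_copy",
    "support_5prime",
    "support_3prime",
    "te_orientation",
]

METHYLATION_COLUMNS = [
    "call_id",
    "side",
    "offset",
    "context",
    "methylated",
    "total",
]


def emit_reports(calls, meth, out_prefix: str | os.PathLike) -> dict[str, str]:
    """Write the insertion TSV, an insertion BED6 and the methylation TSV.

    ``calls`` are InsertionCall objects, ``meth`` CytosineCall objects; both
    are duck-typed on their public attributes so this module stays free of
    circular imports.
    """
    out_prefix = str(out_prefix)
    paths = {
        "insertions_tsv": out_prefix + ".insertions.tsv",
        "insertions_bed": out_prefix + ".insertions.bed",
        "methylation_tsv": out_prefix + ".methylation.tsv",
    }
    rows = []
    for c in calls:
        tsd_len = len(c.tsd_seq)
        rows.append(
            {
                "chrom": c.chrom,
                "position": c.position + 1,
                "tsd_seq": c.tsd_seq if tsd_len else ".",
                "tsd_start": c.tsd_interval[0] + 1 if tsd_len else 0,
                "tsd_end": c.tsd_interval[1] if tsd_len else 0,
                "family": c.family,
                "superfamily": c.superfamily or ".",
                "parental_copy": c.parental_copy,
                "support_5prime": c.support_5,
                "support_3prime": c.support_3,
                "te_orientation": c.te_orientation,
            }
        )
    pd.DataFrame(rows, columns=INSERTION_COLUMNS).to_csv(
        paths["insertions_tsv"], sep="\t", index=False
    )
    with open(paths["insertions_bed"], "w") as fh:
        for c in calls:
            name = f"{c.family}|{c.parental_copy}"
            score = c.support_5 + c.support_3
            strand = c.te_orientation if c.te_orientation in "+-" else "."
            fh.write(
                f"{c.chrom}\t{c.position}\t{c.position + 1}\t{name}\t{score}\t{strand}\n"
            )
    mrows = [
        {
            "call_id": m.call_id,
            "side": m.side,
            "offset": m.offset,
            "context": m.context,
            "methylated": m.methylated,
            "total": m.total,
        }
        for m in meth
    ]
    pd.DataFrame(mrows, columns=METHYLATION_COLUMNS).to_csv(
        paths["methylation_tsv"], sep="\t", index=False
    )
    return paths


def load_insertion_table(path: str | os.PathLike):
    """Re-load an insertion TSV as InsertionCall objects (lossless round trip)."""
    from .caller import InsertionCall  # local import avoids a cycle

    df = pd.read_csv(path, sep="\t", dtype={"tsd_seq": str})
    calls = []
    for _, row in df.iterrows():
        tsd_seq = "" if row.tsd_seq in (".", "nan") or pd.isna(row.tsd_seq) else row.tsd_seq
        if tsd_seq:
            tsd_interval = (int(row.tsd_start) - 1, int(row.tsd_end))
        else:
            p = int(row.position) - 1
            tsd_interval = (p, p)
        calls.append(
            InsertionCall(
                chrom=row.chrom,
                tsd_interval=tsd_interval,
                tsd_seq=tsd_seq,
                family=row.family,
                superfamily="" if row.superfamily == "." else row.superfamily,
                parental_copy=row.parental_copy,
                support_5=int(row.support_5prime),
                support_3=int(row.support_3prime),
                te_orientation=row.te_orientation,
            )
        )
    return calls


def load_methylation_table(path: str | os.PathLike):
    from .methylation import CytosineCall

    df = pd.read_csv(path, sep="\t")
    return [
        CytosineCall(
            call_id=row.call_id,
            side=row.side,
            offset=int(row.offset),
            context=row.context,
            methylated=int(row.methylated),
            total=int(row.total),
        )
        for _, row in df.iterrows()
    ]
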