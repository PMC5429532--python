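"""End-to-end detection pipeline: preprocess → map → split → call → report.

The stages form a funnel: reads that map full length feed the un-split
coverage track and the reference methylation pass; reads that fail to map
are the split-read engine's input; retained TE-junction reads are clustered
into insertion calls whose own reads then yield the methylation state of
the new allele.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import build_index, map_full_read
from .caller import InsertionCall, Rejection, call_insertions
from .evaluate import CoverageCheck, EvalResult, evaluate_calls, unsplit_coverage_check
from .fileio import (
    Genome,
    RawRead,
    TECopyAnnotation,
    emit_reports,
    load_genome,
    load_te_annotation,
    preprocess_reads,
    read_fastq,
)
from .methylation import (
    CytosineCall,
    MetaProfile,
    MethylAccumulator,
    metaprofile,
    methylation_at_insertion,
    parental_te_profile,
    reference_flank_profile,
)
from .splitread import SplitJunctionRead, filter_te_junctions, find_discordant_reads, locate_breakpoint

log = logging.getLogger("methylsplit")


@dataclass
class RunConfig:
    """Every tunable of the pipeline, serialised verbatim into the manifest."""

    # read preprocessing
    preprocess: bool = True
    qual_cutoff: int = 30
    max_n: int = 0
    min_len: int = 25
    phred_offset: int = 33
    # alignment
    seed_len: int = 13
    seed_len_short: int = 8
    max_mismatch: int = 2
    max_hits: int = 10
    # split-read engine
    end_len: int = 25
    min_split_len: int = 25
    edge_tol: int = 10
    # insertion calling
    cluster_window: int = 30
    min_support: int = 6
    max_tsd: int = 20
    max_gap: int = 10
    # methylation meta-profiles
    window: int = 10
    # coverage verification
    core: int = 5
    inner: int = 30
    flank: int = 80
    z_cutoff: float = -1.0
    # evaluation
    tolerance: int = 100
    seed: int = 0
    # debug report toggles
    debug_junctions: bool = False
    debug_clusters: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class DetectResult:
    calls: list[InsertionCall]
    call_members: dict[str, list[SplitJunctionRead]]
    rejections: list[Rejection]
    junction_reads: list[SplitJunctionRead]
    cytosine_calls: list[CytosineCall]
    profiles: list[MetaProfile]
    reference_cytosines: list[CytosineCall]
    parental_cytosines: list[CytosineCall]
    coverage_checks: list[CoverageCheck]
    coverage: dict[str, np.ndarray]
    accumulator: MethylAccumulator
    counts: dict[str, int]


def run_detect(
    genome: Genome,
    te_annot: Sequence[TECopyAnnotation],
    reads: Iterable[RawRead],
    config: RunConfig | None = None,
    reads_are_unmapped: bool = False,
) -> DetectResult:
    """Run the whole detection workflow in memory; deterministic given the
    inputs and configuration.

    With ``reads_are_unmapped`` the input is taken to be the unmapped-read
    pool of an external full-length bisulfite mapping (e.g. imported from
    SAM/BAM); the internal full-length pass is skipped, so the un-split
    coverage track and reference methylation views stay empty.
    """
    cfg = config or RunConfig()
    counts: dict[str, int] = {}

    reads = list(reads)
    counts["reads_input"] = len(reads)
    if cfg.preprocess:
        reads = list(
            preprocess_reads(
                reads,
                qual_cutoff=cfg.qual_cutoff,
                max_n=cfg.max_n,
                min_len=cfg.min_len,
                phred_offset=cfg.phred_offset,
            )
        )
    counts["reads_preprocessed"] = len(reads)
    log.info("preprocessing: %d of %d reads retained", len(reads), counts["reads_input"])

    index = build_index(genome, k=cfg.seed_len, k_short=cfg.seed_len_short)
    acc = MethylAccumulator(genome)
    cov = {c: np.zeros(n, dtype=np.int32) for c, n in genome.lengths.items()}
    n_mapped = n_multi = 0
    if reads_are_unmapped:
        unmapped = reads
    else:
        unmapped = []
        for read in reads:
            status, aln = map_full_read(read, index, max_mismatch=cfg.max_mismatch)
            if status == "mapped":
                n_mapped += 1
                s, e = aln.ref_interval
                cov[aln.chrom][s:e] += 1
                acc.add(aln)
            elif status == "multimapped":
                n_multi += 1
            else:
                unmapped.append(read)
    counts["reads_mapped_unique"] = n_mapped
    counts["reads_multimapped"] = n_multi
    counts["reads_unmapped"] = len(unmapped)
    log.info(
        "full-length mapping: %d unique, %d multimapped, %d unmapped",
        n_mapped, n_multi, len(unmapped),
    )

    discordant = find_discordant_reads(
        unmapped, index, end_len=cfg.end_len, max_mismatch=cfg.max_mismatch
    )
    counts["reads_discordant"] = len(discordant)
    tiers = []
    for cand in discordant:
        tier = locate_breakpoint(
            cand.read,
            index,
            min_split_len=cfg.min_split_len,
            max_mismatch=cfg.max_mismatch,
            prefix_hits=cand.prefix_hits,
            suffix_hits=cand.suffix_hits,
            end_len=cfg.end_len,
        )
        if tier:
            tiers.append(tier)
    counts["reads_breakpoint_found"] = len(tiers)
    junctions = filter_te_junctions(
        tiers,
        te_annot,
        index,
        edge_tol=cfg.edge_tol,
        max_mismatch=cfg.max_mismatch,
        min_split_len=cfg.min_split_len,
    )
    counts["reads_te_junction"] = len(junctions)
    log.info(
        "split engine: %d discordant, %d with breakpoint, %d TE-junction reads",
        len(discordant), len(tiers), len(junctions),
    )

    calls_members, rejections = call_insertions(
        junctions,
        genome,
        cluster_window=cfg.cluster_window,
        min_support=cfg.min_support,
        max_tsd=cfg.max_tsd,
        max_gap=cfg.max_gap,
    )
    calls = [c for c, _ in calls_members]
    members_by_id = {c.call_id: m for c, m in calls_members}
    counts["insertion_calls"] = len(calls)
    counts["clusters_rejected"] = len(rejections)
    log.info("caller: %d insertion calls, %d clusters rejected", len(calls), len(rejections))

    te_sequences = {a.copy_id: genome.fetch(a.chrom, a.start, a.end) for a in te_annot}
    cytosines: list[CytosineCall] = []
    for call in calls:
        cytosines += methylation_at_insertion(
            call, members_by_id[call.call_id], genome, te_sequences
        )
    profiles = metaprofile(cytosines, window=cfg.window)
    ref_cyt = reference_flank_profile(acc, calls)
    par_cyt = parental_te_profile(acc, calls, te_annot)

    checks = [
        unsplit_coverage_check(
            call, cov, core=cfg.core, flank=cfg.flank, inner=cfg.inner,
            z_cutoff=cfg.z_cutoff,
        )
        for call in calls
    ]

    return DetectResult(
        calls=calls,
        call_members=members_by_id,
        rejections=rejections,
        junction_reads=junctions,
        cytosine_calls=cytosines,
        profiles=profiles,
        reference_cytosines=ref_cyt,
        parental_cytosines=par_cyt,
        coverage_checks=checks,
        coverage=cov,
        accumulator=acc,
        counts=counts,
    )


def write_detect_outputs(
    result: DetectResult, out_prefix: str, config: RunConfig
) -> dict[str, str]:
    """Write the report files plus meta-profile, coverage-check and manifest."""
    paths = emit_reports(result.calls, result.cytosine_calls, out_prefix)
    prof_path = f"{out_prefix}.metaprofile.tsv"
    pd.DataFrame(
        [
            {
                "side": p.side,
                "context": p.context,
                "window_start": p.window_start,
                "mean_level": round(p.mean_level, 6),
                "ci_low": round(p.ci_low, 6) if p.ci_low == p.ci_low else "NA",
                "ci_high": round(p.ci_high, 6) if p.ci_high == p.ci_high else "NA",
                "n_elements": p.n_elements,
            }
            for p in result.profiles
        ],
        columns=["side", "context", "window_start", "mean_level", "ci_low", "ci_high", "n_elements"],
    ).to_csv(prof_path, sep="\t", index=False)
    paths["metaprofile_tsv"] = prof_path

    cov_path = f"{out_prefix}.coverage_checks.tsv"
    pd.DataFrame(
        [
            {
                "call_id": c.call_id,
                "site_cov": round(c.site_cov, 4),
                "bg_mean": round(c.bg_mean, 4),
                "bg_sd": round(c.bg_sd, 4),
                "z": round(c.z, 4) if c.z == c.z else "NA",
                "supported": c.supported,
                "reason": c.reason,
            }
            for c in result.coverage_checks
        ],
        columns=["call_id", "site_cov", "bg_mean", "bg_sd", "z", "supported", "reason"],
    ).to_csv(cov_path, sep="\t", index=False)
    paths["coverage_tsv"] = cov_path

    if config.debug_junctions:
        jpath = f"{out_prefix}.junctions.tsv"
        pd.DataFrame(
            [
                {
                    "read_id": j.read_id,
                    "chrom": j.flank_aln.chrom,
                    "junction_pos": j.junction_pos,
                    "junction_side": j.junction_side,
                    "breakpoint": j.breakpoint,
                    "family": j.family,
                    "te_end": j.te_end,
                    "te_edge_offset": j.te_edge_offset,
                    "genome_strand": j.genome_strand,
                    "te_copy_hits": ",".join(j.te_copy_hits),
                }
                for j in result.junction_reads
            ],
            columns=[
                "read_id", "chrom", "junction_pos", "junction_side",
                "breakpoint", "family", "te_end", "te_edge_offset",
                "genome_strand", "te_copy_hits",
            ],
        ).to_csv(jpath, sep="\t", index=False)
        paths["junctions_tsv"] = jpath
    if config.debug_clusters:
        rpath = f"{out_prefix}.rejections.tsv"
        pd.DataFrame(
            [
                {
                    "chrom": r.chrom,
                    "position": r.position,
                    "family": r.family,
                    "reason": r.reason,
                    "support_5prime": r.support_5,
                    "support_3prime": r.support_3,
                }
                for r in result.rejections
            ],
            columns=[
                "chrom", "position", "family", "reason",
                "support_5prime", "support_3prime",
            ],
        ).to_csv(rpath, sep="\t", index=False)
        paths["rejections_tsv"] = rpath

    manifest = {"config": config.to_dict(), "counts": result.counts}
    man_path = f"{out_prefix}.manifest.json"
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["manifest"] = man_path
    return paths


def detect_files(
    genome_path: str,
    te_path: str,
    reads_path: str,
    out_prefix: str,
    config: RunConfig | None = None,
) -> DetectResult:
    """File-based front end of run_detect (the ``detect`` subcommand)."""
    cfg = config or RunConfig()
    genome = load_genome(genome_path)
    te_annot = load_te_annotation(te_path, genome)
    result = run_detect(genome, te_annot, read_fastq(reads_path), cfg)
    write_detect_outputs(result, out_prefix, cfg)
    return result


def evaluate_detection(
    result: DetectResult, truths, tolerance: int = 100, match_family: bool = True
) -> EvalResult:
    return evaluate_calls(
        result.calls, truths, tolerance=tolerance, match_family=match_family
    )
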