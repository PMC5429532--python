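import math

import numpy as np
import pytest
from scipy import stats

from methylsplit.align import SegmentAlignment
from methylsplit.caller import InsertionCall
from methylsplit.fileio import Genome, TECopyAnnotation
from methylsplit.methylation import (
    CytosineCall,
    classify_context,
    flank_resolution,
    metaprofile,
    methylation_at_insertion,
)
from methylsplit.splitread import FIVE, THREE, SplitJunctionRead


class TestClassifyContext:
    @pytest.mark.parametrize(
        "seq,expected", [("CGA", "CG"), ("CAG", "CHG"), ("CAT", "CHH"), ("CCG", "CHG")]
    )
    def test_plus_strand_definitions(self, seq, expected):
        assert classify_context(seq, 0, "+") == expected

    @pytest.mark.parametrize(
        "seq,pos,expected",
        [("TCG", 2, "CG"), ("CTG", 2, "CHG"), ("ATG", 2, "CHH")],
    )
    def test_minus_strand_definitions(self, seq, pos, expected):
        assert classify_context(seq, pos, "-") == expected

    def test_truncated_context_is_none(self):
        assert classify_context("AC", 1, "+") is None
        assert classify_context("CA", 0, "+") is None  # CHx undecidable
        assert classify_context("GA", 0, "-") is None

    def test_non_cytosine_errors(self):
        with pytest.raises(ValueError, match="not C"):
            classify_context("AGT", 0, "+")


def test_flank_resolution_is_read_len_minus_split():
    assert flank_resolution(85, 25) == 60
    assert flank_resolution(100, 25) == 75


# ---------------------------------------------------------------------------
# methylation_at_insertion on a fully constructed toy insertion


def _toy_call():
    # Reference: flank with the TSD "AACCA" ending at p1=59; the C at
    # position 57 is followed by CA on the reference (CHH... actually CAG?)
    flank = (
        "ATATTATAGGATTAGATTATAGATTTAGGATTTAAGGATATTATAGGATTAGAACCA"  # 0..56
        + "AAC"  # 57..59: the junction base 59 is a cytosine
        + "TTAGGATTAGGATTAGGATTAGGATTAGGATTAGGATTAGGA"
    )
    # TE copy: starts GG..., so on the inserted allele the C at the last
    # flank position (offset 0) is followed by G → CG, not CHG.
    te = "G" + "GATTAGGATT" * 12
    chrom = flank[:60] + "T" * 40 + te + "T" * 40 + flank[60:]
    # TE copy annotated at [100, 100+len(te))
    genome = Genome({"chr1": chrom})
    copy = TECopyAnnotation("chr1", 100, 100 + len(te), "+", "TE_c0", "FAM", "Gypsy")
    # Insertion with TSD [55,60) = "ACCAC"; p1 = 59, p2 = 55
    call = InsertionCall(
        chrom="chr1",
        tsd_interval=(55, 60),
        tsd_seq=chrom[55:60],
        family="FAM",
        superfamily="Gypsy",
        parental_copy="TE_c0",
        support_5=1,
        support_3=1,
        te_orientation="+",
    )
    return genome, copy, call, chrom


def _member(read_id, side, flank_iv, te_iv, chrom, copy, meth=True):
    """One junction read whose halves are verbatim genome substrings
    (fully methylated) or fully converted copies."""
    fl_seq = chrom[flank_iv[0] : flank_iv[1]]
    te_seq = chrom[te_iv[0] : te_iv[1]]
    if not meth:
        fl_seq = fl_seq.replace("C", "T")
        te_seq = te_seq.replace("C", "T")
    flank = SegmentAlignment(read_id, (0, 40), "chr1", flank_iv, "top", 0, 1, fl_seq)
    te = SegmentAlignment(read_id, (40, 80), "chr1", te_iv, "top", 0, 1, te_seq)
    return SplitJunctionRead(
        read_id=read_id,
        breakpoint=40,
        flank_aln=flank,
        te_aln=te,
        te_copy_hits=("TE_c0",),
        te_ref_copy=copy,
        family="FAM",
        te_end=FIVE if side == FIVE else THREE,
        junction_side=side,
        junction_pos=flank_iv[1] - 1 if side == FIVE else flank_iv[0],
        genome_strand="top",
    )


class TestMethylationAtInsertion:
    def test_counts_and_reconstructed_context(self):
        genome, copy, call, chrom = _toy_call()
        te_seqs = {"TE_c0": chrom[copy.start : copy.end]}
        members = [
            _member("m1", FIVE, (20, 60), (100, 140), chrom, copy, meth=True),
            _member("m2", FIVE, (20, 60), (100, 140), chrom, copy, meth=True),
            _member("m3", FIVE, (20, 60), (100, 140), chrom, copy, meth=False),
        ]
        calls = {
            (c.side, c.offset, c.context): c
            for c in methylation_at_insertion(call, members, genome, te_seqs)
        }
        # The C at reference position 55 sits at flank5 offset p1−55 = 4:
        # two fully methylated reads and one fully converted read cover it.
        key = next(k for k in calls if k[0] == "flank5" and k[1] == 4)
        c = calls[key]
        assert (c.methylated, c.total) == (2, 3)

    def test_junction_spanning_context_uses_allele(self):
        genome, copy, call, chrom = _toy_call()
        te_seqs = {"TE_c0": chrom[copy.start : copy.end]}
        members = [_member("m1", FIVE, (20, 60), (100, 140), chrom, copy)]
        out = methylation_at_insertion(call, members, genome, te_seqs)
        # Last flank base (offset 0) is C at reference position 59 with
        # reference context C-T-T (CHH, from the empty locus), but the
        # inserted allele continues into the TE, which starts with G → CG.
        at0 = [c for c in out if c.side == "flank5" and c.offset == 0]
        assert [c.context for c in at0] == ["CG"]
        # reference says otherwise — proving the allele was used
        assert classify_context(chrom, 59, "+") != "CG"

    def test_count_conservation(self):
        genome, copy, call, chrom = _toy_call()
        te_seqs = {"TE_c0": chrom[copy.start : copy.end]}
        members = [
            _member("m1", FIVE, (20, 60), (100, 140), chrom, copy),
            _member("m2", THREE, (55, 95), (160, 200), chrom, copy),
        ]
        out = methylation_at_insertion(call, members, genome, te_seqs)
        total = sum(c.total for c in out)
        # every aligned base that is a cytosine on the allele with known
        # context and a C/T read base yields exactly one observation
        assert total > 0
        # no cell exceeds the number of members covering it
        assert all(c.total <= len(members) for c in out)


class TestMetaprofile:
    def test_no_variation_interval_stays_binomially_honest(self):
        # identical element levels collapse the across-element variance to
        # zero; the interval must not collapse with it — the pooled
        # binomial (Wilson) envelope keeps it calibrated
        calls = [
            CytosineCall(f"e{i}", "flank5", 3, "CG", 1, 2) for i in range(4)
        ]
        (p,) = metaprofile(calls)
        assert p.mean_level == 0.5
        assert p.ci_low < 0.5 < p.ci_high
        from scipy import stats as ss

        wlo, whi = ss.binomtest(4, 8).proportion_ci(0.95, method="wilson")
        assert p.ci_low == pytest.approx(float(wlo))
        assert p.ci_high == pytest.approx(float(whi))
        assert p.n_elements == 4

    def test_single_element_ci_undefined(self):
        (p,) = metaprofile([CytosineCall("e", "te5", 12, "CHH", 1, 4)])
        assert p.mean_level == 0.25
        assert math.isnan(p.ci_low) and math.isnan(p.ci_high)

    def test_t_interval_matches_direct_computation(self):
        levels = [0.2, 0.4, 0.6]
        calls = [
            CytosineCall(f"e{i}", "flank3", 5, "CG", int(10 * l), 10)
            for i, l in enumerate(levels)
        ]
        (p,) = metaprofile(calls)
        mean = np.mean(levels)
        se = np.std(levels, ddof=1) / np.sqrt(3)
        tcrit = stats.t.ppf(0.975, 2)
        wlo, whi = stats.binomtest(12, 30).proportion_ci(0.95, method="wilson")
        assert p.mean_level == pytest.approx(mean)
        assert p.ci_low == pytest.approx(max(0.0, min(mean - tcrit * se, float(wlo))))
        assert p.ci_high == pytest.approx(min(1.0, max(mean + tcrit * se, float(whi))))

    def test_windows_aggregate_offsets(self):
        calls = [
            CytosineCall("e1", "flank5", 1, "CG", 1, 1),
            CytosineCall("e1", "flank5", 9, "CG", 0, 1),
            CytosineCall("e1", "flank5", 11, "CG", 1, 1),
        ]
        profs = metaprofile(calls, window=10)
        assert [(p.window_start, p.mean_level) for p in profs] == [(0, 0.5), (10, 1.0)]


class TestPipelineMethylation:
    def test_offsets_within_resolution(self, small_run):
        ds, result = small_run
        max_off = flank_resolution(100, 25)
        for c in result.cytosine_calls:
            if c.side.startswith("flank"):
                assert 0 <= c.offset < max_off

    def test_exact_recovery_of_simulated_levels(self, small_run):
        """Error-free reads: aggregated flank CG levels across calls sit
        inside exact binomial 99.9% bounds of the simulated 20% rate."""
        _, result = small_run
        meth = total = 0
        for c in result.cytosine_calls:
            if c.side.startswith("flank") and c.context == "CG":
                meth += c.methylated
                total += c.total
        assert total > 200
        lo = stats.binom.ppf(0.0005, total, 0.20)
        hi = stats.binom.ppf(0.9995, total, 0.20)
        assert lo <= meth <= hi
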