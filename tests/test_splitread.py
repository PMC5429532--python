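import numpy as np
import pytest

from methylsplit import _dna
from methylsplit.align import build_index
from methylsplit.fileio import Genome, RawRead, TECopyAnnotation
from methylsplit.splitread import (
    filter_te_junctions,
    find_discordant_reads,
    locate_breakpoint,
    n_split_positions,
)

from _oracle import brute_best_splits


def test_candidate_split_count():
    assert n_split_positions(85, 25) == 36  # 85 − 2·25 + 1
    assert n_split_positions(50, 25) == 1
    assert n_split_positions(49, 25) == 0


def _toy(rng, n=6000):
    """Unique random genome with one annotated TE copy and a distant flank."""
    seq = _dna.decode(rng.integers(0, 4, n).astype(np.uint8))
    g = Genome({"chr1": seq})
    te = TECopyAnnotation("chr1", 4000, 4800, "+", "TE1_c0", "FAM1", "Gypsy")
    return g, te


class TestDiscordance:
    def test_distant_ends_are_candidates(self, rng):
        g, _ = self._gen(rng)
        seq = g.sequences["chr1"]
        read = RawRead("r", seq[100:150] + seq[5000:5050], "I" * 100)
        idx = build_index(g)
        cands = find_discordant_reads([read], idx)
        assert [c.read.read_id for c in cands] == ["r"]

    def test_concordant_ends_not_candidates(self, rng):
        g, _ = self._gen(rng)
        seq = g.sequences["chr1"]
        read = RawRead("r", seq[100:200], "I" * 100)  # contiguous fragment
        idx = build_index(g)
        assert find_discordant_reads([read], idx) == []

    def test_one_unmapped_end_not_candidate(self, rng):
        g, _ = self._gen(rng)
        seq = g.sequences["chr1"]
        junk = _dna.decode((np.arange(50) % 2).astype(np.uint8))  # ACAC... alien
        read = RawRead("r", junk + seq[5000:5050], "I" * 100)
        idx = build_index(g)
        assert find_discordant_reads([read], idx) == []

    def test_end_len_validated(self, rng):
        g, _ = self._gen(rng)
        idx = build_index(g)
        with pytest.raises(ValueError, match="end_len"):
            find_discordant_reads([], idx, end_len=20)

    @staticmethod
    def _gen(rng):
        return _toy(rng)


class TestLocateBreakpoint:
    def test_constructed_junction_and_bruteforce(self, rng):
        g, te = _toy(rng)
        seq = g.sequences["chr1"]
        # 40 bp of flank joined to 45 bp of TE 5' end, error free
        read = RawRead("r", seq[960:1000] + seq[4000:4045], "I" * 85)
        idx = build_index(g)
        tier = locate_breakpoint(read, idx)
        assert tier, "no split found"
        keys = {
            (c.breakpoint,
             c.left.chrom, c.left.ref_start, c.left.genome_strand,
             c.right.chrom, c.right.ref_start, c.right.genome_strand)
            for c in tier
        }
        assert (40, "chr1", 960, "top", "chr1", 4000, "top") in keys
        best, winners = brute_best_splits(read.seq, g.sequences, 25, 2)
        assert best == tier[0].total_mismatches
        assert keys == {(b, lc, ls, lst, rc_, rs, rst)
                        for b, lc, ls, lst, rc_, rs, rst, _, _ in winners}

    def test_bottom_strand_junction(self, rng):
        g, te = _toy(rng)
        seq = g.sequences["chr1"]
        fragment = seq[960:1000] + seq[4000:4045]
        read = RawRead("r", _dna.revcomp(fragment).replace("C", "T"), "I" * 85)
        idx = build_index(g)
        tier = locate_breakpoint(read, idx)
        keys = {
            (c.breakpoint, c.left.ref_start, c.left.genome_strand,
             c.right.ref_start, c.right.genome_strand)
            for c in tier
        }
        # reverse complement swaps half order: TE part first, breakpoint 45
        assert (45, 4000, "bottom", 960, "bottom") in keys

    def test_converted_junction_matches_bruteforce(self, rng):
        g, te = _toy(rng)
        seq = g.sequences["chr1"]
        fragment = (seq[960:1000] + seq[4000:4045]).replace("C", "T")
        read = RawRead("r", fragment, "I" * 85)
        idx = build_index(g)
        tier = locate_breakpoint(read, idx)
        best, winners = brute_best_splits(read.seq, g.sequences, 25, 2)
        got = {(c.breakpoint,
                c.left.chrom, c.left.ref_start, c.left.genome_strand,
                c.right.chrom, c.right.ref_start, c.right.genome_strand)
               for c in tier}
        assert got == {(b, lc, ls, lst, rc_, rs, rst)
                       for b, lc, ls, lst, rc_, rs, rst, _, _ in winners}

    def test_short_read_yields_nothing(self, rng):
        g, _ = _toy(rng)
        idx = build_index(g)
        read = RawRead("r", g.sequences["chr1"][0:49], "I" * 49)
        assert locate_breakpoint(read, idx) == []


class TestFilterTEJunctions:
    def _setup(self, rng):
        seq = _dna.decode(rng.integers(0, 4, 9000).astype(np.uint8))
        g = Genome({"chr1": seq})
        # family A: two identical copies; family B: one copy
        copyA = seq[4000:4500]
        seq = seq[:6000] + copyA + seq[6500:]
        g = Genome({"chr1": seq})
        annot = [
            TECopyAnnotation("chr1", 4000, 4500, "+", "A_c0", "FAMA", "Gypsy"),
            TECopyAnnotation("chr1", 6000, 6500, "+", "A_c1", "FAMA", "Gypsy"),
            TECopyAnnotation("chr1", 7500, 8200, "+", "B_c0", "FAMB", "hAT"),
        ]
        return g, annot

    def _junctions(self, g, annot, read):
        idx = build_index(g)
        tier = locate_breakpoint(read, idx)
        return filter_te_junctions([tier], annot, idx)

    def test_edge_split_retained_with_te_end(self, rng):
        g, annot = self._setup(rng)
        seq = g.sequences["chr1"]
        read = RawRead("r", seq[1000:1040] + seq[7500:7545], "I" * 85)
        out = self._junctions(g, annot, read)
        assert len(out) == 1
        j = out[0]
        assert j.te_end == "5prime" and j.junction_side == "5prime"
        assert j.junction_pos == 1039
        assert j.te_copy_hits == ("B_c0",)
        assert j.family == "FAMB"

    def test_same_family_read_discarded(self, rng):
        g, annot = self._setup(rng)
        seq = g.sequences["chr1"]
        # flank half inside copy A_c0 joined to the 5' edge of A_c1
        read = RawRead("r", seq[4200:4240] + seq[6000:6045], "I" * 85)
        assert self._junctions(g, annot, read) == []

    def test_no_edge_near_either_half_discarded(self, rng):
        g, annot = self._setup(rng)
        seq = g.sequences["chr1"]
        # second half lands mid-TE, 100 bp from the nearest terminus
        read = RawRead("r", seq[1000:1040] + seq[7600:7645], "I" * 85)
        assert self._junctions(g, annot, read) == []

    def test_te_three_prime_edge(self, rng):
        g, annot = self._setup(rng)
        seq = g.sequences["chr1"]
        read = RawRead("r", seq[8155:8200] + seq[2000:2040], "I" * 85)
        out = self._junctions(g, annot, read)
        assert len(out) == 1
        j = out[0]
        assert j.te_end == "3prime" and j.junction_side == "3prime"
        assert j.junction_pos == 2000

    def test_identical_copies_all_recorded(self, rng):
        g, annot = self._setup(rng)
        seq = g.sequences["chr1"]
        read = RawRead("r", seq[1000:1040] + seq[4000:4045], "I" * 85)
        out = self._junctions(g, annot, read)
        assert len(out) == 1
        assert out[0].te_copy_hits == ("A_c0", "A_c1")

    def test_min_split_invariant_on_pipeline_output(self, small_run):
        _, result = small_run
        for j in result.junction_reads:
            assert len(j.flank_aln) >= 25 and len(j.te_aln) >= 25
            l, r = sorted([j.flank_aln.read_interval, j.te_aln.read_interval])
            assert l[1] == r[0] == j.breakpoint and l[0] == 0
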