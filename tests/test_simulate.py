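import numpy as np
import pytest
from scipy import stats

from methylsplit import _dna
from methylsplit.fileio import Genome, TECopyAnnotation
from methylsplit.simulate import (
    MethylationModel,
    TEDonor,
    choose_insertion_sites,
    insert_tes,
    make_reference,
    simulate_bisulfite_reads,
    simulate_dataset,
)


def _random_genome(rng, n=20_000):
    return Genome({"chr1": _dna.decode(rng.integers(0, 4, n).astype(np.uint8))})


class TestChooseSites:
    def _annot(self):
        te = [TECopyAnnotation("chr1", 5000, 7000, "+", "t1", "F", "S")]
        genes = [("chr1", 10_000, 13_000)]
        return te, genes

    def test_counts_and_determinism(self, rng):
        g = _random_genome(rng)
        te, genes = self._annot()
        a = choose_insertion_sites(g, te, genes, 4, seed=11)
        b = choose_insertion_sites(g, te, genes, 4, seed=11)
        assert a == b
        labels = [lab for _, _, lab in a]
        assert labels.count("genic") == labels.count("TE") == 4
        for chrom, pos, lab in a:
            if lab == "genic":
                assert 10_000 <= pos < 13_000
            elif lab == "TE":
                assert 5000 <= pos < 7000

    def test_no_genic_context_errors(self, rng):
        g = _random_genome(rng)
        te, _ = self._annot()
        with pytest.raises(ValueError, match="genic"):
            choose_insertion_sites(g, te, [], 2, seed=0)

    def test_min_gap_respected(self, rng):
        g = _random_genome(rng)
        te, genes = self._annot()
        sites = choose_insertion_sites(g, te, genes, 3, seed=5, min_gap=400)
        pos = sorted(p for _, p, _ in sites)
        assert all(b - a >= 400 for a, b in zip(pos, pos[1:]))


class TestInsertTEs:
    def test_length_arithmetic(self, rng):
        g = _random_genome(rng, 1000)
        donor = TEDonor("d", "F", "Copia", "A" * 400)
        mutant, truths = insert_tes(g, [donor], [("chr1", 500, "intergenic")])
        assert mutant.lengths["chr1"] == 1405  # 1000 + 400 + TSD 5

    def test_tsd_duplicated_on_both_sides(self, rng):
        ref = _random_genome(rng, 2000).sequences["chr1"]
        ref = ref[:995] + "ACTTGC" + ref[1001:]  # TSD source ends at pos 1001
        g = Genome({"chr1": ref})
        donor = TEDonor("d", "F", "Gypsy", "GGATTTAGGA" * 30)
        mutant, truths = insert_tes(g, [donor], [("chr1", 1001, "genic")])
        t = truths[0]
        assert t.tsd_seq == "CTTGC"
        m = mutant.sequences["chr1"]
        ins = t.position
        te_len = 300
        assert m[ins : ins + te_len] == donor.seq
        assert m[ins - 5 : ins] == "CTTGC"  # left copy (pre-existing flank end)
        assert m[ins + te_len : ins + te_len + 5] == "CTTGC"  # duplicated copy

    def test_zero_tsd_helitron(self, rng):
        g = _random_genome(rng, 1000)
        donor = TEDonor("d", "F", "Helitron", "T" * 100)
        mutant, truths = insert_tes(g, [donor], [("chr1", 500, "TE")])
        assert truths[0].tsd_len == 0 and truths[0].tsd_seq == ""
        assert mutant.lengths["chr1"] == 1100

    def test_overlapping_sites_error(self, rng):
        g = _random_genome(rng, 1000)
        donor = TEDonor("d", "F", "Copia", "A" * 50)
        with pytest.raises(ValueError, match="overlapping"):
            insert_tes(
                g, [donor], [("chr1", 500, "genic"), ("chr1", 503, "genic")]
            )

    def test_truth_tsd_invariant_against_mutant(self):
        ds = simulate_dataset(
            99, genome_length=80_000, coverage=1,
            n_per_context={"genic": 2, "intergenic": 2, "TE": 2},
        )
        donors = {a.copy_id: ds.reference.fetch(a.chrom, a.start, a.end)
                  for a in ds.te_annot}
        offset = 0
        for t in sorted(ds.truths, key=lambda t: t.position):
            te = donors[t.copy_id]
            if t.orientation == "-":
                te = _dna.revcomp(te)
            m = ds.mutant.sequences[t.chrom]
            ins = t.position + offset
            assert m[ins : ins + len(te)] == te
            assert m[ins - t.tsd_len : ins] == t.tsd_seq
            assert m[ins + len(te) : ins + len(te) + t.tsd_len] == t.tsd_seq
            offset += len(te) + t.tsd_len


class TestBisulfiteReads:
    def test_fully_methylated_reads_equal_fragments(self, rng):
        g = _random_genome(rng, 5000)
        model = MethylationModel(1.0, 1.0, 1.0)
        reads, origins = simulate_bisulfite_reads(g, 60, 2.0, model, seed=3)
        seq = g.sequences["chr1"]
        for read, (_, chrom, start, strand) in zip(reads, origins):
            frag = seq[start : start + 60]
            if strand == "bottom":
                frag = _dna.revcomp(frag)
            assert read.seq == frag

    def test_full_conversion_removes_all_read_cytosines(self, rng):
        g = _random_genome(rng, 5000)
        model = MethylationModel(0.0, 0.0, 0.0)
        reads, origins = simulate_bisulfite_reads(g, 60, 2.0, model, seed=3)
        for read in reads:
            assert "C" not in read.seq  # every read-strand C emitted as T

    def test_strand_correct_conversion(self, rng):
        # a bottom-strand read only converts bottom-strand cytosines:
        # relative to the reverse complement of its origin, differences may
        # appear only where the top strand carries G
        g = _random_genome(rng, 5000)
        model = MethylationModel(0.5, 0.5, 0.5)
        reads, origins = simulate_bisulfite_reads(g, 60, 2.0, model, seed=4)
        seq = g.sequences["chr1"]
        checked = 0
        for read, (_, _, start, strand) in zip(reads, origins):
            if strand != "bottom":
                continue
            frag_rc = _dna.revcomp(seq[start : start + 60])
            for a, b in zip(frag_rc, read.seq):
                if a != b:
                    assert (a, b) == ("C", "T")
            checked += 1
        assert checked > 10

    def test_cg_retention_matches_binomial_model(self, rng):
        """Observed C retention at CG sites ≈ 20% within exact binomial
        99% bounds computed independently."""
        g = _random_genome(rng, 30_000)
        model = MethylationModel()  # 0.20 / 0.03 / 0.03
        reads, origins = simulate_bisulfite_reads(g, 80, 30.0, model, seed=5)
        seq = g.sequences["chr1"]
        ctx = _dna.context_codes_top(_dna.encode(seq))
        retained = total = 0
        for read, (_, _, start, strand) in zip(reads, origins):
            if strand != "top":
                continue
            for i, base in enumerate(read.seq):
                if ctx[start + i] == _dna.CTX_CG and seq[start + i] == "C":
                    total += 1
                    retained += base == "C"
        assert total > 10_000
        lo = stats.binom.ppf(0.005, total, 0.20)
        hi = stats.binom.ppf(0.995, total, 0.20)
        assert lo <= retained <= hi

    def test_snps_visible_and_never_mimic_conversion(self, rng):
        g = _random_genome(rng, 5000)
        model = MethylationModel(1.0, 1.0, 1.0)  # no conversion at all
        reads, origins = simulate_bisulfite_reads(
            g, 60, 2.0, model, n_snps_per_read=2, seed=6
        )
        seq = g.sequences["chr1"]
        for read, (_, _, start, strand) in zip(reads, origins):
            frag = seq[start : start + 60]
            if strand == "bottom":
                frag = _dna.revcomp(frag)
            diffs = [(a, b) for a, b in zip(frag, read.seq) if a != b]
            assert len(diffs) == 2
            assert ("C", "T") not in diffs

    def test_parameter_validation(self, rng):
        g = _random_genome(rng, 1000)
        with pytest.raises(ValueError):
            simulate_bisulfite_reads(g, 50, 0.0)
        with pytest.raises(ValueError):
            simulate_bisulfite_reads(g, 0, 5.0)


class TestMakeReference:
    def test_annotation_consistency(self, rng):
        genome, te, genes = make_reference(rng, length=150_000)
        n = genome.lengths["chr1"]
        ids = [a.copy_id for a in te]
        assert len(ids) == len(set(ids))
        for a in te:
            assert 0 <= a.start < a.end <= n
        fams = {}
        for a in te:
            fams.setdefault(a.family, []).append(
                genome.fetch(a.chrom, a.start, a.end)
            )
        for fam, seqs in fams.items():
            assert len({len(s) for s in seqs}) == 1
            assert len(set(seqs)) == 1  # copies of a family are identical
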