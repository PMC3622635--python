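import filecmp
import os

import pysam
import pytest

from interloc import simulate as sim
from interloc.sam_io import revcomp


@pytest.fixture()
def toy_ref():
    return sim.random_genome({"chrA": 10_000, "chrB": 10_000}, seed=5)


class TestForgeGenome:
    def test_unbalanced_splice_arithmetic(self, toy_ref):
        truth = [sim.TruthRecord("chrA", 1_000, "+", "chrB", 2_000, "+", "U")]
        g = sim.forge_genome(toy_ref, truth, min_residual=1)
        der = next(c for c in g.contigs if c.name.startswith("der"))
        seq = sim.materialize(der, toy_ref)
        # both junction-adjacent bases are retained: chrA[..1000] + chrB[2000..]
        assert seq == toy_ref["chrA"][:1_000] + toy_ref["chrB"][1_999:]
        assert len(der) == 1_000 + (10_000 - 2_000 + 1)
        (j,) = g.truth_junctions
        assert (j.chrom_a, j.flank_a, j.chrom_b, j.flank_b) \
            == ("chrA", 1_000, "chrB", 2_000)
        # leftover arms are kept as residual contigs
        res_names = {c.name for c in g.contigs} - {der.name}
        assert res_names == {"chrA_res1001", "chrB_res1"}

    def test_unbalanced_inverted_side(self, toy_ref):
        truth = [sim.TruthRecord("chrA", 1_000, "+", "chrB", 2_000, "-", "U")]
        g = sim.forge_genome(toy_ref, truth, min_residual=1)
        der = next(c for c in g.contigs if c.name.startswith("der"))
        seq = sim.materialize(der, toy_ref)
        assert seq == toy_ref["chrA"][:1_000] + revcomp(toy_ref["chrB"][:2_000])

    def test_balanced_exchange_conserves_sequence(self, toy_ref):
        truth = [sim.TruthRecord("chrA", 4_000, "+", "chrB", 6_001, "+", "B"),
                 sim.TruthRecord("chrB", 6_000, "+", "chrA", 4_001, "+", "B")]
        g = sim.forge_genome(toy_ref, truth)
        total = sum(len(c) for c in g.contigs)
        assert total == 20_000  # clean reciprocal: nothing gained or lost
        assert len(g.truth_junctions) == 2

    def test_balanced_with_duplication(self, toy_ref):
        # second-row chrB coordinate 1,000 beyond the first: duplicated bases
        truth = [sim.TruthRecord("chrA", 4_000, "+", "chrB", 6_000, "+", "B"),
                 sim.TruthRecord("chrB", 6_999, "+", "chrA", 4_001, "+", "B")]
        g = sim.forge_genome(toy_ref, truth)
        assert sum(len(c) for c in g.contigs) == 20_000 + 1_000

    def test_direct_insertion_moves_segment(self, toy_ref):
        truth = [sim.TruthRecord("chrA", 5_000, "+", "chrB", 2_000, "+", "II"),
                 sim.TruthRecord("chrB", 2_999, "+", "chrA", 5_001, "+", "II")]
        g = sim.forge_genome(toy_ref, truth)
        recip = next(c for c in g.contigs if "ins" in c.name)
        donor = next(c for c in g.contigs if "excised" in c.name)
        assert len(recip) == 10_000 + 1_000
        assert len(donor) == 10_000 - 1_000
        seq = sim.materialize(recip, toy_ref)
        assert seq[5_000:6_000] == toy_ref["chrB"][1_999:2_999]
        dseq = sim.materialize(donor, toy_ref)
        assert dseq == toy_ref["chrB"][:1_999] + toy_ref["chrB"][2_999:]
        assert len(g.truth_junctions) == 2  # the donor gap is intrachromosomal

    def test_inverted_insertion_reverse_complements(self, toy_ref):
        truth = [sim.TruthRecord("chrA", 2_000, "-", "chrB", 7_000, "+", "II"),
                 sim.TruthRecord("chrB", 7_001, "+", "chrA", 2_999, "-", "II")]
        g = sim.forge_genome(toy_ref, truth)
        recip = next(c for c in g.contigs if "ins" in c.name)
        seq = sim.materialize(recip, toy_ref)
        assert seq[7_000:8_000] == revcomp(toy_ref["chrA"][1_999:2_999])
        # physical adjacency pairs the recipient left flank with the segment
        # end, and the segment start with the recipient right flank
        j1, j2 = g.truth_junctions
        assert (j1.flank_a, j1.flank_b) == (7_000, 2_999)
        assert (j2.flank_a, j2.flank_b) == (2_000, 7_001)

    def test_empty_truth_is_identity(self, toy_ref):
        g = sim.forge_genome(toy_ref, [])
        assert {c.name for c in g.contigs} == {"chrA", "chrB"}
        for c in g.contigs:
            assert sim.materialize(c, toy_ref) == toy_ref[c.name]
        assert g.truth_junctions == []

    def test_overlapping_variants_rejected(self, toy_ref):
        truth = [sim.TruthRecord("chrA", 5_000, "+", "chrB", 2_000, "+", "U"),
                 sim.TruthRecord("chrA", 6_000, "+", "chrB", 8_000, "+", "U")]
        with pytest.raises(ValueError, match="overlap"):
            sim.forge_genome(toy_ref, truth)


class TestSimulateReads:
    def test_pair_count_matches_coverage(self, toy_ref, tmp_path):
        g = sim.forge_genome(toy_ref, [])
        cfg = sim.SimConfig(coverage=10, read_len=100, seed=1)
        res = sim.simulate_reads(g, toy_ref, cfg, str(tmp_path / "a.sam"))
        assert res.n_pairs == round(10 * 20_000 / 200)

    def test_error_free_reads_match_reference_exactly(self, toy_ref, tmp_path):
        truth = [sim.TruthRecord("chrA", 5_000, "+", "chrB", 2_000, "+", "U")]
        g = sim.forge_genome(toy_ref, truth, min_residual=1)
        cfg = sim.SimConfig(coverage=8, read_len=100, mut_rate=0.0,
                            base_error=0.0, seed=2)
        sam = str(tmp_path / "clean.sam")
        sim.simulate_reads(g, toy_ref, cfg, sam)
        n_plain = n_clipped = 0
        with pysam.AlignmentFile(sam) as af:
            for rec in af:
                ref = toy_ref[rec.reference_name]
                if rec.cigarstring == "100M":
                    n_plain += 1
                    assert rec.query_sequence \
                        == ref[rec.reference_start:rec.reference_start + 100]
                else:
                    n_clipped += 1
                    # aligned block matches the reference at the stated position
                    start, end = rec.query_alignment_start, rec.query_alignment_end
                    assert rec.query_sequence[start:end] \
                        == ref[rec.reference_start:rec.reference_start
                               + (end - start)]
        assert n_plain > 0 and n_clipped > 0

    def test_junction_reads_clip_at_planted_flank(self, toy_ref, tmp_path):
        truth = [sim.TruthRecord("chrA", 5_000, "+", "chrB", 2_000, "+", "U")]
        g = sim.forge_genome(toy_ref, truth, min_residual=1)
        cfg = sim.SimConfig(coverage=20, read_len=100, mut_rate=0.0,
                            base_error=0.0, seed=3)
        sam = str(tmp_path / "j.sam")
        sim.simulate_reads(g, toy_ref, cfg, sam)
        boundaries = set()
        with pysam.AlignmentFile(sam) as af:
            for rec in af:
                cig = rec.cigartuples
                if cig[0][0] == 4:   # leading soft clip: left boundary
                    boundaries.add((rec.reference_name, rec.reference_start + 1))
                if cig[-1][0] == 4:  # trailing soft clip: right boundary
                    boundaries.add((rec.reference_name, rec.reference_end))
        assert boundaries == {("chrA", 5_000), ("chrB", 2_000)}

    def test_same_seed_byte_identical(self, toy_ref, tmp_path):
        truth = [sim.TruthRecord("chrA", 5_000, "+", "chrB", 2_000, "+", "U")]
        g = sim.forge_genome(toy_ref, truth)
        cfg = sim.SimConfig(coverage=5, read_len=100, seed=7)
        a, b = str(tmp_path / "a.sam"), str(tmp_path / "b.sam")
        sim.simulate_reads(g, toy_ref, cfg, a, fastq_prefix=str(tmp_path / "fa"))
        sim.simulate_reads(g, toy_ref, cfg, b, fastq_prefix=str(tmp_path / "fb"))
        assert filecmp.cmp(a, b, shallow=False)
        assert filecmp.cmp(str(tmp_path / "fa_1.fastq"),
                           str(tmp_path / "fb_1.fastq"), shallow=False)

    def test_mutations_change_reads_but_not_truth(self, toy_ref, tmp_path):
        truth = [sim.TruthRecord("chrA", 5_000, "+", "chrB", 2_000, "+", "U")]
        g = sim.forge_genome(toy_ref, truth)
        cfg = sim.SimConfig(coverage=5, read_len=100, mut_rate=0.01,
                            indel_frac=0.15, seed=7)
        sam = str(tmp_path / "m.sam")
        res = sim.simulate_reads(g, toy_ref, cfg, sam)
        assert res.genome.truth_junctions == g.truth_junctions
        # indels appear in CIGAR strings
        with pysam.AlignmentFile(sam) as af:
            ops = {op for rec in af for op, _ in rec.cigartuples}
        assert ops & {1, 2}  # I and/or D present


class TestDownsample:
    def _sim(self, toy_ref, tmp_path):
        g = sim.forge_genome(toy_ref, [])
        cfg = sim.SimConfig(coverage=100, read_len=100, seed=4)
        sam = str(tmp_path / "full.sam")
        res = sim.simulate_reads(g, toy_ref, cfg, sam)
        return sam, res.n_pairs

    def test_rate_one_is_identity(self, toy_ref, tmp_path):
        sam, _ = self._sim(toy_ref, tmp_path)
        out = str(tmp_path / "ds.sam")
        sim.downsample(sam, out, 1.0, seed=1)
        assert filecmp.cmp(sam, out, shallow=False)

    def test_kept_fraction_within_binomial_bound(self, toy_ref, tmp_path):
        sam, n_pairs = self._sim(toy_ref, tmp_path)  # 10,000 pairs
        out = str(tmp_path / "half.sam")
        kept_records = sim.downsample(sam, out, 0.5, seed=1)
        kept_pairs = kept_records / 2
        sd = (n_pairs * 0.25) ** 0.5
        assert abs(kept_pairs - 0.5 * n_pairs) <= 3 * sd

    def test_mates_kept_atomically(self, toy_ref, tmp_path):
        sam, _ = self._sim(toy_ref, tmp_path)
        out = str(tmp_path / "q.sam")
        sim.downsample(sam, out, 0.3, seed=2)
        counts = {}
        with pysam.AlignmentFile(out) as af:
            for rec in af:
                counts[rec.query_name] = counts.get(rec.query_name, 0) + 1
        assert set(counts.values()) == {2}

    def test_nested_subsets_under_one_seed(self, toy_ref, tmp_path):
        sam, _ = self._sim(toy_ref, tmp_path)
        names = {}
        for rate in (0.5, 0.25, 0.1):
            out = str(tmp_path / f"r{rate}.sam")
            sim.downsample(sam, out, rate, seed=9)
            with pysam.AlignmentFile(out) as af:
                names[rate] = {rec.query_name for rec in af}
        assert names[0.1] <= names[0.25] <= names[0.5]

    def test_invalid_rate_rejected(self, toy_ref, tmp_path):
        sam, _ = self._sim(toy_ref, tmp_path)
        with pytest.raises(ValueError):
            sim.downsample(sam, str(tmp_path / "x.sam"), 0.0, seed=1)
        with pytest.raises(ValueError):
            sim.downsample(sam, str(tmp_path / "x.sam"), 1.5, seed=1)
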