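import numpy as np
import pytest

from interloc import pipeline as pl
from interloc import simulate as sim
from interloc.breakpoints import (BreakWindow, _mode, build_windows,
                                  call_breakpoints, harvest_clips,
                                  realign_clip)
from interloc.clustering import OrientationSignature, cluster_pairs
from interloc.evaluate import evaluate
from interloc.sam_io import InsertStats, SoftClip, revcomp

from helpers import mk_pair, mk_read

STATS = InsertStats(mean=400, stdev=80, k=3)  # L = 640
REF_LENGTHS = {"chr1": 1_000_000, "chr2": 1_000_000}


def _cluster(pos_i, strand_i, pos_j, strand_j, read_len=100):
    pairs = [mk_pair(f"q{n}", "chr1", p, strand_i, "chr2", q, strand_j)
             for n, (p, q) in enumerate(zip(pos_i, pos_j))]
    (c,) = cluster_pairs(pairs, STATS, min_pairs=1)
    return c


class TestBuildWindows:
    def test_forward_cluster_window_covers_span_and_beyond(self):
        # reads span [1000, 1300]: anchored at the outermost (leftmost) read,
        # extending L = 640 rightward across the junction side
        c = _cluster([1_000, 1_101, 1_201], "+", [5_000, 5_060, 5_120], "-")
        W, X = build_windows(c, STATS, REF_LENGTHS)
        assert (W.chrom, W.start, W.end, W.facing) == ("chr1", 1_000, 1_639, "right")

    def test_reverse_cluster_window_extends_left(self):
        # j reads at 5000..5120 (ends 5099..5219), junction to the left:
        # anchored at the rightmost aligned base 5219, extending 640 leftward
        c = _cluster([1_000, 1_101, 1_201], "+", [5_000, 5_060, 5_120], "-")
        W, X = build_windows(c, STATS, REF_LENGTHS)
        assert (X.chrom, X.start, X.end, X.facing) == ("chr2", 4_580, 5_219, "left")

    def test_window_truncated_at_chromosome_start(self):
        c = _cluster([900, 950], "+", [50, 80], "-")
        W, X = build_windows(c, STATS, REF_LENGTHS)
        assert X.start == 1
        assert X.end == 179  # rightmost aligned base of the j reads

    def test_window_truncated_at_chromosome_end(self):
        c = _cluster([900, 950], "+", [100, 130], "-")
        W, _ = build_windows(c, STATS, {"chr1": 1_200, "chr2": 1_000_000})
        assert W.end == 1_200


class TestHarvestClips:
    WINDOW = BreakWindow(chrom="chr1", start=1_301, end=1_940, side="i",
                         facing="right")

    def _read_with_clip(self, qname, pos, cigar):
        return mk_read(qname, "chr1", pos, cigar=cigar)

    def test_qualifying_clip_found(self):
        reads = [self._read_with_clip("a", 1_421, "80M20S")]  # boundary 1500
        clips = harvest_clips(self.WINDOW, reads, min_clip=20, max_clips=5)
        assert len(clips) == 1
        assert clips[0].boundary == 1_500

    def test_cap_at_max_clips(self):
        reads = [self._read_with_clip(f"r{n}", 1_400 + n, "80M20S")
                 for n in range(9)]
        clips = harvest_clips(self.WINDOW, reads, min_clip=20, max_clips=5)
        assert len(clips) == 5
        assert [c.boundary for c in clips] == [1_479 + n for n in range(5)]

    def test_clip_facing_away_excluded(self):
        reads = [self._read_with_clip("a", 1_400, "20S80M")]  # left clip
        assert harvest_clips(self.WINDOW, reads, min_clip=20, max_clips=5) == []

    def test_boundary_outside_window_excluded(self):
        reads = [self._read_with_clip("a", 2_000, "80M20S")]  # boundary 2079
        assert harvest_clips(self.WINDOW, reads, min_clip=20, max_clips=5) == []


class TestRealignClip:
    def setup_method(self):
        rng = np.random.default_rng(33)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        self.window_seq = rng.choice(bases, size=640).tobytes().decode()
        self.window = BreakWindow(chrom="chr2", start=10_001, end=10_640,
                                  side="j", facing="left")
        self.rng = rng

    def _clip(self, seq):
        read = mk_read("c", "chr1", 500, cigar=f"80M{len(seq)}S",
                       seq="A" * 80 + seq)
        return SoftClip(read, "right", seq, len(seq), 579)

    def test_exact_substring_places_at_planted_offset(self):
        clip = self._clip(self.window_seq[100:130])
        sig = OrientationSignature("+", "-")  # opposite strands: no flip
        hit = realign_clip(clip, self.window, self.window_seq, sig, 0.1)
        assert hit is not None
        assert hit.edit_distance == 0
        # left-facing target: junction-adjacent terminus is the placement start
        assert hit.target_pos == 10_101

    def test_opposite_orientation_requires_revcomp(self):
        clip = self._clip(revcomp(self.window_seq[200:240]))
        same = OrientationSignature("+", "+")   # same strands: flip demanded
        oppo = OrientationSignature("+", "-")
        hit = realign_clip(clip, self.window, self.window_seq, same, 0.1)
        miss = realign_clip(clip, self.window, self.window_seq, oppo, 0.1)
        assert hit is not None and hit.edit_distance == 0
        assert hit.target_strand == "-"
        assert miss is None

    def test_monte_carlo_null_rate_below_one_percent(self):
        """A random 20-mer almost never places in an unrelated 640 bp window."""
        bases = np.frombuffer(b"ACGT", dtype="S1")
        sig = OrientationSignature("+", "-")
        hits = 0
        trials = 1_000
        for _ in range(trials):
            wseq = self.rng.choice(bases, size=640).tobytes().decode()
            clip = self._clip(self.rng.choice(bases, size=20).tobytes().decode())
            if realign_clip(clip, self.window, wseq, sig, 0.1) is not None:
                hits += 1
        assert hits / trials < 0.01


class TestCallBreakpoints:
    def test_mode_and_tie_break(self):
        assert _mode([1_940, 1_940, 1_940, 1_939]) == (1_940, 3)
        assert _mode([1_940, 1_939]) == (1_939, 1)  # tie -> smallest
        assert _mode([]) == (None, 0)

    def _setup(self):
        c = _cluster([1_000, 1_101, 1_201], "+", [5_000, 5_060, 5_120], "-")
        W, X = build_windows(c, STATS, REF_LENGTHS)
        read_w = mk_read("w", "chr1", 1_281, cigar="60M40S",
                         seq="A" * 100)
        clip_w = SoftClip(read_w, "right", "A" * 40, 40, 1_340)
        return c, W, X, clip_w

    def test_no_realignment_no_call(self):
        c, W, X, clip_w = self._setup()
        assert call_breakpoints(c, W, X, [clip_w], [], [], []) is None

    def test_one_sided_evidence_supports_call(self):
        from interloc.breakpoints import RealignedClip
        c, W, X, clip_w = self._setup()
        hit = RealignedClip(source=clip_w, target_chrom="chr2",
                            target_pos=4_990, target_strand="+",
                            edit_distance=0)
        call = call_breakpoints(c, W, X, [clip_w], [], [hit], [])
        assert call is not None
        assert call.bkpt_i == 1_340          # the W clip boundary
        assert call.bkpt_j == 4_990          # imputed from the realigned clip
        assert (call.n_clips_i, call.n_clips_j) == (1, 0)
        assert W.start <= call.bkpt_i <= W.end
        assert X.start <= call.bkpt_j <= X.end


def test_exact_breakpoints_on_clean_data(small_clean_run):
    """Error-free reads recover the planted junction exactly (ABE = 0)."""
    run = small_clean_run
    result = pl.call_variants(run["sam"], run["fasta"], pl.CallerConfig())
    assert len(result.calls) == 1
    call = result.calls[0]
    junction = run["genome"].truth_junctions[0]
    assert call.bkpt(junction.chrom_a) == junction.flank_a == 30_000
    assert call.bkpt(junction.chrom_b) == junction.flank_b == 20_000
    res = evaluate(result.calls, run["genome"].truth_junctions,
                   match_tol=result.stats.L)
    assert res.abe == 0.0
    # the call criterion: at least one realigned clip supports every call
    assert call.n_clips_i + call.n_clips_j >= 1


def test_inverted_fusion_resolved(tmp_path):
    """A fusion joining opposite strands is resolved via revcomp realignment."""
    ref = sim.random_genome({"chrA": 60_000, "chrB": 60_000}, seed=13)
    truth = [sim.TruthRecord("chrA", 30_000, "+", "chrB", 20_000, "-", "U")]
    genome = sim.forge_genome(ref, truth)
    config = sim.SimConfig(coverage=30, read_len=100, mut_rate=0.0,
                           base_error=0.0, seed=8)
    sam = str(tmp_path / "inv.sam")
    fasta = str(tmp_path / "ref.fa")
    sim.simulate_reads(genome, ref, config, sam_path=sam)
    from interloc.sam_io import write_fasta
    write_fasta(ref, fasta)
    result = pl.call_variants(sam, fasta, pl.CallerConfig())
    assert len(result.calls) == 1
    call = result.calls[0]
    assert call.strand_i == call.strand_j  # same-strand mapping signature
    assert call.bkpt("chrA") == 30_000
    assert call.bkpt("chrB") == 20_000
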