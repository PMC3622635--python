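import os

import pytest

from interloc import pipeline as pl
from interloc import simulate as sim
from interloc.evaluate import evaluate
from interloc.sam_io import write_fasta

SEED = 1


class StudyRun:
    """One simulated study: genome, truth, alignments and caller output."""

    def __init__(self, workdir, preset, seed=SEED):
        self.dir = str(workdir)
        self.ref, self.truth, self.config = sim.dataset_preset(preset, seed=seed)
        self.genome = sim.forge_genome(self.ref, self.truth)
        self.sam = os.path.join(self.dir, "sim.sam")
        self.fasta = os.path.join(self.dir, "ref.fa")
        self.sim_result = sim.simulate_reads(self.genome, self.ref, self.config,
                                             sam_path=self.sam)
        write_fasta(self.ref, self.fasta)
        self.caller = pl.call_variants(
            self.sam, self.fasta,
            pl.CallerConfig(recip_tol=sim.DATASET_RECIP_TOL),
        )
        self.eval = evaluate(self.caller.calls, self.genome.truth_junctions,
                             match_tol=self.caller.stats.L)


@pytest.fixture(scope="session")
def ds1_run(tmp_path_factory):
    """Full-coverage run of the bundled 100 bp-read study (12 events)."""
    return StudyRun(tmp_path_factory.mktemp("ds1"), preset=1)


@pytest.fixture(scope="session")
def ds2_run(tmp_path_factory):
    """Full-coverage run of the bundled 75 bp-read study (9 events)."""
    return StudyRun(tmp_path_factory.mktemp("ds2"), preset=2)


@pytest.fixture(scope="session")
def small_clean_run(tmp_path_factory):
    """Error-free single-fusion simulation for exact-recovery checks."""
    d = tmp_path_factory.mktemp("clean")
    ref = sim.random_genome({"chrA": 60_000, "chrB": 60_000}, seed=11)
    truth = [sim.TruthRecord("chrA", 30_000, "+", "chrB", 20_000, "+", "U")]
    genome = sim.forge_genome(ref, truth)
    config = sim.SimConfig(coverage=30, read_len=100, mut_rate=0.0,
                           base_error=0.0, seed=5)
    sam = os.path.join(str(d), "sim.sam")
    fasta = os.path.join(str(d), "ref.fa")
    res = sim.simulate_reads(genome, ref, config, sam_path=sam)
    write_fasta(ref, fasta)
    return {"ref": ref, "truth": truth, "genome": genome, "config": config,
            "sam": sam, "fasta": fasta, "result": res, "dir": str(d)}
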