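"""Hand-built alignment/call factories and independent checkers shared by tests."""

from __future__ import annotations

import itertools

import numpy as np

from interloc.breakpoints import BreakpointCall
from interloc.clustering import ChimericPair, OrientationSignature
from interloc.sam_io import AlignedRead


def mk_read(qname, chrom, pos, strand="+", cigar="100M", seq=None,
            mate_chrom="*", mate_pos=0, mate_strand="+", mapq=60, tlen=0):
    """Construct a synthetic AlignedRead with a consistent sequence length."""
    ops = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    qlen = sum(n for op, n in ops if op in "MIS=X")
    if seq is None:
        seq = "A" * qlen
    flag = 0x1
    if strand == "-":
        flag |= 0x10
    if mate_strand == "-":
        flag |= 0x20
    return AlignedRead(qname=qname, flag=flag, chrom=chrom, pos=pos, mapq=mapq,
                       cigar=ops, mate_chrom=mate_chrom, mate_pos=mate_pos,
                       tlen=tlen, seq=seq)


def mk_pair(qname, chrom_i, pos_i, strand_i, chrom_j, pos_j, strand_j):
    ri = mk_read(qname, chrom_i, pos_i, strand_i, mate_chrom=chrom_j,
                 mate_pos=pos_j, mate_strand=strand_j)
    rj = mk_read(qname, chrom_j, pos_j, strand_j, mate_chrom=chrom_i,
                 mate_pos=pos_i, mate_strand=strand_i)
    return ChimericPair(ri, rj)


def mk_call(chrom_i, bkpt_i, strand_i, chrom_j, bkpt_j, strand_j, n_pairs=10):
    return BreakpointCall(
        chrom_i=chrom_i, bkpt_i=bkpt_i, chrom_j=chrom_j, bkpt_j=bkpt_j,
        orientation=OrientationSignature(strand_i, strand_j),
        n_pairs=n_pairs, n_clips_i=2, n_clips_j=2,
        mode_support_i=2, mode_support_j=2,
    )


def random_pairs(rng: np.random.Generator, n: int, n_loci: int = 4,
                 spread: int = 50_000) -> list[ChimericPair]:
    """Random chimeric pairs scattered over a few strata and loci."""
    pairs = []
    for q in range(n):
        ci, cj = "chrA", "chrB"
        si = "+" if rng.random() < 0.5 else "-"
        sj = "+" if rng.random() < 0.5 else "-"
        locus = int(rng.integers(n_loci))
        pi = 1 + locus * spread + int(rng.integers(2_000))
        pj = 1 + locus * spread + int(rng.integers(2_000))
        pairs.append(mk_pair(f"q{q}", ci, pi, si, cj, pj, sj))
    return pairs


def check_cluster_validity(clusters, L, min_pairs):
    """Exhaustive predicate check of the clustering contract.

    Verifies per-cluster cohesion (span <= L on both sides, uniform strands,
    one chromosome pair), the partition property (each input pair lands in at
    most one cluster; leftovers are exactly the sub-minimum groups), and
    pairwise maximality (no two clusters in one stratum could be merged
    without violating cohesion).
    """
    seen = {}
    for c in clusters:
        assert len(c.reads_i) == len(c.reads_j) >= min_pairs
        assert len({r.chrom for r in c.reads_i}) == 1
        assert len({r.strand for r in c.reads_i}) == 1
        assert len({r.strand for r in c.reads_j}) == 1
        assert max(r.pos for r in c.reads_i) - min(r.pos for r in c.reads_i) <= L
        assert max(r.pos for r in c.reads_j) - min(r.pos for r in c.reads_j) <= L
        for r in c.reads_i:
            assert r.qname not in seen, "pair assigned to two clusters"
            seen[r.qname] = c
    for a, b in itertools.combinations(clusters, 2):
        key_a = (a.chrom_i, a.chrom_j, a.strand_i, a.strand_j)
        key_b = (b.chrom_i, b.chrom_j, b.strand_i, b.strand_j)
        if key_a != key_b:
            continue
        pos_i = [r.pos for r in a.reads_i + b.reads_i]
        pos_j = [r.pos for r in a.reads_j + b.reads_j]
        merged_ok = (max(pos_i) - min(pos_i) <= L
                     and max(pos_j) - min(pos_j) <= L)
        assert not merged_ok, "two clusters could be merged within L"


def brute_force_match_count(calls, truth, tol):
    """Exhaustive maximum bipartite matching size (for small instances)."""
    def feasible(c, t):
        if {c.chrom_i, c.chrom_j} != {t.chrom_a, t.chrom_b}:
            return False
        return (abs(c.bkpt(t.chrom_a) - t.flank_a) <= tol
                and abs(c.bkpt(t.chrom_b) - t.flank_b) <= tol)

    n = min(len(calls), len(truth))
    for k in range(n, 0, -1):
        for t_sub in itertools.combinations(range(len(truth)), k):
            for c_perm in itertools.permutations(range(len(calls)), k):
                if all(feasible(calls[c], truth[t])
                       for t, c in zip(t_sub, c_perm)):
                    return k
    return 0
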