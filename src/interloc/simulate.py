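"""Synthetic rearranged genomes and wgsim-style paired-end read simulation.

A truth table of interchromosomal variants (unbalanced ``U``, balanced ``B``
and interchromosomal-insertion ``II`` rows) is spliced into a reference to
produce derived contigs, each represented as an ordered list of oriented
reference pieces. Paired-end fragments are then drawn from the derived
genome under a two-layer wgsim-like model: haplotype mutations (SNVs and
short indels) are planted on the derived sequence first, then per-base
sequencing errors are applied to the reads.

Because every read's derived coordinates map deterministically back to the
reference through the piece lists, the simulator emits a *truth* SAM in
original reference coordinates: a read crossing a junction aligns its longer
segment and soft-clips the remainder, exactly the signal a read aligner
would produce at a rearrangement breakpoint, and mates on opposite junction
sides become chimeric pairs. The physical junction map (reference flank
bases adjacent to each derived junction) is the ground truth used by the
evaluator.
"""

from __future__ import annotations

import zlib
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import numpy as np

from .sam_io import revcomp, write_fasta

TRUTH_COLUMNS = ["Chr1", "Bkpt1", "Strand1", "Chr2", "Bkpt2", "Strand2", "Type"]

#: colinear gaps up to this size are expressed as CIGAR D (deletion) rather
#: than a split alignment, mirroring short-read aligner behaviour
MAX_SMALL_GAP = 100


@dataclass(frozen=True)
class TruthRecord:
    """One planted variant row (Chr1/Bkpt1/Strand1/Chr2/Bkpt2/Strand2/Type).

    A breakpoint coordinate is the junction-adjacent *retained* reference
    base on its side. ``B`` and ``II`` rows come in consecutive partnered
    pairs.
    """

    chr1: str
    bkpt1: int
    strand1: str
    chr2: str
    bkpt2: int
    strand2: str
    type: str

    def __post_init__(self) -> None:
        if self.type not in ("U", "B", "II"):
            raise ValueError(f"unknown variant type {self.type!r}")
        if self.chr1 == self.chr2:
            raise ValueError("variant rows must join two different chromosomes")


@dataclass(frozen=True)
class RefPiece:
    """A contiguous oriented slice of a reference chromosome (1-based incl.)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class InsPiece:
    """Novel inserted bases (haplotype insertion)."""

    seq: str

    def __len__(self) -> int:
        return len(self.seq)


Piece = Union[RefPiece, InsPiece]


@dataclass
class DerivedContig:
    name: str
    pieces: list[Piece]

    def __len__(self) -> int:
        return sum(len(p) for p in self.pieces)


@dataclass(frozen=True)
class JunctionTruth:
    """Physical adjacency created by a splice, in reference coordinates.

    ``flank_a``/``flank_b`` are the junction-adjacent retained bases of the
    left and right pieces of the derived contig at this junction.
    """

    contig: str
    chrom_a: str
    flank_a: int
    strand_a: str
    chrom_b: str
    flank_b: int
    strand_b: str
    kind: str  # U | B | II | donor-gap
    event_id: int

    @property
    def interchromosomal(self) -> bool:
        return self.chrom_a != self.chrom_b


@dataclass
class DerivedGenome:
    contigs: list[DerivedContig]
    junctions: list[JunctionTruth]
    ref_lengths: dict[str, int]
    truth: list[TruthRecord]

    @property
    def truth_junctions(self) -> list[JunctionTruth]:
        """Interchromosomal junctions: the detection ground truth."""
        return [j for j in self.junctions if j.interchromosomal]


@dataclass
class SimConfig:
    """wgsim-style simulation settings."""

    coverage: float = 40.0
    read_len: int = 100
    insert_mean: float = 400.0
    insert_stdev: float = 80.0
    mut_rate: float = 0.001
    indel_frac: float = 0.15
    indel_extend: float = 0.3
    base_error: float = 0.02
    seed: int = 1

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.insert_mean <= 2 * self.read_len:
            raise ValueError("insert mean must exceed twice the read length")
        for name in ("mut_rate", "indel_frac", "base_error"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


# ---------------------------------------------------------------------------
# truth-table I/O
# ---------------------------------------------------------------------------

def read_truth_table(path: str) -> list[TruthRecord]:
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TRUTH_COLUMNS:
            raise ValueError(f"unexpected truth table header: {header}")
        for line in fh:
            if not line.strip():
                continue
            c1, b1, s1, c2, b2, s2, t = line.rstrip("\n").split("\t")
            rows.append(TruthRecord(c1, int(b1), s1, c2, int(b2), s2, t))
    return rows


def write_truth_table(rows: Iterable[TruthRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for r in rows:
            fh.write(f"{r.chr1}\t{r.bkpt1}\t{r.strand1}\t{r.chr2}\t{r.bkpt2}\t"
                     f"{r.strand2}\t{r.type}\n")


def read_truth_bedpe(path: str) -> list[JunctionTruth]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            ca, _, ea, cb, _, eb, name, _, sa, sb = line.rstrip("\n").split("\t")
            kind, event_id = name.split("_")[:2]
            out.append(JunctionTruth("", ca, int(ea), sa, cb, int(eb), sb,
                                     kind, int(event_id)))
    return out


def write_truth_bedpe(junctions: Iterable[JunctionTruth], path: str) -> None:
    """Junction map as BEDPE (0-based half-open, one row per junction)."""
    with open(path, "w") as fh:
        for n, j in enumerate(junctions):
            fh.write(f"{j.chrom_a}\t{j.flank_a - 1}\t{j.flank_a}\t"
                     f"{j.chrom_b}\t{j.flank_b - 1}\t{j.flank_b}\t"
                     f"{j.kind}_{j.event_id}_{n}\t.\t{j.strand_a}\t{j.strand_b}\n")


# ---------------------------------------------------------------------------
# genome forging
# ---------------------------------------------------------------------------

class _UsedIntervals:
    """Per-chromosome bookkeeping of spliced intervals (overlap detection)."""

    def __init__(self) -> None:
        self._used: dict[str, list[tuple[int, int]]] = {}

    def add(self, chrom: str, start: int, end: int) -> None:
        ivs = self._used.setdefault(chrom, [])
        for s, e in ivs:
            if start <= e and s <= end:
                raise ValueError(
                    f"overlapping variants on {chrom}: [{s},{e}] and [{start},{end}]"
                )
        ivs.append((start, end))

    def residuals(self, chrom: str, length: int) -> list[tuple[int, int]]:
        ivs = sorted(self._used.get(chrom, []))
        out, cursor = [], 1
        for s, e in ivs:
            if s > cursor:
                out.append((cursor, s - 1))
            cursor = max(cursor, e + 1)
        if cursor <= length:
            out.append((cursor, length))
        return out


def _left_piece(chrom: str, bkpt: int, strand: str, length: int) -> RefPiece:
    """Piece ending (derived order) at junction-adjacent base ``bkpt``."""
    if strand == "+":
        return RefPiece(chrom, 1, bkpt, "+")
    return RefPiece(chrom, bkpt, length, "-")


def _right_piece(chrom: str, bkpt: int, strand: str, length: int) -> RefPiece:
    """Piece starting (derived order) at junction-adjacent base ``bkpt``."""
    if strand == "+":
        return RefPiece(chrom, bkpt, length, "+")
    return RefPiece(chrom, 1, bkpt, "-")


def forge_genome(
    ref: dict[str, str],
    truth: list[TruthRecord],
    min_residual: int = 5_000,
) -> DerivedGenome:
    """Splice truth-table variants into a reference.

    ``U`` rows fuse a prefix/suffix of two chromosomes; ``B`` row pairs build
    the two reciprocal derivatives (a duplicated stretch at the exchange
    point is expressed by the table coordinates themselves); ``II`` row pairs
    excise the donor segment and insert it (reverse-complemented for an
    inverted insertion) at the recipient site. Leftover chromosome arms and
    untouched chromosomes are emitted as residual contigs so reference
    coverage stays uniform. Overlapping variants on one chromosome are an
    error.
    """
    lengths = {c: len(s) for c, s in ref.items()}
    for r in truth:
        for c, b in ((r.chr1, r.bkpt1), (r.chr2, r.bkpt2)):
            if c not in lengths:
                raise KeyError(f"truth chromosome {c} not in reference")
            if not 1 <= b <= lengths[c]:
                raise ValueError(f"breakpoint {c}:{b} outside chromosome")

    used = _UsedIntervals()
    contigs: list[DerivedContig] = []
    junctions: list[JunctionTruth] = []
    event_id = 0

    def add_junction(contig: str, a: RefPiece, b: RefPiece, kind: str) -> None:
        flank_a = a.end if a.strand == "+" else a.start
        flank_b = b.start if b.strand == "+" else b.end
        junctions.append(JunctionTruth(contig, a.chrom, flank_a, a.strand,
                                       b.chrom, flank_b, b.strand, kind, event_id))

    i = 0
    while i < len(truth):
        row = truth[i]
        if row.type == "U":
            left = _left_piece(row.chr1, row.bkpt1, row.strand1, lengths[row.chr1])
            right = _right_piece(row.chr2, row.bkpt2, row.strand2, lengths[row.chr2])
            name = f"der{event_id}_{row.chr1}_{row.chr2}"
            contigs.append(DerivedContig(name, [left, right]))
            add_junction(name, left, right, "U")
            used.add(row.chr1, left.start, left.end)
            used.add(row.chr2, right.start, right.end)
            i += 1
        elif row.type == "B":
            r2 = truth[i + 1] if i + 1 < len(truth) else None
            if r2 is None or r2.type != "B":
                raise ValueError("B rows must come in consecutive pairs")
            if "-" in (row.strand1, row.strand2, r2.strand1, r2.strand2):
                raise ValueError("inverted balanced exchanges are not supported")
            if {row.chr1, row.chr2} != {r2.chr1, r2.chr2}:
                raise ValueError("B row pair must join the same chromosome pair")
            for n, r in enumerate((row, r2)):
                left = _left_piece(r.chr1, r.bkpt1, "+", lengths[r.chr1])
                right = _right_piece(r.chr2, r.bkpt2, "+", lengths[r.chr2])
                name = f"der{event_id}_{r.chr1}_{r.chr2}"
                contigs.append(DerivedContig(name, [left, right]))
                add_junction(name, left, right, "B")
            # the exchange covers both chromosomes end to end; duplicated or
            # lost bases at the breakpoint are implied by the coordinates
            used.add(row.chr1, 1, lengths[row.chr1])
            used.add(row.chr2, 1, lengths[row.chr2])
            i += 2
        else:  # II
            r2 = truth[i + 1] if i + 1 < len(truth) else None
            if r2 is None or r2.type != "II":
                raise ValueError("II rows must come in consecutive pairs")
            coords: dict[str, list[tuple[int, str]]] = {}
            for r in (row, r2):
                coords.setdefault(r.chr1, []).append((r.bkpt1, r.strand1))
                coords.setdefault(r.chr2, []).append((r.bkpt2, r.strand2))
            if len(coords) != 2 or any(len(v) != 2 for v in coords.values()):
                raise ValueError("II row pair must join the same chromosome pair")
            spans = {c: abs(v[0][0] - v[1][0]) for c, v in coords.items()}
            donor = max(spans, key=lambda c: (spans[c], c))
            recip = next(c for c in coords if c != donor)
            d_lo, d_hi = sorted(p for p, _ in coords[donor])
            r_lo, r_hi = sorted(p for p, _ in coords[recip])
            if r_hi <= r_lo:
                raise ValueError("insertion recipient flanks must be distinct")
            inverted = all(s == "-" for _, s in coords[donor])
            seg_strand = "-" if inverted else "+"
            rec_left = RefPiece(recip, 1, r_lo, "+")
            seg = RefPiece(donor, d_lo, d_hi, seg_strand)
            rec_right = RefPiece(recip, r_hi, lengths[recip], "+")
            name = f"der{event_id}_{recip}_ins_{donor}"
            contigs.append(DerivedContig(name, [rec_left, seg, rec_right]))
            add_junction(name, rec_left, seg, "II")
            add_junction(name, seg, rec_right, "II")
            # donor derivative: segment excised, flanks rejoined
            d_left = RefPiece(donor, 1, d_lo - 1, "+")
            d_right = RefPiece(donor, d_hi + 1, lengths[donor], "+")
            dname = f"der{event_id}_{donor}_excised"
            contigs.append(DerivedContig(dname, [d_left, d_right]))
            add_junction(dname, d_left, d_right, "donor-gap")
            used.add(recip, 1, lengths[recip])
            used.add(donor, 1, lengths[donor])
            i += 2
        event_id += 1

    for chrom in ref:
        for s, e in used.residuals(chrom, lengths[chrom]):
            if e - s + 1 < min_residual:
                continue
            name = chrom if (s, e) == (1, lengths[chrom]) else f"{chrom}_res{s}"
            contigs.append(DerivedContig(name, [RefPiece(chrom, s, e, "+")]))

    return DerivedGenome(contigs=contigs, junctions=junctions,
                         ref_lengths=lengths, truth=list(truth))


def materialize(contig: DerivedContig, ref: dict[str, str]) -> str:
    parts = []
    for p in contig.pieces:
        if isinstance(p, InsPiece):
            parts.append(p.seq)
        elif p.strand == "+":
            parts.append(ref[p.chrom][p.start - 1 : p.end])
        else:
            parts.append(revcomp(ref[p.chrom][p.start - 1 : p.end]))
    return "".join(parts)


# ---------------------------------------------------------------------------
# haplotype mutation layer
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")
#: substitution alternatives per base byte (sequencing-error model)
_SUBST = {65: b"CGT", 67: b"AGT", 71: b"ACT", 84: b"ACG"}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _split_ref(p: RefPiece, off: int) -> tuple[RefPiece, RefPiece]:
    """Split at derived offset ``off`` (first part has ``off`` bases)."""
    if p.strand == "+":
        return (RefPiece(p.chrom, p.start, p.start + off - 1, "+"),
                RefPiece(p.chrom, p.start + off, p.end, "+"))
    return (RefPiece(p.chrom, p.end - off + 1, p.end, "-"),
            RefPiece(p.chrom, p.start, p.end - off, "-"))


def _delete_in_ref(p: RefPiece, off: int, dl: int) -> tuple[RefPiece, RefPiece]:
    """Remove ``dl`` derived bases starting at offset ``off``."""
    if p.strand == "+":
        return (RefPiece(p.chrom, p.start, p.start + off - 1, "+"),
                RefPiece(p.chrom, p.start + off + dl, p.end, "+"))
    return (RefPiece(p.chrom, p.end - off + 1, p.end, "-"),
            RefPiece(p.chrom, p.start, p.end - off - dl, "-"))


def mutate_contig(
    contig: DerivedContig,
    rng: np.random.Generator,
    mut_rate: float,
    indel_frac: float,
    indel_extend: float = 0.3,
) -> tuple[DerivedContig, int]:
    """Plant short indels on a contig's piece list (returns a new contig).

    SNVs are handled separately at materialization time since they do not
    move coordinates. Indels that would touch a piece edge are skipped (they
    would perturb the splice junctions that are the simulation's subject).
    Returns the mutated contig and the number of indels applied.
    """
    total = len(contig)
    n_indel = rng.binomial(total, mut_rate * indel_frac)
    if n_indel == 0:
        return DerivedContig(contig.name, list(contig.pieces)), 0
    positions = np.sort(rng.choice(total, size=n_indel, replace=False))
    is_del = rng.random(n_indel) < 0.5
    sizes = rng.geometric(1.0 - indel_extend, size=n_indel)

    margin = 2  # keep indels away from piece edges (junction flanks)
    new_pieces: list[Piece] = []
    applied = 0
    pos_idx = 0
    offset = 0  # pre-mutation derived start of the remaining part of `p`
    for p in contig.pieces:
        plen = len(p)  # pre-mutation length of the remaining part
        while pos_idx < n_indel and positions[pos_idx] < offset + plen:
            off = int(positions[pos_idx]) - offset  # offset into remaining part
            dl = int(sizes[pos_idx])
            deletion = bool(is_del[pos_idx])
            pos_idx += 1
            if isinstance(p, InsPiece) or off < margin:
                continue
            if off + (dl if deletion else 0) > plen - margin:
                continue
            if deletion:
                left, p = _delete_in_ref(p, off, dl)
                new_pieces.append(left)
                offset += off + dl
                plen -= off + dl
            else:
                left, p = _split_ref(p, off)
                new_pieces.append(left)
                new_pieces.append(InsPiece(_random_seq(rng, dl)))
                offset += off
                plen -= off
            applied += 1
        new_pieces.append(p)
        offset += plen
    return DerivedContig(contig.name, new_pieces), applied


def _apply_snvs(seq: str, rng: np.random.Generator, rate: float) -> str:
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq
    pos = rng.choice(len(seq), size=n, replace=False)
    arr = bytearray(seq, "ascii")
    shift = rng.integers(1, 4, size=n)
    lut = {65: "CGT", 67: "AGT", 71: "ACT", 84: "ACG"}
    for p, s in zip(pos, shift):
        base = arr[p]
        arr[p] = ord(lut.get(base, "ACG")[int(s) - 1])
    return arr.decode()


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass
class _ContigIndex:
    """Flattened piece geometry of one (mutated) contig for read emission."""

    name: str
    seq: str
    qstarts: list[int]          # derived 0-based start of each piece
    pieces: list[Piece]
    boundary: list[tuple]       # between piece b and b+1: ("", ), ("D", gap), ("J",)

    @property
    def length(self) -> int:
        return len(self.seq)


def _classify_boundary(a: Piece, b: Piece) -> tuple:
    if isinstance(a, InsPiece) or isinstance(b, InsPiece):
        return ("",)  # novel bases appear as I ops, no reference gap
    if a.chrom == b.chrom and a.strand == b.strand:
        gap = (b.start - a.end - 1) if a.strand == "+" else (a.start - b.end - 1)
        if gap == 0:
            return ("",)
        if 0 < gap <= MAX_SMALL_GAP:
            return ("D", gap)
    return ("J",)


def _index_contig(contig: DerivedContig, ref: dict[str, str],
                  rng: np.random.Generator, snv_rate: float) -> _ContigIndex:
    seq = materialize(contig, ref)
    if snv_rate > 0:
        seq = _apply_snvs(seq, rng, snv_rate)
    qstarts, q = [], 0
    for p in contig.pieces:
        qstarts.append(q)
        q += len(p)
    boundary = [_classify_boundary(contig.pieces[b], contig.pieces[b + 1])
                for b in range(len(contig.pieces) - 1)]
    return _ContigIndex(contig.name, seq, qstarts, list(contig.pieces), boundary)


@dataclass
class _ReadAln:
    chrom: str
    pos: int                     # 1-based leftmost
    end: int                     # 1-based rightmost aligned base
    ref_strand: str
    cigar: str
    seq: str                     # reference-forward orientation
    crosses_junction: bool


def _emit_read(ci: _ContigIndex, qs: int, rl: int, mate_rev: bool) -> _ReadAln:
    """Alignment of the derived interval [qs, qs+rl) in reference coordinates."""
    qe = qs + rl  # exclusive
    first = bisect_right(ci.qstarts, qs) - 1
    pieces, qstarts, boundary = ci.pieces, ci.qstarts, ci.boundary

    # fast path: read wholly inside one reference piece
    p = pieces[first]
    if (first + 1 == len(pieces) or qstarts[first + 1] >= qe) \
            and isinstance(p, RefPiece):
        off = qs - qstarts[first]
        footprint = ci.seq[qs:qe]
        if p.strand == "+":
            pos = p.start + off
            return _ReadAln(p.chrom, pos, pos + rl - 1, "-" if mate_rev else "+",
                            f"{rl}M", footprint, False)
        pos = p.end - off - rl + 1
        return _ReadAln(p.chrom, pos, pos + rl - 1, "+" if mate_rev else "-",
                        f"{rl}M", revcomp(footprint), False)

    # general path: assemble op list across pieces
    ops: list[tuple] = []  # ("M", qlen, ref_lo, ref_hi, chrom, strand) | ("I", q) | ("D", g) | ("J",)
    idx = first
    cursor = qs
    while cursor < qe and idx < len(pieces):
        p = pieces[idx]
        pstart = qstarts[idx]
        a = cursor - pstart
        b = min(qe - pstart, len(p)) - 1  # inclusive rel offsets [a, b]
        qlen = b - a + 1
        if isinstance(p, InsPiece):
            ops.append(("I", qlen))
        elif p.strand == "+":
            ops.append(("M", qlen, p.start + a, p.start + b, p.chrom, "+"))
        else:
            ops.append(("M", qlen, p.end - b, p.end - a, p.chrom, "-"))
        cursor = pstart + b + 1
        if cursor < qe and idx < len(boundary):
            kind = boundary[idx]
            if kind[0] == "D":
                ops.append(("D", kind[1]))
            elif kind[0] == "J":
                ops.append(("J",))
        idx += 1

    # split at junctions, keep the run with the most aligned (M) bases
    runs: list[list[tuple]] = [[]]
    for op in ops:
        if op[0] == "J":
            runs.append([])
        else:
            runs[-1].append(op)
    crosses = len(runs) > 1

    def m_bases(run):
        return sum(op[1] for op in run if op[0] == "M")

    best = max(range(len(runs)), key=lambda n: (m_bases(runs[n]), -n))
    run = runs[best]
    left_clip = sum(op[1] for r in runs[:best] for op in r if op[0] in "MI")
    right_clip = sum(op[1] for r in runs[best + 1:] for op in r if op[0] in "MI")
    # terminal insertions cannot start or end an alignment
    while run and run[0][0] != "M":
        if run[0][0] == "I":
            left_clip += run[0][1]
        run = run[1:]
    while run and run[-1][0] != "M":
        if run[-1][0] == "I":
            right_clip += run[-1][1]
        run = run[:-1]
    if not run:  # no aligned bases survive; align the whole read as one M? —
        raise RuntimeError("read with no alignable bases (junction pile-up)")

    strand = run[0][5]
    chrom = run[0][4]
    footprint = ci.seq[qs:qe]
    if strand == "+":
        cig = [(op[0], op[1]) for op in run]
        pos = run[0][2]
        end = run[-1][3]
        seq = footprint
        lc, rc = left_clip, right_clip
    else:
        cig = [(op[0], op[1]) for op in reversed(run)]
        pos = run[-1][2]
        end = run[0][3]
        seq = revcomp(footprint)
        lc, rc = right_clip, left_clip
    parts = ([f"{lc}S"] if lc else []) + [f"{n}{o}" for o, n in cig] \
        + ([f"{rc}S"] if rc else [])
    ref_strand = strand if not mate_rev else ("-" if strand == "+" else "+")
    return _ReadAln(chrom, pos, end, ref_strand, "".join(parts), seq, crosses)


@dataclass
class SimResult:
    sam_path: str
    fastq1: Optional[str]
    fastq2: Optional[str]
    genome: DerivedGenome
    n_pairs: int
    config: SimConfig
    straddlers: list[tuple[str, str, str]] = field(default_factory=list)
    # (qname, chrom_a, chrom_b) of fragments whose junction-free mates map
    # to different chromosomes — the expected chimeric pairs


def simulate_reads(
    genome: DerivedGenome,
    ref: dict[str, str],
    config: SimConfig,
    sam_path: str,
    fastq_prefix: Optional[str] = None,
) -> SimResult:
    """Draw paired-end fragments and emit a coordinate-sorted truth SAM.

    Fragments are placed uniformly (contigs weighted by length) with outer
    distance ~ Normal(insert_mean, insert_stdev); draws at or below the read
    length, or longer than the contig, are rejected and redrawn. The RNG is
    fully determined by ``config.seed``. When ``fastq_prefix`` is given,
    ``<prefix>_1.fastq``/``<prefix>_2.fastq`` are written alongside.
    """
    rng = np.random.default_rng(config.seed)
    rl = config.read_len

    mutated = []
    for contig in genome.contigs:
        if config.mut_rate > 0:
            c, _ = mutate_contig(contig, rng, config.mut_rate, config.indel_frac,
                                 config.indel_extend)
        else:
            c = DerivedContig(contig.name, list(contig.pieces))
        mutated.append(c)
    snv_rate = config.mut_rate * (1.0 - config.indel_frac)
    index = [_index_contig(c, ref, rng, snv_rate) for c in mutated]

    lengths = np.array([ci.length for ci in index], dtype=float)
    total = lengths.sum()
    n_pairs = int(round(config.coverage * total / (2 * rl)))

    contig_idx = rng.choice(len(index), size=n_pairs, p=lengths / total)
    inserts = np.rint(rng.normal(config.insert_mean, config.insert_stdev,
                                 size=n_pairs)).astype(np.int64)
    clens = np.array([ci.length for ci in index], dtype=np.int64)[contig_idx]
    bad = (inserts <= rl) | (inserts > clens)
    while bad.any():
        inserts[bad] = np.rint(rng.normal(config.insert_mean, config.insert_stdev,
                                          size=int(bad.sum()))).astype(np.int64)
        bad = (inserts <= rl) | (inserts > clens)
    starts = (rng.random(n_pairs) * (clens - inserts + 1)).astype(np.int64)
    if config.base_error > 0:
        err_counts = rng.binomial(rl, config.base_error, size=2 * n_pairs)
        total_err = int(err_counts.sum())
        err_pos = rng.integers(0, rl, size=total_err)
        err_shift = rng.integers(1, 4, size=total_err)
        err_offsets = np.concatenate(([0], np.cumsum(err_counts)))
    else:
        err_counts = np.zeros(2 * n_pairs, dtype=np.int64)
        err_pos = err_shift = err_offsets = None

    ref_names = list(ref)
    tid_of = {c: t for t, c in enumerate(ref_names)}
    qual = "I" * rl

    lines: list[str] = []
    tids: list[int] = []
    positions: list[int] = []
    straddlers: list[tuple[str, str, str]] = []

    fq1 = fq2 = None
    if fastq_prefix is not None:
        fq1 = open(f"{fastq_prefix}_1.fastq", "w")
        fq2 = open(f"{fastq_prefix}_2.fastq", "w")

    try:
        for n in range(n_pairs):
            ci = index[int(contig_idx[n])]
            f0 = int(starts[n])
            ins = int(inserts[n])
            qname = f"frag{n}"
            r1 = _emit_read(ci, f0, rl, mate_rev=False)
            r2 = _emit_read(ci, f0 + ins - rl, rl, mate_rev=True)
            for m, (r, mate) in enumerate(((r1, r2), (r2, r1))):
                seq = r.seq
                ridx = 2 * n + m
                ec = int(err_counts[ridx])
                if ec:
                    lo = int(err_offsets[ridx])
                    arr = bytearray(seq, "ascii")
                    for p, s in zip(err_pos[lo : lo + ec], err_shift[lo : lo + ec]):
                        arr[p] = _SUBST.get(arr[p], b"ACG")[int(s) - 1]
                    seq = arr.decode()
                same = r.chrom == mate.chrom
                proper = same and r.ref_strand != mate.ref_strand
                if same:
                    outer = max(r.end, mate.end) - min(r.pos, mate.pos) + 1
                    if r.pos < mate.pos or (r.pos == mate.pos and m == 0):
                        tlen = outer
                    else:
                        tlen = -outer
                else:
                    tlen = 0
                flag = 0x1 | (0x40 if m == 0 else 0x80)
                if proper:
                    flag |= 0x2
                if r.ref_strand == "-":
                    flag |= 0x10
                if mate.ref_strand == "-":
                    flag |= 0x20
                rnext = "=" if same else mate.chrom
                lines.append(
                    f"{qname}\t{flag}\t{r.chrom}\t{r.pos}\t60\t{r.cigar}\t"
                    f"{rnext}\t{mate.pos}\t{tlen}\t{seq}\t{qual}"
                )
                tids.append(tid_of[r.chrom])
                positions.append(r.pos)
                if fq1 is not None:
                    read_as_sequenced = seq if (r.ref_strand == "-") == (m == 1) \
                        else revcomp(seq)
                    fh = fq1 if m == 0 else fq2
                    fh.write(f"@{qname}/{m + 1}\n{read_as_sequenced}\n+\n{qual}\n")
            if not r1.crosses_junction and not r2.crosses_junction \
                    and r1.chrom != r2.chrom:
                straddlers.append((qname, *sorted((r1.chrom, r2.chrom))))
    finally:
        if fq1 is not None:
            fq1.close()
            fq2.close()

    order = np.lexsort((np.asarray(positions), np.asarray(tids)))
    with open(sam_path, "w") as out:
        out.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name in ref_names:
            out.write(f"@SQ\tSN:{name}\tLN:{genome.ref_lengths[name]}\n")
        for k in order:
            out.write(lines[int(k)] + "\n")

    return SimResult(
        sam_path=sam_path,
        fastq1=f"{fastq_prefix}_1.fastq" if fastq_prefix else None,
        fastq2=f"{fastq_prefix}_2.fastq" if fastq_prefix else None,
        genome=genome,
        n_pairs=n_pairs,
        config=config,
        straddlers=straddlers,
    )


# ---------------------------------------------------------------------------
# down-sampling
# ---------------------------------------------------------------------------

def _keep(qname: str, rate: float, seed: int) -> bool:
    h = zlib.crc32(f"{seed}:{qname}".encode()) & 0xFFFFFFFF
    return h / 2**32 < rate


def downsample(sam_in: str, sam_out: str, rate: float, seed: int) -> int:
    """Keep each read pair (both mates together) with probability ``rate``.

    The decision is a deterministic hash of (seed, read name), so samples at
    decreasing rates under one seed are nested subsets. Returns the number
    of records written.
    """
    if not 0 < rate <= 1:
        raise ValueError("rate must be in (0, 1]")
    kept = 0
    with open(sam_in) as fin, open(sam_out, "w") as fout:
        for line in fin:
            if line.startswith("@"):
                fout.write(line)
                continue
            qname = line.split("\t", 1)[0]
            if _keep(qname, rate, seed):
                fout.write(line)
                kept += 1
    return kept


# ---------------------------------------------------------------------------
# toy genomes and scaled study presets
# ---------------------------------------------------------------------------

def random_genome(chrom_lengths: dict[str, int], seed: int) -> dict[str, str]:
    """I.i.d. uniform ACGT chromosomes (deterministic in ``seed``)."""
    rng = np.random.default_rng(seed)
    return {c: _random_seq(rng, n) for c, n in chrom_lengths.items()}


#: toy analog of the first simulated study: 12 breakpoint events — six
#: one-way fusions, one reciprocal exchange with a 1,000 bp duplication on
#: the second chromosome, one direct and one inverted interchromosomal
#: insertion (donor segments 40 kb and 80 kb) — on 18 chromosomes of 400 kb.
DATASET1_CHROM_LEN = 400_000

DATASET1_TRUTH = [
    TruthRecord("chr9", 200_000, "+", "chr11", 150_000, "+", "U"),
    TruthRecord("chr5", 240_000, "+", "chr2", 260_000, "+", "U"),
    TruthRecord("chr7", 130_000, "+", "chr12", 210_000, "-", "U"),
    TruthRecord("chr10", 170_000, "-", "chr20", 190_000, "+", "U"),
    TruthRecord("chr16", 220_000, "-", "chr18", 140_000, "+", "U"),
    TruthRecord("chr4", 110_000, "+", "chr17", 230_000, "+", "U"),
    TruthRecord("chr3", 200_000, "+", "chr6", 100_000, "+", "B"),
    TruthRecord("chr6", 100_999, "+", "chr3", 200_001, "+", "B"),
    TruthRecord("chr13", 200_000, "+", "chr14", 100_000, "+", "II"),
    TruthRecord("chr14", 139_999, "+", "chr13", 200_001, "+", "II"),
    TruthRecord("chr1", 100_000, "-", "chr22", 250_000, "+", "II"),
    TruthRecord("chr22", 250_001, "+", "chr1", 179_999, "-", "II"),
]

#: toy analog of the second simulated study (75 bp reads): 9 events — seven
#: one-way fusions and one clean reciprocal exchange — on 16 chromosomes.
DATASET2_TRUTH = [
    TruthRecord("chr15", 210_000, "+", "chr18", 250_000, "+", "U"),
    TruthRecord("chr13", 155_000, "+", "chr20", 215_000, "+", "U"),
    TruthRecord("chr9", 105_000, "-", "chr17", 240_000, "+", "U"),
    TruthRecord("chr21", 150_000, "+", "chr2", 175_000, "-", "U"),
    TruthRecord("chr11", 110_000, "+", "chr12", 268_000, "+", "U"),
    TruthRecord("chr16", 230_000, "+", "chr7", 176_001, "+", "B"),
    TruthRecord("chr7", 176_000, "+", "chr16", 230_001, "+", "B"),
    TruthRecord("chr6", 184_000, "-", "chr10", 130_000, "+", "U"),
    TruthRecord("chr19", 175_000, "+", "chr14", 220_000, "-", "U"),
]

#: classification tolerance used with the toy presets: the 1 Mb reciprocal
#: default scaled with the ~1/100 coordinate scale of the toy genomes
DATASET_RECIP_TOL = 10_000


def _preset_chroms(truth: list[TruthRecord], length: int) -> dict[str, int]:
    names = []
    for r in truth:
        for c in (r.chr1, r.chr2):
            if c not in names:
                names.append(c)
    return {c: length for c in sorted(names, key=lambda c: (len(c), c))}


def dataset_preset(which: int, seed: int) -> tuple[dict[str, str], list[TruthRecord], SimConfig]:
    """Reference, truth table and read settings for a bundled toy study.

    Preset 1 uses 100 bp reads, preset 2 uses 75 bp reads; both simulate 40X
    coverage with 400 +/- 80 bp inserts, mutation rate 0.001 with indel
    fraction 0.15.
    """
    if which == 1:
        truth, read_len = DATASET1_TRUTH, 100
    elif which == 2:
        truth, read_len = DATASET2_TRUTH, 75
    else:
        raise ValueError("preset must be 1 or 2")
    chroms = _preset_chroms(truth, DATASET1_CHROM_LEN)
    ref = random_genome(chroms, seed=seed)
    config = SimConfig(coverage=40.0, read_len=read_len, insert_mean=400.0,
                       insert_stdev=80.0, mut_rate=0.001, indel_frac=0.15,
                       base_error=0.02, seed=seed)
    return ref, truth, config


def write_derived_fasta(genome: DerivedGenome, ref: dict[str, str], path: str) -> None:
    """Materialize the (unmutated) derived genome to FASTA."""
    write_fasta({c.name: materialize(c, ref) for c in genome.contigs}, path)
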