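"""Alignment I/O, CIGAR soft-clip extraction and insert-size estimation.

All coordinates are 1-based inclusive (SAM convention). Reads are streamed
with :func:`read_alignments`; breakpoint evidence is harvested from terminal
soft clips (:func:`extract_softclips`), and the pair-proximity length ``L``
used throughout the caller is derived from the concordant-pair insert
distribution (:func:`estimate_insert_stats`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pysam

#: CIGAR operation codes as emitted by pysam, in SAM order.
CIGAR_OPS = "MIDNSHP=X"
#: operations that consume query bases
QUERY_OPS = frozenset("MIS=X")
#: operations that consume reference bases
REF_OPS = frozenset("MDN=X")

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement (ACGTN alphabet, case preserved)."""
    return seq.translate(_COMP)[::-1]


class SortOrderError(ValueError):
    """Input alignments are not coordinate-sorted."""


@dataclass
class AlignedRead:
    """One mapped SAM record with parsed CIGAR.

    ``pos`` and ``mate_pos`` are 1-based leftmost coordinates. ``cigar`` is an
    ordered list of ``(op, length)`` with ``op`` one of ``MIDNSHP=X``. ``seq``
    is stored in reference-forward orientation exactly as in the SAM record.
    """

    qname: str
    flag: int
    chrom: str
    pos: int
    mapq: int
    cigar: list[tuple[str, int]]
    mate_chrom: str
    mate_pos: int
    tlen: int
    seq: str
    qual: str = "*"

    def __post_init__(self) -> None:
        qlen = sum(n for op, n in self.cigar if op in QUERY_OPS)
        if self.seq not in ("*", "") and qlen != len(self.seq):
            raise ValueError(
                f"CIGAR of {self.qname} consumes {qlen} query bases but "
                f"sequence has {len(self.seq)}"
            )
        if self.pos < 1:
            raise ValueError(f"{self.qname}: position {self.pos} < 1")

    @property
    def strand(self) -> str:
        return "-" if self.flag & 0x10 else "+"

    @property
    def mate_strand(self) -> str:
        return "-" if self.flag & 0x20 else "+"

    @property
    def is_chimeric(self) -> bool:
        """True when the mate maps to a different reference sequence."""
        return self.mate_chrom not in ("=", self.chrom) and self.mate_chrom != "*"

    @property
    def reference_end(self) -> int:
        """1-based inclusive coordinate of the last aligned reference base."""
        return self.pos + sum(n for op, n in self.cigar if op in REF_OPS) - 1


@dataclass
class SoftClip:
    """A terminal soft-clipped segment of a mapped read.

    ``side`` is the clipped end in reference orientation; ``boundary`` is the
    aligned reference base adjacent to the clip (last aligned base for a right
    clip, first aligned base for a left clip).
    """

    read: AlignedRead
    side: str  # "left" | "right"
    clip_seq: str
    clip_len: int
    boundary: int

    def __post_init__(self) -> None:
        if self.clip_len != len(self.clip_seq) or self.clip_len < 1:
            raise ValueError("clip length must match clipped sequence")


@dataclass
class InsertStats:
    """Concordant-pair insert statistics and the proximity length ``L``.

    ``L = mean + k * stdev`` bounds both cluster cohesion and the
    breakpoint-search windows.
    """

    mean: float
    stdev: float
    k: float
    n_pairs: int = 0
    L: float = field(init=False)

    def __post_init__(self) -> None:
        if self.stdev < 0 or self.k <= 0:
            raise ValueError("stdev must be >= 0 and k > 0")
        self.L = self.mean + self.k * self.stdev

    @property
    def window(self) -> int:
        """``L`` rounded to a whole number of bases."""
        return int(round(self.L))


def _parse_cigartuples(cig) -> list[tuple[str, int]]:
    return [(CIGAR_OPS[op], n) for op, n in cig]


def aligned_from_pysam(rec: "pysam.AlignedSegment", af: "pysam.AlignmentFile") -> AlignedRead:
    """Convert a mapped pysam record into an :class:`AlignedRead`."""
    mate_chrom = "*"
    if rec.next_reference_id >= 0:
        mate_chrom = af.get_reference_name(rec.next_reference_id)
    return AlignedRead(
        qname=rec.query_name,
        flag=rec.flag,
        chrom=rec.reference_name,
        pos=rec.reference_start + 1,
        mapq=rec.mapping_quality,
        cigar=_parse_cigartuples(rec.cigartuples),
        mate_chrom=mate_chrom,
        mate_pos=rec.next_reference_start + 1,
        tlen=rec.template_length,
        seq=rec.query_sequence or "*",
        qual="*" if rec.query_qualities is None
        else pysam.qualities_to_qualitystring(rec.query_qualities),
    )


def read_alignments(
    path: str,
    min_mapq: int = 20,
    keep_duplicates: bool = False,
) -> Iterator[AlignedRead]:
    """Stream primary mapped records from a coordinate-sorted SAM/BAM file.

    Unmapped, secondary and supplementary records are skipped, as are records
    below ``min_mapq`` and (by default) duplicate-flagged records. Raises
    :class:`SortOrderError` naming the offending record if coordinates go
    backwards.
    """
    with pysam.AlignmentFile(path, check_sq=False) as af:
        last = (-1, -1)
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            key = (rec.reference_id, rec.reference_start)
            if key < last:
                raise SortOrderError(
                    f"input is not coordinate-sorted at record {rec.query_name!r} "
                    f"({rec.reference_name}:{rec.reference_start + 1})"
                )
            last = key
            if rec.is_duplicate and not keep_duplicates:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            if rec.cigartuples is None:
                raise ValueError(f"mapped record {rec.query_name!r} has no CIGAR")
            yield aligned_from_pysam(rec, af)


def write_alignments(
    reads: Iterable[AlignedRead], path: str, ref_lengths: dict[str, int]
) -> None:
    """Write records to a SAM file with an ``@SQ`` header from ``ref_lengths``."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in ref_lengths.items()],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = r.qname
            seg.flag = r.flag
            seg.reference_id = out.header.get_tid(r.chrom)
            seg.reference_start = r.pos - 1
            seg.mapping_quality = r.mapq
            seg.cigarstring = "".join(f"{n}{op}" for op, n in r.cigar)
            if r.mate_chrom == "*":
                seg.next_reference_id = -1
                seg.next_reference_start = -1
            else:
                mc = r.chrom if r.mate_chrom == "=" else r.mate_chrom
                seg.next_reference_id = out.header.get_tid(mc)
                seg.next_reference_start = r.mate_pos - 1
            seg.template_length = r.tlen
            seg.query_sequence = None if r.seq == "*" else r.seq
            if r.qual != "*":
                seg.query_qualities = pysam.qualitystring_to_array(r.qual)
            out.write(seg)


class InsufficientPairsError(ValueError):
    """Too few concordant pairs to estimate the insert distribution."""


def estimate_insert_stats(
    reads: Iterable[AlignedRead],
    k: float = 3.0,
    max_pairs: int = 200_000,
    min_usable: int = 100,
) -> InsertStats:
    """Estimate mean/stdev of the concordant-pair outer distance.

    A pair contributes once, through its leftmost forward-strand mate, using
    the SAM template length (the 5'-most to 3'-most span of the pair).
    Chimeric pairs carry no mapped distance and contribute nothing. Raises
    :class:`InsufficientPairsError` below ``min_usable`` pairs, in which case
    the caller should supply mean/stdev explicitly.
    """
    dists: list[int] = []
    for r in reads:
        if r.is_chimeric:
            continue
        if r.strand == "+" and r.mate_strand == "-" and r.tlen > 0 and r.pos <= r.mate_pos:
            dists.append(r.tlen)
            if len(dists) >= max_pairs:
                break
    if len(dists) < min_usable:
        raise InsufficientPairsError(
            f"only {len(dists)} concordant pairs found (need >= {min_usable}); "
            "supply --mean/--stdev explicitly"
        )
    arr = np.asarray(dists, dtype=float)
    return InsertStats(mean=float(arr.mean()), stdev=float(arr.std()), k=k,
                       n_pairs=len(dists))


def extract_softclips(read: AlignedRead, min_clip: int = 20) -> list[SoftClip]:
    """Terminal soft clips of length >= ``min_clip``.

    Hard clips are ignored: their bases are absent from the record and cannot
    be realigned. Reads without a qualifying clip return an empty list.
    """
    if read.seq in ("*", ""):
        return []
    clips: list[SoftClip] = []
    cig = read.cigar
    # leading clip (skip hard clips which carry no sequence)
    i = 0
    while i < len(cig) and cig[i][0] == "H":
        i += 1
    if i < len(cig) and cig[i][0] == "S" and cig[i][1] >= min_clip:
        n = cig[i][1]
        clips.append(SoftClip(read, "left", read.seq[:n], n, read.pos))
    j = len(cig) - 1
    while j >= 0 and cig[j][0] == "H":
        j -= 1
    if j > i and cig[j][0] == "S" and cig[j][1] >= min_clip:
        n = cig[j][1]
        clips.append(SoftClip(read, "right", read.seq[-n:], n, read.reference_end))
    return clips


def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    """Write sequences to FASTA and build a .fai index."""
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    pysam.faidx(path)


def read_fasta(path: str) -> dict[str, str]:
    with pysam.FastaFile(path) as fa:
        return {name: fa.fetch(name) for name in fa.references}
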