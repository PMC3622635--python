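"""Discordant chimeric-pair clustering and fusion-orientation typing.

A candidate interchromosomal rearrangement is supported by a cluster of
chimeric read pairs: mates on two different chromosomes, each side's reads
mapped within ``L`` bases of one another and on a common strand. Reads point
into the junction, so the breakpoint lies to the right of a forward-strand
read set and to the left of a reverse-strand read set; the per-side
(strand, breakpoint-side) pair is the cluster's orientation signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .sam_io import AlignedRead, InsertStats

log = logging.getLogger(__name__)


@dataclass
class ChimericPair:
    """A read pair whose mates align to different chromosomes.

    ``read_i`` is the mate on the canonically first chromosome (reference
    header order), ``read_j`` its mate on the other chromosome.
    """

    read_i: AlignedRead
    read_j: AlignedRead

    def __post_init__(self) -> None:
        if self.read_i.chrom == self.read_j.chrom:
            raise ValueError("chimeric pair mates must be on different chromosomes")
        if self.read_i.qname != self.read_j.qname:
            raise ValueError("mates must share a query name")


@dataclass
class OrientationSignature:
    """Strand/side signature of a cluster (optionally with arm nomenclature)."""

    strand_i: str
    strand_j: str
    breakpoint_side_i: str = field(init=False)
    breakpoint_side_j: str = field(init=False)
    arm_fusion: Optional[str] = None

    def __post_init__(self) -> None:
        # reads face the junction: + clusters have it on their right
        self.breakpoint_side_i = "right" if self.strand_i == "+" else "left"
        self.breakpoint_side_j = "right" if self.strand_j == "+" else "left"

    @property
    def same_strand(self) -> bool:
        """True for opposite-orientation fusions (inverted-segment junctions)."""
        return self.strand_i == self.strand_j


@dataclass
class ChimericCluster:
    """Two co-located, same-strand chimeric read sets on different chromosomes."""

    chrom_i: str
    chrom_j: str
    reads_i: list[AlignedRead]
    reads_j: list[AlignedRead]
    strand_i: str
    strand_j: str
    orientation: OrientationSignature = field(init=False)

    def __post_init__(self) -> None:
        self.orientation = OrientationSignature(self.strand_i, self.strand_j)

    @property
    def n_pairs(self) -> int:
        return len(self.reads_i)

    @property
    def span_i(self) -> tuple[int, int]:
        return (min(r.pos for r in self.reads_i),
                max(r.reference_end for r in self.reads_i))

    @property
    def span_j(self) -> tuple[int, int]:
        return (min(r.pos for r in self.reads_j),
                max(r.reference_end for r in self.reads_j))

    def _facing(self, side: str) -> str:
        return (self.orientation.breakpoint_side_i if side == "i"
                else self.orientation.breakpoint_side_j)

    def outer_anchor(self, side: str) -> int:
        """Terminus of the outermost read — the cluster edge farthest from
        the junction. The junction lies within L of this anchor."""
        reads = self.reads_i if side == "i" else self.reads_j
        if self._facing(side) == "right":
            return min(r.pos for r in reads)
        return max(r.reference_end for r in reads)

    def inner_edge(self, side: str) -> int:
        """Junction-proximal aligned terminus of the read set."""
        reads = self.reads_i if side == "i" else self.reads_j
        if self._facing(side) == "right":
            return max(r.reference_end for r in reads)
        return min(r.pos for r in reads)


def collect_chimeric_pairs(
    reads: Iterable[AlignedRead],
    chrom_order: Optional[list[str]] = None,
) -> list[ChimericPair]:
    """Join chimeric records into pairs by query name.

    Chromosome order is canonicalized (``chrom_i`` first by reference-header
    order when given, else lexicographic). Records whose mate never appears
    are logged and dropped.
    """
    rank = {c: n for n, c in enumerate(chrom_order)} if chrom_order else None

    def _rank(c: str):
        return rank[c] if rank is not None else c

    pending: dict[str, AlignedRead] = {}
    pairs: list[ChimericPair] = []
    for r in reads:
        if not r.is_chimeric:
            continue
        mate = pending.pop(r.qname, None)
        if mate is None:
            pending[r.qname] = r
            continue
        a, b = (mate, r) if _rank(mate.chrom) <= _rank(r.chrom) else (r, mate)
        pairs.append(ChimericPair(a, b))
    if pending:
        log.warning("dropped %d chimeric records with missing mates", len(pending))
    return pairs


class _Group:
    """A candidate cluster with cached coordinate extents on both sides."""

    __slots__ = ("members", "min_i", "max_i", "min_j", "max_j")

    def __init__(self, p: ChimericPair) -> None:
        self.members = [p]
        self.min_i = self.max_i = p.read_i.pos
        self.min_j = self.max_j = p.read_j.pos

    def fits(self, p: ChimericPair, L: float) -> bool:
        return (max(self.max_i, p.read_i.pos) - min(self.min_i, p.read_i.pos) <= L
                and max(self.max_j, p.read_j.pos) - min(self.min_j, p.read_j.pos) <= L)

    def add(self, p: ChimericPair) -> None:
        self.members.append(p)
        self.min_i = min(self.min_i, p.read_i.pos)
        self.max_i = max(self.max_i, p.read_i.pos)
        self.min_j = min(self.min_j, p.read_j.pos)
        self.max_j = max(self.max_j, p.read_j.pos)

    def can_merge(self, other: "_Group", L: float) -> bool:
        return (max(self.max_i, other.max_i) - min(self.min_i, other.min_i) <= L
                and max(self.max_j, other.max_j) - min(self.min_j, other.min_j) <= L)

    def merge(self, other: "_Group") -> None:
        self.members.extend(other.members)
        self.min_i = min(self.min_i, other.min_i)
        self.max_i = max(self.max_i, other.max_i)
        self.min_j = min(self.min_j, other.min_j)
        self.max_j = max(self.max_j, other.max_j)


def cluster_pairs(
    pairs: list[ChimericPair],
    stats: InsertStats,
    min_pairs: int = 2,
) -> list[ChimericCluster]:
    """Group chimeric pairs into clusters satisfying the four criteria.

    Pairs are stratified by (chromosome pair, strand pair). Within a stratum
    each pair joins the first existing group it fits (both coordinate spans
    staying within ``L``), sweeping in sorted coordinate order; groups are
    then merged to a fixpoint, so no two emitted clusters of one stratum
    could be united without violating cohesion (pairwise maximality).
    Groups smaller than ``min_pairs`` are discarded. The sweep order is a
    deterministic sort, so output is invariant to input order.
    """
    L = stats.L
    strata: dict[tuple, list[ChimericPair]] = {}
    for p in pairs:
        key = (p.read_i.chrom, p.read_j.chrom, p.read_i.strand, p.read_j.strand)
        strata.setdefault(key, []).append(p)

    clusters: list[ChimericCluster] = []
    for (ci, cj, si, sj) in sorted(strata):
        stratum = sorted(strata[(ci, cj, si, sj)],
                         key=lambda p: (p.read_i.pos, p.read_j.pos, p.read_i.qname))
        groups: list[_Group] = []
        for p in stratum:
            for g in groups:
                if g.fits(p, L):
                    g.add(p)
                    break
            else:
                groups.append(_Group(p))
        merged = True
        while merged:
            merged = False
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    if groups[a].can_merge(groups[b], L):
                        groups[a].merge(groups[b])
                        del groups[b]
                        merged = True
                        break
                if merged:
                    break
        for g in groups:
            if len(g.members) < min_pairs:
                continue
            members = sorted(g.members, key=lambda p: (p.read_i.pos, p.read_j.pos,
                                                       p.read_i.qname))
            clusters.append(ChimericCluster(
                chrom_i=ci, chrom_j=cj,
                reads_i=[p.read_i for p in members],
                reads_j=[p.read_j for p in members],
                strand_i=si, strand_j=sj,
            ))
    clusters.sort(key=lambda c: (c.chrom_i, c.chrom_j, c.span_i, c.span_j,
                                 c.strand_i, c.strand_j))
    return clusters


def load_centromeres(path: str) -> dict[str, tuple[int, int]]:
    """Read a centromere BED (0-based half-open) into 1-based inclusive intervals."""
    out: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split()[:3]
            out[chrom] = (int(start) + 1, int(end))
    return out


def _arm(pos: int, cen: tuple[int, int]) -> Optional[str]:
    if pos < cen[0]:
        return "p"
    if pos > cen[1]:
        return "q"
    return None


def type_fusion(
    cluster: ChimericCluster,
    centromeres: Optional[dict[str, tuple[int, int]]] = None,
) -> OrientationSignature:
    """Deduce the fusion orientation of a cluster.

    The strand/side signature is intrinsic to the read orientations. When a
    centromere annotation is supplied, the chromosomal arm of each junction
    side is added (``p-p``, ``p-q``, ``q-p`` or ``q-q``); a side whose
    junction falls inside the centromere interval leaves ``arm_fusion`` unset
    with a warning.
    """
    sig = OrientationSignature(cluster.strand_i, cluster.strand_j)
    if centromeres and cluster.chrom_i in centromeres and cluster.chrom_j in centromeres:
        arm_i = _arm(cluster.inner_edge("i"), centromeres[cluster.chrom_i])
        arm_j = _arm(cluster.inner_edge("j"), centromeres[cluster.chrom_j])
        if arm_i is None or arm_j is None:
            log.warning(
                "cluster %s/%s abuts a centromere; arm nomenclature suppressed",
                cluster.chrom_i, cluster.chrom_j,
            )
        else:
            sig.arm_fusion = f"{arm_i}-{arm_j}"
    cluster.orientation = sig
    return sig
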