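"""Base-pair breakpoint resolution from soft-clipped reads.

For each chimeric cluster, an ``L``-length window is extended from the
outermost aligned base of each read set toward the presumed junction (``W``
on the first chromosome, ``X`` on the second). Soft-clipped reads whose clip
faces the junction are harvested inside each window; each clipped subread is
realigned end-free against the partner window (reverse-complemented when the
orientation signature marks an opposite-orientation fusion). The breakpoint
on each chromosome is the modal junction-adjacent coordinate over the local
clip boundaries and the realigned subread termini, and a cluster is promoted
to a call only if at least one clipped subread realigned into ``W`` or ``X``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import edlib

from .clustering import ChimericCluster, OrientationSignature
from .sam_io import AlignedRead, InsertStats, SoftClip, extract_softclips, revcomp

log = logging.getLogger(__name__)


@dataclass
class BreakWindow:
    """An L-length breakpoint-search interval on one cluster side.

    The window is anchored at the terminus of the *outermost* read of the
    set — the cluster edge farthest from the junction — and extends L bases
    toward the junction (truncated at the chromosome ends). Cluster cohesion
    guarantees the outermost read maps within L of the true junction, so the
    window covers the read set's clip boundaries, the junction flank, and
    the first L bases of partner-derived sequence beyond it — the landing
    zone for realigned clipped subreads from the partner side.
    """

    chrom: str
    start: int
    end: int
    side: str  # "i" | "j"
    facing: str  # breakpoint side of the cluster: "left" | "right"

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class RealignedClip:
    """A clipped subread placed inside the partner window."""

    source: SoftClip
    target_chrom: str
    target_pos: int  # junction-adjacent terminus of the placement
    target_strand: str
    edit_distance: int


@dataclass
class BreakpointCall:
    """A resolved chimeric breakpoint pair with its support counts."""

    chrom_i: str
    bkpt_i: int
    chrom_j: str
    bkpt_j: int
    orientation: OrientationSignature
    n_pairs: int
    n_clips_i: int
    n_clips_j: int
    mode_support_i: int
    mode_support_j: int
    cluster: Optional[ChimericCluster] = field(default=None, repr=False)

    @property
    def strand_i(self) -> str:
        return self.orientation.strand_i

    @property
    def strand_j(self) -> str:
        return self.orientation.strand_j

    def bkpt(self, chrom: str) -> int:
        if chrom == self.chrom_i:
            return self.bkpt_i
        if chrom == self.chrom_j:
            return self.bkpt_j
        raise KeyError(chrom)

    def side(self, chrom: str) -> str:
        if chrom == self.chrom_i:
            return self.orientation.breakpoint_side_i
        if chrom == self.chrom_j:
            return self.orientation.breakpoint_side_j
        raise KeyError(chrom)

    def strand(self, chrom: str) -> str:
        if chrom == self.chrom_i:
            return self.orientation.strand_i
        if chrom == self.chrom_j:
            return self.orientation.strand_j
        raise KeyError(chrom)


def build_windows(
    cluster: ChimericCluster,
    stats: InsertStats,
    ref_lengths: dict[str, int],
) -> tuple[BreakWindow, BreakWindow]:
    """Windows ``W`` (side i) and ``X`` (side j) for a typed cluster."""
    L = stats.window

    def one(side: str, chrom: str) -> BreakWindow:
        facing = (cluster.orientation.breakpoint_side_i if side == "i"
                  else cluster.orientation.breakpoint_side_j)
        anchor = cluster.outer_anchor(side)
        if facing == "right":
            start, end = anchor, anchor + L - 1
        else:
            start, end = anchor - L + 1, anchor
        start = max(1, start)
        end = min(ref_lengths[chrom], end)
        return BreakWindow(chrom=chrom, start=start, end=end, side=side, facing=facing)

    return one("i", cluster.chrom_i), one("j", cluster.chrom_j)


def harvest_clips(
    window: BreakWindow,
    reads: Iterable[AlignedRead],
    min_clip: int = 20,
    max_clips: int = 5,
) -> list[SoftClip]:
    """Soft clips inside a window, clip facing the junction, capped at
    ``max_clips`` (first encountered in coordinate order).

    ``reads`` may be any iterable of reads overlapping the window region
    (e.g. an indexed fetch or a streamed pre-filter), in coordinate order.
    """
    out: list[SoftClip] = []
    for read in reads:
        if read.chrom != window.chrom:
            continue
        for clip in extract_softclips(read, min_clip=min_clip):
            if clip.side != window.facing:
                continue  # clip points away from the junction
            if clip.boundary in window:
                out.append(clip)
    out.sort(key=lambda c: (c.boundary, c.read.qname, c.side))
    return out[:max_clips]


def realign_clip(
    clip: SoftClip,
    target: BreakWindow,
    window_seq: str,
    orientation: OrientationSignature,
    max_mismatch_frac: float = 0.1,
) -> Optional[RealignedClip]:
    """End-free alignment of a clipped subread against the partner window.

    The clip is reverse-complemented first when the signature marks an
    opposite-orientation fusion (both clusters on the same mapping strand).
    The best placement is accepted if its edit distance is at most
    ``ceil(max_mismatch_frac * clip_len)``; the reported position is the
    placement terminus adjacent to the junction (the window's facing side of
    the target cluster: maximum coordinate when the target cluster faces
    right, minimum when it faces left).
    """
    if len(window_seq) != target.length:
        raise ValueError(
            f"window sequence for {target.chrom} has length {len(window_seq)}, "
            f"expected {target.length}"
        )
    flip = orientation.same_strand
    query = revcomp(clip.clip_seq) if flip else clip.clip_seq
    budget = math.ceil(max_mismatch_frac * clip.clip_len)
    res = edlib.align(query.upper(), window_seq.upper(), mode="HW", task="locations",
                      k=budget)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    # deterministic placement: smallest start among best-scoring locations
    loc = min((s if s is not None else 0, e) for s, e in res["locations"])
    start = target.start + loc[0]
    end = target.start + loc[1]
    # junction-adjacent terminus: breakpoint side of the *target* cluster.
    # The target cluster faces the junction from the opposite direction of the
    # window extension, i.e. the junction flank is at the window's anchored
    # ("facing") side: right-facing cluster -> use the placement's right end.
    pos = end if target.facing == "right" else start
    strand = "-" if flip else "+"
    return RealignedClip(
        source=clip,
        target_chrom=target.chrom,
        target_pos=pos,
        target_strand=strand,
        edit_distance=res["editDistance"],
    )


def _mode(coords: list[int]) -> tuple[Optional[int], int]:
    """Modal coordinate; ties break to the smallest coordinate."""
    if not coords:
        return None, 0
    counts: dict[int, int] = {}
    for c in coords:
        counts[c] = counts.get(c, 0) + 1
    best = min(counts, key=lambda c: (-counts[c], c))
    return best, counts[best]


def call_breakpoints(
    cluster: ChimericCluster,
    W: BreakWindow,
    X: BreakWindow,
    clips_W: list[SoftClip],
    clips_X: list[SoftClip],
    realigned_W_to_X: list[RealignedClip],
    realigned_X_to_W: list[RealignedClip],
) -> Optional[BreakpointCall]:
    """Resolve a cluster to a breakpoint call, or ``None`` if unsupported.

    The i-side coordinate set pools the boundaries of clips harvested in
    ``W`` with the termini of X-harvested clips realigned into ``W`` (and
    symmetrically for j). A call requires at least one successful
    realignment; a side with no coordinates falls back to the window anchor
    with zero modal support so users can filter on the support columns.
    """
    if not realigned_W_to_X and not realigned_X_to_W:
        return None
    S = [c.boundary for c in clips_W] + [r.target_pos for r in realigned_X_to_W]
    T = [c.boundary for c in clips_X] + [r.target_pos for r in realigned_W_to_X]
    bkpt_i, sup_i = _mode(S)
    bkpt_j, sup_j = _mode(T)
    if bkpt_i is None:
        bkpt_i = cluster.inner_edge("i")
        log.debug("cluster %s/%s: i-side breakpoint imputed from cluster edge",
                  cluster.chrom_i, cluster.chrom_j)
    if bkpt_j is None:
        bkpt_j = cluster.inner_edge("j")
        log.debug("cluster %s/%s: j-side breakpoint imputed from window anchor",
                  cluster.chrom_i, cluster.chrom_j)
    return BreakpointCall(
        chrom_i=cluster.chrom_i,
        bkpt_i=bkpt_i,
        chrom_j=cluster.chrom_j,
        bkpt_j=bkpt_j,
        orientation=cluster.orientation,
        n_pairs=cluster.n_pairs,
        n_clips_i=len(clips_W),
        n_clips_j=len(clips_X),
        mode_support_i=sup_i,
        mode_support_j=sup_j,
        cluster=cluster,
    )


def resolve_cluster(
    cluster: ChimericCluster,
    stats: InsertStats,
    ref_lengths: dict[str, int],
    fetch_reads: Callable[[str, int, int], Iterable[AlignedRead]],
    fetch_seq: Callable[[str, int, int], str],
    min_clip: int = 20,
    max_clips: int = 5,
    max_mismatch_frac: float = 0.1,
) -> Optional[BreakpointCall]:
    """Run the full resolution step for one cluster.

    ``fetch_reads(chrom, start, end)`` yields reads overlapping a 1-based
    inclusive region; ``fetch_seq`` returns the corresponding reference
    sequence.
    """
    W, X = build_windows(cluster, stats, ref_lengths)
    clips_W = harvest_clips(W, fetch_reads(W.chrom, W.start, W.end),
                            min_clip=min_clip, max_clips=max_clips)
    clips_X = harvest_clips(X, fetch_reads(X.chrom, X.start, X.end),
                            min_clip=min_clip, max_clips=max_clips)
    seq_W = fetch_seq(W.chrom, W.start, W.end)
    seq_X = fetch_seq(X.chrom, X.start, X.end)
    re_W = [r for c in clips_W
            if (r := realign_clip(c, X, seq_X, cluster.orientation,
                                  max_mismatch_frac)) is not None]
    re_X = [r for c in clips_X
            if (r := realign_clip(c, W, seq_W, cluster.orientation,
                                  max_mismatch_frac)) is not None]
    return call_breakpoints(cluster, W, X, clips_W, clips_X, re_W, re_X)
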