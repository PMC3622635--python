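"""End-to-end caller pipeline and tabular/VCF output.

The caller makes two streaming passes over a coordinate-sorted alignment
file: the first estimates the insert distribution and collects chimeric
pairs, which are clustered and typed and their breakpoint-search windows
laid out; the second pass harvests soft-clipped reads falling inside any
window. Clipped subreads are then realigned across each candidate fusion
and breakpoints are called and classified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import pysam
from intervaltree import IntervalTree

from . import breakpoints as bp
from . import classify as cl
from . import clustering as cluster_mod
from .sam_io import AlignedRead, InsertStats, SoftClip, extract_softclips

log = logging.getLogger(__name__)


@dataclass
class CallerConfig:
    """Tunable parameters of the caller."""

    min_mapq: int = 20
    k: float = 3.0
    min_pairs: int = 2
    min_clip: int = 20
    max_clips: int = 5
    max_mismatch_frac: float = 0.1
    recip_tol: int = 1_000_000
    insertion_site_tol: Optional[int] = None  # defaults to L
    mean: Optional[float] = None   # explicit insert mean override
    stdev: Optional[float] = None
    centromere_bed: Optional[str] = None


@dataclass
class CallerResult:
    stats: InsertStats
    clusters: list[cluster_mod.ChimericCluster]
    calls: list[bp.BreakpointCall]
    events: list[cl.EventClassification]
    unresolved: int = 0


def _reference_info(sam_path: str) -> tuple[list[str], dict[str, int]]:
    with pysam.AlignmentFile(sam_path, check_sq=False) as af:
        names = list(af.references)
        lengths = dict(zip(af.references, af.lengths))
    return names, lengths


def call_variants(
    sam_path: str,
    ref_fasta: str,
    config: CallerConfig = CallerConfig(),
) -> CallerResult:
    """Run estimate -> cluster -> resolve -> classify on one alignment file."""
    chrom_order, ref_lengths = _reference_info(sam_path)

    # pass 1: insert statistics + chimeric pair collection
    chimeric, dists = _scan_chimeric(sam_path, config.min_mapq)
    if config.mean is not None and config.stdev is not None:
        stats = InsertStats(mean=config.mean, stdev=config.stdev, k=config.k)
    else:
        stats = _insert_stats_from(dists, config.k)
    log.info("insert stats: mean=%.1f stdev=%.1f L=%.1f (%d pairs)",
             stats.mean, stats.stdev, stats.L, stats.n_pairs)

    pairs = cluster_mod.collect_chimeric_pairs(chimeric, chrom_order=chrom_order)
    clusters = cluster_mod.cluster_pairs(pairs, stats, min_pairs=config.min_pairs)
    log.info("%d chimeric pairs -> %d clusters", len(pairs), len(clusters))

    centromeres = (cluster_mod.load_centromeres(config.centromere_bed)
                   if config.centromere_bed else None)
    for c in clusters:
        cluster_mod.type_fusion(c, centromeres)

    if not clusters:
        log.info("no candidates: no chimeric clusters found")
        return CallerResult(stats=stats, clusters=[], calls=[], events=[])

    windows: list[tuple[bp.BreakWindow, bp.BreakWindow]] = [
        bp.build_windows(c, stats, ref_lengths) for c in clusters
    ]

    # pass 2: harvest soft clips falling inside any window
    trees: dict[str, IntervalTree] = {}
    for n, (W, X) in enumerate(windows):
        for w in (W, X):
            trees.setdefault(w.chrom, IntervalTree()).addi(w.start, w.end + 1, (n, w))
    window_clips = _scan_clips(sam_path, config.min_mapq, config.min_clip, trees)

    calls: list[bp.BreakpointCall] = []
    unresolved = 0
    with pysam.FastaFile(ref_fasta) as fa:
        for n, (c, (W, X)) in enumerate(zip(clusters, windows)):
            def cap(clips: list[SoftClip]) -> list[SoftClip]:
                clips = sorted(clips, key=lambda x: (x.boundary, x.read.qname))
                return clips[: config.max_clips]

            clips_W = cap(window_clips.get((n, "i"), []))
            clips_X = cap(window_clips.get((n, "j"), []))
            seq_W = fa.fetch(W.chrom, W.start - 1, W.end)
            seq_X = fa.fetch(X.chrom, X.start - 1, X.end)
            re_W = [r for s in clips_W
                    if (r := bp.realign_clip(s, X, seq_X, c.orientation,
                                             config.max_mismatch_frac))]
            re_X = [r for s in clips_X
                    if (r := bp.realign_clip(s, W, seq_W, c.orientation,
                                             config.max_mismatch_frac))]
            call = bp.call_breakpoints(c, W, X, clips_W, clips_X, re_W, re_X)
            if call is None:
                unresolved += 1
                log.debug("cluster %s:%s/%s:%s unresolved (no clip realigned)",
                          c.chrom_i, c.span_i, c.chrom_j, c.span_j)
            else:
                calls.append(call)

    site_tol = config.insertion_site_tol
    if site_tol is None:
        site_tol = stats.window
    events = cl.classify_events(calls, recip_tol=config.recip_tol,
                                insertion_site_tol=site_tol,
                                centromeres=centromeres)
    log.info("%d calls, %d unresolved clusters, %d events",
             len(calls), unresolved, len(events))
    return CallerResult(stats=stats, clusters=clusters, calls=calls,
                        events=events, unresolved=unresolved)


_FLAG_SKIP = 0x4 | 0x100 | 0x800  # unmapped | secondary | supplementary
_MAX_INSERT_SAMPLE = 200_000


def _scan_chimeric(
    sam_path: str, min_mapq: int
) -> tuple[list[AlignedRead], list[int]]:
    """Single pass: collect chimeric records and sample concordant inserts.

    Operates on raw pysam records for speed; only chimeric reads are lifted
    into :class:`AlignedRead`. Enforces coordinate sort order.
    """
    from .sam_io import SortOrderError, aligned_from_pysam

    chimeric: list[AlignedRead] = []
    dists: list[int] = []
    with pysam.AlignmentFile(sam_path, check_sq=False) as af:
        last = (-1, -1)
        for rec in af:
            flag = rec.flag
            if flag & _FLAG_SKIP:
                continue
            key = (rec.reference_id, rec.reference_start)
            if key < last:
                raise SortOrderError(
                    f"input is not coordinate-sorted at record "
                    f"{rec.query_name!r} ({rec.reference_name}:{key[1] + 1})"
                )
            last = key
            if flag & 0x400 or rec.mapping_quality < min_mapq:
                continue
            nrid = rec.next_reference_id
            if nrid >= 0 and nrid != rec.reference_id:
                chimeric.append(aligned_from_pysam(rec, af))
            elif len(dists) < _MAX_INSERT_SAMPLE:
                tlen = rec.template_length
                if tlen > 0 and not flag & 0x10 and flag & 0x20 \
                        and rec.reference_start <= rec.next_reference_start:
                    dists.append(tlen)
    return chimeric, dists


def _insert_stats_from(dists: list[int], k: float) -> InsertStats:
    import numpy as np

    from .sam_io import InsufficientPairsError
    if len(dists) < 100:
        raise InsufficientPairsError(
            f"only {len(dists)} concordant pairs found; supply explicit mean/stdev"
        )
    arr = np.asarray(dists, dtype=float)
    return InsertStats(mean=float(arr.mean()), stdev=float(arr.std()), k=k,
                       n_pairs=len(dists))


def _scan_clips(
    sam_path: str,
    min_mapq: int,
    min_clip: int,
    trees: dict[str, IntervalTree],
) -> dict[tuple[int, str], list[SoftClip]]:
    """Single pass harvesting soft clips whose boundary falls in a window."""
    from .sam_io import aligned_from_pysam

    out: dict[tuple[int, str], list[SoftClip]] = {}
    with pysam.AlignmentFile(sam_path, check_sq=False) as af:
        for rec in af:
            flag = rec.flag
            if flag & (_FLAG_SKIP | 0x400) or rec.mapping_quality < min_mapq:
                continue
            tree = trees.get(rec.reference_name)
            if tree is None:
                continue
            cig = rec.cigarstring
            if cig is None or "S" not in cig:
                continue
            read = aligned_from_pysam(rec, af)
            for clip in extract_softclips(read, min_clip=min_clip):
                for iv in tree[clip.boundary]:
                    n, w = iv.data
                    if clip.side == w.facing:
                        out.setdefault((n, w.side), []).append(clip)
    return out


# ---------------------------------------------------------------------------
# output writers
# ---------------------------------------------------------------------------

CALL_COLUMNS = ["CallId", "Chr1", "Bkpt1", "Strand1", "Chr2", "Bkpt2", "Strand2",
                "Pairs", "Clips1", "Clips2", "ModeSupport1", "ModeSupport2",
                "ArmFusion"]


def write_calls_tsv(calls: list[bp.BreakpointCall], path: str) -> None:
    """Calls as TSV (truth-table column layout plus support columns).

    Strand columns carry the cluster read *mapping* strands; the breakpoint
    lies right of a ``+`` read set and left of a ``-`` read set.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for n, c in enumerate(calls):
            arm = c.orientation.arm_fusion or "."
            fh.write(f"call{n}\t{c.chrom_i}\t{c.bkpt_i}\t{c.strand_i}\t"
                     f"{c.chrom_j}\t{c.bkpt_j}\t{c.strand_j}\t{c.n_pairs}\t"
                     f"{c.n_clips_i}\t{c.n_clips_j}\t{c.mode_support_i}\t"
                     f"{c.mode_support_j}\t{arm}\n")


def read_calls_tsv(path: str) -> list[bp.BreakpointCall]:
    from .clustering import OrientationSignature

    calls = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:7] != CALL_COLUMNS[:7]:
            raise ValueError(f"unexpected call table header: {header}")
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            sig = OrientationSignature(strand_i=f[3], strand_j=f[6])
            if len(f) > 12 and f[12] != ".":
                sig.arm_fusion = f[12]
            calls.append(bp.BreakpointCall(
                chrom_i=f[1], bkpt_i=int(f[2]), chrom_j=f[4], bkpt_j=int(f[5]),
                orientation=sig, n_pairs=int(f[7]), n_clips_i=int(f[8]),
                n_clips_j=int(f[9]), mode_support_i=int(f[10]),
                mode_support_j=int(f[11]),
            ))
    return calls


EVENT_COLUMNS = ["EventId", "Label", "CallIds", "DonorChrom", "DonorStart",
                 "DonorEnd", "RecipientChrom", "RecipientPos", "Confidence"]


def write_events_tsv(events: list[cl.EventClassification],
                     calls: list[bp.BreakpointCall], path: str) -> None:
    index = {id(c): f"call{n}" for n, c in enumerate(calls)}
    with open(path, "w") as fh:
        fh.write("\t".join(EVENT_COLUMNS) + "\n")
        for n, e in enumerate(events):
            ids = ",".join(index.get(id(c), "?") for c in e.calls)
            conf = "low" if e.low_confidence else "high"
            fh.write(f"event{n}\t{e.label}\t{ids}\t"
                     f"{e.donor_chrom or '.'}\t{e.donor_start or '.'}\t"
                     f"{e.donor_end or '.'}\t{e.recipient_chrom or '.'}\t"
                     f"{e.recipient_pos or '.'}\t{conf}\n")


def write_vcf(calls: list[bp.BreakpointCall], ref_fasta: str, path: str) -> None:
    """Paired VCF 4.2 breakend (BND) records, partnered via MATEID."""
    with pysam.FastaFile(ref_fasta) as fa, open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description='
                 '"Type of structural variant">\n')
        fh.write('##INFO=<ID=MATEID,Number=1,Type=String,Description='
                 '"ID of mate breakend">\n')
        fh.write('##INFO=<ID=PAIRS,Number=1,Type=Integer,Description='
                 '"Supporting chimeric read pairs">\n')
        for name, length in zip(fa.references, fa.lengths):
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        rows = []
        for n, c in enumerate(calls):
            for end, (chrom, pos, other_chrom, other_pos) in enumerate((
                (c.chrom_i, c.bkpt_i, c.chrom_j, c.bkpt_j),
                (c.chrom_j, c.bkpt_j, c.chrom_i, c.bkpt_i),
            )):
                side = c.side(chrom)
                other_side = c.side(other_chrom)
                ref_base = fa.fetch(chrom, pos - 1, pos).upper() or "N"
                mate = f"{other_chrom}:{other_pos}"
                if other_side == "left":
                    bracket = f"[{mate}["
                else:
                    bracket = f"]{mate}]"
                alt = ref_base + bracket if side == "right" else bracket + ref_base
                vid = f"bnd_{n}_{end}"
                mate_id = f"bnd_{n}_{1 - end}"
                rows.append((chrom, pos,
                             f"{chrom}\t{pos}\t{vid}\t{ref_base}\t{alt}\t.\tPASS\t"
                             f"SVTYPE=BND;MATEID={mate_id};PAIRS={c.n_pairs}"))
        for _, _, line in sorted(rows):
            fh.write(line + "\n")
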