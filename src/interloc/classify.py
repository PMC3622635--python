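"""Partnering of breakpoint calls into rearrangement events.

Each chimeric breakpoint call is labeled as part of an unbalanced
translocation, a balanced (reciprocal) translocation, or a direct/inverted
interchromosomal insertion. Two calls on the same chromosome pair are
partner candidates when their breakpoint sides are opposite on both
chromosomes; partnered events are labeled by a reconstructed decision rule
(the discriminating geometry is derived in the methods note):

* both calls carry the *same* mapping strand on their two chromosomes
  -> the junctions flank an inverted segment: ``INSERTION_INVERTED``;
* otherwise, if the breakpoints are reciprocal on both chromosomes (each
  separation <= ``recip_tol``, 1 Mb by default, allowing duplications or
  losses at the exchange point) -> ``BALANCED``;
* otherwise, if one chromosome's two breakpoints co-locate within
  ``insertion_site_tol`` (the insertion site) while the other's bracket a
  segment -> ``INSERTION_DIRECT``.

Anything unpartnered is an ``UNBALANCED`` translocation call.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

from .breakpoints import BreakpointCall

UNBALANCED = "UNBALANCED"
BALANCED = "BALANCED"
INSERTION_DIRECT = "INSERTION_DIRECT"
INSERTION_INVERTED = "INSERTION_INVERTED"


@dataclass
class EventClassification:
    """One classified rearrangement event (one call, or two partnered calls)."""

    calls: list[BreakpointCall]
    label: str
    donor_chrom: Optional[str] = None
    donor_start: Optional[int] = None
    donor_end: Optional[int] = None
    recipient_chrom: Optional[str] = None
    recipient_pos: Optional[int] = None
    low_confidence: bool = False

    def __post_init__(self) -> None:
        n = len(self.calls)
        if self.label == UNBALANCED and n != 1:
            raise ValueError("unbalanced events carry exactly one call")
        if self.label != UNBALANCED and n != 2:
            raise ValueError("partnered events carry exactly two calls")
        if self.label in (INSERTION_DIRECT, INSERTION_INVERTED):
            if self.donor_end is None or self.donor_start is None \
                    or self.donor_end <= self.donor_start:
                raise ValueError("insertion donor segment must be a proper interval")


def _chrom_pair(call: BreakpointCall) -> tuple[str, str]:
    return tuple(sorted((call.chrom_i, call.chrom_j)))


def _separations(a: BreakpointCall, b: BreakpointCall) -> dict[str, int]:
    return {c: abs(a.bkpt(c) - b.bkpt(c)) for c in (a.chrom_i, a.chrom_j)}


def _opposite_sides(a: BreakpointCall, b: BreakpointCall) -> bool:
    return all(a.side(c) != b.side(c) for c in (a.chrom_i, a.chrom_j))


def _label_pair(
    a: BreakpointCall,
    b: BreakpointCall,
    recip_tol: int,
    insertion_site_tol: int,
) -> Optional[EventClassification]:
    """Classify a candidate partnership, or None if the calls are unrelated."""
    if _chrom_pair(a) != _chrom_pair(b) or not _opposite_sides(a, b):
        return None
    seps = _separations(a, b)
    chroms = sorted(seps, key=lambda c: (seps[c], c))
    site_chrom, span_chrom = chroms[0], chroms[1]

    same_strand_calls = (a.strand_i == a.strand_j) and (b.strand_i == b.strand_j)
    if same_strand_calls:
        if seps[site_chrom] > insertion_site_tol:
            return None
        label = INSERTION_INVERTED
    elif max(seps.values()) <= recip_tol:
        label = BALANCED
    elif seps[site_chrom] <= insertion_site_tol:
        label = INSERTION_DIRECT
    else:
        return None

    if label == BALANCED:
        return EventClassification(calls=[a, b], label=BALANCED)
    donor, recipient = span_chrom, site_chrom
    d1, d2 = a.bkpt(donor), b.bkpt(donor)
    return EventClassification(
        calls=[a, b],
        label=label,
        donor_chrom=donor,
        donor_start=min(d1, d2),
        donor_end=max(d1, d2),
        recipient_chrom=recipient,
        recipient_pos=min(a.bkpt(recipient), b.bkpt(recipient)),
    )


def classify_events(
    calls: list[BreakpointCall],
    recip_tol: int = 1_000_000,
    insertion_site_tol: Optional[int] = None,
    centromeres: Optional[dict[str, tuple[int, int]]] = None,
) -> list[EventClassification]:
    """Partition calls into classified events.

    ``insertion_site_tol`` defaults to ``recip_tol`` when not given; in the
    pipeline it is set to the proximity length ``L``, since the two recipient
    breakpoints of an insertion arise from one physical site and should
    co-locate within paired-end uncertainty. Partnering is greedy on summed
    breakpoint proximity with a deterministic sort key, so the result is
    invariant to input order; every call joins exactly one event. Events with
    a breakpoint inside a centromere interval (when an annotation is given)
    are flagged low-confidence rather than dropped.
    """
    if insertion_site_tol is None:
        insertion_site_tol = recip_tol
    order = sorted(range(len(calls)),
                   key=lambda n: (calls[n].chrom_i, calls[n].bkpt_i,
                                  calls[n].chrom_j, calls[n].bkpt_j,
                                  calls[n].strand_i, calls[n].strand_j))
    groups: dict[tuple[str, str], list[int]] = {}
    for idx in order:
        groups.setdefault(_chrom_pair(calls[idx]), []).append(idx)

    events: list[EventClassification] = []
    for key in sorted(groups):
        idxs = groups[key]
        candidates = []
        for pa, pb in itertools.combinations(range(len(idxs)), 2):
            a, b = calls[idxs[pa]], calls[idxs[pb]]
            ev = _label_pair(a, b, recip_tol, insertion_site_tol)
            if ev is not None:
                cost = sum(_separations(a, b).values())
                candidates.append((cost, pa, pb, ev))
        used: set[int] = set()
        for cost, pa, pb, ev in sorted(candidates, key=lambda t: t[:3]):
            if pa in used or pb in used:
                continue
            used.update((pa, pb))
            events.append(ev)
        for p in range(len(idxs)):
            if p not in used:
                events.append(EventClassification(calls=[calls[idxs[p]]],
                                                  label=UNBALANCED))

    if centromeres:
        for ev in events:
            for call in ev.calls:
                for chrom, bk in ((call.chrom_i, call.bkpt_i),
                                  (call.chrom_j, call.bkpt_j)):
                    cen = centromeres.get(chrom)
                    if cen and cen[0] <= bk <= cen[1]:
                        ev.low_confidence = True
    events.sort(key=lambda e: (e.calls[0].chrom_i, e.calls[0].bkpt_i,
                               e.calls[0].chrom_j, e.calls[0].bkpt_j))
    return events
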