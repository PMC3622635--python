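"""Scoring of breakpoint calls against a simulated truth set.

Sensitivity (SE) is the fraction of true junctions matched by a call;
"specificity" (SP) is call-denominated — the fraction of calls that match a
true junction, i.e. a precision — matching how these figures are
conventionally tabulated for rearrangement callers. The average breakpoint
error (ABE) is the mean absolute difference in bases between predicted and
true junction coordinates, over both sides of every matched event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import linear_sum_assignment

from .breakpoints import BreakpointCall
from .simulate import JunctionTruth


@dataclass
class MatchedEvent:
    truth: JunctionTruth
    call: BreakpointCall
    err_a: int
    err_b: int


@dataclass
class EvalResult:
    se_num: int
    se_den: int
    sp_num: int
    sp_den: int
    abe: Optional[float]
    per_event: list[MatchedEvent] = field(default_factory=list)

    @property
    def sensitivity(self) -> float:
        return self.se_num / self.se_den if self.se_den else float("nan")

    @property
    def specificity(self) -> float:
        return self.sp_num / self.sp_den if self.sp_den else float("nan")

    def summary(self) -> str:
        abe = "N/A" if self.abe is None else f"{self.abe:.2f}"
        return (f"SE {self.se_num}/{self.se_den}\t"
                f"SP {self.sp_num}/{self.sp_den}\tABE {abe}")


def _errors(call: BreakpointCall, truth: JunctionTruth) -> Optional[tuple[int, int]]:
    """Per-side absolute errors, or None if the chromosome pairs differ."""
    pair_c = {call.chrom_i, call.chrom_j}
    pair_t = {truth.chrom_a, truth.chrom_b}
    if pair_c != pair_t:
        return None
    ea = abs(call.bkpt(truth.chrom_a) - truth.flank_a)
    eb = abs(call.bkpt(truth.chrom_b) - truth.flank_b)
    return ea, eb


def evaluate(
    calls: list[BreakpointCall],
    truth: list[JunctionTruth],
    match_tol: float,
) -> EvalResult:
    """Match calls to true junctions and score SE/SP/ABE.

    A call may match a junction when the chromosome pair agrees and both
    breakpoints are within ``match_tol``; matching is one-to-one, maximising
    the number of matched events and, among maximum matchings, minimising
    the summed breakpoint error (optimal assignment).
    """
    if not truth:
        raise ValueError("truth set must be non-empty")
    if match_tol <= 0:
        raise ValueError("match_tol must be positive")

    n_t, n_c = len(truth), len(calls)
    matches: list[MatchedEvent] = []
    if n_c:
        big = 4 * match_tol * max(n_t, n_c) + 1
        cost = np.full((n_t, n_c), big, dtype=float)
        feasible = np.zeros((n_t, n_c), dtype=bool)
        for a, t in enumerate(truth):
            for b, c in enumerate(calls):
                errs = _errors(c, t)
                if errs is not None and max(errs) <= match_tol:
                    cost[a, b] = errs[0] + errs[1]
                    feasible[a, b] = True
        rows, cols = linear_sum_assignment(cost)
        for a, b in zip(rows, cols):
            if feasible[a, b]:
                ea, eb = _errors(calls[b], truth[a])
                matches.append(MatchedEvent(truth[a], calls[b], ea, eb))

    abe = None
    if matches:
        errs = [e for m in matches for e in (m.err_a, m.err_b)]
        abe = float(np.mean(errs))
    return EvalResult(
        se_num=len(matches),
        se_den=n_t,
        sp_num=len(matches),
        sp_den=n_c,
        abe=abe,
        per_event=sorted(matches, key=lambda m: (m.truth.chrom_a, m.truth.flank_a)),
    )
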