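"""DNA stem-loop (hairpin) detection by reverse-complement self-pairing.

IS200/IS605 element ends carry subterminal hairpins that the Y1-HUH
transposase TnpA must bind for transposition; the tnpB internal inserts
carry one as well.  This module finds such structures by exhaustive
enumeration of (5' stem, loop, 3' stem) partitions, scoring simple
Watson-Crick pairing (A.T, G.C only, no G.T wobble - these hairpins act
in ssDNA transposition intermediates, not RNA).

The score is a pairing count, not a thermodynamic free energy:
``2*paired - mismatches - max(0, loop_len - 8)``.  Published Mfold
delta-G values for these structures are carried in the reference model
definitions as annotations only and never used for scoring.

Mismatches are only allowed interior to the stem: the terminal base
pairs on both the outer and the loop side must be Watson-Crick matched,
which keeps reported stem intervals stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from ._seq import is_wc_pair, revcomp

LOOP_MOTIF = "AAGCT"


@dataclass
class HairpinCall:
    """One candidate stem-loop on the input sequence (1-based closed)."""

    stem5_interval: tuple[int, int]
    stem3_interval: tuple[int, int]
    paired: int
    stem_span: int
    loop_len: int
    mismatches: int
    score: int
    loop_seq: str
    loop_motif_found: bool

    @property
    def span(self) -> tuple[int, int]:
        return (self.stem5_interval[0], self.stem3_interval[1])

    def geometry(self) -> tuple[int, int, int]:
        """(paired, stem_span, loop_len) - e.g. (8, 10, 5) for '8 of 10, loop 5'."""
        return (self.paired, self.stem_span, self.loop_len)


def _contains(outer: HairpinCall, inner: HairpinCall) -> bool:
    (o0, o1), (i0, i1) = outer.span, inner.span
    return o0 <= i0 and i1 <= o1 and (o0, o1) != (i0, i1)


def find_hairpins(
    seq: str,
    min_paired: int = 6,
    max_stem_span: int = 15,
    min_loop: int = 4,
    max_loop: int = 8,
    max_mismatch: int = 2,
) -> list[HairpinCall]:
    """All stem-loops satisfying the thresholds, best first.

    Returns calls sorted by (score desc, stem5 start asc), after removing
    any call whose full span is strictly contained in the span of a
    higher-scoring call.  Sequences too short to host a minimal hairpin
    yield an empty list.

    The default ``min_loop`` is 4 rather than the biophysical minimum of
    3: with Watson-Crick-only pairing and no stacking energetics, a loop
    whose terminal bases happen to complement (as in the conserved AAGCT
    loop, A...T) would otherwise be absorbed into the stem, shrinking a
    5-nt loop to 3 and misreporting the structure's geometry.  All
    catalogued hairpin loops here are 5-8 nt.
    """
    n = len(seq)
    if n < 2 * min_paired + min_loop:
        return []
    calls: list[HairpinCall] = []
    for span in range(min_paired, max_stem_span + 1):
        for loop in range(min_loop, max_loop + 1):
            total = 2 * span + loop
            for i in range(0, n - total + 1):
                # stem5 = [i, i+span), loop = [i+span, i+span+loop), stem3 mirrors.
                j_last = i + total - 1
                if not is_wc_pair(seq[i], seq[j_last]):
                    continue
                if not is_wc_pair(seq[i + span - 1], seq[i + span + loop]):
                    continue
                paired = 0
                for k in range(span):
                    if is_wc_pair(seq[i + k], seq[j_last - k]):
                        paired += 1
                mism = span - paired
                if paired < min_paired or mism > max_mismatch:
                    continue
                loop_seq = seq[i + span:i + span + loop]
                calls.append(
                    HairpinCall(
                        stem5_interval=(i + 1, i + span),
                        stem3_interval=(i + span + loop + 1, i + total),
                        paired=paired,
                        stem_span=span,
                        loop_len=loop,
                        mismatches=mism,
                        score=2 * paired - mism - max(0, loop - 8),
                        loop_seq=loop_seq,
                        loop_motif_found=LOOP_MOTIF in loop_seq,
                    )
                )
    calls.sort(key=lambda c: (-c.score, c.stem5_interval[0], c.span))
    kept: list[HairpinCall] = []
    for c in calls:
        if any(k.score > c.score and _contains(k, c) for k in kept):
            continue
        kept.append(c)
    return kept


def stems_overlap(a: HairpinCall, b: HairpinCall) -> bool:
    """True when any stem interval of ``a`` overlaps any stem of ``b``."""
    for s0, s1 in (a.stem5_interval, a.stem3_interval):
        for t0, t1 in (b.stem5_interval, b.stem3_interval):
            if s0 <= t1 and t0 <= s1:
                return True
    return False


@dataclass
class StructureGroup:
    """Mutually overlapping hairpin calls with co-realizability analysis.

    Two structures are mutually exclusive when their stem intervals
    overlap (the same bases cannot pair in two different stems at once);
    loop overlap alone does not exclude.  ``co_realizable`` lists the
    maximal subsets whose structures can all form simultaneously.
    """

    calls: list[HairpinCall]
    exclusive_pairs: list[tuple[int, int]]
    co_realizable: list[tuple[int, ...]]


def competing_structures(calls: list[HairpinCall]) -> list[StructureGroup]:
    """Group overlapping calls from one sequence and flag exclusivity."""
    n = len(calls)
    adj = [[False] * n for _ in range(n)]
    for i, j in combinations(range(n), 2):
        if stems_overlap(calls[i], calls[j]):
            adj[i][j] = adj[j][i] = True
    # Connected components of the stem-overlap graph.
    seen: set[int] = set()
    groups: list[StructureGroup] = []
    for root in range(n):
        if root in seen:
            continue
        comp = [root]
        seen.add(root)
        stack = [root]
        while stack:
            u = stack.pop()
            for v in range(n):
                if adj[u][v] and v not in seen:
                    seen.add(v)
                    comp.append(v)
                    stack.append(v)
        comp.sort()
        pairs = [(i, j) for i, j in combinations(comp, 2) if adj[i][j]]
        # Maximal independent sets by brute force (groups are tiny).
        indep: list[tuple[int, ...]] = []
        for r in range(len(comp), 0, -1):
            for sub in combinations(comp, r):
                if any(adj[i][j] for i, j in combinations(sub, 2)):
                    continue
                if any(set(sub) < set(big) for big in indep):
                    continue
                indep.append(sub)
        groups.append(StructureGroup(calls=[calls[i] for i in comp],
                                     exclusive_pairs=pairs,
                                     co_realizable=indep))
    return groups


def insert_disrupts(call: HairpinCall, insertion_position: int) -> bool:
    """Whether an insert beginning at ``insertion_position`` breaks the structure.

    ``insertion_position`` is the 1-based position the inserted bases
    occupy (the nucleotide previously there is pushed right).  The
    structure is disrupted iff that point falls strictly inside the
    call's stem-loop span; an insert at or before the span start, or
    anywhere past its end, leaves the structure intact.
    """
    s0, s1 = call.span
    return s0 < insertion_position <= s1
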