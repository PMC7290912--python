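"""Local alignment and boundary-extension engine.

This module provides the search primitives the annotation pipeline is
built on: an exact Gotoh (affine-gap) Smith-Waterman local aligner, a
repeated-masking genome scanner that reports every above-threshold local
match of a model sequence on both strands, fragment merging into
candidate loci, and a sliding-window boundary walker used to delimit
element ends.

The aligner is exact (no heuristic seeding): dynamic programming is run
over the full query x target matrix, with numba-compiled kernels.  The
scanner keeps a per-column "best score ending here" vector so that after
masking a reported hit only the affected column range has to be
recomputed; everything stays deterministic.

Conventions
-----------
* Intervals are 1-based closed, matching the coordinate contract used
  throughout the package.
* CIGAR operations are ``M`` (both sequences consumed; matches and
  mismatches), ``I`` (target/genome-only bases, i.e. an insertion in the
  genome relative to the model) and ``D`` (model-only bases, i.e. bases
  of the model missing from the genome).
* Gap cost for a gap of length L is ``gap_open + L * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from ._seq import encode, revcomp

NEG_INF = np.int32(-(10**7))


@dataclass(frozen=True)
class ScoringScheme:
    """BLASTN-like scoring: positive match score, positive penalties."""

    match: int = 2
    mismatch: int = 3
    gap_open: int = 5
    gap_extend: int = 2

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be > 0")
        if min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties must be >= 0")

    def max_target_span(self, query_len: int) -> int:
        # A positive-scoring local alignment can consume at most
        # query_len matched columns plus gapped target bases whose total
        # extension cost stays below the total match gain.
        ge = max(self.gap_extend, 1)
        return query_len + (query_len * self.match) // ge + 16


@njit(cache=True)
def _colmax_kernel(a, b, match, mismatch, go, ge):  # pragma: no cover - numba
    """For each target column j, best local-alignment score ending at j."""
    m = a.size
    n = b.size
    hp = np.zeros(m + 1, np.int32)
    hc = np.zeros(m + 1, np.int32)
    e = np.full(m + 1, NEG_INF, np.int32)
    colbest = np.zeros(n + 1, np.int32)
    for j in range(1, n + 1):
        bj = b[j - 1]
        f = NEG_INF
        best = np.int32(0)
        for i in range(1, m + 1):
            ei = hp[i] - go - ge
            if e[i] - ge > ei:
                ei = e[i] - ge
            fi = hc[i - 1] - go - ge
            if f - ge > fi:
                fi = f - ge
            f = fi
            if a[i - 1] == bj and a[i - 1] < 4:
                h = hp[i - 1] + match
            else:
                h = hp[i - 1] - mismatch
            if ei > h:
                h = ei
            if fi > h:
                h = fi
            if h < 0:
                h = 0
            hc[i] = h
            e[i] = ei
            if h > best:
                best = h
        colbest[j] = best
        tmp = hp
        hp = hc
        hc = tmp
    return colbest


@njit(cache=True)
def _full_kernel(a, b, match, mismatch, go, ge):  # pragma: no cover - numba
    """Full H/E/F matrices for traceback on modest problem sizes."""
    m = a.size
    n = b.size
    H = np.zeros((m + 1, n + 1), np.int32)
    E = np.full((m + 1, n + 1), NEG_INF, np.int32)
    F = np.full((m + 1, n + 1), NEG_INF, np.int32)
    for j in range(1, n + 1):
        bj = b[j - 1]
        for i in range(1, m + 1):
            ei = H[i, j - 1] - go - ge
            if E[i, j - 1] - ge > ei:
                ei = E[i, j - 1] - ge
            fi = H[i - 1, j] - go - ge
            if F[i - 1, j] - ge > fi:
                fi = F[i - 1, j] - ge
            if a[i - 1] == bj and a[i - 1] < 4:
                h = H[i - 1, j - 1] + match
            else:
                h = H[i - 1, j - 1] - mismatch
            if ei > h:
                h = ei
            if fi > h:
                h = fi
            if h < 0:
                h = 0
            H[i, j] = h
            E[i, j] = ei
            F[i, j] = fi
    return H, E, F


@dataclass
class Alignment:
    """One local alignment of ``a`` (query) against ``b`` (target)."""

    score: int
    a_interval: tuple[int, int] | None
    b_interval: tuple[int, int] | None
    cigar: list[tuple[str, int]] = field(default_factory=list)
    n_match: int = 0
    n_columns: int = 0          # all columns, gaps included
    n_aligned: int = 0          # M columns only

    @property
    def identity_pct(self) -> float:
        """Identity over aligned (M) columns; gap columns excluded.

        Internal indels are legitimate structure in decayed elements
        (inserts, deletions bridged by the affine gap model), so they do
        not count as dissimilarity.
        """
        if self.n_aligned == 0:
            return 0.0
        return 100.0 * self.n_match / self.n_aligned


def _condense(ops: list[str]) -> list[tuple[str, int]]:
    cigar: list[tuple[str, int]] = []
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return cigar


def _traceback(a, b, H, E, F, i, j, sc: ScoringScheme):
    """Deterministic traceback: diagonal preferred, then F, then E."""
    go, ge = sc.gap_open, sc.gap_extend
    cols: list[tuple[str, bool]] = []   # (op, is_match)
    ei, ej = i, j
    state = "H"
    while True:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            is_match = a[i - 1] == b[j - 1] and a[i - 1] < 4
            s = sc.match if is_match else -sc.mismatch
            if i > 0 and j > 0 and h == H[i - 1, j - 1] + s:
                cols.append(("M", is_match))
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = "F"
            elif h == E[i, j]:
                state = "E"
            else:  # pragma: no cover - recurrence guarantees a branch
                raise AssertionError("inconsistent DP matrices")
        elif state == "F":
            cols.append(("D", False))
            nxt = "H" if F[i, j] == H[i - 1, j] - go - ge else "F"
            i -= 1
            state = nxt
        else:  # E
            cols.append(("I", False))
            nxt = "H" if E[i, j] == H[i, j - 1] - go - ge else "E"
            j -= 1
            state = nxt
    cols.reverse()
    aln = Alignment(
        score=int(H[ei, ej]),
        a_interval=(i + 1, ei),
        b_interval=(j + 1, ej),
        cigar=_condense([op for op, _ in cols]),
        n_match=sum(1 for _, m in cols if m),
        n_columns=len(cols),
        n_aligned=sum(1 for op, _ in cols if op == "M"),
    )
    return aln, cols


# Tail-trim weights: matches anchor (+2), mismatches are junk (-5), gap
# columns are neutral - internal indels are score-supported structure in
# decayed elements and must never be trimmed through.
_TRIM_MATCH, _TRIM_MISMATCH = 2, 5


def _trim_alignment(aln: Alignment, cols: list[tuple[str, bool]],
                    sc: ScoringScheme) -> Alignment:
    """Trim low-identity alignment tails.

    A positive-scoring local alignment can drag short chance-match runs
    from the flanking sequence into its ends, shifting the reported
    breakpoints beyond the classifier tolerances.  Each end is cut at
    the point that maximizes the kept columns' trim weight (equivalently:
    the prefix/suffix with the most negative total is removed), then
    trimmed to terminal match columns.
    """
    n = len(cols)
    if n == 0:
        return aln
    w = [(_TRIM_MATCH if m else -_TRIM_MISMATCH) if op == "M" else 0
         for op, m in cols]
    run = best = 0
    lo = 0
    for i, x in enumerate(w, start=1):
        run += x
        if run <= best:
            best, lo = run, i
    run = best = 0
    hi = n
    for i in range(n - 1, lo - 1, -1):
        run += w[i]
        if run <= best:
            best, hi = run, i
    while lo < hi and not (cols[lo][0] == "M" and cols[lo][1]):
        lo += 1
    while hi > lo and not (cols[hi - 1][0] == "M" and cols[hi - 1][1]):
        hi -= 1
    if lo == 0 and hi == n:
        return aln
    kept = cols[lo:hi]
    if not kept:
        return aln
    da0 = sum(1 for op, _ in cols[:lo] if op in ("M", "D"))
    db0 = sum(1 for op, _ in cols[:lo] if op in ("M", "I"))
    da1 = sum(1 for op, _ in cols[hi:] if op in ("M", "D"))
    db1 = sum(1 for op, _ in cols[hi:] if op in ("M", "I"))
    cigar = _condense([op for op, _ in kept])
    score = 0
    for op, m in kept:
        if op == "M":
            score += sc.match if m else -sc.mismatch
    for op, ln in cigar:
        if op in ("I", "D"):
            score -= sc.gap_open + ln * sc.gap_extend
    return Alignment(
        score=score,
        a_interval=(aln.a_interval[0] + da0, aln.a_interval[1] - da1),
        b_interval=(aln.b_interval[0] + db0, aln.b_interval[1] - db1),
        cigar=cigar,
        n_match=sum(1 for _, m in kept if m),
        n_columns=len(kept),
        n_aligned=sum(1 for op, _ in kept if op == "M"),
    )


_MAX_TIE_CELLS = 64


def local_align(a: str, b: str, scoring: ScoringScheme | None = None) -> Alignment:
    """Optimal local alignment of ``a`` vs ``b`` under affine-gap scoring.

    Ties between co-optimal alignments are broken deterministically in
    favour of the lowest start in ``a``, then in ``b`` (then the lowest
    end coordinates).  A best score of zero is reported with ``None``
    intervals (the empty-alignment convention).
    """
    if not a or not b:
        raise ValueError("local_align requires non-empty sequences")
    sc = scoring or ScoringScheme()
    ca, cb = encode(a), encode(b)
    H, E, F = _full_kernel(ca, cb, sc.match, sc.mismatch, sc.gap_open, sc.gap_extend)
    best = int(H.max())
    if best == 0:
        return Alignment(score=0, a_interval=None, b_interval=None)
    cells = np.argwhere(H == best)
    order = np.lexsort((cells[:, 1], cells[:, 0]))
    cells = cells[order][:_MAX_TIE_CELLS]
    cands = [_traceback(ca, cb, H, E, F, int(i), int(j), sc)[0] for i, j in cells]
    return min(
        cands,
        key=lambda al: (al.a_interval[0], al.b_interval[0], al.a_interval[1], al.b_interval[1]),
    )


@dataclass
class SegmentMatch:
    """One local match of a model sequence on the genome.

    ``target_interval`` is always in forward genome coordinates; for
    minus-strand hits the CIGAR (and ``query_interval``) describe the
    alignment of the model against the reverse complement of the genome,
    i.e. the element-strand view of the locus.
    """

    query_interval: tuple[int, int]
    target_interval: tuple[int, int]
    strand: str
    score: int
    identity_pct: float
    cigar: list[tuple[str, int]] = field(default_factory=list)
    n_match: int = 0
    n_columns: int = 0

    @property
    def query_span(self) -> int:
        return self.query_interval[1] - self.query_interval[0] + 1


def _scan_one_strand(model_codes, target_codes, sc: ScoringScheme, min_score: int,
                     min_identity: float) -> list[Alignment]:
    m = model_codes.size
    n = target_codes.size
    span = sc.max_target_span(m)
    b = target_codes.copy()
    colbest = _colmax_kernel(model_codes, b, sc.match, sc.mismatch, sc.gap_open, sc.gap_extend)
    hits: list[Alignment] = []
    while True:
        j = int(np.argmax(colbest))
        best = int(colbest[j])
        if best < min_score:
            break
        w0 = max(0, j - span)
        Hw, Ew, Fw = _full_kernel(
            model_codes, b[w0:j], sc.match, sc.mismatch, sc.gap_open, sc.gap_extend
        )
        jl = j - w0
        i = int(np.argmax(Hw[:, jl]))
        aln, cols = _traceback(model_codes, b[w0:], Hw, Ew, Fw, i, jl, sc)
        b0, b1 = aln.b_interval
        aln.b_interval = (b0 + w0, b1 + w0)
        # Mask the full matched target region (pre-trim extent) and
        # refresh the affected columns.
        ts, te = aln.b_interval
        b[ts - 1:te] = 4
        aln = _trim_alignment(aln, cols, sc)
        lo = max(0, ts - 1 - span)
        hi = min(n, te + span)
        sub = _colmax_kernel(
            model_codes, b[lo:hi], sc.match, sc.mismatch, sc.gap_open, sc.gap_extend
        )
        # Columns before the mask start are unaffected; only overwrite from ts on.
        for jj in range(ts, hi + 1):
            colbest[jj] = sub[jj - lo]
        if aln.identity_pct >= min_identity:
            hits.append(aln)
    return hits


def scan_genome(
    genome: str,
    model_seq: str,
    scoring: ScoringScheme | None = None,
    min_score: int = 40,
    min_identity: float = 80.0,
    both_strands: bool = True,
) -> list[SegmentMatch]:
    """All non-overlapping local matches of ``model_seq`` in ``genome``.

    Hits are found greedily by repeated best-hit masking, independently
    on each strand; sub-threshold-identity regions are masked but not
    reported.  Minus-strand hits are mapped back to forward genome
    coordinates with ``strand='-'``.
    """
    if not genome or not model_seq:
        raise ValueError("scan_genome requires non-empty sequences")
    sc = scoring or ScoringScheme()
    mc = encode(model_seq)
    n = len(genome)
    out: list[SegmentMatch] = []
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        g = genome if strand == "+" else revcomp(genome)
        for aln in _scan_one_strand(mc, encode(g), sc, min_score, min_identity):
            ts, te = aln.b_interval
            if strand == "-":
                ts, te = n - te + 1, n - ts + 1
            out.append(
                SegmentMatch(
                    query_interval=aln.a_interval,
                    target_interval=(ts, te),
                    strand=strand,
                    score=aln.score,
                    identity_pct=aln.identity_pct,
                    cigar=aln.cigar,
                    n_match=aln.n_match,
                    n_columns=aln.n_columns,
                )
            )
    out.sort(key=lambda h: (h.target_interval, h.strand))
    return out


@dataclass
class FragmentGroup:
    """Co-linear same-strand fragments grouped into one candidate locus."""

    matches: list[SegmentMatch]
    strand: str

    @property
    def target_interval(self) -> tuple[int, int]:
        return (
            min(m.target_interval[0] for m in self.matches),
            max(m.target_interval[1] for m in self.matches),
        )

    @property
    def coverage(self) -> list[tuple[int, int]]:
        """Union of model (query) intervals, sorted and merged."""
        ivs = sorted(m.query_interval for m in self.matches)
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [tuple(iv) for iv in merged]

    @property
    def covered_nt(self) -> int:
        return sum(e - s + 1 for s, e in self.coverage)


def merge_fragments(
    matches: list[SegmentMatch],
    max_gap_nt: int = 3000,
    model_overlap_tol: int = 5,
) -> list[FragmentGroup]:
    """Group matches into candidate loci.

    Fragments are chained when they lie on the same strand, are separated
    by at most ``max_gap_nt`` on the genome, and are co-linear in model
    coordinates (model coordinates advance with the genome on '+',
    retreat on '-'), allowing at most ``model_overlap_tol`` nt of model
    overlap between consecutive fragments.  Strands are never merged.
    """
    groups: list[FragmentGroup] = []
    for m in sorted(matches, key=lambda h: h.target_interval):
        placed = False
        for g in groups:
            if g.strand != m.strand:
                continue
            last = g.matches[-1]
            gap = m.target_interval[0] - last.target_interval[1] - 1
            if gap > max_gap_nt or gap < -model_overlap_tol:
                continue
            if m.strand == "+":
                colinear = m.query_interval[0] >= last.query_interval[1] - model_overlap_tol
            else:
                colinear = m.query_interval[1] <= last.query_interval[0] + model_overlap_tol
            if colinear:
                g.matches.append(m)
                placed = True
                break
        if not placed:
            groups.append(FragmentGroup(matches=[m], strand=m.strand))
    groups.sort(key=lambda g: g.target_interval)
    return groups


@dataclass
class BoundaryResult:
    """Outcome of walking an end model outward from an anchor."""

    boundary: int          # nt of similarity found (0 if none)
    flag: str              # 'full' | 'partial' | 'absent' | 'clipped'
    offset: int            # nt of the anchor-proximal model end that were skipped


def _walk(genome: str, edge: int, direction: int, model_adj: str, offset: int,
          window: int, min_window_identity: float):
    """Single ungapped outward walk; returns (boundary, clipped)."""
    n = len(genome)
    mlen = len(model_adj)
    steps = mlen - offset
    bits: list[bool] = []
    clipped = False
    for k in range(steps):
        gpos = edge + direction * (k + 1)
        if gpos < 1 or gpos > n:
            clipped = True
            break
        bits.append(genome[gpos - 1] == model_adj[offset + k])
    thr = min_window_identity * window
    t_fail = None
    for t in range(0, len(bits) - window + 1):
        if sum(bits[t:t + window]) < thr:
            t_fail = t
            break
    if t_fail is None:
        # No dissimilar window observed: similarity up to the last match.
        boundary = max((k + 1 for k, ok in enumerate(bits) if ok), default=0)
        return boundary, clipped, False
    if t_fail == 0:
        return 0, clipped, True
    # Similarity extends through the contiguous match run spanning the
    # failing window's start, then stops.
    k = t_fail
    while k < len(bits) and bits[k]:
        k += 1
    boundary = max((p + 1 for p, ok in enumerate(bits[:k]) if ok), default=0)
    return boundary, False, True


def extend_boundary(
    genome: str,
    anchor_interval: tuple[int, int],
    end_model_adjacent_first: str,
    direction: int,
    window: int = 15,
    min_window_identity: float = 0.6,
    max_offset: int = 12,
) -> BoundaryResult:
    """Walk outward from an anchor, matching an end model until dissimilar.

    ``end_model_adjacent_first`` must be ordered from the anchor-proximal
    nucleotide to the distal one; ``direction`` is +1 (rightward of the
    anchor end) or -1 (leftward of the anchor start).  The walk compares
    genome and model position by position and stops at the first sliding
    ``window`` whose identity drops below ``min_window_identity``,
    returning the last position of similarity.  If the immediate walk
    finds nothing, anchor-proximal truncations of up to ``max_offset`` nt
    of the model are tried (decayed ends may be eroded on the ORF side).
    """
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    if not end_model_adjacent_first:
        raise ValueError("end model must be non-empty")
    edge = anchor_interval[1] if direction > 0 else anchor_interval[0]
    mlen = len(end_model_adjacent_first)

    def result_for(offset: int) -> BoundaryResult:
        boundary, clipped, failed = _walk(
            genome, edge, direction, end_model_adjacent_first, offset,
            window, min_window_identity,
        )
        if clipped:
            flag = "clipped"
        elif boundary < window:
            flag = "absent"
            boundary = boundary if boundary >= window else boundary
        elif not failed and offset == 0 and boundary >= mlen - 2:
            flag = "full"
        else:
            flag = "partial"
        if flag == "absent":
            boundary = 0
        return BoundaryResult(boundary=boundary, flag=flag, offset=offset)

    res = result_for(0)
    if res.flag not in ("absent",):
        return res
    best = res
    for off in range(1, max_offset + 1):
        r = result_for(off)
        if r.flag != "absent" and r.boundary > best.boundary:
            best = r
    return best
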