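"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming / scanning
code paths: the alignment oracle enumerates all sets of aligned position
pairs in closed form, and the hairpin oracle enumerates all
(stem5, stem3) interval pairs directly.
"""

from itertools import combinations

import numpy as np

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def oracle_local_score(a: str, b: str, match=2, mismatch=3, gap_open=5,
                       gap_extend=2) -> int:
    """Optimal local-alignment score by exhaustive enumeration.

    A local alignment is a strictly increasing sequence of aligned
    position pairs; for fixed ordered position subsets I of a and J of b
    (|I| = |J| = k) there is exactly one such pairing, scoring
    sum of match/mismatch terms minus one affine gap charge per skipped
    run.  Enumerating every (I, J) therefore covers every alignment.
    """
    m, n = len(a), len(b)
    M = np.empty((m, n), dtype=np.int64)
    for i in range(m):
        for j in range(n):
            M[i, j] = match if a[i] == b[j] else -mismatch

    def gap_costs(combos: np.ndarray) -> np.ndarray:
        if combos.shape[1] < 2:
            return np.zeros(len(combos), dtype=np.int64)
        d = np.diff(combos, axis=1) - 1
        return ((d > 0) * (gap_open + d * gap_extend)).sum(axis=1)

    best = 0
    for k in range(1, min(m, n) + 1):
        I = np.array(list(combinations(range(m), k)), dtype=np.int64)
        J = np.array(list(combinations(range(n), k)), dtype=np.int64)
        pair_sum = M[I[:, None, :], J[None, :, :]].sum(axis=-1)
        total = pair_sum - gap_costs(I)[:, None] - gap_costs(J)[None, :]
        best = max(best, int(total.max()))
    return best


def oracle_hairpins(seq: str, min_paired=6, max_stem_span=15, min_loop=4,
                    max_loop=8, max_mismatch=2) -> set[tuple]:
    """All stem-loops, enumerated over (stem5, stem3) interval pairs.

    Returns the deduplicated call set as tuples
    (stem5, stem3, paired, span, loop, score) for comparison with the
    implementation's output.
    """
    n = len(seq)
    raw = []
    for s5 in range(n):                      # 0-based stem5 start
        for s3 in range(s5 + 1, n):          # 0-based stem3 start
            for span in range(min_paired, max_stem_span + 1):
                loop = s3 - (s5 + span)
                if not (min_loop <= loop <= max_loop):
                    continue
                if s3 + span > n:
                    continue
                pairs = [
                    _COMP.get(seq[s5 + k]) == seq[s3 + span - 1 - k]
                    for k in range(span)
                ]
                if not (pairs[0] and pairs[-1]):
                    continue
                paired = sum(pairs)
                mism = span - paired
                if paired < min_paired or mism > max_mismatch:
                    continue
                score = 2 * paired - mism - max(0, loop - 8)
                raw.append(((s5 + 1, s5 + span), (s3 + 1, s3 + span),
                            paired, span, loop, score))
    kept = []
    for c in raw:
        span_c = (c[0][0], c[1][1])
        contained = any(
            o[5] > c[5]
            and o[0][0] <= span_c[0] and span_c[1] <= o[1][1]
            and (o[0][0], o[1][1]) != span_c
            for o in raw
        )
        if not contained:
            kept.append(c)
    return set(kept)
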