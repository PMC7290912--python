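"""Local aligner, genome scanner, fragment merging, boundary extension."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from is605scan._seq import random_seq, revcomp
from is605scan.align import (
    ScoringScheme,
    extend_boundary,
    local_align,
    merge_fragments,
    scan_genome,
)

from _oracles import oracle_local_score

SC = ScoringScheme()


class TestLocalAlign:
    def test_identity_case(self):
        aln = local_align("ACGT", "ACGT", SC)
        assert aln.score == 8
        assert aln.a_interval == (1, 4) and aln.b_interval == (1, 4)
        assert aln.identity_pct == 100.0

    def test_no_homology_empty_convention(self):
        aln = local_align("AAAA", "TTTT", SC)
        assert aln.score == 0
        assert aln.a_interval is None and aln.b_interval is None

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")

    def test_matches_bruteforce_oracle(self):
        # 200 seeded random pairs up to 8 nt; the oracle enumerates every
        # aligned-pair subset in closed form.
        rng = np.random.default_rng(42)
        for _ in range(200):
            la, lb = rng.integers(3, 9), rng.integers(3, 9)
            a, b = random_seq(rng, int(la)), random_seq(rng, int(lb))
            assert local_align(a, b, SC).score == oracle_local_score(a, b)

    def test_gap_alignment_cigar(self, rng):
        # One internal deletion in the target must appear as a D run.
        a = random_seq(rng, 60)
        b = a[:30] + a[38:]
        aln = local_align(a, b, SC)
        assert ("D", 8) in aln.cigar
        assert aln.identity_pct == 100.0  # gaps are not dissimilarity

    def test_tiebreak_lowest_start(self):
        # Two identical optimal placements: report the first.
        aln = local_align("ACGTT", "ACGTTACGTT", SC)
        assert aln.b_interval[0] == 1


class TestScanGenome:
    def test_exact_planted_copy(self, rng):
        model = random_seq(rng, 300)
        genome = random_seq(rng, 3000, 0.34) + model + random_seq(rng, 3000, 0.34)
        hits = scan_genome(genome, model, SC)
        assert len(hits) == 1
        h = hits[0]
        assert h.strand == "+"
        assert h.target_interval == (3001, 3300)
        assert h.identity_pct == 100.0

    def test_minus_strand_same_interval(self, rng):
        model = random_seq(rng, 300)
        genome = random_seq(rng, 2000, 0.34) + revcomp(model) + random_seq(rng, 2000, 0.34)
        hits = scan_genome(genome, model, SC)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].target_interval == (2001, 2300)

    def test_multiple_degraded_copies_at_truth_positions(self):
        rng = np.random.default_rng(7)
        model = random_seq(rng, 400)
        pieces, truth = [], []
        pos = 1
        for k in range(5):
            bg = random_seq(rng, 800, 0.34)
            frag = model[: 400 - 40 * k]          # progressively truncated
            pieces += [bg, frag]
            pos += 800
            truth.append((pos, pos + len(frag) - 1))
            pos += len(frag)
        pieces.append(random_seq(rng, 800, 0.34))
        genome = "".join(pieces)
        hits = scan_genome(genome, model, SC)
        found = sorted(h.target_interval for h in hits)
        assert len(found) == 5
        for (fs, fe), (ts, te) in zip(found, truth):
            assert abs(fs - ts) <= 12 and abs(fe - te) <= 12

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_strand_symmetry(self, seed):
        # Reverse-complementing the genome mirrors every hit.
        rng = np.random.default_rng(seed)
        model = random_seq(rng, 120)
        genome = (random_seq(rng, 500, 0.34) + model
                  + random_seq(rng, 400, 0.34) + revcomp(model)
                  + random_seq(rng, 500, 0.34))
        n = len(genome)
        fwd = scan_genome(genome, model, SC)
        rev = scan_genome(revcomp(genome), model, SC)
        mirrored = sorted(
            ((n - h.target_interval[1] + 1, n - h.target_interval[0] + 1),
             "-" if h.strand == "+" else "+")
            for h in rev
        )
        assert sorted((h.target_interval, h.strand) for h in fwd) == mirrored


class TestMergeFragments:
    def _mk(self, q, t, strand="+"):
        from is605scan.align import SegmentMatch

        return SegmentMatch(query_interval=q, target_interval=t, strand=strand,
                            score=100, identity_pct=100.0)

    def test_type5_style_fragments_group(self):
        # Two fragments covering model [1,63] and [347,405], 30 nt apart.
        groups = merge_fragments(
            [self._mk((1, 63), (1000, 1062)), self._mk((347, 405), (1093, 1151))],
            max_gap_nt=3000,
        )
        assert len(groups) == 1
        assert groups[0].coverage == [(1, 63), (347, 405)]

    def test_single_match_is_its_own_group(self):
        groups = merge_fragments([self._mk((1, 405), (50, 454))])
        assert len(groups) == 1 and len(groups[0].matches) == 1

    def test_distant_matches_stay_separate(self):
        groups = merge_fragments(
            [self._mk((1, 405), (1000, 1404)), self._mk((1, 405), (11500, 11904))],
            max_gap_nt=3000,
        )
        assert len(groups) == 2

    def test_gap_rule_enumeration(self):
        # For every gap g, grouping happens iff g <= max_gap.
        for gap in (0, 10, 100, 500, 501, 2000):
            groups = merge_fragments(
                [self._mk((1, 100), (1000, 1099)),
                 self._mk((150, 250), (1100 + gap, 1200 + gap))],
                max_gap_nt=500,
            )
            assert len(groups) == (1 if gap <= 500 else 2)

    def test_never_merges_across_strands(self):
        groups = merge_fragments(
            [self._mk((1, 100), (1000, 1099), "+"),
             self._mk((150, 250), (1150, 1250), "-")]
        )
        assert len(groups) == 2

    def test_model_overlap_tolerance(self):
        # Overlapping model coverage beyond the tolerance is not chained.
        groups = merge_fragments(
            [self._mk((1, 100), (1000, 1099)), self._mk((90, 200), (1120, 1230))],
            model_overlap_tol=5,
        )
        assert len(groups) == 2
        groups = merge_fragments(
            [self._mk((1, 100), (1000, 1099)), self._mk((97, 200), (1120, 1223))],
            model_overlap_tol=5,
        )
        assert len(groups) == 1


class TestExtendBoundary:
    @staticmethod
    def _dissimilar(chars: str) -> str:
        # Per-position guaranteed mismatch: a region of total dissimilarity.
        swap = {"A": "C", "C": "A", "G": "T", "T": "G"}
        return "".join(swap[c] for c in chars)

    def test_full_le_boundary_is_60(self, ref, rng):
        # Element with its complete 60-nt left end planted next to the anchor.
        genome = random_seq(rng, 200, 0.34) + ref.le60 + "ACGT" * 25
        res = extend_boundary(genome, (261, 300), ref.le60[::-1], direction=-1)
        assert res.boundary == 60 and res.flag == "full" and res.offset == 0

    def test_truncated_le_boundary_49_partial(self, ref):
        # LE missing the 11 nt closest to the ORF: the walk recovers the
        # remaining 49 nt through the anchor-proximal offset search.
        kept = ref.le60[:49]
        genome = "ACGT" * 30 + "ACGT" * 5 + kept + "ACGT" * 25
        # layout: pad 1..120, flank 121..140, kept 141..189, anchor from 190
        res = extend_boundary(genome, (190, 240), ref.le60[::-1], direction=-1)
        assert res.flag == "partial"
        assert res.offset == 11
        assert res.boundary == 49

    def test_no_end_flags_absent(self, ref):
        adj = ref.le60[::-1]
        flank = self._dissimilar(adj[:20])[::-1]
        genome = "ACGT" * 30 + flank + "ACGT" * 25
        res = extend_boundary(genome, (141, 161), adj, direction=-1)
        assert res.flag == "absent" and res.boundary == 0

    def test_contig_edge_clipped(self, ref):
        genome = ref.le60[30:] + "ACGT" * 10
        res = extend_boundary(genome, (31, 60), ref.le60[::-1], direction=-1)
        assert res.flag == "clipped"
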