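"""Stem-loop finder, competing-structure analysis, insert disruption."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from is605scan._seq import random_seq, revcomp
from is605scan.hairpin import (
    HairpinCall,
    competing_structures,
    find_hairpins,
    insert_disrupts,
    stems_overlap,
)
from is605scan.realization import (
    LE_HAIRPIN_SPAN,
    RE_S1,
    RE_S2,
    RE_S3,
    CORE_HAIRPIN,
)

from _oracles import oracle_hairpins


class TestFindHairpins:
    def test_constructed_palindrome_with_motif_loop(self):
        seq = "GGCGG" + "AAGCTAAA" + "CCGCC"
        calls = find_hairpins(seq, min_paired=5)
        assert len(calls) == 1
        c = calls[0]
        assert c.paired == 5 and c.stem_span == 5 and c.loop_len == 8
        assert c.loop_motif_found

    def test_poly_a_has_no_complementarity(self):
        assert find_hairpins("A" * 30, min_paired=4) == []

    def test_too_short_sequence_empty(self):
        assert find_hairpins("ACGTACG") == []

    def test_matches_enumeration_oracle(self):
        # 50 seeded 200-nt sequences: the call set must equal exhaustive
        # enumeration over all (stem5, stem3) interval pairs.
        rng = np.random.default_rng(99)
        for _ in range(50):
            seq = random_seq(rng, 200, 0.4)
            got = {
                (c.stem5_interval, c.stem3_interval, c.paired, c.stem_span,
                 c.loop_len, c.score)
                for c in find_hairpins(seq)
            }
            assert got == oracle_hairpins(seq)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_revcomp_symmetry(self, seed):
        # A hairpin is its own reverse complement: calls mirror with
        # identical geometry and score.
        seq = random_seq(np.random.default_rng(seed), 120, 0.45)
        n = len(seq)
        fwd = find_hairpins(seq)
        rev = find_hairpins(revcomp(seq))
        mirrored = sorted(
            ((n - c.stem3_interval[1] + 1, n - c.stem3_interval[0] + 1),
             (n - c.stem5_interval[1] + 1, n - c.stem5_interval[0] + 1),
             c.paired, c.score)
            for c in rev
        )
        assert sorted(
            (c.stem5_interval, c.stem3_interval, c.paired, c.score) for c in fwd
        ) == mirrored

    def test_terminal_pairs_always_match(self, rng):
        from is605scan._seq import is_wc_pair

        for _ in range(10):
            seq = random_seq(rng, 150, 0.45)
            for c in find_hairpins(seq):
                assert is_wc_pair(seq[c.stem5_interval[0] - 1],
                                  seq[c.stem3_interval[1] - 1])
                assert is_wc_pair(seq[c.stem5_interval[1] - 1],
                                  seq[c.stem3_interval[0] - 1])


class TestRealizationGeometries:
    """The packaged end/insert realizations reproduce the catalogued
    hairpin geometries as their top-scoring structures."""

    def test_le_top_call(self, ref):
        calls = find_hairpins(ref.le60)
        top = calls[0]
        assert top.geometry() == (10, 10, 8)
        assert top.span == LE_HAIRPIN_SPAN
        assert top.loop_motif_found

    def test_re_three_structures(self, ref):
        calls = find_hairpins(ref.re_t1)
        geoms = [c.geometry() for c in calls[:3]]
        assert geoms == [(11, 13, 8), (9, 11, 7), (8, 10, 5)]
        spans = {c.span for c in calls[:3]}
        assert spans == {
            (RE_S3["stem5"][0], RE_S3["stem3"][1]),
            (RE_S2["stem5"][0], RE_S2["stem3"][1]),
            (RE_S1["stem5"][0], RE_S1["stem3"][1]),
        }
        by_geom = {c.geometry(): c for c in calls[:3]}
        assert by_geom[(9, 11, 7)].loop_motif_found          # S2 carries AAGCT
        assert not by_geom[(8, 10, 5)].loop_motif_found
        assert not by_geom[(11, 13, 8)].loop_motif_found

    @pytest.mark.parametrize("kind", ["LI", "RI", "HI"])
    def test_insert_hairpin(self, ref, kind):
        calls = find_hairpins(ref.insert(kind))
        assert calls[0].geometry() == (7, 9, 5)
        assert calls[0].loop_motif_found


class TestCompetingStructures:
    def test_re_s2_s3_mutually_exclusive_s1_compatible(self, ref):
        calls = find_hairpins(ref.re_t1)[:3]
        groups = competing_structures(calls)
        grouped = next(g for g in groups if len(g.calls) > 1)
        geoms = {c.geometry() for c in grouped.calls}
        assert geoms == {(9, 11, 7), (11, 13, 8)}            # S2/S3 overlap
        assert len(grouped.exclusive_pairs) == 1
        s1_group = next(g for g in groups if len(g.calls) == 1)
        assert s1_group.calls[0].geometry() == (8, 10, 5)
        assert s1_group.co_realizable == [(0,)] or s1_group.exclusive_pairs == []

    def test_single_call_trivial_group(self):
        c = HairpinCall((1, 6), (11, 16), 6, 6, 4, 0, 12, "AAGC", False)
        groups = competing_structures([c])
        assert len(groups) == 1 and groups[0].exclusive_pairs == []

    def test_exclusivity_matrix_equals_interval_overlap(self, rng):
        # Random overlapping triples: pairwise exclusivity must equal a
        # direct interval-arithmetic check.
        for _ in range(20):
            calls = []
            for _ in range(3):
                s = int(rng.integers(1, 60))
                span = int(rng.integers(5, 10))
                loop = int(rng.integers(4, 9))
                calls.append(
                    HairpinCall((s, s + span - 1),
                                (s + span + loop, s + 2 * span + loop - 1),
                                span, span, loop, 0, 2 * span, "", False)
                )
            groups = competing_structures(calls)
            got = {frozenset(p) for g in groups for p in g.exclusive_pairs}
            direct = {
                frozenset((i, j))
                for i in range(3) for j in range(i + 1, 3)
                if stems_overlap(calls[i], calls[j])
            }
            assert got == direct


class TestInsertDisrupts:
    def test_re_insert_disrupts_s2_and_s3_not_s1(self, ref):
        from is605scan.refmodel import RE_INSERT_POSITION

        calls = find_hairpins(ref.re_t1)[:3]
        by_geom = {c.geometry(): c for c in calls}
        assert insert_disrupts(by_geom[(9, 11, 7)], RE_INSERT_POSITION)
        assert insert_disrupts(by_geom[(11, 13, 8)], RE_INSERT_POSITION)
        assert not insert_disrupts(by_geom[(8, 10, 5)], RE_INSERT_POSITION)

    def test_insert_immediately_after_s2_nt21_and_s3_nt8(self, ref):
        # The insert lands after nucleotide 21 of structure 2 and
        # nucleotide 8 of structure 3.
        from is605scan.refmodel import RE_INSERT_POSITION

        calls = find_hairpins(ref.re_t1)[:3]
        by_geom = {c.geometry(): c for c in calls}
        s2, s3 = by_geom[(9, 11, 7)], by_geom[(11, 13, 8)]
        assert RE_INSERT_POSITION - s2.span[0] == 21
        assert RE_INSERT_POSITION - s3.span[0] == 8

    def test_insert_beyond_sequence_end_false(self, ref):
        calls = find_hairpins(ref.re_t1)
        assert not insert_disrupts(calls[0], 500)

    def test_re_t2_loses_s2_s3_keeps_s1(self, ref):
        # In the realized type-2 RE the 28-nt insert physically separates
        # the S2/S3 stems; only the S1 geometry survives.
        calls = find_hairpins(ref.re_t2)
        geoms = [c.geometry() for c in calls]
        assert (8, 10, 5) in geoms
        assert (9, 11, 7) not in geoms and (11, 13, 8) not in geoms
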