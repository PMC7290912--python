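"""Locus classification and the full annotation pipeline."""

import numpy as np
import pytest

from is605scan._seq import random_seq, revcomp
from is605scan.align import merge_fragments, scan_genome
from is605scan.annotate import (
    annotate_genome,
    classify_re,
    classify_tnpa,
    classify_tnpb,
    detect_pate,
    reconstruct_orf,
)
from is605scan.catalog import compare_catalogs
from is605scan.synthetic import DecaySpec, GenomeBuilder, PateSpec, generate_genome


class TestClassifyTnpA:
    def test_full_length_is_t1(self):
        assert classify_tnpa([(1, 405)])[0] == "T1"

    def test_3prime_234_is_t2(self):
        assert classify_tnpa([(172, 405)])[0] == "T2"

    def test_t5_within_tolerance(self):
        # Slightly eroded breakpoints still match the nearest fingerprint;
        # verified against exhaustive comparison with all five.
        coverage = [(1, 60), (350, 405)]
        name, ev = classify_tnpa(coverage, tol=5)
        assert name == "T5"
        from is605scan.refmodel import TNPA_TYPES

        def unexplained(fp):
            cov = set()
            for s, e in coverage:
                cov.update(range(s, e + 1))
            ref = set()
            for s, e in fp:
                ref.update(range(s, e + 1))
            return len(cov ^ ref)

        best = min(TNPA_TYPES.values(), key=lambda t: unexplained(t.covered_intervals))
        assert best.name == "T5"

    def test_nonmatching_coverage_unclassified(self):
        assert classify_tnpa([(50, 200)])[0] == "unclassified"

    def test_empty_coverage_rejected(self):
        with pytest.raises(ValueError):
            classify_tnpa([])


ALL_TNPB = ["T1A", "T1B", "T2A", "T2Aprime", "T2B", "T2Bprime", "T2C",
            "T3", "T3prime", "MISC"]


class TestClassifyTnpB:
    @pytest.mark.parametrize("name", ALL_TNPB)
    def test_model_roundtrip(self, ref, cfg, name):
        # Plant each type's realized model in background, rescan, classify.
        rng = np.random.default_rng(hash(name) % 2**31)
        region = (random_seq(rng, 300, 0.34) + ref.tnpb_model(name)
                  + random_seq(rng, 300, 0.34))
        hits = scan_genome(region, ref.tnpb1254, cfg.scoring, cfg.min_score,
                           cfg.min_identity, both_strands=False)
        groups = merge_fragments(hits, cfg.merge_max_gap, cfg.model_overlap_tol)
        recon = reconstruct_orf(max(groups, key=lambda g: g.covered_nt).matches)
        got, inserts, disruptions, _ = classify_tnpb(recon, region, ref.insert_def, cfg)
        assert got == name
        if name == "T2Bprime":
            assert disruptions and disruptions[0].length >= 2500

    def test_t2a_insert_positions(self, ref, cfg):
        region = "ACGT" * 50 + ref.tnpb_model("T2A") + "ACGT" * 50
        hits = scan_genome(region, ref.tnpb1254, cfg.scoring, both_strands=False)
        recon = reconstruct_orf(merge_fragments(hits, model_overlap_tol=12)[0].matches)
        got, inserts, _, _ = classify_tnpb(recon, region, ref.insert_def, cfg)
        assert got == "T2A"
        kinds = {(c.kind, c.orf_position) for c in inserts}
        # LI at 433; RI at 1000 in the type-1A reference frame (= 1064 in
        # the type-2A frame, shifted by the 64-nt LI).
        assert ("LI", 433) in kinds and ("RI", 1000) in kinds


class TestClassifyRE:
    def test_consensus_is_re_t1(self, ref, cfg):
        got, iv, _ = classify_re(ref.re_t1 + "ACGT" * 10, ref.re_t1, cfg)
        assert got == "RE_T1"

    def test_28nt_insert_is_re_t2(self, ref, cfg):
        got, iv, det = classify_re(ref.re_t2 + "ACGT" * 10, ref.re_t1, cfg)
        assert got == "RE_T2"
        assert det["insert"] is not None
        assert abs(det["insert"].length - 28) <= 2

    def test_23nt_stub_is_re_misc(self, ref, cfg, rng):
        got, iv, _ = classify_re(ref.re_t1[:23] + random_seq(rng, 100, 0.34),
                                 ref.re_t1, cfg)
        assert got == "RE_MISC"

    def test_empty_window_absent(self, ref, cfg):
        assert classify_re("", ref.re_t1, cfg)[0] == "absent"

    def test_random_window_absent(self, ref, cfg, rng):
        assert classify_re(random_seq(rng, 200, 0.34), ref.re_t1, cfg)[0] == "absent"


class TestDetectPate:
    def test_planted_components(self, ref, cfg):
        b = GenomeBuilder(ref, seed=21)
        b.add_pate(PateSpec(re_type="RE_T2"))
        g, truth = b.build(6000)
        calls = detect_pate(g, ref, cfg)
        assert len(calls) == 1
        c = calls[0]
        assert c.pate_components["re_type"] == "RE_T2"
        assert abs(c.pate_components["le_fragment_nt"] - 28) <= 4
        assert 40 <= c.pate_components["tnpb_tail_nt"] <= 100

    def test_random_contig_no_pate(self, ref, cfg, rng):
        assert detect_pate(random_seq(rng, 20000, 0.34), ref, cfg) == []

    def test_three_planted_pates(self, ref, cfg):
        b = GenomeBuilder(ref, seed=22)
        for re_type in ("RE_T2", "RE_T1", "RE_T2"):
            b.add_pate(PateSpec(re_type=re_type, spacing=1500))
        g, truth = b.build(10000)
        calls = detect_pate(g, ref, cfg)
        assert len(calls) == 3
        for call, planted in zip(sorted(calls, key=lambda c: c.genome_interval),
                                 sorted(truth.pates, key=lambda e: e.genome_interval)):
            ps, pe = call.genome_interval
            ts, te = planted.genome_interval
            assert abs(ps - ts) <= 10 and abs(pe - te) <= 10

    def test_never_fires_inside_assigned_elements(self, ref, cfg):
        specs = [DecaySpec(tnpa_type="T5", tnpb_type="T2A", re_type="RE_T2"),
                 PateSpec(re_type="RE_T2")]
        g, truth = generate_genome(specs, 10000, seed=23)
        res = annotate_genome(g)
        assert len(res.pates) == 1
        for p in res.pates:
            for e in res.elements:
                assert (p.genome_interval[1] < e.genome_interval[0]
                        or p.genome_interval[0] > e.genome_interval[1])


class TestAnnotateGenome:
    def test_empty_background_no_loci(self, rng):
        assert annotate_genome(random_seq(rng, 15000, 0.34)).loci == []

    def test_tiny_genome_warns_empty(self):
        with pytest.warns(UserWarning):
            res = annotate_genome("ACGTACGT")
        assert res.loci == []

    def test_mixed_genome_exact_recovery(self):
        specs = [
            DecaySpec(tnpa_type="T1", tnpb_type="T2A", re_type="RE_T1"),
            DecaySpec(tnpa_type="T3", tnpb_type="T2Aprime", re_type="RE_T1",
                      le=("truncated", 11)),
            DecaySpec(tnpa_type="T4", tnpb_type="T3prime", re_type="RE_MISC"),
            DecaySpec(tnpa_type="IS200", tnpb_type="absent", re_type="absent"),
            PateSpec(re_type="RE_T2"),
        ]
        g, truth = generate_genome(specs, 18000, seed=31)
        res = annotate_genome(g)
        cmp = compare_catalogs(res.to_catalog_rows(), truth.to_catalog_rows())
        assert not cmp.predicted_only and not cmp.truth_only
        for f in ("tnpa_type", "tnpb_type", "le_status", "re_type", "strand_class"):
            assert cmp.field_accuracy[f] == 1.0

    def test_loci_numbered_by_distance_from_origin(self):
        specs = [DecaySpec(), DecaySpec(tnpb_type="T2B")]
        g, truth = generate_genome(specs, 14000, seed=32)
        res = annotate_genome(g)
        dists = [min(abs(l.midpoint - 1), len(g) - abs(l.midpoint - 1))
                 for l in res.elements]
        assert dists == sorted(dists)
        assert [l.locus_id for l in res.elements] == [
            str(i) for i in range(1, len(res.elements) + 1)]

    def test_classification_is_a_partition(self):
        # Every locus carries exactly one tnpA and one tnpB label from the
        # closed vocabulary.
        from is605scan.refmodel import TNPA_TYPES, TNPB_TYPES

        specs = [DecaySpec(tnpa_type="T5", tnpb_type=t) for t in
                 ("T1A", "T2B", "T3")]
        g, truth = generate_genome(specs, 14000, seed=33)
        res = annotate_genome(g)
        tnpa_vocab = set(TNPA_TYPES) | {"IS200", "absent", "unclassified"}
        tnpb_vocab = set(TNPB_TYPES) | {"absent", "unclassified"}
        assert len(res.loci) == 3
        for l in res.loci:
            assert l.tnpa_type in tnpa_vocab
            assert l.tnpb_type in tnpb_vocab

    def test_divergent_orientation_and_strand_reporting(self, ref):
        # The reported locus strand is the tnpA strand, opposite to the
        # tnpB (element) strand.
        g, truth = generate_genome([DecaySpec(strand="+")], 8000, seed=34)
        res = annotate_genome(g)
        l = res.loci[0]
        assert l.strand == "+"
        assert l.evidence["element_strand"] == "-"

    def test_hairpins_reported_on_both_ends(self):
        g, truth = generate_genome([DecaySpec(tnpb_type="T1A")], 8000, seed=35)
        res = annotate_genome(g)
        sides = {h.side for h in res.loci[0].hairpins}
        assert sides == {"LE", "RE"}
        le = next(h for h in res.loci[0].hairpins if h.side == "LE")
        assert le.call.geometry() == (10, 10, 8) and le.call.loop_motif_found
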