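"""Assemble scan results into classified IS200/IS605 element loci.

The pipeline anchors on the tnpB ORF (present in every IS605 locus of
the modelled family), pairs each tnpB locus with its divergent tnpA,
re-characterizes the locus region on the element strand, and classifies:

* tnpA decay type from reference-frame coverage fingerprints,
* tnpB type from the insert/deletion/disruption structure of the
  reconstructed ORF,
* left end (consensus / partial / absent) by boundary extension,
* right end type (RE_T1 / RE_T2 28-nt insert / RE_MISC stub),
* terminal hairpins on both ends,
* ends-only PATE-like relics anywhere outside assigned elements.

Loci are numbered by increasing circular distance from the configured
replication origin, and each receives a leading/lagging classification
of its tnpA strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from ._seq import revcomp
from .align import (
    FragmentGroup,
    SegmentMatch,
    local_align,
    merge_fragments,
    scan_genome,
)
from .catalog import CatalogRow, assign_replichore
from .config import PipelineConfig
from .hairpin import HairpinCall, find_hairpins
from .realization import ReferenceRealization, default_reference
from .refmodel import (
    InsertDef,
    RE_INSERT_LENGTH,
    RE_INSERT_POSITION,
    TNPA_TYPES,
    TNPB_REF_LENGTH,
    classify_insert,
)

MISC_FINGERPRINT = ((1, 102), (1185, 1254))
LI_SITE, RI_SITE, HI_SITE = 433, 1000, 433  # type-1A reference frame
T1B_SITE = 465
T2APRIME_DELETION = (151, 173)
T3PRIME_DELETION = (146, 173)


# ---------------------------------------------------------------------------
# ORF reconstruction

@dataclass
class InsertionEvent:
    position: int                    # model position the inserted bases occupy
    length: int
    t_interval: tuple[int, int]      # element-strand region coordinates


@dataclass
class DeletionEvent:
    position: int
    length: int


@dataclass
class OrfReconstruction:
    """Model-frame structure of one locus's ORF, from fragment CIGARs."""

    blocks: list[tuple[int, int, int, int]]      # (q0, q1, t0, t1)
    coverage: list[tuple[int, int]]
    insertions: list[InsertionEvent]
    deletions: list[DeletionEvent]
    small_insertions: list[InsertionEvent]

    @property
    def covered_nt(self) -> int:
        return sum(e - s + 1 for s, e in self.coverage)

    @property
    def t_span(self) -> tuple[int, int] | None:
        if not self.blocks:
            return None
        return (min(b[2] for b in self.blocks), max(b[3] for b in self.blocks))


def reconstruct_orf(
    matches: list[SegmentMatch],
    indel_tol: int = 4,
    min_event: int = 10,
    coverage_join_gap: int = 5,
) -> OrfReconstruction:
    """Merge element-strand fragment alignments into a model-frame structure.

    Gaps between consecutive aligned blocks are interpreted as insertions
    (genome-only bases), deletions (model-only bases) or both; gaps below
    ``min_event`` nt on the genome side are kept as small insertions (the
    type-1B single-nucleotide diagnostic), and sub-``indel_tol`` jitter is
    ignored.
    """
    blocks: list[tuple[int, int, int, int]] = []
    for m in matches:
        q, t = m.query_interval[0], m.target_interval[0]
        for op, ln in m.cigar:
            if op == "M":
                blocks.append((q, q + ln - 1, t, t + ln - 1))
                q += ln
                t += ln
            elif op == "D":
                q += ln
            else:
                t += ln
    blocks.sort(key=lambda b: (b[0], b[2]))
    merged: list[list[int]] = []
    for b in blocks:
        if merged and b[0] == merged[-1][1] + 1 and b[2] == merged[-1][3] + 1:
            merged[-1][1] = b[1]
            merged[-1][3] = b[3]
        else:
            merged.append(list(b))
    # Neighbouring fragments may claim the same model positions where a
    # chance-match tail ran past the true junction; clip the earlier
    # block back so junction events are still measurable.
    max_overlap_clip = 15
    for prev, nxt in zip(merged, merged[1:]):
        v = prev[1] - nxt[0] + 1
        if 0 < v <= max_overlap_clip and prev[1] - prev[0] + 1 > v:
            prev[1] -= v
            prev[3] -= v
    insertions: list[InsertionEvent] = []
    deletions: list[DeletionEvent] = []
    small: list[InsertionEvent] = []
    for prev, nxt in zip(merged, merged[1:]):
        g_m = nxt[0] - prev[1] - 1
        g_t = nxt[2] - prev[3] - 1
        if g_m < -indel_tol or g_t < -indel_tol:
            continue  # conflicting overlap; leave to coverage arithmetic
        g_m, g_t = max(g_m, 0), max(g_t, 0)
        pos = prev[1] + 1
        if g_t >= min_event:
            insertions.append(InsertionEvent(pos, g_t, (prev[3] + 1, nxt[2] - 1)))
        elif g_t >= 1:
            small.append(InsertionEvent(pos, g_t, (prev[3] + 1, nxt[2] - 1)))
        if g_m >= min_event:
            deletions.append(DeletionEvent(pos, g_m))
    coverage: list[list[int]] = []
    for q0, q1, _, _ in merged:
        if coverage and q0 <= coverage[-1][1] + coverage_join_gap + 1:
            coverage[-1][1] = max(coverage[-1][1], q1)
        else:
            coverage.append([q0, q1])
    return OrfReconstruction(
        blocks=[tuple(b) for b in merged],
        coverage=[tuple(c) for c in coverage],
        insertions=insertions,
        deletions=deletions,
        small_insertions=small,
    )


# ---------------------------------------------------------------------------
# Classifiers

def _fingerprint_mismatch(coverage, intervals, tol: int) -> int | None:
    """None if breakpoints disagree beyond tol, else unexplained nt."""
    if len(coverage) != len(intervals):
        return None
    for (c0, c1), (f0, f1) in zip(coverage, intervals):
        if abs(c0 - f0) > tol or abs(c1 - f1) > tol:
            return None
    cov_pos = set()
    for c0, c1 in coverage:
        cov_pos.update(range(c0, c1 + 1))
    fp_pos = set()
    for f0, f1 in intervals:
        fp_pos.update(range(f0, f1 + 1))
    return len(cov_pos ^ fp_pos)


def classify_tnpa(
    coverage: list[tuple[int, int]],
    identity_pct: float = 100.0,
    tol: int = 5,
) -> tuple[str, dict]:
    """Match reference-frame coverage against the five tnpA fingerprints.

    Returns the unique type whose breakpoints all agree within ``tol``
    nt; ambiguity is broken toward the fingerprint leaving the fewest
    unexplained nucleotides, and an exact tie (or no match) yields
    'unclassified' with the candidate list in the evidence.
    """
    if not coverage:
        raise ValueError("empty coverage")
    scored = []
    for t in TNPA_TYPES.values():
        mm = _fingerprint_mismatch(coverage, t.covered_intervals, tol)
        if mm is not None:
            scored.append((mm, t.name))
    scored.sort()
    ev = {"candidates": scored, "identity_pct": identity_pct}
    if not scored:
        return "unclassified", ev
    if len(scored) > 1 and scored[0][0] == scored[1][0]:
        return "unclassified", ev
    return scored[0][1], ev


def classify_tnpb(
    recon: OrfReconstruction,
    region_seq: str,
    insert_def: InsertDef,
    cfg: PipelineConfig | None = None,
) -> tuple[str, list["InsertCall"], list["Disruption"], dict]:
    """Decision tree over the reconstructed ORF's structural events."""
    cfg = cfg or PipelineConfig()
    tol = cfg.event_tol
    insert_calls: list[InsertCall] = []
    disruptions: list[Disruption] = []
    for ins in recon.insertions:
        t0, t1 = ins.t_interval
        if cfg.min_insert_len <= ins.length <= cfg.max_insert_len:
            cl = classify_insert(region_seq[t0 - 1:t1], insert_def, cfg.scoring)
            insert_calls.append(
                InsertCall(kind=cl.kind, orf_position=ins.position,
                           length=ins.length, t_interval=ins.t_interval,
                           evidence=cl.evidence)
            )
        elif ins.length >= cfg.disruption_min_len:
            disruptions.append(Disruption(orf_position=ins.position,
                                          length=ins.length,
                                          t_interval=ins.t_interval))

    def has(kind: str, site: int) -> bool:
        return any(c.kind == kind and abs(c.orf_position - site) <= tol
                   for c in insert_calls)

    def has_deletion(site: int, length: int) -> bool:
        return any(abs(d.position - site) <= tol and abs(d.length - length) <= tol
                   for d in recon.deletions)

    li, ri, hi = has("LI", LI_SITE), has("RI", RI_SITE), has("HI", HI_SITE)
    inter_absent = any(
        abs(d.position - HI_SITE) <= tol + 5 and d.length >= 400
        for d in recon.deletions
    )
    big_disruption = any(d.length >= cfg.disruption_t2bprime_min for d in disruptions)
    ev = {"li": li, "ri": ri, "hi": hi, "inter_insert_absent": inter_absent,
          "coverage": recon.coverage}

    name = "unclassified"
    if big_disruption and li and not ri and not hi:
        name = "T2Bprime"
    elif li and ri:
        name = "T2Aprime" if has_deletion(*T2APRIME_DELETION) else "T2A"
    elif hi and inter_absent:
        name = "T3prime" if has_deletion(*T3PRIME_DELETION) else "T3"
    elif li:
        name = "T2B"
    elif ri:
        name = "T2C"
    elif not insert_calls:
        if _fingerprint_mismatch(recon.coverage, MISC_FINGERPRINT, tol) is not None:
            name = "MISC"
        elif _fingerprint_mismatch(recon.coverage, ((1, TNPB_REF_LENGTH),), 12) is not None:
            small_at_site = any(
                s.length <= 3 and abs(s.position - T1B_SITE) <= tol
                for s in recon.small_insertions
            )
            name = "T1B" if small_at_site else "T1A"
    return name, insert_calls, disruptions, ev


def classify_re(
    end_seq: str,
    re_t1_model: str,
    cfg: PipelineConfig | None = None,
) -> tuple[str, tuple[int, int] | None, dict]:
    """Type the right end from the sequence downstream of tnpB.

    RE_T2 is a consensus RE carrying a ~28-nt insertion near model
    position 99; RE_T1 is (near-)full consensus coverage without it;
    a short anchored stub is RE_MISC; no alignment at all means absent.
    Returns (type, end interval within ``end_seq``, details).
    """
    cfg = cfg or PipelineConfig()
    if not end_seq or len(end_seq) < 12:
        return "absent", None, {}
    # The 28-nt insert splits the consensus into a 98-nt and a 34-nt
    # piece; a single bridged alignment is fragile when the short piece
    # carries noise, so the end is reconstructed from fragments exactly
    # like the ORFs.
    matches = scan_genome(end_seq, re_t1_model, cfg.scoring,
                          min_score=min(cfg.min_end_score, 25),
                          min_identity=cfg.min_identity, both_strands=False)
    groups = merge_fragments(matches, max_gap_nt=200,
                             model_overlap_tol=cfg.model_overlap_tol)
    group = _best_group(groups)
    if group is None:
        return "absent", None, {}
    recon = reconstruct_orf(group.matches)
    insert28 = next(
        (i for i in recon.insertions
         if abs(i.length - RE_INSERT_LENGTH) <= 8
         and abs(i.position - RE_INSERT_POSITION) <= cfg.event_tol),
        None,
    )
    iv = group.target_interval
    details = {"coverage": recon.coverage, "insert": insert28,
               "score": sum(m.score for m in group.matches)}
    if insert28 is not None:
        return "RE_T2", iv, details
    if recon.covered_nt >= len(re_t1_model) - 8:
        return "RE_T1", iv, details
    return "RE_MISC", iv, details


# ---------------------------------------------------------------------------
# Locus data model

@dataclass
class InsertCall:
    kind: str
    orf_position: int
    length: int
    t_interval: tuple[int, int]
    evidence: dict = field(default_factory=dict)
    genome_interval: tuple[int, int] | None = None


@dataclass
class Disruption:
    orf_position: int
    length: int
    t_interval: tuple[int, int]
    genome_interval: tuple[int, int] | None = None


@dataclass
class LocusHairpin:
    side: str                       # 'LE' | 'RE'
    call: HairpinCall
    genome_interval: tuple[int, int] | None = None


@dataclass
class ElementLocus:
    locus_id: str | None
    genome_interval: tuple[int, int]
    strand: str                      # tnpA strand (tnpB strand if tnpA absent)
    tnpa_type: str
    tnpb_type: str
    le_status: str
    re_type: str
    insert_calls: list[InsertCall] = field(default_factory=list)
    disruptions: list[Disruption] = field(default_factory=list)
    hairpins: list[LocusHairpin] = field(default_factory=list)
    strand_class: str | None = None
    is_pate: bool = False
    pate_components: dict | None = None
    evidence: dict = field(default_factory=dict)

    @property
    def midpoint(self) -> int:
        return (self.genome_interval[0] + self.genome_interval[1]) // 2

    def to_catalog_row(self) -> CatalogRow:
        return CatalogRow(
            locus=self.locus_id or "?",
            tnpa_type=self.tnpa_type,
            tnpb_type=self.tnpb_type,
            le_status=self.le_status,
            re_type=self.re_type,
            strand_class=self.strand_class,
        )


@dataclass
class AnnotationResult:
    loci: list[ElementLocus]
    genome_length: int
    config: PipelineConfig

    @property
    def elements(self) -> list[ElementLocus]:
        return [l for l in self.loci if not l.is_pate]

    @property
    def pates(self) -> list[ElementLocus]:
        return [l for l in self.loci if l.is_pate]

    def to_catalog_rows(self) -> list[CatalogRow]:
        return [l.to_catalog_row() for l in self.loci]

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "locus": l.locus_id,
                    "tnpa_type": l.tnpa_type,
                    "tnpb_type": l.tnpb_type,
                    "le": l.le_status,
                    "re": l.re_type,
                    "strand_class": l.strand_class or "N/A",
                    "strand": l.strand,
                    "start": l.genome_interval[0],
                    "end": l.genome_interval[1],
                    "n_inserts": len(l.insert_calls),
                    "n_disruptions": len(l.disruptions),
                }
                for l in self.loci
            ]
        )


# ---------------------------------------------------------------------------
# Per-locus characterization

def _best_group(groups: list[FragmentGroup]) -> FragmentGroup | None:
    return max(groups, key=lambda g: g.covered_nt) if groups else None


def _characterize_element(
    genome: str,
    tnpb_group: FragmentGroup,
    tnpa_group: FragmentGroup | None,
    ref: ReferenceRealization,
    cfg: PipelineConfig,
) -> ElementLocus:
    strand = tnpb_group.strand          # element strand: tnpB reads forward here
    L = len(genome)
    lo = tnpb_group.target_interval[0]
    hi = tnpb_group.target_interval[1]
    if tnpa_group is not None:
        lo = min(lo, tnpa_group.target_interval[0])
        hi = max(hi, tnpa_group.target_interval[1])
    iv0 = max(1, lo - cfg.region_margin)
    iv1 = min(L, hi + cfg.region_margin)
    region = genome[iv0 - 1:iv1]
    region_es = region if strand == "+" else revcomp(region)
    n = len(region_es)

    def es_to_genome(a: int, b: int) -> tuple[int, int]:
        if strand == "+":
            return (iv0 + a - 1, iv0 + b - 1)
        return (iv1 - b + 1, iv1 - a + 1)

    sc = cfg.scoring
    # tnpB structure on the element strand.
    tb_hits = scan_genome(region_es, ref.tnpb1254, sc, cfg.min_score,
                          cfg.min_identity, both_strands=False)
    tb_group = _best_group(merge_fragments(tb_hits, cfg.merge_max_gap,
                                           cfg.model_overlap_tol))
    if tb_group is None:
        recon = OrfReconstruction([], [], [], [], [])
        tnpb_type, insert_calls, disruptions, tb_ev = "absent", [], [], {}
        tb_span = None
    else:
        recon = reconstruct_orf(tb_group.matches)
        tnpb_type, insert_calls, disruptions, tb_ev = classify_tnpb(
            recon, region_es, ref.insert_def, cfg
        )
        tb_span = recon.t_span
    for c in insert_calls:
        c.genome_interval = es_to_genome(*c.t_interval)
    for d in disruptions:
        d.genome_interval = es_to_genome(*d.t_interval)

    # tnpA reads on the opposite strand; scan the reverse complement.
    region_as = revcomp(region_es)
    ta_hits = scan_genome(region_as, ref.tnpa405, sc, cfg.min_score,
                          cfg.min_identity, both_strands=False)
    ta_group = _best_group(merge_fragments(ta_hits, cfg.tnpa_merge_gap,
                                           cfg.model_overlap_tol))
    tnpa_type, ta_ev = "absent", {}
    ta_span_es = None
    if ta_group is not None and ta_group.covered_nt >= cfg.min_tnpa_nt:
        ta_recon = reconstruct_orf(ta_group.matches)
        mean_id = sum(m.identity_pct * m.n_columns for m in ta_group.matches) / max(
            1, sum(m.n_columns for m in ta_group.matches)
        )
        tnpa_type, ta_ev = classify_tnpa(ta_recon.coverage, mean_id,
                                         cfg.breakpoint_tol)
        s_as, e_as = ta_group.target_interval
        ta_span_es = (n - e_as + 1, n - s_as + 1)

    # Left end: align the LE model to the window upstream of tnpA on the
    # element strand.  (A plain outward walk is brittle here: the tnpA
    # alignment end can sit a few nt off the true ORF boundary.)
    le_status, le_boundary = "unknown", 0
    le_iv_es = None
    hairpins: list[LocusHairpin] = []
    if ta_span_es is not None:
        w1 = ta_span_es[0] - 1
        w0 = max(1, w1 - len(ref.le60) - 12)
        le_status = "absent"
        if w1 >= w0 + 10:
            laln = local_align(ref.le60, region_es[w0 - 1:w1], sc)
            if laln.score >= cfg.min_end_score and laln.a_interval is not None:
                le_boundary = laln.a_interval[1] - laln.a_interval[0] + 1
                le_status = "consensus" if le_boundary >= len(ref.le60) - 2 else "partial"
                le_iv_es = (w0 + laln.b_interval[0] - 1, w0 + laln.b_interval[1] - 1)
                le_seq = region_es[le_iv_es[0] - 1:le_iv_es[1]]
                for call in find_hairpins(le_seq)[:1]:
                    g = es_to_genome(le_iv_es[0] + call.span[0] - 1,
                                     le_iv_es[0] + call.span[1] - 1)
                    hairpins.append(LocusHairpin("LE", call, g))

    # Right end: classify the window downstream of tnpB.
    re_type, re_iv_w = "unknown", None
    if tb_span is not None:
        w0 = tb_span[1] + 1
        wseq = region_es[w0 - 1:w0 - 1 + 230]
        re_type, re_iv_w, re_ev = classify_re(wseq, ref.re_t1, cfg)
        if re_iv_w is not None:
            re_seq = wseq[re_iv_w[0] - 1:re_iv_w[1]]
            for call in find_hairpins(re_seq)[:3]:
                off = w0 + re_iv_w[0] - 1
                g = es_to_genome(off + call.span[0] - 1, off + call.span[1] - 1)
                hairpins.append(LocusHairpin("RE", call, g))

    # Element extent on the element strand: LE start .. RE end.
    if le_iv_es is not None:
        ext0 = le_iv_es[0]
    elif ta_span_es is not None:
        ext0 = ta_span_es[0]
    else:
        ext0 = tb_span[0] if tb_span else 1
    ext1 = tb_span[1] if tb_span else (ta_span_es[1] if ta_span_es else n)
    if re_iv_w is not None and tb_span is not None:
        ext1 = tb_span[1] + re_iv_w[1]
    ext0 = max(1, ext0)
    ext1 = min(n, ext1)
    g0, g1 = es_to_genome(ext0, ext1)

    locus_strand = ("-" if strand == "+" else "+") if ta_span_es is not None else strand
    return ElementLocus(
        locus_id=None,
        genome_interval=(g0, g1),
        strand=locus_strand,
        tnpa_type=tnpa_type,
        tnpb_type=tnpb_type,
        le_status=le_status,
        re_type=re_type,
        insert_calls=insert_calls,
        disruptions=disruptions,
        hairpins=hairpins,
        evidence={"tnpa": ta_ev, "tnpb": tb_ev, "le_boundary": le_boundary,
                  "element_strand": strand},
    )


def _characterize_is200(group: FragmentGroup) -> ElementLocus:
    # The single-replicate IS200 element is catalogued but, matching the
    # published treatment, not characterized further (no IS605 ends).
    return ElementLocus(
        locus_id=None,
        genome_interval=group.target_interval,
        strand=group.strand,
        tnpa_type="IS200",
        tnpb_type="absent",
        le_status="unknown",
        re_type="unknown",
        evidence={"coverage": group.coverage},
    )


# ---------------------------------------------------------------------------
# PATE detection

def _overlap_nt(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def detect_pate(
    genome: str,
    reference: ReferenceRealization | None = None,
    cfg: PipelineConfig | None = None,
    exclude_intervals: list[tuple[int, int]] = (),
    tnpb_matches: list[SegmentMatch] | None = None,
    tnpa_matches: list[SegmentMatch] | None = None,
) -> list[ElementLocus]:
    """Find ends-only (PATE-like) relics: LE/RE matches with no tnpA and
    at most a short tnpB tail, outside any assigned element interval."""
    cfg = cfg or PipelineConfig()
    ref = reference or default_reference(cfg.reference_seed)
    sc = cfg.scoring
    if len(genome) < len(ref.le60):
        return []
    le_hits = scan_genome(genome, ref.le60, sc, cfg.min_end_score, cfg.min_identity)
    re_hits = scan_genome(genome, ref.re_t1, sc, cfg.min_end_score, cfg.min_identity)
    if tnpb_matches is None:
        tnpb_matches = scan_genome(genome, ref.tnpb1254, sc, cfg.min_score,
                                   cfg.min_identity)
    if tnpa_matches is None:
        tnpa_matches = scan_genome(genome, ref.tnpa405, sc, cfg.min_score,
                                   cfg.min_identity)

    def excluded(iv: tuple[int, int]) -> bool:
        return any(_overlap_nt(iv, (x0 - 20, x1 + 20)) > 0
                   for x0, x1 in exclude_intervals)

    cands = [("LE", h) for h in le_hits if not excluded(h.target_interval)]
    cands += [("RE", h) for h in re_hits if not excluded(h.target_interval)]
    cands.sort(key=lambda kh: kh[1].target_interval)
    # Cluster by position only: the LE hairpin is near-palindromic, so a
    # genuine relic can also produce a weak opposite-strand self-hit that
    # must land in the same cluster, not found a second one.
    clusters: list[list[tuple[str, SegmentMatch]]] = []
    for kind, h in cands:
        if (clusters
                and h.target_interval[0] - max(x.target_interval[1]
                                               for _, x in clusters[-1])
                <= cfg.pate_cluster_gap):
            clusters[-1].append((kind, h))
        else:
            clusters.append([(kind, h)])

    out: list[ElementLocus] = []
    for cl in clusters:
        iv = (min(h.target_interval[0] for _, h in cl),
              max(h.target_interval[1] for _, h in cl))
        # The cluster's strand comes from its strongest hit; same-site
        # hits on the opposite strand are palindromic echoes.
        best_hit = max((h for _, h in cl), key=lambda h: h.score)
        if best_hit.score < cfg.pate_min_best_score:
            continue
        cl = [(k, h) for k, h in cl if h.strand == best_hit.strand]
        pad_iv = (iv[0] - 100, iv[1] + 100)
        tnpa_nt = sum(_overlap_nt(m.target_interval, pad_iv) for m in tnpa_matches)
        tnpb_nt = sum(_overlap_nt(m.target_interval, pad_iv) for m in tnpb_matches)
        if tnpa_nt > 30 or tnpb_nt > cfg.pate_max_tnpb_nt:
            continue
        strand = cl[0][1].strand
        le_nt = sum(h.query_span for kind, h in cl if kind == "LE")
        region = genome[max(0, iv[0] - 51):iv[1] + 50]
        region_es = region if strand == "+" else revcomp(region)
        re_type, _, _ = classify_re(region_es, ref.re_t1, cfg)
        hairpins = []
        for kind, h in cl:
            if kind != "LE":
                continue
            s0, s1 = h.target_interval
            seq = genome[s0 - 1:s1] if strand == "+" else revcomp(genome[s0 - 1:s1])
            for call in find_hairpins(seq)[:1]:
                hairpins.append(LocusHairpin("LE", call, h.target_interval))
        out.append(
            ElementLocus(
                locus_id=None,
                genome_interval=iv,
                strand=strand,
                tnpa_type="absent",
                tnpb_type="absent",
                le_status="hairpin" if le_nt else "absent",
                re_type=re_type,
                hairpins=hairpins,
                is_pate=True,
                pate_components={
                    "le_fragment_nt": le_nt,
                    "tnpb_tail_nt": tnpb_nt,
                    "re_type": re_type,
                },
            )
        )
    return out


# ---------------------------------------------------------------------------
# Full pipeline

def annotate_genome(
    genome: str,
    reference: ReferenceRealization | None = None,
    config: PipelineConfig | None = None,
) -> AnnotationResult:
    """Detect, classify and number every IS200/IS605 locus in a genome."""
    cfg = config or PipelineConfig()
    ref = reference or default_reference(cfg.reference_seed)
    L = len(genome)
    if L < len(ref.le60):
        warnings.warn("genome shorter than the smallest end model; nothing to scan")
        return AnnotationResult([], L, cfg)
    sc = cfg.scoring

    tnpb_hits = scan_genome(genome, ref.tnpb1254, sc, cfg.min_score, cfg.min_identity)
    tnpa_hits = scan_genome(genome, ref.tnpa405, sc, cfg.min_score, cfg.min_identity)
    is200_hits = scan_genome(genome, ref.is200_tnpa, sc, cfg.min_score, cfg.min_identity)

    tnpb_groups = merge_fragments(tnpb_hits, cfg.merge_max_gap, cfg.model_overlap_tol)
    tnpa_groups = merge_fragments(tnpa_hits, cfg.tnpa_merge_gap, cfg.model_overlap_tol)
    is200_groups = merge_fragments(is200_hits, cfg.tnpa_merge_gap, cfg.model_overlap_tol)

    element_tnpb = [g for g in tnpb_groups if g.covered_nt > cfg.pate_max_tnpb_nt]

    # Pair each tnpB locus with the nearest opposite-strand tnpA upstream
    # of its 5' end (divergent arrangement).
    used_tnpa: set[int] = set()
    elements: list[ElementLocus] = []
    for g in element_tnpb:
        five_prime = g.target_interval[0] if g.strand == "+" else g.target_interval[1]
        best_i, best_d = None, None
        for i, ag in enumerate(tnpa_groups):
            if i in used_tnpa or ag.strand == g.strand:
                continue
            if g.strand == "+":
                d = five_prime - ag.target_interval[1]
            else:
                d = ag.target_interval[0] - five_prime
            if -30 <= d <= cfg.pairing_max_gap:
                if best_d is None or abs(d) < abs(best_d):
                    best_i, best_d = i, d
        ag = None
        if best_i is not None:
            used_tnpa.add(best_i)
            ag = tnpa_groups[best_i]
        elements.append(_characterize_element(genome, g, ag, ref, cfg))

    for g in is200_groups:
        if g.covered_nt >= 150:
            elements.append(_characterize_is200(g))

    exclude = [e.genome_interval for e in elements]
    pates = detect_pate(genome, ref, cfg, exclude,
                        tnpb_matches=tnpb_hits, tnpa_matches=tnpa_hits)

    origin = cfg.origin_position
    terminus = cfg.terminus_position or ((origin - 1 + L // 2) % L + 1)

    def dist(l: ElementLocus) -> int:
        d = abs(l.midpoint - origin) % L
        return min(d, L - d)

    elements.sort(key=dist)
    for i, e in enumerate(elements, start=1):
        e.locus_id = str(i)
    pates.sort(key=dist)
    for i, p in enumerate(pates, start=1):
        p.locus_id = "PATE" if i == 1 else f"PATE{i}"
    for l in elements + pates:
        l.strand_class = assign_replichore(l.midpoint, l.strand, origin,
                                           terminus, L)
    return AnnotationResult(elements + pates, L, cfg)
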