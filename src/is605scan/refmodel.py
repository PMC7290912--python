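"""Declarative reference models for IS200/IS605 decay-state types.

The IS605 elements of a genome can be catalogued against two reference
ORFs - a 405-nt tnpA (the Y1-HUH transposase) and a 1254-nt tnpB (the
accessory ORF) - plus left/right end models.  Decayed copies fall into a
small set of structural types defined entirely by which reference
intervals they retain and which insertions they carry:

tnpA types (coverage of the 405-nt type-1 reference, 1-based closed)
    T1  [1,405]                          intact, 405 nt
    T2  [172,405]                        3'-most 234 nt
    T3  [172,291]                        central 120 nt
    T4  [298,405]                        3'-most 108 nt
    T5  [1,63] + [347,405]               122 nt, the commonest type

tnpB types (edits applied to the 1254-nt type-1A reference)
    T1A intact; T1B single-nt insertion at 465; T2A left + right 64-nt
    inserts (LI at 433, RI at 1064 of the edited frame) for 1382 nt;
    T2A' additionally missing 173 nt from position 151; T2B LI only
    (1318 nt); T2B' a T2B disrupted by a nested ~2.6 kb element; T2C RI
    only (1318 nt); T3 a 67-nt hybrid insert (HI) with the inter-insert
    region absent (724 nt); T3' further missing 173 nt at 146 and 52 nt
    at 422 (499 nt); MISC only the 5'-most 102 plus 3'-most 70 nt
    (172 nt).

The inserts share a 61-nt core.  LI = TCA + core (64 nt), RI = core +
GCT (64 nt), HI = TCA + core + GCT (67 nt).  The core carries two
diagnostics nine nucleotides apart: a 4-nt motif (ATAA in the LI
lineage, TAAT in the RI lineage) and a single base (A vs T); the hybrid
carries the LI motif with the RI base, the recombinant signature.

Edit positions follow the convention that "insert at position N" means
the inserted bases occupy positions N..N+len-1 of the edited ORF (the
nucleotide previously at N is pushed right).  Multi-edit types apply
their edits sequentially, each position interpreted in the frame left by
the preceding edits.

The type-3 printed length (724) does not close arithmetically from the
printed inter-insert arithmetic; the model honours the printed length by
placing the absent region between the HI and the RI site.  Likewise the
type-3' 52-nt deletion is applied sequentially, which lands it 3' of the
HI and keeps the HI (which type-3' copies demonstrably retain) intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import ScoringScheme, local_align


# ---------------------------------------------------------------------------
# tnpA

TNPA_REF_LENGTH = 405


@dataclass(frozen=True)
class TnpATypeDef:
    name: str
    covered_intervals: tuple[tuple[int, int], ...]

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.covered_intervals)


TNPA_TYPES: dict[str, TnpATypeDef] = {
    t.name: t
    for t in (
        TnpATypeDef("T1", ((1, 405),)),
        TnpATypeDef("T2", ((172, 405),)),
        TnpATypeDef("T3", ((172, 291),)),
        TnpATypeDef("T4", ((298, 405),)),
        TnpATypeDef("T5", ((1, 63), (347, 405))),
    )
}

TNPA_PRINTED_LENGTHS = {"T1": 405, "T2": 234, "T3": 120, "T4": 108, "T5": 122}


def construct_tnpA_model(type_name: str, reference_seq: str) -> str:
    """Concatenate the covered reference intervals of a tnpA type."""
    if type_name not in TNPA_TYPES:
        raise KeyError(f"unknown tnpA type: {type_name!r}")
    if len(reference_seq) != TNPA_REF_LENGTH:
        raise ValueError(f"tnpA reference must be {TNPA_REF_LENGTH} nt, got {len(reference_seq)}")
    t = TNPA_TYPES[type_name]
    return "".join(reference_seq[s - 1:e] for s, e in t.covered_intervals)


# ---------------------------------------------------------------------------
# tnpB inserts

INSERT_CORE_LENGTH = 61
LI_PREFIX = "TCA"
RI_SUFFIX = "GCT"
MOTIF_SITE = (17, 20)   # core-frame positions of the 4-nt diagnostic
BASE_SITE = 30          # core-frame position of the 1-nt diagnostic
LI_MOTIF, RI_MOTIF = "ATAA", "TAAT"
LI_BASE, RI_BASE = "A", "T"


@dataclass(frozen=True)
class InsertDef:
    """Concrete 61-nt cores for the three insert lineages.

    The three cores must be identical outside the diagnostic sites; the
    hybrid core carries the LI motif with the RI base.  Diagnostic
    positions are counted in the core frame because the LI and RI differ
    in their terminal trinucleotides, which makes absolute insert-frame
    offsets ambiguous.
    """

    core_li: str
    core_ri: str
    core_hi: str

    def __post_init__(self) -> None:
        for name, core in (("core_li", self.core_li), ("core_ri", self.core_ri),
                           ("core_hi", self.core_hi)):
            if len(core) != INSERT_CORE_LENGTH:
                raise ValueError(f"{name} must be {INSERT_CORE_LENGTH} nt")
        m0, m1 = MOTIF_SITE
        checks = (
            (self.core_li, LI_MOTIF, LI_BASE),
            (self.core_ri, RI_MOTIF, RI_BASE),
            (self.core_hi, LI_MOTIF, RI_BASE),
        )
        for core, motif, base in checks:
            if core[m0 - 1:m1] != motif or core[BASE_SITE - 1] != base:
                raise ValueError("insert core diagnostics do not match lineage definition")
        diag = set(range(m0 - 1, m1)) | {BASE_SITE - 1}
        for i in range(INSERT_CORE_LENGTH):
            if i in diag:
                continue
            if not (self.core_li[i] == self.core_ri[i] == self.core_hi[i]):
                raise ValueError("insert cores differ outside the diagnostic sites")

    def core(self, kind: str) -> str:
        return {"LI": self.core_li, "RI": self.core_ri, "HI": self.core_hi}[kind]


def build_insert(kind: str, insert_def: InsertDef) -> str:
    """Realize an LI (64 nt), RI (64 nt) or HI (67 nt) insert sequence."""
    if kind == "LI":
        return LI_PREFIX + insert_def.core_li
    if kind == "RI":
        return insert_def.core_ri + RI_SUFFIX
    if kind == "HI":
        return LI_PREFIX + insert_def.core_hi + RI_SUFFIX
    raise KeyError(f"unknown insert kind: {kind!r}")


@dataclass
class InsertClassification:
    kind: str                 # 'LI' | 'RI' | 'HI' | 'unknown'
    evidence: dict


def _trinucleotide_hit(observed: str, expected: str, min_matches: int = 2) -> bool:
    if len(observed) < len(expected):
        return False
    return sum(a == b for a, b in zip(observed, expected)) >= min_matches


def classify_insert(
    seq: str,
    insert_def: InsertDef,
    scoring: ScoringScheme | None = None,
    min_core_identity: float = 70.0,
) -> InsertClassification:
    """Classify an internal insert as LI/RI/HI by core-anchored alignment.

    The sequence is locally aligned to the 61-nt core; the terminal
    trinucleotides are then read off relative to the aligned core frame
    (TCA expected 5' of core position 1, GCT 3' of position 61), allowing
    one mismatch within each trinucleotide so that point-mutation noise
    does not flip the call.  Below-threshold core identity gives
    'unknown'.
    """
    if not seq:
        raise ValueError("empty insert sequence")
    core = insert_def.core_li  # anchor frame; lineages differ at 5 positions only
    aln = local_align(core, seq, scoring)
    unknown_ev = {"has_tca": False, "has_gct": False, "motif_state": "?",
                  "base_state": "?", "core_identity_pct": 0.0}
    if aln.score == 0:
        return InsertClassification("unknown", unknown_ev)
    core_identity = 100.0 * aln.n_match / INSERT_CORE_LENGTH
    if core_identity < min_core_identity:
        unknown_ev["core_identity_pct"] = core_identity
        return InsertClassification("unknown", unknown_ev)

    # Map core positions to seq positions through the alignment columns,
    # extrapolating ungapped past the aligned ends.
    q0, q1 = aln.a_interval
    t0, t1 = aln.b_interval
    qpos, tpos = q0, t0
    q_to_t: dict[int, int] = {}
    for op, ln in aln.cigar:
        for _ in range(ln):
            if op == "M":
                q_to_t[qpos] = tpos
                qpos += 1
                tpos += 1
            elif op == "D":
                qpos += 1
            else:  # I
                tpos += 1

    def mapped(p: int) -> int | None:
        if p in q_to_t:
            return q_to_t[p]
        if p < q0:
            t = t0 - (q0 - p)
        elif p > q1:
            t = t1 + (p - q1)
        else:
            return None
        return t if 1 <= t <= len(seq) else None

    def base_at(p: int) -> str:
        t = mapped(p)
        return seq[t - 1] if t is not None else "-"

    t_first = mapped(1)
    prefix = ""
    if t_first is not None and t_first >= 2:
        prefix = seq[max(0, t_first - 4):t_first - 1]
    t_last = mapped(INSERT_CORE_LENGTH)
    suffix = ""
    if t_last is not None:
        suffix = seq[t_last:t_last + 3]
    has_tca = _trinucleotide_hit(prefix[-3:], LI_PREFIX) if len(prefix) >= 3 else False
    has_gct = _trinucleotide_hit(suffix, RI_SUFFIX) if len(suffix) >= 3 else False
    motif = "".join(base_at(p) for p in range(MOTIF_SITE[0], MOTIF_SITE[1] + 1))
    base = base_at(BASE_SITE)
    # Primary rule: the terminal trinucleotides.  When they are
    # inconclusive (eroded or cut off by alignment-boundary jitter), fall
    # back to the full lineage signature including the internal
    # diagnostics, requiring a unique best fit of at least 3 of 4 items.
    if has_tca and has_gct:
        kind = "HI"
    elif has_tca:
        kind = "LI"
    elif has_gct:
        kind = "RI"
    else:
        kind = "unknown"
    signatures = {
        "LI": (True, False, LI_MOTIF, LI_BASE),
        "RI": (False, True, RI_MOTIF, RI_BASE),
        "HI": (True, True, LI_MOTIF, RI_BASE),
    }
    scores = {}
    for name, (exp_tca, exp_gct, exp_motif, exp_base) in signatures.items():
        s = int(has_tca == exp_tca) + int(has_gct == exp_gct)
        s += int(sum(a == b for a, b in zip(motif, exp_motif)) >= 3)
        s += int(base == exp_base)
        scores[name] = s
    if kind == "unknown":
        best = max(scores.values())
        top = [k for k, v in scores.items() if v == best]
        if best >= 3 and len(top) == 1:
            kind = top[0]
    return InsertClassification(
        kind,
        {
            "has_tca": has_tca,
            "has_gct": has_gct,
            "motif_state": motif,
            "base_state": base,
            "core_identity_pct": core_identity,
            "lineage_scores": scores,
        },
    )


# ---------------------------------------------------------------------------
# tnpB

TNPB_REF_LENGTH = 1254


@dataclass(frozen=True)
class Edit:
    kind: str                  # 'insert' | 'delete'
    position: int              # 1-based, in the frame left by preceding edits
    length: int = 0            # for deletions
    payload: str | None = None  # 'LI' | 'RI' | 'HI' | 'single_nt' | 'disruption'


@dataclass(frozen=True)
class TnpBTypeDef:
    name: str
    edits: tuple[Edit, ...]
    printed_length: int | None = None


TNPB_TYPES: dict[str, TnpBTypeDef] = {
    t.name: t
    for t in (
        TnpBTypeDef("T1A", (), 1254),
        TnpBTypeDef("T1B", (Edit("insert", 465, payload="single_nt"),)),
        TnpBTypeDef("T2A", (Edit("insert", 433, payload="LI"),
                            Edit("insert", 1064, payload="RI")), 1382),
        TnpBTypeDef("T2Aprime", (Edit("insert", 433, payload="LI"),
                                 Edit("insert", 1064, payload="RI"),
                                 Edit("delete", 151, 173))),
        TnpBTypeDef("T2B", (Edit("insert", 433, payload="LI"),), 1318),
        TnpBTypeDef("T2Bprime", (Edit("insert", 433, payload="LI"),
                                 Edit("insert", 800, payload="disruption"))),
        # RI position in the type-1A frame: 1064 - 64 (no LI precedes it).
        TnpBTypeDef("T2C", (Edit("insert", 1000, payload="RI"),), 1318),
        # Absent region placed between the HI and the RI site so that the
        # printed length closes: 432 + 67 + 225 = 724.
        TnpBTypeDef("T3", (Edit("insert", 433, payload="HI"),
                           Edit("delete", 500, 597)), 724),
        TnpBTypeDef("T3prime", (Edit("insert", 433, payload="HI"),
                                Edit("delete", 500, 597),
                                Edit("delete", 146, 173),
                                Edit("delete", 422, 52)), 499),
        TnpBTypeDef("MISC", (Edit("delete", 103, 1082),), 172),
    )
}

TNPB_PRINTED_LENGTHS = {
    name: t.printed_length for name, t in TNPB_TYPES.items() if t.printed_length
}

SINGLE_NT_PAYLOAD = "A"  # the type-1B extra nucleotide (identity not printed)
DEFAULT_DISRUPTION_LENGTH = 2600


def construct_tnpB_model(
    type_name: str,
    reference_seq: str,
    insert_def: InsertDef,
    disruption_seq: str | None = None,
) -> str:
    """Apply a tnpB type's ordered edits to the 1254-nt reference."""
    if type_name not in TNPB_TYPES:
        raise KeyError(f"unknown tnpB type: {type_name!r}")
    if len(reference_seq) != TNPB_REF_LENGTH:
        raise ValueError(f"tnpB reference must be {TNPB_REF_LENGTH} nt, got {len(reference_seq)}")
    seq = reference_seq
    for edit in TNPB_TYPES[type_name].edits:
        if edit.kind == "insert":
            payload = _payload_seq(edit.payload, insert_def, disruption_seq)
            if not 1 <= edit.position <= len(seq) + 1:
                raise ValueError(f"insert position {edit.position} out of range")
            seq = seq[:edit.position - 1] + payload + seq[edit.position - 1:]
        else:
            if edit.position - 1 + edit.length > len(seq):
                raise ValueError(f"deletion {edit.length}@{edit.position} out of range")
            seq = seq[:edit.position - 1] + seq[edit.position - 1 + edit.length:]
    t = TNPB_TYPES[type_name]
    if t.printed_length is not None and len(seq) != t.printed_length:  # pragma: no cover
        raise AssertionError(f"{type_name}: realized {len(seq)} != printed {t.printed_length}")
    return seq


def _payload_seq(payload: str | None, insert_def: InsertDef,
                 disruption_seq: str | None) -> str:
    if payload in ("LI", "RI", "HI"):
        return build_insert(payload, insert_def)
    if payload == "single_nt":
        return SINGLE_NT_PAYLOAD
    if payload == "disruption":
        if disruption_seq is None:
            raise ValueError("this type needs a disruption sequence")
        return disruption_seq
    raise KeyError(f"unknown payload: {payload!r}")


# ---------------------------------------------------------------------------
# Element ends

@dataclass(frozen=True)
class HairpinSpec:
    """Printed stem-loop geometry; delta-G is annotation only, never scored."""

    name: str
    paired: int
    stem_span: int
    loop_len: int
    loop_motif: str | None = None
    printed_dG: float | None = None

    def geometry(self) -> tuple[int, int, int]:
        return (self.paired, self.stem_span, self.loop_len)


LE_HAIRPIN = HairpinSpec("LE", 10, 10, 8, "AAGCT", 6.31)
RE_HAIRPINS = (
    HairpinSpec("S1", 8, 10, 5, None, 1.87),
    HairpinSpec("S2", 9, 11, 7, "AAGCT", 0.11),
    HairpinSpec("S3", 11, 13, 8, None, 4.96),
)
INSERT_HAIRPIN = HairpinSpec("insert", 7, 9, 5, "AAGCT", -1.54)

RE_INSERT_LENGTH = 28
RE_INSERT_POSITION = 99
RE_MISC_STUB_LENGTH = 23


@dataclass(frozen=True)
class EndDef:
    side: str                  # 'LE' | 'RE'
    name: str
    length: int
    hairpin_specs: tuple[HairpinSpec, ...] = ()
    re_insert: tuple[int, int] | None = None   # (length, position) for RE_T2


END_TYPES: dict[str, EndDef] = {
    e.name: e
    for e in (
        EndDef("LE", "LE_consensus", 60, (LE_HAIRPIN,)),
        EndDef("RE", "RE_T1", 132, RE_HAIRPINS),
        EndDef("RE", "RE_T2", 160, RE_HAIRPINS, (RE_INSERT_LENGTH, RE_INSERT_POSITION)),
        EndDef("RE", "RE_MISC", RE_MISC_STUB_LENGTH),
    )
}

END_PRINTED_LENGTHS = {"LE_consensus": 60, "RE_T1": 132, "RE_T2": 160}

INSERT_PRINTED_LENGTHS = {"LI": 64, "RI": 64, "HI": 67}
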