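"""Seeded concrete reference sequences ("reference realization").

The published element catalog defines its reference ORFs and ends by
accession and by structural constraints (lengths, hairpin geometries,
loop motifs, insert diagnostics) but does not print the sequences
themselves machine-readably.  This module therefore generates a concrete
realization: a set of seeded random sequences engineered to satisfy
every structural constraint the models state, so the whole pipeline is
exercisable without downloads.  Users with the real sequences can
substitute them via :meth:`ReferenceRealization.from_fasta`.

Hairpin-bearing sequences (left end, right end, insert core) are built
with a small pairing-constraint solver: stem positions that must pair
are linked through a union-find with complement parity, loop motifs and
insert diagnostics are pinned, designated interior stem positions are
forced to mismatch, and the remaining positions are drawn i.i.d.  Each
candidate is then validated against the package's own hairpin finder
(the designed structures must come out as the top-scoring calls, with
the printed geometries) and against cross-similarity limits (no two
distinct reference components may produce an above-threshold local
alignment, on either strand); failing candidates are redrawn, so the
result is deterministic for a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ._seq import complement_base, random_seq, revcomp
from .align import local_align
from .hairpin import find_hairpins
from .refmodel import (
    DEFAULT_DISRUPTION_LENGTH,
    BASE_SITE,
    InsertDef,
    LI_MOTIF,
    LI_BASE,
    MOTIF_SITE,
    RE_INSERT_LENGTH,
    RE_INSERT_POSITION,
    RE_MISC_STUB_LENGTH,
    RI_MOTIF,
    RI_BASE,
    TNPA_REF_LENGTH,
    TNPB_REF_LENGTH,
    build_insert,
    construct_tnpA_model,
    construct_tnpB_model,
)

DEFAULT_SEED = 605
IS200_TNPA_LENGTH = 420     # distinct IS200 transposase ORF; length not printed
ORF_GC = 0.37               # halophile-like coding GC
CROSS_SCORE_LIMIT = 40      # no two components may locally align at >= this

# Designed placements (1-based, on the respective sequence).
LE_LENGTH = 60
LE_STEM5 = (17, 26)
LE_LOOP = (27, 34)
LE_STEM3 = (35, 44)
LE_HAIRPIN_SPAN = (17, 44)          # 28 nt - exactly the PATE LE fragment

RE_LENGTH = 132
RE_S1 = {"stem5": (52, 61), "loop": (62, 66), "stem3": (67, 76), "mism": (3, 6)}
RE_S2 = {"stem5": (78, 88), "loop": (89, 95), "stem3": (96, 106), "mism": (4, 7)}
RE_S3 = {"stem5": (91, 103), "loop": (104, 111), "stem3": (112, 124), "mism": (5, 9)}

CORE_HAIRPIN = {"stem5": (36, 44), "loop": (45, 49), "stem3": (50, 58), "mism": (3, 5)}

LOOP_MOTIF = "AAGCT"


class PairingBuilder:
    """Assemble a sequence under pair/mismatch/fixed-base constraints."""

    def __init__(self, length: int, rng: np.random.Generator):
        self.n = length
        self.rng = rng
        self._parent = list(range(length))
        self._parity = [0] * length          # 0 same as root, 1 complement of root
        self._fixed: dict[int, str] = {}
        self._mispairs: list[tuple[int, int]] = []

    def _find(self, x: int) -> tuple[int, int]:
        if self._parent[x] == x:
            return x, 0
        root, par = self._find(self._parent[x])
        par ^= self._parity[x]
        self._parent[x] = root
        self._parity[x] = par
        return root, par

    def fix(self, pos: int, base: str) -> None:
        self._fixed[pos - 1] = base

    def fix_run(self, start: int, bases: str) -> None:
        for k, b in enumerate(bases):
            self.fix(start + k, b)

    def pair(self, i: int, j: int) -> None:
        """Positions i and j (1-based) must be Watson-Crick complements."""
        xi, xj = i - 1, j - 1
        ri, pi = self._find(xi)
        rj, pj = self._find(xj)
        if ri == rj:
            if pi ^ pj != 1:
                raise ValueError(f"contradictory pairing constraint at {i},{j}")
            return
        self._parent[rj] = ri
        self._parity[rj] = pi ^ pj ^ 1

    def mispair(self, i: int, j: int) -> None:
        """Positions i and j (1-based) must NOT be complements."""
        self._mispairs.append((i - 1, j - 1))

    def stem(self, stem5: tuple[int, int], stem3: tuple[int, int],
             mismatch_offsets: tuple[int, ...] = ()) -> None:
        """Constrain a stem: pair (stem5[0]+k, stem3[1]-k), except offsets."""
        s0, s1 = stem5
        e1 = stem3[1]
        span = s1 - s0 + 1
        for k in range(span):
            if k in mismatch_offsets:
                self.mispair(s0 + k, e1 - k)
            else:
                self.pair(s0 + k, e1 - k)

    def realize(self) -> str:
        classes: dict[int, list[tuple[int, int]]] = {}
        for x in range(self.n):
            r, p = self._find(x)
            classes.setdefault(r, []).append((x, p))
        seq: list[str] = [""] * self.n
        for members in classes.values():
            root_base: str | None = None
            for x, p in members:
                if x in self._fixed:
                    b = self._fixed[x] if p == 0 else complement_base(self._fixed[x])
                    if root_base is not None and b != root_base:
                        raise ValueError("fixed bases conflict with pairing constraints")
                    root_base = b
            if root_base is None:
                root_base = "ACGT"[self.rng.integers(4)]
            for x, p in members:
                seq[x] = root_base if p == 0 else complement_base(root_base)
        # Enforce must-not-pair constraints by redrawing a free side.
        degree: dict[int, int] = {}
        for i, j in self._mispairs:
            degree[i] = degree.get(i, 0) + 1
            degree[j] = degree.get(j, 0) + 1
        class_size = {x: len(classes[self._find(x)[0]]) for x in range(self.n)}
        for i, j in self._mispairs:
            if seq[i] != complement_base(seq[j]):
                continue
            for cand, other in ((i, j), (j, i)):
                if class_size[cand] == 1 and cand not in self._fixed and degree[cand] == 1:
                    choices = [b for b in "ACGT" if b != complement_base(seq[other])]
                    seq[cand] = choices[self.rng.integers(len(choices))]
                    break
            else:
                raise ValueError("mismatch constraint has no free side")
        return "".join(seq)


def _top_calls(seq: str):
    return find_hairpins(seq)


def _call_matches(call, geometry: tuple[int, int, int], span: tuple[int, int],
                  motif: bool) -> bool:
    return (call.geometry() == geometry and call.span == span
            and call.loop_motif_found == motif)


def _build_le(rng: np.random.Generator, max_attempts: int = 500) -> str:
    for _ in range(max_attempts):
        b = PairingBuilder(LE_LENGTH, rng)
        b.stem(LE_STEM5, LE_STEM3)
        b.fix_run(LE_LOOP[0], LOOP_MOTIF)
        # Guard the perfect stem against outward extension: the three
        # flanking pairs must not complement (a 10/10 stem could otherwise
        # grow to a higher-scoring 11/11..13/13 variant).
        for d in (1, 2, 3):
            b.mispair(LE_STEM5[0] - d, LE_STEM3[1] + d)
        # ... and against inward absorption of the loop termini.
        b.mispair(LE_LOOP[0], LE_LOOP[1])
        seq = b.realize()
        calls = _top_calls(seq)
        if not calls:
            continue
        if not _call_matches(calls[0], (10, 10, 8), LE_HAIRPIN_SPAN, True):
            continue
        if len(calls) > 1 and calls[1].score >= calls[0].score:
            continue
        return seq
    raise RuntimeError("could not realize a valid LE sequence")


def _build_re(rng: np.random.Generator, max_attempts: int = 2000) -> str:
    expect = (
        ((11, 13, 8), (RE_S3["stem5"][0], RE_S3["stem3"][1]), False),
        ((9, 11, 7), (RE_S2["stem5"][0], RE_S2["stem3"][1]), True),
        ((8, 10, 5), (RE_S1["stem5"][0], RE_S1["stem3"][1]), False),
    )
    for _ in range(max_attempts):
        b = PairingBuilder(RE_LENGTH, rng)
        for spec in (RE_S1, RE_S2, RE_S3):
            b.stem(spec["stem5"], spec["stem3"], spec["mism"])
            # One flank guard per structure: with two interior mismatches
            # already spent, blocking the first outward pair is enough to
            # stop any higher-scoring extended variant.
            b.mispair(spec["stem5"][0] - 1, spec["stem3"][1] + 1)
            if spec["loop"][1] - spec["loop"][0] + 1 > 5:
                # Loops longer than 5 could shrink by one absorbed pair and
                # still clear min_loop; keep their termini unpaired.
                b.mispair(spec["loop"][0], spec["loop"][1])
        b.fix_run(RE_S2["loop"][0], LOOP_MOTIF)
        try:
            seq = b.realize()
        except ValueError:
            continue
        calls = _top_calls(seq)
        if len(calls) < 3:
            continue
        if not all(_call_matches(c, g, s, m) for c, (g, s, m) in zip(calls[:3], expect)):
            continue
        if len(calls) > 3 and calls[3].score >= calls[2].score:
            continue
        return seq
    raise RuntimeError("could not realize a valid RE sequence")


def _build_cores(rng: np.random.Generator, max_attempts: int = 500) -> tuple[str, str, str]:
    hp = CORE_HAIRPIN
    span = (hp["stem5"][0], hp["stem3"][1])
    for _ in range(max_attempts):
        b = PairingBuilder(61, rng)
        b.stem(hp["stem5"], hp["stem3"], hp["mism"])
        b.mispair(hp["stem5"][0] - 1, hp["stem3"][1] + 1)  # block stem extension
        b.fix_run(hp["loop"][0], LOOP_MOTIF)
        b.fix_run(MOTIF_SITE[0], LI_MOTIF)
        b.fix(BASE_SITE, LI_BASE)
        try:
            core_li = b.realize()
        except ValueError:
            continue
        m0 = MOTIF_SITE[0] - 1
        core_ri = (core_li[:m0] + RI_MOTIF + core_li[m0 + 4:BASE_SITE - 1]
                   + RI_BASE + core_li[BASE_SITE:])
        core_hi = core_li[:BASE_SITE - 1] + RI_BASE + core_li[BASE_SITE:]
        ok = True
        for core in (core_li, core_ri, core_hi):
            calls = _top_calls(core)
            if not calls or not _call_matches(calls[0], (7, 9, 5), span, True):
                ok = False
                break
            if len(calls) > 1 and calls[1].score >= calls[0].score:
                ok = False
                break
        if ok:
            return core_li, core_ri, core_hi
    raise RuntimeError("could not realize valid insert cores")


def _cross_clean(candidate: str, others: list[str]) -> bool:
    for o in others:
        for target in (o, revcomp(o)):
            if local_align(candidate, target).score >= CROSS_SCORE_LIMIT:
                return False
    if local_align(candidate, revcomp(candidate)).score >= CROSS_SCORE_LIMIT:
        return False
    return True


def _build_random(rng: np.random.Generator, length: int, others: list[str],
                  gc: float = ORF_GC, max_attempts: int = 50) -> str:
    for _ in range(max_attempts):
        seq = random_seq(rng, length, gc)
        if _cross_clean(seq, others):
            return seq
    raise RuntimeError(f"could not draw a {length}-nt sequence clear of cross-matches")


@dataclass(frozen=True)
class ReferenceRealization:
    """Concrete reference sequences satisfying every structural constraint."""

    seed: int | None
    tnpa405: str
    tnpb1254: str
    is200_tnpa: str
    le60: str
    re_t1: str
    re28: str
    core_li: str
    core_ri: str
    core_hi: str
    disruption: str

    @classmethod
    def from_seed(cls, seed: int = DEFAULT_SEED) -> "ReferenceRealization":
        rng = np.random.default_rng(seed)
        le60 = _build_le(rng)
        re_t1 = _build_re(rng)
        core_li, core_ri, core_hi = _build_cores(rng)
        built = [le60, re_t1, core_li]
        tnpa405 = _build_random(rng, TNPA_REF_LENGTH, built)
        built.append(tnpa405)
        tnpb1254 = _build_random(rng, TNPB_REF_LENGTH, built)
        built.append(tnpb1254)
        is200 = _build_random(rng, IS200_TNPA_LENGTH, built)
        built.append(is200)
        re28 = _build_random(rng, RE_INSERT_LENGTH, built)
        built.append(re28)
        disruption = _build_random(rng, DEFAULT_DISRUPTION_LENGTH, built)
        return cls(
            seed=seed, tnpa405=tnpa405, tnpb1254=tnpb1254, is200_tnpa=is200,
            le60=le60, re_t1=re_t1, re28=re28,
            core_li=core_li, core_ri=core_ri, core_hi=core_hi,
            disruption=disruption,
        )

    @classmethod
    def from_fasta(cls, path) -> "ReferenceRealization":
        """Load a realization (e.g. real accession sequences) from FASTA.

        Records must be named ``tnpa_ref`` (405 nt), ``tnpb_ref``
        (1254 nt), ``is200_tnpa``, ``le`` (60 nt), ``re_t1`` (132 nt),
        ``re_insert28``, ``core_li``, ``core_ri``, ``core_hi`` and
        ``disruption``; missing records fall back to the default seeded
        realization.
        """
        from Bio import SeqIO

        records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
        fallback = default_reference()
        return cls(
            seed=None,
            tnpa405=records.get("tnpa_ref", fallback.tnpa405),
            tnpb1254=records.get("tnpb_ref", fallback.tnpb1254),
            is200_tnpa=records.get("is200_tnpa", fallback.is200_tnpa),
            le60=records.get("le", fallback.le60),
            re_t1=records.get("re_t1", fallback.re_t1),
            re28=records.get("re_insert28", fallback.re28),
            core_li=records.get("core_li", fallback.core_li),
            core_ri=records.get("core_ri", fallback.core_ri),
            core_hi=records.get("core_hi", fallback.core_hi),
            disruption=records.get("disruption", fallback.disruption),
        )

    def to_fasta(self, path) -> None:
        names = ["tnpa_ref", "tnpb_ref", "is200_tnpa", "le", "re_t1",
                 "re_insert28", "core_li", "core_ri", "core_hi", "disruption"]
        seqs = [self.tnpa405, self.tnpb1254, self.is200_tnpa, self.le60,
                self.re_t1, self.re28, self.core_li, self.core_ri,
                self.core_hi, self.disruption]
        with open(path, "w") as fh:
            for name, seq in zip(names, seqs):
                fh.write(f">{name}\n{seq}\n")

    # -- derived sequences ---------------------------------------------------

    @property
    def insert_def(self) -> InsertDef:
        return InsertDef(core_li=self.core_li, core_ri=self.core_ri, core_hi=self.core_hi)

    @property
    def re_t2(self) -> str:
        p = RE_INSERT_POSITION
        return self.re_t1[:p - 1] + self.re28 + self.re_t1[p - 1:]

    def insert(self, kind: str) -> str:
        return build_insert(kind, self.insert_def)

    def tnpa_model(self, type_name: str) -> str:
        return construct_tnpA_model(type_name, self.tnpa405)

    def tnpb_model(self, type_name: str) -> str:
        return construct_tnpB_model(type_name, self.tnpb1254, self.insert_def,
                                    disruption_seq=self.disruption)

    def end_seq(self, name: str) -> str:
        if name in ("LE", "LE_consensus"):
            return self.le60
        if name == "RE_T1":
            return self.re_t1
        if name == "RE_T2":
            return self.re_t2
        if name == "RE_MISC":
            return self.re_t1[:RE_MISC_STUB_LENGTH]
        raise KeyError(f"unknown end name: {name!r}")

    def le_hairpin_fragment(self) -> str:
        """The 28-nt hairpin-containing LE fragment (the PATE LE piece)."""
        s, e = LE_HAIRPIN_SPAN
        return self.le60[s - 1:e]

    def tnpb_tail(self, n: int = 58) -> str:
        """The 3'-most n nucleotides of the tnpB ORF (the PATE tail piece)."""
        return self.tnpb1254[-n:]

    def pate_seq(self, re_type: str = "RE_T2") -> str:
        return self.le_hairpin_fragment() + self.tnpb_tail() + self.end_seq(re_type)


@lru_cache(maxsize=4)
def default_reference(seed: int = DEFAULT_SEED) -> ReferenceRealization:
    return ReferenceRealization.from_seed(seed)
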