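"""Seeded synthetic genomes with planted IS605 elements and truth.

The generator plants elements in specified decay states - any tnpA type
x tnpB type combination, consensus/truncated/absent left ends, all right
end types, the nested ~2.6 kb disruption of type-2B' copies, point
mutation noise - on an i.i.d. random background (default 34% GC,
halophile-like), together with a machine-readable ground truth.  This
gives the whole pipeline a closed test loop with no downloads: the
catalog recovered by :func:`is605scan.annotate.annotate_genome` can be
diffed against what was planted.

Layout convention (matching the element model): on the element strand,
an element reads  LE | revcomp(tnpA) | tnpB | RE , i.e. tnpA and tnpB
are divergently oriented, the LE lies downstream of tnpA and the RE
downstream of tnpB.  A DecaySpec's ``strand`` is the strand the *tnpA*
ORF reads on (the classification variable of the published catalog); the
element strand is its opposite.

Mutation noise uses common random numbers: for a given generator seed,
the per-position uniform draws deciding whether a site mutates are
independent of the rate, so the mutated position sets are nested across
rates.  Label-recovery curves over a rate grid are then monotone by
construction rather than by sampling luck.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._seq import encode, decode, random_seq, revcomp
from .catalog import CatalogRow, assign_replichore
from .realization import ReferenceRealization, default_reference
from .refmodel import TNPA_TYPES, TNPB_TYPES

# Realized insert content per tnpB type, in type-1A reference coordinates
# (the same frame the annotation pipeline reports).
TRUTH_INSERTS: dict[str, tuple[tuple[str, int], ...]] = {
    "T1A": (), "T1B": (), "MISC": (),
    "T2A": (("LI", 433), ("RI", 1000)),
    "T2Aprime": (("LI", 433), ("RI", 1000)),
    "T2B": (("LI", 433),),
    "T2Bprime": (("LI", 433),),
    "T2C": (("RI", 1000),),
    "T3": (("HI", 433),),
    "T3prime": (("HI", 433),),
}

PATE_LE_FRAGMENT_NT = 28
PATE_TNPB_TAIL_NT = 58


@dataclass
class DecaySpec:
    """One planted element: types, end states, noise, placement."""

    tnpa_type: str = "T5"
    tnpb_type: str = "T1A"
    le: str | tuple[str, int] = "consensus"   # 'consensus' | ('truncated', n) | 'absent'
    re_type: str = "RE_T1"                    # 'RE_T1' | 'RE_T2' | 'RE_MISC' | 'absent'
    point_mutation_rate: float = 0.0
    strand: str | None = None                 # tnpA strand; None = random
    spacing: int = 400                        # min background nt before this element
    strand_class_target: str | None = None    # 'Lead'/'Lag': choose strand to match

    def __post_init__(self) -> None:
        if not 0.0 <= self.point_mutation_rate <= 1.0:
            raise ValueError("point_mutation_rate must be in [0, 1]")
        if self.tnpa_type not in TNPA_TYPES and self.tnpa_type not in ("IS200", "absent"):
            raise ValueError(f"unknown tnpa_type {self.tnpa_type!r}")
        if self.tnpb_type not in TNPB_TYPES and self.tnpb_type != "absent":
            raise ValueError(f"unknown tnpb_type {self.tnpb_type!r}")


@dataclass
class PateSpec:
    """One planted ends-only (PATE-like) relic."""

    re_type: str = "RE_T2"
    point_mutation_rate: float = 0.0
    strand: str | None = None                 # element (tnpB) strand
    spacing: int = 400
    strand_class_target: str | None = None


@dataclass
class TruthElement:
    locus_id: str | None
    genome_interval: tuple[int, int]
    strand: str                               # tnpA strand (element strand for PATE)
    tnpa_type: str
    tnpb_type: str
    le_status: str
    re_type: str
    insert_positions: tuple[tuple[str, int], ...] = ()
    disruption_intervals: tuple[tuple[int, int], ...] = ()
    is_pate: bool = False
    pate_components: dict | None = None
    strand_class: str | None = None

    @property
    def midpoint(self) -> int:
        return (self.genome_interval[0] + self.genome_interval[1]) // 2


@dataclass
class SyntheticTruth:
    elements: list[TruthElement]
    genome_length: int
    gc: float
    seed: int
    origin_position: int
    terminus_position: int

    @property
    def planted(self) -> list[TruthElement]:
        return [e for e in self.elements if not e.is_pate]

    @property
    def pates(self) -> list[TruthElement]:
        return [e for e in self.elements if e.is_pate]

    def to_catalog_rows(self) -> list[CatalogRow]:
        return [
            CatalogRow(
                locus=e.locus_id,
                tnpa_type=e.tnpa_type,
                tnpb_type=e.tnpb_type,
                le_status=e.le_status,
                re_type=e.re_type,
                strand_class=e.strand_class,
            )
            for e in self.elements
        ]

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            [
                {
                    "locus": e.locus_id,
                    "tnpa_type": e.tnpa_type,
                    "tnpb_type": e.tnpb_type,
                    "le": e.le_status,
                    "re": e.re_type,
                    "strand_class": e.strand_class or "N/A",
                    "strand": e.strand,
                    "start": e.genome_interval[0],
                    "end": e.genome_interval[1],
                }
                for e in self.elements
            ]
        ).to_csv(path, sep="\t", index=False)

    def to_gff3(self, path, seqid: str = "synthetic") -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for e in self.elements:
                s, t = e.genome_interval
                ftype = "sequence_feature" if e.is_pate else "mobile_genetic_element"
                attrs = (
                    f"ID=truth_{e.locus_id};tnpa_type={e.tnpa_type};"
                    f"tnpb_type={e.tnpb_type};le={e.le_status};re={e.re_type}"
                )
                fh.write(
                    f"{seqid}\tis605scan-sim\t{ftype}\t{s}\t{t}\t.\t{e.strand}\t.\t{attrs}\n"
                )

    def to_json(self, path) -> None:
        meta = {
            "genome_length": self.genome_length,
            "gc": self.gc,
            "seed": self.seed,
            "origin_position": self.origin_position,
            "terminus_position": self.terminus_position,
            "n_elements": len(self.planted),
            "n_pates": len(self.pates),
        }
        with open(path, "w") as fh:
            json.dump(meta, fh, indent=2)


class GenomeBuilder:
    """Accumulates element/PATE specs, then lays out a genome + truth."""

    def __init__(
        self,
        reference: ReferenceRealization | None = None,
        seed: int = 0,
        gc: float = 0.34,
        origin_position: int = 1,
        terminus_position: int | None = None,
    ):
        self.ref = reference or default_reference()
        self.seed = seed
        self.gc = gc
        self.origin = origin_position
        self.terminus = terminus_position
        self.items: list[DecaySpec | PateSpec] = []

    def add_element(self, spec: DecaySpec) -> int:
        self.items.append(spec)
        return len(self.items) - 1

    def add_pate(self, spec: PateSpec) -> int:
        self.items.append(spec)
        return len(self.items) - 1

    # -- assembly ------------------------------------------------------------

    def _element_strand_seq(self, item) -> tuple[str, dict]:
        """Sequence on its natural strand, plus component offsets (1-based)."""
        ref = self.ref
        if isinstance(item, PateSpec):
            le = ref.le_hairpin_fragment()
            tail = ref.tnpb_tail(PATE_TNPB_TAIL_NT)
            re_seq = ref.end_seq(item.re_type)
            return le + tail + re_seq, {
                "pate_components": {
                    "le_fragment_nt": len(le),
                    "tnpb_tail_nt": len(tail),
                    "re_type": item.re_type,
                }
            }
        if item.tnpa_type == "IS200":
            # Lone IS200 transposase, no IS605 ends; built on the tnpA strand.
            return ref.is200_tnpa, {"on_tnpa_strand": True}
        parts = []
        if item.le == "consensus":
            parts.append(ref.le60)
            le_status = "consensus"
        elif item.le == "absent":
            parts.append("")
            le_status = "absent"
        else:
            kind, n = item.le
            if kind != "truncated" or not 0 < n < 60:
                raise ValueError(f"bad le spec {item.le!r}")
            # Truncation removes the n nucleotides closest to tnpA
            # (the 3'-most positions of the LE on the element strand).
            parts.append(ref.le60[: 60 - n])
            le_status = "partial"
        if item.tnpa_type != "absent":
            parts.append(revcomp(ref.tnpa_model(item.tnpa_type)))
        tnpb_off = sum(len(p) for p in parts)
        if item.tnpb_type != "absent":
            parts.append(ref.tnpb_model(item.tnpb_type))
        if item.re_type != "absent":
            parts.append(ref.end_seq(item.re_type))
        meta: dict = {"le_status": le_status}
        if item.tnpb_type == "T2Bprime":
            # In the T2B' model the disruption occupies positions 800..
            # 800+len-1 of the edited ORF.
            d0 = tnpb_off + 800
            meta["disruption_es"] = (d0, d0 + len(self.ref.disruption) - 1)
        return "".join(parts), meta

    def _mutate(self, seq: str, rate: float, idx: int) -> str:
        if rate <= 0.0 or not seq:
            return seq
        # Rate-independent streams: nested mutation sets across rates.
        rng_u = np.random.default_rng([self.seed, 100 + idx, 1])
        rng_alt = np.random.default_rng([self.seed, 100 + idx, 2])
        codes = encode(seq)
        u = rng_u.random(len(seq))
        alts = rng_alt.integers(1, 4, size=len(seq)).astype(np.uint8)
        hit = (u < rate) & (codes < 4)
        codes[hit] = (codes[hit] + alts[hit]) % 4
        return decode(codes)

    def build(self, genome_length: int, max_spacing: int | None = None
              ) -> tuple[str, SyntheticTruth]:
        if not self.items:
            rng_bg = np.random.default_rng([self.seed, 2])
            genome = random_seq(rng_bg, genome_length, self.gc)
            term = self.terminus or self._default_terminus(genome_length)
            return genome, SyntheticTruth([], genome_length, self.gc, self.seed,
                                          self.origin, term)
        rng_layout = np.random.default_rng([self.seed, 1])
        rng_bg = np.random.default_rng([self.seed, 2])
        term = self.terminus or self._default_terminus(genome_length)

        built = [self._element_strand_seq(item) for item in self.items]
        lengths = [len(seq) for seq, _ in built]
        n = len(self.items)
        min_gaps = [getattr(item, "spacing", 400) for item in self.items] + [0]
        content = sum(lengths)
        extra = genome_length - content - sum(min_gaps)
        if extra < 0:
            raise ValueError(
                f"infeasible packing: {content} nt of elements + {sum(min_gaps)} nt "
                f"spacing exceed genome_length={genome_length}"
            )
        extra_alloc = rng_layout.multinomial(extra, [1.0 / (n + 1)] * (n + 1))
        gaps = [g + int(e) for g, e in zip(min_gaps, extra_alloc)]
        if max_spacing is not None:
            surplus = 0
            for i in range(n):
                cap = max(min_gaps[i], max_spacing)
                if gaps[i] > cap:
                    surplus += gaps[i] - cap
                    gaps[i] = cap
            gaps[n] += surplus

        # Positions first, so strand_class targets can be resolved.
        starts = []
        pos = 1
        for i in range(n):
            pos += gaps[i]
            starts.append(pos)
            pos += lengths[i]

        pieces: list[str] = []
        elements: list[TruthElement] = []
        for i, (item, (seq_es, meta)) in enumerate(zip(self.items, built)):
            start = starts[i]
            end = start + lengths[i] - 1
            mid = (start + end) // 2
            strand = item.strand
            if item.strand_class_target is not None:
                arm1 = ((mid - self.origin) % genome_length) < (
                    (term - self.origin) % genome_length
                )
                want_lead = item.strand_class_target == "Lead"
                strand = "+" if (want_lead == arm1) else "-"
            elif strand is None:
                strand = "+" if rng_layout.integers(2) == 0 else "-"
            mutated = self._mutate(seq_es, getattr(item, "point_mutation_rate", 0.0), i)
            # The assembled sequence sits on the element (tnpB) strand for
            # IS605 elements and PATEs, on the tnpA strand for IS200.
            if isinstance(item, PateSpec) or meta.get("on_tnpa_strand"):
                natural_strand = strand
            else:
                natural_strand = "-" if strand == "+" else "+"
            planted = mutated if natural_strand == "+" else revcomp(mutated)
            pieces.append(random_seq(rng_bg, gaps[i], self.gc))
            pieces.append(planted)

            def es_to_genome(a: int, b: int) -> tuple[int, int]:
                if natural_strand == "+":
                    return (start + a - 1, start + b - 1)
                return (end - b + 1, end - a + 1)

            disr = ()
            if "disruption_es" in meta:
                disr = (es_to_genome(*meta["disruption_es"]),)
            if isinstance(item, PateSpec):
                elements.append(
                    TruthElement(
                        locus_id=None, genome_interval=(start, end), strand=strand,
                        tnpa_type="absent", tnpb_type="absent",
                        le_status="hairpin", re_type=item.re_type,
                        is_pate=True, pate_components=meta["pate_components"],
                        strand_class=assign_replichore(mid, strand, self.origin,
                                                       term, genome_length),
                    )
                )
            else:
                le_status = "unknown" if item.tnpa_type == "IS200" else meta["le_status"]
                re_type = "unknown" if item.tnpa_type == "IS200" else item.re_type
                elements.append(
                    TruthElement(
                        locus_id=None, genome_interval=(start, end), strand=strand,
                        tnpa_type=item.tnpa_type, tnpb_type=item.tnpb_type,
                        le_status=le_status, re_type=re_type,
                        insert_positions=TRUTH_INSERTS.get(item.tnpb_type, ()),
                        disruption_intervals=disr,
                        strand_class=assign_replichore(mid, strand, self.origin,
                                                       term, genome_length),
                    )
                )
        pieces.append(random_seq(rng_bg, gaps[n], self.gc))
        genome = "".join(pieces)
        assert len(genome) == genome_length

        truth = SyntheticTruth(elements, genome_length, self.gc, self.seed,
                               self.origin, term)
        _assign_locus_ids(truth)
        return genome, truth

    def _default_terminus(self, genome_length: int) -> int:
        return (self.origin - 1 + genome_length // 2) % genome_length + 1


def _assign_locus_ids(truth: SyntheticTruth) -> None:
    """Number loci by increasing circular distance from the origin.

    The same rule the annotation pipeline applies, so truth and predicted
    catalogs share locus keys.  PATEs are labelled separately.
    """
    L, o = truth.genome_length, truth.origin_position

    def dist(e: TruthElement) -> int:
        d = abs(e.midpoint - o) % L
        return min(d, L - d)

    for i, e in enumerate(sorted(truth.planted, key=dist), start=1):
        e.locus_id = str(i)
    for i, e in enumerate(sorted(truth.pates, key=dist), start=1):
        e.locus_id = "PATE" if i == 1 else f"PATE{i}"
    truth.elements.sort(key=lambda e: (e.is_pate, dist(e)))


def plant_pate(
    builder: GenomeBuilder,
    re_type: str = "RE_T2",
    strand: str | None = None,
    spacing: int = 400,
) -> int:
    """Queue an ends-only relic: 28 nt of hairpin-bearing LE, the last
    58 nt of the tnpB ORF, and a full RE of the stated type."""
    return builder.add_pate(PateSpec(re_type=re_type, strand=strand, spacing=spacing))


def generate_genome(
    specs: list[DecaySpec | PateSpec],
    genome_length: int,
    gc: float = 0.34,
    seed: int = 0,
    reference: ReferenceRealization | None = None,
    origin_position: int = 1,
    terminus_position: int | None = None,
    max_spacing: int | None = None,
) -> tuple[str, SyntheticTruth]:
    """Deterministically generate (genome, truth) for a list of specs."""
    builder = GenomeBuilder(reference, seed=seed, gc=gc,
                            origin_position=origin_position,
                            terminus_position=terminus_position)
    for s in specs:
        builder.items.append(s)
    return builder.build(genome_length, max_spacing=max_spacing)


def table1_specs(point_mutation_rate: float = 0.0) -> list[DecaySpec | PateSpec]:
    """Spec list emulating the published catalog's composition.

    23 numbered loci (22 IS605 + 1 IS200) plus one PATE, with each row's
    tnpA/tnpB/RE types, the locus-13 left-end truncation (missing the
    11 nt closest to tnpA), the locus-15 truncated RE, the locus-18
    nested disruption, and strands chosen so the planted Lead/Lag tallies
    match the published ones.
    """
    t1 = [
        # (tnpa, tnpb, re, strand_class)
        ("T2", "T1B", "RE_T2", "Lead"),
        ("T5", "T2C", "RE_T1", "Lead"),
        ("T5", "T2C", "RE_T1", "Lag"),
        ("T5", "T2A", "RE_T2", "Lead"),
        ("T5", "T1A", "RE_T1", "Lead"),
        ("T5", "T2A", "RE_T2", "Lag"),
        ("IS200", "absent", "absent", "Lag"),
        ("T5", "T1A", "RE_T1", "Lag"),
        ("T1", "T2A", "RE_T1", "Lag"),
        ("T5", "T1A", "RE_T1", "Lag"),
        ("T5", "T3", "RE_T1", "Lag"),
        ("T5", "T3", "RE_T1", "Lag"),
        ("T3", "T2Aprime", "RE_T1", "Lag"),
        ("T5", "MISC", "RE_T2", "Lead"),
        ("T4", "T3prime", "RE_MISC", "Lead"),
        ("T5", "T1A", "RE_T1", "Lag"),
        ("T5", "T2B", "RE_T1", "Lag"),
        ("T5", "T2Bprime", "RE_T1", "Lead"),
        ("T5", "T2B", "RE_T1", "Lag"),
        ("T2", "T2B", "RE_T1", "Lead"),
        ("T5", "T3", "RE_T2", "Lead"),
        ("T5", "T3", "RE_T1", "Lead"),
        ("T5", "T3", "RE_T1", "Lag"),
    ]
    specs: list[DecaySpec | PateSpec] = []
    for i, (ta, tb, re_t, sclass) in enumerate(t1, start=1):
        le: str | tuple[str, int] = "consensus"
        if i == 13:
            le = ("truncated", 11)
        if ta == "IS200":
            le = "absent"
            re_t = "absent"
        specs.append(
            DecaySpec(tnpa_type=ta, tnpb_type=tb, le=le, re_type=re_t,
                      point_mutation_rate=point_mutation_rate,
                      strand_class_target=sclass)
        )
    specs.append(PateSpec(re_type="RE_T2", strand_class_target="Lag",
                          point_mutation_rate=point_mutation_rate))
    return specs


def table1_genome(
    seed: int = 0,
    point_mutation_rate: float = 0.0,
    genome_length: int = 120_000,
    reference: ReferenceRealization | None = None,
) -> tuple[str, SyntheticTruth]:
    """A genome emulating the published element composition."""
    return generate_genome(
        table1_specs(point_mutation_rate), genome_length=genome_length,
        seed=seed, reference=reference, max_spacing=800,
    )
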