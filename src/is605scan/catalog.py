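"""Element catalog: typed rows, summary tallies, replichore assignment.

The package ships the published 24-row locus catalog (23 numbered loci -
one IS200, 22 IS605 - plus one PATE-like ends-only relic) as a TSV
fixture; the same schema is produced by the annotation pipeline and the
synthetic-truth writer, so predicted, packaged and planted catalogs can
all be loaded, summarized and diffed with the same functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

TABLE1_RESOURCE = "table1_catalog.tsv"

# Accepted vocabularies: the published table's wording and the package's
# internal tokens both normalize to the internal tokens.
_TNPA_VOCAB = {
    "type 1": "T1", "type 2": "T2", "type 3": "T3", "type 4": "T4", "type 5": "T5",
    "t1": "T1", "t2": "T2", "t3": "T3", "t4": "T4", "t5": "T5",
    "is200": "IS200", "na": "absent", "n/a": "absent", "absent": "absent",
    "unclassified": "unclassified",
}
_TNPB_VOCAB = {
    "1a": "T1A", "1b": "T1B", "2a": "T2A", "2a'": "T2Aprime", "2a’": "T2Aprime",
    "2b": "T2B", "2b'": "T2Bprime", "2b’": "T2Bprime", "2c": "T2C",
    "3": "T3", "3'": "T3prime", "3’": "T3prime", "misc": "MISC",
    "t1a": "T1A", "t1b": "T1B", "t2a": "T2A", "t2aprime": "T2Aprime",
    "t2b": "T2B", "t2bprime": "T2Bprime", "t2c": "T2C",
    "t3": "T3", "t3prime": "T3prime",
    "na": "absent", "n/a": "absent", "absent": "absent",
    "unclassified": "unclassified",
}
_LE_VOCAB = {
    "consensus": "consensus", "partial": "partial", "truncated": "partial",
    "absent": "absent", "unknown": "unknown", "hairpin": "hairpin",
}
_RE_VOCAB = {
    "type 1": "RE_T1", "type 2": "RE_T2", "misc": "RE_MISC",
    "re_t1": "RE_T1", "re_t2": "RE_T2", "re_misc": "RE_MISC",
    "na": "absent", "n/a": "absent", "absent": "absent", "unknown": "unknown",
}
_STRAND_VOCAB = {"lead": "Lead", "lag": "Lag", "na": None, "n/a": None, "": None}

SUMMARY_FIELDS = ("tnpa_type", "tnpb_type", "le_status", "re_type", "strand_class")


@dataclass
class CatalogRow:
    locus: str
    tnpa_type: str
    tnpb_type: str
    le_status: str
    re_type: str
    tnpa_locus_id: str | None = None
    tnpb_locus_id: str | None = None
    strand_class: str | None = None

    @property
    def is_pate(self) -> bool:
        return self.locus.upper().startswith("PATE")

    @property
    def is_is200(self) -> bool:
        return self.tnpa_type == "IS200"

    @property
    def is_is605(self) -> bool:
        return not self.is_pate and not self.is_is200


def _norm(vocab: dict, raw, column: str, line: int):
    key = str(raw).strip().lower()
    if key not in vocab:
        raise ValueError(f"line {line}: unrecognized {column} value {raw!r}")
    return vocab[key]


def load_catalog(path_or_buf) -> list[CatalogRow]:
    """Load and validate a catalog TSV into typed rows.

    Requires columns locus / tnpa_type / tnpb_type / le / re (plus
    optional locus-tag and strand-class columns); enumeration values are
    validated and malformed rows rejected with their line number.
    """
    df = pd.read_csv(path_or_buf, sep="\t", dtype=str, keep_default_na=False)
    required = {"locus", "tnpa_type", "tnpb_type", "le", "re"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"catalog is missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("catalog has no rows")
    rows: list[CatalogRow] = []
    for idx, rec in df.iterrows():
        line = idx + 2  # header is line 1
        locus = str(rec["locus"]).strip()
        if not locus:
            raise ValueError(f"line {line}: empty locus id")
        strand_class = None
        if "strand_class" in df.columns:
            strand_class = _norm(_STRAND_VOCAB, rec["strand_class"], "strand_class", line)
        rows.append(
            CatalogRow(
                locus=locus,
                tnpa_type=_norm(_TNPA_VOCAB, rec["tnpa_type"], "tnpa_type", line),
                tnpb_type=_norm(_TNPB_VOCAB, rec["tnpb_type"], "tnpb_type", line),
                le_status=_norm(_LE_VOCAB, rec["le"], "le", line),
                re_type=_norm(_RE_VOCAB, rec["re"], "re", line),
                tnpa_locus_id=(rec.get("tnpa_locus_id") or None),
                tnpb_locus_id=(rec.get("tnpb_locus_id") or None),
                strand_class=strand_class,
            )
        )
    return rows


def load_table1() -> list[CatalogRow]:
    """The packaged published catalog (23 loci + 1 PATE)."""
    src = resources.files("is605scan") / "data" / TABLE1_RESOURCE
    with resources.as_file(src) as path:
        return load_catalog(path)


@dataclass
class SummaryCounts:
    """Tallies per (field, value), with explicit denominators.

    Tallies follow the catalog's "of 22" convention: counts are taken
    over the IS605 rows only, excluding the single-replicate IS200 locus
    and PATE rows, whose totals are reported separately.
    """

    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    denominators: dict[str, int] = field(default_factory=dict)
    totals: dict[str, int] = field(default_factory=dict)

    def get(self, field_name: str, value: str) -> int:
        return self.counts.get(field_name, {}).get(value, 0)


def summarize(rows: list[CatalogRow]) -> SummaryCounts:
    is605 = [r for r in rows if r.is_is605]
    out = SummaryCounts(
        totals={
            "n_rows": len(rows),
            "n_elements": sum(1 for r in rows if not r.is_pate),
            "n_is605": len(is605),
            "n_is200": sum(1 for r in rows if r.is_is200),
            "n_pate": sum(1 for r in rows if r.is_pate),
        }
    )
    for f in SUMMARY_FIELDS:
        vals = [getattr(r, f) for r in is605]
        vals = [v for v in vals if v is not None]
        counts: dict[str, int] = {}
        for v in vals:
            counts[v] = counts.get(v, 0) + 1
        out.counts[f] = counts
        out.denominators[f] = len(vals)
    return out


def assign_replichore(
    locus_position: int,
    strand: str,
    origin_position: int,
    terminus_position: int,
    genome_length: int,
) -> str:
    """Leading/lagging-strand classification on a circular chromosome.

    The clockwise replichore runs origin -> terminus in increasing
    (wrapped) coordinates.  A gene there reads off the leading-strand
    template when it points '+'; on the other replichore the fork runs
    the opposite way, so '-' is leading.
    """
    if origin_position == terminus_position:
        raise ValueError("origin and terminus must differ")
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    arm1 = ((locus_position - origin_position) % genome_length) < (
        (terminus_position - origin_position) % genome_length
    )
    lead = (arm1 and strand == "+") or (not arm1 and strand == "-")
    return "Lead" if lead else "Lag"


@dataclass
class CatalogDiff:
    locus: str
    field_name: str
    predicted: str | None
    truth: str | None


@dataclass
class CatalogComparison:
    matched_loci: list[str]
    predicted_only: list[str]
    truth_only: list[str]
    field_accuracy: dict[str, float]
    diffs: list[CatalogDiff]

    @property
    def locus_precision(self) -> float:
        n_pred = len(self.matched_loci) + len(self.predicted_only)
        return len(self.matched_loci) / n_pred if n_pred else 1.0

    @property
    def locus_recall(self) -> float:
        n_truth = len(self.matched_loci) + len(self.truth_only)
        return len(self.matched_loci) / n_truth if n_truth else 1.0


def compare_catalogs(
    predicted: list[CatalogRow],
    truth: list[CatalogRow],
    fields: tuple[str, ...] = ("tnpa_type", "tnpb_type", "le_status", "re_type",
                               "strand_class"),
) -> CatalogComparison:
    """Per-field accuracy and per-locus diff between two catalogs."""
    pmap = {r.locus: r for r in predicted}
    tmap = {r.locus: r for r in truth}
    matched = sorted(set(pmap) & set(tmap), key=_locus_sort_key)
    diffs: list[CatalogDiff] = []
    acc: dict[str, float] = {}
    for f in fields:
        n_ok = 0
        for k in matched:
            pv, tv = getattr(pmap[k], f), getattr(tmap[k], f)
            if pv == tv:
                n_ok += 1
            else:
                diffs.append(CatalogDiff(k, f, pv, tv))
        acc[f] = n_ok / len(matched) if matched else 1.0
    return CatalogComparison(
        matched_loci=matched,
        predicted_only=sorted(set(pmap) - set(tmap), key=_locus_sort_key),
        truth_only=sorted(set(tmap) - set(pmap), key=_locus_sort_key),
        field_accuracy=acc,
        diffs=diffs,
    )


def _locus_sort_key(locus: str):
    return (0, int(locus)) if locus.isdigit() else (1, locus)
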