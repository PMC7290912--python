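"""GFF3 and tabular output for annotation results."""

from __future__ import annotations

from .annotate import AnnotationResult, ElementLocus

_SOURCE = "is605scan"


def _attrs(**kv) -> str:
    return ";".join(f"{k}={v}" for k, v in kv.items() if v not in (None, ""))


def _feature(fh, seqid, ftype, start, end, strand, attrs, score="."):
    fh.write(f"{seqid}\t{_SOURCE}\t{ftype}\t{start}\t{end}\t{score}\t{strand}\t.\t{attrs}\n")


def write_gff3(result: AnnotationResult, path, seqid: str = "genome") -> None:
    """One parent feature per locus; children for inserts, disruptions
    and hairpins, with the type labels carried as attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {seqid} 1 {result.genome_length}\n")
        for locus in result.loci:
            _write_locus(fh, seqid, locus)


def _write_locus(fh, seqid: str, l: ElementLocus) -> None:
    lid = f"locus_{l.locus_id}"
    s, e = l.genome_interval
    ftype = "sequence_feature" if l.is_pate else "mobile_genetic_element"
    _feature(
        fh, seqid, ftype, s, e, l.strand,
        _attrs(
            ID=lid,
            tnpa_type=l.tnpa_type,
            tnpb_type=l.tnpb_type,
            le=l.le_status,
            re=l.re_type,
            strand_class=l.strand_class,
            pate="true" if l.is_pate else None,
        ),
    )
    for k, c in enumerate(l.insert_calls, start=1):
        if c.genome_interval is None:
            continue
        _feature(
            fh, seqid, "insertion_site", c.genome_interval[0], c.genome_interval[1],
            l.strand,
            _attrs(ID=f"{lid}.insert{k}", Parent=lid, kind=c.kind,
                   orf_position=c.orf_position, length=c.length),
        )
    for k, d in enumerate(l.disruptions, start=1):
        if d.genome_interval is None:
            continue
        _feature(
            fh, seqid, "insertion_site", d.genome_interval[0], d.genome_interval[1],
            l.strand,
            _attrs(ID=f"{lid}.disruption{k}", Parent=lid, kind="disruption",
                   orf_position=d.orf_position, length=d.length),
        )
    for k, hp in enumerate(l.hairpins, start=1):
        if hp.genome_interval is None:
            continue
        _feature(
            fh, seqid, "stem_loop", hp.genome_interval[0], hp.genome_interval[1],
            l.strand,
            _attrs(ID=f"{lid}.hairpin{k}", Parent=lid, side=hp.side,
                   paired=hp.call.paired, stem_span=hp.call.stem_span,
                   loop_len=hp.call.loop_len,
                   loop_motif="AAGCT" if hp.call.loop_motif_found else None),
            score=str(hp.call.score),
        )


def write_table(result: AnnotationResult, path) -> None:
    """The catalog-shaped TSV (loadable by :func:`catalog.load_catalog`)."""
    result.to_table().to_csv(path, sep="\t", index=False)


def write_hairpin_report(result: AnnotationResult, path) -> None:
    """Per-locus hairpin TSV: geometry, score, motif flag, coordinates."""
    import pandas as pd

    rows = []
    for l in result.loci:
        for hp in l.hairpins:
            rows.append(
                {
                    "locus": l.locus_id,
                    "side": hp.side,
                    "paired": hp.call.paired,
                    "stem_span": hp.call.stem_span,
                    "loop_len": hp.call.loop_len,
                    "mismatches": hp.call.mismatches,
                    "score": hp.call.score,
                    "loop_motif": hp.call.loop_motif_found,
                    "start": hp.genome_interval[0] if hp.genome_interval else "",
                    "end": hp.genome_interval[1] if hp.genome_interval else "",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
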