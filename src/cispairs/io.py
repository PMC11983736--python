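"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: TSV for matrices and tables, GTF for annotation,
JSON for truth sidecars and manifests, BEDPE for genome-browser export of
pairs.  Numeric TSV output uses full repr precision so round-trips are
lossless.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .containers import AnnotationSet, ExpressionMatrix, TranscriptAnnotation

__all__ = [
    "write_expression", "read_expression",
    "write_annotation_tsv", "read_annotation_tsv",
    "write_annotation_gtf", "read_annotation_gtf",
    "write_probe_map", "read_probe_map",
    "write_json", "read_json",
    "write_pairs_bedpe",
]


def write_expression(matrix: ExpressionMatrix, values_path, design_path) -> None:
    matrix.values.to_csv(values_path, sep="\t", index_label="feature_id", float_format="%.17g")
    matrix.design.to_csv(design_path, sep="\t", index_label="sample_id")


def read_expression(values_path, design_path) -> ExpressionMatrix:
    values = pd.read_csv(
        values_path, sep="\t", index_col="feature_id", float_precision="round_trip"
    )
    design = pd.read_csv(design_path, sep="\t", index_col="sample_id")
    return ExpressionMatrix(values, design)


def write_annotation_tsv(annotation: AnnotationSet, path) -> None:
    annotation.tss_table().to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path) -> AnnotationSet:
    table = pd.read_csv(path, sep="\t")
    return AnnotationSet(table.drop(columns=[c for c in ("tss",) if c in table]))


def write_annotation_gtf(annotation: AnnotationSet, path) -> None:
    """Write transcripts as GTF (1-based inclusive, 'transcript' features)."""
    with open(path, "w") as fh:
        for r in annotation.records():
            attrs = (
                f'transcript_id "{r.transcript_id}"; '
                f'gene_biotype "{r.biotype}";'
            )
            fh.write(
                "\t".join(
                    [
                        r.chromosome, "cispairs", "transcript",
                        str(r.start), str(r.end), ".", r.strand, ".", attrs,
                    ]
                )
                + "\n"
            )


def read_annotation_gtf(path) -> AnnotationSet:
    """Read transcript features from a GTF file (via gffutils)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    records = []
    for feat in db.features_of_type("transcript", order_by=("seqid", "start")):
        records.append(
            TranscriptAnnotation(
                transcript_id=feat.attributes["transcript_id"][0],
                biotype=feat.attributes.get("gene_biotype", ["coding"])[0],
                chromosome=feat.seqid,
                strand=feat.strand,
                start=feat.start,
                end=feat.end,
            )
        )
    return AnnotationSet.from_records(records)


def write_probe_map(probe_map: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {"probe_id": list(probe_map), "feature_id": list(probe_map.values())}
    ).to_csv(path, sep="\t", index=False)


def read_probe_map(path) -> dict[str, str]:
    table = pd.read_csv(path, sep="\t")
    return dict(zip(table["probe_id"], table["feature_id"]))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_pairs_bedpe(pairs, annotation: AnnotationSet, path) -> None:
    """BEDPE companion export of cis pairs (0-based half-open spans)."""
    with open(path, "w") as fh:
        for p in pairs:
            a = annotation.get(p.lnc_id)
            b = annotation.get(p.mrna_id)
            fh.write(
                "\t".join(
                    [
                        a.chromosome, str(a.start - 1), str(a.end),
                        b.chromosome, str(b.start - 1), str(b.end),
                        f"{p.lnc_id}|{p.mrna_id}", str(p.distance),
                        a.strand, b.strand,
                    ]
                )
                + "\n"
            )
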