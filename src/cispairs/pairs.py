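"""Cis-pair discovery: proximity pairing of lncRNAs with coding genes.

A cis pair is a differentially expressed lncRNA and a differentially
expressed protein-coding gene on the same chromosome whose transcription
start sites lie strictly closer than a distance threshold (default 0.5 Mb).
Each pair is classified by transcriptional orientation — divergent
(head-to-head, transcription proceeding apart), convergent, or tandem —
and by the direction pattern of its two fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import AnnotationSet, TranscriptAnnotation
from .differential import DifferentialRecord

__all__ = [
    "CisPair",
    "classify_orientation",
    "find_cis_pairs",
    "rank_pairs",
    "pairs_to_frame",
]

DEFAULT_MAX_DISTANCE = 500_000


@dataclass(frozen=True)
class CisPair:
    lnc_id: str
    mrna_id: str
    chromosome: str
    distance: int  # |tss_lnc - tss_mrna|
    orientation: str  # divergent | convergent | tandem
    pattern: str  # lnc_up_mrna_down | lnc_down_mrna_up | both_up | both_down


def classify_orientation(a: TranscriptAnnotation, b: TranscriptAnnotation) -> str:
    """Orientation of two same-chromosome transcripts.

    Same strand is tandem.  On opposite strands the pair is divergent when
    the minus-strand TSS lies at or upstream of the plus-strand TSS (the
    two transcripts are read away from each other), convergent otherwise.
    """
    if a.chromosome != b.chromosome:
        raise ValueError(
            f"{a.transcript_id} and {b.transcript_id} are on different chromosomes"
        )
    if a.strand == b.strand:
        return "tandem"
    minus, plus = (a, b) if a.strand == "-" else (b, a)
    return "divergent" if minus.tss <= plus.tss else "convergent"


def _pattern(lnc: DifferentialRecord, mrna: DifferentialRecord) -> str:
    key = (lnc.direction, mrna.direction)
    return {
        ("up", "down"): "lnc_up_mrna_down",
        ("down", "up"): "lnc_down_mrna_up",
        ("up", "up"): "both_up",
        ("down", "down"): "both_down",
    }.get(key, "flat")


def find_cis_pairs(
    de_lnc: Sequence[DifferentialRecord],
    de_mrna: Sequence[DifferentialRecord],
    annotation: AnnotationSet,
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> list[CisPair]:
    """All (lncRNA, coding) pairs with TSS distance strictly below the threshold.

    Both members must appear in the annotation (an unannotated feature is an
    error naming it).  Candidates on the same chromosome are found with a
    sorted-TSS window query (binary search), which agrees exactly with the
    exhaustive all-pairs predicate scan.  Output is sorted by
    (chromosome, distance ascending, lnc_id).
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be > 0")
    lnc_ann: list[TranscriptAnnotation] = []
    for rec in de_lnc:
        if rec.feature_id not in annotation:
            raise KeyError(f"unannotated feature: {rec.feature_id}")
        lnc_ann.append(annotation.get(rec.feature_id))
    mrna_by_chrom: dict[str, list[TranscriptAnnotation]] = {}
    mrna_rec = {}
    for rec in de_mrna:
        if rec.feature_id not in annotation:
            raise KeyError(f"unannotated feature: {rec.feature_id}")
        ann = annotation.get(rec.feature_id)
        mrna_by_chrom.setdefault(ann.chromosome, []).append(ann)
        mrna_rec[rec.feature_id] = rec
    lnc_rec = {rec.feature_id: rec for rec in de_lnc}

    # sorted-TSS index per chromosome
    index: dict[str, tuple[np.ndarray, list[TranscriptAnnotation]]] = {}
    for chrom, anns in mrna_by_chrom.items():
        anns = sorted(anns, key=lambda a: (a.tss, a.transcript_id))
        index[chrom] = (np.array([a.tss for a in anns]), anns)

    pairs: list[CisPair] = []
    for lnc in lnc_ann:
        if lnc.chromosome not in index:
            continue
        tss_arr, anns = index[lnc.chromosome]
        lo = int(np.searchsorted(tss_arr, lnc.tss - max_distance + 1, side="left"))
        hi = int(np.searchsorted(tss_arr, lnc.tss + max_distance - 1, side="right"))
        for mrna in anns[lo:hi]:
            distance = abs(lnc.tss - mrna.tss)
            if distance >= max_distance:
                continue
            pairs.append(
                CisPair(
                    lnc_id=lnc.transcript_id,
                    mrna_id=mrna.transcript_id,
                    chromosome=lnc.chromosome,
                    distance=int(distance),
                    orientation=classify_orientation(lnc, mrna),
                    pattern=_pattern(lnc_rec[lnc.transcript_id], mrna_rec[mrna.transcript_id]),
                )
            )
    pairs.sort(key=lambda p: (p.chromosome, p.distance, p.lnc_id))
    return pairs


_ANTI_CONCORDANT = {"lnc_up_mrna_down", "lnc_down_mrna_up"}


def rank_pairs(
    pairs: Iterable[CisPair], de_index: Mapping[str, DifferentialRecord]
) -> list[CisPair]:
    """Stable ranking: anti-concordant patterns first, then by joint effect size.

    Sort key is (pattern anti-concordant first, product of the two members'
    fold changes descending, distance ascending); equal keys preserve input
    order.
    """
    pairs = list(pairs)
    for p in pairs:
        for member in (p.lnc_id, p.mrna_id):
            if member not in de_index:
                raise KeyError(f"pair member missing from differential index: {member}")

    def key(p: CisPair):
        product = de_index[p.lnc_id].fold_change * de_index[p.mrna_id].fold_change
        return (p.pattern not in _ANTI_CONCORDANT, -product, p.distance)

    return sorted(pairs, key=key)


def pairs_to_frame(pairs: Sequence[CisPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lnc_id": p.lnc_id,
                "mrna_id": p.mrna_id,
                "chromosome": p.chromosome,
                "distance": p.distance,
                "orientation": p.orientation,
                "pattern": p.pattern,
            }
            for p in pairs
        ],
        columns=["lnc_id", "mrna_id", "chromosome", "distance", "orientation", "pattern"],
    )
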