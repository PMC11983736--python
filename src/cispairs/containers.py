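"""Shared in-memory containers for expression and annotation data.

The pipeline moves three kinds of tables around: a linear-scale expression
matrix (features x samples) with a sample design, a transcript annotation
table (genomic addresses plus biotype), and small per-stage result tables
that are plain :class:`pandas.DataFrame` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "TranscriptAnnotation",
    "AnnotationSet",
]


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


@dataclass
class ExpressionMatrix:
    """Linear-scale intensities, features x samples, with a sample design.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample id.
        Values are linear-scale intensities (finite, non-negative).
    design
        DataFrame indexed by sample id with columns ``condition`` and
        ``replicate``; must cover every sample column of ``values``.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate feature ids")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and (not np.all(np.isfinite(arr)) or arr.min() < 0):
            raise ValidationError("intensities must be finite and >= 0")
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise ValidationError(f"design missing samples: {sorted(missing)}")
        if "condition" not in self.design.columns:
            raise ValidationError("design must have a 'condition' column")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def conditions(self) -> dict[str, list[str]]:
        """Map condition name -> sample ids, in design order."""
        out: dict[str, list[str]] = {}
        for sample in self.values.columns:
            out.setdefault(str(self.design.loc[sample, "condition"]), []).append(sample)
        return out

    def subset(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[feature_ids], self.design)

    def copy_with(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.design)


@dataclass(frozen=True)
class TranscriptAnnotation:
    """One transcript's genomic address (1-based, inclusive) and biotype."""

    transcript_id: str
    biotype: str  # "lncRNA" or "coding"
    chromosome: str
    strand: str  # "+" or "-"
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"{self.transcript_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.chromosome:
            raise ValidationError(f"{self.transcript_id}: empty chromosome")

    @property
    def tss(self) -> int:
        """Transcription start site: start on '+', end on '-'."""
        return self.start if self.strand == "+" else self.end


COLUMNS = ["transcript_id", "biotype", "chromosome", "strand", "start", "end"]


@dataclass
class AnnotationSet:
    """An ordered collection of transcript annotations with id lookup."""

    table: pd.DataFrame
    truth: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"annotation table missing columns: {missing}")
        if self.table["transcript_id"].duplicated().any():
            raise ValidationError("duplicate transcript ids")
        bad = self.table[self.table["start"] > self.table["end"]]
        if len(bad):
            raise ValidationError(
                f"start > end for {bad['transcript_id'].tolist()[:5]}"
            )
        self._index = {
            tid: i for i, tid in enumerate(self.table["transcript_id"].to_numpy())
        }

    @classmethod
    def from_records(cls, records, truth: Mapping | None = None) -> "AnnotationSet":
        rows = [
            (r.transcript_id, r.biotype, r.chromosome, r.strand, r.start, r.end)
            for r in records
        ]
        return cls(pd.DataFrame(rows, columns=COLUMNS), dict(truth or {}))

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._index

    def get(self, transcript_id: str) -> TranscriptAnnotation:
        try:
            row = self.table.iloc[self._index[transcript_id]]
        except KeyError:
            raise KeyError(f"unannotated feature: {transcript_id}") from None
        return TranscriptAnnotation(
            transcript_id=row["transcript_id"],
            biotype=row["biotype"],
            chromosome=row["chromosome"],
            strand=row["strand"],
            start=int(row["start"]),
            end=int(row["end"]),
        )

    def records(self) -> Iterator[TranscriptAnnotation]:
        for tid in self.table["transcript_id"]:
            yield self.get(tid)

    def tss_table(self) -> pd.DataFrame:
        """Annotation table with a derived tss column."""
        t = self.table.copy()
        t["tss"] = np.where(t["strand"] == "+", t["start"], t["end"])
        return t
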