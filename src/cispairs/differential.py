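"""Per-feature fold changes between two conditions and the fold-change screen."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = ["DifferentialRecord", "fold_changes", "filter_de", "records_to_frame"]

logger = logging.getLogger(__name__)

DEFAULT_FC_THRESHOLD = 2.0


@dataclass(frozen=True)
class DifferentialRecord:
    """Fold change of one feature between the two conditions.

    ``fold_change`` is the linear ratio folded to >= 1; ``direction`` is
    "up" or "down" relative to the treated condition, or "flat" when the
    two means are equal.  ``defined`` is False when a condition mean is 0,
    in which case the record is excluded downstream.
    """

    feature_id: str
    mean_control: float
    mean_treated: float
    fold_change: float
    direction: str  # up | down | flat
    defined: bool = True


def fold_changes(
    matrix: ExpressionMatrix,
    treated: str | None = None,
    log_scale_means: bool = False,
) -> list[DifferentialRecord]:
    """One record per feature: condition means and folded linear ratio.

    Means are arithmetic means of linear intensities per condition (the
    conventional scale for reporting linear fold values); pass
    ``log_scale_means=True`` for geometric means instead.  ``treated``
    names the condition treated as the numerator for direction calls; by
    default the design's non-"control" condition (or the second condition
    in design order) is used.
    """
    groups = matrix.conditions()
    if len(groups) != 2:
        raise ValueError(f"design must have exactly 2 conditions, got {list(groups)}")
    names = list(groups)
    if treated is None:
        others = [c for c in names if c.lower() != "control"]
        treated = others[0] if len(others) == 1 else names[1]
    if treated not in groups:
        raise ValueError(f"treated condition {treated!r} not in design")
    control = next(c for c in names if c != treated)

    vals = matrix.values
    if log_scale_means:
        with np.errstate(divide="ignore"):
            mc = np.exp2(np.log2(vals[groups[control]]).mean(axis=1))
            mt = np.exp2(np.log2(vals[groups[treated]]).mean(axis=1))
    else:
        mc = vals[groups[control]].mean(axis=1)
        mt = vals[groups[treated]].mean(axis=1)

    records = []
    n_undefined = 0
    for fid in vals.index:
        c, t = float(mc[fid]), float(mt[fid])
        if c == 0.0 or t == 0.0:
            records.append(DifferentialRecord(fid, c, t, float("nan"), "flat", False))
            n_undefined += 1
            continue
        if t > c:
            fc, direction = t / c, "up"
        elif t < c:
            fc, direction = c / t, "down"
        else:
            fc, direction = 1.0, "flat"
        records.append(DifferentialRecord(fid, c, t, fc, direction))
    if n_undefined:
        logger.info("%d features with a zero condition mean flagged undefined", n_undefined)
    return records


def filter_de(
    records: list[DifferentialRecord], threshold: float = DEFAULT_FC_THRESHOLD
) -> list[DifferentialRecord]:
    """Retain defined records with fold_change >= threshold, in input order."""
    if threshold <= 1:
        raise ValueError("fold-change threshold must be > 1")
    return [r for r in records if r.defined and r.fold_change >= threshold]


def records_to_frame(
    records: list[DifferentialRecord], threshold: float = DEFAULT_FC_THRESHOLD
) -> pd.DataFrame:
    """Tabular view with a pass/fail flag at the given threshold."""
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "mean_control": [r.mean_control for r in records],
            "mean_treated": [r.mean_treated for r in records],
            "fold_change": [r.fold_change for r in records],
            "direction": [r.direction for r in records],
            "passes": [
                r.defined and r.fold_change >= threshold for r in records
            ],
        }
    )
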