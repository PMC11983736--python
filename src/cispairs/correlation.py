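"""Pearson correlation of one gene pair, globally and per stratum.

Reproduces the single-cell and cohort correlation stage: the Pearson
coefficient with its t statistic and two-sided p-value for the whole
population and for every observed (cell type x exposure) stratum, plus the
cell-type by exposure contingency summary.  Tail probabilities are also
reported in log10 space so that extremely small p-values (common at
tens of thousands of cells) are exact rather than underflow bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StratumCorrelation",
    "pearson",
    "stratified_correlation",
    "celltype_contingency",
    "fisher_z_compare",
    "correlations_to_frame",
]

ALL = "ALL"


@dataclass(frozen=True)
class StratumCorrelation:
    """Pearson correlation in one stratum (or globally, stratum = ALL/ALL)."""

    cell_type: str
    exposure: str
    n: int
    r: float
    df: int
    t: float
    p: float
    log10_p: float
    defined: bool = True
    flag: str = ""


def _undefined(cell_type: str, exposure: str, n: int, flag: str) -> StratumCorrelation:
    nan = float("nan")
    return StratumCorrelation(
        cell_type, exposure, n, nan, max(n - 2, 0), nan, nan, nan, False, flag
    )


def pearson(
    x: Sequence[float],
    y: Sequence[float],
    cell_type: str = ALL,
    exposure: str = ALL,
) -> StratumCorrelation:
    """Pearson r with Student-t two-sided p on n - 2 degrees of freedom.

    r = cov(x, y) / (sd_x * sd_y) with n-1 denominators;
    t = r * sqrt((n - 2) / (1 - r^2)).  Inputs of length < 3 or with zero
    variance yield a flagged undefined result; |r| = 1 returns p = 0 with a
    "perfect" flag (the boundary convention).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        return _undefined(cell_type, exposure, n, "n < 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        return _undefined(cell_type, exposure, n, "zero variance")
    r = float(xc @ yc) / math.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2
    if abs(r) == 1.0:
        return StratumCorrelation(
            cell_type, exposure, n, r, df, math.inf * math.copysign(1, r),
            0.0, -math.inf, True, "perfect",
        )
    t = r * math.sqrt(df / (1.0 - r * r))
    log_sf = stats.t.logsf(abs(t), df)
    p = float(min(1.0, 2.0 * math.exp(log_sf)))
    log10_p = float((log_sf + math.log(2.0)) / math.log(10.0))
    return StratumCorrelation(cell_type, exposure, n, r, df, t, p, log10_p)


def stratified_correlation(
    cells: pd.DataFrame,
    strata_keys: Sequence[str] = ("cell_type", "exposure"),
) -> list[StratumCorrelation]:
    """Global plus per-stratum Pearson correlations of value_a vs value_b.

    ``cells`` needs columns value_a, value_b and the requested strata key
    columns.  One result is returned per observed combination of the keys,
    plus the global ALL/ALL result; undefined strata (n < 3 or zero
    variance) are carried with flags rather than dropped, so per-stratum
    cell counts always sum to the global count.  Output is sorted by
    descending n (global first).
    """
    if cells.empty:
        raise ValueError("cells table is empty")
    keys = [k for k in ("cell_type", "exposure") if k in strata_keys]
    results = [pearson(cells["value_a"], cells["value_b"], ALL, ALL)]
    if keys:
        for combo, sub in cells.groupby(keys, sort=True, observed=True):
            if not isinstance(combo, tuple):
                combo = (combo,)
            labels = dict(zip(keys, (str(c) for c in combo)))
            results.append(
                pearson(
                    sub["value_a"],
                    sub["value_b"],
                    labels.get("cell_type", ALL),
                    labels.get("exposure", ALL),
                )
            )
    results.sort(key=lambda s: -s.n)
    return results


def celltype_contingency(cells: pd.DataFrame) -> pd.DataFrame:
    """Cell counts per (cell type x exposure), with margins.

    Rows (cell types) are ordered by descending total frequency, ties broken
    lexicographically; a "total" margin row and column are included and the
    grand total equals the number of cells.
    """
    if cells.empty:
        raise ValueError("cells table is empty")
    table = pd.crosstab(cells["cell_type"], cells["exposure"])
    totals = table.sum(axis=1)
    order = sorted(table.index, key=lambda ct: (-totals[ct], ct))
    table = table.loc[order]
    table["total"] = table.sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    return table


def fisher_z_compare(a: StratumCorrelation, b: StratumCorrelation) -> dict:
    """Fisher-z comparison of two strata's coefficients (plumbing only).

    Provided for completeness; excluded from default reports, which present
    coefficients side by side without a between-stratum test.
    """
    if not (a.defined and b.defined):
        raise ValueError("both correlations must be defined")
    za = math.atanh(a.r)
    zb = math.atanh(b.r)
    se = math.sqrt(1.0 / (a.n - 3) + 1.0 / (b.n - 3))
    z = (za - zb) / se
    return {"z": z, "p": float(2 * stats.norm.sf(abs(z)))}


def correlations_to_frame(results: Sequence[StratumCorrelation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_type": s.cell_type,
                "exposure": s.exposure,
                "n": s.n,
                "r": s.r,
                "df": s.df,
                "t": s.t,
                "p": s.p,
                "log10_p": s.log10_p,
                "defined": s.defined,
                "flag": s.flag,
            }
            for s in results
        ]
    )
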