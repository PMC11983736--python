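"""Nonparametric inference toolkit for the two-group comparisons.

Implements the quantification layer of the pipeline: the Wilcoxon
signed-rank test for paired tumor/normal differences, the
Wilcoxon-Mann-Whitney test for independent groups, bias-corrected and
accelerated (BCa) bootstrap confidence intervals for the difference of
group medians, and single-step min-P resampling adjustment for multiple
testing (Westfall-Young style family-wise error control).

Exact small-sample null distributions are computed by dynamic programming;
larger samples (or ties) use the tie-corrected normal approximation with a
0.5 continuity correction.  Everything that resamples takes an explicit
seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "BootstrapCI",
    "wilcoxon_signed_rank",
    "mann_whitney",
    "bca_bootstrap_median_diff",
    "bca_endpoint_probs",
    "resampling_adjust",
    "batch_adjust",
]

EXACT_SIGNED_RANK_MAX_N = 25
EXACT_MANN_WHITNEY_MAX_NM = 400
DEFAULT_B = 2000


@dataclass(frozen=True)
class TestResult:
    """Outcome of one rank test (optionally with a resampling-adjusted p)."""

    method: str  # signed_rank | mann_whitney
    statistic: float  # W+ or U
    n: int
    m: int | None
    mode: str  # exact | approximate
    p_raw: float
    p_adjusted: float | None = None
    feature_id: str | None = None
    defined: bool = True
    flag: str = ""


@dataclass(frozen=True)
class BootstrapCI:
    """BCa interval for a median difference, with its internals."""

    estimate: float
    lower: float
    upper: float
    level: float
    B: int
    z0: float
    a: float
    seed: int | None
    flag: str = ""


# ---------------------------------------------------------------------------
# Exact null distributions


def _signed_rank_counts(n: int) -> np.ndarray:
    """counts[w] = number of the 2^n sign assignments with W+ == w."""
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1, dtype=float)
    counts[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r else counts
        counts = counts + shifted
    return counts


def _mann_whitney_counts(n: int, m: int) -> np.ndarray:
    """counts[u] = number of the C(n+m, n) rank arrangements with U == u."""
    # recurrence over items: distribution of sum of a size-n subset of
    # ranks, shifted to U in [0, n*m]
    max_u = n * m
    counts = np.zeros((n + 1, max_u + 1), dtype=float)
    counts[0, 0] = 1.0
    for item in range(1, n + m + 1):
        for k in range(min(item, n), 0, -1):
            # choosing rank `item` as the k-th chosen adds item - k to U
            shift = item - k
            if shift == 0:
                counts[k] += counts[k - 1]
            else:
                counts[k, shift:] += counts[k - 1, : max_u + 1 - shift]
    return counts[n]


def _two_sided_from_counts(counts: np.ndarray, stat: float) -> float:
    total = counts.sum()
    cdf = counts.cumsum()
    idx_le = int(math.floor(stat + 1e-9))
    idx_ge = int(math.ceil(stat - 1e-9))
    p_le = cdf[min(idx_le, len(counts) - 1)] / total if idx_le >= 0 else 0.0
    p_ge = (total - (cdf[idx_ge - 1] if idx_ge > 0 else 0.0)) / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def _tie_term(values: np.ndarray) -> float:
    """sum(t^3 - t) over groups of tied values."""
    _, counts = np.unique(values, return_counts=True)
    t = counts.astype(float)
    return float(np.sum(t**3 - t))


# ---------------------------------------------------------------------------
# Signed-rank test


def wilcoxon_signed_rank(paired_differences: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon's convention, flagged when it
    happens); tied absolute differences get midranks.  The exact two-sided
    p is computed by enumeration of the 2^n sign assignments (via dynamic
    programming) when the effective n is at most 25 and there are no ties;
    otherwise a tie-corrected normal approximation with a 0.5 continuity
    correction is used.
    """
    d = np.asarray(paired_differences, dtype=float)
    flag = ""
    n_zero = int(np.sum(d == 0))
    if n_zero:
        d = d[d != 0]
        flag = f"{n_zero} zero differences dropped"
    n = d.size
    if n == 0:
        return TestResult(
            "signed_rank", float("nan"), 0, None, "exact", float("nan"),
            defined=False, flag="all differences zero",
        )
    absd = np.abs(d)
    ranks = sps.rankdata(absd)
    w_plus = float(ranks[d > 0].sum())
    has_ties = len(np.unique(absd)) < n
    if n <= EXACT_SIGNED_RANK_MAX_N and not has_ties:
        counts = _signed_rank_counts(n)
        p = _two_sided_from_counts(counts, w_plus)
        return TestResult("signed_rank", w_plus, n, None, "exact", p, flag=flag)
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - _tie_term(absd) / 48.0
    if var <= 0:
        return TestResult(
            "signed_rank", w_plus, n, None, "approximate", 1.0,
            flag=(flag + "; " if flag else "") + "degenerate variance",
        )
    z = max(abs(w_plus - mean) - 0.5, 0.0) / math.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(z)))
    return TestResult("signed_rank", w_plus, n, None, "approximate", p, flag=flag)


# ---------------------------------------------------------------------------
# Mann-Whitney test


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon-Mann-Whitney test from joint midranks.

    U is the Mann-Whitney statistic of ``x`` (number of (x, y) pairs with
    x above y, counting ties half).  Exact two-sided p by enumeration of
    rank arrangements when n*m <= 400 and there are no ties; otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r1 = float(ranks[:n].sum())
    u = r1 - n * (n + 1) / 2.0
    has_ties = len(np.unique(combined)) < n + m
    if n * m <= EXACT_MANN_WHITNEY_MAX_NM and not has_ties:
        counts = _mann_whitney_counts(n, m)
        p = _two_sided_from_counts(counts, u)
        return TestResult("mann_whitney", u, n, m, "exact", p)
    nm = n + m
    mean = n * m / 2.0
    var = n * m / 12.0 * (nm + 1 - _tie_term(combined) / (nm * (nm - 1)))
    if var <= 0:
        return TestResult(
            "mann_whitney", u, n, m, "approximate", 1.0, flag="degenerate variance"
        )
    z = max(abs(u - mean) - 0.5, 0.0) / math.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(z)))
    return TestResult("mann_whitney", u, n, m, "approximate", p)


# ---------------------------------------------------------------------------
# BCa bootstrap


def bca_endpoint_probs(z0: float, a: float, level: float) -> tuple[float, float]:
    """Adjusted quantile probabilities (alpha_1, alpha_2) of the BCa interval.

    With z0 = 0 and a = 0 these reduce algebraically to the plain
    percentile probabilities ((1 - level)/2, (1 + level)/2).
    """
    z_alpha = sps.norm.ppf((1 - level) / 2.0)
    probs = []
    for z_tail in (z_alpha, -z_alpha):
        arg = z0 + z_tail
        probs.append(float(sps.norm.cdf(z0 + arg / (1.0 - a * arg))))
    return probs[0], probs[1]


def _jackknife_medians_diff(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leave-one-out median differences pooled across both groups."""
    out = np.empty(x.size + y.size)
    med_y = np.median(y)
    med_x = np.median(x)
    for i in range(x.size):
        out[i] = np.median(np.delete(x, i)) - med_y
    for j in range(y.size):
        out[x.size + j] = med_x - np.median(np.delete(y, j))
    return out


def bca_bootstrap_median_diff(
    x: Sequence[float],
    y: Sequence[float],
    B: int = DEFAULT_B,
    level: float = 0.95,
    seed: int | None = None,
    paired: bool = False,
) -> BootstrapCI:
    """BCa bootstrap confidence interval for median(x) - median(y).

    Replicates resample the two groups independently (``paired=True``
    resamples patient pairs jointly instead, for matched designs).  The
    bias correction z0 uses a half-count for replicates exactly equal to
    the point estimate; the acceleration comes from a grouped jackknife
    pooled over leave-one-out deletions in both groups.  Endpoint
    probabilities are alpha_1 = Phi(z0 + (z0 + z_{alpha/2}) /
    (1 - a (z0 + z_{alpha/2}))) and the symmetric counterpart; endpoints
    are the corresponding quantiles of the bootstrap distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(x.size, y.size) < 5:
        raise ValueError("each group must have n >= 5")
    if B < 999:
        raise ValueError("B must be >= 999")
    if paired and x.size != y.size:
        raise ValueError("paired resampling needs equal group sizes")
    rng = np.random.default_rng(seed)
    theta_hat = float(np.median(x) - np.median(y))

    if paired:
        idx = rng.integers(0, x.size, size=(B, x.size))
        boot = np.median(x[idx], axis=1) - np.median(y[idx], axis=1)
    else:
        ix = rng.integers(0, x.size, size=(B, x.size))
        iy = rng.integers(0, y.size, size=(B, y.size))
        boot = np.median(x[ix], axis=1) - np.median(y[iy], axis=1)

    flag = ""
    if np.all(boot == boot[0]):
        return BootstrapCI(
            theta_hat, theta_hat, theta_hat, level, B, 0.0, 0.0, seed,
            flag="degenerate bootstrap distribution",
        )

    prop = (np.sum(boot < theta_hat) + 0.5 * np.sum(boot == theta_hat)) / B
    eps = 0.5 / B
    if prop <= 0 or prop >= 1:
        prop = min(max(prop, eps), 1 - eps)
        flag = "z0 proportion clipped"
    z0 = float(sps.norm.ppf(prop))

    jack = _jackknife_medians_diff(x, y)
    dev = jack.mean() - jack
    denom = np.sum(dev**2)
    if denom == 0:
        a = 0.0
        flag = (flag + "; " if flag else "") + "zero jackknife variance, a = 0"
    else:
        a = float(np.sum(dev**3) / (6.0 * denom**1.5))

    lower, upper = np.quantile(boot, bca_endpoint_probs(z0, a, level))
    if not (lower <= theta_hat <= upper):
        flag = (flag + "; " if flag else "") + "estimate outside interval"
    return BootstrapCI(theta_hat, float(lower), float(upper), level, B, z0, a, seed, flag)


# ---------------------------------------------------------------------------
# min-P resampling adjustment


def _mw_pvalues(rank_matrix: np.ndarray, indicator: np.ndarray, n1: int) -> np.ndarray:
    """Vectorized two-sided Mann-Whitney p for many features and label vectors.

    ``rank_matrix`` is samples x features of joint midranks; ``indicator``
    is draws x samples of 0/1 group-one memberships (each row summing to
    n1).  The permutation-exact moments of the rank sum are used, so ties
    are handled without explicit tie counts: Var(W) = n1 n2 s_R^2 / N with
    s_R^2 the sample variance of the ranks.
    """
    N, _ = rank_matrix.shape
    n2 = N - n1
    w = indicator @ rank_matrix  # draws x features
    mean = n1 * rank_matrix.mean(axis=0)
    var = n1 * n2 / N * rank_matrix.var(axis=0, ddof=1)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.maximum(np.abs(w - mean) - 0.5, 0.0) / sd
    p = 2.0 * sps.norm.sf(z)
    p = np.where(np.isfinite(p), np.minimum(p, 1.0), 1.0)
    return p


def _sr_pvalues(signed_ranks: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """Vectorized two-sided signed-rank p under sign-flip draws.

    ``signed_ranks`` is samples x features of sign(d) * midrank(|d|)
    (zeros contribute rank 0); ``signs`` is draws x samples of +/-1.
    W+ = (T + sum_i eps_i * signed_rank_i) / 2 with T the rank total.
    """
    absr = np.abs(signed_ranks)
    total = absr.sum(axis=0)
    var = (absr**2).sum(axis=0) / 4.0
    w = 0.5 * (total + signs @ signed_ranks)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.maximum(np.abs(w - total / 2.0) - 0.5, 0.0) / sd
    p = 2.0 * sps.norm.sf(z)
    p = np.where(np.isfinite(p), np.minimum(p, 1.0), 1.0)
    return p


def resampling_adjust(
    data: pd.DataFrame,
    group: Sequence | None = None,
    test: str = "mann_whitney",
    B: int = DEFAULT_B,
    seed: int | None = None,
    hypotheses: Sequence[str] | None = None,
) -> list[TestResult]:
    """Single-step min-P resampling adjustment across features.

    ``data`` is samples x features.  For ``test="mann_whitney"``,
    ``group`` assigns each row to one of two groups and group labels are
    permuted jointly across all features; for ``test="signed_rank"`` the
    rows are paired differences and their signs are flipped jointly.  For
    each of B draws the minimum p across features is recorded and the
    adjusted p of feature i is (1 + #{b : min_b <= p_raw_i}) / (B + 1),
    then enforced monotone nondecreasing in the raw p.  Raw and resampled
    p-values use the same permutation-moment normal approximation, so the
    comparison is like-for-like.

    Features with undefined raw p (zero rank variance) are excluded from
    the min and returned flagged.
    """
    if B < 999:
        raise ValueError("B must be >= 999")
    if hypotheses is not None:
        data = data[list(hypotheses)]
    if data.shape[1] < 1:
        raise ValueError("need at least one hypothesis")
    features = list(data.columns)
    values = data.to_numpy(dtype=float)
    N = values.shape[0]
    rng = np.random.default_rng(seed)

    if test == "mann_whitney":
        if group is None:
            raise ValueError("mann_whitney requires group labels")
        group = np.asarray(group)
        levels = pd.unique(group)
        if len(levels) != 2:
            raise ValueError(f"need exactly 2 group levels, got {list(levels)}")
        ind_obs = (group == levels[0]).astype(float)
        n1 = int(ind_obs.sum())
        ranks = sps.rankdata(values, axis=0)
        p_raw = _mw_pvalues(ranks, ind_obs[None, :], n1)[0]
        # joint label permutations
        keys = rng.random((B, N))
        perm = np.argsort(keys, axis=1)
        indicator = np.zeros((B, N))
        np.put_along_axis(indicator, perm[:, :n1], 1.0, axis=1)
        p_perm = _mw_pvalues(ranks, indicator, n1)
        statistic = (ind_obs @ ranks) - n1 * (n1 + 1) / 2.0
        n_report, m_report = n1, N - n1
    elif test == "signed_rank":
        nonzero = values != 0
        absr = np.zeros_like(values)
        for j in range(values.shape[1]):
            nz = nonzero[:, j]
            if nz.any():
                absr[nz, j] = sps.rankdata(np.abs(values[nz, j]))
        signed_ranks = absr * np.sign(values)
        p_raw = _sr_pvalues(signed_ranks, np.ones((1, N)))[0]
        signs = rng.choice([-1.0, 1.0], size=(B, N))
        p_perm = _sr_pvalues(signed_ranks, signs)
        statistic = np.where(signed_ranks > 0, signed_ranks, 0.0).sum(axis=0)
        n_report, m_report = N, None
    else:
        raise ValueError(f"unknown test {test!r}")

    defined = np.isfinite(p_raw) & (np.abs(values).sum(axis=0) > 0)
    # zero rank variance -> p forced to 1 upstream; treat those as defined
    usable = defined
    if not usable.any():
        raise ValueError("no feature has a defined raw p")
    min_b = p_perm[:, usable].min(axis=1)
    adjusted = np.full(len(features), np.nan)
    counts = (min_b[:, None] <= p_raw[None, usable]).sum(axis=0)
    adjusted[usable] = (1.0 + counts) / (B + 1.0)

    # enforce monotonicity in raw p
    order = np.argsort(p_raw[usable], kind="stable")
    adj_sorted = np.maximum.accumulate(adjusted[usable][order])
    tmp = adjusted[usable]
    tmp[order] = adj_sorted
    adjusted[usable] = tmp

    results = []
    for i, fid in enumerate(features):
        results.append(
            TestResult(
                method=test,
                statistic=float(statistic[i]),
                n=n_report,
                m=m_report,
                mode="approximate",
                p_raw=float(p_raw[i]),
                p_adjusted=float(adjusted[i]) if usable[i] else None,
                feature_id=str(fid),
                defined=bool(usable[i]),
                flag="" if usable[i] else "undefined raw p",
            )
        )
    return results


def batch_adjust(
    table: pd.DataFrame,
    test: str = "mann_whitney",
    B: int = DEFAULT_B,
    seed: int | None = None,
) -> pd.DataFrame:
    """Long-format batch interface to :func:`resampling_adjust`.

    ``table`` has columns (feature, sample, group, value); for
    ``test="signed_rank"`` the values are the paired differences and the
    group column is ignored.  Returns one row per feature carrying the
    statistic, raw and adjusted p, mode, B and seed for provenance.
    """
    required = {"feature", "sample", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"long table missing columns: {sorted(missing)}")
    wide = table.pivot(index="sample", columns="feature", values="value")
    if wide.isna().any().any():
        raise ValueError("every feature must be observed in every sample")
    group = None
    if test == "mann_whitney":
        if "group" not in table.columns:
            raise ValueError("mann_whitney requires a group column")
        groups = table.drop_duplicates("sample").set_index("sample")["group"]
        group = groups.loc[wide.index].to_numpy()
    results = resampling_adjust(wide, group=group, test=test, B=B, seed=seed)
    return pd.DataFrame(
        [
            {
                "feature": r.feature_id,
                "method": r.method,
                "statistic": r.statistic,
                "n": r.n,
                "m": r.m,
                "mode": r.mode,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "B": B,
                "seed": seed,
                "flag": r.flag,
            }
            for r in results
        ]
    )
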