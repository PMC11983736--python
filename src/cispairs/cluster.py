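"""Hierarchical clustering of differential features for heatmap ordering."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix

__all__ = ["Dendrogram", "hierarchical_cluster", "feature_distances"]

logger = logging.getLogger(__name__)

_MAX_CORR_DIST = 2.0  # 1 - r is bounded by 2; assigned to zero-variance rows


@dataclass
class Dendrogram:
    """Merge table and leaf order of an agglomerative clustering.

    ``merges`` has one row per merge: the two cluster indices joined (leaves
    are 0..n-1, internal clusters n, n+1, ... in merge order), the merge
    height, and the size of the new cluster.  ``leaf_order`` is the left-
    before-right traversal of the tree, a permutation of the feature ids.
    """

    merges: pd.DataFrame
    leaf_order: list[str]
    flagged_features: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.merges["height"].to_numpy()


def feature_distances(
    log2_values: np.ndarray, metric: str, standardize: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise feature distances; returns (square matrix, zero-variance mask).

    correlation distance is 1 - Pearson r between feature rows; euclidean
    operates on rows standardized to mean 0 / sd 1 unless ``standardize``
    is False.  Zero-variance rows get the maximal correlation distance to
    every other row (and are left unstandardized for euclidean).
    """
    x = np.asarray(log2_values, dtype=float)
    sd = x.std(axis=1, ddof=1)
    zero_var = sd == 0
    if metric == "correlation":
        xc = x - x.mean(axis=1, keepdims=True)
        norm = np.sqrt((xc**2).sum(axis=1))
        safe = np.where(zero_var, 1.0, norm)
        unit = xc / safe[:, None]
        dist = 1.0 - unit @ unit.T
        dist[zero_var, :] = _MAX_CORR_DIST
        dist[:, zero_var] = _MAX_CORR_DIST
    elif metric == "euclidean":
        if standardize:
            centered = x - x.mean(axis=1, keepdims=True)
            x = np.where(zero_var[:, None], centered, centered / np.where(zero_var, 1.0, sd)[:, None])
        diff = x[:, None, :] - x[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=-1))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    return dist, zero_var


def hierarchical_cluster(
    matrix: ExpressionMatrix,
    metric: str = "correlation",
    linkage: str = "average",
    log2: bool = True,
    standardize: bool = True,
) -> Dendrogram:
    """Agglomerative clustering of feature rows for display ordering.

    Operates on log2 intensities by default; with the euclidean metric the
    rows are additionally standardized (display convention; pass
    ``standardize=False`` for raw mode).  Linkage is "average" or
    "complete", both monotone, so merge heights are nondecreasing.  The
    merge sequence is deterministic: exact ties are resolved by the
    underlying nearest-neighbor chain order, which is fixed for fixed
    input.
    """
    if matrix.n_features < 2:
        raise ValueError("clustering needs >= 2 features")
    if linkage not in ("average", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    x = matrix.values.to_numpy(dtype=float)
    if log2:
        x = np.log2(np.maximum(x, np.finfo(float).tiny))
    dist, zero_var = feature_distances(x, metric, standardize=standardize)
    flagged = [fid for fid, z in zip(matrix.feature_ids, zero_var) if z]
    if flagged:
        logger.info("zero-variance features assigned maximal distance: %s", flagged[:10])
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    order = hierarchy.leaves_list(Z)
    merges = pd.DataFrame(
        {
            "cluster_a": Z[:, 0].astype(int),
            "cluster_b": Z[:, 1].astype(int),
            "height": Z[:, 2],
            "size": Z[:, 3].astype(int),
        }
    )
    leaf_order = [matrix.feature_ids[i] for i in order]
    return Dendrogram(merges, leaf_order, flagged)
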