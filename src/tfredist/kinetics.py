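"""Cluster dynamic features over the depletion time course into response
groups with summary kinetic traces.

Profiles are replicate-averaged normalized counts per timepoint, z-scored
across timepoints; clustering is hierarchical with 1 - Pearson correlation
distance and Ward linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.metrics import silhouette_score

from .diffcount import size_factors
from .io_formats import CountMatrix

__all__ = ["ResponseCluster", "standardize_profiles", "cluster_profiles"]

logger = logging.getLogger(__name__)


@dataclass
class ResponseCluster:
    cluster_id: int
    members: list[str]
    centroid: pd.Series  # median z-profile per timepoint
    iqr_low: pd.Series
    iqr_high: pd.Series

    @property
    def size(self) -> int:
        return len(self.members)


def standardize_profiles(
    counts: CountMatrix,
    dynamic_ids: Sequence[str],
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Feature x timepoint z-score matrix for the dynamic features.

    Counts are size-factor normalized, averaged over replicates within each
    timepoint, then z-scored per feature across timepoints.  Zero-variance
    features are dropped (logged).
    """
    missing = set(dynamic_ids) - set(counts.feature_ids)
    if missing:
        raise ValueError(f"unknown dynamic feature ids: {sorted(missing)[:5]}")
    if factors is None:
        factors = size_factors(counts)
    norm = counts.counts.loc[list(dynamic_ids)].div(factors, axis=1)
    tps = counts.sample_meta["timepoint"]
    per_tp = norm.T.groupby(tps.loc[norm.columns]).mean().T  # feature x timepoint
    per_tp = per_tp[sorted(per_tp.columns)]
    sd = per_tp.std(axis=1, ddof=0)
    zero_var = sd == 0
    if zero_var.any():
        logger.info("dropping %d zero-variance features", int(zero_var.sum()))
    kept = per_tp.loc[~zero_var]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd.loc[~zero_var], axis=0)
    return z


def _choose_k(z: np.ndarray, link: np.ndarray, dmat: np.ndarray, k_max: int) -> int:
    """Smallest k whose silhouette is within 5% of the best over 2..k_max."""
    n = z.shape[0]
    k_max = min(k_max, n - 1)
    scores = {}
    square = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    square[iu] = dmat
    square += square.T
    for k in range(2, k_max + 1):
        labels = fcluster(link, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        scores[k] = silhouette_score(square, labels, metric="precomputed")
    if not scores:
        return 2
    best = max(scores.values())
    for k in sorted(scores):
        if scores[k] >= best - 0.05 * abs(best):
            return k
    return min(scores)


def cluster_profiles(
    z: pd.DataFrame,
    k: int | None = None,
    min_size: int = 15,
    discard_small: bool = False,
    k_max: int = 8,
) -> list[ResponseCluster]:
    """Hierarchical clustering of z-profiles into response groups.

    Distance is 1 - Pearson correlation between profiles, Ward linkage; the
    tree is cut at ``k`` clusters (when None, the smallest k whose silhouette
    is within 5% of the best over 2..k_max).  Clusters below ``min_size`` are
    merged into the nearest centroid by correlation distance, or discarded
    when ``discard_small``.  Rows are sorted by feature id first so the
    result is order-independent.
    """
    z = z.sort_index()
    n = len(z)
    if k is not None and k > n:
        raise ValueError(f"k={k} exceeds {n} features")
    if k is None and n < 2 * min_size:
        raise ValueError(f"need >= {2 * min_size} features for automatic k")
    arr = z.to_numpy()
    if k == 1:
        labels = np.ones(n, dtype=int)
    else:
        dmat = pdist(arr, metric="correlation")
        link = linkage(dmat, method="ward")
        if k is None:
            k = _choose_k(arr, link, dmat, k_max)
        labels = fcluster(link, t=k, criterion="maxclust")

    def centroid(mask: np.ndarray) -> np.ndarray:
        return np.median(arr[mask], axis=0)

    # merge or discard undersized clusters
    ids = sorted(np.unique(labels))
    small = [c for c in ids if (labels == c).sum() < min_size]
    big = [c for c in ids if c not in small]
    if small and big:
        if discard_small:
            keep = np.isin(labels, big)
            arr, labels = arr[keep], labels[keep]
            z = z.loc[keep]
        else:
            cents = {c: centroid(labels == c) for c in big}
            for c in small:
                for i in np.nonzero(labels == c)[0]:
                    dists = {
                        b: 1 - np.corrcoef(arr[i], cent)[0, 1]
                        for b, cent in cents.items()
                    }
                    labels[i] = min(dists, key=dists.get)

    clusters = []
    for new_id, c in enumerate(sorted(np.unique(labels)), start=1):
        mask = labels == c
        block = arr[mask]
        clusters.append(
            ResponseCluster(
                cluster_id=new_id,
                members=list(z.index[mask]),
                centroid=pd.Series(np.median(block, axis=0), index=z.columns),
                iqr_low=pd.Series(np.percentile(block, 25, axis=0), index=z.columns),
                iqr_high=pd.Series(np.percentile(block, 75, axis=0), index=z.columns),
            )
        )
    return clusters
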