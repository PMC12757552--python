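"""Cluster Cys sites by their oxidation profiles across conditions.

Agglomerative hierarchical clustering (average linkage, Euclidean distance,
optional per-row z-scoring) cut to exactly k clusters, followed by an
automated merge of clusters with correlated centroids into lettered groups
(A, B, C, ...). The lettered grouping mirrors the manual "similar profile"
grouping commonly drawn on clustered heatmaps; it is governed by a single
centroid-correlation threshold rather than claimed to reproduce any manual
choice.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .io_formats import ParameterError

logger = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    assignments: pd.Series          # site_key -> cluster_id (1..k)
    centroids: pd.DataFrame         # cluster_id x profile column (original scale)
    groups: pd.Series | None = None  # cluster_id -> group letter
    params: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.centroids)

    def site_groups(self) -> pd.Series:
        """Per-site group letter (requires group_clusters to have run)."""
        if self.groups is None:
            raise ParameterError("no group labels: run group_clusters first")
        return self.assignments.map(self.groups)


def _group_label(i: int) -> str:
    letters = string.ascii_uppercase
    label = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        label = letters[rem] + label
    return label


def cluster_profiles(profiles: pd.DataFrame, k: int,
                     standardize: bool = False) -> ClusterResult:
    """Hierarchical clustering of site x condition oxidation profiles.

    Rows with missing values are dropped (and logged). Rows are sorted by
    site_key before linkage so the result is invariant to input row order;
    ties in the dendrogram are broken by that lexicographic order. Cluster
    ids are relabelled 1..k by first appearance in sorted site order.
    ``standardize`` z-scores each row first (zero-variance rows become
    all-zero profiles).
    """
    complete = profiles.dropna(axis=0)
    n_dropped = len(profiles) - len(complete)
    if n_dropped:
        logger.info("cluster_profiles: dropped %d rows with missing values",
                    n_dropped)
    complete = complete.sort_index()
    n = len(complete)
    if n == 0:
        raise ParameterError("no complete profiles to cluster")
    if k < 1 or k > n:
        raise ParameterError(f"k={k} must be in [1, {n}]")

    x = complete.to_numpy(dtype=float)
    if standardize:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=0, keepdims=True)
        x = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    if k == n:
        raw = np.arange(1, n + 1)
    else:
        z = linkage(x, method="average", metric="euclidean")
        raw = fcluster(z, t=k, criterion="maxclust")

    # deterministic relabelling: 1..k in order of first appearance
    relabel: dict[int, int] = {}
    for c in raw:
        if c not in relabel:
            relabel[c] = len(relabel) + 1
    ids = np.array([relabel[c] for c in raw])
    assignments = pd.Series(ids, index=complete.index, name="cluster_id")

    centroids = (complete.groupby(assignments).mean()
                 .sort_index())
    centroids.index.name = "cluster_id"
    return ClusterResult(
        assignments=assignments,
        centroids=centroids,
        params={"k": k, "linkage": "average", "metric": "euclidean",
                "standardize": standardize},
    )


def group_clusters(result: ClusterResult,
                   min_centroid_correlation: float = 0.8) -> ClusterResult:
    """Merge clusters whose centroid profiles correlate into lettered groups.

    Single-linkage merge: clusters whose centroid Pearson correlation meets
    the threshold are connected, and connected components become groups
    labelled A, B, C, ... in order of descending member count (ties broken
    by smallest cluster id). Constant centroids correlate 1 with an equal
    centroid and are otherwise left unmerged.
    """
    if not (0.0 < min_centroid_correlation <= 1.0):
        raise ParameterError("min_centroid_correlation must be in (0, 1]")
    cent = result.centroids.to_numpy(dtype=float)
    k = len(cent)
    sd = cent.std(axis=1, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(cent) if k > 1 else np.ones((1, 1))
    corr = np.atleast_2d(corr)
    for i in range(k):
        for j in range(k):
            if np.isnan(corr[i, j]):
                corr[i, j] = 1.0 if (sd[i] == 0 and sd[j] == 0
                                     and np.allclose(cent[i], cent[j])) else -1.0

    # union-find over the threshold graph
    parent = list(range(k))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(k):
        for j in range(i + 1, k):
            if corr[i, j] >= min_centroid_correlation:
                parent[find(i)] = find(j)

    cluster_ids = list(result.centroids.index)
    sizes = result.assignments.value_counts()
    components: dict[int, list] = {}
    for idx, cid in enumerate(cluster_ids):
        components.setdefault(find(idx), []).append(cid)
    ordered = sorted(
        components.values(),
        key=lambda cids: (-sum(int(sizes.get(c, 0)) for c in cids), min(cids)),
    )
    groups = pd.Series(index=pd.Index(cluster_ids, name="cluster_id"),
                       dtype=object)
    for rank, cids in enumerate(ordered):
        for c in cids:
            groups.loc[c] = _group_label(rank)
    logger.info("group_clusters: %d clusters -> %d groups at r >= %g",
                k, len(ordered), min_centroid_correlation)
    params = dict(result.params)
    params["min_centroid_correlation"] = min_centroid_correlation
    return ClusterResult(assignments=result.assignments,
                         centroids=result.centroids,
                         groups=groups, params=params)
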