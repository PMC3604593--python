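"""Minimal Discriminant Analysis on Principal Components (DAPC).

The architecture is: k-means on the gene scores in the (already reduced)
PC space proposes k groups without any a priori on the data structure, then
a linear discriminant analysis trained on those groups re-assigns every
gene to its highest-membership group.  With k = 3 the three groups are
interpreted as "no differential gene expression" (the cluster hugging the
origin) plus one group per biological condition; cluster → condition names
are resolved geometrically against the condition directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .datamodel import UNASSIGNED
from .pcspace import Direction, PCSpace

logger = logging.getLogger(__name__)

#: number of random k-means restarts (best within-cluster SS kept)
KMEANS_RESTARTS = 25


class DegenerateClusteringError(ValueError):
    """Raised when fewer than k clusters remain populated."""


@dataclass
class DapcResult:
    """k-means + DA group assignment of genes in PC space.

    ``cluster`` holds 0-based cluster indices after the DA re-assignment;
    ``membership`` the DA posterior probability of the assigned group;
    ``cluster_labels`` maps cluster index → semantic label once
    :func:`map_clusters_to_conditions` has run.
    """

    gene_ids: list[str]
    cluster: np.ndarray
    membership: np.ndarray
    centroids: np.ndarray
    k: int
    seed: int
    cluster_labels: dict[int, str] | None = None

    @property
    def labels(self) -> np.ndarray:
        """Per-gene semantic labels (requires a mapped result)."""
        if self.cluster_labels is None:
            raise ValueError("clusters have not been mapped to conditions yet")
        lut = np.array(
            [self.cluster_labels[i] for i in range(self.k)], dtype=object
        )
        return lut[self.cluster]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"gene_id": self.gene_ids, "cluster": self.cluster + 1,
             "membership_score": self.membership}
        )
        if self.cluster_labels is not None:
            df["mapped_label"] = self.labels
        return df


def dapc_assign(
    scores: np.ndarray, k: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """k-means grouping followed by LDA re-assignment on raw score arrays.

    Returns ``(cluster, membership, centroids)`` where centroids are the
    means of the re-assigned clusters.  Deterministic given ``seed``.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if n < 10 * k:
        raise ValueError(f"need at least {10 * k} genes for k={k}, got {n}")
    km = KMeans(n_clusters=k, n_init=KMEANS_RESTARTS, random_state=int(seed))
    init_labels = km.fit_predict(scores)
    if len(np.unique(init_labels)) < k:
        raise DegenerateClusteringError(
            f"k-means produced an empty cluster; try a smaller k than {k}"
        )
    lda = LinearDiscriminantAnalysis()
    lda.fit(scores, init_labels)
    proba = lda.predict_proba(scores)
    cluster = np.argmax(proba, axis=1)
    membership = proba[np.arange(n), cluster]
    sizes = np.bincount(cluster, minlength=k)
    if np.any(sizes == 0):
        raise DegenerateClusteringError(
            f"discriminant re-assignment emptied a cluster (sizes {sizes.tolist()}); "
            f"try a smaller k than {k}"
        )
    centroids = np.stack([scores[cluster == i].mean(axis=0) for i in range(k)])
    return cluster, membership, centroids


def run_dapc(space: PCSpace, k: int = 3, seed: int = 0) -> DapcResult:
    """Run DAPC on all genes of a fitted PC space."""
    cluster, membership, centroids = dapc_assign(space.gene_scores, k, seed)
    return DapcResult(
        gene_ids=list(space.gene_ids),
        cluster=cluster,
        membership=membership,
        centroids=centroids,
        k=k,
        seed=int(seed),
    )


def map_centroids_to_conditions(
    centroids: np.ndarray, directions: list[Direction], with_null: bool
) -> dict[int, str]:
    """Geometric cluster → label rule.

    With ``with_null`` (k = 3), the centroid with the smallest norm is
    labeled "no differential expression"; each remaining cluster takes the
    condition whose direction gives its centroid the largest |cosine|
    (sign-blind, since genes of one condition sit on both sides of the
    origin).  If both clusters prefer the same condition, the
    better-matching one wins and the other takes the remaining label
    (logged as a warning).
    """
    k = centroids.shape[0]
    labels: dict[int, str] = {}
    remaining = list(range(k))
    if with_null:
        null_idx = int(np.argmin(np.linalg.norm(centroids, axis=1)))
        labels[null_idx] = UNASSIGNED
        remaining.remove(null_idx)
    if len(remaining) != 2:
        raise ValueError(
            f"condition mapping expects 2 non-null clusters, got {len(remaining)}"
        )
    D = np.stack([d.vector for d in directions])
    dnorm = np.linalg.norm(D, axis=1)
    C = centroids[remaining]
    cnorm = np.linalg.norm(C, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.abs(C @ D.T) / np.outer(cnorm, dnorm)
    cos = np.nan_to_num(cos)
    prefs = np.argmax(cos, axis=1)
    if prefs[0] == prefs[1]:
        logger.warning(
            "WARN: both clusters best match condition %r; resolving by "
            "strength of match", directions[prefs[0]].condition
        )
        winner = int(np.argmax(cos[:, prefs[0]]))
        loser = 1 - winner
        labels[remaining[winner]] = directions[prefs[0]].condition
        labels[remaining[loser]] = directions[1 - prefs[0]].condition
    else:
        labels[remaining[0]] = directions[prefs[0]].condition
        labels[remaining[1]] = directions[prefs[1]].condition
    return labels


def map_clusters_to_conditions(
    dapc: DapcResult, directions: list[Direction], space: PCSpace | None = None
) -> DapcResult:
    """Attach semantic labels to a k = 3 DAPC result.

    Never fails on pathological geometry — ambiguous mappings are resolved
    with a warning (see :func:`map_centroids_to_conditions`).
    """
    if dapc.k != 3:
        raise ValueError(f"condition mapping requires k=3, got k={dapc.k}")
    labels = map_centroids_to_conditions(dapc.centroids, directions, with_null=True)
    return replace(dapc, cluster_labels=labels)
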