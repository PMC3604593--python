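"""The four classification strategies.

Each strategy turns upstream C_d and/or DAPC output into a per-gene final
label: one of the two condition labels, or "none" (no differential
expression detected).

* ``dapc`` — k = 3 DAPC alone; labels come from the cluster → condition map.
* ``cd`` — C_d alone: genes with |C_d| above a threshold are assigned to
  their closest direction.
* ``cd+dapc`` — DAPC restricted to the genes C_d places in the zone of
  interest (|C_d| > threshold); everything else is "none".
* ``cd-inter-dapc`` — the consensus: a gene keeps a condition label only
  when the ``cd`` and ``dapc`` strategies agree on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cd import CdResult, assign_by_cd, _as_threshold_vector
from .dapc import DapcResult, dapc_assign, map_centroids_to_conditions
from .datamodel import UNASSIGNED
from .pcspace import Direction, PCSpace

STRATEGY_DAPC = "dapc"
STRATEGY_CD = "cd"
STRATEGY_CD_WITH_DAPC = "cd+dapc"
STRATEGY_CD_INTER_DAPC = "cd-inter-dapc"
STRATEGIES = (
    STRATEGY_DAPC, STRATEGY_CD, STRATEGY_CD_WITH_DAPC, STRATEGY_CD_INTER_DAPC
)


@dataclass
class ClassificationResult:
    """Final per-gene labels produced by one strategy."""

    strategy: str
    gene_ids: list[str]
    labels: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != (len(self.gene_ids),):
            raise ValueError("one label per gene is required")

    def counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.gene_ids, "label": self.labels})


def classify_dapc_only(dapc: DapcResult) -> ClassificationResult:
    """Labels straight from a mapped k = 3 DAPC result."""
    if dapc.cluster_labels is None:
        raise ValueError("DAPC clusters must be mapped to conditions first")
    return ClassificationResult(
        strategy=STRATEGY_DAPC,
        gene_ids=list(dapc.gene_ids),
        labels=dapc.labels,
        params={"k": dapc.k, "seed": dapc.seed},
    )


def classify_cd_only(
    cd: CdResult, threshold: float | dict[str, float]
) -> ClassificationResult:
    """C_d thresholding alone (after the norm filter)."""
    assigned = assign_by_cd(cd, threshold)
    return ClassificationResult(
        strategy=STRATEGY_CD,
        gene_ids=list(cd.gene_ids),
        labels=assigned.assigned,
        params={"threshold": threshold, "filter_quantile": cd.filter_quantile},
    )


def classify_cd_with_dapc(
    cd: CdResult,
    space: PCSpace,
    directions: list[Direction],
    threshold: float | dict[str, float],
    k: int = 2,
    seed: int = 0,
) -> ClassificationResult:
    """DAPC run on only the genes C_d finds close to either direction.

    The subset k defaults to 2 because thresholding has already removed the
    centre-of-map mass that would form a null cluster; k = 3 is available.
    Full-data PC coordinates are reused (re-fitting the PCA on the subset
    would move the directions).
    """
    thr = _as_threshold_vector(threshold, cd.conditions)
    mask = np.any(cd.abs_cd > thr[None, :], axis=1) & ~cd.filtered
    n_pass = int(mask.sum())
    if n_pass < 10 * k:
        raise ValueError(
            f"only {n_pass} genes pass the C_d threshold; at least {10 * k} "
            f"are required for a k={k} DAPC"
        )
    cluster, _membership, centroids = dapc_assign(
        space.gene_scores[mask], k, seed
    )
    cmap = map_centroids_to_conditions(centroids, directions, with_null=(k == 3))
    labels = np.full(cd.n_genes, UNASSIGNED, dtype=object)
    lut = np.array([cmap[i] for i in range(k)], dtype=object)
    labels[mask] = lut[cluster]
    return ClassificationResult(
        strategy=STRATEGY_CD_WITH_DAPC,
        gene_ids=list(cd.gene_ids),
        labels=labels,
        params={"threshold": threshold, "k": k, "seed": int(seed)},
    )


def classify_cd_inter_dapc(
    cd_result: ClassificationResult, dapc_result: ClassificationResult
) -> ClassificationResult:
    """Consensus of the independent ``cd`` and ``dapc`` classifications."""
    if list(cd_result.gene_ids) != list(dapc_result.gene_ids):
        raise ValueError(
            "cd and dapc classifications cover different gene sets"
        )
    agree = cd_result.labels == dapc_result.labels
    labels = np.where(agree, cd_result.labels, UNASSIGNED).astype(object)
    labels[cd_result.labels == UNASSIGNED] = UNASSIGNED
    return ClassificationResult(
        strategy=STRATEGY_CD_INTER_DAPC,
        gene_ids=list(cd_result.gene_ids),
        labels=labels,
        params={"cd": cd_result.params, "dapc": dapc_result.params},
    )
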