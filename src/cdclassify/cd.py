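"""The C_d closeness measure.

For a gene with score vector ``g`` and a condition direction ``d`` in the
retained PC space,

    C_d(g, d) = sign(<g, d>) * ||proj_d(g)|| / ||g||

i.e. the signed cosine of the angle between gene and direction.  It is ±1
exactly when ``g`` is collinear with ``d`` (a strong relationship to that
condition — the sign only encodes on which side of the origin the gene
lies), and 0 when the gene is orthogonal to the direction (no relationship,
no differential expression).  Values in between grade the closeness.

Because a cosine cannot see how far a gene sits from the origin, genes whose
expression is mostly noise (small score norm, centre of the factorial map)
are removed by the norm-quartile filter: the 25 % of genes with the smallest
norms have their C_d fixed to 0 before any assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datamodel import UNASSIGNED
from .pcspace import Direction, PCSpace

logger = logging.getLogger(__name__)


def cd_value(gene_vector: np.ndarray, direction: np.ndarray) -> float:
    """Signed closeness of one gene vector to one direction.

    Computed through the orthogonal projection: the ratio of the norm of
    the projection of ``gene_vector`` onto ``direction`` to the gene
    vector's own norm, carrying the sign of the inner product.

    A zero-norm direction is an error; a zero-norm gene returns 0 (a gene
    at the origin is noise and has no relationship to any direction).
    """
    g = np.asarray(gene_vector, dtype=float)
    d = np.asarray(direction, dtype=float)
    nd = np.linalg.norm(d)
    if nd == 0:
        raise ValueError("direction has zero norm")
    ng = np.linalg.norm(g)
    if ng == 0:
        logger.info("zero-norm gene vector: C_d set to 0")
        return 0.0
    coef = float(np.dot(g, d)) / (nd * nd)
    proj_norm = abs(coef) * nd
    return float(np.sign(coef)) * proj_norm / ng


@dataclass
class CdResult:
    """Per-gene signed closeness to each condition direction.

    ``cd`` has one column per condition (order of ``conditions``);
    ``filtered`` marks genes removed by the norm-quartile filter (their
    ``cd`` row is 0); ``assigned`` holds the condition label after
    :func:`assign_by_cd`, else :data:`~cdclassify.datamodel.UNASSIGNED`.
    """

    gene_ids: list[str]
    conditions: list[str]
    cd: np.ndarray
    norm: np.ndarray
    filtered: np.ndarray
    assigned: np.ndarray
    threshold: float | dict[str, float] | None = None
    filter_quantile: float | None = None

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_filtered(self) -> int:
        return int(self.filtered.sum())

    @property
    def abs_cd(self) -> np.ndarray:
        return np.abs(self.cd)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"gene_id": self.gene_ids, "norm": self.norm})
        for j, cond in enumerate(self.conditions):
            df[f"cd_{cond}"] = self.cd[:, j]
        df["filtered"] = self.filtered
        df["assigned"] = self.assigned
        return df


def compute_cd(space: PCSpace, directions: list[Direction]) -> CdResult:
    """C_d of every gene against every condition direction (unfiltered)."""
    D = np.stack([d.vector for d in directions])          # (2, K)
    dnorm = np.linalg.norm(D, axis=1)
    if np.any(dnorm == 0):
        raise ValueError("direction has zero norm")
    scores = space.gene_scores
    gnorm = space.gene_norms
    coef = (scores @ D.T) / (dnorm ** 2)                  # projection coefficients
    proj_norm = np.abs(coef) * dnorm                      # ||proj_d(g)||
    with np.errstate(invalid="ignore", divide="ignore"):
        cd = np.sign(coef) * proj_norm / gnorm[:, None]
    zero = gnorm == 0
    if zero.any():
        logger.info("%d zero-norm genes: C_d set to 0", int(zero.sum()))
        cd[zero] = 0.0
    return CdResult(
        gene_ids=list(space.gene_ids),
        conditions=[d.condition for d in directions],
        cd=cd,
        norm=gnorm,
        filtered=np.zeros(len(space.gene_ids), dtype=bool),
        assigned=np.full(len(space.gene_ids), UNASSIGNED, dtype=object),
    )


def apply_norm_filter(result: CdResult, quantile: float = 0.25) -> CdResult:
    """Zero out C_d for genes with score norms in the lowest quantile.

    The cutoff is the empirical quantile (linear interpolation) of all gene
    norms; a gene is filtered when its norm is *strictly* below the cutoff,
    so if all norms are identical nothing is filtered.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError(f"quantile must be in (0, 1), got {quantile}")
    cutoff = float(np.quantile(result.norm, quantile))
    mask = result.norm < cutoff
    cd = result.cd.copy()
    cd[mask] = 0.0
    logger.info(
        "norm filter: %d of %d genes below the %.0f%% cutoff (%.4g)",
        int(mask.sum()), result.n_genes, 100 * quantile, cutoff,
    )
    return replace(
        result, cd=cd, filtered=mask,
        assigned=np.full(result.n_genes, UNASSIGNED, dtype=object),
        filter_quantile=quantile,
    )


def assign_by_cd(
    result: CdResult, threshold: float | dict[str, float]
) -> CdResult:
    """Assign each unfiltered gene to its closest direction above threshold.

    A gene is assigned to the condition with the largest ``|C_d|`` provided
    that value exceeds the (possibly per-condition) threshold; sign is
    ignored (−1 and 1 both mean a close relationship, on opposite sides of
    the origin).  Exact ties between the two directions are left
    unassigned.
    """
    thr = _as_threshold_vector(threshold, result.conditions)
    a = result.abs_cd
    best = np.argmax(a, axis=1)
    best_val = a[np.arange(result.n_genes), best]
    tie = a[:, 0] == a[:, 1]
    passed = best_val > thr[best]
    assigned = np.full(result.n_genes, UNASSIGNED, dtype=object)
    ok = passed & ~tie & ~result.filtered
    assigned[ok] = np.asarray(result.conditions, dtype=object)[best[ok]]
    n_tie = int((tie & passed & ~result.filtered).sum())
    if n_tie:
        logger.info("%d genes tied between directions left unassigned", n_tie)
    return replace(result, assigned=assigned, threshold=threshold)


def _as_threshold_vector(
    threshold: float | dict[str, float], conditions: list[str]
) -> np.ndarray:
    if isinstance(threshold, dict):
        vals = [threshold[c] for c in conditions]
    else:
        vals = [float(threshold)] * len(conditions)
    arr = np.asarray(vals, dtype=float)
    if np.any((arr <= 0) | (arr >= 1)):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return arr
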