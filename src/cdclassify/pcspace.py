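"""Correlation PCA of the expression matrix and per-condition directions.

Genes are the observations and replicate arrays the variables.  The PCA is
run on centred, unit-variance columns (correlation PCA), so the variable
coordinates are the correlations of each replicate with the retained
components and live inside the unit circle ("corcircle" convention,
loading × sqrt(eigenvalue)).  A *direction* is the arithmetic mean of the
variable-coordinate vectors of all replicates of one condition — the
geometric proxy for that biological condition against which gene closeness
is measured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datamodel import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class PCSpace:
    """Retained principal axes of a correlation PCA.

    ``gene_scores`` are the coordinates of genes (observations) on the
    factorial map; ``variable_coords`` the correlation-circle coordinates of
    the replicates (variables).  ``eigenvalues`` are the per-axis variances
    (population convention: their full-spectrum sum equals the number of
    standardized variables).
    """

    n_components: int
    eigenvalues: np.ndarray
    gene_scores: np.ndarray
    variable_coords: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    replicate_ids: list[str] = field(default_factory=list)

    @property
    def gene_norms(self) -> np.ndarray:
        """Euclidean norm of each gene's score vector in the retained space."""
        return np.linalg.norm(self.gene_scores, axis=1)


@dataclass
class Direction:
    """Mean variable-coordinate vector of one condition's replicates."""

    condition: str
    vector: np.ndarray
    members: list[str]

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if np.linalg.norm(self.vector) < 1e-12:
            raise ValueError(
                f"direction for condition {self.condition!r} has zero norm"
            )


def fit_pca(matrix: ExpressionMatrix, n_components: int = 2) -> PCSpace:
    """Fit a correlation PCA with genes as observations.

    Columns (replicates) are centred and scaled to unit variance
    (population sd); the decomposition is the SVD of the standardized
    matrix.  Axis signs are fixed so that the first condition's mean
    variable coordinate is non-negative on every retained axis, making
    output deterministic across runs and linear-algebra backends.

    Raises
    ------
    ValueError
        If a replicate column is constant (zero variance) or
        ``n_components`` is out of range.
    """
    X = matrix.values
    n, p = X.shape
    if p < 2:
        raise ValueError("at least 2 replicates are required")
    if not 1 <= n_components <= min(n, p):
        raise ValueError(
            f"n_components={n_components} out of range 1..{min(n, p)}"
        )
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    dead = np.flatnonzero(scale <= 0)
    if dead.size:
        raise ValueError(
            f"replicate column {matrix.replicate_ids[dead[0]]!r} is constant "
            "(zero variance); correlation PCA is undefined"
        )
    Z = (X - center) / scale

    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    eigenvalues = (S ** 2) / n
    gene_scores = U * S
    # correlation of variable j with component k: V[j,k] * sqrt(lambda_k)
    variable_coords = Vt.T * (S / np.sqrt(n))

    k = n_components
    eigenvalues = eigenvalues[:k]
    gene_scores = gene_scores[:, :k]
    variable_coords = variable_coords[:, :k]

    first = matrix.conditions[0]
    cols = matrix.columns_for(first)
    flip = variable_coords[cols].mean(axis=0) < 0
    gene_scores[:, flip] *= -1.0
    variable_coords[:, flip] *= -1.0

    return PCSpace(
        n_components=k,
        eigenvalues=eigenvalues,
        gene_scores=gene_scores,
        variable_coords=variable_coords,
        center=center,
        scale=scale,
        gene_ids=list(matrix.gene_ids),
        replicate_ids=list(matrix.replicate_ids),
    )


def build_directions(space: PCSpace, matrix: ExpressionMatrix) -> list[Direction]:
    """One direction per condition: mean of its replicates' variable coords."""
    directions = []
    for cond in matrix.conditions:
        cols = matrix.columns_for(cond)
        if cols.size == 0:
            raise ValueError(f"condition {cond!r} has no replicates")
        vec = space.variable_coords[cols].mean(axis=0)
        directions.append(
            Direction(cond, vec, [matrix.replicate_ids[i] for i in cols])
        )
    return directions


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


@dataclass
class CoherenceReport:
    """Diagnostics on how well replicates agree with their direction."""

    within_cosine: dict[str, float]
    between_cosine: float
    warnings: list[str]

    @property
    def ok(self) -> bool:
        return not self.warnings


def check_direction_coherence(
    space: PCSpace,
    directions: list[Direction],
    min_cohesion: float = 0.5,
    max_between: float = 0.6,
) -> CoherenceReport:
    """Diagnose whether the two condition directions are trustworthy.

    Reports the mean cosine between each member replicate's coordinate
    vector and its condition direction, and the cosine between the two
    directions.  Warns when within-condition cohesion drops below
    ``min_cohesion`` or when the two directions are nearly collinear
    (``|cosine| > max_between``: conditions confounded).  Diagnostic only —
    never raises.
    """
    rep_index = {r: i for i, r in enumerate(space.replicate_ids)}
    within: dict[str, float] = {}
    warnings: list[str] = []
    for d in directions:
        cosines = [
            _cosine(space.variable_coords[rep_index[r]], d.vector)
            for r in d.members
        ]
        within[d.condition] = float(np.mean(cosines))
        if within[d.condition] < min_cohesion:
            warnings.append(
                f"WARN: condition {d.condition!r} replicates are weakly aligned "
                f"with their direction (mean cosine "
                f"{within[d.condition]:.3f} < {min_cohesion})"
            )
    between = _cosine(directions[0].vector, directions[1].vector)
    if abs(between) > max_between:
        warnings.append(
            f"WARN: the two condition directions are nearly collinear "
            f"(|cosine| {abs(between):.3f} > {max_between}); conditions may "
            "be confounded"
        )
    for w in warnings:
        logger.warning(w)
    return CoherenceReport(within, between, warnings)
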