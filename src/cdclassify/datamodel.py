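"""Core domain types shared by every module.

The central object is :class:`ExpressionMatrix`: a genes × replicates numeric
matrix (intensities assumed already calibrated / log-scale) together with a
design mapping each replicate (array) to one of exactly two biological
condition labels.  Genes play the role of individuals and replicates the role
of variables throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Label used for "no differential gene expression" / not assigned.
UNASSIGNED = "none"


@dataclass
class ExpressionMatrix:
    """Two-condition replicated expression matrix.

    Parameters
    ----------
    gene_ids
        Unique row identifiers (genes).
    replicate_ids
        Unique column identifiers (replicate arrays), order as in the input.
    values
        Numeric matrix of shape ``(len(gene_ids), len(replicate_ids))``;
        all entries finite.
    condition_of
        Map replicate_id → condition label; exactly two distinct labels,
        each with at least two replicates.
    """

    gene_ids: list[str]
    replicate_ids: list[str]
    values: np.ndarray
    condition_of: dict[str, str]

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.replicate_ids = [str(r) for r in self.replicate_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.gene_ids):
            raise ValueError(
                f"row count {n} does not match number of gene ids {len(self.gene_ids)}"
            )
        if p != len(self.replicate_ids):
            raise ValueError(
                f"column count {p} does not match number of replicate ids "
                f"{len(self.replicate_ids)}"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.replicate_ids, "replicate id")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"replicate {self.replicate_ids[bad[1]]!r}"
            )
        missing = [r for r in self.replicate_ids if r not in self.condition_of]
        if missing:
            raise ValueError(f"replicate {missing[0]!r} missing from design")
        labels = self.conditions
        if len(labels) != 2:
            raise ValueError(
                f"expected exactly 2 condition labels, got {len(labels)}: {labels}"
            )
        for lab in labels:
            if len(self.columns_for(lab)) < 2:
                raise ValueError(f"condition {lab!r} has fewer than 2 replicates")

    # -- convenience views ------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    @property
    def conditions(self) -> list[str]:
        """The two condition labels, in order of first appearance."""
        seen: list[str] = []
        for r in self.replicate_ids:
            lab = self.condition_of.get(r)
            if lab is not None and lab not in seen:
                seen.append(lab)
        return seen

    @property
    def replicate_conditions(self) -> np.ndarray:
        return np.array([self.condition_of[r] for r in self.replicate_ids])

    def columns_for(self, condition: str) -> np.ndarray:
        """Column indices of the replicates belonging to ``condition``."""
        return np.flatnonzero(self.replicate_conditions == condition)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.replicate_ids,
        )


@dataclass
class TruthLabels:
    """Ground-truth condition membership of simulated genes.

    ``labels[i]`` is the true condition of ``gene_ids[i]`` or
    :data:`UNASSIGNED` for genes with no differential expression.
    """

    gene_ids: list[str]
    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != (len(self.gene_ids),):
            raise ValueError("one truth label per gene is required")

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.gene_ids, name="true_label")

    def label_of(self, gene_id: str) -> str:
        return self.as_series()[gene_id]


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what}: {x!r}")
        seen.add(x)
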