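"""Readers and writers for the package's delimited-text interfaces.

All files are plain delimited text (tab by default, comma via ``sep=","``),
decimal point only.  The expression matrix has gene ids in the first column
and replicate ids in the header row; the design file has two columns,
``replicate_id`` and ``condition``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, TruthLabels

logger = logging.getLogger(__name__)


def read_design(path: str | Path, sep: str = "\t") -> dict[str, str]:
    """Read a two-column replicate → condition design table."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    cols = [c.strip() for c in df.columns]
    if "replicate_id" in cols and "condition" in cols:
        df.columns = cols
        rep, cond = df["replicate_id"], df["condition"]
    elif len(df.columns) >= 2:  # headerless or renamed: first two columns
        rep, cond = df.iloc[:, 0], df.iloc[:, 1]
    else:
        raise ValueError(f"design file {path} needs columns replicate_id, condition")
    design: dict[str, str] = {}
    for r, c in zip(rep, cond):
        r = str(r).strip()
        if r in design:
            raise ValueError(f"duplicate replicate id in design: {r!r}")
        design[r] = str(c).strip()
    return design


def read_expression(
    path: str | Path,
    design_path: str | Path,
    sep: str = "\t",
    impute_missing: bool = False,
) -> ExpressionMatrix:
    """Load an expression matrix plus its design file.

    Parameters
    ----------
    path
        Delimited table, first column gene ids, header row replicate ids.
    design_path
        Two-column table mapping every replicate id to a condition label.
    sep
        Field delimiter for both files (tab by default).
    impute_missing
        If true, missing cells are replaced by the gene's (row) mean;
        by default any missing value is a hard error.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = [str(c) for c in df.columns]

    # non-numeric cells must be reported with their coordinates
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        raw_na = df[col].isna()
        bad = converted.isna() & ~raw_na
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric value {df[col].iloc[i]!r} at row {df.index[i]!r} "
                f"(line {i + 2}), column {col!r} (column {j + 2})"
            )
        df[col] = converted

    if df.isna().any().any():
        if impute_missing:
            n_missing = int(df.isna().to_numpy().sum())
            df = df.apply(lambda row: row.fillna(row.mean()), axis=1)
            logger.info("imputed %d missing values with per-gene means", n_missing)
            if df.isna().any().any():
                raise ValueError("gene with all values missing cannot be imputed")
        else:
            i, j = np.argwhere(df.isna().to_numpy())[0]
            raise ValueError(
                f"missing value at gene {df.index[i]!r}, replicate "
                f"{df.columns[j]!r} (use impute_missing to allow)"
            )

    design = read_design(design_path, sep=sep)
    matrix_reps = set(df.columns)
    design_reps = set(design)
    only_matrix = sorted(matrix_reps - design_reps)
    if only_matrix:
        raise ValueError(f"replicate {only_matrix[0]!r} absent from design file")
    only_design = sorted(design_reps - matrix_reps)
    if only_design:
        raise ValueError(f"replicate {only_design[0]!r} in design but absent from matrix")

    m = ExpressionMatrix(
        gene_ids=list(df.index),
        replicate_ids=list(df.columns),
        values=df.to_numpy(dtype=float),
        condition_of=design,
    )
    logger.info("loaded %d genes × %d replicates from %s", m.n_genes, m.n_replicates, path)
    return m


def write_expression(matrix: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    matrix.to_frame().to_csv(path, sep=sep)


def write_design(matrix: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(
        {"replicate_id": matrix.replicate_ids,
         "condition": [matrix.condition_of[r] for r in matrix.replicate_ids]}
    ).to_csv(path, sep=sep, index=False)


def write_truth(truth: TruthLabels, path: str | Path, sep: str = "\t") -> None:
    truth.as_series().rename_axis("gene_id").to_frame().to_csv(path, sep=sep)


def read_truth(path: str | Path, sep: str = "\t") -> TruthLabels:
    df = pd.read_csv(path, sep=sep, dtype=str).set_index("gene_id")
    return TruthLabels(list(df.index), df["true_label"].to_numpy(dtype=object))


def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write any result table (CdResult / classification / report rows)."""
    df.to_csv(path, sep=sep, index=False)


def read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)


def write_eval_report(report, path: str | Path) -> None:
    """Serialize an :class:`~cdclassify.evaluate.EvalReport` as JSON."""
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)


def read_eval_report(path: str | Path):
    from .evaluate import EvalReport

    with open(path) as fh:
        d = json.load(fh)
    return EvalReport.from_dict(d)
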