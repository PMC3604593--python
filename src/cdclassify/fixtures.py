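"""Deterministic hand-built fixtures for tests and documentation.

No randomness here: the geometry fixture is a fixed 2-axis layout of five
gene points around one condition direction that exercises every regime of
the closeness measure (strongly positive, negative side, near-orthogonal,
near-origin/filtered), and the toy expression matrix is a tiny constant
two-condition table for IO and CLI round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import ExpressionMatrix


@dataclass
class GeometryFixture:
    """Named points and a direction with the expected C_d regimes."""

    points: dict[str, np.ndarray]
    direction: np.ndarray
    #: name → (lower, upper) bounds expected for C_d
    expected_cd_bounds: dict[str, tuple[float, float]]
    #: names expected to fall below the 25% norm quantile
    expected_filtered: tuple[str, ...]


def closeness_demo_geometry() -> GeometryFixture:
    """Five genes around a direction along the first axis.

    * g1, g3 sit close to the direction (g3 farther from the origin) and
      score C_d > 0.9;
    * g2 lies on the opposite side of the origin: negative C_d;
    * g4 is nearly orthogonal to the direction: |C_d| < 0.3;
    * g5 hugs the origin and is removed by the norm-quartile filter.
    """
    points = {
        "g1": np.array([2.0, 0.3]),
        "g2": np.array([-3.0, -0.8]),
        "g3": np.array([5.0, 0.5]),
        "g4": np.array([0.15, 1.9]),
        "g5": np.array([0.2, -0.25]),
    }
    return GeometryFixture(
        points=points,
        direction=np.array([1.0, 0.0]),
        expected_cd_bounds={
            "g1": (0.9, 1.0),
            "g2": (-1.0, 0.0),
            "g3": (0.9, 1.0),
            "g4": (-0.3, 0.3),
            "g5": (-1.0, 1.0),
        },
        expected_filtered=("g5",),
    )


def toy_expression_matrix() -> ExpressionMatrix:
    """A 6-gene × 6-replicate two-condition matrix with visible structure.

    Genes t1–t2 are high under condition A, t3–t4 under condition B, and
    t5–t6 are flat background; values carry a small deterministic ripple so
    no column is constant.
    """
    base = np.array(
        [
            [5.0, 5.2, 4.9, 1.0, 1.1, 0.9],
            [4.8, 5.1, 5.0, 1.2, 0.8, 1.0],
            [1.1, 0.9, 1.0, 5.1, 4.9, 5.2],
            [0.9, 1.0, 1.2, 4.8, 5.0, 5.1],
            [2.0, 2.1, 1.9, 2.0, 2.2, 1.8],
            [2.1, 1.9, 2.0, 2.1, 1.9, 2.2],
        ]
    )
    ripple = 0.01 * np.arange(36, dtype=float).reshape(6, 6)
    reps = [f"a{i}" for i in range(1, 4)] + [f"b{i}" for i in range(1, 4)]
    design = {r: ("A" if r.startswith("a") else "B") for r in reps}
    return ExpressionMatrix(
        gene_ids=[f"t{i}" for i in range(1, 7)],
        replicate_ids=reps,
        values=base + ripple,
        condition_of=design,
    )
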