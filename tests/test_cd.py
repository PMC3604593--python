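import numpy as np
import pytest
from hypothesis import given, strategies as st

from cdclassify.cd import (
    CdResult, apply_norm_filter, assign_by_cd, cd_value, compute_cd,
)
from cdclassify.datamodel import UNASSIGNED
from cdclassify.pcspace import Direction, PCSpace


def cosine_oracle(g, d):
    """Independent brute-force signed cosine."""
    g, d = np.asarray(g, float), np.asarray(d, float)
    return float(np.dot(g, d) / (np.linalg.norm(g) * np.linalg.norm(d)))


@pytest.mark.parametrize(
    "g, d, expected",
    [
        ([2.0, 4.0], [1.0, 2.0], 1.0),       # g = 2d, collinear
        ([-3.0, -6.0], [1.0, 2.0], -1.0),    # g = -3d, opposite side
        ([0.0, 1.0], [1.0, 0.0], 0.0),       # orthogonal
        ([1.0, 1.0], [1.0, 0.0], 1 / np.sqrt(2)),  # 45 degrees
    ],
)
def test_cd_value_exact_geometries(g, d, expected):
    assert cd_value(g, d) == pytest.approx(expected, abs=1e-12)


def test_cd_value_zero_direction_is_error_zero_gene_is_zero():
    with pytest.raises(ValueError, match="zero norm"):
        cd_value([1.0, 0.0], [0.0, 0.0])
    assert cd_value([0.0, 0.0], [1.0, 0.0]) == 0.0


vec = st.integers(2, 5).flatmap(
    lambda k: st.lists(
        st.floats(-10, 10, allow_nan=False, allow_infinity=False),
        min_size=k, max_size=k,
    )
)


@given(vec, st.data())
def test_cd_value_invariances(g, data):
    """Positive scaling of gene or direction leaves C_d unchanged; negating
    the gene flips the sign; the value matches the cosine oracle."""
    g = np.asarray(g)
    d = np.asarray(data.draw(st.lists(
        st.floats(-10, 10, allow_nan=False, allow_infinity=False),
        min_size=len(g), max_size=len(g),
    )))
    if np.linalg.norm(g) < 1e-6 or np.linalg.norm(d) < 1e-6:
        return
    c = data.draw(st.floats(0.1, 100.0))
    v = cd_value(g, d)
    assert abs(v) <= 1 + 1e-12
    assert v == pytest.approx(cosine_oracle(g, d), abs=1e-10)
    assert cd_value(c * g, d) == pytest.approx(v, abs=1e-12)
    assert cd_value(g, c * d) == pytest.approx(v, abs=1e-12)
    assert cd_value(-g, d) == pytest.approx(-v, abs=1e-12)


def _cd_table(norms, cd=None, conditions=("A", "B")):
    norms = np.asarray(norms, float)
    n = norms.size
    if cd is None:
        cd = np.tile([0.5, 0.1], (n, 1))
    return CdResult(
        gene_ids=[f"g{i}" for i in range(n)],
        conditions=list(conditions),
        cd=np.asarray(cd, float),
        norm=norms,
        filtered=np.zeros(n, bool),
        assigned=np.full(n, UNASSIGNED, dtype=object),
    )


def test_norm_filter_distinct_norms_removes_exact_quartile(rng):
    res = _cd_table(rng.permutation(np.arange(1.0, 101.0)))
    out = apply_norm_filter(res, 0.25)
    assert out.n_filtered == 25
    assert np.all(out.cd[out.filtered] == 0.0)
    assert np.all(out.norm[out.filtered] <= 25)
    # unfiltered genes keep their values
    assert np.all(out.cd[~out.filtered] == res.cd[~out.filtered])


def test_norm_filter_all_ties_filters_nothing():
    out = apply_norm_filter(_cd_table(np.full(10, 3.0)), 0.25)
    assert out.n_filtered == 0


def test_norm_filter_interpolated_cutoff():
    # norms 1..8: the 25% quantile with linear interpolation is 2.75,
    # so exactly the genes with norms 1 and 2 are filtered
    out = apply_norm_filter(_cd_table(np.arange(1.0, 9.0)), 0.25)
    assert sorted(out.norm[out.filtered]) == [1.0, 2.0]


@pytest.mark.parametrize("q", [0.0, 1.0, -0.1, 1.5])
def test_norm_filter_quantile_validation(q):
    with pytest.raises(ValueError, match="quantile"):
        apply_norm_filter(_cd_table([1.0, 2.0]), q)


@pytest.mark.parametrize(
    "cd_row, threshold, expected",
    [
        ([0.999, 0.20], 0.99, "A"),        # clear margin
        ([-0.995, 0.10], 0.99, "A"),       # sign ignored
        ([0.95, 0.30], 0.99, UNASSIGNED),  # below threshold
        ([0.5, 0.5], 0.3, UNASSIGNED),     # exact tie
        ([0.2, -0.95], 0.9, "B"),
    ],
)
def test_assign_by_cd_cases(cd_row, threshold, expected):
    out = assign_by_cd(_cd_table([5.0], cd=[cd_row]), threshold)
    assert out.assigned[0] == expected


def test_assign_by_cd_respects_filter_and_per_condition_thresholds():
    res = _cd_table([1.0, 5.0], cd=[[0.999, 0.0], [0.0, 0.95]])
    res.filtered[0] = True
    res.cd[0] = 0.0
    out = assign_by_cd(res, {"A": 0.99, "B": 0.9})
    assert out.assigned[0] == UNASSIGNED  # filtered stays unassigned
    assert out.assigned[1] == "B"


def test_assign_threshold_validation():
    with pytest.raises(ValueError, match="threshold"):
        assign_by_cd(_cd_table([1.0]), 1.5)


def _toy_space():
    scores = np.array([
        [3.0, 0.1], [2.5, -0.2], [0.1, 2.8], [-0.2, 3.2],
        [0.1, 0.1], [1.0, 1.0],
    ])
    return PCSpace(
        n_components=2, eigenvalues=np.array([1.5, 0.5]),
        gene_scores=scores, variable_coords=np.zeros((4, 2)),
        center=np.zeros(4), scale=np.ones(4),
        gene_ids=[f"g{i}" for i in range(6)],
        replicate_ids=[f"r{i}" for i in range(4)],
    )


def test_compute_cd_three_zones_partition():
    space = _toy_space()
    dirs = [Direction("A", np.array([1.0, 0.0]), ["r0", "r1"]),
            Direction("B", np.array([0.0, 1.0]), ["r2", "r3"])]
    res = assign_by_cd(apply_norm_filter(compute_cd(space, dirs), 0.25), 0.99)
    assigned = res.assigned != UNASSIGNED
    # assigned, unassigned-but-scored, filtered partition the gene set
    assert assigned.sum() + (~assigned & ~res.filtered).sum() + res.filtered.sum() == 6
    assert np.all(np.abs(res.cd[assigned]).max(axis=1) > 0.99)
    assert np.all(res.cd[res.filtered] == 0.0)


def test_raising_threshold_never_assigns_more():
    space = _toy_space()
    dirs = [Direction("A", np.array([1.0, 0.0]), ["r0"]),
            Direction("B", np.array([0.0, 1.0]), ["r2"])]
    cd = apply_norm_filter(compute_cd(space, dirs), 0.25)
    counts = [
        (assign_by_cd(cd, t).assigned != UNASSIGNED).sum()
        for t in (0.5, 0.9, 0.99, 0.999)
    ]
    assert counts == sorted(counts, reverse=True)


def test_cd_scale_invariance_end_to_end():
    """Rescaling a direction leaves every C_d value unchanged."""
    space = _toy_space()
    d1 = [Direction("A", np.array([1.0, 0.0]), ["r0"]),
          Direction("B", np.array([0.0, 1.0]), ["r2"])]
    d2 = [Direction("A", np.array([7.3, 0.0]), ["r0"]),
          Direction("B", np.array([0.0, 0.02]), ["r2"])]
    np.testing.assert_allclose(
        compute_cd(space, d1).cd, compute_cd(space, d2).cd, atol=1e-12
    )
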