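import numpy as np
import pytest

from cdclassify import (
    ExpressionMatrix, build_directions, check_direction_coherence, fit_pca,
)
from cdclassify.pcspace import Direction, PCSpace


def _matrix(values, conditions=("A", "A", "B", "B")):
    values = np.asarray(values, dtype=float)
    reps = [f"r{i+1}" for i in range(values.shape[1])]
    return ExpressionMatrix(
        [f"g{i+1}" for i in range(values.shape[0])],
        reps, values, dict(zip(reps, conditions)),
    )


@pytest.fixture
def random_matrix(rng):
    return _matrix(rng.normal(size=(100, 6)), ("A",) * 3 + ("B",) * 3)


def test_perfectly_correlated_columns_are_rank_one(rng):
    base = rng.normal(size=50)
    m = _matrix(np.column_stack([base, 2 * base + 1, -base, 0.5 * base]))
    space = fit_pca(m, n_components=4)
    assert space.eigenvalues[0] == pytest.approx(4.0, abs=1e-8)
    assert np.all(space.eigenvalues[1:] < 1e-8)


def test_eigenvalue_trace_equals_number_of_variables(random_matrix):
    space = fit_pca(random_matrix, n_components=6)
    assert space.eigenvalues.sum() == pytest.approx(6.0, abs=1e-8)
    assert np.all(np.diff(space.eigenvalues) <= 1e-12)
    assert np.all(space.eigenvalues >= -1e-12)


def test_decomposition_matches_correlation_eigen_oracle(random_matrix):
    """Eigenvalues and coordinates agree with a direct eigendecomposition
    of the correlation matrix, and the full reconstruction recovers the
    standardized input."""
    X = random_matrix.values
    Z = (X - X.mean(0)) / X.std(0)
    R = (Z.T @ Z) / Z.shape[0]
    w = np.sort(np.linalg.eigvalsh(R))[::-1]

    space = fit_pca(random_matrix, n_components=6)
    np.testing.assert_allclose(space.eigenvalues, w, atol=1e-8)
    # variable coordinate = correlation of the variable with the component
    for j in range(6):
        for k in range(6):
            r = np.corrcoef(Z[:, j], space.gene_scores[:, k])[0, 1]
            assert r == pytest.approx(space.variable_coords[j, k], abs=1e-8)
    # reconstruction with all components: scores * V^T == Z where
    # V = variable_coords / sqrt(eigenvalue)
    V = space.variable_coords / np.sqrt(space.eigenvalues)
    np.testing.assert_allclose(space.gene_scores @ V.T, Z, atol=1e-8)


def test_gene_score_columns_are_orthogonal(random_matrix):
    space = fit_pca(random_matrix, n_components=6)
    G = space.gene_scores.T @ space.gene_scores
    off = G - np.diag(np.diag(G))
    assert np.max(np.abs(off)) / np.max(np.abs(np.diag(G))) < 1e-6


def test_variable_coords_inside_unit_disk(random_matrix):
    space = fit_pca(random_matrix, n_components=6)
    norms = np.linalg.norm(space.variable_coords, axis=1)
    assert np.all(norms <= 1 + 1e-9)


def test_sign_convention_and_determinism(random_matrix):
    a = fit_pca(random_matrix, n_components=2)
    b = fit_pca(random_matrix, n_components=2)
    np.testing.assert_array_equal(a.gene_scores, b.gene_scores)
    first_cols = random_matrix.columns_for("A")
    assert np.all(a.variable_coords[first_cols].mean(axis=0) >= 0)


def test_constant_column_is_rejected(rng):
    vals = rng.normal(size=(20, 4))
    vals[:, 2] = 7.0
    with pytest.raises(ValueError, match="r3"):
        fit_pca(_matrix(vals))


def test_n_components_out_of_range(random_matrix):
    with pytest.raises(ValueError, match="out of range"):
        fit_pca(random_matrix, n_components=7)
    with pytest.raises(ValueError, match="out of range"):
        fit_pca(random_matrix, n_components=0)


def _space(coords, reps=None):
    coords = np.asarray(coords, dtype=float)
    return PCSpace(
        n_components=coords.shape[1],
        eigenvalues=np.ones(coords.shape[1]),
        gene_scores=np.zeros((1, coords.shape[1])),
        variable_coords=coords,
        center=np.zeros(coords.shape[0]),
        scale=np.ones(coords.shape[0]),
        gene_ids=["g1"],
        replicate_ids=reps or [f"r{i+1}" for i in range(coords.shape[0])],
    )


def test_direction_is_arithmetic_mean_of_members():
    m = _matrix(np.ones((1, 4)) * np.arange(4))  # values unused here
    space = _space([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.2], [-1.0, 0.4]])
    d = build_directions(space, m)
    assert [x.condition for x in d] == ["A", "B"]
    np.testing.assert_allclose(d[0].vector, [0.5, 0.5])
    np.testing.assert_allclose(d[1].vector, [-1.0, 0.3])
    assert d[0].members == ["r1", "r2"]


def test_direction_zero_norm_rejected():
    with pytest.raises(ValueError, match="zero norm"):
        Direction("A", np.zeros(2), ["r1"])


def test_coherence_identical_replicates_score_one():
    space = _space([[0.6, 0.2], [0.6, 0.2], [-0.1, 0.7], [-0.1, 0.7]])
    dirs = [
        Direction("A", np.array([0.6, 0.2]), ["r1", "r2"]),
        Direction("B", np.array([-0.1, 0.7]), ["r3", "r4"]),
    ]
    rep = check_direction_coherence(space, dirs)
    assert rep.within_cosine["A"] == pytest.approx(1.0)
    assert rep.within_cosine["B"] == pytest.approx(1.0)


def test_coherence_orthogonal_directions_do_not_warn():
    space = _space([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
    dirs = [
        Direction("A", np.array([1.0, 0.0]), ["r1", "r2"]),
        Direction("B", np.array([0.0, 1.0]), ["r3", "r4"]),
    ]
    rep = check_direction_coherence(space, dirs)
    assert rep.between_cosine == pytest.approx(0.0)
    assert rep.ok


def test_coherence_flags_collinear_directions():
    space = _space([[1.0, 0.0], [1.0, 0.1], [0.9, 0.05], [1.0, 0.0]])
    dirs = [
        Direction("A", np.array([1.0, 0.05]), ["r1", "r2"]),
        Direction("B", np.array([0.95, 0.02]), ["r3", "r4"]),
    ]
    rep = check_direction_coherence(space, dirs)
    assert not rep.ok
    assert any("collinear" in w for w in rep.warnings)
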