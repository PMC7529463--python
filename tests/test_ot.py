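"""Wasserstein-1 solvers, population distance matrices, linkage ordering and
neighbor-joining trees."""

import numpy as np
import pytest

from rmtot import (
    WassersteinMatrix,
    hierarchical_order,
    nj_tree,
    population_distance_matrix,
    wasserstein1,
)


# ---------------------------------------------------------------------------
# closed forms and axioms
# ---------------------------------------------------------------------------


def test_identity_of_indiscernibles():
    A = np.random.default_rng(0).normal(0, 1, (40, 3))
    assert wasserstein1(A, A, exact=True).value == pytest.approx(0.0, abs=1e-10)


def test_singleton_pair_is_euclidean_distance():
    r = wasserstein1(np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]]))
    assert r.value == pytest.approx(5.0, abs=1e-12)


def test_two_by_two_vertical_matching():
    # plans: vertical matching costs 1, crossed matching costs sqrt(2)
    A = np.array([[0.0, 0], [1.0, 0]])
    B = np.array([[0.0, 1], [1.0, 1]])
    assert wasserstein1(A, B).value == pytest.approx(1.0, abs=1e-12)


def test_metric_axioms_on_random_triples():
    rng = np.random.default_rng(1)
    for _ in range(25):
        A, B, C = (rng.normal(rng.normal(), 1.0, (rng.integers(5, 20), 2)) for _ in range(3))
        ab = wasserstein1(A, B, exact=True).value
        ba = wasserstein1(B, A, exact=True).value
        ac = wasserstein1(A, C, exact=True).value
        cb = wasserstein1(C, B, exact=True).value
        assert abs(ab - ba) < 1e-8
        assert ab >= -1e-12
        assert ab <= ac + cb + 1e-8


def test_translation_invariance_and_shift_distance():
    rng = np.random.default_rng(2)
    A = rng.normal(0, 1, (30, 2))
    B = rng.normal(0, 1, (47, 2))
    v = np.array([2.0, -1.0])
    d0 = wasserstein1(A, B, exact=True).value
    d1 = wasserstein1(A + v, B + v, exact=True).value
    assert abs(d0 - d1) < 1e-8
    # translating one copy of the same set moves mass exactly by |v|
    assert wasserstein1(A, A + v, exact=True).value == pytest.approx(
        np.linalg.norm(v), abs=1e-8
    )
    s = wasserstein1(A, A + v, exact=False)
    assert abs(s.value - np.linalg.norm(v)) / np.linalg.norm(v) < 0.01


def test_unequal_sizes_use_lp_and_match_refined_assignment():
    """LP on a 2-vs-4 instance vs hand-checkable splitting: each of the two
    sources ships half its mass to its two nearest sinks."""
    A = np.array([[0.0, 0.0], [10.0, 0.0]])
    B = np.array([[0.0, 1.0], [0.0, -1.0], [10.0, 1.0], [10.0, -1.0]])
    r = wasserstein1(A, B, exact=True)
    assert r.method == "lp"
    assert r.value == pytest.approx(1.0, abs=1e-9)


def test_sinkhorn_matches_exact_oracle_within_one_percent():
    rng = np.random.default_rng(3)
    for _ in range(5):
        A = rng.normal(0, 1, (int(rng.integers(20, 65)), 3))
        B = rng.normal(0.5, 1.2, (int(rng.integers(20, 65)), 3))
        exact = wasserstein1(A, B, exact=True).value
        approx = wasserstein1(A, B, exact=False).value
        assert abs(approx - exact) / exact < 0.01


def test_nan_rejected_and_empty_rejected():
    with pytest.raises(ValueError, match="NaN"):
        wasserstein1(np.array([[np.nan, 0.0]]), np.array([[0.0, 0.0]]))
    with pytest.raises(ValueError, match="nonempty"):
        wasserstein1(np.empty((0, 2)), np.array([[0.0, 0.0]]))


# ---------------------------------------------------------------------------
# population distance matrix
# ---------------------------------------------------------------------------


def _three_pops(seed=4):
    rng = np.random.default_rng(seed)
    centers = {"p0": (0.0, 0.0), "p1": (10.0, 0.0), "p2": (10.0, 2.0)}
    pts, labels = [], []
    for name, c in centers.items():
        pts.append(np.asarray(c) + 0.1 * rng.standard_normal((60, 2)))
        labels += [name] * 60
    return np.vstack(pts), np.asarray(labels)


def test_population_matrix_reproduces_planted_ordering():
    X, labels = _three_pops()
    wm = population_distance_matrix(X, labels)
    D = wm.to_frame()
    assert D.loc["p0", "p1"] == pytest.approx(10.0, rel=0.05)
    assert D.loc["p0", "p2"] == pytest.approx(np.hypot(10, 2), rel=0.05)
    assert D.loc["p1", "p2"] == pytest.approx(2.0, rel=0.05)
    assert np.allclose(wm.D, wm.D.T) and np.all(np.diag(wm.D) == 0)


def test_duplicate_population_has_zero_distance():
    rng = np.random.default_rng(5)
    pts = rng.normal(0, 1, (50, 2))
    X = np.vstack([pts, pts])
    labels = np.asarray(["a"] * 50 + ["b"] * 50)
    wm = population_distance_matrix(X, labels)
    assert wm.to_frame().loc["a", "b"] == pytest.approx(0.0, abs=1e-8)


def test_label_permutation_permutes_rows_consistently():
    X, labels = _three_pops()
    wm = population_distance_matrix(X, labels)
    relabel = {"p0": "z_last", "p1": "a_first", "p2": "m_mid"}
    wm2 = population_distance_matrix(X, np.asarray([relabel[l] for l in labels]))
    inv = {v: k for k, v in relabel.items()}
    for la in wm2.labels:
        for lb in wm2.labels:
            assert wm2.to_frame().loc[la, lb] == pytest.approx(
                wm.to_frame().loc[inv[la], inv[lb]], abs=1e-10
            )


def test_subsampling_recorded_and_stable():
    rng = np.random.default_rng(6)
    X = np.vstack([rng.normal(0, 1, (3000, 2)), rng.normal(6, 1, (500, 2))])
    labels = np.asarray(["big"] * 3000 + ["small"] * 500)
    d1 = population_distance_matrix(X, labels, size_cap=400, seed=1).to_frame().loc["big", "small"]
    d2 = population_distance_matrix(X, labels, size_cap=400, seed=2).to_frame().loc["big", "small"]
    assert abs(d1 - d2) / d1 < 0.05


def test_empty_population_named_in_error():
    X = np.random.default_rng(0).random((4, 2))
    with pytest.raises(ValueError, match="at least 2 populations"):
        population_distance_matrix(X, np.asarray(["only"] * 4))


# ---------------------------------------------------------------------------
# hierarchical ordering
# ---------------------------------------------------------------------------


def test_ultrametric_linkage_recovers_generating_hierarchy():
    # tree: ((A,B),(C,D)) with merge heights 1, 1, 4
    labels = ["A", "B", "C", "D"]
    D = np.array(
        [
            [0.0, 1.0, 4.0, 4.0],
            [1.0, 0.0, 4.0, 4.0],
            [4.0, 4.0, 0.0, 1.0],
            [4.0, 4.0, 1.0, 0.0],
        ]
    )
    order, Z = hierarchical_order(WassersteinMatrix(labels=labels, D=D))
    pairs = {frozenset(order[:2]), frozenset(order[2:])}
    assert pairs == {frozenset({"A", "B"}), frozenset({"C", "D"})}
    assert Z[-1, 2] == pytest.approx(4.0)


def test_two_population_single_merge():
    wm = WassersteinMatrix(labels=["x", "y"], D=np.array([[0.0, 2.5], [2.5, 0.0]]))
    order, Z = hierarchical_order(wm)
    assert sorted(order) == ["x", "y"]
    assert Z.shape == (1, 4) and Z[0, 2] == pytest.approx(2.5)


def test_constant_shift_preserves_topology():
    rng = np.random.default_rng(7)
    D = rng.random((5, 5))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0)
    labels = [f"p{i}" for i in range(5)]
    order1, _ = hierarchical_order(WassersteinMatrix(labels=labels, D=D))
    shifted = D + 3.0
    np.fill_diagonal(shifted, 0)
    order2, _ = hierarchical_order(WassersteinMatrix(labels=labels, D=shifted))
    assert order1 == order2


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def test_three_taxon_closed_form():
    D = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
    tree = nj_tree(WassersteinMatrix(labels=["a", "b", "c"], D=D))
    lengths = {t.name: t.length for t in tree.tree.tips()}
    assert lengths["a"] == pytest.approx(1.0, abs=1e-9)
    assert lengths["b"] == pytest.approx(2.0, abs=1e-9)
    assert lengths["c"] == pytest.approx(3.0, abs=1e-9)


def random_additive_matrix(n_taxa, seed):
    """Distances generated from a random binary tree with positive branch
    lengths; pairwise distances are path sums, hence exactly additive."""
    rng = np.random.default_rng(seed)

    def build(leaves):
        if len(leaves) == 1:
            return leaves[0]
        cut = int(rng.integers(1, len(leaves)))
        return (
            build(leaves[:cut]),
            build(leaves[cut:]),
            rng.uniform(0.5, 2.0),
            rng.uniform(0.5, 2.0),
        )

    D = np.zeros((n_taxa, n_taxa))

    def collect(node):
        """Return [(leaf, depth below this node)] and fill cross distances."""
        if isinstance(node, int):
            return [(node, 0.0)]
        left, right, ll, lr = node
        a = [(leaf, d + ll) for leaf, d in collect(left)]
        b = [(leaf, d + lr) for leaf, d in collect(right)]
        for i, di in a:
            for j, dj in b:
                D[i, j] = D[j, i] = di + dj
        return a + b

    collect(build(list(range(n_taxa))))
    return D


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_additive_eight_taxon_distances_recovered_exactly(seed):
    D = random_additive_matrix(8, seed)
    labels = [f"t{i}" for i in range(8)]
    tree = nj_tree(WassersteinMatrix(labels=labels, D=D))
    # the tree must reproduce the input distances exactly (additivity)
    recovered = {t.name: t for t in tree.tree.tips()}
    for i in range(8):
        for j in range(i + 1, 8):
            d = recovered[f"t{i}"].distance(recovered[f"t{j}"])
            assert d == pytest.approx(D[i, j], abs=1e-9)


def test_negative_branch_lengths_flagged_and_clampable():
    # deliberately non-additive noisy matrix often yields negative branches
    rng = np.random.default_rng(9)
    D = rng.random((6, 6)) * 0.2 + 1.0
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0)
    labels = [f"p{i}" for i in range(6)]
    tree = nj_tree(WassersteinMatrix(labels=labels, D=D))
    clamped = nj_tree(WassersteinMatrix(labels=labels, D=D), clamp_negative=True)
    assert all(
        t.length is None or t.length >= 0
        for t in clamped.tree.traverse(include_self=False)
    )
    if tree.has_negative_branches:
        assert any(
            t.length is not None and t.length < 0
            for t in tree.tree.traverse(include_self=False)
        )


def test_nj_requires_three_taxa_and_finite_distances():
    with pytest.raises(ValueError, match="at least 3"):
        nj_tree(WassersteinMatrix(labels=["a", "b"], D=np.zeros((2, 2))))
    D = np.zeros((3, 3))
    D[0, 1] = D[1, 0] = np.inf
    with pytest.raises(ValueError, match="finite"):
        nj_tree(WassersteinMatrix(labels=["a", "b", "c"], D=D))
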