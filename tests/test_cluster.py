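"""Gower, generalized-Ward, silhouette and concordance oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import silhouette_samples

from dietscore.cluster import (
    DissimilarityMatrix,
    FeatureTable,
    choose_k,
    cut_dendrogram,
    gower_matrix,
    region_concordance,
    silhouette,
    ward_agglomerate,
)
from dietscore.errors import ClusteringError, IncomparablePairError, ParameterError


def _dm(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"u{i}" for i in range(len(values))]
    return DissimilarityMatrix(ids=tuple(ids), values=values)


def _numeric_table(rows, ids=None, columns=None):
    rows = np.asarray(rows, dtype=float)
    ids = ids or [f"u{i}" for i in range(len(rows))]
    columns = columns or [f"v{j}" for j in range(rows.shape[1])]
    return FeatureTable(data=pd.DataFrame(rows, index=ids, columns=columns))


# --- Gower -------------------------------------------------------------------

def test_gower_identical_rows_have_zero_distance():
    D = gower_matrix(_numeric_table([[1.0, 2.0], [1.0, 2.0], [3.0, 4.0]]))
    assert D.values[0, 1] == 0.0


def test_gower_hand_worked_two_units():
    # ranges 10 and 2; |5-0|/10 = 0.5 and |1-0|/2 = 0.5 average to 0.5
    table = _numeric_table([[0.0, 0.0], [5.0, 1.0], [10.0, 2.0]])
    D = gower_matrix(table)
    assert D.values[0, 1] == pytest.approx(0.5)


def test_gower_categorical_mismatch_averages_with_numeric():
    df = pd.DataFrame(
        {"diet": ["omnivore", "vegetarian"], "intake": [5.0, 5.0], "other": [0.0, 10.0]},
        index=["i", "j"],
    )
    # intake has zero range -> dropped; remaining: categorical mismatch 1, numeric 1
    table = FeatureTable(data=df[["diet", "other"]], categorical=("diet",))
    D = gower_matrix(table)
    assert D.values[0, 1] == pytest.approx((1.0 + 1.0) / 2.0)

    equal_numeric = FeatureTable(
        data=pd.DataFrame(
            {"diet": ["omnivore", "vegetarian"], "x": [0.0, 0.0], "y": [0.0, 4.0]},
            index=["i", "j"],
        ),
        categorical=("diet",),
    )
    with pytest.warns(UserWarning, match="zero range"):
        D2 = gower_matrix(equal_numeric)
    assert D2.values[0, 1] == pytest.approx((1.0 + 1.0) / 2.0)


def test_gower_unit_range_equals_mean_absolute_difference():
    rng = np.random.default_rng(42)
    rows = rng.uniform(size=(6, 4))
    # force every column to span exactly [0, 1]
    rows[0] = 0.0
    rows[1] = 1.0
    D = gower_matrix(_numeric_table(rows))
    expected = np.abs(rows[:, None, :] - rows[None, :, :]).mean(axis=2)
    np.fill_diagonal(expected, 0.0)
    np.testing.assert_allclose(D.values, expected, atol=1e-12)


@given(a=st.floats(min_value=0.1, max_value=50.0), b=st.floats(min_value=-100.0, max_value=100.0))
def test_gower_invariant_to_affine_rescaling(a, b):
    rng = np.random.default_rng(3)
    rows = rng.uniform(0.0, 10.0, size=(5, 3))
    base = gower_matrix(_numeric_table(rows))
    scaled = rows.copy()
    scaled[:, 0] = a * scaled[:, 0] + b
    rescaled = gower_matrix(_numeric_table(scaled))
    np.testing.assert_allclose(base.values, rescaled.values, atol=1e-9)


def test_gower_incomparable_pair_raises():
    df = pd.DataFrame(
        {"x": [1.0, np.nan, 2.0], "y": [np.nan, 1.0, 2.0]}, index=["a", "b", "c"]
    )
    with pytest.raises(IncomparablePairError):
        gower_matrix(FeatureTable(data=df))


def test_gower_missing_values_drop_from_the_average():
    df = pd.DataFrame({"x": [0.0, 10.0, 5.0], "y": [np.nan, 4.0, 0.0]}, index=list("abc"))
    D = gower_matrix(FeatureTable(data=df))
    # pair (a, b): only x comparable -> d = 10/10
    assert D.values[0, 1] == pytest.approx(1.0)
    # pair (b, c): both -> (5/10 + 4/4) / 2
    assert D.values[1, 2] == pytest.approx(0.75)


# --- generalized Ward --------------------------------------------------------

def test_ward_lance_williams_hand_worked_example():
    """1-D points {0, 1, 10}: {0, 1} merge first at height 1 and the updated
    distance to {10} is (2*10 + 2*9 - 1)/3 = 37/3."""
    D = _dm([[0, 1, 10], [1, 0, 9], [10, 9, 0]])
    tree = ward_agglomerate(D)
    assert tree.merges[0][:3].tolist() == [0.0, 1.0, 1.0]
    assert tree.merges[1][2] == pytest.approx(37.0 / 3.0)
    assert tree.monotonic


def test_ward_identical_units_merge_first_at_zero_height():
    D = _dm([[0, 5, 0], [5, 0, 5], [0, 5, 0]])
    tree = ward_agglomerate(D)
    a, b, h, size = tree.merges[0]
    assert {int(a), int(b)} == {0, 2}
    assert h == 0.0
    assert size == 2


def _greedy_ess_partitions(points):
    """Oracle: agglomerate by exhaustively minimizing Ward's within-cluster
    sum-of-squares increase at every step, recomputed from raw points."""
    def ess(idx):
        pts = points[list(idx)]
        return float(((pts - pts.mean(axis=0)) ** 2).sum())

    clusters = [(i,) for i in range(len(points))]
    partitions = []
    deltas = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                delta = ess(clusters[i] + clusters[j]) - ess(clusters[i]) - ess(clusters[j])
                fi, fj = sorted((min(clusters[i]), min(clusters[j])))
                key = (delta, fi, fj)
                if best is None or key < best[0]:
                    best = (key, i, j)
        (delta, _, _), i, j = best
        merged = tuple(sorted(clusters[i] + clusters[j]))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        partitions.append(frozenset(frozenset(c) for c in clusters))
        deltas.append(delta)
    return partitions, deltas


def _tree_partitions(tree):
    n = tree.n
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for step, (a, b, _, _) in enumerate(tree.merges):
        members[n + step] = members.pop(int(a)) | members.pop(int(b))
        out.append(frozenset(members.values()))
    return out


@pytest.mark.parametrize("n, dim, seed", [(5, 1, 0), (6, 2, 1), (6, 3, 2), (8, 2, 3)])
def test_ward_on_squared_euclidean_matches_exhaustive_ess_oracle(n, dim, seed):
    """On squared Euclidean dissimilarities the Lance-Williams recurrence must
    reproduce textbook Ward: the same merge sequence as a brute-force oracle
    that re-evaluates the within-cluster sum-of-squares increase of every
    candidate merge from the raw points, with heights equal to twice the
    objective increase."""
    rng = np.random.default_rng(seed)
    points = rng.normal(size=(n, dim))
    sq = ((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
    tree = ward_agglomerate(_dm(sq))
    expected_partitions, expected_deltas = _greedy_ess_partitions(points)
    assert _tree_partitions(tree) == expected_partitions
    np.testing.assert_allclose(tree.heights, 2.0 * np.asarray(expected_deltas), rtol=1e-9)


def test_ward_rejects_asymmetric_input():
    with pytest.raises(ClusteringError):
        _dm([[0, 1], [2, 0]])


# --- cutting & silhouette ----------------------------------------------------

def test_cut_dendrogram_extremes_and_worked_partition():
    D = _dm([[0, 1, 10], [1, 0, 9], [10, 9, 0]])
    tree = ward_agglomerate(D)
    assert cut_dendrogram(tree, 3).tolist() == [0, 1, 2]
    assert cut_dendrogram(tree, 1).tolist() == [0, 0, 0]
    assert cut_dendrogram(tree, 2).tolist() == [0, 0, 1]
    with pytest.raises(ParameterError):
        cut_dendrogram(tree, 4)
    with pytest.raises(ParameterError):
        cut_dendrogram(tree, 0)


def test_silhouette_direct_formula_and_conventions():
    # two tight pairs far apart: a(i)=1 within, b(i)=9 across -> S = 8/9
    values = np.array(
        [
            [0.0, 1.0, 9.0, 9.0],
            [1.0, 0.0, 9.0, 9.0],
            [9.0, 9.0, 0.0, 1.0],
            [9.0, 9.0, 1.0, 0.0],
        ]
    )
    report = silhouette(_dm(values), [0, 0, 1, 1])
    np.testing.assert_allclose(report.a, 1.0)
    np.testing.assert_allclose(report.b, 9.0)
    np.testing.assert_allclose(report.s, 8.0 / 9.0)
    assert report.overall == pytest.approx(8.0 / 9.0)


def test_silhouette_singleton_is_zero_and_single_cluster_rejected():
    values = np.array([[0.0, 1.0, 5.0], [1.0, 0.0, 5.0], [5.0, 5.0, 0.0]])
    report = silhouette(_dm(values), [0, 0, 1])
    assert report.s[2] == 0.0
    with pytest.raises(ClusteringError):
        silhouette(_dm(values), [0, 0, 0])


def test_silhouette_perfect_separation_of_zero_diameter_blobs():
    values = np.zeros((4, 4))
    values[:2, 2:] = 7.0
    values[2:, :2] = 7.0
    report = silhouette(_dm(values), [0, 0, 1, 1])
    assert report.overall == 1.0


@pytest.mark.parametrize("seed", [0, 1])
def test_silhouette_matches_sklearn_on_random_partitions(seed):
    rng = np.random.default_rng(seed)
    points = rng.normal(size=(10, 3))
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2))
    labels = rng.integers(0, 3, size=10)
    while len(np.unique(labels)) < 2:
        labels = rng.integers(0, 3, size=10)
    report = silhouette(_dm(d), labels)
    expected = silhouette_samples(d, labels, metric="precomputed")
    np.testing.assert_allclose(report.s, expected, atol=1e-12)
    assert np.all(report.s >= -1.0) and np.all(report.s <= 1.0)


# --- k selection & concordance ----------------------------------------------

def _blob_matrix():
    rng = np.random.default_rng(11)
    points = np.concatenate([rng.normal(0, 0.1, (5, 2)), rng.normal(5, 0.1, (5, 2))])
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2))
    return _dm(d)


def test_choose_k_finds_two_separated_blobs():
    D = _blob_matrix()
    tree = ward_agglomerate(D)
    result = choose_k(tree, D, range(2, D.n))
    assert result.k == 2
    assert len(result.merge_heights) == D.n - 1


def test_choose_k_tie_breaks_to_smallest_k_and_validates_range():
    # four equidistant units: every cut scores an overall silhouette of 0,
    # so the tie resolves to the smallest candidate k
    values = 7.0 * (np.ones((4, 4)) - np.eye(4))
    D = _dm(values)
    tree = ward_agglomerate(D)
    result = choose_k(tree, D, [3, 2])
    assert result.silhouette_by_k[2] == pytest.approx(0.0)
    assert result.silhouette_by_k[3] == pytest.approx(0.0)
    assert result.k == 2
    with pytest.raises(ParameterError):
        choose_k(tree, D, [])
    with pytest.raises(ParameterError):
        choose_k(tree, D, [1, 2])


def test_region_concordance_perfect_and_random():
    ids = [f"c{i}" for i in range(12)]
    regions = {i: r for i, r in zip(ids, ["N", "E", "W", "S"] * 3)}
    labels = [["N", "E", "W", "S"].index(regions[i]) for i in ids]
    report = region_concordance(ids, labels, regions)
    assert report.ari == pytest.approx(1.0)
    assert report.table.values.sum() == 12

    rng = np.random.default_rng(0)
    aris = []
    for _ in range(1000):
        permuted = rng.permutation(labels)
        aris.append(region_concordance(ids, permuted, regions).ari)
    assert abs(np.mean(aris)) < 0.02  # chance-corrected: ~0 in expectation

    with pytest.raises(ParameterError):
        region_concordance(ids, labels, {k: v for k, v in regions.items() if k != "c0"})


# --- tree housekeeping -------------------------------------------------------

def test_tree_newick_and_scipy_export():
    D = _dm([[0, 1, 10], [1, 0, 9], [10, 9, 0]], ids=["A", "B", "C"])
    tree = ward_agglomerate(D)
    newick = tree.to_newick()
    assert newick.endswith(";") and "A" in newick and "C" in newick
    Z = tree.to_scipy_linkage()
    assert Z.shape == (2, 4)
    from scipy.cluster.hierarchy import fcluster

    labels = fcluster(Z, t=2, criterion="maxclust")
    assert labels[0] == labels[1] != labels[2]
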