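import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from volatax import (
    canonical_analysis,
    cap_analysis,
    compound_vectors,
    gower_center,
    loo_misclassification,
    pcoa,
    permutation_test,
    select_m,
)
from volatax.errors import DegenerateInputError, GroupingError
from volatax.preprocess import DistanceMatrix

from conftest import euclidean_dm, make_peak_table


# ---------------------------------------------------------------------------
# Gower centering
# ---------------------------------------------------------------------------

def test_gower_2x2_closed_form():
    d = 3.0
    dm = euclidean_dm([[0.0], [d]])
    g = gower_center(dm)
    expected = np.array([[d * d / 4, -d * d / 4], [-d * d / 4, d * d / 4]])
    np.testing.assert_allclose(g, expected, atol=1e-12)


def test_gower_zero_matrix():
    dm = DistanceMatrix(("a", "b", "c"), np.zeros((3, 3)), "euclidean")
    np.testing.assert_allclose(gower_center(dm), 0.0, atol=1e-15)


def test_gower_equals_centered_cross_products(rng):
    points = rng.normal(size=(5, 3))
    dm = euclidean_dm(points)
    centered = points - points.mean(axis=0)
    np.testing.assert_allclose(
        gower_center(dm), centered @ centered.T, atol=1e-10
    )


def test_gower_rejects_asymmetric():
    with pytest.raises(DegenerateInputError, match="symmetric"):
        gower_center(np.array([[0.0, 1.0], [2.0, 0.0]]))


def test_gower_rows_and_columns_sum_to_zero(rng):
    for _ in range(5):
        d = np.abs(rng.normal(size=(6, 6)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        g = gower_center(d)
        scale = max(np.abs(g).max(), 1.0)
        assert np.abs(g.sum(axis=0)).max() < 1e-10 * scale
        assert np.abs(g.sum(axis=1)).max() < 1e-10 * scale


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

def test_pcoa_collinear_points():
    dm = euclidean_dm([[0.0], [3.0], [4.0]])
    pc = pcoa(dm)
    assert pc.retained_axes == 1
    # sum of squared deviations from the centroid of {0, 3, 4} = 26/3
    assert pc.eigenvalues[0] == pytest.approx(26.0 / 3.0)
    assert pc.eigenvalues[1:] == pytest.approx([0.0, 0.0], abs=1e-9)


def test_pcoa_two_points_closed_form():
    d = 5.0
    pc = pcoa(euclidean_dm([[0.0], [d]]))
    assert pc.retained_axes == 1
    np.testing.assert_allclose(
        np.sort(pc.axis_scores[:, 0]), [-d / 2, d / 2], atol=1e-12
    )


def test_pcoa_reconstructs_euclidean_distances(rng):
    points = rng.normal(size=(8, 3))
    dm = euclidean_dm(points)
    pc = pcoa(dm)
    rec = squareform(pdist(pc.axis_scores))
    np.testing.assert_allclose(rec, dm.values, atol=1e-8)


def test_pcoa_matches_skbio(rng):
    skbio = pytest.importorskip("skbio")
    points = rng.normal(size=(7, 4))
    dm = euclidean_dm(points)
    ours = pcoa(dm)
    theirs = skbio.stats.ordination.pcoa(
        skbio.DistanceMatrix(dm.values.copy(), ids=list(dm.sample_ids))
    )
    np.testing.assert_allclose(
        ours.eigenvalues[: ours.retained_axes],
        theirs.eigvals.to_numpy()[: ours.retained_axes],
        atol=1e-8,
    )
    np.testing.assert_allclose(
        np.abs(ours.axis_scores),
        np.abs(theirs.samples.to_numpy()[:, : ours.retained_axes]),
        atol=1e-6,
    )


def test_pcoa_degenerate_all_zero():
    dm = DistanceMatrix(("a", "b", "c"), np.zeros((3, 3)), "euclidean")
    with pytest.raises(DegenerateInputError):
        pcoa(dm)


def test_pcoa_braycurtis_scores_do_not_stretch_distances(rng):
    profiles = rng.random((8, 12))
    profiles /= profiles.sum(axis=1, keepdims=True)
    d = squareform(pdist(profiles, metric="braycurtis"))
    dm = DistanceMatrix(tuple(f"s{i}" for i in range(8)), d, "bray-curtis")
    pc = pcoa(dm)
    rec = squareform(pdist(pc.axis_scores))
    neg = -pc.eigenvalues[pc.eigenvalues < 0].sum()
    # retained-axis distances exceed inputs at most by the dropped-axis share
    assert (rec - dm.values).max() <= np.sqrt(2 * neg) + 1e-8


def test_pcoa_axis_scores_are_centered(rng):
    pc = pcoa(euclidean_dm(rng.normal(size=(6, 3))))
    scale = np.abs(pc.axis_scores).max()
    assert np.abs(pc.axis_scores.sum(axis=0)).max() < 1e-9 * max(scale, 1)


def test_pcoa_eigenvalue_sum_equals_trace(rng):
    dm = euclidean_dm(rng.normal(size=(9, 4)))
    g = gower_center(dm)
    pc = pcoa(dm)
    scale = max(abs(np.trace(g)), 1.0)
    assert abs(pc.eigenvalues.sum() - np.trace(g)) < 1e-8 * scale


# ---------------------------------------------------------------------------
# Canonical analysis
# ---------------------------------------------------------------------------

def cva_oracle(points, labels, g):
    """Canonical correlations + unit-norm canonical scores from coordinates."""
    x = points - points.mean(axis=0)
    y = np.zeros((len(labels), g))
    y[np.arange(len(labels)), labels] = 1.0
    y = y - y.mean(axis=0)
    ux, sx, _ = np.linalg.svd(x, full_matrices=False)
    qx = ux[:, sx > 1e-10 * sx[0]]
    uy, sy, _ = np.linalg.svd(y, full_matrices=False)
    qy = uy[:, sy > 1e-10 * sy[0]]
    u, s, _ = np.linalg.svd(qx.T @ qy)
    return s ** 2, qx @ u


def nearest_centroid(scores, labels, g):
    centroids = np.vstack([scores[labels == k].mean(axis=0) for k in range(g)])
    d = ((scores[:, None, :] - centroids[None]) ** 2).sum(axis=-1)
    return np.argmin(d, axis=1)


def test_separated_groups_axis1(two_cluster_dm):
    dm, groups = two_cluster_dm
    pc = pcoa(dm)
    cap = canonical_analysis(pc, groups, m=1)
    assert cap.delta_sq[0] > 0.95
    err, _ = loo_misclassification(dm, groups, m=1)
    assert err == 0.0


def test_single_group_rejected(two_cluster_dm):
    dm, _ = two_cluster_dm
    pc = pcoa(dm)
    with pytest.raises(GroupingError):
        canonical_analysis(pc, ["X"] * dm.n_samples, m=2)


def test_full_m_cap_equals_cva_oracle(rng):
    for _ in range(5):
        points = rng.normal(size=(10, 3))
        labels = np.array([i % 3 for i in range(10)])
        dm = euclidean_dm(points)
        pc = pcoa(dm)
        cap = canonical_analysis(pc, [f"g{k}" for k in labels], pc.retained_axes)
        s2, oracle_scores = cva_oracle(points, labels, 3)
        a = len(cap.delta_sq)
        np.testing.assert_allclose(
            cap.delta_sq, np.sort(s2)[::-1][:a], atol=1e-8
        )
        np.testing.assert_array_equal(
            nearest_centroid(cap.canonical_scores, labels, 3),
            nearest_centroid(oracle_scores[:, :a], labels, 3),
        )


def test_delta_sq_bounds_and_axis_count(rng):
    points = rng.normal(size=(12, 4))
    labels = [f"g{i % 4}" for i in range(12)]
    dm = euclidean_dm(points)
    pc = pcoa(dm)
    for m in range(1, pc.retained_axes + 1):
        cap = canonical_analysis(pc, labels, m)
        assert cap.canonical_scores.shape[1] == min(m, 3)
        assert ((cap.delta_sq >= 0) & (cap.delta_sq <= 1)).all()
        assert cap.trace_statistic <= 3 + 1e-9


# ---------------------------------------------------------------------------
# m selection
# ---------------------------------------------------------------------------

def test_select_m_two_clusters_reaches_zero_error(two_cluster_dm):
    dm, groups = two_cluster_dm
    m = select_m(dm, groups)
    err, _ = loo_misclassification(dm, groups, m)
    assert err == 0.0


def test_select_m_single_candidate(two_cluster_dm):
    dm, groups = two_cluster_dm
    assert select_m(dm, groups, m_max=1) == 1


def test_select_m_random_labels_near_chance(rng):
    # g=2 equal groups: chance LOO error ~50%; average over repeats
    errors = []
    for _ in range(10):
        points = rng.normal(size=(16, 3))
        labels = list(rng.permutation(["a"] * 8 + ["b"] * 8))
        dm = euclidean_dm(points)
        m = select_m(dm, labels, m_max=4)
        err, _ = loo_misclassification(dm, labels, m)
        errors.append(err)
    assert 20.0 < np.mean(errors) < 80.0


# ---------------------------------------------------------------------------
# Leave-one-out allocation
# ---------------------------------------------------------------------------

def test_loo_two_tight_clusters_zero(two_cluster_dm):
    dm, groups = two_cluster_dm
    err, confusion = loo_misclassification(dm, groups, m=2)
    assert err == 0.0
    assert confusion.loc["A", "A"] == 5 and confusion.loc["B", "B"] == 5


def test_loo_swapped_sample_exact_error():
    # 3 A's at 0, 3 B's at 10, one A-labelled sample inside B's cluster
    points = [[0.0], [0.1], [0.2], [10.0], [10.1], [10.2], [10.05]]
    groups = ["A", "A", "A", "B", "B", "B", "A"]
    dm = euclidean_dm(points)
    err, confusion = loo_misclassification(dm, groups, m=1)
    assert err == pytest.approx(100.0 / 7)
    assert confusion.loc["A", "B"] == 1


def test_loo_invariant_under_reordering_and_relabeling(rng, two_cluster_dm):
    dm, groups = two_cluster_dm
    err, _ = loo_misclassification(dm, groups, m=2)
    perm = rng.permutation(dm.n_samples)
    dm2 = DistanceMatrix(
        tuple(dm.sample_ids[i] for i in perm),
        dm.values[np.ix_(perm, perm)],
        dm.metric_name,
    )
    groups2 = ["X" if groups[i] == "A" else "Y" for i in perm]
    err2, _ = loo_misclassification(dm2, groups2, m=2)
    assert err == err2


def test_loo_confusion_rows_sum_to_group_sizes(rng):
    points = rng.normal(size=(9, 2))
    groups = [f"g{i % 3}" for i in range(9)]
    _, confusion = loo_misclassification(euclidean_dm(points), groups, m=2)
    assert (confusion.sum(axis=1) == 3).all()


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def test_permutation_strong_separation_minimal_p():
    # large enough that no random permutation reproduces the split
    rng = np.random.default_rng(5)
    points = np.vstack(
        [rng.normal(0, 0.3, (8, 2)), rng.normal(0, 0.3, (8, 2)) + [10, 0]]
    )
    groups = ["A"] * 8 + ["B"] * 8
    dm = euclidean_dm(points)
    p_trace, p_first = permutation_test(dm, groups, m=2, n_perm=99, seed=0)
    assert p_trace == pytest.approx(1.0 / 100)
    assert p_first == pytest.approx(1.0 / 100)


def test_permutation_deterministic(two_cluster_dm):
    dm, groups = two_cluster_dm
    a = permutation_test(dm, groups, m=2, n_perm=199, seed=42)
    b = permutation_test(dm, groups, m=2, n_perm=199, seed=42)
    assert a == b


def test_permutation_requires_99(two_cluster_dm):
    dm, groups = two_cluster_dm
    with pytest.raises(DegenerateInputError):
        permutation_test(dm, groups, m=2, n_perm=10)


# ---------------------------------------------------------------------------
# Compound vectors
# ---------------------------------------------------------------------------

def _cap_fixture(rng):
    points = np.vstack(
        [rng.normal(0, 0.3, (4, 2)),
         rng.normal(0, 0.3, (4, 2)) + [6, 0],
         rng.normal(0, 0.3, (4, 2)) + [0, 6]]
    )
    groups = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
    dm = euclidean_dm(points)
    pc = pcoa(dm)
    return canonical_analysis(pc, groups, m=2), dm


def test_vector_for_compound_equal_to_axis1(rng):
    cap, dm = _cap_fixture(rng)
    axis1 = cap.canonical_scores[:, 0]
    table = make_peak_table(
        np.vstack([axis1 - axis1.min() + 1.0]), samples=list(dm.sample_ids)
    )
    vec = compound_vectors(table, cap, sig_cutoff=0.2, sig_mode="abs_r")[0]
    assert vec.x == pytest.approx(1.0)
    assert vec.significant


def test_constant_compound_gets_zero_vector(rng, caplog):
    cap, dm = _cap_fixture(rng)
    table = make_peak_table(
        np.ones((1, len(dm.sample_ids))), samples=list(dm.sample_ids)
    )
    with caplog.at_level("WARNING"):
        vec = compound_vectors(table, cap, sig_cutoff=0.1)[0]
    assert (vec.x, vec.y) == (0.0, 0.0)
    assert not vec.significant
    assert any("zero-variance" in rec.message for rec in caplog.records)


def test_vectors_match_direct_correlations(rng):
    cap, dm = _cap_fixture(rng)
    matrix = rng.random((5, len(dm.sample_ids)))
    table = make_peak_table(matrix, samples=list(dm.sample_ids))
    vectors = compound_vectors(table, cap, sig_cutoff=0.65)
    for row, vec in zip(matrix, vectors):
        assert vec.x == pytest.approx(
            pearsonr(row, cap.canonical_scores[:, 0]).statistic, abs=1e-10
        )
        assert vec.y == pytest.approx(
            pearsonr(row, cap.canonical_scores[:, 1]).statistic, abs=1e-10
        )
        assert vec.significant == (vec.squared_length > 0.65)


def test_vectors_single_axis_sets_y_zero(two_cluster_dm, caplog):
    dm, groups = two_cluster_dm
    pc = pcoa(dm)
    cap = canonical_analysis(pc, groups, m=1)
    table = make_peak_table(
        np.random.default_rng(0).random((2, dm.n_samples)),
        samples=list(dm.sample_ids),
    )
    with caplog.at_level("WARNING"):
        vectors = compound_vectors(table, cap, sig_cutoff=0.2)
    assert all(v.y == 0.0 for v in vectors)


def test_vectors_sample_order_mismatch(rng):
    cap, dm = _cap_fixture(rng)
    table = make_peak_table(
        rng.random((1, dm.n_samples)),
        samples=list(reversed(dm.sample_ids)),
    )
    with pytest.raises(GroupingError):
        compound_vectors(table, cap, sig_cutoff=0.2)


# ---------------------------------------------------------------------------
# cap_analysis convenience
# ---------------------------------------------------------------------------

def test_cap_analysis_full_pipeline(two_cluster_dm):
    dm, groups = two_cluster_dm
    result = cap_analysis(dm, groups, n_perm=99, seed=3)
    assert result.loo_error_pct == 0.0
    assert result.p_trace == pytest.approx(0.01)
    assert result.confusion is not None
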