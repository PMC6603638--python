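import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from nodulemap.classify import (
    ClassificationMap,
    DegenerateClusteringError,
    FcmParams,
    assign_classes,
    classify_values,
    fcm_cluster,
    fcm_objective,
    fuse_and,
    fuse_or,
    load_classification,
    save_classification,
)


def reduced_objective(x, c, m):
    """FCM objective with memberships optimal for centroids c (closed form)."""
    d2 = (x[:, None] - np.asarray(c)[None, :]) ** 2
    if np.any(d2 == 0):
        # a coincident point contributes zero with full membership there
        out = 0.0
        for row in d2:
            if np.any(row == 0):
                continue
            out += float(np.sum(row ** (-1 / (m - 1))) ** (1 - m))
        return out
    return float(np.sum(np.sum(d2 ** (-1 / (m - 1)), axis=1) ** (1 - m)))


def brute_force_objective(x, m, grid_n=400):
    """Independent oracle: dense centroid-grid search plus local polish."""
    lo, hi = x.min(), x.max()
    pad = 0.05 * (hi - lo)
    axis = np.linspace(lo - pad, hi + pad, grid_n)
    best, best_c = np.inf, None
    for i, c1 in enumerate(axis):
        for c2 in axis[i + 1 :]:
            val = reduced_objective(x, (c1, c2), m)
            if val < best:
                best, best_c = val, (c1, c2)
    res = minimize(
        lambda c: reduced_objective(x, c, m), best_c, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12},
    )
    return min(best, float(res.fun))


def points_for(n):
    return np.column_stack([np.arange(n, dtype=float), np.zeros(n)])


class TestFcm:
    def test_well_separated_clusters(self):
        x = np.array([0.0, 0.0, 0.0, 10.0, 10.0, 10.0])
        u, c = fcm_cluster(x, FcmParams(seed=0))
        assert np.sort(c) == pytest.approx([0.0, 10.0], abs=1e-2)
        near = np.argmin(np.abs(x[:, None] - c[None, :]), axis=1)
        assert np.all(u[np.arange(6), near] >= 0.99)

    def test_matches_brute_force_oracle_small_instances(self):
        """FCM objective equals an exhaustive centroid search on <= 8 points."""
        cases = [
            np.array([0.0, 0.0, 0.0, 10.0, 10.0, 10.0]),
            np.array([0.1, 0.2, 0.3, 4.0, 4.1]),
            np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]),
            np.array([0.0, 0.5, 1.0, 9.0]),
        ]
        for x in cases:
            u, c = fcm_cluster(x, FcmParams(seed=1, tolerance=1e-9, max_iterations=2000))
            j_impl = fcm_objective(x, u, c, m=2.0)
            j_oracle = brute_force_objective(x, m=2.0)
            assert j_impl == pytest.approx(j_oracle, abs=1e-6)

    @given(
        values=st.lists(st.floats(-5, 5), min_size=3, max_size=40).filter(
            lambda v: len(set(v)) >= 2
        ),
        seed=st.integers(0, 10),
    )
    @settings(max_examples=60, deadline=None)
    def test_memberships_normalized(self, values, seed):
        u, _ = fcm_cluster(np.array(values), FcmParams(seed=seed))
        assert np.allclose(u.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((u >= 0) & (u <= 1))

    def test_permutation_equivariance(self):
        x = np.array([0.0, 1.0, 2.0, 8.0, 9.0, 10.0])
        perm = np.array([3, 0, 5, 1, 4, 2])
        params = FcmParams(seed=4, tolerance=1e-10, max_iterations=2000)
        u1, c1 = fcm_cluster(x, params)
        u2, c2 = fcm_cluster(x[perm], params)
        assert np.sort(c1) == pytest.approx(np.sort(c2), abs=1e-6)
        t1 = u1[:, np.argmax(c1)]
        t2 = u2[:, np.argmax(c2)]
        assert t1[perm] == pytest.approx(t2, abs=1e-4)

    def test_small_fuzzifier_approaches_kmeans(self):
        """As m -> 1+ the fuzzy labels coincide with 2-means on separated data."""
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 0.3, 30), rng.normal(5, 0.3, 30)])
        u, c = fcm_cluster(x, FcmParams(seed=0, m=1.05))
        fuzzy_labels = np.argmax(u, axis=1) == np.argmax(c)

        # Lloyd's algorithm as the crisp oracle
        centers = np.array([x.min(), x.max()])
        for _ in range(100):
            assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
            centers = np.array([x[assign == j].mean() for j in (0, 1)])
        kmeans_labels = assign == np.argmax(centers)
        assert np.array_equal(fuzzy_labels, kmeans_labels)

    def test_identical_values_degenerate(self):
        with pytest.raises(DegenerateClusteringError):
            fcm_cluster(np.ones(10), FcmParams())

    def test_coincident_point_gets_full_membership(self):
        x = np.array([0.0, 0.0, 0.0, 0.0, 10.0, 10.0, 10.0, 10.0])
        u, c = fcm_cluster(x, FcmParams(seed=2, tolerance=1e-9))
        # centroids converge onto the two atoms; memberships there are one-hot
        near0 = np.argmin(np.abs(c))
        assert u[0, near0] == pytest.approx(1.0, abs=1e-3)


class TestAssignment:
    def test_larger_centroid_is_tumor(self):
        u = np.array([[0.9, 0.1], [0.2, 0.8]])
        cmap = assign_classes(u, np.array([0.3, 4.0]), points_for(2), "stiffness")
        assert list(cmap.labels) == [False, True]

    def test_exact_tie_goes_healthy(self):
        u = np.array([[0.5, 0.5]])
        cmap = assign_classes(u, np.array([0.0, 1.0]), points_for(1), "stiffness")
        assert not cmap.labels[0]

    def test_equal_centroids_degenerate(self):
        with pytest.raises(DegenerateClusteringError):
            assign_classes(np.array([[0.5, 0.5]]), np.array([1.0, 1.0]), points_for(1), "x")


def random_map(rng, n, method="stiffness"):
    labels = rng.random(n) < 0.4
    return ClassificationMap(
        points=points_for(n),
        labels=labels,
        tumor_membership=np.where(labels, 0.9, 0.1),
        method=method,
    )


class TestFusion:
    def test_truth_table(self):
        a = ClassificationMap(points_for(4), [1, 1, 0, 0], [0.9, 0.9, 0.1, 0.1], "stiffness")
        b = ClassificationMap(points_for(4), [1, 0, 1, 0], [0.9, 0.1, 0.9, 0.1], "ultrasound")
        assert list(fuse_and(a, b).labels) == [True, False, False, False]
        assert list(fuse_or(a, b).labels) == [True, True, True, False]

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        a = random_map(rng, 20)
        assert np.array_equal(fuse_and(a, a).labels, a.labels)
        assert np.array_equal(fuse_or(a, a).labels, a.labels)

    def test_grid_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        a, b = random_map(rng, 5), random_map(rng, 6)
        with pytest.raises(ValueError):
            fuse_and(a, b)

    @given(seed=st.integers(0, 50))
    @settings(max_examples=30, deadline=None)
    def test_count_bounds_and_error_set_identities(self, seed):
        """AND shrinks positives below both inputs; OR grows them above; the
        false-negative set of OR is contained in both inputs' FN sets and the
        false-positive set of AND in both inputs' FP sets, for any truth."""
        rng = np.random.default_rng(seed)
        n = 40
        a, b = random_map(rng, n), random_map(rng, n, "ultrasound")
        fused_and, fused_or = fuse_and(a, b), fuse_or(a, b)
        assert fused_and.n_tumor <= min(a.n_tumor, b.n_tumor)
        assert fused_or.n_tumor >= max(a.n_tumor, b.n_tumor)

        truth = rng.random(n) < 0.3
        fn = lambda m: set(np.flatnonzero(~m.labels & truth))
        fp = lambda m: set(np.flatnonzero(m.labels & ~truth))
        assert fn(fused_or) <= fn(a) & fn(b)
        assert fp(fused_and) <= fp(a) & fp(b)


def test_classification_file_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    cmap = classify_values(
        np.concatenate([rng.normal(0.3, 0.02, 20), rng.normal(1.2, 0.05, 8)]),
        points_for(28),
        "stiffness",
        FcmParams(seed=0),
    )
    path = tmp_path / "labels.tsv"
    save_classification(cmap, path)
    back = load_classification(path)
    assert back.method == "stiffness"
    assert np.array_equal(back.labels, cmap.labels)
    assert np.allclose(back.tumor_membership, cmap.tumor_membership)
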