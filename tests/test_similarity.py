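import math

import numpy as np
import pytest

from asymkit.atlas import CORTICAL, default_atlas
from asymkit.similarity import (
    _assign_nearest,
    mirror_conjugate,
    pattern_correlation,
    pairwise_spin_tests,
    random_rotations,
    spin_null,
    spin_test,
    ward_cluster,
)


# ---- independent oracles --------------------------------------------------


def brute_force_pearson(a, b):
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    va = sum((x - ma) ** 2 for x in a)
    vb = sum((y - mb) ** 2 for y in b)
    return cov / math.sqrt(va * vb)


def brute_force_ward_heights(points):
    """Agglomerative Ward by the Lance-Williams recurrence, 1-D points."""
    clusters = {i: [float(p)] for i, p in enumerate(points)}
    dist = {}
    for i in clusters:
        for j in clusters:
            if i < j:
                dist[(i, j)] = abs(clusters[i][0] - clusters[j][0])
    heights = []
    next_id = len(points)
    sizes = {i: 1 for i in clusters}
    while len(clusters) > 1:
        (i, j), d_ij = min(dist.items(), key=lambda kv: kv[1])
        heights.append(d_ij)
        merged = clusters.pop(i) + clusters.pop(j)
        ni, nj = sizes.pop(i), sizes.pop(j)
        nk_new = ni + nj
        new_dist = {}
        for k in clusters:
            nk = sizes[k]
            d_ik = dist[(min(i, k), max(i, k))]
            d_jk = dist[(min(j, k), max(j, k))]
            d_new = math.sqrt(
                (
                    (ni + nk) * d_ik**2
                    + (nj + nk) * d_jk**2
                    - nk * d_ij**2
                )
                / (ni + nj + nk)
            )
            new_dist[(min(k, next_id), max(k, next_id))] = d_new
        dist = {
            key: v
            for key, v in dist.items()
            if i not in key and j not in key
        }
        dist.update(new_dist)
        clusters[next_id] = merged
        sizes[next_id] = nk_new
        next_id += 1
    return heights


class TestPatternCorrelation:
    def test_self_correlation_one(self):
        a = np.array([1.0, 2.0, 5.0])
        assert pattern_correlation(a, a) == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        a = np.array([1.0, 2.0, 5.0])
        assert pattern_correlation(a, -a) == pytest.approx(-1.0)

    def test_hand_oracle_small_vectors(self):
        a = [1.0, 2.0, 3.0]
        b = [1.0, 2.0, 4.0]
        assert pattern_correlation(a, b) == pytest.approx(
            brute_force_pearson(a, b), abs=1e-12
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pattern_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRotations:
    def test_orthogonal_with_unit_determinant(self):
        R = random_rotations(200, np.random.default_rng(0))
        eye = np.einsum("sij,skj->sik", R, R)
        assert np.abs(eye - np.eye(3)).max() < 1e-10
        assert np.allclose(np.linalg.det(R), 1.0, atol=1e-10)

    def test_matches_scipy_uniformity_convention(self):
        """Column vectors of random rotations cover the sphere uniformly
        (moment check against scipy's uniform sampler)."""
        scipy_rot = pytest.importorskip("scipy.spatial.transform")
        R = random_rotations(4000, np.random.default_rng(1))
        ours = R[:, :, 0]
        ref = scipy_rot.Rotation.random(4000, rng=2).as_matrix()[:, :, 0]
        assert np.abs(ours.mean(axis=0)).max() < 0.05
        assert np.abs(ours.mean(axis=0) - ref.mean(axis=0)).max() < 0.1

    def test_mirror_conjugate_flips_x(self):
        R = random_rotations(5, np.random.default_rng(2))
        M = np.diag([-1.0, 1.0, 1.0])
        for r in R:
            assert np.allclose(mirror_conjugate(r), M @ r @ M)


class TestSpinNull:
    def test_identity_rotation_gives_identity_assignment(self, atlas):
        pts = atlas.centroid_left[atlas.indices_of(CORTICAL)]
        assert np.array_equal(_assign_nearest(pts, pts), np.arange(len(pts)))

    def test_cortical_assignments_stay_cortical(self, atlas):
        table = spin_null(atlas, n_spin=200, seed=0)
        cort = atlas.indices_of(CORTICAL)
        assert np.all(np.isin(table[:, cort], cort))

    def test_noncortical_are_within_class_permutations(self, atlas):
        table = spin_null(atlas, n_spin=100, seed=1)
        for tissue in ("subcortical", "cerebellar"):
            idx = atlas.indices_of(tissue)
            assert np.all(np.sort(table[:, idx], axis=1) == idx)

    def test_every_cortical_region_selected_over_many_spins(self, atlas):
        table = spin_null(atlas, n_spin=2000, seed=2)
        cort = atlas.indices_of(CORTICAL)
        selected = np.unique(table[:, cort])
        assert set(cort.tolist()) <= set(selected.tolist())

    def test_deterministic_given_seed(self, atlas):
        assert np.array_equal(
            spin_null(atlas, n_spin=50, seed=3), spin_null(atlas, n_spin=50, seed=3)
        )

    def test_mirrored_rotation_reproduces_left_assignment(self, atlas):
        """Conjugate rotation applied to the mirrored hemisphere yields the
        same reassignment as the original rotation on the left."""
        cort = atlas.indices_of(CORTICAL)
        left = atlas.centroid_left[cort]
        right = atlas.centroid_right[cort]  # x-mirror of left
        R = random_rotations(20, np.random.default_rng(4))
        for r in R:
            a_left = _assign_nearest(left, left @ r.T)
            a_right = _assign_nearest(right, right @ mirror_conjugate(r).T)
            assert np.array_equal(a_left, a_right)

    def test_zero_spins_rejected(self, atlas):
        with pytest.raises(ValueError):
            spin_null(atlas, n_spin=0)


@pytest.fixture(scope="module")
def null_table():
    return spin_null(default_atlas(), n_spin=500, seed=5)


class TestSpinTest:
    def test_empirical_p_floor(self, null_table, atlas):
        """A map correlated with itself: no spin reproduces |r| = 1, so the
        p-value attains its smallest possible value 1/(n_spin+1)."""
        rng = np.random.default_rng(6)
        a = rng.standard_normal(atlas.n_regions)
        res = spin_test(a, a, null_table)
        assert res.r_obs == pytest.approx(1.0)
        assert res.p_empirical == pytest.approx(1.0 / (500 + 1))

    def test_p_never_zero_and_bounded(self, null_table, atlas):
        rng = np.random.default_rng(7)
        for _ in range(10):
            a = rng.standard_normal(65)
            b = rng.standard_normal(65)
            res = spin_test(a, b, null_table)
            assert 1.0 / 501 <= res.p_empirical <= 1.0

    def test_null_values_use_original_map_values(self, null_table, atlas):
        rng = np.random.default_rng(8)
        b = rng.standard_normal(65)
        perm = b[null_table[0]]
        assert set(np.round(perm, 12)) <= set(np.round(b, 12))

    def test_empty_null_rejected(self, atlas):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError):
            spin_test(
                rng.standard_normal(65),
                rng.standard_normal(65),
                np.empty((0, 65), dtype=int),
            )

    def test_pairwise_matrix_symmetric_with_unit_diagonal(self, null_table):
        rng = np.random.default_rng(10)
        pats = {f"g{i}": rng.standard_normal(65) for i in range(4)}
        r, p, p_fdr = pairwise_spin_tests(pats, null_table)
        assert np.allclose(r.to_numpy(), r.to_numpy().T)
        assert np.allclose(np.diag(r.to_numpy()), 1.0)
        off = ~np.eye(4, dtype=bool)
        assert np.all(p_fdr.to_numpy()[off] >= p.to_numpy()[off] - 1e-12)


class TestWardCluster:
    def test_duplicate_vectors_merge_first_at_zero_height(self):
        u = np.array([0.0, 0.0, 0.0])
        v = np.array([10.0, 10.0, 10.0])
        res = ward_cluster({"u1": u, "u2": u + 0.0, "v1": v, "v2": v + 0.0})
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert res.linkage[1, 2] == pytest.approx(0.0, abs=1e-12)

    def test_heights_match_lance_williams_oracle(self):
        points = [0.0, 1.0, 10.0]
        res = ward_cluster({f"p{i}": np.array([p]) for i, p in enumerate(points)})
        expected = brute_force_ward_heights(points)
        assert res.linkage[:, 2].tolist() == pytest.approx(expected, abs=1e-10)

    def test_heights_match_oracle_random_1d(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            points = rng.normal(size=6).tolist()
            res = ward_cluster(
                {f"p{i}": np.array([p]) for i, p in enumerate(points)}
            )
            expected = brute_force_ward_heights(points)
            assert res.linkage[:, 2].tolist() == pytest.approx(expected, abs=1e-8)

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(12)
        pats = {f"g{i}": rng.standard_normal(65) for i in range(8)}
        res = ward_cluster(pats)
        heights = res.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(13)
        pats = {f"g{i}": rng.standard_normal(10) for i in range(6)}
        res1 = ward_cluster(pats)
        reordered = dict(reversed(list(pats.items())))
        res2 = ward_cluster(reordered)
        assert np.allclose(
            np.sort(res1.linkage[:, 2]), np.sort(res2.linkage[:, 2]), atol=1e-10
        )
        assert res1.flat_clusters(2).items() >= {}.items()  # callable
        # same partition at k=2 regardless of input order
        f1 = res1.flat_clusters(2)
        f2 = res2.flat_clusters(2)
        group_of = lambda f: frozenset(
            frozenset(k for k, v in f.items() if v == c) for c in set(f.values())
        )
        assert group_of(f1) == group_of(f2)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            ward_cluster({"only": np.arange(3.0)})
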