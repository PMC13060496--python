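"""Unit tests for the evaluation metrics (with brute-force oracles)."""

import numpy as np
import pandas as pd
import pytest

from slabimpute import (SegmentationVolume, SurfaceMesh,
                        closest_point_distances, cortical_thickness,
                        dice_score, make_sphere_mesh, mean_parcel_distance,
                        region_dice_table, resample_labels_nearest,
                        thickness_error)


def seg(arr, affine=None):
    return SegmentationVolume(np.asarray(arr, dtype=np.int32), affine)


class TestDice:
    def test_identical_masks(self, rng):
        a = rng.integers(0, 3, (6, 6, 6))
        assert dice_score(seg(a), seg(a), 1) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4)); a[0] = 1
        b = np.zeros((4, 4, 4)); b[2] = 1
        assert dice_score(seg(a), seg(b), 1) == 0.0

    def test_counting_oracle(self):
        a = np.zeros((5, 5, 5)); b = np.zeros((5, 5, 5))
        a.flat[:10] = 1
        b.flat[4:14] = 1  # overlap = 6
        assert dice_score(seg(a), seg(b), 1) == pytest.approx(0.6)

    def test_symmetry_and_permutation_invariance(self, rng):
        a = rng.integers(0, 3, (5, 5, 5))
        b = rng.integers(0, 3, (5, 5, 5))
        assert dice_score(seg(a), seg(b), 2) == dice_score(seg(b), seg(a), 2)
        perm = rng.permutation(125)
        ap = a.ravel()[perm].reshape(a.shape)
        bp = b.ravel()[perm].reshape(b.shape)
        assert dice_score(seg(ap), seg(bp), 2) == dice_score(seg(a), seg(b), 2)

    def test_empty_empty_convention(self):
        z = np.zeros((3, 3, 3))
        assert dice_score(seg(z), seg(z), 5) == 1.0
        one = z.copy(); one[0, 0, 0] = 5
        assert dice_score(seg(one), seg(z), 5) == 0.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_score(seg(np.zeros((3, 3, 3))), seg(np.zeros((4, 4, 4))), 1)
        with pytest.raises(ValueError):
            dice_score(seg(np.zeros((3, 3, 3))),
                       seg(np.zeros((3, 3, 3)), affine=np.diag([2, 1, 1, 1.0])), 1)


class TestRegionDiceTable:
    def test_single_label_reduces_to_dice(self, rng):
        a = rng.integers(0, 2, (4, 4, 4))
        b = rng.integers(0, 2, (4, 4, 4))
        table = region_dice_table(seg(a), seg(b), [1])
        assert len(table) == 1
        assert table.dice.iloc[0] == dice_score(seg(a), seg(b), 1)

    def test_identical_inputs_all_ones(self, rng):
        a = rng.integers(0, 4, (4, 4, 4))
        table = region_dice_table(seg(a), seg(a), [1, 2, 3])
        assert (table.dice == 1.0).all()

    def test_absent_label_flagged(self):
        z = seg(np.zeros((3, 3, 3)))
        table = region_dice_table(z, z, [7])
        assert table.dice.iloc[0] == 1.0
        assert table.note.iloc[0] == "empty-empty"


def brute_force_point_triangle(p, tri):
    """Dense-sampling oracle: min distance from p to barycentric samples."""
    a, b, c = tri
    u = np.linspace(0, 1, 120)
    uu, vv = np.meshgrid(u, u)
    keep = uu + vv <= 1.0
    pts = (a[None, :] + uu[keep][:, None] * (b - a)[None, :]
           + vv[keep][:, None] * (c - a)[None, :])
    return np.sqrt(((pts - p) ** 2).sum(axis=1)).min()


class TestClosestPointDistances:
    def test_self_distance_zero(self):
        m = make_sphere_mesh(5.0, 2)
        assert np.allclose(closest_point_distances(m, m), 0.0, atol=1e-9)

    def test_concentric_spheres(self):
        inner = make_sphere_mesh(10.0, 3)
        outer = make_sphere_mesh(12.0, 3)
        d = closest_point_distances(inner, outer)
        assert np.all(np.abs(d - 2.0) < 0.05)

    def test_point_to_triangle_not_vertex(self):
        # a single large triangle; the probe faces its interior, far from
        # every vertex
        tri = SurfaceMesh(np.array([[-10.0, -10.0, 0.0], [10.0, -10.0, 0.0],
                                    [0.0, 15.0, 0.0]]),
                          np.array([[0, 1, 2]]))
        probe = SurfaceMesh(np.array([[0.0, 0.0, 3.0]]), np.array([[0, 0, 0]]))
        d = closest_point_distances(probe, tri)
        assert np.isclose(d[0], 3.0)

    def test_matches_brute_force_on_random_mesh(self, rng):
        verts = rng.random((12, 3)) * 10
        tris = np.array([[0, 1, 2], [3, 4, 5], [6, 7, 8], [9, 10, 11],
                         [0, 4, 8], [1, 5, 9]])
        ref = SurfaceMesh(verts, tris)
        src = SurfaceMesh(rng.random((20, 3)) * 10, np.array([[0, 1, 2]]))
        d = closest_point_distances(src, ref)
        for k in range(len(src.vertices)):
            oracle = min(brute_force_point_triangle(src.vertices[k],
                                                    verts[t]) for t in tris)
            assert abs(d[k] - oracle) < 2e-3  # oracle sampling resolution

    def test_translation_triangle_inequality(self, rng):
        ref = make_sphere_mesh(6.0, 2)
        src = make_sphere_mesh(5.0, 2)
        base = closest_point_distances(src, ref)
        t = np.array([0.5, -0.25, 0.3])
        moved = SurfaceMesh(src.vertices + t, src.triangles)
        shifted = closest_point_distances(moved, ref)
        assert np.all(shifted <= base + np.linalg.norm(t) + 1e-9)

    def test_empty_mesh_rejected(self):
        m = make_sphere_mesh(3.0, 1)
        empty = SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(ValueError):
            closest_point_distances(m, empty)


class TestParcelAggregation:
    def test_all_zero_distances(self):
        per, grand = mean_parcel_distance(np.zeros(10),
                                          np.repeat([1, 2], 5))
        assert (per == 0).all() and grand == 0.0

    def test_mean_of_means_ignores_parcel_size(self):
        d = np.array([1.0] * 9 + [3.0])
        labels = np.array([1] * 9 + [2])
        per, grand = mean_parcel_distance(d, labels)
        assert grand == pytest.approx(2.0)

    def test_matches_brute_force_group_by(self, rng):
        d = rng.random(200)
        labels = rng.integers(0, 34, 200)
        per, grand = mean_parcel_distance(d, labels)
        means = {}
        for lab in np.unique(labels):
            means[lab] = d[labels == lab].mean()
        for lab, m in means.items():
            assert np.isclose(per.loc[lab], m)
        assert np.isclose(grand, np.mean(list(means.values())))


class TestThickness:
    def test_identical_surfaces_zero_thickness(self):
        m = make_sphere_mesh(8.0, 2)
        assert np.allclose(cortical_thickness(m, m), 0.0, atol=1e-9)

    def test_concentric_analytic_thickness(self):
        white = make_sphere_mesh(10.0, 3)
        pial = make_sphere_mesh(12.5, 3)
        th = cortical_thickness(white, pial)
        assert np.all(np.abs(th - 2.5) < 0.06)
        assert np.all(th >= 0)

    def test_thickness_error_identity_and_offset(self, rng):
        th = rng.random(50) + 1.0
        labels = rng.integers(0, 5, 50)
        per, grand = thickness_error(th, th, labels)
        assert (per == 0).all() and grand == 0.0
        per2, grand2 = thickness_error(th, th + 0.4, labels)
        assert np.allclose(per2, 0.4)
        assert grand2 == pytest.approx(0.4)

    def test_error_matches_brute_force_group_means(self, rng):
        a = rng.random(100)
        b = rng.random(100)
        labels = rng.integers(0, 7, 100)
        per, grand = thickness_error(a, b, labels)
        for lab in np.unique(labels):
            mask = labels == lab
            assert np.isclose(per.loc[lab],
                              abs(a[mask].mean() - b[mask].mean()))


class TestResampler:
    def test_identity_resample(self, rng):
        a = seg(rng.integers(0, 3, (6, 6, 6)))
        out = resample_labels_nearest(a, a.affine, a.labels.shape)
        assert np.array_equal(out.labels, a.labels)

    def test_downsample_by_two(self):
        labels = np.zeros((6, 6, 6), dtype=np.int32)
        labels[3:, :, :] = 2
        a = seg(labels)
        target_affine = np.diag([2.0, 2.0, 2.0, 1.0])
        out = resample_labels_nearest(a, target_affine, (3, 3, 3))
        assert np.array_equal(out.labels, labels[::2, ::2, ::2])
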