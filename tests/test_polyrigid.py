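"""Structure weights and log-Euclidean polyrigid field construction."""

import numpy as np
import pytest

from polypose import se3
from polypose.polyrigid import (
    build_field,
    build_structure_set,
    build_weights,
    compute_distance_maps,
    compute_masses,
)
from polypose.volume import Labelmap


def two_blob_labelmap(shape=(20, 20, 20), spacing=(1.0, 1.0, 1.0)):
    labels = np.zeros(shape, dtype=np.int32)
    labels[3:7, 3:7, 3:7] = 1
    labels[12:18, 12:18, 12:18] = 2
    return Labelmap.from_spacing(labels, spacing)


class TestMasses:
    def test_equal_structures(self):
        labels = np.zeros((10, 10, 10), dtype=np.int32)
        labels[1:3, 1:3, 1:3] = 1
        labels[6:8, 6:8, 6:8] = 2
        lm = Labelmap.from_spacing(labels, (1.0, 1.0, 1.0))
        np.testing.assert_allclose(compute_masses(lm), [0.5, 0.5])

    def test_single_structure(self):
        labels = np.zeros((5, 5, 5), dtype=np.int32)
        labels[2, 2, 2] = 1
        lm = Labelmap.from_spacing(labels, (1.0, 1.0, 1.0))
        np.testing.assert_allclose(compute_masses(lm), [1.0])

    def test_proportional_to_counts(self):
        labels = np.zeros((20, 20, 20), dtype=np.int32)
        labels.ravel()[:100] = 1
        labels.ravel()[100:400] = 2
        lm = Labelmap.from_spacing(labels, (0.7, 0.7, 0.7))
        np.testing.assert_allclose(compute_masses(lm), [0.25, 0.75])

    def test_empty_structure_named_in_error(self):
        lm = two_blob_labelmap()
        with pytest.raises(ValueError, match="7"):
            compute_masses(lm, ids=[1, 7])


class TestDistanceMaps:
    def test_zero_on_structure(self):
        lm = two_blob_labelmap()
        d = compute_distance_maps(lm)
        assert d[0][lm.labels == 1].max() == 0.0
        assert d[1][lm.labels == 2].max() == 0.0

    def test_single_voxel_neighbour_distance(self):
        labels = np.zeros((7, 7, 7), dtype=np.int32)
        labels[3, 3, 3] = 1
        lm = Labelmap.from_spacing(labels, (1.0, 1.0, 1.0))
        d = compute_distance_maps(lm)[0]
        assert d[4, 3, 3] == pytest.approx(1.0)
        assert d[4, 4, 3] == pytest.approx(np.sqrt(2.0))

    def test_anisotropic_matches_brute_force(self):
        rng = np.random.default_rng(0)
        labels = np.zeros((10, 10, 10), dtype=np.int32)
        labels[rng.uniform(size=(10, 10, 10)) > 0.9] = 1
        if not (labels == 1).any():
            labels[5, 5, 5] = 1
        lm = Labelmap.from_spacing(labels, (1.0, 1.0, 2.0))
        d = compute_distance_maps(lm)[0]
        centers = lm.grid.voxel_centers()
        struct_pts = centers[labels == 1].reshape(-1, 3)
        for idx in [(0, 0, 0), (3, 7, 2), (9, 9, 9), (5, 5, 5)]:
            brute = np.linalg.norm(struct_pts - centers[idx], axis=1).min()
            assert d[idx] == pytest.approx(brute, abs=1e-9)

    def test_axial_neighbour_along_z_spacing_2(self):
        labels = np.zeros((5, 5, 5), dtype=np.int32)
        labels[2, 2, 2] = 1
        lm = Labelmap.from_spacing(labels, (1.0, 1.0, 2.0))
        d = compute_distance_maps(lm)[0]
        assert d[2, 2, 3] == pytest.approx(2.0)


class TestWeights:
    def setup_method(self):
        self.ss = build_structure_set(two_blob_labelmap())

    def test_rows_sum_to_one(self):
        for wf in (build_weights(self.ss, "mass"), build_weights(self.ss, "reciprocal", 0.1)):
            sums = wf.table.sum(axis=1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-6)
            assert wf.weights.min() >= 0.0 and wf.weights.max() <= 1.0

    def test_mass_mode_unnormalized_equals_mass_inside_structure(self):
        """Inside S_k, d_k = 0, so the unnormalized weight is exactly m_k."""
        d2 = self.ss.distance_maps**2
        unnorm = self.ss.masses[:, None, None, None] / (1.0 + d2)
        inside = self.ss.masks[0]
        np.testing.assert_allclose(unnorm[0][inside], self.ss.masses[0])

    def test_mass_formula_value(self):
        # m_k = 0.5 at distance 3 mm: 0.5 / (1 + 9) = 0.05
        assert 0.5 / (1.0 + 3.0**2) == pytest.approx(0.05)
        d2 = self.ss.distance_maps[0] ** 2
        w_un = self.ss.masses[0] / (1.0 + d2)
        pick = np.isclose(self.ss.distance_maps[0], 3.0)
        if pick.any():
            np.testing.assert_allclose(w_un[pick], self.ss.masses[0] / 10.0)

    def test_reciprocal_formula_value(self):
        # eps=1, d=1: 1 / (1 + 1) = 0.5
        wf = build_weights(self.ss, "reciprocal", 1.0)
        d = self.ss.distance_maps
        unnorm = 1.0 / (1.0 + 1.0 * d**2)
        at_one = np.isclose(d[0], 1.0)
        np.testing.assert_allclose(unnorm[0][at_one], 0.5)
        # and the normalized field reconstructs from the same unnormalized form
        recon = np.moveaxis(unnorm, 0, -1)
        recon = recon / recon.sum(axis=-1, keepdims=True)
        np.testing.assert_allclose(wf.weights, recon, atol=1e-12)

    def test_epsilon_in_mass_mode_rejected(self):
        with pytest.raises(ValueError, match="hyperparameter-free"):
            build_weights(self.ss, "mass", epsilon=0.5)

    def test_reciprocal_requires_epsilon(self):
        with pytest.raises(ValueError, match="epsilon"):
            build_weights(self.ss, "reciprocal")


class TestPolyrigidField:
    def setup_method(self):
        self.lm = two_blob_labelmap()
        self.ss = build_structure_set(self.lm)
        self.wf = build_weights(self.ss, "mass")

    def test_identity_with_zero_twists(self):
        field = build_field(self.wf, np.zeros((2, 6)))
        disp = field.displacement()
        assert np.abs(disp).max() == 0.0

    def test_single_structure_reduces_to_rigid(self):
        labels = (two_blob_labelmap().labels == 1).astype(np.int32)
        lm = Labelmap.from_spacing(labels, (1.0, 1.0, 1.0))
        wf = build_weights(build_structure_set(lm), "mass")
        xi = np.array([[0.1, -0.05, 0.2, 3.0, -1.0, 2.0]])
        field = build_field(wf, xi)
        T = se3.exp_se3(xi[0])
        x = lm.grid.voxel_centers().reshape(-1, 3)
        expected = x @ T[:3, :3].T + T[:3, 3]
        np.testing.assert_allclose(field.mapped_coords().reshape(-1, 3), expected, atol=1e-9)

    def test_identical_twists_reduce_to_rigid(self):
        xi = np.array([0.08, 0.02, -0.1, 1.0, 2.0, -0.5])
        field = build_field(self.wf, np.stack([xi, xi]))
        T = se3.exp_se3(xi)
        x = self.lm.grid.voxel_centers().reshape(-1, 3)
        expected = x @ T[:3, :3].T + T[:3, 3]
        np.testing.assert_allclose(field.mapped_coords().reshape(-1, 3), expected, atol=1e-9)

    def test_vectorized_matches_per_voxel_loop(self):
        """Batched field equals the naive per-voxel weighted-log fusion, K=3, 32^3."""
        labels = np.zeros((32, 32, 32), dtype=np.int32)
        labels[4:10, 4:10, 4:10] = 1
        labels[20:28, 20:28, 20:28] = 2
        labels[4:9, 20:26, 4:9] = 3
        lm = Labelmap.from_spacing(labels, (1.0, 1.0, 1.0))
        wf = build_weights(build_structure_set(lm), "mass")
        rng = np.random.default_rng(1)
        twists = np.concatenate(
            [rng.uniform(-0.15, 0.15, (3, 3)), rng.uniform(-8, 8, (3, 3))], axis=1
        )
        field = build_field(wf, twists)
        fast = field.mapped_coords().reshape(-1, 3)

        W = wf.table
        x = lm.grid.voxel_centers().reshape(-1, 3)
        slow = np.empty_like(fast)
        for i in range(W.shape[0]):
            eta = W[i] @ twists
            T = se3.exp_se3(eta)
            slow[i] = T[:3, :3] @ x[i] + T[:3, 3]
        assert np.abs(fast - slow).max() < 1e-8

    def test_locality_of_influence(self):
        """Inside S_k the field is closer to T_k than anywhere outside it."""
        twists = np.array([[0, 0, 0, 10.0, 0, 0], [0, 0, 0, -10.0, 0, 0]])
        field = build_field(self.wf, twists)
        mapped = field.mapped_coords()
        x = self.lm.grid.voxel_centers()
        T1 = se3.exp_se3(twists[0])
        target1 = x @ T1[:3, :3].T + T1[:3, 3]
        err = np.linalg.norm(mapped - target1, axis=-1)
        inside = self.lm.labels == 1
        outside = ~inside
        assert err[inside].mean() < err[outside].mean()
        assert err[inside].max() < err[self.lm.labels == 2].min()
        # influence decays with distance from S_1: error grows with d_1 on average
        d1 = self.ss.distance_maps[0]
        near = (d1 > 0) & (d1 <= 3)
        far = d1 > 8
        assert err[near].mean() < err[far].mean()

    def test_at_points_matches_lattice(self):
        rng = np.random.default_rng(2)
        twists = np.concatenate([rng.uniform(-0.1, 0.1, (2, 3)), rng.uniform(-5, 5, (2, 3))], axis=1)
        field = build_field(self.wf, twists)
        pts = self.lm.grid.voxel_centers().reshape(-1, 3)[::37]
        lattice_vals = field.mapped_coords().reshape(-1, 3)[::37]
        np.testing.assert_allclose(field.at_points(pts), lattice_vals, atol=1e-9)

    def test_at_points_zero_twists_is_identity(self):
        field = build_field(self.wf, np.zeros((2, 6)))
        pts = np.array([[1.3, 5.2, 9.9], [100.0, -50.0, 3.0]])
        np.testing.assert_allclose(field.at_points(pts), pts, atol=1e-12)

    def test_off_lattice_point_bounded_by_bracketing_voxels(self):
        """Along a 1-D varying field, an off-lattice sample lies between neighbours."""
        twists = np.array([[0, 0, 0, 6.0, 0, 0], [0, 0, 0, -6.0, 0, 0]])
        field = build_field(self.wf, twists)
        mapped = field.mapped_coords()
        disp = mapped - self.lm.grid.voxel_centers()
        i, j, k = 8, 10, 10
        p0 = self.lm.grid.voxel_centers()[i, j, k]
        p1 = self.lm.grid.voxel_centers()[i + 1, j, k]
        mid = 0.5 * (p0 + p1)
        d_mid = field.at_points(mid[None])[0] - mid
        lo = np.minimum(disp[i, j, k], disp[i + 1, j, k]) - 1e-6
        hi = np.maximum(disp[i, j, k], disp[i + 1, j, k]) + 1e-6
        assert np.all(d_mid >= lo) and np.all(d_mid <= hi)

    def test_k_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_field(self.wf, np.zeros((3, 6)))
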