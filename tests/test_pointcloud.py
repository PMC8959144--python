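"""Point recording, z-jitter, slab slicing and group-comparison metrics."""

import numpy as np
import pytest
from scipy import stats as sps

from ponsquant import pointcloud
from ponsquant.pointcloud import (
    centroid_shift,
    density_overlap,
    jitter_z,
    record_points,
    slice_points,
)
from ponsquant.types import PointCloud3D, RegionVolume, SlabSpec


def uniform_cloud(n, lo, hi, seed=0, group=""):
    rng = np.random.default_rng(seed)
    return PointCloud3D(xyz=rng.uniform(lo, hi, size=(n, 3)), group=group)


class TestRecordPoints:
    def test_zero_map_empty_cloud(self):
        cloud = record_points(np.zeros((20, 20)), 5.0, seed=1)
        assert len(cloud) == 0

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            record_points(np.array([[-1.0]]), 1.0)

    def test_poisson_count_concentration(self):
        rate, area = 0.5, 50 * 40
        cloud = record_points(np.ones((50, 40)), rate, seed=2)
        expected = rate * area
        assert abs(len(cloud) - expected) < 4 * np.sqrt(expected)

    def test_density_ratio_one_to_two(self):
        dmap = np.zeros((1, 2))
        dmap[0, 0], dmap[0, 1] = 1.0, 2.0
        cloud = record_points(dmap, 3000.0, pixel_size=1.0, seed=3)
        n0 = np.sum(cloud.xyz[:, 0 + 0] < 1.0)  # x < 1 -> first pixel
        n1 = len(cloud) - n0
        assert n1 / n0 == pytest.approx(2.0, rel=0.1)

    def test_z_is_section_midplane(self):
        cloud = record_points(np.ones((5, 5)), 1.0, section_index=3,
                              section_spacing=100.0, seed=4)
        assert np.allclose(cloud.xyz[:, 2], 350.0)

    def test_deterministic(self):
        a = record_points(np.ones((10, 10)), 2.0, seed=9)
        b = record_points(np.ones((10, 10)), 2.0, seed=9)
        assert (a.xyz == b.xyz).all()


class TestJitterZ:
    def test_gap_zero_identity(self):
        cloud = uniform_cloud(100, 0, 500, seed=1)
        out = jitter_z(cloud, 0.0, seed=2)
        assert (out.xyz == cloud.xyz).all()

    def test_bounds_and_xy_preserved(self):
        cloud = uniform_cloud(5000, 0, 500, seed=1)
        out = jitter_z(cloud, 100.0, seed=2)
        dz = out.xyz[:, 2] - cloud.xyz[:, 2]
        assert np.abs(dz).max() <= 50.0
        assert (out.xyz[:, :2] == cloud.xyz[:, :2]).all()
        assert len(out) == len(cloud)

    def test_displacement_uniformity(self):
        cloud = uniform_cloud(10000, 0, 500, seed=1)
        dz = jitter_z(cloud, 100.0, seed=7).xyz[:, 2] - cloud.xyz[:, 2]
        p = sps.kstest(dz, "uniform", args=(-50.0, 100.0)).pvalue
        assert p > 0.01

    def test_forward_mode_one_sided(self):
        cloud = uniform_cloud(1000, 0, 500, seed=1)
        dz = jitter_z(cloud, 100.0, seed=2, mode="forward").xyz[:, 2] - cloud.xyz[:, 2]
        assert dz.min() >= 0.0 and dz.max() <= 100.0

    def test_seeded_repeatability(self):
        cloud = uniform_cloud(500, 0, 500, seed=1)
        a = jitter_z(cloud, 100.0, seed=3)
        b = jitter_z(cloud, 100.0, seed=3)
        assert (a.xyz == b.xyz).all()

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            jitter_z(uniform_cloud(10, 0, 1), -1.0)


class TestSlicePoints:
    def test_centre_included_boundary_excluded(self):
        cloud = PointCloud3D(xyz=np.array([[0, 0, 100.0], [0, 0, 150.0], [0, 0, 50.0]]))
        slab = SlabSpec(axis="sagittal", centre=100.0, thickness=100.0)
        kept = slice_points(cloud, slab)
        # z=100 (centre) and z=50 (lower bound, closed) kept; z=150 (upper, open) excluded
        assert sorted(kept.xyz[:, 2]) == [50.0, 100.0]

    def test_tiling_slabs_partition(self):
        cloud = uniform_cloud(20000, 0, 1000, seed=5)
        total = 0
        seen = np.zeros(len(cloud), dtype=int)
        for centre in np.arange(50.0, 1000.0, 100.0):
            slab = SlabSpec(axis="frontal", centre=centre, thickness=100.0)
            lo, hi = slab.bounds
            members = (cloud.xyz[:, 0] >= lo) & (cloud.xyz[:, 0] < hi)
            kept = slice_points(cloud, slab)
            assert len(kept) == members.sum()
            seen += members
            total += len(kept)
        assert (seen == 1).all()
        assert total == len(cloud)

    def test_attributes_preserved(self):
        cloud = PointCloud3D(
            xyz=np.array([[0, 0, 10.0], [0, 0, 500.0]]),
            density_class=np.array([3, 1]),
            source_section=np.array([7, 8]),
            group="ctrl",
        )
        kept = slice_points(cloud, SlabSpec(axis="sagittal", centre=0.0, thickness=100.0))
        assert kept.density_class.tolist() == [3]
        assert kept.source_section.tolist() == [7]
        assert kept.group == "ctrl"


class TestCentroidShift:
    def test_identical_clouds_zero(self):
        cloud = uniform_cloud(500, 0, 100, seed=2)
        shift, ci = centroid_shift(cloud, cloud, n_boot=50, seed=1)
        assert np.allclose(shift, 0)

    def test_translation_equivariance(self):
        cloud = uniform_cloud(500, 0, 100, seed=2)
        moved = PointCloud3D(xyz=cloud.xyz + np.array([200.0, 0.0, 0.0]))
        shift, _ = centroid_shift(cloud, moved, n_boot=50, seed=1)
        assert np.allclose(shift, [200.0, 0.0, 0.0])

    def test_antisymmetry(self):
        a = uniform_cloud(300, 0, 100, seed=3)
        b = uniform_cloud(300, 50, 150, seed=4)
        s_ab, _ = centroid_shift(a, b, n_boot=50, seed=1)
        s_ba, _ = centroid_shift(b, a, n_boot=50, seed=1)
        assert np.allclose(s_ab, -s_ba)

    def test_planted_shift_recovered(self, cloud_pair):
        _, control, shifted, true_shift = cloud_pair
        shift, ci = centroid_shift(control, shifted, seed=6)
        assert abs(shift[0] - true_shift[0]) < 20.0
        assert ci[0, 0] <= true_shift[0] <= ci[1, 0]

    def test_empty_cloud_errors(self):
        empty = PointCloud3D(xyz=np.empty((0, 3)))
        with pytest.raises(ValueError):
            centroid_shift(empty, uniform_cloud(10, 0, 1))


class TestDensityOverlap:
    def _volume(self):
        return RegionVolume(mask=np.ones((10, 10, 10), dtype=bool), voxel_size=10.0)

    def test_self_overlap_is_one(self):
        cloud = uniform_cloud(2000, 5, 95, seed=1)
        assert density_overlap(cloud, cloud, self._volume()) == pytest.approx(1.0)

    def test_disjoint_supports_zero(self):
        a = uniform_cloud(500, 0, 40, seed=1)
        b = uniform_cloud(500, 60, 99, seed=2)
        assert density_overlap(a, b, self._volume()) == 0.0

    def test_half_overlapping_boxes(self):
        # uniform boxes [0,50) and [25,75) along x: analytic intersection of
        # normalized densities = 0.5
        rng = np.random.default_rng(3)
        n = 40000
        a = PointCloud3D(xyz=np.column_stack([rng.uniform(0, 50, n),
                                              rng.uniform(0, 100, n),
                                              rng.uniform(0, 100, n)]))
        b = PointCloud3D(xyz=np.column_stack([rng.uniform(25, 75, n),
                                              rng.uniform(0, 100, n),
                                              rng.uniform(0, 100, n)]))
        ov = density_overlap(a, b, self._volume())
        assert ov == pytest.approx(0.5, abs=0.05)
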