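import math

import numpy as np
import pytest

from lacuna3d import (PhantomParams, VoxelGrid, degrade, label_components,
                      make_phantom, preset_params, rasterize,
                      sample_population, segment)
from lacuna3d.errors import ConfigError, PackingError
from lacuna3d.phantom import CanalSpec, EllipsoidSpec, PhantomTruth


class TestSpecs:
    def test_ellipsoid_volume_and_ar(self):
        e = EllipsoidSpec(center=(0, 0, 0), semi_axes=(5, 4, 2), rotation=np.eye(3))
        assert e.true_volume_um3 == pytest.approx(4 / 3 * math.pi * 40)
        assert e.true_ar == pytest.approx(0.4)

    def test_semi_axis_ordering_enforced(self):
        with pytest.raises(ConfigError):
            EllipsoidSpec(center=(0, 0, 0), semi_axes=(2, 4, 5), rotation=np.eye(3))

    def test_canal_must_exceed_cutoff(self):
        with pytest.raises(ConfigError):
            CanalSpec(start=(0, 0, 0), end=(0, 0, 10), radius_um=1.0)  # ~31 um^3
        ok = CanalSpec(start=(0, 0, 0), end=(0, 0, 100), radius_um=4.0)
        assert ok.volume_um3 > 2000


class TestSamplePopulation:
    @pytest.mark.parametrize("conc,expected", [(95_000, 760), (27_000, 216)])
    def test_exact_planted_count(self, conc, expected):
        params = PhantomParams(shape=(200, 200, 200), spacing=(1, 1, 1),
                               concentration_per_mm3=conc, seed=1)
        truth = sample_population(params)
        assert len(truth.lacunae) == expected
        assert truth.planted_concentration_per_mm3 == pytest.approx(conc)

    def test_bounding_spheres_disjoint_and_inside_domain(self, small_params):
        truth = sample_population(small_params)
        centers = np.array([e.center for e in truth.lacunae])
        radii = np.array([e.semi_axes[0] for e in truth.lacunae])
        L = small_params.domain_size_um
        assert np.all(centers - radii[:, None] >= 0)
        assert np.all(centers + radii[:, None] <= L)
        d = np.linalg.norm(centers[:, None] - centers[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert np.all(d >= radii[:, None] + radii[None])

    def test_deterministic_given_seed(self, small_params):
        t1 = sample_population(small_params)
        t2 = sample_population(small_params)
        assert len(t1.lacunae) == len(t2.lacunae)
        for a, b in zip(t1.lacunae, t2.lacunae):
            assert a.center == b.center and a.semi_axes == b.semi_axes
            np.testing.assert_array_equal(a.rotation, b.rotation)

    def test_packing_failure_is_fatal(self):
        params = PhantomParams(shape=(40, 40, 40), spacing=(1, 1, 1),
                               concentration_per_mm3=3_000_000, n_canals=0, seed=0)
        with pytest.raises(PackingError):
            sample_population(params)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigError):
            preset_params("xx")


class TestRasterize:
    def test_voxel_center_aligned_sphere_count(self):
        # sphere centered exactly on a voxel center: 123 lattice points in r=3
        params = PhantomParams(shape=(16, 16, 16), spacing=(1, 1, 1),
                               concentration_per_mm3=1000, n_canals=0)
        spec = EllipsoidSpec(center=(7.5, 7.5, 7.5), semi_axes=(3, 3, 3),
                             rotation=np.eye(3))
        truth = PhantomTruth([spec], [], params.domain_volume_mm3, 0)
        _, mask = rasterize(truth, params)
        analytic = 4 / 3 * math.pi * 27
        assert mask.data.sum() == pytest.approx(analytic, rel=0.15)

    def test_empty_truth(self):
        params = PhantomParams(shape=(8, 8, 8), concentration_per_mm3=1000, n_canals=0)
        grid, mask = rasterize(PhantomTruth([], [], params.domain_volume_mm3, 0), params)
        assert not mask.data.any()
        assert grid.data.min() == grid.data.max() == params.bone_level

    def test_disjoint_ellipsoids_give_two_components(self):
        params = PhantomParams(shape=(30, 30, 30), concentration_per_mm3=1000, n_canals=0)
        e1 = EllipsoidSpec(center=(8, 8, 8), semi_axes=(3, 3, 3), rotation=np.eye(3))
        e2 = EllipsoidSpec(center=(22, 22, 22), semi_axes=(3, 2, 2), rotation=np.eye(3))
        _, mask = rasterize(PhantomTruth([e1, e2], [], params.domain_volume_mm3, 0), params)
        assert label_components(mask).n_labels == 2

    def test_two_level_grid(self, small_params):
        grid, mask, _ = make_phantom(small_params)
        levels = np.unique(grid.data)
        assert set(levels.tolist()) == {small_params.void_level, small_params.bone_level}
        assert np.array_equal(grid.data == small_params.void_level, mask.data)


class TestDegrade:
    def test_zero_degradation_is_identity(self, small_params):
        grid, _, _ = make_phantom(small_params)
        out = degrade(grid, 0.0, 0.0, seed=1)
        assert out is grid

    def test_noise_sd_matches_request(self):
        grid = VoxelGrid(np.full((50, 50, 50), 100.0, np.float32), (1, 1, 1))
        out = degrade(grid, 0.0, 10.0, seed=3)
        sd = float(out.data.std())
        assert sd == pytest.approx(10.0, rel=0.05)

    def test_blur_preserves_global_mean(self, small_params):
        grid, _, _ = make_phantom(small_params)
        out = degrade(grid, 1.2, 0.0, seed=0)
        assert float(out.data.mean()) == pytest.approx(float(grid.data.mean()), rel=1e-6)

    def test_deterministic_given_seed(self):
        grid = VoxelGrid(np.full((20, 20, 20), 50.0, np.float32), (1, 1, 1))
        a = degrade(grid, 0.8, 5.0, seed=9)
        b = degrade(grid, 0.8, 5.0, seed=9)
        assert np.array_equal(a.data, b.data)

    def test_negative_parameters_fatal(self, small_params):
        grid, _, _ = make_phantom(small_params)
        with pytest.raises(ConfigError):
            degrade(grid, -1.0, 0.0, seed=0)

    def test_anisotropic_blur_uses_physical_sigma(self):
        # an impulse blurred with sigma=2 um must be wider (in voxels) along
        # the finer-sampled axis
        data = np.zeros((41, 41, 41), np.float32)
        data[20, 20, 20] = 1.0
        grid = VoxelGrid(data, spacing=(2.0, 1.0, 1.0))
        out = degrade(grid, 2.0, 0.0, seed=0)
        prof_z = out.data[:, 20, 20]
        prof_y = out.data[20, :, 20]
        width_z = (prof_z > prof_z.max() / 2).sum()
        width_y = (prof_y > prof_y.max() / 2).sum()
        assert width_y > width_z


class TestReproducibilityContract:
    def test_same_seed_bit_identical_phantom(self, small_params):
        g1, m1, _ = make_phantom(small_params)
        g2, m2, _ = make_phantom(small_params)
        assert np.array_equal(g1.data, g2.data)
        assert np.array_equal(m1.data, m2.data)

    def test_clean_phantom_full_pipeline_recovers_planted_count(self, clean_small_phantom):
        params, (grid, mask, truth) = clean_small_phantom
        seg_mask, _ = segment(grid)
        lm = label_components(seg_mask)
        vols = lm.volumes_um3()
        in_window = ((vols >= 10) & (vols <= 2000)).sum()
        assert in_window == len(truth.lacunae)
        assert (vols > 2000).sum() == len(truth.canals)

    def test_truth_roster_frame(self, clean_small_phantom):
        _, (_, _, truth) = clean_small_phantom
        df = truth.to_frame()
        assert (df["kind"] == "lacuna").sum() == len(truth.lacunae)
        assert (df["kind"] == "canal").sum() == len(truth.canals)
        lac = df[df["kind"] == "lacuna"]
        np.testing.assert_allclose(
            lac["true_volume_um3"],
            4 / 3 * np.pi * lac["a_um"] * lac["b_um"] * lac["c_um"],
        )
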