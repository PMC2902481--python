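"""Rigid/deformable registration, landmark initialization, region projection."""

import numpy as np
import pytest
from dataclasses import replace

from lymphatlas import ffd, phantom as ph, registration as rg
from lymphatlas.correspondence import LandmarkPairs
from lymphatlas.spatial import RegionMask, VolumeGeometry, VolumeImage


@pytest.fixture(scope="module")
def textured_phantom():
    spec = replace(
        ph.default_phantom_spec(
            dims=(48, 48, 36), spacing=(4.0, 4.0, 5.0), noise_sd=10.0,
            texture_sd=50.0, seed=3,
        ),
        texture_length_mm=8.0,
    )
    vol, struct, nodal = ph.generate_phantom(spec)
    return spec, vol, struct, nodal


@pytest.fixture(scope="module")
def fast_config():
    return rg.RegistrationConfig(
        resolution_schedule=((5, 5, 4),),
        iterations_per_level=15,
        rigid_iterations=120,
        sample_fraction=0.2,
        shrink_factors=(2,),
        smoothing_sigmas=(1.0,),
    )


def integer_shift(volume: VolumeImage, shift_vox) -> VolumeImage:
    """target(x) = volume(x - s) for an integer-voxel shift s."""
    values = np.roll(volume.values, shift_vox, axis=(0, 1, 2))
    return VolumeImage(volume.geometry, values)


class TestConfig:
    def test_decreasing_schedule_rejected(self):
        with pytest.raises(ValueError):
            rg.RegistrationConfig(resolution_schedule=((8, 8, 8), (6, 6, 6)))

    def test_bins_and_fraction_validated(self):
        with pytest.raises(ValueError):
            rg.RegistrationConfig(mi_bins=4)
        with pytest.raises(ValueError):
            rg.RegistrationConfig(sample_fraction=0.0)


class TestRigidRegister:
    def test_constant_image_raises_metric_error(self, textured_phantom, fast_config):
        spec, vol, _, _ = textured_phantom
        flat = VolumeImage(spec.geometry, np.zeros(spec.geometry.dims))
        with pytest.raises(rg.MetricError):
            rg.rigid_register(vol, flat, fast_config)

    def test_self_registration_near_identity(self, textured_phantom, fast_config):
        spec, vol, _, _ = textured_phantom
        rigid = rg.rigid_register(vol, vol, fast_config)
        assert np.linalg.norm(rigid.translation) < 0.5 * min(spec.geometry.spacing)
        assert np.max(np.abs(rigid.euler_angles)) < np.deg2rad(1.0)

    def test_known_translation_recovered(self, textured_phantom, fast_config):
        spec, vol, _, _ = textured_phantom
        # shift by 2 voxels = 8 mm along x: target(x) = vol(x - s)
        target = integer_shift(vol, (2, 0, 0))
        rigid = rg.rigid_register(vol, target, fast_config)
        # g maps target frame -> reference frame, so g(x) = x - s
        assert np.abs(rigid.translation[0] - (-8.0)) < 1.0
        assert np.abs(rigid.translation[1]) < 1.0 and np.abs(rigid.translation[2]) < 1.0

    def test_recovery_invariant_to_monotone_intensity_remap(
        self, textured_phantom, fast_config
    ):
        spec, vol, _, _ = textured_phantom
        shifted = integer_shift(vol, (2, 0, 0))
        # simulate contrast difference with a monotone nonlinear remap
        remapped = VolumeImage(
            spec.geometry, 120.0 * np.tanh(shifted.values / 400.0) + 30.0
        )
        rigid = rg.rigid_register(vol, remapped, fast_config)
        assert np.abs(rigid.translation[0] - (-8.0)) < 1.0

    def test_deterministic_given_seed(self, textured_phantom, fast_config):
        spec, vol, _, _ = textured_phantom
        target = integer_shift(vol, (1, 1, 0))
        a = rg.rigid_register(vol, target, fast_config)
        b = rg.rigid_register(vol, target, fast_config)
        assert np.array_equal(a.translation, b.translation)
        assert np.array_equal(a.euler_angles, b.euler_angles)


class TestLandmarkInitialization:
    def test_empty_landmarks_is_noop(self, small_geometry):
        grid = ffd.build_control_grid((5, 5, 4), small_geometry)
        grid.coefficients = np.random.default_rng(0).normal(size=grid.coefficients.shape)
        out = rg.initialize_deformation_from_landmarks(
            grid, LandmarkPairs(np.empty((0, 3)), np.empty((0, 3))), 10.0
        )
        assert np.allclose(out.coefficients, grid.coefficients)

    def test_single_landmark_at_control_point(self, small_geometry):
        grid = ffd.build_control_grid((5, 5, 4), small_geometry)
        lam = grid.interior_positions()[17]
        lm = LandmarkPairs(lam[None], np.array([[3.0, 0.0, 0.0]]))
        out = rg.initialize_deformation_from_landmarks(grid, lm, proximity_radius=1.0)
        got = ffd.evaluate_deformation(lam, out)
        assert np.allclose(got, [3.0, 0.0, 0.0], atol=1e-8)
        # a lattice point far from the landmark keeps its (zero) value
        far = grid.interior_positions()[0]
        assert np.linalg.norm(far - lam) > 2.0
        assert np.allclose(ffd.evaluate_deformation(far, out), 0.0, atol=1e-8)

    def test_matches_brute_force_nearest_neighbor(self, small_geometry):
        rng = np.random.default_rng(5)
        grid = ffd.build_control_grid((5, 5, 4), small_geometry)
        grid.coefficients = rng.normal(size=grid.coefficients.shape)
        pts = rng.uniform(0, 40, size=(50, 3))
        zeta = rng.normal(size=(50, 3))
        radius = 9.0
        out = rg.initialize_deformation_from_landmarks(
            grid, LandmarkPairs(pts, zeta), radius
        )
        lattice = np.stack(
            np.meshgrid(*grid.lattice_positions(), indexing="ij"), axis=-1
        ).reshape(-1, 3)
        expected = ffd.grid_values(grid).reshape(-1, 3)
        for i, lam in enumerate(lattice):
            d = np.linalg.norm(pts - lam, axis=1)
            if d.min() <= radius:
                expected[i] = zeta[np.argmin(d)]
        got = ffd.grid_values(out).reshape(-1, 3)
        assert np.abs(got - expected).max() < 1e-7


class TestDeformableRegister:
    def test_self_registration_small_field(self, textured_phantom, fast_config):
        spec, vol, _, _ = textured_phantom
        init = ffd.TransformParameters.identity(
            ffd.build_control_grid((5, 5, 4), spec.geometry),
            rg.volume_center(spec.geometry),
        )
        res = rg.deformable_register(vol, vol, init=init, config=fast_config)
        disp = rg.dense_transform_displacement(res.params, spec.geometry)
        mags = np.linalg.norm(disp, axis=-1)
        assert mags.mean() < 0.5 * min(spec.geometry.spacing)
        assert res.converged

    def test_landmarks_required_when_enabled(self, textured_phantom):
        spec, vol, _, _ = textured_phantom
        cfg = rg.RegistrationConfig(use_landmarks=True)
        with pytest.raises(ValueError, match="landmark"):
            rg.deformable_register(vol, vol, config=cfg)

    def test_deterministic_given_seed(self, textured_phantom, fast_config):
        spec, vol, _, _ = textured_phantom
        target = integer_shift(vol, (1, 0, 0))
        init = ffd.TransformParameters.identity(
            ffd.build_control_grid((5, 5, 4), spec.geometry),
            rg.volume_center(spec.geometry),
        )
        a = rg.deformable_register(vol, target, init=init, config=fast_config)
        b = rg.deformable_register(vol, target, init=init, config=fast_config)
        assert np.array_equal(a.params.grid.coefficients, b.params.grid.coefficients)

    def test_known_warp_recovery_under_one_voxel(self, textured_phantom):
        spec, _, _, _ = textured_phantom
        cs = ph.CohortSpec(
            base=spec, n_subjects=2, jitter_mm=0, jitter_scale=0,
            warp_amplitude_mm=5.0, seed=7,
        )
        b = ph.generate_cohort(cs)[1]
        cfg = rg.RegistrationConfig(
            resolution_schedule=((5, 5, 4), (8, 8, 6)),
            iterations_per_level=30,
            sample_fraction=0.2,
            shrink_factors=(2, 1),
            smoothing_sigmas=(1.0, 0.0),
        )
        init = ffd.TransformParameters.identity(
            ffd.build_control_grid((5, 5, 4), spec.geometry),
            rg.volume_center(spec.geometry),
        )
        res = rg.deformable_register(b.prewarp_volume, b.volume, init=init, config=cfg)
        disp = rg.dense_transform_displacement(res.params, spec.geometry)
        true = ph.dense_displacement(b.warp, spec.geometry)
        body = b.volume.values > -500
        err = np.linalg.norm(disp - true, axis=-1)[body].mean()
        assert err < float(np.mean(spec.geometry.spacing))  # < 1 voxel


class TestProjectRegion:
    def test_identity_transform_is_identity(self, textured_phantom):
        spec, _, _, nodal = textured_phantom
        grid = ffd.build_control_grid((5, 5, 4), spec.geometry)
        params = ffd.TransformParameters.identity(grid, rg.volume_center(spec.geometry))
        out = rg.project_region(nodal, params, spec.geometry)
        assert np.array_equal(out.labels, nodal.labels)

    def test_integer_voxel_translation_shifts_labels(self, textured_phantom):
        spec, _, _, nodal = textured_phantom
        grid = ffd.build_control_grid((5, 5, 4), spec.geometry)
        # g(x) = x + (8, 0, 0) mm = 2 voxels along x
        params = ffd.TransformParameters(
            ffd.RigidParameters(translation=(8.0, 0.0, 0.0)), grid
        )
        out = rg.project_region(nodal, params, spec.geometry)
        expected = np.zeros_like(nodal.labels)
        expected[:-2] = nodal.labels[2:]
        assert np.array_equal(out.labels, expected)

    def test_voxels_mapping_outside_become_background(self, textured_phantom):
        spec, _, _, nodal = textured_phantom
        grid = ffd.build_control_grid((5, 5, 4), spec.geometry)
        params = ffd.TransformParameters(
            ffd.RigidParameters(translation=(10_000.0, 0.0, 0.0)), grid
        )
        out = rg.project_region(nodal, params, spec.geometry)
        assert not out.labels.any()
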