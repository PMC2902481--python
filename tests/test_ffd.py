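"""Free-form deformation transform model: B-spline evaluation, fitting, rigid part."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lymphatlas import ffd
from lymphatlas.spatial import VolumeGeometry


def cubic_bspline(u: np.ndarray) -> np.ndarray:
    """Cardinal cubic B-spline basis (support |u| < 2)."""
    u = np.abs(u)
    out = np.zeros_like(u)
    m1 = u < 1
    m2 = (u >= 1) & (u < 2)
    out[m1] = (4 - 6 * u[m1] ** 2 + 3 * u[m1] ** 3) / 6
    out[m2] = (2 - u[m2]) ** 3 / 6
    return out


def brute_force_field(points: np.ndarray, grid: ffd.ControlGrid) -> np.ndarray:
    """Full tensor-product summation over every (mirror-extended) control point."""
    res = np.asarray(grid.resolution)
    n = res + 3
    pad = 4
    out = np.zeros((len(points), 3))
    coeffs = np.pad(grid.coefficients, [(pad, pad)] * 3 + [(0, 0)], mode="reflect")
    for p_i, x in enumerate(points):
        u = (np.asarray(x) - grid.origin) / grid.spacing + 1.0  # lattice coords
        acc = np.zeros(3)
        for i in range(n[0] + 2 * pad):
            wi = cubic_bspline(np.array([u[0] - (i - pad)]))[0]
            if wi == 0:
                continue
            for j in range(n[1] + 2 * pad):
                wj = cubic_bspline(np.array([u[1] - (j - pad)]))[0]
                if wj == 0:
                    continue
                for k in range(n[2] + 2 * pad):
                    wk = cubic_bspline(np.array([u[2] - (k - pad)]))[0]
                    if wk:
                        acc += wi * wj * wk * coeffs[i, j, k]
        out[p_i] = acc
    return out


@pytest.fixture(scope="module")
def geometry():
    return VolumeGeometry((60, 60, 60))


@pytest.fixture(scope="module")
def random_grid(geometry):
    grid = ffd.build_control_grid((6, 6, 6), geometry)
    rng = np.random.default_rng(42)
    grid.coefficients = rng.normal(size=grid.coefficients.shape)
    return grid


class TestControlGrid:
    def test_printed_resolution_gives_expected_count_and_spacing(self):
        geom = VolumeGeometry((150, 150, 110))
        grid = ffd.build_control_grid((15, 15, 11), geom)
        assert grid.n_interior == 2475
        assert np.allclose(grid.spacing, (10.0, 10.0, 10.0))

    def test_resolution_below_cubic_support_rejected(self, geometry):
        with pytest.raises(ffd.ConfigurationError):
            ffd.build_control_grid((3, 4, 4), geometry)

    def test_parameter_vector_length(self, random_grid):
        params = ffd.TransformParameters.identity(random_grid)
        assert params.n_parameters == 6 + 3 * 6**3


class TestEvaluateDeformation:
    def test_zero_field(self, geometry):
        grid = ffd.build_control_grid((6, 6, 6), geometry)
        pts = np.random.default_rng(0).uniform(0, 60, (20, 3))
        assert np.allclose(ffd.evaluate_deformation(pts, grid), 0.0)

    def test_partition_of_unity(self, geometry):
        grid = ffd.build_control_grid((6, 6, 6), geometry)
        grid.coefficients[:] = np.array([1.5, -2.0, 0.25])
        pts = np.random.default_rng(1).uniform(0, 60, (200, 3))
        assert np.allclose(
            ffd.evaluate_deformation(pts, grid), [1.5, -2.0, 0.25], atol=1e-12
        )

    def test_matches_full_tensor_product_summation(self, random_grid):
        pts = np.random.default_rng(2).uniform(0, 60, (25, 3))
        fast = ffd.evaluate_deformation(pts, random_grid)
        slow = brute_force_field(pts, random_grid)
        assert np.abs(fast - slow).max() < 1e-10

    def test_outside_support_raises(self, random_grid):
        with pytest.raises(ffd.OutOfDomainError):
            ffd.evaluate_deformation(np.array([120.0, 30.0, 30.0]), random_grid)

    def test_locality_of_single_control_point(self, geometry):
        grid = ffd.build_control_grid((8, 8, 8), geometry)
        grid.coefficients[4, 4, 4] = np.array([1.0, 0.0, 0.0])
        # lattice index 4 = interior point 3 at 3*7.5 mm; support radius 2 cells
        center = grid.origin + 3 * grid.spacing
        far = center + 2.5 * grid.spacing
        assert np.allclose(ffd.evaluate_deformation(far, grid), 0.0, atol=1e-12)
        near = center + 0.5 * grid.spacing
        assert np.abs(ffd.evaluate_deformation(near, grid)).max() > 0


class TestRigid:
    def test_identity_and_pure_translation(self, random_grid, geometry):
        zero = ffd.build_control_grid((6, 6, 6), geometry)
        params = ffd.TransformParameters(ffd.RigidParameters(), zero)
        x = np.array([10.0, 20.0, 30.0])
        assert np.allclose(ffd.transform_point(x, params), x)
        params = ffd.TransformParameters(
            ffd.RigidParameters(translation=(5.0, 0.0, 0.0)), zero
        )
        assert np.allclose(ffd.transform_point(x, params), x + [5, 0, 0])

    def test_quarter_turn_about_z(self, geometry):
        zero = ffd.build_control_grid((6, 6, 6), geometry)
        c = (30.0, 30.0, 30.0)
        params = ffd.TransformParameters(
            ffd.RigidParameters(euler_angles=(np.pi / 2, 0, 0), center=c), zero
        )
        x = np.array(c) + [1.0, 0.0, 0.0]
        assert np.allclose(ffd.transform_point(x, params), np.array(c) + [0, 1, 0], atol=1e-12)

    def test_rotation_matrix_orthonormal(self):
        rp = ffd.RigidParameters(euler_angles=(0.3, -0.2, 0.7))
        R = rp.rotation_matrix()
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_matrix_round_trip(self):
        rp = ffd.RigidParameters((0.2, 0.1, -0.4), (3.0, -1.0, 2.0), (5.0, 5.0, 5.0))
        back = ffd.RigidParameters.from_matrix(
            rp.rotation_matrix(), rp.translation, rp.center
        )
        assert np.allclose(back.euler_angles, rp.euler_angles)


class TestFitAndRefine:
    def test_fit_zero_and_constant(self, geometry):
        grid = ffd.build_control_grid((6, 6, 6), geometry)
        shape = grid.coefficients.shape
        fitted = ffd.fit_coefficients_from_values(np.zeros(shape), grid)
        assert np.allclose(fitted.coefficients, 0.0)
        const = np.broadcast_to([2.0, 0.0, -1.0], shape).copy()
        fitted = ffd.fit_coefficients_from_values(const, grid)
        pts = np.random.default_rng(3).uniform(0, 60, (50, 3))
        assert np.allclose(
            ffd.evaluate_deformation(pts, fitted), [2.0, 0.0, -1.0], atol=1e-8
        )

    def test_fit_interpolates_random_values(self, geometry):
        grid = ffd.build_control_grid((6, 6, 6), geometry)
        values = np.random.default_rng(4).normal(size=grid.coefficients.shape)
        fitted = ffd.fit_coefficients_from_values(values, grid)
        assert np.abs(ffd.grid_values(fitted) - values).max() < 1e-8

    def test_refine_preserves_zero_and_constant(self, geometry):
        grid = ffd.build_control_grid((5, 5, 5), geometry)
        fine = ffd.refine_grid(grid, (9, 9, 9))
        assert np.allclose(fine.coefficients, 0.0)
        grid.coefficients[:] = np.array([1.0, 2.0, 3.0])
        fine = ffd.refine_grid(grid, (9, 9, 9))
        pts = np.random.default_rng(5).uniform(1, 59, (100, 3))
        assert np.allclose(
            ffd.evaluate_deformation(pts, fine), [1.0, 2.0, 3.0], atol=1e-8
        )

    def test_refine_reproduces_random_field(self, geometry):
        # interior discrepancy frozen from the full-summation oracle: the
        # coarse spline is not exactly representable on non-nested knots,
        # leaving a few-percent residual (largest near the extent's edges)
        grid = ffd.build_control_grid((5, 5, 5), geometry)
        rng = np.random.default_rng(0)
        grid.coefficients = rng.normal(size=grid.coefficients.shape)
        fine = ffd.refine_grid(grid, (9, 9, 9))
        pts = rng.uniform(6, 54, (200, 3))
        err = np.abs(
            ffd.evaluate_deformation(pts, fine) - ffd.evaluate_deformation(pts, grid)
        ).max()
        rms = float(np.sqrt((grid.coefficients**2).mean()))
        assert err < 0.05 * rms

    def test_refine_below_coarse_resolution_rejected(self, geometry):
        grid = ffd.build_control_grid((6, 6, 6), geometry)
        with pytest.raises(ffd.ConfigurationError):
            ffd.refine_grid(grid, (5, 6, 6))


class TestSerialization:
    def test_transform_round_trip(self, tmp_path, random_grid):
        params = ffd.TransformParameters(
            ffd.RigidParameters((0.1, 0.2, 0.3), (1, 2, 3), (30, 30, 30)), random_grid
        )
        path = tmp_path / "transform.json"
        params.save(path)
        back = ffd.TransformParameters.load(path)
        assert np.allclose(back.rigid.euler_angles, params.rigid.euler_angles)
        assert np.allclose(back.grid.coefficients, params.grid.coefficients)
        x = np.array([12.0, 34.0, 25.0])
        assert np.allclose(
            ffd.transform_point(x, back), ffd.transform_point(x, params)
        )


@settings(max_examples=20, deadline=None)
@given(
    cx=st.floats(-1.0, 1.0), cy=st.floats(-1.0, 1.0), cz=st.floats(-1.0, 1.0),
)
def test_property_constant_coefficients_give_constant_field(cx, cy, cz):
    """Partition of unity holds for arbitrary constant coefficient vectors."""
    geom = VolumeGeometry((40, 40, 40))
    grid = ffd.build_control_grid((5, 5, 5), geom)
    grid.coefficients[:] = np.array([cx, cy, cz])
    pts = np.random.default_rng(6).uniform(0, 40, (30, 3))
    assert np.allclose(ffd.evaluate_deformation(pts, grid), [cx, cy, cz], atol=1e-10)
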