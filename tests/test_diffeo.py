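"""Oracle tests for the stationary-velocity-field geometry."""

import numpy as np
import pytest
from scipy.linalg import expm

from diffatlas.diffeo import compose, integrate_svf, jacobian_determinant, warp
from diffatlas.grids import ImageGrid, VectorField, identity_grid

from conftest import make_smooth_velocity


def linear_velocity(A, shape, x0):
    """v(x) = A (x - x0) on the given grid."""
    g = identity_grid(shape)
    x0 = np.asarray(x0, dtype=float).reshape(-1, *([1] * len(shape)))
    return VectorField(np.einsum("ij,j...->i...", A, g - x0), "velocity")


class TestIntegrateSVF:
    def test_zero_field_is_exact_identity(self):
        phi = integrate_svf(VectorField(np.zeros((2, 8, 8))), steps=7)
        assert phi.role == "deformation"
        assert np.all(phi.data == 0.0)

    def test_constant_field_translates(self):
        v = np.zeros((2, 16, 16))
        v[0] = 1.25
        v[1] = -0.5
        phi = integrate_svf(VectorField(v), steps=7)
        interior = (slice(None), slice(4, -4), slice(4, -4))
        assert np.allclose(phi.data[interior], v[interior], atol=1e-5)

    @pytest.mark.parametrize(
        "shape,x0",
        [((32, 32), (15.5, 15.5)), ((16, 16, 16), (7.5, 7.5, 7.5))],
        ids=["2d-32", "3d-16"],
    )
    def test_linear_field_matches_matrix_exponential(self, shape, x0):
        """For v(x) = A(x-x0) the flow is x0 + expm(A)(x-x0).

        For linear fields the integrator reduces to (I + A/2^s)^(2^s), whose
        distance to expm(A) scales like |A|^2 / 2^(s+1); nine squarings put
        that discretization error well below the 1e-3 tolerance at |A| = 0.5.
        """
        d = len(shape)
        rng = np.random.default_rng(3)
        A = rng.normal(0.0, 1.0, (d, d))
        A *= 0.5 / np.linalg.norm(A, 2)
        v = linear_velocity(A, shape, x0)
        phi = integrate_svf(v, steps=9)
        g = identity_grid(shape)
        x0a = np.asarray(x0).reshape(-1, *([1] * d))
        target = np.einsum("ij,j...->i...", expm(A), g - x0a) + x0a - g
        m = shape[0] // 4 + 2
        interior = (slice(None),) + (slice(m, -m),) * d
        err = np.abs(phi.data[interior] - target[interior]).max()
        assert err / (np.abs(target[interior]).max() + 1e-12) < 1e-3

    def test_squaring_steps_converge(self):
        """More scaling-and-squaring steps give a closer match to expm."""
        shape = (32, 32)
        A = np.array([[0.25, -0.2], [0.15, 0.2]])
        v = linear_velocity(A, shape, (15.5, 15.5))
        g = identity_grid(shape)
        x0 = np.array([15.5, 15.5]).reshape(2, 1, 1)
        target = np.einsum("ij,j...->i...", expm(A), g - x0) + x0 - g
        interior = (slice(None), slice(8, -8), slice(8, -8))
        errs = {
            s: np.abs(integrate_svf(v, steps=s).data[interior] - target[interior]).max()
            for s in (3, 7)
        }
        assert errs[7] < errs[3]

    def test_rejects_bad_input(self):
        v = np.zeros((2, 8, 8))
        with pytest.raises(ValueError):
            integrate_svf(VectorField(v), steps=0)
        bad = VectorField(v.copy())
        bad.data[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            integrate_svf(bad)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_inverse_consistency(self, seed):
        """phi(v) o phi(-v) stays within 0.1 voxel of identity (interior)."""
        v = make_smooth_velocity((32, 32), 2.0, seed=seed)
        fwd = integrate_svf(v)
        bwd = integrate_svf(VectorField(-v.data, "velocity"))
        residual = compose(fwd, bwd)
        assert np.abs(residual.data[:, 4:-4, 4:-4]).max() < 0.1

    def test_smooth_fields_stay_diffeomorphic(self, smooth_velocity_2d):
        det = jacobian_determinant(integrate_svf(smooth_velocity_2d))
        assert det.data[1:-1, 1:-1].min() > 0


class TestWarp:
    def test_identity_leaves_image_unchanged(self):
        rng = np.random.default_rng(0)
        img = ImageGrid(rng.uniform(0, 1, (12, 12)))
        phi = VectorField(np.zeros((2, 12, 12)), "deformation")
        out = warp(img, phi)
        assert np.allclose(out.data, img.data)

    def test_integer_translation_shifts_lattice(self):
        rng = np.random.default_rng(1)
        img = ImageGrid(rng.uniform(0, 1, (10, 10)))
        u = np.zeros((2, 10, 10))
        u[0] = 1.0
        out = warp(img, VectorField(u, "deformation"))
        assert np.allclose(out.data[:-1, :], img.data[1:, :], atol=1e-12)

    def test_half_voxel_shift_on_ramp(self):
        """Linear interpolation of a coordinate ramp shifts values by 0.5."""
        ramp = ImageGrid(identity_grid((12, 12))[0])
        u = np.zeros((2, 12, 12))
        u[0] = 0.5
        out = warp(ramp, VectorField(u, "deformation"))
        assert np.allclose(out.data[:-1, :], ramp.data[:-1, :] + 0.5, atol=1e-12)

    def test_nearest_mode_preserves_labels(self):
        labels = ImageGrid(np.arange(64.0).reshape(8, 8) % 5)
        u = np.full((2, 8, 8), 0.3)
        out = warp(labels, VectorField(u, "deformation"), mode="nearest")
        assert set(np.unique(out.data)) <= set(np.unique(labels.data))

    def test_linearity_in_intensities(self, smooth_velocity_2d):
        rng = np.random.default_rng(5)
        phi = integrate_svf(smooth_velocity_2d)
        i1 = ImageGrid(rng.uniform(0, 1, (32, 32)))
        i2 = ImageGrid(rng.uniform(0, 1, (32, 32)))
        a, b = 0.7, -1.3
        lhs = warp(ImageGrid(a * i1.data + b * i2.data), phi).data
        rhs = a * warp(i1, phi).data + b * warp(i2, phi).data
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_grid_mismatch_rejected(self):
        img = ImageGrid(np.zeros((8, 8)))
        phi = VectorField(np.zeros((2, 10, 10)), "deformation")
        with pytest.raises(ValueError):
            warp(img, phi)


class TestCompose:
    def test_identity_neutral(self, smooth_velocity_2d):
        phi = integrate_svf(smooth_velocity_2d)
        ident = VectorField(np.zeros_like(phi.data), "deformation")
        assert np.allclose(compose(phi, ident).data, phi.data, atol=1e-6)
        inner = compose(ident, phi)
        assert np.allclose(inner.data[:, 3:-3, 3:-3], phi.data[:, 3:-3, 3:-3], atol=1e-6)

    def test_translations_add(self):
        a = np.zeros((2, 16, 16))
        a[0] = 0.75
        b = np.zeros((2, 16, 16))
        b[1] = -0.5
        out = compose(
            VectorField(a, "deformation"), VectorField(b, "deformation")
        )
        interior = (slice(None), slice(2, -2), slice(2, -2))
        assert np.allclose(out.data[interior], (a + b)[interior], atol=1e-12)


class TestJacobianDeterminant:
    def test_identity_is_one_everywhere(self):
        phi = VectorField(np.zeros((2, 9, 9)), "deformation")
        det = jacobian_determinant(phi)
        assert np.allclose(det.data, 1.0)

    @pytest.mark.parametrize("s,d", [(1.1, 2), (0.9, 3)])
    def test_uniform_scaling(self, s, d):
        shape = (11,) * d
        g = identity_grid(shape)
        centre = (np.array(shape) - 1) / 2.0
        u = (s - 1.0) * (g - centre.reshape(-1, *([1] * d)))
        det = jacobian_determinant(VectorField(u, "deformation"))
        interior = (slice(1, -1),) * d
        assert np.allclose(det.data[interior], s**d, atol=1e-6)

    def test_matches_brute_force_oracle(self, smooth_velocity_2d):
        """Central-difference dets agree with an explicit per-voxel oracle."""
        phi = integrate_svf(smooth_velocity_2d)
        det = jacobian_determinant(phi).data
        u = phi.data
        h, w = u.shape[1:]
        for (i, j) in [(5, 9), (16, 16), (25, 4)]:
            J = np.eye(2)
            for a in range(2):
                J[a, 0] += (u[a, i + 1, j] - u[a, i - 1, j]) / 2.0
                J[a, 1] += (u[a, i, j + 1] - u[a, i, j - 1]) / 2.0
            assert abs(det[i, j] - np.linalg.det(J)) < 1e-10

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            jacobian_determinant(VectorField(np.zeros((2, 2, 8)), "deformation"))
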