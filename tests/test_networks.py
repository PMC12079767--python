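"""Network-stage contracts: shapes, determinism, zero-velocity start."""

import numpy as np
import pytest

from diffatlas.autodiff import Tensor, concat
from diffatlas.grids import ImageGrid
from diffatlas.meantrack import BinTracker
from diffatlas.networks import (
    Stage1Config,
    Stage1Net,
    Stage2Config,
    Stage2Net,
    build_templates,
)
from diffatlas.phantoms import PhantomSpec, build_group_template
from diffatlas.spatial import (
    bending_energy_t,
    displacement_magnitude_t,
    integrate_velocity,
    mse,
    warp_image,
)


@pytest.fixture
def stage1():
    return Stage1Net(Stage1Config(grid_shape=(32, 32)), np.random.default_rng(0))


@pytest.fixture
def stage2():
    return Stage2Net(Stage2Config(grid_shape=(32, 32)), np.random.default_rng(1))


class TestStage1:
    def test_deterministic_mode_is_reproducible(self, stage1):
        a = stage1(np.array([[70.0]]), sample=False)
        b = stage1(np.array([[70.0]]), sample=False)
        assert np.array_equal(a.data, b.data)

    def test_sampling_seed_contract(self, stage1):
        # perturb the zero-initialized head so latent noise reaches the output
        stage1.head.weight.data += np.float32(0.01)
        a = stage1(np.array([[70.0]]), sample=True, rng=np.random.default_rng(5))
        b = stage1(np.array([[70.0]]), sample=True, rng=np.random.default_rng(5))
        c = stage1(np.array([[70.0]]), sample=True, rng=np.random.default_rng(6))
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_output_shape_and_finiteness(self, stage1):
        v = stage1(np.array([[55.0], [88.0]]), sample=False)
        # native velocity grid is half the image resolution
        assert v.shape == (2, 2, 16, 16)
        assert np.all(np.isfinite(v.data))

    def test_zero_initialized_head_gives_zero_velocity(self, stage1):
        v = stage1(np.array([[62.0]]), sample=False)
        assert np.allclose(v.data, 0.0)

    def test_covariate_normalization_clips_to_bounds(self, stage1):
        lo = stage1.normalize(np.array([[10.0]]))
        hi = stage1.normalize(np.array([[200.0]]))
        assert lo[0, 0] == -1.0 and hi[0, 0] == 1.0
        with pytest.raises(ValueError):
            stage1.normalize(np.array([[np.nan]]))


class TestStage2:
    def test_determinism_and_shape(self, stage2):
        rng = np.random.default_rng(2)
        x = Tensor(rng.uniform(0, 1, (3, 2, 32, 32)).astype(np.float32))
        a = stage2(x)
        b = stage2(x)
        assert np.array_equal(a.data, b.data)
        assert a.shape == (3, 2, 16, 16)  # (B, vector-dim, h, w) at velocity resolution

    def test_zero_initialized_head(self, stage2):
        x = Tensor(np.random.default_rng(3).uniform(0, 1, (1, 2, 32, 32)).astype(np.float32))
        assert np.allclose(stage2(x).data, 0.0)

    def test_channel_mismatch_rejected(self, stage2):
        with pytest.raises(ValueError):
            stage2(Tensor(np.zeros((1, 3, 32, 32), dtype=np.float32)))


class TestSpatialAgreesWithNumpyRoute:
    """The differentiable spatial ops must match the numpy geometry."""

    def test_integration_matches_diffeo_core(self):
        from diffatlas.diffeo import integrate_svf
        from diffatlas.grids import VectorField
        from conftest import make_smooth_velocity

        v = make_smooth_velocity((32, 32), 1.5, seed=9)
        u_np = integrate_svf(v, steps=7).data
        u_t = integrate_velocity(Tensor(v.data[None].astype(np.float64)), steps=7).data[0]
        assert np.abs(u_np - u_t).max() < 1e-6

    def test_warp_matches_diffeo_core(self):
        from diffatlas.diffeo import integrate_svf, warp
        from conftest import make_smooth_velocity

        rng = np.random.default_rng(10)
        img = ImageGrid(rng.uniform(0, 1, (32, 32)))
        v = make_smooth_velocity((32, 32), 1.5, seed=11)
        phi = integrate_svf(v, steps=7)
        out_np = warp(img, phi).data
        out_t = warp_image(
            Tensor(img.data[None, None]), Tensor(phi.data[None].astype(np.float64))
        ).data[0, 0]
        assert np.abs(out_np - out_t).max() < 1e-10

    def test_loss_terms_match_numpy_losses(self):
        from diffatlas.grids import VectorField
        from diffatlas.losses import bending_energy, displacement_magnitude, recon_mse

        rng = np.random.default_rng(12)
        u = rng.normal(0, 1, (2, 16, 16))
        assert bending_energy_t(Tensor(u[None])).data == pytest.approx(
            bending_energy(VectorField(u, "deformation")), rel=1e-10
        )
        assert displacement_magnitude_t(Tensor(u[None])).data == pytest.approx(
            displacement_magnitude(VectorField(u, "deformation")), rel=1e-10
        )
        a, b = rng.uniform(0, 1, (2, 16, 16))
        assert mse(Tensor(a[None, None]), Tensor(b[None, None])).data == pytest.approx(
            recon_mse(ImageGrid(a), ImageGrid(b)), rel=1e-10
        )


class TestBuildTemplates:
    def test_untrained_model_reproduces_group_template(self, monkeypatch):
        spec = PhantomSpec(shape=(32, 32))
        template = build_group_template(spec)
        stage1 = Stage1Net(Stage1Config(grid_shape=(32, 32)), np.random.default_rng(4))
        entries = build_templates(stage1, None, [55.0, 75.0], template)
        for e in entries:
            assert np.allclose(e["template"].data, template.data, atol=1e-6)
            assert np.allclose(e["phi"].data, 0.0)

    def test_zero_tracked_means_make_adjusted_equal_plain(self):
        spec = PhantomSpec(shape=(32, 32))
        template = build_group_template(spec)
        stage1 = Stage1Net(Stage1Config(grid_shape=(32, 32)), np.random.default_rng(4))
        tracker = BinTracker([50.0, 70.0, 90.0], (2, 16, 16))
        entries = build_templates(stage1, tracker, [60.0], template)
        e = entries[0]
        assert np.allclose(e["template"].data, e["template_adj"].data)
        assert np.allclose(e["phi"].data, e["phi_adj"].data)

    def test_nonzero_mean_changes_adjusted_template(self):
        spec = PhantomSpec(shape=(32, 32))
        template = build_group_template(spec)
        stage1 = Stage1Net(Stage1Config(grid_shape=(32, 32)), np.random.default_rng(4))
        tracker = BinTracker([50.0, 70.0, 90.0], (2, 16, 16))
        tracker.means[1, 0] = 0.75  # half-voxel (native grid) mean shift at 70y
        e = build_templates(stage1, tracker, [70.0], template)[0]
        assert not np.allclose(e["template"].data, e["template_adj"].data)
        assert np.abs(e["phi_adj"].data).max() > 1.0  # 0.75 native voxels = 1.5 full-grid
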