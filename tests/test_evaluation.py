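"""Evaluation metrics: Jacobian reports, SSIM, RMSD, Dice, volume trends."""

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter

from diffatlas.diffeo import integrate_svf
from diffatlas.evaluation import (
    binned_reference_volumes,
    dice,
    jacobian_report,
    normalized_volumes,
    rmsd,
    ssim,
    trend_recovery,
)
from diffatlas.grids import ImageGrid, VectorField, identity_grid

from conftest import make_smooth_velocity


class TestJacobianReport:
    def test_identity_fields(self):
        phis = [VectorField(np.zeros((2, 8, 8)), "deformation") for _ in range(3)]
        per_field, pooled = jacobian_report(phis)
        assert pooled.min == pooled.max == 1.0
        assert pooled.nonpos_count == 0
        assert len(per_field) == 3

    def test_uniform_scaling_det(self):
        g = identity_grid((12, 12))
        centre = 5.5
        u = 0.1 * (g - centre)  # scaling by 1.1
        _, pooled = jacobian_report([VectorField(u, "deformation")])
        interior_val = 1.1**2
        assert pooled.mean == pytest.approx(interior_val, rel=1e-6)

    def test_smooth_svf_regime_has_no_folding(self):
        phis = [
            integrate_svf(make_smooth_velocity((32, 32), 2.0, seed=s)) for s in range(4)
        ]
        _, pooled = jacobian_report(phis)
        assert pooled.nonpos_count == 0
        assert pooled.min > 0

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            jacobian_report([])


class TestSSIM:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(0)
        x = ImageGrid(rng.uniform(0, 1, (48, 48)))
        assert ssim(x, x) == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x = ImageGrid(rng.uniform(0, 1, (48, 48)))
        y = ImageGrid(rng.uniform(0, 1, (48, 48)))
        assert abs(ssim(x, y) - ssim(y, x)) < 1e-12

    def test_noise_hurts_more_than_smoothing(self):
        rng = np.random.default_rng(2)
        base = gaussian_filter(rng.uniform(0, 1, (48, 48)), 2.0)
        x = ImageGrid(base)
        noisy = ImageGrid(base + rng.normal(0, base.std(), base.shape))
        smoothed = ImageGrid(gaussian_filter(base, 0.5))
        assert ssim(x, noisy) < ssim(x, smoothed)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ssim(ImageGrid(np.zeros((8, 8))), ImageGrid(np.zeros((9, 9))))


class TestRMSD:
    def test_forced_cases(self):
        rng = np.random.default_rng(3)
        x = ImageGrid(rng.uniform(0, 1, (16, 16)))
        assert rmsd(x, x) == 0.0
        y = ImageGrid(x.data - 0.25)
        assert rmsd(x, y) == pytest.approx(0.25)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 1, (9, 9))
        b = rng.uniform(0, 1, (9, 9))
        expected = np.sqrt(np.mean((a - b) ** 2))
        assert abs(rmsd(ImageGrid(a), ImageGrid(b)) - expected) < 1e-12

    def test_triangle_inequality_spot_check(self):
        rng = np.random.default_rng(5)
        imgs = [ImageGrid(rng.uniform(0, 1, (8, 8))) for _ in range(3)]
        for (i, j, k) in [(0, 1, 2), (1, 2, 0), (2, 0, 1)]:
            assert rmsd(imgs[i], imgs[j]) <= rmsd(imgs[i], imgs[k]) + rmsd(imgs[k], imgs[j]) + 1e-12


class TestDice:
    def test_forced_values(self):
        a = np.zeros((8, 8))
        a[:4] = 1
        b = a.copy()
        full = dice(ImageGrid(a), ImageGrid(b), [1])
        assert full[1] == pytest.approx(1.0)

        b2 = np.zeros((8, 8))
        b2[4:] = 1  # disjoint
        assert dice(ImageGrid(a), ImageGrid(b2), [1])[1] == pytest.approx(0.0)

        # |A| = |B| = 16 with overlap 8 -> 0.5
        a3 = np.zeros((8, 8))
        a3[:2] = 1
        b3 = np.zeros((8, 8))
        b3[1:3] = 1
        assert dice(ImageGrid(a3), ImageGrid(b3), [1])[1] == pytest.approx(0.5)

    def test_absent_label_reported_missing(self):
        z = ImageGrid(np.zeros((4, 4)))
        assert dice(z, z, [7])[7] is None


class TestVolumeTables:
    def test_normalized_volumes_identities(self):
        out = normalized_volumes({50.0: 2.0, 60.0: 4.0, 70.0: 6.0})
        assert np.allclose(sorted(out["vnorm"]), [0.5, 1.0, 1.5])
        rng = np.random.default_rng(6)
        vols = {float(a): float(v) for a, v in zip(range(20), rng.uniform(1, 9, 20))}
        out = normalized_volumes(vols)
        assert out["vnorm"].mean() == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            normalized_volumes({50.0: 1.0, 60.0: 0.0})

    def test_binned_reference_forced_cases(self):
        ages = np.array([50.1, 50.2, 52.5, 52.9])
        vols = np.array([10.0, 10.0, 30.0, 30.0])
        df = binned_reference_volumes(vols, ages, bin_width=2.0)
        filled = df.dropna(subset=["vnorm"])
        assert np.allclose(sorted(filled["vnorm"]), [0.5, 1.5])
        single = binned_reference_volumes(vols, ages, bin_width=10.0)
        assert single["vnorm"].dropna().iloc[0] == pytest.approx(1.0)

    def test_binned_reference_recovers_linear_slope(self):
        """Zero-jitter phantom volumes reproduce the generating line."""
        from diffatlas.phantoms import PhantomSpec, generate_phantom

        spec = PhantomSpec()
        ages = np.arange(50.0, 91.0, 2.0)
        vols = np.array(
            [generate_phantom(spec, a, seed=None)[2]["ventricles"] for a in ages], dtype=float
        )
        df = binned_reference_volumes(vols, ages, bin_width=2.0)
        ok = df.dropna(subset=["vnorm"])
        # generating line, normalized the same way
        line = 1.0 + spec.slopes["ventricles"] * (ok["bin_centre"].to_numpy() - 50.0) / 40.0
        expected = line / line.mean()
        # rasterization granularity: the ~130-voxel ventricles have ~70
        # boundary voxels, so counts can sit a few percent off the line
        assert np.abs(ok["vnorm"].to_numpy() - expected).max() < 0.06


class TestTrendRecovery:
    def _curves(self):
        ages = np.arange(50.0, 91.0, 5.0)
        vnorm = np.linspace(0.8, 1.2, len(ages))
        curve = pd.DataFrame({"alpha": ages, "vnorm": vnorm})
        ref = pd.DataFrame({"bin_centre": ages, "vnorm": vnorm})
        return curve, ref

    def test_identical_curves(self):
        curve, ref = self._curves()
        out = trend_recovery(curve, ref)
        assert out["spearman"] == pytest.approx(1.0)
        assert out["max_abs_gap"] == pytest.approx(0.0)
        assert out["sign_agree"]

    def test_reversed_curve_anticorrelates(self):
        curve, ref = self._curves()
        curve["vnorm"] = curve["vnorm"].to_numpy()[::-1]
        out = trend_recovery(curve, ref)
        assert out["spearman"] == pytest.approx(-1.0)
        assert not out["sign_agree"]

    def test_too_few_points_rejected(self):
        curve, ref = self._curves()
        with pytest.raises(ValueError):
            trend_recovery(curve.iloc[:2], ref)
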