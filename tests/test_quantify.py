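"""Metrics, VOI statistics and quantification-error bookkeeping."""

import numpy as np
import pytest

import mr2pet as m
from mr2pet.quantify import _peak_map


class TestMae:
    def test_zero_at_equality(self, rng):
        y = rng.random((5, 5, 5))
        assert m.mae(y, y) == 0.0

    def test_hand_arithmetic(self):
        assert m.mae(np.array([[[0.0, 2.0]]]), np.array([[[1.0, 1.0]]])) == 1.0

    def test_scales_linearly(self, rng):
        y, yh = rng.random((4, 4, 4)), rng.random((4, 4, 4))
        assert m.mae(2 * y, 2 * yh) == pytest.approx(2 * m.mae(y, yh))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            m.mae(np.zeros((2, 2, 2)), np.zeros((3, 3, 3)))


class TestMrae:
    def test_threshold_excludes_cold_voxels(self):
        y = np.array([[[0.05, 1.0]]])
        yh = np.array([[[9.0, 1.5]]])
        assert m.mrae(y, yh) == pytest.approx(0.5)

    def test_zero_at_equality_above_threshold(self, rng):
        y = rng.random((4, 4, 4)) + 0.2
        assert m.mrae(y, y) == 0.0

    def test_all_below_threshold_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            m.mrae(np.full((3, 3, 3), 0.01), np.zeros((3, 3, 3)))


class TestSSIM3D:
    def test_self_similarity_is_one(self, rng):
        x = rng.random((12, 12, 12))
        assert m.ssim3d(x, x, window_vox=5) == pytest.approx(1.0)

    def test_symmetric(self, rng):
        x = rng.random((12, 12, 12))
        y = x + 0.3 * rng.standard_normal(x.shape)
        assert m.ssim3d(x, y, 5) == pytest.approx(m.ssim3d(y, x, 5))

    def test_monotone_degradation(self, rng):
        x = rng.random((16, 16, 16))
        small = x + 0.05 * rng.standard_normal(x.shape)
        large = x + 1.5 * rng.standard_normal(x.shape)
        assert m.ssim3d(x, large, 5) < m.ssim3d(x, small, 5)

    def test_window_validation(self, rng):
        x = rng.random((8, 8, 8))
        with pytest.raises(ValueError):
            m.ssim3d(x, x, window_vox=4)
        with pytest.raises(ValueError):
            m.ssim3d(x, x, window_vox=9)

    def test_windowed_formula_cross_check(self, rng):
        # independent direct evaluation of the SSIM formula on one window
        x = rng.random((7, 7, 7))
        y = x + 0.2 * rng.standard_normal(x.shape)
        L = float(max(x.max(), y.max()) - min(x.min(), y.min()))
        c1, c2 = (0.01 * L) ** 2, (0.03 * L) ** 2
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        cov = np.mean((x - mx) * (y - my)) * x.size / (x.size - 1)
        expected = ((2 * mx * my + c1) * (2 * cov + c2)
                    / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2)))
        assert m.ssim3d(x, y, window_vox=7, dynamic_range=L) == pytest.approx(
            expected, rel=1e-10)


class TestVOIStats:
    def _uniform_voi(self, value=8.0):
        data = np.zeros((32, 32, 32))
        data[8:24, 8:24, 8:24] = value
        vol = m.Volume3D(data, (2.0,) * 3, "suv")
        mask = np.zeros((32, 32, 32), bool)
        mask[12:20, 12:20, 12:20] = True  # interior of the uniform region
        return vol, m.VOI(mask, "uniform")

    def test_uniform_region_mean_max_peak_coincide(self):
        vol, voi = self._uniform_voi()
        stats = m.voi_stats(vol, voi)
        assert stats["mean"] == stats["max"] == 8.0
        assert stats["peak"] == pytest.approx(8.0)

    def test_single_hot_voxel_orders_max_peak_mean(self):
        data = np.zeros((24, 24, 24))
        data[12, 12, 12] = 10.0
        vol = m.Volume3D(data, (2.0,) * 3, "suv")
        mask = np.zeros((24, 24, 24), bool)
        mask[10:15, 10:15, 10:15] = True
        stats = m.voi_stats(vol, m.VOI(mask, "hot"))
        assert stats["max"] == 10.0
        assert stats["max"] > stats["peak"] > stats["mean"]

    def test_mean_max_ignore_outside_voxels(self, rng):
        vol, voi = self._uniform_voi()
        other = vol.with_data(vol.data + 50.0 * ~voi.mask)
        a, b = m.voi_stats(vol, voi), m.voi_stats(other, voi)
        assert a["mean"] == b["mean"] and a["max"] == b["max"]

    def test_peak_neighbourhood_has_unit_cm3(self):
        # kernel volume within 5% of 1 cm^3 on a 1 mm grid
        vol = m.Volume3D(np.ones((32, 32, 32)), (1.0,) * 3, "suv")
        peak = _peak_map(vol)
        assert peak[16, 16, 16] == pytest.approx(1.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            m.VOI(np.zeros((4, 4, 4), bool), "empty")


class TestQuantErrors:
    def _vols(self, a, b):
        va = m.Volume3D(np.full((16, 16, 16), float(a)), (2.0,) * 3, "suv")
        vb = m.Volume3D(np.full((16, 16, 16), float(b)), (2.0,) * 3, "suv")
        return va, vb

    def _voi(self):
        mask = np.zeros((16, 16, 16), bool)
        mask[4:12, 4:12, 4:12] = True
        return m.VOI(mask, "lesion")

    def test_identical_recons_give_zero_delta(self, rng):
        data = rng.random((16, 16, 16))
        v = m.Volume3D(data, (2.0,) * 3, "suv")
        rep = m.quant_errors(v, v.copy(), [self._voi()])
        assert np.all(rep.table.delta == 0.0)

    def test_delta_symmetry(self):
        va, vb = self._vols(3.0, 2.0)
        voi = self._voi()
        r1 = m.quant_errors(va, vb, [voi])
        r2 = m.quant_errors(vb, va, [voi])
        assert np.allclose(r1.table.delta, r2.table.delta)

    def test_hand_arithmetic_delta_dev_and_gamma(self):
        # delta_true 0.5, delta 0.4 -> delta_dev 0.1, gamma 20%
        va, vb = self._vols(1.0, 0.6)
        voi = self._voi()
        rep = m.quant_errors(va, vb, [voi],
                             ref_delta={("lesion", s): 0.5 for s in ("mean", "max", "peak")},
                             source="test")
        assert rep.lookup("test", "lesion", "mean") == pytest.approx(0.4)
        assert rep.lookup("test", "lesion", "mean", "delta_dev") == pytest.approx(0.1)
        assert rep.lookup("test", "lesion", "mean", "gamma_pct") == pytest.approx(20.0)

    def test_matching_delta_gives_zero_deviation(self):
        va, vb = self._vols(1.0, 0.5)
        voi = self._voi()
        rep = m.quant_errors(va, vb, [voi],
                             ref_delta={("lesion", s): 0.5 for s in ("mean", "max", "peak")})
        assert rep.lookup("source", "lesion", "mean", "delta_dev") == 0.0
        assert rep.lookup("source", "lesion", "mean", "gamma_pct") == 0.0

    def test_zero_reference_reports_undefined_gamma(self):
        va, vb = self._vols(1.0, 0.6)
        rep = m.quant_errors(va, vb, [self._voi()],
                             ref_delta={("lesion", s): 0.0 for s in ("mean", "max", "peak")})
        assert np.isnan(rep.lookup("source", "lesion", "mean", "gamma_pct"))
        assert rep.lookup("source", "lesion", "mean", "delta_dev") == pytest.approx(0.4)

    def test_background_gets_no_relative_error(self):
        va, vb = self._vols(1.0, 0.6)
        mask = np.zeros((16, 16, 16), bool)
        mask[2:6, 2:6, 2:6] = True
        voi = m.VOI(mask, "background")
        rep = m.quant_errors(va, vb, [voi],
                             ref_delta={("background", s): 0.5 for s in ("mean", "max", "peak")})
        assert np.isnan(rep.lookup("source", "background", "mean", "gamma_pct"))
        assert np.isfinite(rep.lookup("source", "background", "mean", "delta_dev"))


class TestExperimentDriver:
    def test_unknown_sources_rejected(self, case48):
        with pytest.raises(ValueError):
            m.run_quant_experiment(case48, ("listmode",))

    def test_synthetic_without_model_rejected(self, case48):
        with pytest.raises(ValueError, match="model"):
            m.run_quant_experiment(case48, ("synthetic",))

    def test_uniform_source_recovers_suv_one_background(self, case48, geom48):
        rep = m.run_quant_experiment(
            case48, ("uniform",), geom=geom48,
            recon_cfg=m.ReconConfig(subsets=8, iterations=4,
                                    filter_fwhm_transverse_mm=0,
                                    filter_fwhm_axial_mm=0))
        # re-run the uniform reconstruction path directly for the CTAC mean
        from mr2pet.quantify import body_mask_from_mri
        mask = body_mask_from_mri(case48.mri)
        src = case48.pet_truth.with_data(mask.astype(float), "suv")
        sino = m.forward_project(src, case48.mu_ct, geom48)
        rec = m.osem_reconstruct(sino, case48.mu_ct, geom48,
                                 m.ReconConfig(subsets=8, iterations=4,
                                               filter_fwhm_transverse_mm=0,
                                               filter_fwhm_axial_mm=0))
        assert rec.data[mask].mean() == pytest.approx(1.0, rel=0.10)
        assert set(rep.table.source) == {"uniform"}
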