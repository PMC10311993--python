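"""Projector, adjoint, OSEM and filters against independent oracles."""

import numpy as np
import pytest

import mr2pet as m
from mr2pet.tomo import ReconConfig, attenuation_factors, slice_system_matrix


def _bruteforce_sinogram(act: np.ndarray, mu: np.ndarray | None,
                         geom: m.ProjectionGeometry) -> np.ndarray:
    """Independent per-ray marcher using the documented discretization:
    half-voxel steps, bilinear sampling, attenuation over the full chord."""
    nx, ny, nz = geom.image_shape
    sx, sy = geom.voxel_spacing_mm[:2]
    cx, cy = nx * sx / 2.0, ny * sy / 2.0
    half_diag = 0.5 * float(np.hypot(nx * sx, ny * sy))
    step = 0.5 * min(sx, sy)
    n_steps = int(np.ceil(2.0 * (half_diag + step) / step))
    t = (np.arange(n_steps) + 0.5) * step - (n_steps * step) / 2.0
    offsets = (np.arange(geom.n_bins) - (geom.n_bins - 1) / 2.0) * geom.bin_spacing_mm

    def bilinear(img, x, y):
        gx, gy = x / sx - 0.5, y / sy - 0.5
        i0, j0 = int(np.floor(gx)), int(np.floor(gy))
        fx, fy = gx - i0, gy - j0
        total = 0.0
        for di, wx in ((0, 1 - fx), (1, fx)):
            for dj, wy in ((0, 1 - fy), (1, fy)):
                ii, jj = i0 + di, j0 + dj
                if 0 <= ii < nx and 0 <= jj < ny:
                    total += wx * wy * img[ii, jj]
        return total

    out = np.zeros((nz, geom.n_angles, geom.n_bins))
    for z in range(nz):
        act_sl = act[:, :, z]
        mu_sl = mu[:, :, z] if mu is not None else None
        for a, theta in enumerate(np.deg2rad(geom.angles_deg)):
            d = np.array([np.cos(theta), np.sin(theta)])
            nvec = np.array([-np.sin(theta), np.cos(theta)])
            for b, u in enumerate(offsets):
                line_act = 0.0
                line_mu = 0.0
                for tv in t:
                    px = cx + u * nvec[0] + tv * d[0]
                    py = cy + u * nvec[1] + tv * d[1]
                    line_act += bilinear(act_sl, px, py) * step
                    if mu_sl is not None:
                        line_mu += bilinear(mu_sl, px, py) * step
                out[z, a, b] = np.exp(-line_mu) * line_act
    return out


@pytest.fixture(scope="module")
def small_case():
    return m.generate_phantom(11, shape=(32, 32, 32), spacing_mm=3.0)


@pytest.fixture(scope="module")
def small_geom(small_case):
    return m.ProjectionGeometry.for_volume(small_case.pet_truth, n_angles=12)


class TestForwardProject:
    def test_zero_activity_returns_background(self, small_case, small_geom):
        zero = small_case.pet_truth.with_data(np.zeros(small_case.pet_truth.shape))
        bg = m.Sinogram(np.full((32, small_geom.n_angles, small_geom.n_bins), 0.7),
                        small_geom)
        out = m.forward_project(zero, small_case.mu_ct, small_geom, background=bg)
        assert np.array_equal(out.data, bg.data)

    def test_matches_bruteforce_oracle(self, small_case, small_geom):
        # single central slice keeps the scalar oracle affordable
        sl = slice(14, 16)
        act = np.zeros(small_case.pet_truth.shape)
        act[:, :, sl] = small_case.pet_truth.data[:, :, sl]
        mu = np.zeros(small_case.mu_ct.shape)
        mu[:, :, sl] = small_case.mu_ct.data[:, :, sl]
        sino = m.forward_project(small_case.pet_truth.with_data(act),
                                 small_case.mu_ct.with_data(mu), small_geom)
        oracle = _bruteforce_sinogram(act, mu, small_geom)
        scale = np.abs(oracle[sl.start]).max()
        rel = np.abs(sino.data[sl] - oracle[sl.start:sl.stop]) / scale
        assert rel.max() < 1e-6

    def test_point_source_seen_equally_from_all_angles(self):
        vol = m.Volume3D(np.zeros((32, 32, 4)), (2.0, 2.0, 2.0), "suv")
        vol.data[16, 16, 2] = 1.0
        geom = m.ProjectionGeometry.for_volume(vol, n_angles=24)
        sino = m.forward_project(vol, None, geom)
        totals = sino.data[2].sum(axis=1)
        assert totals.std() / totals.mean() < 0.05

    def test_uniform_disc_attenuates_by_chord_length(self):
        vol = m.Volume3D(np.zeros((32, 32, 4)), (2.0, 2.0, 2.0), "suv")
        vol.data[16, 16, 2] = 1.0
        mu_val, radius = 0.01, 20.0
        xs = (np.arange(32) + 0.5) * 2.0
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        disc = (X - 32.0) ** 2 + (Y - 32.0) ** 2 <= radius ** 2
        mu = np.zeros((32, 32, 4))
        mu[disc] = mu_val
        geom = m.ProjectionGeometry.for_volume(vol, n_angles=24)
        plain = m.forward_project(vol, None, geom)
        atten = m.forward_project(vol, vol.with_data(mu, "mu_per_mm"), geom)
        ratio = atten.data[2].sum(axis=1) / plain.data[2].sum(axis=1)
        # every LOR through the centre crosses the full 2R chord
        assert np.allclose(ratio, np.exp(-mu_val * 2 * radius), rtol=0.02)

    def test_linear_in_activity(self, small_case, small_geom, rng):
        x1 = small_case.pet_truth
        x2 = x1.with_data(rng.random(x1.shape) * 5)
        s1 = m.forward_project(x1, small_case.mu_ct, small_geom).data
        s2 = m.forward_project(x2, small_case.mu_ct, small_geom).data
        combo = m.forward_project(x1.with_data(2 * x1.data + 3 * x2.data),
                                  small_case.mu_ct, small_geom).data
        assert np.allclose(combo, 2 * s1 + 3 * s2, atol=1e-10 * np.abs(combo).max())

    def test_mass_conservation_per_angle(self, rng):
        act = np.zeros((32, 32, 4))
        act[8:24, 8:24, :] = rng.random((16, 16, 4))
        vol = m.Volume3D(act, (2.0, 2.0, 2.0), "suv")
        geom = m.ProjectionGeometry.for_volume(vol, n_angles=16)
        sino = m.forward_project(vol, None, geom)
        voxel_area = 4.0
        expected = act[:, :, 1].sum() * voxel_area / geom.bin_spacing_mm
        per_angle = sino.data[1].sum(axis=1)
        assert np.allclose(per_angle, expected, rtol=0.01)

    def test_grid_mismatch_rejected(self, small_case, small_geom):
        other = m.Volume3D(np.zeros((16, 16, 16)), (3.0,) * 3, "suv")
        with pytest.raises(ValueError):
            m.forward_project(other, None, small_geom)


class TestBackProject:
    def test_adjoint_identity(self, small_geom, rng):
        nx, ny, nz = small_geom.image_shape
        x = m.Volume3D(rng.random((nx, ny, nz)), small_geom.voxel_spacing_mm, "suv")
        y = m.Sinogram(rng.random((nz, small_geom.n_angles, small_geom.n_bins)),
                       small_geom)
        ax = m.forward_project(x, None, small_geom)
        aty = m.back_project(y, small_geom)
        lhs = float(np.sum(ax.data * y.data))
        rhs = float(np.sum(x.data * aty.data))
        assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_zero_sinogram_gives_zero_volume(self, small_geom):
        nz = small_geom.image_shape[2]
        sino = m.Sinogram(np.zeros((nz, small_geom.n_angles, small_geom.n_bins)),
                          small_geom)
        assert np.all(m.back_project(sino).data == 0)

    def test_single_ray_smears_along_one_line(self, small_geom):
        nz = small_geom.image_shape[2]
        data = np.zeros((nz, small_geom.n_angles, small_geom.n_bins))
        data[0, 0, small_geom.n_bins // 2] = 1.0  # angle 0: ray along +x
        vol = m.back_project(m.Sinogram(data, small_geom)).data
        assert vol[:, :, 1:].sum() == 0  # only slice 0 receives anything
        support_y = np.unique(np.nonzero(vol[:, :, 0])[1])
        assert len(support_y) <= 3  # a thin stripe at the central bin


class TestOSEM:
    def test_single_subset_equals_mlem_update_for_update(self, small_case):
        geom = m.ProjectionGeometry.for_volume(small_case.pet_truth, n_angles=16)
        sino = m.forward_project(small_case.pet_truth, small_case.mu_ct, geom)
        cfg = ReconConfig(subsets=1, iterations=3,
                          filter_fwhm_transverse_mm=0, filter_fwhm_axial_mm=0)
        osem = m.osem_reconstruct(sino, small_case.mu_ct, geom, cfg)
        # independent MLEM loop on the same operator
        P = slice_system_matrix(geom)
        a = attenuation_factors(small_case.mu_ct, geom)
        y = sino.data.transpose(1, 2, 0).reshape(-1, 32)
        X = np.ones((32 * 32, 32))
        sens = P.T @ a
        X[sens <= 0] = 0.0
        for _ in range(3):
            fwd = a * (P @ X)
            ratio = np.where(fwd > 1e-30, y / np.maximum(fwd, 1e-30), 0.0)
            X *= np.where(sens > 0, (P.T @ (a * ratio)) / np.maximum(sens, 1e-30), 1.0)
        assert np.allclose(osem.data, X.reshape(32, 32, 32), rtol=1e-10, atol=1e-12)

    def test_noiseless_recovery_and_attenuation_monotonicity(self, case48, geom48):
        sino = m.forward_project(case48.pet_truth, case48.mu_ct, geom48)
        cfg = ReconConfig(subsets=8, iterations=6,
                          filter_fwhm_transverse_mm=0, filter_fwhm_axial_mm=0)
        rec = m.osem_reconstruct(sino, case48.mu_ct, geom48, cfg)
        body = case48.body_mask.data.astype(bool)
        assert m.mrae(case48.pet_truth.data, rec.data, 0.1) < 0.10
        rec_none = m.osem_reconstruct(sino, None, geom48, cfg)
        assert rec_none.data[body].mean() < rec.data[body].mean()

    def test_output_nonnegative(self, case48, geom48):
        sino = m.forward_project(case48.pet_truth, case48.mu_ct, geom48)
        rec = m.osem_reconstruct(sino, case48.mu_ct, geom48,
                                 ReconConfig(subsets=4, iterations=1))
        assert np.all(rec.data >= 0)
        assert np.all(np.isfinite(rec.data))


class TestPostfilterAndMu:
    def test_zero_fwhm_is_identity(self, case48):
        out = m.gaussian_postfilter(case48.pet_truth, 0.0, 0.0)
        assert np.array_equal(out.data, case48.pet_truth.data)

    def test_interior_mass_preserved(self):
        vol = m.Volume3D(np.zeros((32, 32, 32)), (2.0,) * 3, "suv")
        vol.data[16, 16, 16] = 100.0
        out = m.gaussian_postfilter(vol, 4.0, 4.0)
        assert out.data.sum() == pytest.approx(100.0, rel=1e-3)

    def test_impulse_response_has_requested_fwhm(self):
        vol = m.Volume3D(np.zeros((41, 41, 41)), (1.0,) * 3, "suv")
        vol.data[20, 20, 20] = 1.0
        fwhm = 6.0
        out = m.gaussian_postfilter(vol, fwhm, fwhm)
        profile = out.data[:, 20, 20]
        half = profile.max() / 2.0
        above = np.flatnonzero(profile >= half)
        measured = above[-1] - above[0] + 1
        assert abs(measured - fwhm) <= 1.0  # within half a voxel each side

    def test_negative_fwhm_rejected(self, case48):
        with pytest.raises(ValueError):
            m.gaussian_postfilter(case48.pet_truth, -1.0, 0.0)

    @pytest.mark.parametrize("hu,expected", [(0.0, 0.0096), (-1000.0, 0.0),
                                             (-500.0, 0.0048), (1000.0, 0.0150)])
    def test_hu_conversion(self, hu, expected):
        vol = m.Volume3D(np.full((2, 2, 2), hu), (1.0,) * 3, "arbitrary")
        assert m.hu_to_mu511(vol).data[0, 0, 0] == pytest.approx(expected)

    def test_hu_below_air_clamped_to_zero(self):
        vol = m.Volume3D(np.full((2, 2, 2), -2000.0), (1.0,) * 3, "arbitrary")
        assert np.all(m.hu_to_mu511(vol).data == 0.0)


class TestSinogramContainer:
    def test_roundtrip_with_geometry_header(self, small_case, small_geom, tmp_path):
        sino = m.forward_project(small_case.pet_truth, small_case.mu_ct, small_geom)
        path = tmp_path / "sino.npz"
        sino.save(path)
        loaded = m.Sinogram.load(path)
        assert np.array_equal(loaded.data, sino.data)
        assert loaded.geometry.to_dict() == small_geom.to_dict()

    def test_shape_must_match_geometry(self, small_geom):
        with pytest.raises(ValueError):
            m.Sinogram(np.zeros((2, 3, 4)), small_geom)
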