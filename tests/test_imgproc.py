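"""Image I/O, calibration and preprocessing chain."""

import numpy as np
import pytest

from tibiamct import imgproc
from tibiamct.imgproc import (
    AmbiguityError, BoneMask, CalibrationCurve, GeometryError, VoxelImage,
    align_principal_axis, close_cortical_pores, compute_threshold, despeckle,
    fit_calibration, gaussian_filter, largest_component, read_image, segment,
    tibia_length, to_tmd, write_image,
)

from conftest import flood_fill_label_sizes


@pytest.fixture
def random_image(rng=np.random.default_rng(0)) -> VoxelImage:
    return VoxelImage(rng.normal(100, 20, size=(12, 14, 16)), spacing=10.4)


class TestIO:
    @pytest.mark.parametrize("fmt,ext", [("tiff-stack", "tif"),
                                         ("mhd", "mhd"), ("nifti", "nii")])
    def test_round_trip_preserves_grid_and_spacing(self, tmp_path, fmt, ext,
                                                   random_image):
        path = tmp_path / f"img.{ext}"
        write_image(random_image, path, fmt)
        back = read_image(path, fmt)
        assert back.spacing == pytest.approx(10.4)
        np.testing.assert_allclose(back.data, random_image.data)

    def test_tiff_stack_shape_convention(self, tmp_path):
        img = VoxelImage(np.zeros((10, 6, 8), dtype=np.uint8), spacing=10.4)
        path = write_image(img, tmp_path / "s.tif")
        assert read_image(path).shape == (10, 6, 8)

    def test_mhd_spacing_passthrough(self, tmp_path):
        img = VoxelImage(np.zeros((4, 4, 4)), spacing=10.4)
        back = read_image(write_image(img, tmp_path / "s.mhd"))
        assert back.spacing == pytest.approx(10.4)

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            read_image(write_image(
                VoxelImage(np.zeros((2, 2, 2)), 10.4), tmp_path / "a.mhd"),
                format="weird")

    def test_anisotropic_spacing_rejected(self, tmp_path):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.zeros((3, 3, 3)))
        img.SetSpacing((10.4, 10.4, 20.8))
        sitk.WriteImage(img, str(tmp_path / "aniso.mhd"))
        with pytest.raises(GeometryError):
            read_image(tmp_path / "aniso.mhd")


class TestCalibration:
    def test_two_point_line(self):
        curve = fit_calibration([(0, 0), (1000, 800)])
        assert curve.slope == pytest.approx(0.8)
        assert curve.intercept == pytest.approx(0.0)

    def test_five_nominal_densities_recover_generating_line(self):
        densities = np.array([800, 400, 200, 100, 0], dtype=float)
        grey = (densities - (-60.0)) / 0.75  # generating line TMD = -60 + 0.75 g
        curve = fit_calibration(list(zip(grey, densities)))
        assert curve.slope == pytest.approx(0.75)
        assert curve.intercept == pytest.approx(-60.0)

    def test_noisy_fit_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        grey = np.array([100.0, 300.0, 500.0, 700.0, 900.0])
        dens = 0.8 * grey - 50 + rng.normal(0, 5, 5)
        curve = fit_calibration(list(zip(grey, dens)))
        # brute-force normal equations
        A = np.stack([grey, np.ones(5)], 1)
        beta = np.linalg.solve(A.T @ A, A.T @ dens)
        assert curve.slope == pytest.approx(beta[0], rel=1e-9)
        assert curve.intercept == pytest.approx(beta[1], rel=1e-9)

    def test_degenerate_points_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(100, 0)])
        with pytest.raises(ValueError):
            fit_calibration([(100, 0), (100, 800)])

    def test_to_tmd_affine_and_clamp(self):
        img = VoxelImage(np.array([[[500.0, 10.0, -5.0]]]), 10.4)
        out = to_tmd(img, CalibrationCurve(0.8, 0.0))
        np.testing.assert_allclose(out.data, [[[400.0, 8.0, 0.0]]])
        assert out.value_kind == "tmd"
        ident = to_tmd(img, CalibrationCurve(1.0, 0.0))
        np.testing.assert_allclose(ident.data, np.maximum(img.data, 0))
        with pytest.raises(ValueError):
            to_tmd(out, CalibrationCurve(1.0, 0.0))

    def test_calibration_round_trip_identity(self):
        curve = CalibrationCurve(0.73, -41.0)
        g = np.linspace(100, 2000, 17)
        np.testing.assert_allclose(curve.tmd_to_grey(curve.grey_to_tmd(g)), g)


class TestGaussianFilter:
    def test_constant_preserved(self):
        img = VoxelImage(np.full((8, 8, 8), 37.5), 10.4)
        np.testing.assert_allclose(gaussian_filter(img).data, 37.5)

    def test_impulse_matches_tabulated_kernel(self):
        """Centre response equals the normalised 3³ Gaussian tabulation."""
        sigma = 0.65
        offs = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                         for k in (-1, 0, 1)])
        w = np.exp(-(offs**2).sum(1) / (2 * sigma**2))
        w /= w.sum()
        center_weight = w[(offs == 0).all(1)][0]
        data = np.zeros((7, 7, 7))
        data[3, 3, 3] = 1.0
        out = gaussian_filter(VoxelImage(data, 10.4)).data
        assert out[3, 3, 3] == pytest.approx(center_weight, rel=1e-12)
        assert out[2, 3, 3] == pytest.approx(
            w[np.all(offs == (-1, 0, 0), 1)][0], rel=1e-12)
        # kernel support is 3x3x3: nothing beyond distance 1
        assert out[1, 3, 3] == 0.0

    def test_interior_impulse_mass_conserved(self):
        data = np.zeros((9, 9, 9))
        data[4, 4, 4] = 3.7
        out = gaussian_filter(VoxelImage(data, 10.4)).data
        assert out.sum() == pytest.approx(3.7, rel=1e-12)


class TestThreshold:
    def test_two_delta_peaks_midpoint(self):
        vals = np.concatenate([np.full(600, 100.0), np.full(400, 220.0)])
        img = VoxelImage(vals.reshape(10, 10, 10), 10.4)
        assert compute_threshold(img) == pytest.approx(160.0)

    def test_gaussian_mixture_peaks_located(self):
        rng = np.random.default_rng(12)
        vals = np.concatenate([rng.normal(80, 10, 4000),
                               rng.normal(200, 10, 2000)])
        img = VoxelImage(vals.reshape(20, 20, 15), 10.4)
        t, (p1, p2) = compute_threshold(img, return_peaks=True)
        binw = np.ptp(vals) / 256
        assert abs(p1 - 80) <= 2 * binw
        assert abs(p2 - 200) <= 2 * binw

    def test_flip_symmetry(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([np.full(500, 20.0), np.full(300, 200.0),
                               rng.uniform(230, 240, 40)])
        rng.shuffle(vals)
        img = VoxelImage(vals.reshape(10, 12, 7), 10.4)
        t = compute_threshold(img)
        m = vals.min() + vals.max()
        flipped = VoxelImage(m - img.data, 10.4)
        assert compute_threshold(flipped) == pytest.approx(m - t)

    def test_unimodal_raises(self):
        img = VoxelImage(np.random.default_rng(0).normal(100, 5, (10, 10, 10)),
                         10.4)
        with pytest.raises(AmbiguityError):
            compute_threshold(img, smooth_window=31)


class TestSegmentation:
    def test_segment_matches_voxelwise_comparison(self, random_image):
        t = 100.0
        mask = segment(random_image, t)
        np.testing.assert_array_equal(mask.data, random_image.data >= t)
        assert mask.threshold == t

    def test_threshold_boundaries(self, random_image):
        assert segment(random_image, random_image.data.min()).data.all()
        assert not segment(random_image,
                           random_image.data.max() + 1).data.any()

    def test_despeckle_size_boundary(self):
        """'Smaller than 10 voxels' is strict: 9 removed, 10 kept."""
        data = np.zeros((10, 20, 10), dtype=bool)
        data[1, 1:10, 1] = True  # 9-voxel line
        assert despeckle(BoneMask(data, 10.4)).count() == 0
        data10 = np.zeros((10, 20, 10), dtype=bool)
        data10[1, 1:11, 1] = True  # 10-voxel line
        assert despeckle(BoneMask(data10, 10.4)).count() == 10

    def test_despeckle_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(9)
        blob = rng.random((18, 18, 18)) > 0.72
        kept = despeckle(BoneMask(blob, 10.4), min_size=10)
        expect = sum(s for s in flood_fill_label_sizes(blob) if s >= 10)
        assert kept.count() == expect

    def test_despeckle_idempotent(self):
        rng = np.random.default_rng(2)
        blob = rng.random((15, 15, 15)) > 0.7
        once = despeckle(BoneMask(blob, 10.4))
        twice = despeckle(once)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_largest_component_six_connectivity(self):
        data = np.zeros((10, 10, 10), dtype=bool)
        data[1:4, 1:4, 1:4] = True  # 27 voxels
        data[6:8, 6:8, 6:8] = True  # 8 voxels
        out = largest_component(BoneMask(data, 10.4))
        assert out.count() == 27
        # diagonal touch does not connect under 6-connectivity
        diag = np.zeros((4, 4, 4), dtype=bool)
        diag[0, 0, 0] = diag[1, 1, 1] = True
        out = largest_component(BoneMask(diag, 10.4))
        assert out.count() == 1
        assert out.data[0, 0, 0]  # tie broken by lowest linear index
        with pytest.raises(ValueError):
            largest_component(BoneMask(np.zeros((3, 3, 3), bool), 10.4))


class TestClosing:
    def test_pore_filled(self):
        """An intracortical pore of a few pixels closes; oracle: explicit
        dilate-then-erode with the same structuring element."""
        from scipy import ndimage
        from skimage.morphology import disk

        yy, xx = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        r = np.hypot(yy - 31.5, xx - 31.5)
        annulus = (r <= 25) & (r >= 15)
        pore = np.hypot(yy - 31.5, xx - 11.5) <= 1.6
        holey = annulus & ~pore
        mask = BoneMask(holey[None], 10.4)
        closed = close_cortical_pores(mask, radius_px=10)
        selem = disk(10).astype(bool)
        pad = 11
        oracle = ndimage.binary_erosion(
            ndimage.binary_dilation(np.pad(holey, pad), selem), selem
        )[pad:-pad, pad:-pad]
        np.testing.assert_array_equal(closed.data[0], oracle | holey)
        assert closed.data[0][annulus].all()

    def test_solid_disk_unchanged(self):
        yy, xx = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        solid = np.hypot(yy - 31.5, xx - 31.5) <= 20
        closed = close_cortical_pores(BoneMask(solid[None], 10.4), 10)
        np.testing.assert_array_equal(closed.data[0], solid)

    def test_extensive(self):
        rng = np.random.default_rng(3)
        blob = rng.random((4, 40, 40)) > 0.8
        closed = close_cortical_pores(BoneMask(blob, 10.4), 5)
        assert (closed.data | blob).sum() == closed.data.sum()


class TestAlignment:
    def _prism(self, axis: str) -> np.ndarray:
        data = np.zeros((40, 40, 40), dtype=bool)
        if axis == "z":
            data[5:35, 17:23, 17:23] = True
        else:  # along y
            data[17:23, 5:35, 17:23] = True
        return data

    def test_prism_on_axis_identity(self):
        mask = BoneMask(self._prism("z"), 10.4)
        aligned, tr = align_principal_axis(mask)
        np.testing.assert_array_equal(aligned.data, mask.data)
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-12)

    def test_rotated_prism_realigned_volume_preserved(self):
        mask = BoneMask(self._prism("y"), 10.4)
        aligned, _ = align_principal_axis(mask)
        occupied = np.flatnonzero(aligned.data.any(axis=(1, 2)))
        assert occupied.size >= 28  # long axis now along Z
        assert abs(aligned.count() - mask.count()) / mask.count() <= 0.01

    def test_mirror_commutes_for_sagittal_symmetric_axis(self):
        """With the bone axis in the z-y plane, aligning a mirrored mask
        equals mirroring the aligned mask."""
        data = np.zeros((40, 40, 40), dtype=bool)
        data[17:23, 5:35, 10:18] = True  # prism along y, off-centre in x
        mask = BoneMask(data, 10.4)
        a1, _ = align_principal_axis(BoneMask(data[:, :, ::-1], 10.4))
        a2, _ = align_principal_axis(mask, mirror=True)
        np.testing.assert_array_equal(a1.data, a2.data)

    def test_isotropic_blob_ambiguous(self):
        data = np.zeros((20, 20, 20), dtype=bool)
        data[5:15, 5:15, 5:15] = True
        with pytest.raises(AmbiguityError):
            align_principal_axis(BoneMask(data, 10.4))


class TestLength:
    def test_slab_convention(self):
        data = np.zeros((120, 5, 5), dtype=bool)
        data[0:100, 2, 2] = True
        assert tibia_length(BoneMask(data, 10.4)) == pytest.approx(1.04)

    def test_single_slice(self):
        data = np.zeros((5, 5, 5), dtype=bool)
        data[2, 2, 2] = True
        assert tibia_length(BoneMask(data, 10.4)) == pytest.approx(0.0104)

    def test_phantom_ground_truth_length(self, clean_phantom_spec):
        from tibiamct.phantom import generate_tibia_phantom

        left, _, gt = generate_tibia_phantom(clean_phantom_spec)
        mask = BoneMask(gt.labels_left > 0, gt.spacing)
        nz = clean_phantom_spec.image_shape[0]
        assert tibia_length(mask) == pytest.approx(nz * gt.spacing / 1000.0)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            tibia_length(BoneMask(np.zeros((3, 3, 3), bool), 10.4))
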