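"""Geometry, sampling, resampling and ROI algebra."""

import numpy as np
import pytest

from regsurrogate.image_model import (
    DeformationField,
    GeometryError,
    ROIMask,
    PointSet,
    RigidTransform,
    VolumetricImage,
    combine_masks,
    expand_mask,
    load_dvf,
    load_fiducials,
    load_image,
    load_mask,
    resample_deformable,
    resample_rigid,
    save_dvf,
    save_fiducials,
    save_image,
    save_mask,
    trilinear_sample,
)


def _rot_z(deg):
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])


class TestCoordinates:
    def test_origin_is_center_of_first_voxel(self):
        img = VolumetricImage(np.zeros((4, 4, 4)), (1, 1, 1), (10, 20, 30))
        assert np.allclose(img.voxel_to_physical([0, 0, 0]), (10, 20, 30))

    def test_anisotropic_spacing_maps_one_index_step(self):
        img = VolumetricImage(np.zeros((4, 4, 4)), (1.25, 1.25, 2.5), (0, 0, 0))
        assert np.allclose(img.voxel_to_physical([1, 0, 0]), (1.25, 0, 0))
        assert np.allclose(img.voxel_to_physical([0, 0, 1]), (0, 0, 2.5))

    def test_round_trip_bijection(self):
        rng = np.random.default_rng(0)
        img = VolumetricImage(
            np.zeros((5, 6, 7)), (1.25, 1.0, 2.5), (3, -4, 5), _rot_z(30)
        )
        idx = rng.uniform(-2, 8, size=(100, 3))
        back = img.physical_to_voxel(img.voxel_to_physical(idx))
        assert np.abs(back - idx).max() < 1e-9

    def test_invalid_geometry_rejected(self):
        with pytest.raises(GeometryError):
            VolumetricImage(np.zeros((4, 4, 4)), (0, 1, 1), (0, 0, 0))
        with pytest.raises(GeometryError):
            VolumetricImage(np.zeros((4, 4, 4)), (1, 1, 1), (0, 0, 0),
                            orientation=np.eye(3) * 2)


class TestTrilinear:
    def test_voxel_center_is_exact(self):
        rng = np.random.default_rng(1)
        img = VolumetricImage(rng.normal(size=(5, 5, 5)), (2, 2, 2), (0, 0, 0))
        p = img.voxel_to_physical([2, 3, 1])
        assert trilinear_sample(img, p) == pytest.approx(img.voxels[2, 3, 1], abs=1e-12)

    def test_midpoint_linearity(self):
        img = VolumetricImage(np.zeros((3, 3, 3)), (1, 1, 1), (0, 0, 0))
        img.voxels[1, 1, 1] = 0.0
        img.voxels[2, 1, 1] = 10.0
        assert trilinear_sample(img, (1.5, 1, 1)) == pytest.approx(5.0)

    def test_against_nearest8_oracle(self):
        rng = np.random.default_rng(2)
        img = VolumetricImage(rng.normal(size=(6, 7, 8)), (1.25, 1.0, 2.5), (1, 2, 3))
        pts_idx = rng.uniform(0, [5, 6, 7], size=(50, 3))
        pts = img.voxel_to_physical(pts_idx)

        def oracle(i):
            lo = np.floor(i).astype(int)
            f = i - lo
            val = 0.0
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        w = ((f[0] if dx else 1 - f[0])
                             * (f[1] if dy else 1 - f[1])
                             * (f[2] if dz else 1 - f[2]))
                        c = np.minimum(lo + (dx, dy, dz), np.array(img.shape) - 1)
                        val += w * img.voxels[tuple(c)]
            return val

        got = trilinear_sample(img, pts)
        want = np.array([oracle(i) for i in pts_idx])
        assert np.abs(got - want).max() < 1e-10

    def test_outside_returns_fill_exactly(self):
        img = VolumetricImage(np.ones((4, 4, 4)), (1, 1, 1), (0, 0, 0))
        assert trilinear_sample(img, (-0.01, 1, 1), fill=-7.0) == -7.0
        assert trilinear_sample(img, (3.01, 1, 1), fill=-7.0) == -7.0


class TestResampling:
    def test_identity_transform_preserves_image(self, smooth_image):
        out = resample_rigid(smooth_image, smooth_image, RigidTransform.identity())
        assert np.allclose(out.voxels, smooth_image.voxels, atol=1e-12)

    def test_one_voxel_translation_shifts_grid(self, smooth_image):
        # transform maps fixed coords to moving coords: +1 voxel along x
        t = RigidTransform.translation_only((1.25, 0, 0))
        out = resample_rigid(smooth_image, smooth_image, t)
        assert np.allclose(out.voxels[:-1], smooth_image.voxels[1:], atol=1e-10)

    def test_rigid_inverse_composition_small_error(self, smooth_image):
        t = RigidTransform(_rot_z(7), (2.0, -1.5, 1.0))
        fwd = resample_rigid(smooth_image, smooth_image, t)
        back = resample_rigid(fwd, smooth_image, t.inverse())
        interior = (slice(4, -4),) * 2 + (slice(3, -3),)
        rng_i = smooth_image.voxels.max() - smooth_image.voxels.min()
        rmse = np.sqrt(((back.voxels - smooth_image.voxels)[interior] ** 2).mean())
        assert rmse < 0.01 * rng_i

    def test_zero_field_equals_identity(self, smooth_image):
        dvf = DeformationField(np.zeros((*smooth_image.shape, 3)),
                               smooth_image.spacing, smooth_image.origin)
        out = resample_deformable(smooth_image, smooth_image, dvf)
        assert np.allclose(out.voxels, smooth_image.voxels, atol=1e-12)

    def test_constant_field_equals_rigid_translation(self, smooth_image):
        t = np.array([2.5, -1.25, 2.5])
        d = np.broadcast_to(t, (*smooth_image.shape, 3)).copy()
        dvf = DeformationField(d, smooth_image.spacing, smooth_image.origin)
        a = resample_deformable(smooth_image, smooth_image, dvf, fill=0.0)
        b = resample_rigid(smooth_image, smooth_image,
                           RigidTransform.translation_only(t), fill=0.0)
        assert np.allclose(a.voxels, b.voxels, atol=1e-12)

    def test_analytic_warp_recovered(self, smooth_image):
        # forward model: build the warped volume by sampling the analytic image
        geom = smooth_image

        def f(x):
            return (100.0 * np.sin(x[..., 0] / 7.0) * np.cos(x[..., 1] / 9.0)
                    + 40.0 * np.sin(x[..., 2] / 11.0))

        x = geom.physical_grid()
        d = np.stack([1.5 * np.sin(x[..., 1] / 10.0),
                      1.0 * np.cos(x[..., 0] / 12.0),
                      0.5 * np.ones(geom.shape)], axis=-1)
        dvf = DeformationField(d, geom.spacing, geom.origin)
        warped = resample_deformable(geom, geom, dvf)
        expected = f(x + d)
        interior = (slice(2, -2),) * 2 + (slice(1, -1),)
        rng_i = geom.voxels.max() - geom.voxels.min()
        rmse = np.sqrt(((warped.voxels - expected)[interior] ** 2).mean())
        assert rmse < 0.02 * rng_i

    def test_constant_image_conserved(self):
        img = VolumetricImage(np.full((10, 10, 10), 3.25), (1, 1, 1), (0, 0, 0))
        t = RigidTransform(_rot_z(13), (0.4, -0.2, 0.1))
        out = resample_rigid(img, img, t, fill=np.nan)
        inside = ~np.isnan(out.voxels)
        assert inside.any()
        assert np.allclose(out.voxels[inside], 3.25, atol=1e-12)

    def test_field_geometry_mismatch_rejected(self, smooth_image):
        dvf = DeformationField(np.zeros((4, 4, 4, 3)), (1, 1, 1), (0, 0, 0))
        with pytest.raises(GeometryError):
            resample_deformable(smooth_image, smooth_image, dvf)


class TestMaskAlgebra:
    def _mask(self, vox, name="m"):
        return ROIMask(vox, (1.0, 1.0, 1.0), (0, 0, 0), name=name)

    def test_combine_single_and_disjoint(self):
        a = np.zeros((6, 6, 6), dtype=int)
        a[1, 1, 1] = 1
        b = np.zeros((6, 6, 6), dtype=int)
        b[4, 4, 4] = 1
        ma, mb = self._mask(a), self._mask(b)
        assert combine_masks([ma]).voxel_count() == 1
        assert combine_masks([ma, mb]).voxel_count() == 2

    def test_combine_matches_set_union(self):
        rng = np.random.default_rng(3)
        ms = [self._mask(rng.integers(0, 2, size=(5, 5, 5))) for _ in range(3)]
        got = set(map(tuple, np.argwhere(combine_masks(ms).voxels)))
        want = set()
        for m in ms:
            want |= set(map(tuple, np.argwhere(m.voxels)))
        assert got == want

    def test_combine_geometry_mismatch(self):
        a = self._mask(np.zeros((5, 5, 5), dtype=int))
        b = ROIMask(np.zeros((5, 5, 5), dtype=int), (2, 2, 2), (0, 0, 0))
        with pytest.raises(GeometryError):
            combine_masks([a, b])

    def test_expand_zero_margin_identity(self):
        rng = np.random.default_rng(4)
        m = self._mask(rng.integers(0, 2, size=(6, 6, 6)))
        assert np.array_equal(expand_mask(m, 0.0).voxels, m.voxels)

    def test_single_voxel_unit_margin_gives_plus_shape(self):
        v = np.zeros((5, 5, 5), dtype=int)
        v[2, 2, 2] = 1
        got = expand_mask(self._mask(v), 1.0)
        assert got.voxel_count() == 7
        for off in [(0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0),
                    (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
            assert got.voxels[2 + off[0], 2 + off[1], 2 + off[2]]

    def test_expansion_respects_anisotropic_spacing(self):
        v = np.zeros((5, 5, 5), dtype=int)
        v[2, 2, 2] = 1
        m = ROIMask(v, (1.25, 1.25, 2.5), (0, 0, 0))
        got = expand_mask(m, 2.0)
        assert got.voxels[3, 2, 2]       # 1.25 mm away
        assert not got.voxels[2, 2, 3]   # 2.5 mm away > 2 mm margin

    def test_expand_against_brute_force_distance(self):
        rng = np.random.default_rng(5)
        v = (rng.random((6, 6, 4)) < 0.15).astype(int)
        v[3, 3, 2] = 1
        m = ROIMask(v, (1.25, 1.0, 2.5), (0, 0, 0))
        margin = 2.6
        got = expand_mask(m, margin)
        pts = np.argwhere(v) * m.spacing
        all_idx = np.argwhere(np.ones_like(v))
        d = np.linalg.norm(all_idx[:, None, :] * m.spacing - pts[None], axis=-1).min(axis=1)
        want = (d <= margin).reshape(v.shape)
        assert np.array_equal(got.voxels, want)

    @pytest.mark.parametrize("a,b", [(0.0, 1.0), (1.0, 2.5), (2.5, 2.5)])
    def test_expansion_monotone_in_margin(self, a, b):
        rng = np.random.default_rng(6)
        m = self._mask((rng.random((6, 6, 6)) < 0.2).astype(int))
        small, big = expand_mask(m, a).voxels, expand_mask(m, b).voxels
        assert not np.any(small & ~big)

    def test_expand_of_union_equals_union_of_expands(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            va = (rng.random((6, 6, 6)) < 0.1).astype(int)
            vb = (rng.random((6, 6, 6)) < 0.1).astype(int)
            if not (va.any() and vb.any()):
                continue
            ma, mb = self._mask(va, "a"), self._mask(vb, "b")
            r = 1.8
            lhs = expand_mask(combine_masks([ma, mb]), r).voxels
            rhs = combine_masks([expand_mask(ma, r), expand_mask(mb, r)]).voxels
            assert np.array_equal(lhs, rhs)


class TestIO:
    def test_image_nifti_round_trip(self, tmp_path, smooth_image):
        p = tmp_path / "img.nii.gz"
        save_image(smooth_image, p)
        back = load_image(p)
        assert back.same_geometry(smooth_image, atol=1e-5)
        assert np.allclose(back.voxels, smooth_image.voxels, atol=1e-3)

    def test_mask_and_dvf_round_trip(self, tmp_path):
        m = ROIMask((np.random.default_rng(0).random((5, 5, 5)) < 0.3).astype(int),
                    (1.25, 1.25, 2.5), (1, 2, 3), name="roi")
        save_mask(m, tmp_path / "m.nii.gz")
        back = load_mask(tmp_path / "m.nii.gz", "roi")
        assert np.array_equal(back.voxels, m.voxels)
        d = DeformationField(np.random.default_rng(1).normal(size=(5, 5, 5, 3)),
                             (1.25, 1.25, 2.5), (1, 2, 3))
        save_dvf(d, tmp_path / "d.nii.gz")
        back_d = load_dvf(tmp_path / "d.nii.gz")
        assert np.allclose(back_d.displacement, d.displacement, atol=1e-5)

    def test_fiducial_csv_round_trip(self, tmp_path):
        pts = PointSet(["F1", "F2"], [[1.5, -2.0, 3.25], [0, 0, 7]])
        save_fiducials(pts, tmp_path / "f.csv")
        back = load_fiducials(tmp_path / "f.csv")
        assert back.labels == pts.labels
        assert np.allclose(back.positions, pts.positions)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PointSet(["F1", "F1"], [[0, 0, 0], [1, 1, 1]])
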