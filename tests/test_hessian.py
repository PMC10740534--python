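"""Hessian field, convexity masks and blobness scoring."""

import numpy as np
import pytest

from blobcut import hessian, phantom
from blobcut.hessian import (
    HessianField,
    blobness,
    blobness_voxelwise,
    compute_hessian,
    convexity_count,
    convexity_indicator,
    convexity_mask_of_image,
    negative_definite,
)


def field_from_matrices(mats: np.ndarray) -> HessianField:
    """Wrap an (n, 3, 3) batch of symmetric matrices as an (n,1,1) field."""
    n = mats.shape[0]
    h = np.stack(
        [mats[:, 0, 0], mats[:, 0, 1], mats[:, 0, 2],
         mats[:, 1, 1], mats[:, 1, 2], mats[:, 2, 2]]
    ).reshape(6, n, 1, 1)
    return HessianField(h=h, valid=np.ones((n, 1, 1), dtype=bool))


def grid(shape):
    return np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")


class TestComputeHessian:
    def test_exact_on_sphere_quadratic(self):
        i, j, k = grid((7, 8, 9))
        f = i**2 + j**2 + k**2
        field = compute_hessian(f)
        m = field.matrices()[field.valid]
        assert np.allclose(m, np.diag([2.0, 2.0, 2.0]), atol=1e-10)

    def test_exact_on_bilinear(self):
        i, j, k = grid((7, 7, 7))
        field = compute_hessian(i * j)
        m = field.matrices()[field.valid]
        expect = np.zeros((3, 3))
        expect[0, 1] = expect[1, 0] = 1.0
        assert np.allclose(m, expect, atol=1e-10)

    def test_exact_on_general_quadratic(self):
        i, j, k = grid((6, 7, 8))
        f = 1.5 * i**2 - 0.5 * j**2 + 2.0 * k**2 + 0.7 * i * j - 1.1 * j * k + 0.3 * i * k
        field = compute_hessian(f)
        expect = np.array([[3.0, 0.7, 0.3], [0.7, -1.0, -1.1], [0.3, -1.1, 4.0]])
        assert np.allclose(field.matrices()[field.valid], expect, atol=1e-9)

    def test_gaussian_peak_is_negative_definite(self):
        spec = phantom.BlobSpec((5.0, 5.0, 5.0), 0.0, 0.0, 2.0, 2.0, 2.0)
        vol = phantom.render_blob(spec, (11, 11, 11))
        field = compute_hessian(vol)
        m = field.matrices()[5, 5, 5]
        assert np.all(np.linalg.eigvalsh(m) < 0)
        # isotropic peak: diagonal entries equal, off-diagonals negligible
        assert np.allclose(np.diag(m), m[0, 0], rtol=1e-6)
        assert np.allclose(m - np.diag(np.diag(m)), 0.0, atol=1e-9)

    def test_small_volume_rejected(self):
        with pytest.raises(ValueError):
            compute_hessian(np.zeros((2, 5, 5)))

    def test_antisymmetry_of_inversion(self, small_phantom):
        f = small_phantom.image.astype(np.float64)
        h1 = compute_hessian(1.0 - f).h
        h2 = -compute_hessian(f).h
        assert np.allclose(h1, h2, atol=1e-12)


class TestConvexityIndicator:
    def test_diag_negative_definite_everywhere(self):
        mats = np.tile(np.diag([-1.0, -1.0, -1.0]), (10, 1, 1))
        assert convexity_indicator(field_from_matrices(mats)).all()

    def test_indefinite_rejected(self):
        mats = np.tile(np.diag([-1.0, -1.0, 1.0]), (10, 1, 1))
        assert not convexity_indicator(field_from_matrices(mats)).any()

    def test_sylvester_matches_eigenvalue_oracle(self):
        """10^4 random symmetric matrices, including near-singular ones."""
        rng = np.random.default_rng(0)
        m = rng.normal(0, 1, (10_000, 3, 3))
        m = (m + m.transpose(0, 2, 1)) / 2
        m[::7] *= 1e-6  # near-singular block
        m[::11] -= 2 * np.eye(3)  # enrich the negative-definite class
        field = field_from_matrices(m)
        ours = negative_definite(field).ravel()
        oracle = np.all(np.linalg.eigvalsh(m) < 0, axis=1)
        assert np.array_equal(ours, oracle)

    def test_constant_volume_has_empty_mask(self):
        assert convexity_count(convexity_mask_of_image(np.full((8, 8, 8), 0.3))) == 0

    def test_interior_count_on_concave_quadratic(self):
        i, j, k = grid((5, 5, 5))
        f = -(i**2 + j**2 + k**2)
        mask = convexity_indicator(compute_hessian(f))
        assert convexity_count(mask) == 27  # the 3^3 interior

    def test_inverted_and_plain_masks_disjoint(self, small_phantom):
        a = convexity_mask_of_image(small_phantom.image, invert=True)
        b = convexity_mask_of_image(small_phantom.image, invert=False)
        assert not np.any(a & b)

    def test_clean_phantom_mask_covers_blobs(self, small_phantom):
        from blobcut import identify

        conv = convexity_mask_of_image(small_phantom.image, invert=True)
        n = identify.connected_components(conv, min_size=1).count
        assert n >= small_phantom.n_blobs

    def test_noise_adds_convex_voxels(self, noisy_pair):
        ph, noisy = noisy_pair
        c_clean = convexity_count(convexity_mask_of_image(ph.image, invert=True))
        c_noisy = convexity_count(convexity_mask_of_image(noisy, invert=True))
        assert c_clean <= c_noisy

    def test_adding_blobs_never_decreases_convexity_count(self):
        ph = phantom.compose_phantom((16, 32, 32), (8, 8), (0.8, 1.5), seed=13)
        shape = ph.image.shape
        field = np.zeros(shape)
        counts = []
        for spec in ph.blobs:
            np.maximum(field, phantom.render_blob(spec, shape), out=field)
            img = 1.0 - np.clip(field, 0, 1)
            counts.append(convexity_count(convexity_mask_of_image(img, invert=True)))
        assert np.all(np.diff(counts) >= 0)


class TestBlobness:
    def test_isotropic_voxel_scores_one(self):
        mats = np.array([np.diag([-l, -l, -l]) for l in (0.5, 1.0, 4.0)])
        v = blobness_voxelwise(field_from_matrices(mats)).ravel()
        assert np.allclose(v, 1.0, atol=1e-12)

    def test_anisotropic_voxel_value(self):
        # diag(-4,-1,-1): 3*|det|^(2/3)/pm = 3*4^(2/3)/9
        mats = np.diag([-4.0, -1.0, -1.0])[None]
        v = blobness_voxelwise(field_from_matrices(mats)).ravel()[0]
        assert v == pytest.approx(3 * 4 ** (2 / 3) / 9, rel=1e-9)
        assert v == pytest.approx(0.8399, abs=5e-4)

    def test_bounded_in_unit_interval_and_one_iff_isotropic(self):
        rng = np.random.default_rng(4)
        lams = rng.uniform(0.1, 5.0, (500, 3))
        mats = np.array([np.diag(-l) for l in lams])
        v = blobness_voxelwise(field_from_matrices(mats)).ravel()
        assert np.all((v > 0) & (v <= 1.0 + 1e-12))
        iso = np.isclose(lams, lams[:, :1]).all(axis=1)
        assert np.allclose(v[iso], 1.0)
        assert np.all(v[~iso] < 1.0 - 1e-9)

    def test_nan_outside_negative_definite(self):
        mats = np.diag([1.0, -1.0, -1.0])[None]
        assert np.isnan(blobness_voxelwise(field_from_matrices(mats))).all()

    def test_blob_score_on_rendered_blob(self):
        spec = phantom.BlobSpec((6.0, 6.0, 6.0), 0.0, 0.0, 1.4, 1.4, 1.4)
        vol = 1.0 - phantom.render_blob(spec, (13, 13, 13))
        pts = phantom.blob_support(spec, (13, 13, 13))
        s = blobness(vol, pts, mode="center")
        assert s == pytest.approx(1.0, abs=1e-6)  # isotropic curvature at center

    def test_undefined_score_is_nan(self):
        vol = np.full((8, 8, 8), 0.5)
        assert np.isnan(blobness(vol, np.array([[4, 4, 4]])))

    def test_empty_voxel_set_rejected(self):
        with pytest.raises(ValueError):
            blobness(np.zeros((8, 8, 8)), np.empty((0, 3)))
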