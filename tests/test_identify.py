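"""Blob identification: masks, joint operation, connected components."""

import numpy as np
import pytest

from blobcut import hessian, identify, phantom
from blobcut.identify import blob_mask, connected_components, detect, joint_mask


def bfs_components(mask: np.ndarray, connectivity: int) -> list[frozenset]:
    """Flood-fill reference labeling; returns the partition as voxel sets."""
    if connectivity == 26:
        offs = [
            (dz, dy, dx)
            for dz in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    else:
        offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    mask = np.asarray(mask) > 0
    seen = np.zeros_like(mask)
    comps = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        stack, comp = [start], set()
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.add(v)
            for dz, dy, dx in offs:
                w = (v[0] + dz, v[1] + dy, v[2] + dx)
                if all(0 <= w[i] < mask.shape[i] for i in range(3)) and mask[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(frozenset(comp))
    return comps


class TestMasks:
    def test_all_bright_volume_gives_empty_blob_mask(self):
        assert not blob_mask(np.ones((6, 6, 6)), 0.5).any()

    def test_threshold_monotonicity(self, noisy_pair):
        _, noisy = noisy_pair
        lo = blob_mask(noisy, 0.3)
        hi = blob_mask(noisy, 0.7)
        assert np.all(hi >= lo)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            blob_mask(np.zeros((4, 4, 4)), 1.5)

    def test_joint_mask_identity_and_disjoint(self):
        rng = np.random.default_rng(0)
        m = (rng.random((5, 6, 7)) > 0.5).astype(np.uint8)
        ones = np.ones_like(m)
        assert np.array_equal(joint_mask(ones, m), m)
        assert not joint_mask(m, 1 - m).any()

    def test_joint_mask_shape_mismatch(self):
        with pytest.raises(ValueError):
            joint_mask(np.zeros((4, 4, 4)), np.zeros((4, 4, 5)))


class TestConnectedComponents:
    def test_corner_touching_voxels(self):
        m = np.zeros((4, 4, 4), dtype=np.uint8)
        m[1, 1, 1] = m[2, 2, 2] = 1  # share only a corner
        assert connected_components(m, connectivity=26, min_size=1).count == 1
        assert connected_components(m, connectivity=6, min_size=1).count == 2

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(3)
        for _ in range(100):
            m = rng.random((8, 16, 16)) < rng.uniform(0.05, 0.3)
            res = connected_components(m, connectivity=connectivity, min_size=1)
            ours = [
                frozenset(zip(*np.nonzero(res.labels == lab)))
                for lab in range(1, res.count + 1)
            ]
            oracle = bfs_components(m, connectivity)
            assert res.count == len(oracle)
            assert set(ours) == set(oracle)

    def test_26_count_never_exceeds_6_count(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            m = rng.random((8, 12, 12)) < 0.2
            n26 = connected_components(m, connectivity=26, min_size=1).count
            n6 = connected_components(m, connectivity=6, min_size=1).count
            assert n26 <= n6

    def test_min_size_filter_and_count_consistency(self):
        m = np.zeros((6, 6, 6), dtype=np.uint8)
        m[1, 1, 1] = 1  # singleton, dropped at min_size=2
        m[3, 3, 3] = m[3, 3, 4] = 1
        res = connected_components(m, min_size=2)
        assert res.count == 1
        assert len(res.table) == res.count
        assert res.labels.max() == res.count
        assert np.count_nonzero(res.mask) == 2

    def test_centroids_inside_component_bounding_box(self):
        rng = np.random.default_rng(5)
        m = rng.random((10, 14, 14)) < 0.15
        res = connected_components(m, min_size=1)
        for _, row in res.table.iterrows():
            sel = res.labels == row["label"]
            zz, yy, xx = np.nonzero(sel)
            assert zz.min() <= row["z"] <= zz.max()
            assert yy.min() <= row["y"] <= yy.max()
            assert xx.min() <= row["x"] <= xx.max()


class TestDetect:
    def test_single_blob_identity_translation(self):
        spec = phantom.BlobSpec((8.0, 8.0, 8.0), 0.0, 0.0, 1.5, 1.5, 1.5)
        vol = 1.0 - phantom.render_blob(spec, (17, 17, 17))
        res = detect(vol, None)
        assert res.count == 1
        assert np.allclose(res.centroids[0], (8, 8, 8), atol=0.75)

    def test_constant_volume_yields_no_detections(self):
        res = detect(np.ones((8, 8, 8), dtype=np.float32), None)
        assert res.count == 0

    def test_final_mask_subset_of_both_masks(self, noisy_pair):
        _, noisy = noisy_pair
        res = detect(noisy, None)
        conv = hessian.convexity_mask_of_image(noisy, invert=True)
        bm = blob_mask(noisy, 0.5)
        assert np.all(res.mask <= conv)
        assert np.all(res.mask <= bm)

    def test_overlapping_blobs_separated_by_joint_mask(self):
        """Three overlapping blobs merge in the dark mask but stay distinct
        in the convexity mask, so the joint mask identifies all four blobs."""
        shape = (16, 28, 28)
        specs = [
            phantom.BlobSpec((8.0, 8.0, 8.0), 0.0, 0.0, 1.5, 1.5, 1.5),
            phantom.BlobSpec((8.0, 8.0, 10.5), 0.0, 0.0, 1.5, 1.5, 1.5),
            phantom.BlobSpec((8.0, 10.5, 8.0), 0.0, 0.0, 1.5, 1.5, 1.5),
            phantom.BlobSpec((8.0, 20.0, 20.0), 0.0, 0.0, 1.5, 1.5, 1.5),
        ]
        field = np.zeros(shape)
        for s in specs:
            np.maximum(field, phantom.render_blob(s, shape), out=field)
        img = 1.0 - np.clip(field, 0, 1)
        n_dark = connected_components(blob_mask(img, 0.5), min_size=1).count
        res = detect(img, None)
        assert n_dark == 2  # under-segmented dark mask
        assert res.count == 4  # joint operation separates them

    def test_blobness_attached_to_detections(self, small_phantom):
        res = detect(small_phantom.image, None)
        scores = res.table["blobness"].to_numpy(dtype=float)
        finite = scores[np.isfinite(scores)]
        assert len(finite) > 0
        assert np.all((finite > 0) & (finite <= 1.0 + 1e-9))
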