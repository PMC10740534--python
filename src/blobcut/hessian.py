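"""Per-voxel Hessian analysis: convexity masks and blobness scoring.

A voxel of a volume ``f`` is *convex* (peak-like) when the 3x3 Hessian of
second partial derivatives at that voxel is negative definite.  Because the
blobs of interest are dark on a bright background, convexity is evaluated on
the inverted image ``J - f`` (J the all-ones volume), whose Hessian is exactly
``-H(f)``.

Negative definiteness is decided by Sylvester's criterion on the leading
principal minors (m1 < 0, m2 > 0, m3 < 0), which vectorizes to O(1) work per
voxel; an eigenvalue-based test is used as an independent oracle in the test
suite.

The blobness of a convex voxel is

    3 * |det H|^(2/3) / pm(H),    pm = sum of the three 2x2 principal minors.

Writing the (negative) eigenvalues as -l1, -l2, -l3, this equals the ratio of
the geometric to the arithmetic mean of the pairwise products l_i l_j, so it
lies in (0, 1] with equality iff the curvature is isotropic.  Per-blob scores
aggregate per-voxel values over the blob's convex voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "HessianField",
    "compute_hessian",
    "negative_definite",
    "convexity_indicator",
    "convexity_mask_of_image",
    "convexity_count",
    "blobness_voxelwise",
    "blobness",
]

# Index order of the six unique Hessian components, axes (0, 1, 2) = (z, y, x).
_COMPONENTS = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))

_D2 = np.array([1.0, -2.0, 1.0])  # second derivative, same axis
_D1 = np.array([0.5, 0.0, -0.5])  # first derivative, central


@dataclass
class HessianField:
    """Unique components of per-voxel symmetric 3x3 Hessians.

    ``h`` has shape (6,) + volume shape, ordered (00, 01, 02, 11, 12, 22);
    ``valid`` flags interior voxels (the 1-voxel border, where the finite
    difference stencil leans on replicated edge values, is excluded).
    """

    h: np.ndarray
    valid: np.ndarray

    @property
    def shape(self) -> tuple[int, ...]:
        return self.h.shape[1:]

    def matrices(self) -> np.ndarray:
        """Full per-voxel 3x3 matrices, shape = volume shape + (3, 3)."""
        m = np.empty(self.shape + (3, 3), dtype=self.h.dtype)
        for k, (i, j) in enumerate(_COMPONENTS):
            m[..., i, j] = self.h[k]
            m[..., j, i] = self.h[k]
        return m

    def __neg__(self) -> "HessianField":
        return HessianField(-self.h, self.valid)


def compute_hessian(volume: np.ndarray) -> HessianField:
    """Second-order central-difference Hessian of a 3D volume.

    Same-axis second derivatives use the compact [1, -2, 1] stencil; mixed
    partials apply the central first-difference along each of the two axes,
    which keeps the matrix symmetric by construction.  Edges are replicated;
    the 1-voxel border is flagged invalid.  Exact for quadratic polynomials
    at interior voxels.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3 or min(volume.shape) < 3:
        raise ValueError(f"need a 3D volume with >=3 voxels per axis, got shape {volume.shape}")
    h = np.empty((6,) + volume.shape)
    for k, (i, j) in enumerate(_COMPONENTS):
        if i == j:
            h[k] = ndimage.correlate1d(volume, _D2, axis=i, mode="nearest")
        else:
            tmp = ndimage.correlate1d(volume, _D1, axis=i, mode="nearest")
            h[k] = ndimage.correlate1d(tmp, _D1, axis=j, mode="nearest")
    valid = np.zeros(volume.shape, dtype=bool)
    valid[1:-1, 1:-1, 1:-1] = True
    return HessianField(h=h, valid=valid)


def _minors(field: HessianField):
    """Leading principal minors m1, m2, m3 and the 2x2 principal-minor sum."""
    h00, h01, h02, h11, h12, h22 = field.h
    m1 = h00
    m2 = h00 * h11 - h01**2
    m3 = (
        h00 * (h11 * h22 - h12**2)
        - h01 * (h01 * h22 - h12 * h02)
        + h02 * (h01 * h12 - h11 * h02)
    )
    pm = (h00 * h11 - h01**2) + (h00 * h22 - h02**2) + (h11 * h22 - h12**2)
    return m1, m2, m3, pm


def negative_definite(field: HessianField) -> np.ndarray:
    """Boolean volume: True where the Hessian is negative definite.

    Sylvester's criterion on -H: the matrix is negative definite iff the
    leading principal minors alternate as m1 < 0, m2 > 0, m3 < 0.  Border
    voxels are always False.
    """
    m1, m2, m3, _ = _minors(field)
    return (m1 < 0) & (m2 > 0) & (m3 < 0) & field.valid


def convexity_indicator(field: HessianField) -> np.ndarray:
    """Binary (uint8) convexity mask of a Hessian field."""
    return negative_definite(field).astype(np.uint8)


def convexity_mask_of_image(volume: np.ndarray, invert: bool = True) -> np.ndarray:
    """Convexity mask of an image; with ``invert`` (default) of ``J - volume``.

    Inversion targets dark blobs: H(J - f) = -H(f), so a dark blob's core
    becomes a negative-definite (peak-like) region.
    """
    field = compute_hessian(volume)
    if invert:
        field = -field
    return convexity_indicator(field)


def convexity_count(mask: np.ndarray) -> int:
    """Number of foreground voxels of a convexity mask."""
    return int(np.count_nonzero(mask))


def blobness_voxelwise(field: HessianField) -> np.ndarray:
    """Per-voxel blobness of a (negative-definite) Hessian field.

    Returns NaN where the Hessian is not negative definite (the score is
    undefined there).  On negative-definite voxels the value lies in (0, 1].
    """
    _, _, m3, pm = _minors(field)
    nd = negative_definite(field)
    out = np.full(field.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        np.divide(3.0 * np.abs(m3) ** (2.0 / 3.0), pm, out=out, where=nd)
    out[~nd] = np.nan
    return out


def blobness(
    volume: np.ndarray,
    blob_voxels: np.ndarray,
    mode: str = "center",
    field: HessianField | None = None,
) -> float:
    """Blobness score of one blob of a normalized dark-blob volume.

    ``blob_voxels`` is an integer array (k, 3) of (z, y, x) voxel coordinates
    belonging to the blob.  The per-voxel score is computed on the inverted
    image's Hessian ``H(J - volume)`` and aggregated over the blob's
    negative-definite voxels:

    - ``mode='center'``: score of the negative-definite voxel nearest the
      blob's voxel centroid;
    - ``mode='mean'``: average of per-voxel scores.

    Returns NaN when the blob has no negative-definite voxel.  Pass a
    precomputed ``field`` (= H of the *inverted* volume) to amortize the
    Hessian over many blobs.
    """
    pts = np.asarray(blob_voxels, dtype=int).reshape(-1, 3)
    if pts.shape[0] == 0:
        raise ValueError("blob_voxels is empty")
    if field is None:
        field = compute_hessian(1.0 - np.asarray(volume, dtype=np.float64))
    scores = blobness_voxelwise(field)
    vals = scores[pts[:, 0], pts[:, 1], pts[:, 2]]
    ok = np.isfinite(vals)
    if not ok.any():
        return float("nan")
    if mode == "mean":
        return float(vals[ok].mean())
    if mode == "center":
        centroid = pts.mean(axis=0)
        good = pts[ok]
        dist = np.linalg.norm(good - centroid, axis=1)
        return float(vals[ok][np.argmin(dist)])
    raise ValueError(f"unknown aggregation mode {mode!r}")
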