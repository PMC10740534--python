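"""Final blob identification.

The Hessian convexity mask over-segments (noise voxels can be locally convex)
while the translated blob mask under-segments (overlapping blobs merge into
one dark region).  Their voxelwise intersection keeps only voxels that are
both dark in the translated image and peak-like in the input, which separates
touching blobs while suppressing noise.  Blobs are the 26-connected
components of that joint mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import hessian

__all__ = [
    "DetectionResult",
    "blob_mask",
    "joint_mask",
    "connected_components",
    "detect",
]

#: full 3x3x3 neighborhood -> 26-connectivity
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class DetectionResult:
    """Labeled blob detections for one volume.

    ``mask`` is the final binary identification mask, ``labels`` the int32
    component labeling (0 = background), ``table`` one row per blob with
    voxel count, centroid (z, y, x) and blobness, and ``count`` the total
    number of detected blobs (N_glom).
    """

    mask: np.ndarray
    labels: np.ndarray
    table: pd.DataFrame
    count: int
    translated: np.ndarray | None = None
    convexity_mask: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    @property
    def centroids(self) -> np.ndarray:
        """Blob centroids, shape (count, 3), (z, y, x) order."""
        return self.table[["z", "y", "x"]].to_numpy(dtype=float).reshape(-1, 3)


def blob_mask(translated_volume: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary mask of dark objects: voxels with intensity below ``threshold``."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return (np.asarray(translated_volume) < threshold).astype(np.uint8)


def joint_mask(convexity_mask: np.ndarray, blob_mask: np.ndarray) -> np.ndarray:
    """Hadamard (voxelwise AND) product of the two binary masks."""
    convexity_mask = np.asarray(convexity_mask)
    blob_mask = np.asarray(blob_mask)
    if convexity_mask.shape != blob_mask.shape:
        raise ValueError(
            f"shape mismatch: {convexity_mask.shape} vs {blob_mask.shape}"
        )
    return ((convexity_mask > 0) & (blob_mask > 0)).astype(np.uint8)


def connected_components(
    mask: np.ndarray,
    connectivity: int = 26,
    min_size: int = 2,
    volume: np.ndarray | None = None,
    blobness_mode: str = "center",
) -> DetectionResult:
    """Label connected foreground components and summarize each blob.

    Components smaller than ``min_size`` voxels are treated as residual noise
    and dropped (the final mask is updated accordingly, so it stays a subset
    of the input mask).  When ``volume`` (the original dark-blob image) is
    given, each blob receives a blobness score from the inverted image's
    Hessian.
    """
    if connectivity not in (6, 26):
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    struct = _STRUCT26 if connectivity == 26 else _STRUCT6
    mask = (np.asarray(mask) > 0)
    labels, n = ndimage.label(mask, structure=struct)

    if n and min_size > 1:
        sizes = np.bincount(labels.ravel(), minlength=n + 1)
        keep = np.flatnonzero(sizes[1:] >= min_size) + 1
        relabel = np.zeros(n + 1, dtype=np.int32)
        relabel[keep] = np.arange(1, len(keep) + 1, dtype=np.int32)
        labels = relabel[labels]
        n = len(keep)
    labels = labels.astype(np.int32)
    final = (labels > 0).astype(np.uint8)

    inv_field = None
    if volume is not None:
        inv_field = hessian.compute_hessian(1.0 - np.asarray(volume, dtype=np.float64))

    rows = []
    if n:
        idx = np.arange(1, n + 1)
        centroids = ndimage.center_of_mass(final, labels, idx)
        sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
        objects = ndimage.find_objects(labels)
        for lab, (cz, cy, cx), size, sl in zip(idx, centroids, sizes, objects):
            score = np.nan
            if inv_field is not None:
                zz, yy, xx = np.nonzero(labels[sl] == lab)
                pts = np.stack(
                    [zz + sl[0].start, yy + sl[1].start, xx + sl[2].start], axis=1
                )
                score = hessian.blobness(
                    volume, pts, mode=blobness_mode, field=inv_field
                )
            rows.append(
                {"label": int(lab), "voxels": int(size), "z": cz, "y": cy, "x": cx,
                 "blobness": score}
            )
    table = pd.DataFrame(rows, columns=["label", "voxels", "z", "y", "x", "blobness"])
    return DetectionResult(mask=final, labels=labels, table=table, count=int(n))


def detect(
    volume: np.ndarray,
    translator=None,
    *,
    threshold: float = 0.5,
    connectivity: int = 26,
    min_size: int = 2,
    invert: bool = True,
    blobness_mode: str = "center",
) -> DetectionResult:
    """End-to-end identification on one volume.

    ``translator`` maps a volume to its denoised version (e.g. a trained
    ``BlobTranslator.translate``); ``None`` uses the identity, i.e. detection
    on the raw input.  Pipeline: inverted-image convexity mask of the input,
    translate, dark-object blob mask, Hadamard intersection, 26-connected
    component labeling with per-blob blobness from the input volume.
    """
    volume = np.asarray(volume, dtype=np.float32)
    conv = hessian.convexity_mask_of_image(volume, invert=invert)
    translated = volume if translator is None else np.asarray(translator(volume))
    if translated.shape != volume.shape:
        raise ValueError(
            f"translator changed shape: {volume.shape} -> {translated.shape}"
        )
    bm = blob_mask(translated, threshold)
    mf = joint_mask(conv, bm)
    result = connected_components(
        mf, connectivity=connectivity, min_size=min_size, volume=volume,
        blobness_mode=blobness_mode,
    )
    result.translated = translated
    result.convexity_mask = conv
    result.params = {
        "threshold": threshold,
        "connectivity": connectivity,
        "min_size": min_size,
        "invert": invert,
    }
    return result
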