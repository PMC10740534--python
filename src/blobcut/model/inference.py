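"""Preprocessing, translation and whole-volume patch/stitch inference."""

from __future__ import annotations

import numpy as np

from ..nn import Tensor

__all__ = ["preprocess", "postprocess", "patch_and_stitch"]


def _upsample2_axis(vol: np.ndarray, axis: int) -> np.ndarray:
    """Linear x2 upsampling along one axis; even samples hit the input grid."""
    vol = np.moveaxis(vol, axis, 0)
    n = vol.shape[0]
    out = np.empty((2 * n,) + vol.shape[1:], dtype=vol.dtype)
    out[0::2] = vol
    out[1:-1:2] = 0.5 * (vol[:-1] + vol[1:])
    out[-1] = vol[-1]  # replicate beyond the last sample
    return np.moveaxis(out, 0, axis)


def _resize_dyadic(vol: np.ndarray, factor: int) -> np.ndarray:
    if factor < 1 or factor & (factor - 1):
        raise ValueError(f"resize factor must be a power of two, got {factor}")
    while factor > 1:
        for ax in range(3):
            vol = _upsample2_axis(vol, ax)
        factor //= 2
    return vol


def preprocess(volume: np.ndarray, factor: int = 2) -> tuple[np.ndarray, dict]:
    """Trilinear upsample by ``factor`` and min-max normalize to [0, 1].

    The upsampling grid is aligned so that every ``factor``-th voxel
    coincides with an input voxel, making :func:`postprocess` an exact
    inverse for unchanged volumes.  Returns the model-ready (1, D, H, W)
    float32 array and the metadata needed to invert the transform; a
    constant volume (degenerate range) maps to all zeros.
    """
    volume = np.asarray(volume, dtype=np.float32)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {volume.shape}")
    up = _resize_dyadic(volume, factor)
    vmin, vmax = float(up.min()), float(up.max())
    scale = vmax - vmin
    norm = (up - vmin) / scale if scale > 0 else np.zeros_like(up)
    meta = {"orig_shape": volume.shape, "factor": factor, "vmin": vmin, "vmax": vmax}
    return norm[None].astype(np.float32), meta


def postprocess(volume01: np.ndarray, meta: dict) -> np.ndarray:
    """Inverse-resize a [0, 1] volume back to the original grid."""
    vol = np.asarray(volume01, dtype=np.float32)
    if vol.ndim == 4:
        vol = vol[0]
    f = meta["factor"]
    if f != 1:
        vol = vol[::f, ::f, ::f]
    if vol.shape != tuple(meta["orig_shape"]):
        raise ValueError(
            f"cannot invert resize: got {vol.shape}, expected {meta['orig_shape']}"
        )
    scale = meta["vmax"] - meta["vmin"]
    if scale > 0:
        vol = vol * scale + meta["vmin"]
    else:
        vol = vol + meta["vmin"]
    return np.clip(vol, 0.0, 1.0)


def run_generator(generator, volume: np.ndarray, factor: int = 2) -> np.ndarray:
    """preprocess -> generator -> map tanh output to [0, 1] -> inverse resize."""
    x, meta = preprocess(volume, factor)
    y = generator(Tensor(x))
    y01 = (y.data + 1.0) * 0.5
    return postprocess(y01, meta).astype(np.float32)


def patch_and_stitch(
    translate_fn,
    volume: np.ndarray,
    patch_shape: tuple[int, int, int] = (32, 64, 64),
) -> np.ndarray:
    """Tile a large volume into non-overlapping patches, translate, reassemble.

    The volume shape must be an exact multiple of ``patch_shape`` per axis
    (no implicit padding); a 256^3 volume with the default (z, y, x) patch
    shape of (32, 64, 64) yields 8 * 4 * 4 = 128 patches.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {volume.shape}")
    for ax, (n, p) in enumerate(zip(volume.shape, patch_shape)):
        if n % p != 0:
            raise ValueError(
                f"axis {ax}: size {n} is not divisible by patch size {p}"
            )
    out = np.empty_like(volume, dtype=np.float32)
    nz, ny, nx = (n // p for n, p in zip(volume.shape, patch_shape))
    pz, py, px = patch_shape
    for iz in range(nz):
        for iy in range(ny):
            for ix in range(nx):
                sl = (
                    slice(iz * pz, (iz + 1) * pz),
                    slice(iy * py, (iy + 1) * py),
                    slice(ix * px, (ix + 1) * px),
                )
                patch = translate_fn(volume[sl])
                if np.shape(patch) != patch_shape:
                    raise ValueError(
                        f"translator returned shape {np.shape(patch)}, expected {patch_shape}"
                    )
                out[sl] = patch
    return out
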