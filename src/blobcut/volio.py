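"""Volume I/O: NIfTI (canonical interchange) and multi-page TIFF stacks.

Arrays are (z, y, x) throughout the package.  NIfTI stores fastest-varying
axis first, so volumes are transposed on the way in/out such that a TIFF
stack of k pages of r x c pixels and the equivalent NIfTI file both load as
shape (k, r, c).  Masks are written as uint8 {0, 1}, images as float32,
label volumes as int32; no implicit intensity normalization is applied.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

__all__ = ["read_volume", "write_volume"]

_DTYPES = {"float32": np.float32, "uint8": np.uint8, "int32": np.int32}


class VolumeFormatError(ValueError):
    """Unrecognized or unreadable volume file."""


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def _is_tiff(path: Path) -> bool:
    return path.suffix.lower() in (".tif", ".tiff")


def read_volume(path: str | Path) -> np.ndarray:
    """Read a 3D volume as a (z, y, x) array; floats are cast to float32."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        vol = np.transpose(data, (2, 1, 0))
    elif _is_tiff(path):
        vol = tifffile.imread(str(path))
    else:
        raise VolumeFormatError(f"unrecognized volume format: {path}")
    if vol.ndim != 3:
        raise VolumeFormatError(f"expected a 3D volume in {path}, got shape {vol.shape}")
    if np.issubdtype(vol.dtype, np.floating):
        vol = vol.astype(np.float32)
    return vol


def write_volume(volume: np.ndarray, path: str | Path, dtype: str = "float32") -> None:
    """Write a (z, y, x) volume; format chosen from the file extension."""
    path = Path(path)
    if dtype not in _DTYPES:
        raise ValueError(f"dtype must be one of {sorted(_DTYPES)}, got {dtype!r}")
    vol = np.asarray(volume).astype(_DTYPES[dtype])
    if vol.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {vol.shape}")
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        img = nib.Nifti1Image(np.transpose(vol, (2, 1, 0)), affine=np.eye(4))
        nib.save(img, str(path))
    elif _is_tiff(path):
        tifffile.imwrite(str(path), vol, photometric="minisblack")
    else:
        raise VolumeFormatError(f"unrecognized volume format: {path}")
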