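"""File I/O for the standard formats the pipeline exchanges.

DWI volumes, masks and derived maps go through NIfTI-1 (nibabel) with the
acquisition scheme in FSL-style ``.bval``/``.bvec`` sidecars; fluorescence
channels are single-page grayscale TIFFs (tifffile); truths and summaries
are JSON/CSV.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .tensor_model import (
    AcquisitionScheme,
    DiffusionTensorField,
    DWIVolume,
    read_scheme,
    write_scheme,
)

__all__ = [
    "save_dwi",
    "load_dwi",
    "save_mask",
    "load_mask",
    "save_tensor_field",
    "save_scalar_map",
    "save_channel_tiff",
    "load_channel_tiff",
]

# lower-triangular component order used in the tensor NIfTI, noted in the
# header description
_TENSOR_NIFTI_ORDER = "Dxx Dxy Dyy Dxz Dyz Dzz"


def _affine(voxel_size) -> np.ndarray:
    return np.diag([voxel_size[0], voxel_size[1], voxel_size[2], 1.0])


def save_dwi(dwi: DWIVolume, out_prefix: str | Path) -> dict[str, Path]:
    """Write a DWI volume as ``<prefix>.nii.gz`` + ``.bval``/``.bvec``."""
    prefix = Path(out_prefix)
    nii = prefix.with_suffix(".nii.gz")
    img = nib.Nifti1Image(dwi.data.astype(np.float32), _affine(dwi.voxel_size))
    nib.save(img, nii)
    bval = prefix.with_suffix(".bval")
    bvec = prefix.with_suffix(".bvec")
    write_scheme(dwi.scheme, bval, bvec)
    return {"nifti": nii, "bval": bval, "bvec": bvec}


def load_dwi(
    nifti_path: str | Path,
    bval_path: str | Path | None = None,
    bvec_path: str | Path | None = None,
    scheme: AcquisitionScheme | None = None,
) -> DWIVolume:
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    if scheme is None:
        if bval_path is None or bvec_path is None:
            raise ValueError("need bval/bvec paths or an explicit scheme")
        scheme = read_scheme(bval_path, bvec_path)
    return DWIVolume(data=data, voxel_size=voxel_size, scheme=scheme)


def save_mask(mask: np.ndarray, voxel_size, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(voxel_size))
    nib.save(img, path)
    return path


def load_mask(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    return (
        np.asarray(img.dataobj) > 0,
        tuple(float(z) for z in img.header.get_zooms()[:3]),
    )


def save_tensor_field(
    tf: DiffusionTensorField, voxel_size, path: str | Path
) -> Path:
    """Write the tensor field as a 6-component 4-D NIfTI (lower-triangular
    order, documented in the header description)."""
    t = tf.tensors
    lower = np.stack(
        [t[..., 0], t[..., 3], t[..., 1], t[..., 4], t[..., 5], t[..., 2]], axis=-1
    )
    img = nib.Nifti1Image(lower.astype(np.float32), _affine(voxel_size))
    img.header["descrip"] = _TENSOR_NIFTI_ORDER.encode()
    nib.save(img, str(path))
    return Path(path)


def save_scalar_map(data: np.ndarray, voxel_size, path: str | Path) -> Path:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_size))
    nib.save(img, str(path))
    return Path(path)


def save_channel_tiff(image: np.ndarray, path: str | Path) -> Path:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))
    return Path(path)


def load_channel_tiff(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=float)
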