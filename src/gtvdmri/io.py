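"""Reading and writing diffusion-weighted MRI volumes.

Volumes travel as NIfTI-1 images accompanied by FSL-style ``.bval``/``.bvec``
whitespace-separated text files. Intensities are always held as float64 in
memory regardless of the on-disk integer type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from os import PathLike
from typing import Union

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

PathType = Union[str, PathLike]

__all__ = [
    "GradientTable",
    "DWIVolume",
    "DWIFormatError",
    "InconsistentInputError",
    "read_dwi",
    "write_dwi",
]


class DWIFormatError(ValueError):
    """A file exists but is not in the expected format (e.g. non-4-D NIfTI)."""


class InconsistentInputError(ValueError):
    """Image and gradient files disagree on the number of volumes."""


def _normalize_bvecs(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Scale each diffusion-weighted direction to unit length.

    b=0 rows are kept as stored (their direction is physically undefined and
    must not be consumed downstream).
    """
    out = np.array(bvecs, dtype=np.float64)
    dw = bvals > 0
    norms = np.linalg.norm(out[dw], axis=1)
    if np.any(norms == 0):
        raise DWIFormatError("zero-length gradient direction for a b>0 volume")
    out[dw] /= norms[:, None]
    return out


@dataclass(frozen=True)
class GradientTable:
    """Per-volume diffusion weightings b_j (s/mm^2) and unit directions q̂_j.

    Directions of b>0 volumes are normalized to unit length on construction.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=np.float64))
        bvecs = np.atleast_2d(np.asarray(self.bvecs, dtype=np.float64))
        if bvals.ndim != 1 or bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise DWIFormatError("bvals must be (V,), bvecs must be (V, 3)")
        if len(bvals) != len(bvecs):
            raise InconsistentInputError(
                f"{len(bvals)} b-values but {len(bvecs)} gradient directions"
            )
        if np.any(bvals < 0):
            raise DWIFormatError("negative b-value")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", _normalize_bvecs(bvals, bvecs))

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def dw_mask(self) -> np.ndarray:
        """Boolean mask of diffusion-weighted (b > 0) volumes."""
        return self.bvals > 0

    @property
    def b0_mask(self) -> np.ndarray:
        return ~self.dw_mask


@dataclass
class DWIVolume:
    """A 4-D diffusion MRI dataset: X*Y*Z voxels by V volumes.

    ``data`` holds the signal S_{i,j}; ``voxel_size`` is mm per spatial axis.
    """

    data: np.ndarray
    gradients: GradientTable
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise DWIFormatError(f"expected 4-D data, got {self.data.ndim}-D")
        if self.data.shape[3] != len(self.gradients):
            raise InconsistentInputError(
                f"data has {self.data.shape[3]} volumes but gradient table "
                f"has {len(self.gradients)}"
            )
        self.voxel_size = np.asarray(self.voxel_size, dtype=np.float64).reshape(3)
        if np.any(self.voxel_size <= 0):
            raise DWIFormatError("voxel_size must be strictly positive")

    @property
    def shape(self) -> tuple:
        return self.data.shape


def _parse_bvecs(raw: np.ndarray) -> np.ndarray:
    """Return bvecs as (V, 3) from either FSL 3xV or transposed Vx3 layout."""
    arr = np.atleast_2d(np.asarray(raw, dtype=np.float64))
    if arr.shape[0] == 3 and arr.shape[1] == 3:
        # V == 3 is genuinely ambiguous; FSL convention is 3 rows of V entries.
        logger.warning("3x3 bvec file is ambiguous; assuming FSL 3xV layout")
        return arr.T
    if arr.shape[0] == 3:
        return arr.T
    if arr.shape[1] == 3:
        return arr
    raise DWIFormatError(f"bvec file has shape {arr.shape}, expected 3xV or Vx3")


def read_dwi(nifti_path: PathType, bval_path: PathType, bvec_path: PathType) -> DWIVolume:
    """Load a NIfTI volume plus FSL ``.bval``/``.bvec`` files into a :class:`DWIVolume`.

    Directions of b>0 volumes are unit-normalized; voxel size is taken from
    the NIfTI header zooms.
    """
    img = nib.load(str(nifti_path))
    if img.ndim != 4:
        raise DWIFormatError(f"expected a 4-D NIfTI image, got {img.ndim}-D")
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    bvals = np.atleast_1d(np.loadtxt(bval_path, dtype=np.float64))
    bvecs = _parse_bvecs(np.loadtxt(bvec_path, dtype=np.float64))
    if len(bvals) != data.shape[3] or len(bvecs) != data.shape[3]:
        raise InconsistentInputError(
            f"image has {data.shape[3]} volumes; bval/bvec have "
            f"{len(bvals)}/{len(bvecs)} entries"
        )
    voxel_size = np.asarray(img.header.get_zooms()[:3], dtype=np.float64)
    return DWIVolume(data, GradientTable(bvals, bvecs), voxel_size)


def write_dwi(
    vol: DWIVolume, nifti_path: PathType, bval_path: PathType, bvec_path: PathType
) -> None:
    """Write a :class:`DWIVolume` as NIfTI + FSL bval/bvec, round-trippable by :func:`read_dwi`."""
    affine = np.diag([*vol.voxel_size, 1.0])
    img = nib.Nifti1Image(vol.data, affine)
    img.header.set_zooms((*vol.voxel_size, 1.0))
    nib.save(img, str(nifti_path))
    np.savetxt(bval_path, vol.gradients.bvals[None, :], fmt="%.10g")
    # FSL convention: three rows of V entries.
    np.savetxt(bvec_path, vol.gradients.bvecs.T, fmt="%.17g")
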