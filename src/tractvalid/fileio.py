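"""NIfTI, FSL bvec/bval, TRK, and CSV readers/writers.

The voxel grid uses the convention that voxel ``(i, j, k)`` is centered at
world ``(i, j, k) * voxel_size`` mm, so volumes carry a diagonal affine with
zero offset and streamline points are already in this world frame.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import DwiVolume, GradientScheme
from .tracking import Streamline

__all__ = [
    "write_nifti",
    "read_nifti",
    "write_bvals_bvecs",
    "read_bvals_bvecs",
    "write_dwi",
    "read_dwi",
    "write_trk",
    "read_trk",
]


def _affine(voxel_size: float) -> np.ndarray:
    return np.diag([voxel_size, voxel_size, voxel_size, 1.0])


def write_nifti(path, array: np.ndarray, voxel_size: float = 1.0) -> None:
    data = np.asarray(array)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, _affine(voxel_size)), str(path))


def read_nifti(path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), float(img.header.get_zooms()[0])


def write_bvals_bvecs(prefix, scheme: GradientScheme) -> None:
    """FSL dialect: ``<prefix>.bval`` one row of b-values, ``<prefix>.bvec``
    three rows (x, y, z components)."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".bval"), scheme.bvalues[None], fmt="%.1f")
    np.savetxt(prefix.with_suffix(".bvec"), scheme.directions.T, fmt="%.8f")


def read_bvals_bvecs(bval_path, bvec_path) -> GradientScheme:
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    # tolerate non-unit vectors in external files by renormalizing DW rows
    dw = bvals > 0
    norms = np.linalg.norm(bvecs[dw], axis=1)
    if np.any(norms == 0):
        raise ValueError("diffusion-weighted bvec with zero norm")
    bvecs = bvecs.copy()
    bvecs[dw] /= norms[:, None]
    return GradientScheme(bvecs, bvals)


def write_dwi(out_dir, dwi: DwiVolume, stem: str = "dwi") -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_nifti(out_dir / f"{stem}.nii.gz", dwi.signal, dwi.voxel_size)
    write_bvals_bvecs(out_dir / stem, dwi.scheme)


def read_dwi(nii_path, bval_path, bvec_path) -> DwiVolume:
    signal, voxel_size = read_nifti(nii_path)
    return DwiVolume(np.asarray(signal, dtype=float), voxel_size,
                     read_bvals_bvecs(bval_path, bvec_path))


def write_trk(path, streamlines: list[Streamline], grid_shape, voxel_size: float) -> None:
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(s.points, dtype=np.float32) for s in streamlines],
        affine_to_rasmm=np.eye(4),
    )
    header = {
        "voxel_sizes": (voxel_size,) * 3,
        "dimensions": tuple(int(x) for x in grid_shape),
        "voxel_to_rasmm": _affine(voxel_size).astype(np.float32),
        "voxel_order": "RAS",
    }
    nib.streamlines.save(tractogram, str(path), header=header)


def read_trk(path) -> list[np.ndarray]:
    return [np.asarray(s) for s in nib.streamlines.load(str(path)).streamlines]
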