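"""Reading and writing of every on-disk artifact the pipeline touches.

All volumes are NIfTI-1 (``.nii``/``.nii.gz``); gradient tables are
FSL-dialect whitespace-separated text files (``.bval``: one row of N
b-values in s/mm^2; ``.bvec``: 3 rows by N columns of unit gradient
directions in image/voxel coordinates).  Eigenvalue/eigenvector fields use
the dtifit-style layout ``<prefix>_L1.nii.gz`` ... ``<prefix>_V3.nii.gz``.

The canonical diffusivity unit throughout the package is mm^2/s, so
healthy white matter has MD around 9e-4.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

#: b-values at or below this (s/mm^2) mark a volume as an unweighted baseline.
DEFAULT_LOW_B_CUTOFF = 50.0

_NIFTI_EXTS = (".nii.gz", ".nii")


@dataclass
class DWIVolume:
    """A diffusion-weighted acquisition: 4D signal plus its gradient table.

    Parameters
    ----------
    signal : ndarray, shape (x, y, z, n)
        Non-negative magnitude intensities, one 3D volume per gradient.
    bvals : ndarray, shape (n,)
        Diffusion weighting per volume, s/mm^2.
    bvecs : ndarray, shape (n, 3)
        Unit gradient directions in image/voxel coordinates (FSL
        convention); the zero vector is allowed for b~0 volumes.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform, mm.
    low_b_cutoff : float
        Volumes with b-value <= this are flagged as baselines.
    """

    signal: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    affine: np.ndarray
    low_b_cutoff: float = DEFAULT_LOW_B_CUTOFF

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        self.bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError(f"signal must be 4D, got {self.signal.ndim}D")
        n = self.signal.shape[3]
        if len(self.bvals) != n or self.bvecs.shape != (n, 3):
            raise ValueError(
                f"gradient table mismatch: image has {n} volumes, "
                f"{len(self.bvals)} b-values, {self.bvecs.shape[0]} b-vectors"
            )
        weighted = self.bvals > self.low_b_cutoff
        norms = np.linalg.norm(self.bvecs, axis=1)
        bad = np.flatnonzero(weighted & (np.abs(norms - 1.0) > 1e-3))
        if bad.size:
            raise ValueError(
                f"non-unit gradient directions at b>0 for volume indices {bad.tolist()}"
            )
        if np.any(self.voxel_size <= 0):
            raise ValueError("affine implies non-positive voxel size")

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[3]

    @property
    def baseline_mask(self) -> np.ndarray:
        """Boolean flag per volume: True where b <= low_b_cutoff."""
        return self.bvals <= self.low_b_cutoff

    @property
    def voxel_size(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]


@dataclass
class EigenField:
    """Per-voxel sorted eigenvalues and eigenvectors of the diffusion tensor.

    ``L1 >= L2 >= L3`` at every voxel (descending), diffusivities in mm^2/s.
    ``V1, V2, V3`` are (x, y, z, 3) unit-vector volumes.  ``clamped`` records
    whether negative (non-physical) eigenvalues have been zeroed.
    """

    L1: np.ndarray
    L2: np.ndarray
    L3: np.ndarray
    V1: np.ndarray
    V2: np.ndarray
    V3: np.ndarray
    affine: np.ndarray
    clamped: bool = False

    def __post_init__(self) -> None:
        shape = self.L1.shape
        for name in ("L2", "L3"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != L1 shape {shape}")
        for name in ("V1", "V2", "V3"):
            if getattr(self, name).shape != shape + (3,):
                raise ValueError(f"{name} must have shape {shape + (3,)}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.L1.shape

    def eigenvalues(self) -> np.ndarray:
        """Stacked (x, y, z, 3) eigenvalue array, descending along the last axis."""
        return np.stack([self.L1, self.L2, self.L3], axis=-1)


@dataclass
class Mask:
    """Binary region mask on the same grid as the volumes it selects from."""

    flags: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags).astype(bool)
        if self.flags.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def n_voxels(self) -> int:
        return int(self.flags.sum())


# ---------------------------------------------------------------------------
# DWI + gradient tables


def read_dwi(image_path, bval_path, bvec_path, low_b_cutoff: float = DEFAULT_LOW_B_CUTOFF) -> DWIVolume:
    """Load a 4D DWI NIfTI together with its FSL-dialect .bval/.bvec tables.

    Raises
    ------
    ValueError
        If the number of image volumes disagrees with the gradient table,
        or a diffusion-weighted direction is not unit norm.
    """
    img = nib.load(str(image_path))
    signal = np.asarray(img.dataobj)
    bvals = np.loadtxt(bval_path, ndmin=1).ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        # ambiguous square table; FSL dialect stores 3 rows x N columns
        bvecs = bvecs.T
    if signal.ndim != 4:
        raise ValueError(f"{image_path}: expected a 4D image, got {signal.ndim}D")
    if signal.shape[3] != len(bvals):
        raise ValueError(
            f"image has {signal.shape[3]} volumes but bval table lists {len(bvals)}"
        )
    return DWIVolume(signal, bvals, bvecs, img.affine, low_b_cutoff=low_b_cutoff)


def write_dwi(dwi: DWIVolume, image_path, bval_path, bvec_path) -> None:
    """Write a DWIVolume as NIfTI + FSL .bval/.bvec (3 rows x N columns)."""
    nib.save(nib.Nifti1Image(dwi.signal, dwi.affine), str(image_path))
    np.savetxt(bval_path, dwi.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, dwi.bvecs.T, fmt="%.17g")


# ---------------------------------------------------------------------------
# Eigenvalue / eigenvector fields (dtifit layout)

_COMPONENTS = ("L1", "L2", "L3", "V1", "V2", "V3")


def _find_component(prefix: str, name: str) -> str:
    for ext in _NIFTI_EXTS:
        path = f"{prefix}_{name}{ext}"
        if os.path.exists(path):
            return path
    raise FileNotFoundError(f"{name} not found: expected {prefix}_{name}.nii[.gz]")


def read_eigenfield(prefix) -> EigenField:
    """Read ``<prefix>_L1 .. <prefix>_V3`` NIfTI maps into an EigenField.

    Eigenvalues are re-sorted to descending order per voxel if the input
    violates it (the eigenvector volumes are permuted to match, and the
    number of re-sorted voxels is logged); affines must agree to 1e-4.
    """
    prefix = str(prefix)
    vols = {}
    affine = None
    for name in _COMPONENTS:
        img = nib.load(_find_component(prefix, name))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if affine is None:
            affine = img.affine
        elif not np.allclose(img.affine, affine, atol=1e-4):
            raise ValueError(f"{name} affine disagrees with L1 affine beyond 1e-4")
        vols[name] = data
    L = np.stack([vols["L1"], vols["L2"], vols["L3"]], axis=-1)
    V = np.stack([vols["V1"], vols["V2"], vols["V3"]], axis=-2)  # (...,3 eig,3 comp)
    order = np.argsort(-L, axis=-1, kind="stable")
    n_resorted = int(np.any(order != np.array([0, 1, 2]), axis=-1).sum())
    if n_resorted:
        logger.warning("re-sorted eigenvalues at %d voxels while reading %s", n_resorted, prefix)
        L = np.take_along_axis(L, order, axis=-1)
        V = np.take_along_axis(V, order[..., None], axis=-2)
    return EigenField(
        L1=L[..., 0], L2=L[..., 1], L3=L[..., 2],
        V1=V[..., 0, :], V2=V[..., 1, :], V3=V[..., 2, :],
        affine=affine, clamped=False,
    )


def write_eigenfield(ef: EigenField, prefix) -> None:
    """Write an EigenField in the dtifit-style ``<prefix>_L1..V3`` layout."""
    prefix = str(prefix)
    for name in ("L1", "L2", "L3"):
        nib.save(
            nib.Nifti1Image(getattr(ef, name).astype(np.float32), ef.affine),
            f"{prefix}_{name}.nii.gz",
        )
    for name in ("V1", "V2", "V3"):
        nib.save(
            nib.Nifti1Image(getattr(ef, name).astype(np.float32), ef.affine),
            f"{prefix}_{name}.nii.gz",
        )


# ---------------------------------------------------------------------------
# Scalar maps and masks


def write_scalar_map(volume: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a 3D scalar volume (FA, MD, RD, ...) as float32 NIfTI.

    NaN voxels (e.g. FA outside tissue) are preserved.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"scalar map must be 3D, got {volume.ndim}D")
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    nib.save(nib.Nifti1Image(volume.astype(np.float32), affine), str(path))


def read_scalar_map(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def read_mask(path) -> Mask:
    img = nib.load(str(path))
    return Mask(np.asarray(img.dataobj) > 0, img.affine)


def write_mask(mask: Mask, path) -> None:
    nib.save(nib.Nifti1Image(mask.flags.astype(np.uint8), mask.affine), str(path))
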