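"""Voxel-wise diffusion-tensor estimation and scalar diffusion metrics.

The diffusion tensor D is a symmetric 3x3 matrix per voxel; the
diffusion-weighted signal follows ``S_i = S0 * exp(-b_i g_i^T D g_i)``.
Taking logs makes the model linear in the six unique tensor components
and ln(S0), which is solved by ordinary least squares over all volumes
(an optional signal-weighted variant down-weights low-SNR measurements).

From the eigenvalues L1 >= L2 >= L3 the standard rotation-invariant
scalars are

    FA = sqrt( ((L1-L2)^2 + (L2-L3)^2 + (L1-L3)^2) / (2 (L1^2+L2^2+L3^2)) )
    MD = (L1 + L2 + L3) / 3
    RD = (L2 + L3) / 2

Noise and signal dropout can produce negative (non-physical) eigenvalues;
these are clamped to zero before any scalar map is computed, and the
fraction of affected voxels is a simple image-quality measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_dti import DWIVolume, EigenField, Mask

logger = logging.getLogger(__name__)

_COND_LIMIT = 1e8


@dataclass
class TensorField:
    """Fitted diffusion tensors: 6 unique components per voxel plus S0.

    ``D`` has shape (x, y, z, 6) ordered (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz),
    in mm^2/s; symmetry is guaranteed by construction.
    """

    D: np.ndarray
    S0: np.ndarray
    affine: np.ndarray

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.S0.shape

    def as_matrices(self) -> np.ndarray:
        """Expand to full symmetric (x, y, z, 3, 3) tensors."""
        xx, yy, zz, xy, xz, yz = np.moveaxis(self.D, -1, 0)
        M = np.empty(self.D.shape[:-1] + (3, 3), dtype=self.D.dtype)
        M[..., 0, 0] = xx
        M[..., 1, 1] = yy
        M[..., 2, 2] = zz
        M[..., 0, 1] = M[..., 1, 0] = xy
        M[..., 0, 2] = M[..., 2, 0] = xz
        M[..., 1, 2] = M[..., 2, 1] = yz
        return M


@dataclass
class ScalarMaps:
    """FA (unitless, NaN where the tensor vanishes), MD and RD (mm^2/s)."""

    FA: np.ndarray
    MD: np.ndarray
    RD: np.ndarray
    affine: np.ndarray


@dataclass
class QCReport:
    """Percentages of voxels whose pre-clamp eigenvalues are negative."""

    negative_fraction_L1: float
    negative_fraction_L2: float
    negative_fraction_L3: float
    n_voxels: int

    def as_dict(self) -> dict:
        return {
            "negative_fraction_L1_percent": self.negative_fraction_L1,
            "negative_fraction_L2_percent": self.negative_fraction_L2,
            "negative_fraction_L3_percent": self.negative_fraction_L3,
            "n_voxels": self.n_voxels,
        }


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows of the log-linear model: ln S = A @ [ln S0, Dxx..Dyz].

    Column order matches :class:`TensorField.D`; off-diagonal columns carry
    the factor 2 from expanding g^T D g.
    """
    b = np.asarray(bvals, dtype=float)
    g = np.asarray(bvecs, dtype=float)
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack([
        np.ones_like(b),
        -b * gx * gx,
        -b * gy * gy,
        -b * gz * gz,
        -2 * b * gx * gy,
        -2 * b * gx * gz,
        -2 * b * gy * gz,
    ])


def fit_tensor(dwi: DWIVolume, mask: Mask | None = None, weighted: bool = False) -> TensorField:
    """Fit the diffusion tensor voxel-by-voxel by log-linear least squares.

    Baseline (b~0) volumes are averaged into a single b=0 measurement
    before fitting.  Voxels containing non-positive signals are fitted on
    their strictly positive subset only (logged), or set to the zero
    tensor when fewer than 7 usable measurements remain.

    Parameters
    ----------
    dwi : DWIVolume
        At least 7 volumes including at least one baseline.
    mask : Mask, optional
        Restrict the fit to these voxels; outside voxels get zero tensors.
    weighted : bool
        If True, weight each log-signal equation by the signal amplitude
        (WLS), the usual variance-stabilizing choice for log-transformed
        Rician data.  Default is plain OLS.

    Raises
    ------
    ValueError
        Fewer than 7 volumes, no baseline volumes, a mask shape mismatch,
        or a (near-)singular gradient design.
    """
    if dwi.n_volumes < 7:
        raise ValueError(f"need at least 7 volumes to fit a tensor, got {dwi.n_volumes}")
    base = dwi.baseline_mask
    if not base.any():
        raise ValueError("no baseline (b~0) volumes in the acquisition")
    if mask is not None and mask.flags.shape != dwi.grid_shape:
        raise ValueError(
            f"mask shape {mask.flags.shape} does not match image grid {dwi.grid_shape}"
        )

    signal = np.asarray(dwi.signal, dtype=np.float64)
    # collapse the baseline volumes to their mean, keeping one b=0 row
    s0_mean = signal[..., base].mean(axis=-1)
    signal = np.concatenate([s0_mean[..., None], signal[..., ~base]], axis=-1)
    bvals = np.concatenate([[0.0], dwi.bvals[~base]])
    bvecs = np.vstack([[0.0, 0.0, 0.0], dwi.bvecs[~base]])

    A = design_matrix(bvals, bvecs)
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise ValueError(
            f"singular gradient design (condition number {cond:.3g}); "
            "directions do not span the space of symmetric tensors"
        )

    shape = dwi.grid_shape
    flat = signal.reshape(-1, signal.shape[-1])
    in_mask = (
        mask.flags.reshape(-1) if mask is not None else np.ones(flat.shape[0], dtype=bool)
    )
    positive = flat > 0
    clean = in_mask & positive.all(axis=1)

    coef = np.zeros((flat.shape[0], 7))
    if clean.any():
        # one shared pseudo-inverse covers every voxel with all-positive signal
        pinv = np.linalg.pinv(A)
        logs = np.log(flat[clean])
        if weighted:
            w = flat[clean]
            for row, (y, wi) in zip(np.flatnonzero(clean), zip(logs, w)):
                Aw = A * wi[:, None]
                coef[row] = np.linalg.lstsq(Aw, y * wi, rcond=None)[0]
        else:
            coef[clean] = logs @ pinv.T

    ragged = np.flatnonzero(in_mask & ~positive.all(axis=1))
    n_zeroed = 0
    for row in ragged:
        keep = positive[row]
        if keep.sum() < 7:
            n_zeroed += 1
            continue  # leave the zero tensor
        Ak = A[keep]
        y = np.log(flat[row, keep])
        if weighted:
            wk = flat[row, keep]
            Ak = Ak * wk[:, None]
            y = y * wk
        coef[row] = np.linalg.lstsq(Ak, y, rcond=None)[0]
    if ragged.size:
        logger.info(
            "%d voxels had non-positive signals (%d set to zero tensor)",
            ragged.size, n_zeroed,
        )

    S0 = np.exp(coef[:, 0]).reshape(shape)
    S0[~in_mask.reshape(shape)] = 0.0
    D = coef[:, 1:].reshape(shape + (6,))
    return TensorField(D=D, S0=S0, affine=dwi.affine)


def eigendecompose(tf: TensorField) -> EigenField:
    """Per-voxel symmetric eigendecomposition, eigenvalues sorted descending."""
    M = tf.as_matrices()
    w, v = np.linalg.eigh(M)  # ascending; v[..., :, k] is the k-th eigenvector
    w = w[..., ::-1]
    v = v[..., ::-1]
    return EigenField(
        L1=np.ascontiguousarray(w[..., 0]),
        L2=np.ascontiguousarray(w[..., 1]),
        L3=np.ascontiguousarray(w[..., 2]),
        V1=np.ascontiguousarray(v[..., :, 0]),
        V2=np.ascontiguousarray(v[..., :, 1]),
        V3=np.ascontiguousarray(v[..., :, 2]),
        affine=tf.affine,
        clamped=False,
    )


def clamp_negative(ef: EigenField) -> EigenField:
    """Zero all negative (non-physical) eigenvalues; eigenvectors untouched.

    Clamping at zero preserves the descending order, so the operation is
    idempotent and never increases any |L|.
    """
    return EigenField(
        L1=np.maximum(ef.L1, 0.0),
        L2=np.maximum(ef.L2, 0.0),
        L3=np.maximum(ef.L3, 0.0),
        V1=ef.V1, V2=ef.V2, V3=ef.V3,
        affine=ef.affine,
        clamped=True,
    )


def compute_scalars(ef: EigenField) -> ScalarMaps:
    """FA, MD and RD maps from a clamped EigenField.

    FA is NaN where all three eigenvalues vanish (no tissue signal);
    downstream display logic excludes those voxels.

    Raises
    ------
    ValueError
        If the field has not been clamped (negative eigenvalues would make
        FA ill-defined).
    """
    if not ef.clamped:
        raise ValueError("compute_scalars requires a clamped EigenField; call clamp_negative first")
    L1, L2, L3 = ef.L1, ef.L2, ef.L3
    sumsq = L1 ** 2 + L2 ** 2 + L3 ** 2
    num = (L1 - L2) ** 2 + (L2 - L3) ** 2 + (L1 - L3) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        FA = np.sqrt(num / (2.0 * sumsq))
    FA = np.where(sumsq > 0, FA, np.nan)
    MD = (L1 + L2 + L3) / 3.0
    RD = (L2 + L3) / 2.0
    return ScalarMaps(FA=FA, MD=MD, RD=RD, affine=ef.affine)


def qc_negative_fraction(ef_preclamp: EigenField, mask: Mask | None = None) -> QCReport:
    """Percentage of voxels with a negative pre-clamp eigenvalue, per map.

    Counts over the whole grid by default, or within ``mask`` if given.

    Raises
    ------
    ValueError
        If the field was already clamped (all fractions would be zero by
        construction, hiding the quality information).
    """
    if ef_preclamp.clamped:
        raise ValueError("qc_negative_fraction must run on the pre-clamp EigenField")
    if mask is not None:
        if mask.flags.shape != ef_preclamp.grid_shape:
            raise ValueError("mask shape does not match the eigenvalue grid")
        sel = mask.flags
    else:
        sel = np.ones(ef_preclamp.grid_shape, dtype=bool)
    n = int(sel.sum())
    if n == 0:
        raise ValueError("empty mask: no voxels to count")
    fracs = [100.0 * float((getattr(ef_preclamp, name)[sel] < 0).sum()) / n
             for name in ("L1", "L2", "L3")]
    return QCReport(*fracs, n_voxels=n)
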