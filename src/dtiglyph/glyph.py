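"""Per-voxel glyph coding: direction, length, opacity, color and display flag.

Each voxel is drawn as a line segment along the principal eigenvector V1.
Four scalar codings turn the raw tensor field into a readable image of
fibrous structures such as the optic nerve:

* length      = alpha * (L1 - RD)^2       -- long where diffusion is
                                             strongly directional
* opacity     = clip(beta * MD * FA, 0, 1) -- opaque where diffusion is
                                             strong and anisotropic
* color       = (clip(gamma * L1N, 0, 1), clip(1 - L1N, 0, 1), 0)
                where L1N = L1 / L1max    -- red/green balance encodes
                                             axial diffusivity
* display     = L1N > RDN + sigma         -- the threshold that removes
                                             weakly directional voxels

L1N and RDN share the common denominator L1max (the maximum axial
diffusivity over all voxels, or over a mask if given), so L1N - RDN is
proportional to the physical difference L1 - RD; the sigma threshold and
the atrophy score built on it are therefore comparable across regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_dti import EigenField, Mask
from .tensor import ScalarMaps

#: Defaults used for the published optic-nerve renderings.
DEFAULT_ALPHA = 250.0
DEFAULT_BETA = 1000.0
DEFAULT_GAMMA = 1.2
DEFAULT_SIGMA = 0.2
DEFAULT_N_LAYERS = 7

PLANES = ("transverse", "sagittal", "coronal")
#: Image axis dropped by each orthographic projection.
PLANE_DROP_AXIS = {"transverse": 2, "sagittal": 0, "coronal": 1}


@dataclass
class RenderParams:
    """The four algorithm parameters plus projection plane and layers.

    alpha : length scaling, display units per (mm^2/s)^2
    beta  : opacity scaling, s/mm^2
    gamma : red-channel gain, unitless
    sigma : display threshold on the normalized L1-RD difference, unitless
    plane : one of 'transverse', 'sagittal', 'coronal'
    layers: contiguous slice indices along the projection axis
    """

    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA
    gamma: float = DEFAULT_GAMMA
    sigma: float = DEFAULT_SIGMA
    plane: str = "transverse"
    layers: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma", "sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.plane not in PLANES:
            raise ValueError(f"plane must be one of {PLANES}, got {self.plane!r}")
        self.layers = tuple(int(i) for i in self.layers)

    @property
    def drop_axis(self) -> int:
        return PLANE_DROP_AXIS[self.plane]


@dataclass
class NormalizedMaps:
    """L1 and RD divided by the shared maximum axial diffusivity L1max."""

    L1N: np.ndarray
    RDN: np.ndarray
    L1max: float


@dataclass
class GlyphField:
    """Display primitives per voxel: direction (sign-free), length, opacity,
    RGB color, and the boolean display flag."""

    direction: np.ndarray  # (x, y, z, 3)
    length: np.ndarray
    opacity: np.ndarray
    rgb: np.ndarray  # (x, y, z, 3)
    display: np.ndarray  # bool
    affine: np.ndarray

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.length.shape


def normalize_maps(
    ef: EigenField,
    sc: ScalarMaps,
    mask: Mask | None = None,
    per_map: bool = False,
) -> NormalizedMaps:
    """Normalize L1 and RD by the maximum axial diffusivity.

    Parameters
    ----------
    mask : Mask, optional
        Restrict the search for L1max to these voxels (useful when fat or
        CSF dominates the global maximum).  The normalization itself is
        still applied everywhere.
    per_map : bool
        Sensitivity option: normalize RD by its own maximum instead of
        L1max.  Off by default; the sigma atrophy score assumes the common
        denominator.
    """
    if not ef.clamped:
        raise ValueError("normalize_maps requires a clamped EigenField")
    L1 = ef.L1
    sel = mask.flags if mask is not None else None
    if sel is not None and sel.shape != L1.shape:
        raise ValueError("mask shape does not match the eigenvalue grid")
    L1max = float(L1[sel].max() if sel is not None else L1.max())
    if L1max <= 0:
        raise ValueError("field has no positive axial diffusivity")
    rd_den = float(sc.RD[sel].max() if sel is not None else sc.RD.max()) if per_map else L1max
    if per_map and rd_den <= 0:
        rd_den = L1max
    return NormalizedMaps(L1N=L1 / L1max, RDN=sc.RD / rd_den, L1max=L1max)


def segment_length(L1: np.ndarray, RD: np.ndarray, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Glyph length alpha * (L1 - RD)^2; zero for isotropic voxels."""
    return alpha * (np.asarray(L1) - np.asarray(RD)) ** 2


def segment_opacity(MD: np.ndarray, FA: np.ndarray, beta: float = DEFAULT_BETA) -> np.ndarray:
    """Glyph opacity clip(beta * MD * FA, 0, 1)."""
    return np.clip(beta * np.asarray(MD) * np.asarray(FA), 0.0, 1.0)


def segment_color(L1N: np.ndarray, gamma: float = DEFAULT_GAMMA) -> np.ndarray:
    """RGB color (clip(gamma*L1N), clip(1-L1N), 0), stacked on the last axis."""
    L1N = np.asarray(L1N)
    red = np.clip(gamma * L1N, 0.0, 1.0)
    green = np.clip(1.0 - L1N, 0.0, 1.0)
    return np.stack([red, green, np.zeros_like(L1N)], axis=-1)


def display_flags(nm: NormalizedMaps, sigma: float = DEFAULT_SIGMA) -> np.ndarray:
    """Boolean volume: True exactly where L1N > RDN + sigma (strict).

    Voxels with no axial diffusivity (L1N = 0) can never pass since
    RDN >= 0, so they are excluded automatically.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return nm.L1N > nm.RDN + sigma


def build_glyphs(
    ef: EigenField,
    sc: ScalarMaps,
    params: RenderParams | None = None,
    mask: Mask | None = None,
) -> GlyphField:
    """Compose all per-voxel codings into a GlyphField.

    Voxels where FA is undefined (zero tensor) get length 0, opacity 0 and
    display False regardless of the threshold.
    """
    if params is None:
        params = RenderParams()
    nm = normalize_maps(ef, sc, mask=mask)
    length = segment_length(ef.L1, sc.RD, params.alpha)
    fa = np.nan_to_num(sc.FA, nan=0.0)
    opacity = segment_opacity(sc.MD, fa, params.beta)
    rgb = segment_color(nm.L1N, params.gamma)
    display = display_flags(nm, params.sigma)
    empty = ~(np.isfinite(sc.FA)) | (ef.L1 <= 0)
    length = np.where(empty, 0.0, length)
    opacity = np.where(empty, 0.0, opacity)
    display = display & ~empty
    return GlyphField(
        direction=ef.V1,
        length=length,
        opacity=opacity,
        rgb=rgb,
        display=display,
        affine=ef.affine,
    )
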