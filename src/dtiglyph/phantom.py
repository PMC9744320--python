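"""Synthetic optic-nerve phantoms: curved anisotropic fibers in isotropic CSF.

Every other module is testable without scanner data through these
generators.  A phantom is a curved tube of axially-symmetric anisotropic
tensors (V1 along the local curve tangent) embedded in a free-water-like
isotropic background, emitted either directly as an eigenvalue/
eigenvector field (fast path) or as a forward-modelled diffusion-weighted
acquisition ``S = S0 exp(-b g^T D g)`` with Rician noise (full path).

Tissue profiles are specified by their target (FA, MD); the unique
cylindrically-symmetric eigenvalue triple with those scalars is

    L1      = MD (1 + 2 FA / sqrt(3 - 2 FA^2))
    L2 = L3 = MD (1 -   FA / sqrt(3 - 2 FA^2))

The healthy-nerve preset uses FA = 0.53, MD = 0.9e-3 mm^2/s, typical ROI
values for a functional optic nerve.  The atrophic preset models tissue
whose axonal structure has degenerated toward free water: elevated
MD = 2.81e-3 mm^2/s and no per-voxel anisotropy, so the nerve is absent
from the display at any threshold (sigma* = 0).  Clinical ROI statistics
can still show moderate apparent FA over such tissue because magnitude
noise inflates measured FA at low SNR; that is a property of the
measurement, not of the tissue, and the generator reproduces it only
through its noise model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_dti import DWIVolume, EigenField, Mask

#: Healthy optic-nerve ROI profile.
HEALTHY_FA = 0.53
HEALTHY_MD = 0.9e-3
#: Atrophic (free-water-replaced) profile: isotropic at elevated MD.
ATROPHIC_FA = 0.0
ATROPHIC_MD = 2.81e-3
#: CSF-like isotropic background diffusivity, mm^2/s.
BACKGROUND_MD = 3.0e-3


@dataclass
class PhantomSpec:
    """Geometry, diffusivity and noise parameters of a synthetic fiber."""

    grid_shape: tuple = (40, 40, 12)
    voxel_size: tuple = (1.3, 1.3, 2.0)
    curve: np.ndarray | None = None  # (n, 3) control points, mm; None -> default arc
    radius: float = 2.0  # fiber tube radius, mm
    fiber_FA: float = HEALTHY_FA
    fiber_MD: float = HEALTHY_MD
    background_MD: float = BACKGROUND_MD
    noise_sd: float = 0.0  # eigenvalue sd (mm^2/s) or Rician sd (signal units)
    seed: int = 0
    b_value: float = 1000.0
    n_dirs: int = 64
    n_b0: int = 6
    S0: float = 1000.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fiber_FA < 1.0):
            raise ValueError("fiber_FA must be in [0, 1)")
        if self.fiber_MD <= 0 or self.background_MD < 0:
            raise ValueError("diffusivities must be positive")
        if self.radius <= 0:
            raise ValueError("radius must be positive")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        return aff

    @property
    def extent_mm(self) -> np.ndarray:
        return (np.array(self.grid_shape) - 1) * np.array(self.voxel_size)

    def default_curve(self, y_frac: float = 0.5, amplitude_mm: float = 6.0) -> np.ndarray:
        """A bowed arc spanning the x extent at mid depth, mimicking the
        curvature of the optic nerve between eyeball and optic canal."""
        ext = self.extent_mm
        t = np.linspace(0.0, 1.0, 64)
        x = ext[0] * (0.08 + 0.84 * t)
        amp = max(0.0, min(amplitude_mm, ext[1] * (0.95 - y_frac)))
        y = ext[1] * y_frac + amp * np.sin(np.pi * t)
        z = np.full_like(t, ext[2] / 2.0)
        return np.column_stack([x, y, z])

    def expected_sigma(self) -> float:
        """Closed-form noiseless sigma* of the fiber ROI.

        With a global L1max = max(background_MD, fiber L1), the fiber's
        normalized axial-radial difference is (L1_f - RD_f) / L1max at
        every fiber voxel, which is exactly the max over the ROI.
        """
        L1, L23 = eigenvalues_from_fa_md(self.fiber_FA, self.fiber_MD)
        l1max = max(self.background_MD, L1)
        return max(0.0, (L1 - L23) / l1max)


def healthy_spec(**overrides) -> PhantomSpec:
    """Preset: healthy optic-nerve fiber (FA 0.53, MD 0.9e-3 mm^2/s)."""
    return PhantomSpec(fiber_FA=HEALTHY_FA, fiber_MD=HEALTHY_MD, **overrides)


def atrophic_spec(**overrides) -> PhantomSpec:
    """Preset: atrophic nerve, free-water-like (isotropic, MD 2.81e-3)."""
    return PhantomSpec(fiber_FA=ATROPHIC_FA, fiber_MD=ATROPHIC_MD, **overrides)


def eigenvalues_from_fa_md(FA: float, MD: float) -> tuple[float, float]:
    """The unique cylindrically-symmetric triple (L1, L2=L3) with given FA, MD.

    Returns (L1, L23).  Inverse of the FA/MD formulas under L2 = L3.
    """
    if not (0.0 <= FA < 1.0):
        raise ValueError(f"FA must be in [0, 1), got {FA}")
    if MD <= 0:
        raise ValueError(f"MD must be positive, got {MD}")
    s = np.sqrt(3.0 - 2.0 * FA ** 2)
    return MD * (1.0 + 2.0 * FA / s), MD * (1.0 - FA / s)


def spread_directions(n: int, n_iter: int = 150, step: float = 2e-3) -> np.ndarray:
    """A deterministic electrostatically-spread set of n unit directions.

    Starts from a Fibonacci hemisphere and relaxes under antipodally
    symmetric Coulomb repulsion (each point repels every other point and
    its antipode), the standard construction for diffusion gradient
    schemes.  Fully deterministic: no randomness involved.
    """
    i = np.arange(n)
    z = (i + 0.5) / n  # upper hemisphere
    r = np.sqrt(1.0 - z ** 2)
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    p = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    for _ in range(n_iter):
        diff = p[:, None, :] - p[None, :, :]
        diff_anti = p[:, None, :] + p[None, :, :]
        d3 = (np.linalg.norm(diff, axis=-1) ** 3)[..., None]
        d3a = (np.linalg.norm(diff_anti, axis=-1) ** 3)[..., None]
        np.fill_diagonal(d3[..., 0], np.inf)
        force = (diff / d3).sum(axis=1) + (diff_anti / d3a).sum(axis=1)
        force -= (force * p).sum(axis=1, keepdims=True) * p  # tangential part
        p = p + step * force
        p /= np.linalg.norm(p, axis=1, keepdims=True)
    return p


def _resample_curve(points: np.ndarray, n: int = 400) -> tuple[np.ndarray, np.ndarray]:
    """Densely resample a polyline by arclength; return samples and unit tangents."""
    points = np.asarray(points, dtype=float)
    seg = np.diff(points, axis=0)
    arclen = np.concatenate([[0.0], np.cumsum(np.linalg.norm(seg, axis=1))])
    s = np.linspace(0.0, arclen[-1], n)
    samples = np.column_stack([np.interp(s, arclen, points[:, k]) for k in range(3)])
    tang = np.gradient(samples, s, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    return samples, tang


def _fiber_geometry(spec: PhantomSpec, curve: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fiber membership mask and per-voxel tangent of the nearest curve point."""
    curve = np.asarray(curve, dtype=float)
    ext = spec.extent_mm
    if np.any(curve < -1e-9) or np.any(curve > ext + 1e-9):
        raise ValueError("fiber curve leaves the grid")
    samples, tang = _resample_curve(curve)
    idx = np.indices(spec.grid_shape).reshape(3, -1).T
    centers = idx * np.array(spec.voxel_size)
    # (n_vox, n_samples) distances; grids are small enough to do this densely
    d2 = ((centers[:, None, :] - samples[None, :, :]) ** 2).sum(axis=-1)
    nearest = d2.argmin(axis=1)
    dist = np.sqrt(d2[np.arange(len(centers)), nearest])
    in_fiber = (dist <= spec.radius).reshape(spec.grid_shape)
    tangents = tang[nearest].reshape(spec.grid_shape + (3,))
    return in_fiber, tangents


def _orthonormal_complement(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit fields orthogonal to v (and each other), any consistent choice."""
    helper = np.zeros_like(v)
    dominant = np.abs(v).argmax(axis=-1)
    helper[dominant != 0, 0] = 1.0
    helper[dominant == 0, 1] = 1.0
    u = np.cross(v, helper)
    u /= np.linalg.norm(u, axis=-1, keepdims=True)
    w = np.cross(v, u)
    w /= np.linalg.norm(w, axis=-1, keepdims=True)
    return u, w


def make_eigenfield_phantom(spec: PhantomSpec) -> tuple[EigenField, Mask, Mask]:
    """Build the phantom directly as an EigenField (fast path).

    Fiber voxels (within ``radius`` of the centerline) carry the
    axially-symmetric fiber triple with V1 along the local tangent;
    everything else is isotropic background.  If ``noise_sd`` > 0,
    zero-mean Gaussian perturbations are added to the eigenvalues, which
    are then re-sorted and clamped non-negative.  Deterministic given
    (spec, seed).  Returns (field, fiber mask, background mask).
    """
    curve = spec.curve if spec.curve is not None else spec.default_curve()
    in_fiber, tangents = _fiber_geometry(spec, curve)
    L1f, L23f = eigenvalues_from_fa_md(spec.fiber_FA, spec.fiber_MD)

    shape = spec.grid_shape
    L = np.empty(shape + (3,))
    L[...] = spec.background_MD
    L[in_fiber, 0] = L1f
    L[in_fiber, 1] = L23f
    L[in_fiber, 2] = L23f

    V1 = np.zeros(shape + (3,))
    V1[..., 0] = 1.0
    V1[in_fiber] = tangents[in_fiber]
    V2, V3 = _orthonormal_complement(V1)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        L = L + rng.normal(0.0, spec.noise_sd, size=L.shape)
        L = -np.sort(-L, axis=-1)  # restore descending order
        L = np.maximum(L, 0.0)

    ef = EigenField(
        L1=L[..., 0], L2=L[..., 1], L3=L[..., 2],
        V1=V1, V2=V2, V3=V3,
        affine=spec.affine, clamped=True,
    )
    fiber = Mask(in_fiber, spec.affine)
    background = Mask(~in_fiber, spec.affine)
    return ef, fiber, background


def make_dwi_phantom(spec: PhantomSpec) -> DWIVolume:
    """Forward-model the phantom as a diffusion-weighted acquisition.

    ``n_b0`` unweighted volumes plus ``n_dirs`` electrostatically-spread
    directions at ``b_value``; noise, if any, is Rician on the complex
    signal at level ``noise_sd`` (in signal units), applied to every
    volume.  Deterministic given (spec, seed).
    """
    noiseless = replace(spec, noise_sd=0.0)
    ef, _, _ = make_eigenfield_phantom(noiseless)
    L = np.stack([ef.L1, ef.L2, ef.L3], axis=-1)
    V = np.stack([ef.V1, ef.V2, ef.V3], axis=-1)  # (..., comp, eig)
    D = np.einsum("...ik,...k,...jk->...ij", V, L, V)

    dirs = spread_directions(spec.n_dirs)
    bvecs = np.vstack([np.zeros((spec.n_b0, 3)), dirs])
    bvals = np.concatenate([np.zeros(spec.n_b0), np.full(spec.n_dirs, spec.b_value)])

    adc = np.einsum("ni,...ij,nj->...n", bvecs, D, bvecs)  # g^T D g per volume
    signal = spec.S0 * np.exp(-bvals * adc)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        re = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)
        im = rng.normal(0.0, spec.noise_sd, size=signal.shape)
        signal = np.sqrt(re ** 2 + im ** 2)

    return DWIVolume(signal, bvals, bvecs, spec.affine)


def make_discrimination_phantom(
    noise_sd: float = 2e-4,
    seed: int = 0,
    grid_shape: tuple = (40, 40, 12),
    voxel_size: tuple = (1.3, 1.3, 2.0),
    radius: float = 2.0,
) -> tuple[EigenField, Mask, Mask]:
    """One volume holding a healthy and an atrophic fiber side by side.

    Returns (field, healthy ROI mask, atrophic ROI mask).  The two tubes
    run as parallel arcs offset across the volume, sharing the isotropic
    background and hence the global L1max, so their sigma* scores are
    directly comparable — the end-to-end discrimination setup.
    """
    base = PhantomSpec(grid_shape=grid_shape, voxel_size=voxel_size, radius=radius)
    h = healthy_spec(grid_shape=grid_shape, voxel_size=voxel_size, radius=radius)
    a = atrophic_spec(grid_shape=grid_shape, voxel_size=voxel_size, radius=radius)

    fib_h, tan_h = _fiber_geometry(base, base.default_curve(y_frac=0.3))
    fib_a, tan_a = _fiber_geometry(base, base.default_curve(y_frac=0.7))
    fib_a &= ~fib_h  # healthy wins any overlap (none with default geometry)

    L = np.empty(grid_shape + (3,))
    L[...] = base.background_MD
    L1h, L23h = eigenvalues_from_fa_md(h.fiber_FA, h.fiber_MD)
    L1a, L23a = eigenvalues_from_fa_md(a.fiber_FA, a.fiber_MD)
    L[fib_h] = (L1h, L23h, L23h)
    L[fib_a] = (L1a, L23a, L23a)

    V1 = np.zeros(grid_shape + (3,))
    V1[..., 0] = 1.0
    V1[fib_h] = tan_h[fib_h]
    V1[fib_a] = tan_a[fib_a]
    V2, V3 = _orthonormal_complement(V1)

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        L = L + rng.normal(0.0, noise_sd, size=L.shape)
        L = -np.sort(-L, axis=-1)
        L = np.maximum(L, 0.0)

    ef = EigenField(
        L1=L[..., 0], L2=L[..., 1], L3=L[..., 2],
        V1=V1, V2=V2, V3=V3,
        affine=base.affine, clamped=True,
    )
    return ef, Mask(fib_h, base.affine), Mask(fib_a, base.affine)
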