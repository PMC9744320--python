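"""Multi-layer orthographic projection and figure output.

A small stack of contiguous slices ("layers") is projected onto one of
the three anatomical planes by dropping the out-of-plane coordinate of
each glyph's endpoints.  Superposing several layers greatly improves the
visibility of thin curved structures such as the optic nerve at the cost
of depth information.  Figures are drawn on a black background with each
segment's own opacity and RGB color; world-mm aspect is preserved so
anisotropic voxels do not distort anatomy.

The diagnostic density plot shows every voxel of the selected layers in
the (RDN, L1N) plane, split by the display condition L1N > RDN + sigma,
with the threshold line L1N = RDN + sigma dashed in red.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.collections import LineCollection

from .glyph import GlyphField, NormalizedMaps, RenderParams

# fixed salt keeps SVG clip-path ids reproducible across runs
matplotlib.rcParams["svg.hashsalt"] = "dtiglyph"

#: In-plane axes kept for each dropped image axis (plot x, plot y).
_KEEP_AXES = {2: (0, 1), 0: (1, 2), 1: (0, 2)}


@dataclass
class ProjectedSegment:
    """A glyph after orthographic projection onto the viewing plane."""

    center: np.ndarray  # 2D plot coordinates, mm
    direction2d: np.ndarray  # in-plane unit vector (zero if perpendicular)
    length2d: float  # foreshortened length, display units
    opacity: float
    rgb: tuple
    source_voxel: tuple


def project_layers(gf: GlyphField, params: RenderParams) -> list[ProjectedSegment]:
    """Project every displayed voxel of the selected layers onto the plane.

    Each displayed voxel contributes exactly one segment.  Projection is
    orthographic: voxel centers are mapped through the affine to world mm
    and the out-of-plane coordinate is dropped; directions are rotated to
    world axes and foreshortened by their in-plane norm.  Segments are
    returned in lexicographic voxel order so overlapping translucent
    glyphs composite reproducibly.
    """
    if len(params.layers) == 0:
        raise ValueError("empty layer range")
    axis = params.drop_axis
    n_slices = gf.grid_shape[axis]
    for k in params.layers:
        if not (0 <= k < n_slices):
            raise ValueError(f"layer {k} outside grid (axis {axis} has {n_slices} slices)")

    in_layers = np.zeros(gf.grid_shape, dtype=bool)
    sl = [slice(None)] * 3
    sl[axis] = list(params.layers)
    in_layers[tuple(sl)] = True
    sel = gf.display & in_layers
    idx = np.argwhere(sel)  # already lexicographic

    # rotation part of the affine with voxel scaling removed
    R = gf.affine[:3, :3] / np.linalg.norm(gf.affine[:3, :3], axis=0)
    keep = _KEEP_AXES[axis]

    segments: list[ProjectedSegment] = []
    for i, j, k in idx:
        center_world = gf.affine @ np.array([i, j, k, 1.0])
        d_world = R @ gf.direction[i, j, k]
        d2 = d_world[list(keep)]
        norm2 = float(np.linalg.norm(d2))
        length = float(gf.length[i, j, k])
        segments.append(ProjectedSegment(
            center=center_world[list(keep)],
            direction2d=d2 / norm2 if norm2 > 1e-12 else np.zeros(2),
            length2d=length * norm2,
            opacity=float(gf.opacity[i, j, k]),
            rgb=tuple(gf.rgb[i, j, k]),
            source_voxel=(int(i), int(j), int(k)),
        ))
    return segments


def default_device_scale(segments, voxel_extent: float = 1.0) -> float:
    """Plot-mm per display unit: 99th-percentile segment spans one voxel."""
    lengths = [s.length2d for s in segments if s.length2d > 0]
    if not lengths:
        return 1.0
    return voxel_extent / float(np.percentile(lengths, 99))


def render_projection(
    segments,
    out_path,
    background: np.ndarray | None = None,
    background_extent: tuple | None = None,
    device_scale: float | None = None,
    voxel_extent: float = 1.0,
    radiological: bool = True,
    figsize: tuple = (6.0, 6.0),
) -> None:
    """Draw projected segments (optionally over a T1 slice) and save PNG/SVG.

    Parameters
    ----------
    background : 2D array, optional
        A morphological slice drawn in greyscale under the glyphs; its
        world extent is ``background_extent`` = (xmin, xmax, ymin, ymax).
        Multi-layer glyph stacks can only be paired with the single
        nearest morphological slice, so any depth mismatch is inherent.
    device_scale : float, optional
        Plot mm per glyph display unit.  Default scales the
        99th-percentile segment to one in-plane voxel extent.
    radiological : bool
        Flip the horizontal axis at display time (subject's left appears
        on the image's right).
    """
    if device_scale is None:
        device_scale = default_device_scale(segments, voxel_extent)

    fig, ax = plt.subplots(figsize=figsize)
    fig.patch.set_facecolor("black")
    ax.set_facecolor("black")
    if background is not None:
        extent = background_extent
        ax.imshow(background.T, cmap="gray", origin="lower",
                  extent=extent, interpolation="nearest")
    if segments:
        lines, colors = [], []
        for s in segments:
            half = 0.5 * s.length2d * device_scale * s.direction2d
            lines.append([tuple(s.center - half), tuple(s.center + half)])
            colors.append((*s.rgb, s.opacity))
        ax.add_collection(LineCollection(lines, colors=colors, linewidths=1.0))
        ax.autoscale()
    ax.set_aspect("equal")
    if radiological:
        ax.invert_xaxis()
    ax.set_xticks([])
    ax.set_yticks([])
    for spine in ax.spines.values():
        spine.set_visible(False)
    _savefig(fig, out_path)
    plt.close(fig)


def density_plot(
    nm: NormalizedMaps,
    sigma: float,
    layers,
    out_path,
    drop_axis: int = 2,
    figsize: tuple = (5.0, 5.0),
) -> tuple[int, int]:
    """Scatter (RDN, L1N) for all voxels of the selected layers.

    Voxels satisfying the display condition are black, omitted voxels
    grey; the dashed red line marks L1N = RDN + sigma.  Returns the
    (n_displayed, n_omitted) point counts, which partition the voxels.
    """
    sl = [slice(None)] * nm.L1N.ndim
    sl[drop_axis] = list(layers)
    l1n = nm.L1N[tuple(sl)].ravel()
    rdn = nm.RDN[tuple(sl)].ravel()
    shown = l1n > rdn + sigma

    fig, ax = plt.subplots(figsize=figsize)
    ax.scatter(rdn[~shown], l1n[~shown], s=2, c="0.6", linewidths=0, label="omitted")
    ax.scatter(rdn[shown], l1n[shown], s=2, c="black", linewidths=0, label="displayed")
    lim = max(1.0, float(l1n.max(initial=0.0)), float(rdn.max(initial=0.0)))
    x = np.array([0.0, lim])
    ax.plot(x, x + sigma, "r--", linewidth=1.0)
    ax.set_xlabel("RDN")
    ax.set_ylabel("L1N")
    ax.set_xlim(0, lim)
    ax.set_ylim(0, max(1.0, lim))
    _savefig(fig, out_path)
    plt.close(fig)
    return int(shown.sum()), int((~shown).sum())


def _savefig(fig, out_path) -> None:
    out_path = str(out_path)
    kwargs = {}
    if out_path.endswith(".svg"):
        kwargs["metadata"] = {"Date": None}  # byte-identical reruns
    fig.savefig(out_path, facecolor=fig.get_facecolor(), **kwargs)
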