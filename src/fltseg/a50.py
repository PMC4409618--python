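"""Background-adapted 50% isocontour segmentation (A50%).

A semi-automatic relative-threshold technique for static uptake images (here,
the duration-weighted mean of the last three frames of a dynamic scan).
Starting from a user seed the maximum uptake voxel is located, a preliminary
70%-of-max isocontour is grown around it, the local background is measured on
a one-voxel-thick shell 1.5 cm outside that contour's boundary, and the final
volume of interest is the connected region above

    threshold = 0.5 * (max + background).

Because both threshold levels are relative, the segmentation is invariant to
global rescaling of the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "A50Params",
    "A50SegmentationResult",
    "find_max_voxel",
    "grow_isocontour",
    "local_background",
    "a50_segment",
]

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class A50Params:
    """Tunables of the A50% procedure (defaults are the standard settings)."""

    initial_fraction: float = 0.70  # preliminary isocontour level, fraction of max
    threshold_fraction: float = 0.50  # final level, fraction of (max + background)
    shell_distance_mm: float = 15.0  # background shell offset from the 70% contour
    shell_thickness_voxels: float = 1.0  # shell thickness in mean voxel pitches
    seed_search_radius_mm: float = 20.0
    connectivity: int = 26

    def __post_init__(self) -> None:
        if not 0 < self.initial_fraction < 1:
            raise ValueError("initial fraction must be in (0, 1)")
        if not 0 < self.threshold_fraction < 1:
            raise ValueError("threshold fraction must be in (0, 1)")
        if self.shell_distance_mm <= 0:
            raise ValueError("shell distance must be positive")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")


@dataclass
class A50SegmentationResult:
    """Outcome of one A50% segmentation."""

    voi: np.ndarray
    detected: bool
    max_value: float
    background: float
    threshold: float
    volume_cm3: float
    n_components_at_threshold: int
    leaked: bool


def find_max_voxel(
    image3d: np.ndarray,
    seed_mm: tuple[float, float, float],
    search_radius_mm: float,
    spacing_mm: tuple[float, float, float],
) -> tuple[int, int, int]:
    """Locate the hottest voxel within a sphere around a seed point.

    The seed is in mm (voxel-centre convention: voxel i spans
    ``[i*s, (i+1)*s]`` with centre ``(i+0.5)*s``).  Ties resolve to the
    lowest linear (C-order) index.
    """
    image3d = np.asarray(image3d, float)
    coords = np.meshgrid(
        *[(np.arange(n) + 0.5) * s for n, s in zip(image3d.shape, spacing_mm)],
        indexing="ij",
    )
    in_grid = all(0 <= p <= n * s for p, n, s in zip(seed_mm, image3d.shape, spacing_mm))
    if not in_grid:
        raise ValueError(f"seed {seed_mm} mm lies outside the image grid")
    dist2 = sum((c - p) ** 2 for c, p in zip(coords, seed_mm))
    sphere = dist2 <= search_radius_mm**2
    if not sphere.any():
        raise ValueError(
            f"search radius {search_radius_mm} mm covers no voxel centres"
        )
    masked = np.where(sphere, image3d, -np.inf)
    flat_idx = int(np.argmax(masked))  # first occurrence = lowest linear index
    return tuple(int(i) for i in np.unravel_index(flat_idx, image3d.shape))


def grow_isocontour(
    image3d: np.ndarray,
    start_voxel: tuple[int, int, int],
    threshold: float,
    connectivity: int = 26,
) -> np.ndarray:
    """Region-grow from a start voxel: the connected component of
    ``{value >= threshold}`` containing it."""
    image3d = np.asarray(image3d, float)
    if image3d[start_voxel] < threshold:
        raise ValueError(
            f"start voxel value {image3d[start_voxel]} is below threshold {threshold}"
        )
    above = image3d >= threshold
    lab, _ = ndimage.label(above, structure=_STRUCTS[connectivity])
    return lab == lab[start_voxel]


def local_background(
    image3d: np.ndarray,
    contour70: np.ndarray,
    params: A50Params,
    spacing_mm: tuple[float, float, float],
) -> float:
    """Mean uptake on a thin shell at a fixed distance outside the contour.

    Distances are Euclidean (mm, anisotropy-aware) from the contour surface;
    the shell is ``[d, d + thickness]`` where the thickness is
    ``shell_thickness_voxels`` mean voxel pitches.  An empty shell (lesion
    too close to the image border) is an error.
    """
    contour70 = np.asarray(contour70, bool)
    if not contour70.any():
        raise ValueError("empty initial isocontour")
    dist = ndimage.distance_transform_edt(~contour70, sampling=spacing_mm)
    pitch = float(np.mean(spacing_mm)) * params.shell_thickness_voxels
    shell = (
        ~contour70
        & (dist >= params.shell_distance_mm)
        & (dist <= params.shell_distance_mm + pitch)
    )
    if not shell.any():
        raise ValueError(
            f"background shell at {params.shell_distance_mm} mm is empty; "
            "the lesion is too close to the image border"
        )
    return float(np.asarray(image3d, float)[shell].mean())


def a50_segment(
    image3d: np.ndarray,
    seed_mm: tuple[float, float, float],
    spacing_mm: tuple[float, float, float],
    params: A50Params = A50Params(),
    bounding_mask: np.ndarray | None = None,
) -> A50SegmentationResult:
    """Full A50% segmentation from a seed point.

    ``bounding_mask``, when given, flags (but does not clip) segmentations
    that escape the expected region — e.g. a threshold low enough to merge
    the lesion with surrounding structures.  A flat or inverted contrast
    (threshold not above background) marks the lesion as not detected.
    """
    image3d = np.asarray(image3d, float)
    mx_idx = find_max_voxel(image3d, seed_mm, params.seed_search_radius_mm, spacing_mm)
    mx = float(image3d[mx_idx])
    contour70 = grow_isocontour(
        image3d, mx_idx, params.initial_fraction * mx, params.connectivity
    )
    # contour filling the whole grid means there is no surrounding background:
    # treat as zero contrast rather than an empty-shell error
    bg = mx if contour70.all() else local_background(image3d, contour70, params, spacing_mm)
    threshold = params.threshold_fraction * (mx + bg)
    voxel_vol = float(np.prod(spacing_mm)) / 1000.0

    if threshold <= bg or mx < threshold:
        return A50SegmentationResult(
            voi=np.zeros_like(image3d, dtype=bool),
            detected=False,
            max_value=mx,
            background=bg,
            threshold=threshold,
            volume_cm3=0.0,
            n_components_at_threshold=0,
            leaked=False,
        )

    voi = grow_isocontour(image3d, mx_idx, threshold, params.connectivity)
    _, n_comp = ndimage.label(image3d >= threshold, structure=_STRUCTS[params.connectivity])
    leaked = bool(bounding_mask is not None and (voi & ~np.asarray(bounding_mask, bool)).any())
    return A50SegmentationResult(
        voi=voi,
        detected=not leaked,
        max_value=mx,
        background=bg,
        threshold=threshold,
        volume_cm3=float(voi.sum()) * voxel_vol,
        n_components_at_threshold=int(n_comp),
        leaked=leaked,
    )
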