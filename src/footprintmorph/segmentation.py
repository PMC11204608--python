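"""HU-window segmentation of CT volumes and isosurface extraction.

Bone and radiopaque paint are recovered from a CT-like volume by a primary
Hounsfield-unit window (default 250..3000 HU, the established cortical-bone
window), a secondary threshold separating the barium-sulfate paint from bone
(default 2000 HU), and marching-cubes isosurfacing of the binary masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .errors import EmptyInputError, ParameterError

__all__ = [
    "CTVolume",
    "LabelMask",
    "threshold_segment",
    "split_paint",
    "extract_surface",
    "DEFAULT_HU_MIN",
    "DEFAULT_HU_MAX",
    "DEFAULT_PAINT_HU_MIN",
]

DEFAULT_HU_MIN = 250.0
DEFAULT_HU_MAX = 3000.0
DEFAULT_PAINT_HU_MIN = 2000.0


@dataclass
class CTVolume:
    """3D scalar grid of Hounsfield units.

    ``values[i, j, k]`` sits at ``origin + (i, j, k) * spacing`` (mm).
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.values.ndim != 3:
            raise ParameterError("CTVolume requires a 3D value grid")
        if np.any(self.spacing <= 0):
            raise ParameterError("voxel spacing components must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("HU values must be finite")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass
class LabelMask:
    """Binary mask on the same grid as its source volume."""

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    label: str = "bone"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=bool)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def masked_volume(self) -> float:
        """Total volume of masked voxels in mm^3."""
        return self.voxel_count * float(np.prod(self.spacing))


def threshold_segment(
    volume: CTVolume,
    hu_min: float = DEFAULT_HU_MIN,
    hu_max: float = DEFAULT_HU_MAX,
) -> LabelMask:
    """Select voxels whose HU lies in the inclusive window [hu_min, hu_max].

    The default window (250..3000 HU) captures cortical bone together with
    the radiopaque paint; :func:`split_paint` separates the two afterwards.
    An empty result is legal (a warning is emitted, not an error).
    """
    if not hu_min < hu_max:
        raise ParameterError(f"hu_min ({hu_min}) must be < hu_max ({hu_max})")
    mask = (volume.values >= hu_min) & (volume.values <= hu_max)
    if not mask.any():
        warnings.warn(
            f"HU window [{hu_min}, {hu_max}] selected no voxels", stacklevel=2
        )
    return LabelMask(mask, volume.spacing, volume.origin, label="bone")


def split_paint(
    volume: CTVolume,
    bone_mask: LabelMask,
    paint_hu_min: float = DEFAULT_PAINT_HU_MIN,
) -> tuple[LabelMask, LabelMask]:
    """Separate paint from bone inside the primary mask.

    Voxels at or above ``paint_hu_min`` (within the primary mask) seed the
    paint label; the seed is dilated by one voxel and re-intersected with the
    primary mask so that partial-volume voxels at the paint/bone interface go
    with the paint.  Bone is the set difference, so the two masks always
    partition the primary mask.
    """
    primary = bone_mask.values
    seeds = primary & (volume.values >= paint_hu_min)
    if seeds.any():
        paint = ndimage.binary_dilation(seeds, iterations=1) & primary
    else:
        paint = seeds
    bone = primary & ~paint
    return (
        LabelMask(bone, volume.spacing, volume.origin, label="bone"),
        LabelMask(paint, volume.spacing, volume.origin, label="paint"),
    )


def extract_surface(
    mask: LabelMask,
    keep: str = "largest_component",
    smooth_sigma: float = 0.8,
) -> trimesh.Trimesh:
    """Triangulated isosurface of a binary mask (marching cubes at 0.5).

    The binary grid is pre-filtered with a Gaussian of ``smooth_sigma``
    voxels before isosurfacing: raw binary marching cubes produces a
    staircase surface whose area overestimates smooth anatomy by ~8%,
    while the anti-aliased isosurface stays within half a voxel of the
    mask boundary and recovers smooth-surface areas to a few percent.
    Structures so small that the filter would erase them (fewer than ~27
    voxels) are extracted from the raw binary grid instead.

    The grid is zero-padded so structures touching the volume border still
    close.  With ``keep='largest_component'`` only the largest connected
    surface component (by area) is returned — the automated stand-in for
    manually discarding small disconnected ossifications.  Output is
    consistently oriented with outward normals.
    """
    if keep not in ("largest_component", "all"):
        raise ParameterError(f"unknown keep mode: {keep!r}")
    if not mask.values.any():
        raise EmptyInputError("cannot extract a surface from an empty mask")
    padded = np.pad(mask.values.astype(np.float32), 2)
    if smooth_sigma > 0 and mask.voxel_count >= 27:
        padded = ndimage.gaussian_filter(padded, sigma=smooth_sigma)
        # the filter must not disconnect thin structures entirely
        if padded.max() <= 0.5:
            padded = np.pad(mask.values.astype(np.float32), 2)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(mask.spacing))
    verts = verts - 2 * mask.spacing + mask.origin  # undo the pad shift
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if keep == "largest_component":
        parts = mesh.split(only_watertight=False)
        if len(parts) > 1:
            mesh = max(parts, key=lambda m: m.area)
    if mesh.is_volume and mesh.volume < 0:
        mesh.invert()
    else:
        trimesh.repair.fix_normals(mesh)
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
    return mesh
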