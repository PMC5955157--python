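"""Metric image grids and NIfTI-1 I/O for SUV volumes and binary masks.

Conventions used throughout the package
---------------------------------------
* Arrays are indexed ``values[i, j, k]`` with axis 0 = x, 1 = y, 2 = z
  (x varies fastest when iterating the flattened C-ordered array last
  axis first; "linear index" always means the C-order flat index of this
  layout).
* Voxel indices are 0-based.  World coordinates are in millimetres and
  refer to voxel *centers*: ``world = origin + index * spacing``.
* Grids are axis-aligned with strictly positive spacing (a diagonal,
  positive NIfTI affine).  Oblique or flipped affines are rejected on
  read rather than silently reinterpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "WorldBox",
    "SuvImage",
    "BinaryMask",
    "read_volume",
    "read_mask",
    "write_volume",
]

Modality = Literal["PET", "ANAT"]


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D metric sampling grid (shape, spacing and origin, all per axis)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be a positive integer triple, got {self.shape}")
        if len(self.spacing) != 3 or any(not (s > 0) for s in self.spacing):
            raise ValueError(f"grid spacing must be strictly positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def affine(self) -> np.ndarray:
        """4x4 index->world affine (diagonal; voxel-center convention)."""
        a = np.diag(list(self.spacing) + [1.0])
        a[:3, 3] = self.origin
        return a

    @property
    def center_mm(self) -> np.ndarray:
        """World coordinate of the geometric grid center."""
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) / 2.0 * np.asarray(self.spacing)

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        return np.asarray(index, dtype=float) * np.asarray(self.spacing) + np.asarray(self.origin)

    def world_to_index(self, world: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel index of world points."""
        return (np.asarray(world, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_centers(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-center world coordinates."""
        axes = [self.origin[d] + self.spacing[d] * np.arange(self.shape[d]) for d in range(3)]
        grids = np.meshgrid(*axes, indexing="ij")
        return np.stack(grids, axis=-1)

    def domain_box(self) -> "WorldBox":
        """Axis-aligned box spanning all voxel centers."""
        lo = np.asarray(self.origin)
        hi = self.index_to_world(np.asarray(self.shape) - 1)
        return WorldBox(tuple(lo), tuple(hi))


@dataclass(frozen=True)
class WorldBox:
    """Axis-aligned box in world millimetres (inclusive bounds)."""

    lower_mm: tuple[float, float, float]
    upper_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower_mm, dtype=float)
        hi = np.asarray(self.upper_mm, dtype=float)
        if lo.shape != (3,) or hi.shape != (3,):
            raise ValueError("box bounds must be mm triples")
        if np.any(hi < lo):
            raise ValueError(f"box upper bound below lower bound: {self.lower_mm} .. {self.upper_mm}")
        object.__setattr__(self, "lower_mm", tuple(lo))
        object.__setattr__(self, "upper_mm", tuple(hi))

    def expand(self, margin_mm: float) -> "WorldBox":
        lo = np.asarray(self.lower_mm) - margin_mm
        hi = np.asarray(self.upper_mm) + margin_mm
        return WorldBox(tuple(lo), tuple(hi))

    def clip_to(self, grid: VolumeGrid) -> "WorldBox":
        dom = grid.domain_box()
        lo = np.maximum(self.lower_mm, dom.lower_mm)
        hi = np.minimum(self.upper_mm, dom.upper_mm)
        if np.any(hi < lo):
            raise ValueError("box does not intersect the image domain")
        return WorldBox(tuple(lo), tuple(hi))

    def index_slices(self, grid: VolumeGrid) -> tuple[slice, slice, slice]:
        """Slices selecting voxels whose centers fall inside the box (clipped)."""
        lo_idx = np.ceil(grid.world_to_index(self.lower_mm) - 1e-9).astype(int)
        hi_idx = np.floor(grid.world_to_index(self.upper_mm) + 1e-9).astype(int)
        shape = np.asarray(grid.shape)
        if np.any(hi_idx < 0) or np.any(lo_idx > shape - 1) or np.any(hi_idx < lo_idx):
            raise ValueError("box selects no voxel centers inside the image domain")
        lo_idx = np.clip(lo_idx, 0, shape - 1)
        hi_idx = np.clip(hi_idx, 0, shape - 1)
        return tuple(slice(int(a), int(b) + 1) for a, b in zip(lo_idx, hi_idx))


@dataclass
class SuvImage:
    """A 3-D scalar volume (SUV for PET, arbitrary units for anatomy) on a grid."""

    grid: VolumeGrid
    values: np.ndarray
    modality: Modality = "PET"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"value array shape {self.values.shape} does not match grid shape {self.grid.shape}"
            )
        bad = np.argwhere(~np.isfinite(self.values))
        if bad.size:
            raise ValueError(f"non-finite voxel value at index {tuple(int(i) for i in bad[0])}")
        if self.modality == "PET" and float(self.values.min()) < 0:
            raise ValueError("PET values must be non-negative (SUV)")


@dataclass
class BinaryMask:
    """A boolean voxel membership map on a grid."""

    grid: VolumeGrid
    membership: np.ndarray

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=bool)
        if self.membership.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.membership.shape} does not match grid shape {self.grid.shape}"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.membership.sum())

    @property
    def volume_cc(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_cc


def _grid_from_affine(affine: np.ndarray, shape: tuple[int, ...], path: Path) -> VolumeGrid:
    rot = np.asarray(affine[:3, :3], dtype=float)
    off_diag = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off_diag)) > 1e-4 * max(1.0, np.max(np.abs(rot))):
        raise ValueError(f"{path}: only axis-aligned (diagonal-affine) volumes are supported")
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise ValueError(f"{path}: affine diagonal must be positive (no axis flips), got {spacing}")
    return VolumeGrid(tuple(int(s) for s in shape), tuple(spacing), tuple(affine[:3, 3]))


def read_volume(path: str | Path, modality: Modality = "PET") -> SuvImage:
    """Read a 3-D scalar NIfTI-1 volume; grid taken from the affine.

    Raises with a diagnostic for missing files, non-3-D arrays, oblique
    affines and non-finite voxels (the offending index is named).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(s == 1 for s in data.shape[3:]) else data
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got array of shape {data.shape}")
    grid = _grid_from_affine(np.asarray(img.affine), data.shape, path)
    bad = np.argwhere(~np.isfinite(data))
    if bad.size:
        raise ValueError(f"{path}: non-finite voxel value at index {tuple(int(i) for i in bad[0])}")
    return SuvImage(grid=grid, values=np.asarray(data, dtype=np.float32), modality=modality)


def read_mask(path: str | Path) -> BinaryMask:
    """Read a 0/1 NIfTI volume as a binary mask (any nonzero voxel is a member)."""
    img = read_volume(path, modality="ANAT")
    return BinaryMask(grid=img.grid, membership=img.values > 0.5)


def write_volume(obj: SuvImage | BinaryMask, path: str | Path) -> None:
    """Write an image (float32) or mask (uint8 0/1) as NIfTI-1."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if isinstance(obj, BinaryMask):
        data = obj.membership.astype(np.uint8)
        grid = obj.grid
    else:
        data = obj.values.astype(np.float32)
        grid = obj.grid
    nib.Nifti1Image(data, grid.affine).to_filename(str(path))
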