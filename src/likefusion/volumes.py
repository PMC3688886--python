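"""Typed volumes on voxel grids, NIfTI round-trip, and ROI cropping.

Conventions: voxel indexing is 0-based; boxes are half-open ``[lower, upper)``;
the affine maps homogeneous voxel indices to world coordinates in mm.  All
atlases and the target are assumed pre-resampled to a common grid before
fusion; :func:`resample_to_grid` provides nearest/linear resampling onto a
target grid for inputs that are not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "VoxelGrid", "IntensityVolume", "LabelVolume", "RoiBox",
    "read_volume", "write_volume", "read_labels", "write_labels",
    "compute_roi", "crop", "uncrop", "resample_to_grid",
    "read_label_dictionary", "write_label_dictionary",
]


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3-D voxel lattice with physical spacing and orientation."""

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float]
    affine: np.ndarray  # 4x4 voxel -> world (mm)

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        spacing = tuple(float(s) for s in self.spacing)
        affine = np.asarray(self.affine, dtype=float)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValueError(f"dims must be 3 positive integers, got {self.dims}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) <= 0:
            raise ValueError("affine 3x3 block is singular")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "affine", affine)

    @classmethod
    def from_spacing(cls, dims: Sequence[int], spacing: Sequence[float]) -> "VoxelGrid":
        affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
        return cls(tuple(dims), tuple(spacing), affine)

    def voxel_to_world(self, index: Sequence[float]) -> np.ndarray:
        hom = np.append(np.asarray(index, dtype=float), 1.0)
        return (self.affine @ hom)[:3]

    def same_lattice(self, other: "VoxelGrid", atol: float = 1e-5) -> bool:
        return self.dims == other.dims and np.allclose(self.affine, other.affine, atol=atol)


@dataclass(frozen=True)
class IntensityVolume:
    """A scalar image (arbitrary MR units) on a voxel grid."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.shape != self.grid.dims:
            raise ValueError(f"values shape {values.shape} != grid dims {self.grid.dims}")
        if not np.issubdtype(values.dtype, np.floating):
            values = values.astype(np.float32)
        if not np.all(np.isfinite(values)):
            raise ValueError("intensity values must be finite")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class LabelVolume:
    """An integer label field with a label-id -> structure-name dictionary.

    Label 0 is reserved for unlabeled/background and need not be in the
    dictionary.
    """

    grid: VoxelGrid
    labels: np.ndarray
    dictionary: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.shape != self.grid.dims:
            raise ValueError(f"labels shape {labels.shape} != grid dims {self.grid.dims}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        if labels.min() < 0:
            raise ValueError("labels must be non-negative")
        dictionary = {int(k): str(v) for k, v in self.dictionary.items()}
        present = set(np.unique(labels).tolist()) - {0}
        missing = present - set(dictionary)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from dictionary")
        object.__setattr__(self, "labels", labels.astype(np.int32))
        object.__setattr__(self, "dictionary", dictionary)

    @property
    def label_ids(self) -> list[int]:
        """Declared label ids (dictionary order, ascending)."""
        return sorted(self.dictionary)


@dataclass(frozen=True)
class RoiBox:
    """Half-open axis-aligned voxel box [lower, upper)."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]

    def __post_init__(self) -> None:
        lower = tuple(int(v) for v in self.lower)
        upper = tuple(int(v) for v in self.upper)
        if any(lo >= up for lo, up in zip(lower, upper)):
            raise ValueError(f"RoiBox requires lower < upper, got {lower}, {upper}")
        if any(lo < 0 for lo in lower):
            raise ValueError("RoiBox lower must be non-negative")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(up - lo for lo, up in zip(self.lower, self.upper))

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, up) for lo, up in zip(self.lower, self.upper))

    def within(self, grid: VoxelGrid) -> bool:
        return all(up <= d for up, d in zip(self.upper, grid.dims))


def _grid_from_nifti(img: nib.Nifti1Image) -> VoxelGrid:
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelGrid(tuple(int(d) for d in img.shape[:3]), zooms, np.asarray(img.affine))


def read_volume(path: str | Path) -> IntensityVolume:
    """Read a single-component 3-D NIfTI intensity volume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D scalar volume, got shape {data.shape}")
    return IntensityVolume(_grid_from_nifti(img), np.ascontiguousarray(data, dtype=np.float32))


def write_volume(volume: IntensityVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float32), volume.grid.affine)
    img.header.set_zooms(volume.grid.spacing)
    nib.save(img, str(path))


def read_labels(path: str | Path, dictionary: Mapping[int, str]) -> LabelVolume:
    """Read an integer-valued NIfTI label volume and verify dictionary coverage."""
    vol = read_volume(path)
    rounded = np.rint(vol.values)
    if np.max(np.abs(vol.values - rounded)) > 1e-6:
        raise ValueError(f"{path}: label volume has non-integer values")
    return LabelVolume(vol.grid, rounded.astype(np.int32), dictionary)


def write_labels(labels: LabelVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(labels.labels.astype(np.int16), labels.grid.affine)
    img.header.set_zooms(labels.grid.spacing)
    nib.save(img, str(path))


def read_label_dictionary(path: str | Path) -> dict[int, str]:
    with open(path) as fh:
        raw = json.load(fh)
    return {int(k): str(v) for k, v in raw.items()}


def write_label_dictionary(dictionary: Mapping[int, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({str(k): v for k, v in dictionary.items()}, fh, indent=2, sort_keys=True)


def compute_roi(label_volumes: Sequence[LabelVolume], margin_vox: int = 4) -> RoiBox:
    """Smallest box containing every nonzero label in every input, dilated and clipped.

    The default 4-voxel margin gives overlapping chart neighbourhoods room at
    structure boundaries.
    """
    if not label_volumes:
        raise ValueError("need at least one label volume")
    if margin_vox < 0:
        raise ValueError("margin must be >= 0")
    grid = label_volumes[0].grid
    for lv in label_volumes[1:]:
        if not lv.grid.same_lattice(grid):
            raise ValueError("all label volumes must share one grid")
    lower = np.array(grid.dims, dtype=int)
    upper = np.zeros(3, dtype=int)
    any_nonzero = False
    for lv in label_volumes:
        nz = np.nonzero(lv.labels)
        if nz[0].size == 0:
            continue
        any_nonzero = True
        for ax in range(3):
            lower[ax] = min(lower[ax], int(nz[ax].min()))
            upper[ax] = max(upper[ax], int(nz[ax].max()) + 1)
    if not any_nonzero:
        raise ValueError("no nonzero labels in any input volume")
    lower = np.maximum(lower - margin_vox, 0)
    upper = np.minimum(upper + margin_vox, grid.dims)
    return RoiBox(tuple(lower), tuple(upper))


def _cropped_grid(grid: VoxelGrid, box: RoiBox) -> VoxelGrid:
    affine = grid.affine.copy()
    affine[:3, 3] = grid.voxel_to_world(box.lower)
    return VoxelGrid(box.shape, grid.spacing, affine)


def crop(volume: IntensityVolume | LabelVolume, box: RoiBox):
    """Extract the sub-volume in ``box``, preserving world coordinates."""
    if not box.within(volume.grid):
        raise ValueError(f"box {box} exceeds grid dims {volume.grid.dims}")
    grid = _cropped_grid(volume.grid, box)
    if isinstance(volume, LabelVolume):
        return LabelVolume(grid, volume.labels[box.slices()].copy(), volume.dictionary)
    return IntensityVolume(grid, volume.values[box.slices()].copy())


def uncrop(volume: IntensityVolume | LabelVolume, box: RoiBox, full_grid: VoxelGrid, fill=0):
    """Place a cropped sub-volume back into ``full_grid``, `fill` outside the box."""
    if not box.within(full_grid):
        raise ValueError(f"box {box} exceeds grid dims {full_grid.dims}")
    if box.shape != volume.grid.dims:
        raise ValueError("volume shape does not match box")
    if isinstance(volume, LabelVolume):
        full = np.full(full_grid.dims, int(fill), dtype=np.int32)
        full[box.slices()] = volume.labels
        return LabelVolume(full_grid, full, volume.dictionary)
    full = np.full(full_grid.dims, float(fill), dtype=volume.values.dtype)
    full[box.slices()] = volume.values
    return IntensityVolume(full_grid, full)


def resample_to_grid(volume: IntensityVolume | LabelVolume, grid: VoxelGrid,
                     mode: str = "linear"):
    """Resample onto ``grid`` via world coordinates (nearest or linear)."""
    if mode not in ("nearest", "linear"):
        raise ValueError(f"unknown mode {mode!r}")
    # world coords of the target lattice, pulled back to source voxel indices
    idx = np.indices(grid.dims, dtype=float).reshape(3, -1)
    hom = np.vstack([idx, np.ones((1, idx.shape[1]))])
    src = np.linalg.inv(volume.grid.affine) @ (grid.affine @ hom)
    coords = src[:3]
    if isinstance(volume, LabelVolume):
        out = map_coordinates(volume.labels, coords, order=0, mode="nearest")
        return LabelVolume(grid, out.reshape(grid.dims).astype(np.int32), volume.dictionary)
    order = 0 if mode == "nearest" else 1
    out = map_coordinates(volume.values, coords, order=order, mode="nearest")
    return IntensityVolume(grid, out.reshape(grid.dims).astype(np.float32))
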