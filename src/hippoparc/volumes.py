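"""Volumetric containers and NIfTI I/O.

The package works on a region of interest (ROI) extracted from a 3D grid:
the N voxels inside the ROI mask become graph nodes 0..N-1, ordered by
ascending C-order flat index over (x, y, z) array indices.  That ordering
is the contract every other module relies on, so it is fixed here and
round-trips exactly through NIfTI files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "RoiMask",
    "LabelMap",
    "Bold4D",
    "read_mask",
    "read_label_map",
    "read_bold",
    "extract_timeseries",
    "write_labels",
    "write_volume",
]


@dataclass(frozen=True)
class VolumeGrid:
    """Geometry of a 3D voxel grid: shape plus voxel-to-world affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return tuple(np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0)))

    def matches(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)


class RoiMask:
    """Boolean ROI on a grid with a fixed voxel <-> node bijection.

    Nodes are numbered 0..N-1 in ascending C-order flat index of the
    (x, y, z) array indices, so the ordering is deterministic for a given
    mask and identical across runs.
    """

    def __init__(self, grid: VolumeGrid, in_roi: np.ndarray):
        in_roi = np.asarray(in_roi, dtype=bool)
        if in_roi.shape != grid.shape:
            raise ValueError(f"mask shape {in_roi.shape} != grid shape {grid.shape}")
        if not in_roi.any():
            raise ValueError("empty ROI: mask has no nonzero voxels")
        self.grid = grid
        self.in_roi = in_roi
        flat = np.flatnonzero(in_roi.ravel(order="C"))
        self._flat_index = flat
        self.coords = np.stack(np.unravel_index(flat, grid.shape), axis=1)

    @property
    def n_nodes(self) -> int:
        return len(self._flat_index)

    def node_of(self, x: int, y: int, z: int) -> int:
        """Node id of an in-ROI voxel; raises for voxels outside the ROI."""
        flat = np.ravel_multi_index((x, y, z), self.grid.shape)
        idx = np.searchsorted(self._flat_index, flat)
        if idx >= len(self._flat_index) or self._flat_index[idx] != flat:
            raise KeyError(f"voxel ({x},{y},{z}) is not in the ROI")
        return int(idx)

    def volume_from_nodes(self, values: np.ndarray, fill=0) -> np.ndarray:
        """Scatter a per-node vector back into a full 3D volume."""
        values = np.asarray(values)
        out = np.full(self.grid.shape, fill, dtype=values.dtype)
        out[tuple(self.coords.T)] = values
        return out


@dataclass
class LabelMap:
    """Integer labels on a grid; 0 is background / unlabeled."""

    grid: VolumeGrid
    label: np.ndarray

    def __post_init__(self) -> None:
        self.label = np.asarray(self.label)
        if self.label.shape != self.grid.shape:
            raise ValueError("label volume shape mismatch")
        if not np.issubdtype(self.label.dtype, np.integer):
            lab = np.asarray(self.label)
            if not np.allclose(lab, np.round(lab)):
                raise ValueError("labels must be integers")
            self.label = lab.astype(np.int32)
        if (self.label < 0).any():
            raise ValueError("labels must be non-negative")

    def node_labels(self, mask: RoiMask) -> np.ndarray:
        """Per-node label vector in node order."""
        if not self.grid.matches(mask.grid):
            raise ValueError("label map grid does not match mask grid")
        return self.label[tuple(mask.coords.T)]


@dataclass
class Bold4D:
    """A 4D BOLD acquisition: one time series per voxel."""

    grid: VolumeGrid
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D (x, y, z, t)")
        if self.data.shape[:3] != self.grid.shape:
            raise ValueError("BOLD spatial shape does not match grid")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 timepoints")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


def read_mask(path) -> RoiMask:
    """Read a 3D NIfTI volume and treat every nonzero voxel as ROI."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D mask, got {data.ndim}D")
    grid = VolumeGrid(data.shape, img.affine)
    return RoiMask(grid, data != 0)


def read_label_map(path) -> LabelMap:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D label map, got {data.ndim}D")
    return LabelMap(VolumeGrid(data.shape, img.affine), np.rint(data).astype(np.int32))


def read_bold(path) -> Bold4D:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected 4D BOLD, got {data.ndim}D")
    return Bold4D(VolumeGrid(data.shape[:3], img.affine), data)


def extract_timeseries(bold: Bold4D, mask: RoiMask) -> np.ndarray:
    """Raw node-by-time matrix: row u is the series of node u."""
    if not bold.grid.matches(mask.grid):
        raise ValueError("BOLD grid does not match mask grid")
    ts = bold.data[tuple(mask.coords.T)]
    if not np.isfinite(ts).all():
        raise ValueError("non-finite BOLD values inside the ROI")
    return ts


def write_labels(labels: np.ndarray, mask: RoiMask, path) -> None:
    """Write per-node parcel labels (1..k) as a NIfTI label map, 0 outside."""
    labels = np.asarray(labels)
    if labels.shape != (mask.n_nodes,):
        raise ValueError("need one label per ROI node")
    if (labels < 1).any():
        raise ValueError("unassigned node: all labels must be >= 1")
    vol = mask.volume_from_nodes(labels.astype(np.int16), fill=np.int16(0))
    nib.save(nib.Nifti1Image(vol, mask.grid.affine), str(path))


def write_volume(volume: np.ndarray, grid: VolumeGrid, path) -> None:
    if volume.shape[:3] != grid.shape:
        raise ValueError("volume shape does not match grid")
    nib.save(nib.Nifti1Image(np.asarray(volume), grid.affine), str(path))
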