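"""Labeled-volume I/O and candidate electrode centroid extraction.

The upstream segmentation (a network prediction or a manual ground
truth) is a NIfTI volume of integer voxel labels: 0 is background and
each value ``k >= 1`` marks one electrode candidate. Detection reduces
this map to points: connected components are computed *within each label
value* with 26-connectivity, tiny components are discarded, and each
surviving component contributes the world-space position of its center
(the unweighted mean of its voxel indices mapped through the header
affine).
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

from .points import read_points_tsv, write_points_tsv

__all__ = [
    "LabeledVolume",
    "DetectionCloud",
    "read_labeled_volume",
    "write_labeled_volume",
    "extract_centroids",
]

#: 26-connectivity structuring element (all face/edge/corner neighbours).
_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)

#: Voxel values farther than this from an integer are rejected on read.
_INTEGER_TOL = 1e-3


@dataclass
class LabeledVolume:
    """3-D integer label lattice plus its voxel-index→world-mm affine."""

    grid: np.ndarray  # (i, j, k) integers >= 0
    affine: np.ndarray  # (4, 4)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError(f"grid must be 3-D, got shape {self.grid.shape}")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("grid must hold integers")
        if self.grid.size and self.grid.min() < 0:
            raise ValueError("grid values must be non-negative")
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        return nib.affines.apply_affine(self.affine, np.asarray(idx, dtype=float))


@dataclass
class DetectionCloud:
    """Candidate electrode positions in world mm.

    ``provisional_labels`` carries the voxel label of each component; the
    refinement stage deliberately ignores it when assigning final names.
    """

    points: np.ndarray  # (n, 3) mm
    provisional_labels: np.ndarray | None = None  # (n,) int
    component_sizes: np.ndarray | None = None  # (n,) voxel counts

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("detection points contain non-finite coordinates")
        n = len(self.points)
        for name in ("provisional_labels", "component_sizes"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val, dtype=int).reshape(-1)
                if len(val) != n:
                    raise ValueError(f"{name} length {len(val)} != {n} points")
                setattr(self, name, val)

    def __len__(self) -> int:
        return len(self.points)

    def to_tsv(self, path) -> None:
        n = len(self)
        labels = (
            self.provisional_labels
            if self.provisional_labels is not None
            else np.zeros(n, dtype=int)
        )
        sizes = (
            self.component_sizes
            if self.component_sizes is not None
            else np.zeros(n, dtype=int)
        )
        write_points_tsv(path, labels, self.points, extra={"n_voxels": sizes})

    @classmethod
    def from_tsv(cls, path) -> "DetectionCloud":
        labels, points, extras = read_points_tsv(path)
        sizes = extras.get("n_voxels")
        return cls(
            points,
            provisional_labels=np.asarray(labels, dtype=int),
            component_sizes=None if sizes is None else np.asarray(sizes, dtype=int),
        )


def read_labeled_volume(path) -> LabeledVolume:
    """Load a NIfTI-1 label map, verifying integer voxel values.

    Values are rounded to the nearest integer; any voxel farther than
    1e-3 from an integer means the file is not a label map and a
    ``ValueError`` is raised.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if np.max(np.abs(data - rounded)) > _INTEGER_TOL:
            raise ValueError(f"{path}: voxel values are not integers")
        data = rounded
    return LabeledVolume(data.astype(np.int32), img.affine)


def write_labeled_volume(vol: LabeledVolume, path) -> None:
    nib.save(nib.Nifti1Image(vol.grid.astype(np.int16), vol.affine), str(path))


def extract_centroids(vol: LabeledVolume, min_voxels: int = 2) -> DetectionCloud:
    """One world-space centroid per connected component of each label.

    Components are found with 26-connectivity separately within each
    label value, so touching spheres of different labels stay distinct; a
    label split into several blobs yields several detections. Components
    smaller than ``min_voxels`` voxels are dropped as speckle. The
    centroid is the unweighted mean voxel index of the component mapped
    through the affine. Ordering is deterministic: ascending label value,
    then component discovery order.
    """
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    points: list[np.ndarray] = []
    prov: list[int] = []
    sizes: list[int] = []
    max_label = int(vol.grid.max(initial=0))
    # Per-label bounding boxes keep component labeling local and fast.
    boxes = ndimage.find_objects(vol.grid, max_label=max_label)
    for value, box in enumerate(boxes, start=1):
        if box is None:
            continue
        offset = np.array([s.start for s in box], dtype=float)
        comp, n_comp = ndimage.label(
            vol.grid[box] == value, structure=_STRUCTURE_26
        )
        if n_comp == 0:
            continue
        counts = np.bincount(comp.ravel(), minlength=n_comp + 1)
        centers = ndimage.center_of_mass(
            np.ones_like(comp, dtype=np.uint8), comp, range(1, n_comp + 1)
        )
        for ci, center in enumerate(centers, start=1):
            if counts[ci] < min_voxels:
                continue
            points.append(vol.voxel_to_world(offset + np.asarray(center)))
            prov.append(int(value))
            sizes.append(int(counts[ci]))
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    return DetectionCloud(
        pts,
        provisional_labels=np.asarray(prov, dtype=int),
        component_sizes=np.asarray(sizes, dtype=int),
    )
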