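"""Gridded 3D volumes with world-coordinate metadata.

One lightweight container backs scalar images, binary masks and label
maps; the distinction is carried by dtype.  World mapping follows the
usual convention  world = origin + direction @ (index * spacing)  with
0-based indices and LPS axes.  NIfTI I/O goes through nibabel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, Tuple

import nibabel as nib
import numpy as np

__all__ = ["Volume", "LABELS", "LABEL_NAMES", "load_nifti", "save_nifti"]

#: Segment label encoding for label maps (0 = background).
LABELS: Dict[str, int] = {
    "background": 0,
    "condyle_L": 1,
    "coronoid_L": 2,
    "ramus_L": 3,
    "hemibody_L": 4,
    "condyle_R": 5,
    "coronoid_R": 6,
    "ramus_R": 7,
    "hemibody_R": 8,
}
LABEL_NAMES = {v: k for k, v in LABELS.items()}


@dataclass
class Volume:
    """A 3D grid plus spacing/origin/direction metadata.

    ``values`` is indexed [i, j, k] along the world x/y/z-ish axes given by
    the columns of ``direction``.
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be strictly positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if not np.allclose(self.direction @ self.direction.T, np.eye(3),
                           atol=1e-6):
            raise ValueError("direction matrix must be orthonormal")

    # ------------------------------------------------------------------
    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def affine(self) -> np.ndarray:
        A = np.eye(4)
        A[:3, :3] = self.direction * self.spacing[None, :]
        A[:3, 3] = self.origin
        return A

    def index_to_world(self, indices) -> np.ndarray:
        idx = np.asarray(indices, dtype=float)
        return idx * self.spacing @ self.direction.T + self.origin

    def axis_coordinates(self):
        """Per-axis world coordinates (valid for axis-aligned grids)."""
        if not np.allclose(self.direction, np.eye(3)):
            raise ValueError("axis coordinates require an identity direction")
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def foreground_indices(self) -> np.ndarray:
        """(n, 3) integer indices of nonzero voxels."""
        return np.argwhere(self.values)

    def foreground_points(self) -> np.ndarray:
        """(n, 3) world coordinates of nonzero voxel centers."""
        return self.index_to_world(self.foreground_indices())

    def with_values(self, values: np.ndarray) -> "Volume":
        return Volume(values, self.spacing.copy(), self.origin.copy(),
                      self.direction.copy())

    def same_grid(self, other: "Volume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def save_nifti(volume: Volume, path, *, labels_sidecar: bool = False) -> None:
    """Write a volume as NIfTI; optionally a JSON sidecar naming the labels.

    NIfTI affines are RAS; the stored affine converts from our LPS world by
    negating the first two rows.
    """
    path = Path(path)
    lps_to_ras = np.diag([-1.0, -1.0, 1.0, 1.0])
    img = nib.Nifti1Image(np.asarray(volume.values), lps_to_ras @ volume.affine)
    nib.save(img, str(path))
    if labels_sidecar:
        sidecar = path.with_name(path.name.split(".")[0] + "_labels.json")
        sidecar.write_text(json.dumps(LABEL_NAMES, indent=2))


def load_nifti(path, dtype=None) -> Volume:
    """Read a NIfTI file into a Volume (world converted RAS -> LPS)."""
    img = nib.load(str(path))
    affine = np.diag([-1.0, -1.0, 1.0, 1.0]) @ img.affine
    R = affine[:3, :3]
    spacing = np.linalg.norm(R, axis=0)
    direction = R / spacing[None, :]
    values = np.asarray(img.dataobj)
    if dtype is not None:
        values = values.astype(dtype)
    return Volume(values, spacing, affine[:3, 3], direction)
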