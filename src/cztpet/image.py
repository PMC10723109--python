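"""Voxelised activity images: phantom inputs and reconstruction outputs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ActivityImage:
    """A voxel grid of non-negative activity.

    ``data[i, j, k]`` is the activity in the voxel whose lower corner sits at
    ``origin + (i, j, k) * spacing`` (mm); ``origin`` is the grid's lower
    corner, so the voxel centre is offset by half a spacing.
    """

    data: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    spacing: np.ndarray = field(default_factory=lambda: np.full(3, 0.25))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.broadcast_to(np.asarray(self.spacing, float), (3,)).copy()
        if np.any(self.data < 0) or not np.all(np.isfinite(self.data)):
            raise ValueError("activity must be non-negative and finite")

    @classmethod
    def empty(cls, shape, spacing, centre=(0.0, 0.0, 0.0)) -> "ActivityImage":
        shape = np.asarray(shape, int)
        spacing = np.broadcast_to(np.asarray(spacing, float), (3,))
        origin = np.asarray(centre, float) - shape * spacing / 2.0
        return cls(np.zeros(shape), origin, spacing)

    @property
    def total_activity(self) -> float:
        return float(self.data.sum())

    @property
    def shape(self):
        return self.data.shape

    def voxel_centres(self) -> np.ndarray:
        """(N, 3) centres of all voxels in index order."""
        axes = [self.origin[d] + (np.arange(self.data.shape[d]) + 0.5) * self.spacing[d]
                for d in range(3)]
        g = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([a.ravel() for a in g])

    def copy_with(self, data: np.ndarray) -> "ActivityImage":
        return ActivityImage(data, self.origin.copy(), self.spacing.copy())

    def save_nifti(self, path) -> None:
        """Optional NIfTI export (requires nibabel)."""
        import nibabel as nib
        affine = np.diag([*self.spacing, 1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), affine), str(path))
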