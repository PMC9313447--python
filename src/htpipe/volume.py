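"""Minimal 3-D image container shared by every stage.

Axis convention: axis 0 is the left–right axis (index 0 = leftmost sagittal
slice), axis 1 anterior–posterior, axis 2 inferior–superior.  Mirroring about
the mid-sagittal plane is therefore a flip along axis 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: axis about which the brain is (assumed) bilaterally symmetric
SYMMETRY_AXIS = 0


@dataclass
class ImageVolume:
    """A 3-D scalar array with voxel spacing in millimetres."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"ImageVolume requires a 3-D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def like(self, data: np.ndarray) -> "ImageVolume":
        """New volume on the same grid/spacing with different data."""
        return ImageVolume(data, self.spacing)

    # ------------------------------------------------------------------ I/O
    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing) + [1.0])
        img = nib.Nifti1Image(np.asanyarray(self.data), affine)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "ImageVolume":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj), spacing)
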