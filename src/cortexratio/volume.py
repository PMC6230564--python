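"""3D scalar volumes with physical voxel spacing.

A :class:`ScalarVolume` is the carrier for every image in the pipeline:
the T1-weighted and T2-weighted contrasts, bias fields, normalized depth
maps and ratio images.  Volumes live on an axis-aligned RAS grid whose
world coordinate of voxel index ``i`` along axis ``k`` is
``i * spacing[k]`` (origin at the first voxel, no rotation in the
affine).  That convention keeps the phantom geometry, the rigid
transforms and the NIfTI headers consistent with each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np


@dataclass
class ScalarVolume:
    """A 3D intensity grid plus per-axis voxel size in mm (RAS)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be three positive numbers, got {self.spacing}")
        # NaN is permitted as a missing-value marker in derived images
        # (e.g. ratio voxels excluded by the denominator floor); infinities
        # always indicate a bug upstream.
        if np.any(np.isinf(self.data)):
            raise ValueError("volume contains infinite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def like(self, data: np.ndarray) -> "ScalarVolume":
        """New volume on this grid with different data."""
        return ScalarVolume(np.asarray(data, dtype=np.float64), self.spacing)

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.data.copy(), self.spacing)

    def same_grid(self, other: "ScalarVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    # --- coordinates -------------------------------------------------

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World (mm) coordinate arrays of every voxel center."""
        ax = [np.arange(n) * s for n, s in zip(self.shape, self.spacing)]
        return np.meshgrid(*ax, indexing="ij")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        return aff

    # --- I/O ---------------------------------------------------------

    def to_nifti(self, path: str) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, path)

    @classmethod
    def from_nifti(cls, path: str) -> "ScalarVolume":
        img = nib.load(path)
        data = np.asanyarray(img.dataobj, dtype=np.float64)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(data, spacing)


@dataclass
class BinaryMask:
    """Boolean grid tied to a source volume's grid, with a provenance tag."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tag: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def to_nifti(self, path: str) -> None:
        aff = np.diag(list(self.spacing) + [1.0])
        img = nib.Nifti1Image(self.data.astype(np.uint8), aff)
        img.header.set_zooms(self.spacing)
        nib.save(img, path)

    @classmethod
    def from_nifti(cls, path: str, tag: str = "") -> "BinaryMask":
        img = nib.load(path)
        data = np.asanyarray(img.dataobj) > 0
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(data, spacing, tag)


def save_labels(labels: np.ndarray, spacing, path: str) -> None:
    """Write an integer label volume as NIfTI (int16)."""
    aff = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), aff)
    img.header.set_zooms(tuple(spacing))
    nib.save(img, path)


def load_labels(path: str) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(path)
    data = np.asanyarray(img.dataobj).astype(np.int32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing
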