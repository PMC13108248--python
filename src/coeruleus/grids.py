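"""Volumetric containers shared by every imaging stage.

A :class:`VolumeGrid` is a 3D scalar image (neuromelanin slab, SUVR map,
statistical map) together with its voxel size; a :class:`MaskSet` bundles the
three anatomical regions the LC pipeline needs — left and right LC search
spaces and the pontomesencephalic reference region — as boolean arrays on the
same grid.  NIfTI-1 round-tripping goes through nibabel; the affine is a
diagonal scaling by the voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VolumeGrid", "MaskSet"]


@dataclass
class VolumeGrid:
    """A 3D scalar image with voxel-size metadata.

    Parameters
    ----------
    data
        3D array of intensities (scanner units, normalized units, or SUVR).
    voxel_size
        Edge length of a voxel along each axis, in mm.
    slice_axis
        Axis indexing axial slices (the slab's through-plane direction).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    slice_axis: int = 2

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"invalid voxel size {self.voxel_size}")
        if self.slice_axis not in (0, 1, 2):
            raise ValueError("slice_axis must be 0, 1 or 2")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[self.slice_axis]

    def slice_view(self, index: int) -> np.ndarray:
        """A view of axial slice ``index`` (writable)."""
        sl: list = [slice(None)] * 3
        sl[self.slice_axis] = index
        return self.data[tuple(sl)]

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        return aff

    def copy(self) -> "VolumeGrid":
        return VolumeGrid(self.data.copy(), tuple(self.voxel_size), self.slice_axis)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.float32), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, img_or_path, slice_axis: int = 2) -> "VolumeGrid":
        img = img_or_path
        if not isinstance(img, nib.spatialimages.SpatialImage):
            img = nib.load(str(img_or_path))
        data = np.asanyarray(img.dataobj, dtype=float)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(data, zooms, slice_axis)


@dataclass
class MaskSet:
    """Left/right LC search spaces plus the reference region on one grid."""

    lc_search_left: np.ndarray
    lc_search_right: np.ndarray
    reference: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.lc_search_left = np.asarray(self.lc_search_left, dtype=bool)
        self.lc_search_right = np.asarray(self.lc_search_right, dtype=bool)
        self.reference = np.asarray(self.reference, dtype=bool)
        shapes = {self.lc_search_left.shape, self.lc_search_right.shape, self.reference.shape}
        if len(shapes) != 1:
            raise ValueError(f"mask shapes differ: {shapes}")
        for name in ("lc_search_left", "lc_search_right", "reference"):
            if not getattr(self, name).any():
                raise ValueError(f"mask {name!r} is empty")
        if (self.reference & (self.lc_search_left | self.lc_search_right)).any():
            raise ValueError("reference region overlaps an LC search space")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.reference.shape

    def search(self, side: str) -> np.ndarray:
        if side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        return self.lc_search_left if side == "left" else self.lc_search_right

    def check_grid(self, volume: VolumeGrid) -> None:
        if volume.shape != self.shape:
            raise ValueError(
                f"mask shape {self.shape} does not match volume shape {volume.shape}"
            )

    def save(self, path) -> None:
        """Write a single label volume: 1=left search, 2=right search, 3=reference."""
        lab = np.zeros(self.shape, dtype=np.int16)
        lab[self.lc_search_left] = 1
        lab[self.lc_search_right] = 2
        lab[self.reference] = 3
        aff = np.diag(list(self.voxel_size) + [1.0])
        nib.save(nib.Nifti1Image(lab, aff), str(path))

    @classmethod
    def from_nifti(cls, img_or_path) -> "MaskSet":
        img = img_or_path
        if not isinstance(img, nib.spatialimages.SpatialImage):
            img = nib.load(str(img_or_path))
        lab = np.asanyarray(img.dataobj)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(lab == 1, lab == 2, lab == 3, zooms)
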