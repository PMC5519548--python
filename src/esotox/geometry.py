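"""Voxel-lattice containers for serial esophagus geometry and planned dose.

Conventions used throughout the package:

* axial slices are ordered superior -> inferior and indexed from 0;
* slice masks are binary (a voxel belongs to the esophagus or it does not);
* the dose grid shares the geometry's voxel lattice exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EsophagusGeometry", "DoseGrid", "LatticeMismatchError"]


class LatticeMismatchError(ValueError):
    """Two objects that must share one voxel lattice do not."""


@dataclass(eq=False)
class EsophagusGeometry:
    """Per-slice binary esophagus masks on a regular voxel lattice.

    Parameters
    ----------
    slice_masks : ndarray of bool, shape (n_slices, ny, nx)
        Axial cross-sectional masks, superior to inferior. Slices outside the
        contoured extent (above the cricoid, below the gastroesophageal
        junction) are empty.
    slice_thickness : float
        Axial voxel size in mm.
    in_plane_spacing : float
        Isotropic in-plane voxel size in mm.
    """

    slice_masks: np.ndarray
    slice_thickness: float
    in_plane_spacing: float

    def __post_init__(self) -> None:
        self.slice_masks = np.asarray(self.slice_masks, dtype=bool)
        if self.slice_masks.ndim != 3:
            raise ValueError("slice_masks must be a 3-D (n_slices, ny, nx) array")
        if self.slice_thickness <= 0 or self.in_plane_spacing <= 0:
            raise ValueError("voxel dimensions must be positive")

    @property
    def n_slices(self) -> int:
        return self.slice_masks.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.slice_masks.shape

    def voxel_counts(self) -> np.ndarray:
        """Per-slice esophagus voxel counts."""
        return self.slice_masks.sum(axis=(1, 2))

    def areas_mm2(self) -> np.ndarray:
        """Per-slice cross-sectional areas in mm^2."""
        return self.voxel_counts() * self.in_plane_spacing**2

    def length_cm(self) -> float:
        """Contoured esophagus length (sum of non-empty slice thicknesses), cm."""
        return float((self.voxel_counts() > 0).sum() * self.slice_thickness / 10.0)

    def same_lattice(self, other: "EsophagusGeometry") -> bool:
        return (
            self.shape == other.shape
            and self.slice_thickness == other.slice_thickness
            and self.in_plane_spacing == other.in_plane_spacing
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EsophagusGeometry):
            return NotImplemented
        return self.same_lattice(other) and np.array_equal(
            self.slice_masks, other.slice_masks
        )


@dataclass(eq=False)
class DoseGrid:
    """Planned physical dose (Gy) voxel-aligned with an :class:`EsophagusGeometry`."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("dose values must be a 3-D array")
        if np.any(self.values < 0):
            raise ValueError("dose values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def check_aligned(self, geometry: EsophagusGeometry) -> None:
        if self.shape != geometry.shape:
            raise LatticeMismatchError(
                f"dose grid shape {self.shape} != geometry shape {geometry.shape}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DoseGrid):
            return NotImplemented
        return self.values.dtype == other.values.dtype and np.array_equal(
            self.values, other.values
        )
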