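"""Rectilinear voxel containers: density phantoms, structure masks, dose grids.

All grids are axis-aligned in the patient coordinate system (mm).  Voxel
indexing is 0-based and a voxel's stored position is its centre, so voxel
``(i, j, k)`` sits at ``origin + (i, j, k) * spacing``.  Arrays are indexed
``[ix, iy, iz]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import ValidationError


def _as_spacing(spacing) -> np.ndarray:
    s = np.asarray(spacing, dtype=float)
    if s.ndim == 0:
        s = np.repeat(s, 3)
    if s.shape != (3,) or np.any(s <= 0):
        raise ValidationError("spacing must be a positive 3-vector")
    return s


@dataclass
class GridGeometry:
    """Shape-free geometry descriptor shared by all grid types."""

    spacing_mm: np.ndarray
    origin_mm: np.ndarray

    def __post_init__(self) -> None:
        self.spacing_mm = _as_spacing(self.spacing_mm)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.origin_mm.shape != (3,):
            raise ValidationError("origin must be a 3-vector")

    def axes(self, shape) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin_mm[i] + self.spacing_mm[i] * np.arange(shape[i])
            for i in range(3)
        )

    def voxel_centers(self, shape) -> np.ndarray:
        """All voxel centre positions, shape (N, 3), C order."""
        ax = self.axes(shape)
        xx, yy, zz = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    def to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of physical points, shape (N, 3)."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (pts - self.origin_mm) / self.spacing_mm

    def same_as(self, other: "GridGeometry", atol: float = 1e-9) -> bool:
        return (np.allclose(self.spacing_mm, other.spacing_mm, atol=atol)
                and np.allclose(self.origin_mm, other.origin_mm, atol=atol))


class _Grid:
    """Mixin for objects carrying an array plus a GridGeometry."""

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(self.spacing_mm, self.origin_mm)

    @property
    def voxel_volume_ccm(self) -> float:
        return float(np.prod(_as_spacing(self.spacing_mm))) / 1000.0


@dataclass
class PhantomVolume(_Grid):
    """Voxel grid of mass density (g/cm^3) standing in for a patient CT."""

    density: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        self.spacing_mm = _as_spacing(self.spacing_mm)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.density.ndim != 3 or self.density.size == 0:
            raise ValidationError("density must be a non-empty 3D array")
        if np.any(self.density < 0) or not np.all(np.isfinite(self.density)):
            raise ValidationError("densities must be finite and >= 0")

    def sample_density(self, points_mm: np.ndarray) -> np.ndarray:
        """Trilinear density at physical points; 0 outside the grid."""
        idx = self.geometry.to_index(points_mm)
        return ndimage.map_coordinates(
            self.density, idx.T, order=1, mode="constant", cval=0.0)


@dataclass
class StructureSet(_Grid):
    """Named regions of interest as boolean masks on one grid geometry.

    Recognised role names: ``PTV``, ``rectum``, ``bladder``, ``femur_left``,
    ``femur_right``, ``external``.
    """

    masks: dict[str, np.ndarray]
    spacing_mm: np.ndarray
    origin_mm: np.ndarray

    ROLES = ("PTV", "rectum", "bladder", "femur_left", "femur_right",
             "external")

    def __post_init__(self) -> None:
        self.spacing_mm = _as_spacing(self.spacing_mm)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        self.masks = {k: np.asarray(v, dtype=bool) for k, v in self.masks.items()}
        self.validate()

    def validate(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValidationError("all masks must share one grid shape")
        if "PTV" in self.masks and not self.masks["PTV"].any():
            raise ValidationError("PTV mask must be non-empty")

    def volume_ccm(self, name: str) -> float:
        return float(self.masks[name].sum()) * self.voxel_volume_ccm

    def mask_on(self, geometry: GridGeometry, shape) -> dict[str, np.ndarray]:
        """Masks resampled (nearest neighbour) onto another grid geometry."""
        if self.geometry.same_as(geometry):
            return dict(self.masks)
        pts = geometry.voxel_centers(shape)
        idx = self.geometry.to_index(pts)
        out = {}
        for name, mask in self.masks.items():
            vals = ndimage.map_coordinates(
                mask.astype(np.float32), idx.T, order=0, mode="constant",
                cval=0.0)
            out[name] = (vals > 0.5).reshape(shape)
        return out


@dataclass
class DoseGrid(_Grid):
    """3D absorbed dose (Gy) with geometry and a statistical-uncertainty label."""

    dose: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray
    uncertainty_label: str = "none"  # one of: fine, extra_fine, none

    LABELS = ("fine", "extra_fine", "none")

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.spacing_mm = _as_spacing(self.spacing_mm)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.dose.ndim != 3 or self.dose.size == 0:
            raise ValidationError("dose must be a non-empty 3D array")
        if not np.all(np.isfinite(self.dose)) or np.any(self.dose < 0):
            raise ValidationError("doses must be finite and >= 0")
        if self.uncertainty_label not in self.LABELS:
            raise ValidationError(
                f"uncertainty label must be one of {self.LABELS}")

    def sample(self, points_mm: np.ndarray) -> np.ndarray:
        """Trilinear dose at physical points (must lie inside the grid)."""
        idx = self.geometry.to_index(points_mm)
        upper = np.array(self.dose.shape) - 1
        if np.any(idx < -1e-9) or np.any(idx > upper + 1e-9):
            raise ValidationError("point lies outside the dose grid")
        return ndimage.map_coordinates(
            self.dose, idx.T, order=1, mode="nearest")
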