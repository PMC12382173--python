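"""Scalar 3-D volumes with world-space geometry.

A :class:`Volume3D` couples a voxel grid with a NIfTI-style 4x4 affine
(voxel index -> world mm, RAS+). Arrays are indexed ``[i, j, k]`` in the
same axis order nibabel uses, so round-trips through ``.nii`` files are
lossless. Conversion helpers to/from SimpleITK keep the affine's world
frame as the ITK physical space, which makes transform parameters
directly comparable across the phantom and registration modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = ["Volume3D", "RigidTransform", "centered_affine"]


def centered_affine(shape: tuple[int, int, int], voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    """Axis-aligned affine placing the grid center at the world origin.

    Voxel centers span symmetrically around 0 on every axis, so mirroring
    index ``i -> n-1-i`` is an exact world-space reflection about the
    midplane (used for contralateral lookups).
    """
    affine = np.eye(4)
    for ax in range(3):
        affine[ax, ax] = voxel_size_mm[ax]
        affine[ax, 3] = -0.5 * (shape[ax] - 1) * voxel_size_mm[ax]
    return affine


@dataclass
class Volume3D:
    """A 3-D scalar voxel grid with an invertible voxel-to-world affine."""

    values: np.ndarray
    affine: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D array, got shape {self.values.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm per axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_centers_mm(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape ``(*grid, 3)``."""
        idx = np.stack(
            np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij"), axis=-1
        ).astype(float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def same_grid_as(self, other: "Volume3D", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)

    # -- I/O --------------------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.values, dtype=np.float32), self.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path, **meta: Any) -> "Volume3D":
        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine), meta)

    # -- SimpleITK bridge -------------------------------------------------
    def to_sitk(self) -> sitk.Image:
        img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(self.values, (2, 1, 0)).astype(np.float64)))
        spacing = self.spacing
        direction = self.affine[:3, :3] / spacing[np.newaxis, :]
        img.SetSpacing(tuple(float(s) for s in spacing))
        img.SetDirection(tuple(direction.flatten()))
        img.SetOrigin(tuple(float(o) for o in self.affine[:3, 3]))
        return img

    @classmethod
    def from_sitk(cls, img: sitk.Image, **meta: Any) -> "Volume3D":
        values = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0)).astype(float)
        direction = np.asarray(img.GetDirection()).reshape(3, 3)
        spacing = np.asarray(img.GetSpacing())
        affine = np.eye(4)
        affine[:3, :3] = direction * spacing[np.newaxis, :]
        affine[:3, 3] = img.GetOrigin()
        return cls(values, affine, meta)


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF rigid body transform: Euler rotations (deg) about a center, plus translation (mm).

    Maps a world point ``p`` to ``R (p - c) + c + t`` with ``R`` built from
    rotations about the x, y, z axes (applied z-last, matching ITK's
    Euler3DTransform in its default ZYX composition).
    """

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def to_sitk(self) -> sitk.Euler3DTransform:
        t = sitk.Euler3DTransform()
        t.SetCenter([float(c) for c in self.center_mm])
        t.SetRotation(*[float(np.deg2rad(a)) for a in self.rotation_deg])
        t.SetTranslation([float(x) for x in self.translation_mm])
        return t

    @classmethod
    def from_sitk(cls, t: sitk.Euler3DTransform) -> "RigidTransform":
        angles = np.rad2deg([t.GetAngleX(), t.GetAngleY(), t.GetAngleZ()])
        return cls(
            rotation_deg=tuple(float(a) for a in angles),
            translation_mm=tuple(float(x) for x in t.GetTranslation()),
            center_mm=tuple(float(c) for c in t.GetCenter()),
        )

    @property
    def rotation_matrix(self) -> np.ndarray:
        return np.asarray(self.to_sitk().GetMatrix()).reshape(3, 3)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform world points; accepts any ``(..., 3)`` array."""
        p = np.asarray(points, dtype=float)
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        return (p - c) @ self.rotation_matrix.T + c + t

    def inverse(self) -> "RigidTransform":
        # closed form (ITK's GetInverse runs an SVD that chokes on denormal
        # angles): x = R^T (y - c) + c - R^T t
        rot = self.rotation_matrix
        t = sitk.Euler3DTransform()
        t.SetCenter([float(v) for v in self.center_mm])
        t.SetMatrix([float(v) for v in rot.T.flatten()])
        t.SetTranslation([float(v) for v in -rot.T @ np.asarray(self.translation_mm)])
        return RigidTransform.from_sitk(t)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform ``self o other`` (apply ``other`` first)."""
        m_self = self.rotation_matrix
        m_other = other.rotation_matrix
        rot = m_self @ m_other
        # composed: x -> Rs(Ro(x-co)+co+to-cs)+cs+ts; express about self.center
        c = np.asarray(self.center_mm)
        offset = m_self @ (other.apply(c) - c) + np.asarray(self.translation_mm)
        t = sitk.Euler3DTransform()
        t.SetCenter([float(v) for v in c])
        t.SetMatrix([float(v) for v in rot.flatten()])
        t.SetTranslation([float(v) for v in offset])
        return RigidTransform.from_sitk(t)

    def magnitude(self, reference_point: np.ndarray | None = None) -> tuple[float, float]:
        """(displacement mm at ``reference_point`` or the center, rotation angle deg)."""
        p = np.asarray(reference_point if reference_point is not None else self.center_mm, dtype=float)
        disp = float(np.linalg.norm(self.apply(p) - p))
        tr = np.clip((np.trace(self.rotation_matrix) - 1.0) / 2.0, -1.0, 1.0)
        return disp, float(np.rad2deg(np.arccos(tr)))
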