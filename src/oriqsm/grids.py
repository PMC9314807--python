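"""Core spatial containers: 3D volumes on a regular lattice and unit directions.

A :class:`VolumeGrid` carries a scalar 3D array together with its voxel size
and a world affine, and is the common currency for field maps, masks and
susceptibility maps throughout the package.  Directions (the main field B0
and the dominant fiber axis of a specimen) are thin unit-vector wrappers that
make the sign conventions explicit: B0 has a physical sign, a fiber axis is
antipodally symmetric (v and -v describe the same axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "B0Direction",
    "FiberDirection",
    "InvalidDirectionError",
]


class InvalidDirectionError(ValueError):
    """Raised for zero-norm or badly normalised direction vectors."""


def _default_affine(voxel_size: np.ndarray) -> np.ndarray:
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = voxel_size
    return affine


@dataclass
class VolumeGrid:
    """A 3D scalar lattice with voxel size [mm] and a 4x4 world affine.

    Parameters
    ----------
    data:
        Real or complex 3D array.  All dimensions must be >= 4.
    voxel_size:
        Edge lengths of a voxel in mm, strictly positive.
    affine:
        4x4 voxel-to-world transform; defaults to a diagonal scaling by the
        voxel size.
    """

    data: np.ndarray
    voxel_size: np.ndarray = field(default=None)  # type: ignore[assignment]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 4:
            raise ValueError(f"all dimensions must be >= 4, got {self.data.shape}")
        if self.voxel_size is None:
            self.voxel_size = np.ones(3)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.voxel_size.shape != (3,) or np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be 3 strictly positive lengths")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def like(self, data: np.ndarray) -> "VolumeGrid":
        """A new grid with the same geometry and different data."""
        return VolumeGrid(data, voxel_size=self.voxel_size.copy(), affine=self.affine.copy())

    def require_finite(self, name: str = "volume") -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"{name} contains non-finite values")

    def same_geometry(self, other: "VolumeGrid", atol: float = 1e-9) -> bool:
        return self.shape == other.shape and np.allclose(
            self.voxel_size, other.voxel_size, atol=atol
        )

    # --- NIfTI I/O -------------------------------------------------------
    @classmethod
    def from_nifti(cls, path: str | Path) -> "VolumeGrid":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim == 4 and data.shape[3] == 1:
            data = data[..., 0]
        zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
        return cls(np.asarray(data, dtype=float), voxel_size=zooms, affine=np.asarray(img.affine))

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float64), self.affine)
        img.header.set_zooms(tuple(self.voxel_size))
        nib.save(img, str(path))


def _unit_vector(vector, what: str) -> np.ndarray:
    v = np.asarray(vector, dtype=float).reshape(-1)
    if v.shape != (3,):
        raise InvalidDirectionError(f"{what} must be a 3-vector, got shape {v.shape}")
    norm = float(np.linalg.norm(v))
    if norm < 1e-12:
        raise InvalidDirectionError(f"{what} has zero norm")
    return v / norm


@dataclass(frozen=True)
class B0Direction:
    """Unit vector of the main magnetic field in the common (registered) frame."""

    vector: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "vector", _unit_vector(self.vector, "B0 direction"))

    def angle_to(self, other: "B0Direction") -> float:
        """Angle in degrees, folded to [0, 90] (dipole physics is antipodal)."""
        c = abs(float(np.dot(self.vector, other.vector)))
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass(frozen=True)
class FiberDirection:
    """Dominant fiber axis of a specimen; antipodally equivalent (v == -v)."""

    vector: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "vector", _unit_vector(self.vector, "fiber direction"))


def mean_fiber_direction(vectors: np.ndarray) -> FiberDirection:
    """Mean axis of a bundle of (possibly sign-flipped) unit vectors.

    Naive averaging cancels antipodal pairs, so the mean axis is taken as the
    principal eigenvector of the dyadic average sum(v v^T), which is invariant
    under per-vector sign flips.
    """
    v = np.asarray(vectors, dtype=float)
    if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] == 0:
        raise ValueError("expected an (n, 3) array of direction samples")
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    if np.any(norms < 1e-12):
        raise InvalidDirectionError("zero-norm fiber sample")
    v = v / norms
    dyad = v.T @ v
    _, eigvecs = np.linalg.eigh(dyad)
    return FiberDirection(eigvecs[:, -1])
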