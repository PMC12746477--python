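"""Grid-attached 3D volumes and displacement fields.

Conventions used throughout the package:

* voxel indices are 0-based ``(i, j, k)`` along axes ``(x, y, z)``;
* displacement fields live on the *fixed* grid and are stored in **voxel
  units**: a field ``u`` maps fixed-image coordinates ``x`` to moving-image
  coordinates ``x + u(x)``;
* physical quantities (spacings, margins, Hausdorff distances) are in mm.

:func:`mm_to_voxel` / :func:`voxel_to_mm` are the single owners of the unit
conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

Modality = str  # one of {"CT-like", "MR-like", "mask", "field-component"}

_MODALITIES = ("CT-like", "MR-like", "mask", "field-component")


@dataclass
class Volume3D:
    """A scalar 3D image on a regular grid.

    Parameters
    ----------
    data
        3D array of voxel values.
    spacing
        Physical voxel size in mm along each axis; strictly positive.
    origin
        Physical coordinate (mm) of voxel ``(0, 0, 0)``.
    modality
        Semantic tag; masks are validated to be binary.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: Modality = "CT-like"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D requires a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume3D data contains non-finite values")
        if self.modality not in _MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == "mask":
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("mask volumes must contain only {0, 1}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray, modality: Modality | None = None) -> "Volume3D":
        """Copy of this volume carrying new voxel data on the same grid."""
        return replace(self, data=data, modality=modality or self.modality)

    def same_grid(self, other: "Volume3D", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class DisplacementField:
    """Per-voxel 3-vector displacement over the fixed grid.

    ``u`` has shape ``(3, nx, ny, nz)`` with components in voxel units of the
    fixed grid; it maps fixed coordinates ``x`` to moving coordinates
    ``x + u(x)``.
    """

    u: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        if self.u.ndim != 4 or self.u.shape[0] != 3:
            raise ValueError(f"field must have shape (3, nx, ny, nz), got {self.u.shape}")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement field contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def grid_shape(self) -> Tuple[int, int, int]:
        return self.u.shape[1:]  # type: ignore[return-value]

    def magnitude_mm(self) -> np.ndarray:
        """Voxelwise displacement magnitude in mm (spacing applied per axis)."""
        sp = np.asarray(self.spacing).reshape(3, 1, 1, 1)
        return np.sqrt(np.sum((self.u * sp) ** 2, axis=0))

    def magnitude_voxels(self) -> np.ndarray:
        return np.sqrt(np.sum(self.u**2, axis=0))

    def mean_magnitude_mm(self, mask: np.ndarray | None = None) -> float:
        """Mean displacement magnitude in mm, optionally restricted to a mask."""
        mag = self.magnitude_mm()
        if mask is None:
            return float(mag.mean())
        mask = np.asarray(mask).astype(bool)
        if mask.shape != mag.shape:
            raise ValueError("mask shape does not match field grid")
        if not mask.any():
            raise ValueError("mask is empty")
        return float(mag[mask].mean())


def mm_to_voxel(mm, spacing) -> np.ndarray:
    """Convert physical lengths (mm) to voxel units, per axis."""
    return np.asarray(mm, dtype=float) / np.asarray(spacing, dtype=float)


def voxel_to_mm(vox, spacing) -> np.ndarray:
    """Convert voxel-unit lengths to mm, per axis."""
    return np.asarray(vox, dtype=float) * np.asarray(spacing, dtype=float)
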