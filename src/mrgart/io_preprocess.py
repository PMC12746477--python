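"""NIfTI I/O, grid resampling, rigid pre-alignment and ROI construction.

The registration network requires image pairs on a common grid, roughly
aligned; clinically that preprocessing happens on a planning workstation.
Here it is: :func:`read_volume`/:func:`write_volume` for NIfTI round trips,
:func:`resample_to_grid` for extent-preserving resampling about the grid
centre, :func:`rigid_prealign` for translation-only alignment (intensity
centroid, or a coarse mutual-information search over integer shifts), and
:func:`expand_mask` for the uniform physical-margin expansion that builds
the PTV+margin region of interest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Tuple

import nibabel as nib
import numpy as np
from scipy import ndimage

from .volume import DisplacementField, Volume3D


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def write_volume(volume: Volume3D, path: str | Path) -> Path:
    """Write a volume as NIfTI; spacing/origin go into a diagonal affine."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32),
                          _affine(volume.spacing, volume.origin))
    nib.save(img, str(path))
    return path


def write_field(field: DisplacementField, path: str | Path,
                origin=(0.0, 0.0, 0.0)) -> Path:
    """Write a displacement field as 4D NIfTI, vector components last axis."""
    path = Path(path)
    data = np.moveaxis(field.u, 0, -1).astype(np.float32)  # (nx, ny, nz, 3)
    img = nib.Nifti1Image(data, _affine(field.spacing, origin))
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path, modality: str = "CT-like") -> Volume3D:
    """Read a 3D NIfTI volume.

    Raises on missing files, non-3D payloads and NaN voxels. 4D files are
    displacement fields and must go through :func:`read_field`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(
            f"{path.name}: expected a 3D volume, got ndim={data.ndim} "
            "(4D files are displacement fields; use read_field)"
        )
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path.name}: volume contains NaN/Inf voxels")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    if modality == "mask":
        data = (data > 0.5).astype(np.float64)
    return Volume3D(data, spacing=zooms, origin=origin, modality=modality)


def read_field(path: str | Path) -> DisplacementField:
    """Read a 4D NIfTI displacement field (3 vector components, last axis)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"{path.name}: expected a 4D field with 3 components, got {data.shape}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path.name}: field contains NaN/Inf values")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return DisplacementField(np.moveaxis(data, -1, 0), spacing=zooms)


def resample_to_grid(
    volume: Volume3D,
    target_shape: Tuple[int, int, int],
    target_spacing: Tuple[float, float, float],
    interpolation: Literal["trilinear", "nearest"] = "trilinear",
) -> Volume3D:
    """Resample onto a new grid, preserving physical extent about the centre.

    Masks should use ``nearest`` (output stays binary), images ``trilinear``.
    """
    target_shape = tuple(int(s) for s in target_shape)
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_shape) or any(s <= 0 for s in target_spacing):
        raise ValueError("target shape and spacing must be positive")
    src_shape = np.array(volume.shape, dtype=float)
    src_sp = np.array(volume.spacing)
    tgt_shape = np.array(target_shape, dtype=float)
    tgt_sp = np.array(target_spacing)
    # physical position of output voxel j, measured from the grid centre,
    # mapped back to source voxel index
    out_idx = np.meshgrid(*[np.arange(n) for n in target_shape], indexing="ij")
    coords = []
    for ax in range(3):
        phys = (out_idx[ax] - (tgt_shape[ax] - 1) / 2.0) * tgt_sp[ax]
        coords.append(phys / src_sp[ax] + (src_shape[ax] - 1) / 2.0)
    order = 0 if interpolation == "nearest" else 1
    out = ndimage.map_coordinates(
        np.asarray(volume.data, dtype=np.float64), np.stack(coords), order=order, mode="nearest"
    )
    center_shift = (src_shape - 1) / 2.0 * src_sp - (tgt_shape - 1) / 2.0 * tgt_sp
    new_origin = tuple(np.asarray(volume.origin) + center_shift)
    if volume.modality == "mask":
        out = (out > 0.5).astype(np.float64)
    return Volume3D(out, spacing=target_spacing, origin=new_origin, modality=volume.modality)


def _centroid_vox(data: np.ndarray) -> np.ndarray:
    w = data - data.min()
    tot = w.sum()
    if tot <= 0:
        raise ValueError("flat image: intensity centroid undefined")
    idx = np.meshgrid(*[np.arange(n) for n in data.shape], indexing="ij")
    return np.array([float((w * g).sum() / tot) for g in idx])


def _translate(data: np.ndarray, shift_vox: np.ndarray) -> np.ndarray:
    # sample moving at x - shift so content moves by +shift
    idx = np.meshgrid(*[np.arange(n) for n in data.shape], indexing="ij")
    coords = np.stack([g - s for g, s in zip(idx, shift_vox)]).astype(float)
    return ndimage.map_coordinates(data, coords, order=1, mode="nearest")


def rigid_prealign(
    moving: Volume3D,
    fixed: Volume3D,
    method: Literal["centroid", "mi"] = "centroid",
    search_vox: int = 5,
    bins: int = 16,
) -> Tuple[Volume3D, Tuple[float, float, float]]:
    """Translate ``moving`` onto ``fixed``; returns (translated, shift_mm).

    ``centroid`` matches intensity centroids; ``mi`` exhaustively searches
    integer voxel shifts in ``[-search_vox, search_vox]^3`` maximizing
    hard-binned mutual information (robust across modalities, slower).
    The applied translation is rounded to whole voxels so that voxel values
    are moved, never interpolated (placement-only guarantee, at the cost of
    up to half a voxel of residual shift).
    """
    if moving.shape != fixed.shape:
        raise ValueError("rigid_prealign requires volumes on a common grid")
    if method == "centroid":
        shift_vox = _centroid_vox(fixed.data) - _centroid_vox(moving.data)
        shift_vox = np.round(shift_vox)
    elif method == "mi":
        from .dlir import mutual_information_hard

        if np.ptp(moving.data) == 0 or np.ptp(fixed.data) == 0:
            raise ValueError("flat image: MI alignment undefined")
        best, shift_vox = -np.inf, np.zeros(3)
        rng_ = range(-search_vox, search_vox + 1)
        for dx in rng_:
            for dy in rng_:
                for dz in rng_:
                    rolled = np.roll(moving.data, (dx, dy, dz), axis=(0, 1, 2))
                    mi, _ = mutual_information_hard(fixed.data, rolled, bins=bins)
                    if mi > best:
                        best, shift_vox = mi, np.array([dx, dy, dz], dtype=float)
    else:
        raise ValueError(f"unknown method {method!r}")
    translated = moving.with_data(_translate(np.asarray(moving.data, float), shift_vox))
    shift_mm = tuple(float(v) for v in shift_vox * np.asarray(moving.spacing))
    return translated, shift_mm


@dataclass
class ROIMask:
    """A structure mask expanded by a uniform physical margin."""

    mask: Volume3D
    source_structure: str
    margin_mm: float

    def __post_init__(self) -> None:
        if self.mask.modality != "mask":
            raise ValueError("ROIMask.mask must have modality 'mask'")
        if self.margin_mm < 0:
            raise ValueError("margin must be non-negative")


def expand_mask(structure: Volume3D, margin_mm: float, name: str = "structure") -> ROIMask:
    """Dilate a binary structure by a Euclidean ball of ``margin_mm``.

    Anisotropic spacing is respected: the distance transform is computed in
    physical units, so a 50 mm margin reaches 50 voxels at 1 mm spacing but
    only ⌊50/3⌋ slices at 3 mm slice thickness.
    """
    if margin_mm < 0:
        raise ValueError("margin must be non-negative")
    data = np.asarray(structure.data) > 0.5
    if not data.any():
        raise ValueError("cannot expand an empty structure")
    if margin_mm == 0:
        out = data.astype(np.float64)
    else:
        dist = ndimage.distance_transform_edt(~data, sampling=structure.spacing)
        out = (dist <= margin_mm).astype(np.float64)
    vol = Volume3D(out, spacing=structure.spacing, origin=structure.origin, modality="mask")
    return ROIMask(mask=vol, source_structure=name, margin_mm=float(margin_mm))
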