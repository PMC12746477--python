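"""Synthetic multimodal phantoms for adaptive-strategy pipelines.

One "treatment fraction" is emulated as a pair of 3D volumes of the same
pelvic-like anatomy — a pseudo-CT reference (moving image) and a pseudo-MR
daily image (fixed image) — related by a known smooth non-rigid deformation.
The anatomy is a set of overlapping soft ellipsoids (prostate-, bladder- and
rectum-like structures inside a body outline). The two modalities are
rendered through two fixed monotone intensity transfer functions: a
piecewise-linear "CT" map and a saturating nonlinear "MR" map plus Gaussian
noise, so that voxelwise intensity agreement between the pair is broken
while their mutual information is preserved — the regime in which an MI
similarity term is required for registration.

The deformation is a Gaussian-correlated random vector field (white noise
smoothed to a controllable correlation length, rescaled to a peak
magnitude). The fraction's ground-truth strategy label is geometric: the
case is ATS (adapt to shape, i.e. replan) when the mean displacement
magnitude inside the PTV-surrogate ROI exceeds ``label_threshold`` mm, ATP
(adapt to position) otherwise. A matching pair of DVH metric tables is
emitted whose dosimetric labeling agrees with the geometric label.

All randomness flows from integer seeds through named generators; identical
``(spec, patient_id, fraction_index)`` inputs are bit-for-bit reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_preprocess import expand_mask, read_field, read_volume, write_field, write_volume
from .labeler import DVHMetricTable, StrategyLabel
from .volume import DisplacementField, Volume3D


@dataclass(frozen=True)
class PhantomSpec:
    """Generator parameters for one synthetic fraction.

    ``deformation_amplitude`` is the peak displacement magnitude in mm;
    ``deformation_smoothness`` the Gaussian correlation length in mm;
    ``label_threshold`` the mean in-ROI displacement (mm) above which the
    fraction is labeled ATS. ``roi_margin_mm`` is the PTV-to-ROI expansion
    (the clinical analogue uses 50 mm; the desk-scale default keeps part of
    the grid outside the ROI so masking invariances stay observable).
    """

    grid_shape: Tuple[int, int, int] = (64, 64, 32)
    voxel_spacing: Tuple[float, float, float] = (2.0, 2.0, 3.0)
    deformation_amplitude: float = 4.0
    deformation_smoothness: float = 12.0
    noise_sigma: float = 0.02
    label_threshold: float = 2.0
    ptv_margin_mm: float = 3.0
    roi_margin_mm: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) < 8 for s in self.grid_shape):
            raise ValueError("grid_shape components must be >= 8")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")
        if self.deformation_amplitude < 0:
            raise ValueError("deformation_amplitude must be non-negative")
        if self.deformation_smoothness <= max(self.voxel_spacing):
            raise ValueError("deformation_smoothness must exceed the voxel spacing")
        if self.label_threshold <= 0:
            raise ValueError("label_threshold must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    @property
    def physical_extent(self) -> Tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.grid_shape, self.voxel_spacing))

    def max_safe_amplitude(self) -> float:
        """Largest peak displacement that keeps structures inside the grid.

        Structures occupy the central half of the volume, so a peak
        displacement below a third of the smallest physical extent cannot
        push them off the grid (border clamping then only touches the
        periphery of the body outline).
        """
        return min(self.physical_extent) / 3.0


@dataclass
class SyntheticCase:
    """One synthetic treatment fraction.

    ``fixed`` is the daily pseudo-MR, ``moving`` the reference pseudo-CT,
    ``true_field`` the generating deformation (voxel units, fixed grid).
    ``structures`` are daily-anatomy masks on the fixed grid;
    ``structures_moving`` their undeformed counterparts on the reference
    grid (needed for pre/post registration overlap comparisons).
    """

    fixed: Volume3D
    moving: Volume3D
    true_field: DisplacementField
    structures: Dict[str, Volume3D]
    structures_moving: Dict[str, Volume3D]
    roi_mask: Volume3D
    dvh_atp: DVHMetricTable
    dvh_ats: DVHMetricTable
    label: StrategyLabel
    patient_id: str
    fraction_index: int
    spec: PhantomSpec

    def validate(self) -> None:
        shape = self.fixed.shape
        if self.moving.shape != shape or self.true_field.grid_shape != shape:
            raise ValueError("fixed, moving and field must share the grid")
        occupancy = np.zeros(shape)
        for name, m in self.structures.items():
            if m.shape != shape:
                raise ValueError(f"structure {name} off-grid")
            if not (m.data > 0).any():
                raise ValueError(f"structure {name} is empty")
            occupancy += m.data
        if occupancy.max() > 1:
            raise ValueError("structures must be mutually disjoint")
        recomputed = recompute_label(self.true_field, self.roi_mask.data,
                                     self.spec.label_threshold)
        if recomputed != self.label:
            raise ValueError("stored label inconsistent with the true field")


def recompute_label(field: DisplacementField, roi_mask: np.ndarray,
                    threshold_mm: float) -> StrategyLabel:
    """Geometric ground-truth rule: ATS iff mean in-ROI |u| > threshold."""
    mean_mm = field.mean_magnitude_mm(np.asarray(roi_mask) > 0.5)
    return StrategyLabel.ATS if mean_mm > threshold_mm else StrategyLabel.ATP


# ---------------------------------------------------------------------------
# anatomy and modality rendering
# ---------------------------------------------------------------------------

# ellipsoid centres (mm, grid-centred coords) and radii (mm); additive
# intensity contributions of the base anatomy map
_STRUCTURES = {
    "body": {"center": (0.0, 0.0, 0.0), "radii": (60.0, 60.0, 45.0), "intensity": 0.35},
    "prostate-like": {"center": (0.0, 0.0, 0.0), "radii": (14.0, 12.0, 11.0), "intensity": 0.30},
    "bladder-like": {"center": (0.0, -30.0, 6.0), "radii": (18.0, 16.0, 13.0), "intensity": 0.45},
    "rectum-like": {"center": (0.0, 26.0, 0.0), "radii": (9.0, 8.0, 30.0), "intensity": -0.22},
}
STRUCTURE_NAMES = ("prostate-like", "bladder-like", "rectum-like")


def _phys_coords(spec: PhantomSpec) -> List[np.ndarray]:
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * sp
        for n, sp in zip(spec.grid_shape, spec.voxel_spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_r(coords, center, radii) -> np.ndarray:
    return np.sqrt(sum(((c - mu) / r) ** 2 for c, mu, r in zip(coords, center, radii)))


def _soft_edge(r: np.ndarray, width: float = 0.12) -> np.ndarray:
    # smooth indicator of r <= 1 with a sigmoid shoulder of relative width
    return 1.0 / (1.0 + np.exp((r - 1.0) / width))


def base_anatomy(spec: PhantomSpec) -> np.ndarray:
    """Smooth anatomy map in [0, ~1.1] built from overlapping ellipsoids."""
    coords = _phys_coords(spec)
    a = np.zeros(spec.grid_shape)
    for params in _STRUCTURES.values():
        r = _ellipsoid_r(coords, params["center"], params["radii"])
        a += params["intensity"] * _soft_edge(r)
    return np.clip(a, 0.0, 1.2)


def structure_masks(spec: PhantomSpec) -> Dict[str, np.ndarray]:
    """Hard binary masks of the three organ-like structures (reference grid)."""
    coords = _phys_coords(spec)
    out = {}
    for name in STRUCTURE_NAMES:
        p = _STRUCTURES[name]
        out[name] = (_ellipsoid_r(coords, p["center"], p["radii"]) <= 1.0).astype(np.float64)
    return out


def ct_transfer(a: np.ndarray) -> np.ndarray:
    """Piecewise-linear monotone 'CT' intensity transfer."""
    knots_in = np.array([0.0, 0.2, 0.5, 0.8, 1.2])
    knots_out = np.array([0.02, 0.18, 0.55, 0.78, 1.0])
    return np.interp(a, knots_in, knots_out)


def mr_transfer(a: np.ndarray) -> np.ndarray:
    """Saturating nonlinear monotone 'MR' intensity transfer (non-affine)."""
    g = np.power(np.clip(a, 0.0, None), 0.45)
    h = np.power(0.35, 0.45)
    return g / (g + h)


# ---------------------------------------------------------------------------
# deformation fields
# ---------------------------------------------------------------------------


def _smooth_unit_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Gaussian-correlated random field in mm units, peak magnitude 1."""
    sigmas_vox = [spec.deformation_smoothness / sp for sp in spec.voxel_spacing]
    comps = []
    for _ in range(3):
        white = rng.standard_normal(spec.grid_shape)
        comps.append(ndimage.gaussian_filter(white, sigma=sigmas_vox, mode="reflect"))
    u_mm = np.stack(comps)
    peak = np.sqrt((u_mm**2).sum(axis=0)).max()
    if peak < 1e-12:
        return np.zeros_like(u_mm)
    return u_mm / peak


def _field_to_voxels(u_mm: np.ndarray, spacing) -> np.ndarray:
    sp = np.asarray(spacing, dtype=float).reshape(3, 1, 1, 1)
    return u_mm / sp


def _warp_array(a: np.ndarray, u_vox: np.ndarray, order: int = 1) -> np.ndarray:
    idx = np.meshgrid(*[np.arange(n) for n in a.shape], indexing="ij")
    coords = np.stack(idx).astype(float) + u_vox
    return ndimage.map_coordinates(a, coords, order=order, mode="nearest")


# ---------------------------------------------------------------------------
# case generation
# ---------------------------------------------------------------------------


def _case_rng(spec: PhantomSpec, patient_id: str, fraction_index: int) -> np.random.Generator:
    pid_hash = zlib.crc32(str(patient_id).encode())
    return np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, pid_hash, int(fraction_index)])


def generate_case(spec: PhantomSpec, patient_id: str = "P000",
                  fraction_index: int = 0,
                  _target_mean_mm: Optional[float] = None) -> SyntheticCase:
    """Generate one fraction: image pair, truth field, masks, DVH tables, label.

    ``_target_mean_mm`` (internal, used by :func:`generate_cohort`) rescales
    the drawn field so its mean in-ROI magnitude hits the given value instead
    of using ``spec.deformation_amplitude`` as the peak.
    """
    rng = _case_rng(spec, patient_id, fraction_index)
    anatomy = base_anatomy(spec)
    masks_moving = structure_masks(spec)

    ptv = expand_mask(
        Volume3D(masks_moving["prostate-like"], spacing=spec.voxel_spacing, modality="mask"),
        spec.ptv_margin_mm, name="prostate-like",
    ).mask
    roi = expand_mask(ptv, spec.roi_margin_mm, name="ptv-surrogate").mask

    if _target_mean_mm is not None:
        # draw fields until the peak needed to hit the target mean is safe
        # (smooth random fields occasionally dip in the central ROI, which
        # would demand an off-grid peak; redrawing keeps labels exact and
        # the procedure deterministic under the case rng stream)
        for _attempt in range(25):
            unit_mm = _smooth_unit_field(spec, rng)
            unit_vox = _field_to_voxels(unit_mm, spec.voxel_spacing)
            unit_field = DisplacementField(unit_vox, spacing=spec.voxel_spacing)
            mean_unit = unit_field.mean_magnitude_mm(roi.data > 0.5)
            if mean_unit < 1e-12:
                continue
            amplitude = _target_mean_mm / mean_unit  # peak achieving the mean
            if amplitude <= spec.max_safe_amplitude():
                break
        else:
            raise ValueError(
                f"cannot reach a mean in-ROI displacement of {_target_mean_mm:.1f} mm "
                f"within the safe peak bound {spec.max_safe_amplitude():.1f} mm"
            )
    else:
        unit_mm = _smooth_unit_field(spec, rng)
        amplitude = spec.deformation_amplitude
        if amplitude > spec.max_safe_amplitude():
            raise ValueError(
                f"deformation amplitude {amplitude:.1f} mm exceeds the safe bound "
                f"{spec.max_safe_amplitude():.1f} mm for this grid: structures would "
                "be pushed off the volume"
            )
    u_mm = unit_mm * amplitude
    u_vox = _field_to_voxels(u_mm, spec.voxel_spacing)
    true_field = DisplacementField(u_vox, spacing=spec.voxel_spacing)

    moving_img = ct_transfer(anatomy)
    warped_anatomy = anatomy if amplitude == 0 else _warp_array(anatomy, u_vox)
    fixed_img = mr_transfer(warped_anatomy)
    if spec.noise_sigma > 0:
        fixed_img = fixed_img + rng.normal(0.0, spec.noise_sigma, size=fixed_img.shape)

    structures_fixed: Dict[str, Volume3D] = {}
    structures_moving: Dict[str, Volume3D] = {}
    for name, m in masks_moving.items():
        warped_m = m if amplitude == 0 else (_warp_array(m, u_vox) > 0.5).astype(np.float64)
        structures_fixed[name] = Volume3D(warped_m, spacing=spec.voxel_spacing, modality="mask")
        structures_moving[name] = Volume3D(m, spacing=spec.voxel_spacing, modality="mask")

    label = recompute_label(true_field, roi.data, spec.label_threshold)
    dvh_atp, dvh_ats = generate_dvh_tables(
        true_field, structures_fixed, rng,
        label_threshold=spec.label_threshold, roi_mask=roi.data,
    )

    case = SyntheticCase(
        fixed=Volume3D(fixed_img, spacing=spec.voxel_spacing, modality="MR-like"),
        moving=Volume3D(moving_img, spacing=spec.voxel_spacing, modality="CT-like"),
        true_field=true_field,
        structures=structures_fixed,
        structures_moving=structures_moving,
        roi_mask=roi,
        dvh_atp=dvh_atp,
        dvh_ats=dvh_ats,
        label=label,
        patient_id=str(patient_id),
        fraction_index=int(fraction_index),
        spec=spec,
    )
    case.validate()
    return case


# ---------------------------------------------------------------------------
# DVH tables tied to the deformation magnitude
# ---------------------------------------------------------------------------


def generate_dvh_tables(
    case_field: DisplacementField,
    structures: Dict[str, Volume3D],
    rng: np.random.Generator,
    label_threshold: float = 2.0,
    roi_mask: Optional[np.ndarray] = None,
) -> Tuple[DVHMetricTable, DVHMetricTable]:
    """Emit (ATP, ATS) DVH tables consistent with the geometric label.

    The ATS plan (full replan) always satisfies every criterion. The ATP
    plan degrades monotonically with the mean in-ROI deformation ``d``:
    below the threshold all its metrics are inside the tolerances; above it
    the rectum D_max crosses its 40 Gy limit (zero tolerance), with other
    metrics drifting monotonically as well. Jitter stays within safe bands.
    """
    if not structures:
        raise ValueError("structures must be non-empty")
    if roi_mask is None:
        roi_mask = np.zeros(case_field.grid_shape, dtype=bool)
        for m in structures.values():
            roi_mask |= np.asarray(m.data) > 0.5
    d = case_field.mean_magnitude_mm(np.asarray(roi_mask) > 0.5)
    r = d / label_threshold

    def j(scale: float) -> float:
        return float(rng.uniform(-scale, scale))

    ats = DVHMetricTable()
    ats.set("CTV4000", "V_40Gy", 97.5 + j(0.5), "%")
    ats.set("PTV", "V_36.25Gy", 97.5 + j(0.5), "%")
    ats.set("PTV", "V_34.4Gy", 99.0 + j(0.4), "%")
    ats.set("Rectum", "D_max", 38.0 + j(0.5), "Gy")
    ats.set("Rectum", "V_38Gy", max(0.0, 0.02 + j(0.02)), "cc")
    ats.set("Rectum", "V_36Gy", 0.3 + j(0.1), "cc")
    ats.set("Rectum", "V_29Gy", 15.0 + j(1.0), "%")
    ats.set("Bladder", "V_37Gy", 6.0 + j(1.0), "cc")
    ats.set("Bladder", "V_18.1Gy", 40.0 + j(2.0), "%")
    ats.set("Femur_R", "V_14.5Gy", 3.0 + j(0.5), "%")
    ats.set("Femur_L", "V_14.5Gy", 3.0 + j(0.5), "%")
    ats.set("Urethra", "D_50%", 39.5 + j(0.4), "Gy")

    atp = DVHMetricTable()
    # the discriminating criterion: rectum D_max crosses 40 Gy exactly at r=1
    if r <= 1.0:
        atp.set("Rectum", "D_max", 38.0 + 1.5 * r + j(0.2), "Gy")
    else:
        atp.set("Rectum", "D_max", 40.3 + 2.0 * (r - 1.0) + j(0.2), "Gy")
    # monotone drifts, within tolerance for r <= 1
    atp.set("CTV4000", "V_40Gy", 97.0 - 4.0 * r + j(0.3), "%")
    atp.set("PTV", "V_36.25Gy", 97.0 - 3.5 * r + j(0.3), "%")
    atp.set("PTV", "V_34.4Gy", 99.0 - 3.0 * r + j(0.3), "%")
    atp.set("Rectum", "V_38Gy", max(0.0, min(0.09, 0.02 + 0.03 * r) + j(0.005)), "cc")
    atp.set("Rectum", "V_36Gy", 0.3 + 0.9 * r + j(0.05), "cc")
    atp.set("Rectum", "V_29Gy", 15.0 + 4.0 * r + j(0.3), "%")
    atp.set("Bladder", "V_37Gy", 5.0 + 4.0 * r + j(0.2), "cc")
    atp.set("Bladder", "V_18.1Gy", 40.0 + 8.0 * r + j(0.5), "%")
    atp.set("Femur_R", "V_14.5Gy", min(3.0 + 1.5 * r, 4.8) + j(0.1), "%")
    atp.set("Femur_L", "V_14.5Gy", min(3.0 + 1.5 * r, 4.8) + j(0.1), "%")
    atp.set("Urethra", "D_50%", 39.5 + 1.2 * r + j(0.1), "Gy")
    return atp, ats


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

# mean in-ROI displacement as a multiple of the label threshold: clearly-ATP
# and clearly-ATS bands with a guard gap around the decision boundary
_ATP_BAND = (0.30, 0.85)
_ATS_BAND = (1.15, 2.20)


def generate_cohort(
    spec: PhantomSpec,
    n_patients: int,
    fractions_per_patient: int,
    ats_fraction_target: float = 0.77,
) -> List[SyntheticCase]:
    """Generate ``n_patients x fractions_per_patient`` labeled fractions.

    Per-fraction deformation magnitudes are drawn so the realized ATS
    proportion matches ``ats_fraction_target`` (the clinical cohort has
    77% ATS); patient ids support leakage-free patient-level splits.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    if fractions_per_patient < 1:
        raise ValueError("need at least 1 fraction per patient")
    if not 0.0 <= ats_fraction_target <= 1.0:
        raise ValueError("ats_fraction_target must be in [0, 1]")
    n_total = n_patients * fractions_per_patient
    n_ats = int(round(ats_fraction_target * n_total))
    flags = np.zeros(n_total, dtype=bool)
    flags[:n_ats] = True
    rng = np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, 192837])
    rng.shuffle(flags)

    cases: List[SyntheticCase] = []
    i = 0
    for p in range(n_patients):
        pid = f"P{p:03d}"
        for fx in range(fractions_per_patient):
            is_ats = bool(flags[i])
            band = _ATS_BAND if is_ats else _ATP_BAND
            target_mean = float(rng.uniform(*band)) * spec.label_threshold
            case = generate_case(spec, pid, fx, _target_mean_mm=target_mean)
            assert case.label == (StrategyLabel.ATS if is_ats else StrategyLabel.ATP)
            cases.append(case)
            i += 1
    return cases


def split_by_patient(cases: List[SyntheticCase], n_train_patients: int
                     ) -> Tuple[List[SyntheticCase], List[SyntheticCase]]:
    """Patient-level split: no patient contributes to both subsets."""
    pids = sorted({c.patient_id for c in cases})
    train_ids = set(pids[:n_train_patients])
    train = [c for c in cases if c.patient_id in train_ids]
    test = [c for c in cases if c.patient_id not in train_ids]
    return train, test


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------


def write_case(case: SyntheticCase, out_dir: str | Path) -> Path:
    """Write one case as NIfTI volumes plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(case.fixed, out / "fixed.nii.gz")
    write_volume(case.moving, out / "moving.nii.gz")
    write_field(case.true_field, out / "true_field.nii.gz")
    write_volume(case.roi_mask, out / "roi_mask.nii.gz")
    for name, m in case.structures.items():
        write_volume(m, out / f"structure_{name}.nii.gz")
    for name, m in case.structures_moving.items():
        write_volume(m, out / f"structure_moving_{name}.nii.gz")
    case.dvh_atp.to_csv(out / "dvh_atp.csv")
    case.dvh_ats.to_csv(out / "dvh_ats.csv")
    sidecar = {
        "patient_id": case.patient_id,
        "fraction_index": case.fraction_index,
        "label": case.label.name,
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in vars(case.spec).items()},
    }
    (out / "case.json").write_text(json.dumps(sidecar, indent=2))
    return out


def write_cohort(cases: List[SyntheticCase], out_dir: str | Path) -> Path:
    """Write all cases plus a manifest CSV (patient, fraction, label, path)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        sub = out / f"{case.patient_id}_fx{case.fraction_index}"
        write_case(case, sub)
        rows.append({
            "patient_id": case.patient_id,
            "fraction_index": case.fraction_index,
            "label": case.label.name,
            "path": str(sub.relative_to(out)),
        })
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    return out / "manifest.csv"


def read_case(case_dir: str | Path) -> SyntheticCase:
    """Load a case written by :func:`write_case`."""
    d = Path(case_dir)
    sidecar = json.loads((d / "case.json").read_text())
    spec_kw = sidecar["spec"]
    spec = PhantomSpec(**{k: (tuple(v) if isinstance(v, list) else v)
                          for k, v in spec_kw.items()})
    structures = {}
    structures_moving = {}
    for p in sorted(d.glob("structure_*.nii.gz")):
        name = p.name[len("structure_"):-len(".nii.gz")]
        if name.startswith("moving_"):
            structures_moving[name[len("moving_"):]] = read_volume(p, modality="mask")
        else:
            structures[name] = read_volume(p, modality="mask")
    case = SyntheticCase(
        fixed=read_volume(d / "fixed.nii.gz", modality="MR-like"),
        moving=read_volume(d / "moving.nii.gz", modality="CT-like"),
        true_field=read_field(d / "true_field.nii.gz"),
        structures=structures,
        structures_moving=structures_moving,
        roi_mask=read_volume(d / "roi_mask.nii.gz", modality="mask"),
        dvh_atp=DVHMetricTable.from_csv(d / "dvh_atp.csv"),
        dvh_ats=DVHMetricTable.from_csv(d / "dvh_ats.csv"),
        label=StrategyLabel[sidecar["label"]],
        patient_id=sidecar["patient_id"],
        fraction_index=int(sidecar["fraction_index"]),
        spec=spec,
    )
    return case


def read_cohort(manifest_csv: str | Path) -> List[SyntheticCase]:
    """Load every case listed in a cohort manifest."""
    manifest = Path(manifest_csv)
    df = pd.read_csv(manifest)
    return [read_case(manifest.parent / row.path) for row in df.itertuples(index=False)]
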