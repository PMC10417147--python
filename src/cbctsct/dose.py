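"""Simplified proton dose proxy and DVH coverage metrics.

The engine is a deliberate simplification of pencil-beam-scanning transport:
each beam deposits a spread-out-Bragg-peak-like depth dose in
water-equivalent-path-length (WEPL) coordinates along parallel rays through
an aperture, with a flat plateau up to the planned distal range and a sharp
distal falloff.  No lateral scatter is modeled.  What the proxy preserves is
the mechanism that matters for coverage monitoring: density errors upstream
of a target shift the distal edge in WEPL space and erode D99.

Doses are relative; a plan is normalized so that D99 of the high-risk CTV on
the planning anatomy equals 100 %.  Evaluation doses recomputed on other
image sets reuse the plan's beams, ranges and normalization, so coverage
change reflects anatomy/setup change only.  The default clinical dose grid is
2x2x2 mm; on the downscaled test preset doses are computed on the image grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core_images import (
    GeometryError,
    GridSpec,
    IntensityKind,
    StructureRole,
    StructureSet,
    VolumeImage,
    mask_centroid_mm,
)

log = logging.getLogger("cbctsct")

__all__ = [
    "DEFAULT_SPR_TABLE",
    "BeamSpec",
    "DoseConfig",
    "DoseGrid",
    "DVH",
    "PlanResult",
    "hu_to_spr",
    "compute_wepl",
    "plan_beams",
    "compute_dose_proxy",
    "make_plan",
    "evaluate_dose",
    "compute_dvh",
    "d_metric",
]

#: piecewise-linear HU -> relative stopping power anchors (water = 1)
DEFAULT_SPR_TABLE: Tuple[Tuple[float, float], ...] = (
    (-1000.0, 0.001),
    (0.0, 1.0),
    (1500.0, 1.55),
)


def hu_to_spr(
    img: VolumeImage, calibration: Sequence[Tuple[float, float]] = DEFAULT_SPR_TABLE
) -> VolumeImage:
    """Piecewise-linear HU -> stopping-power ratio, floored at zero."""
    if img.intensity_kind != IntensityKind.HU:
        raise ValueError("hu_to_spr expects an HU image")
    xs = np.array([t[0] for t in calibration], dtype=float)
    ys = np.array([t[1] for t in calibration], dtype=float)
    if np.any(np.diff(xs) <= 0) or np.any(np.diff(ys) <= 0):
        raise ValueError("SPR calibration table must be strictly monotone")
    spr = np.interp(img.voxels, xs, ys)
    lo = (ys[1] - ys[0]) / (xs[1] - xs[0])
    hi = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
    spr = np.where(img.voxels < xs[0], ys[0] + lo * (img.voxels - xs[0]), spr)
    spr = np.where(img.voxels > xs[-1], ys[-1] + hi * (img.voxels - xs[-1]), spr)
    return img.with_voxels(np.maximum(spr, 0.0), IntensityKind.DENSITY)


def compute_wepl(
    spr: VolumeImage,
    entry_mm: Sequence[float],
    direction: Sequence[float],
    step_mm: Optional[float] = None,
    max_length_mm: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Cumulative water-equivalent path length along a ray.

    Returns ``(distances_mm, wepl_mm)`` sampled by uniform stepping (step at
    most half the minimum voxel spacing); empty arrays if the ray misses the
    grid.  Points outside the grid contribute the air stopping power.
    """
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("direction must be a non-zero vector")
    d = d / n
    entry = np.asarray(entry_mm, dtype=float)
    origin = np.asarray(spr.origin)
    extent = np.asarray(spr.grid.extent_mm)
    # slab test for ray-box intersection
    t0, t1 = -np.inf, np.inf
    for a in range(3):
        if abs(d[a]) < 1e-12:
            if not (origin[a] <= entry[a] <= origin[a] + extent[a]):
                return np.array([]), np.array([])
        else:
            ta = (origin[a] - entry[a]) / d[a]
            tb = (origin[a] + extent[a] - entry[a]) / d[a]
            t0, t1 = max(t0, min(ta, tb)), min(t1, max(ta, tb))
    if t1 < max(t0, 0.0):
        return np.array([]), np.array([])
    step = step_mm if step_mm is not None else 0.5 * min(spr.spacing)
    length = max_length_mm if max_length_mm is not None else max(t1, 0.0)
    dist = np.arange(0.0, length + step, step)
    pts = entry[None, :] + dist[:, None] * d[None, :]
    coords = (pts - origin[None, :]) / np.asarray(spr.spacing)[None, :]
    vals = ndimage.map_coordinates(
        spr.voxels.astype(np.float64), coords.T, order=1, mode="constant", cval=0.001
    )
    # midpoint rule on the sampled stopping powers
    wepl = np.concatenate([[0.0], np.cumsum(0.5 * (vals[1:] + vals[:-1]) * step)])
    return dist, wepl


@dataclass
class BeamSpec:
    """One parallel beam: axial gantry angle, aperture, planned distal ranges.

    The distal edge is conformed per ray (as spot-scanning plans do): for
    every aperture position the planned range is the WEPL of the target's
    distal surface along that ray plus the distal margin.  ``range_mm`` keeps
    the deepest of these for reporting.
    """

    angle_deg: float  # 0 = anterior beam (traveling anterior -> posterior)
    direction: Tuple[float, float, float]
    aperture: np.ndarray  # 2D mask in the beam-rotated (x, z) plane
    range_map_mm: np.ndarray  # 2D per-ray distal range, water-equivalent
    range_mm: float  # deepest planned range, water-equivalent
    weight: float


@dataclass
class DoseConfig:
    falloff_mm: float = 5.0  # WEPL width of the distal falloff
    aperture_margin_mm: float = 5.0
    # distal water-equivalent margin; sized like the clinical robustness
    # margins (3 mm setup + 3.5 % density) so voxelization-level range noise
    # does not eat into target coverage
    distal_margin_mm: float = 5.0
    arrangements: Dict[str, Tuple[float, ...]] = dfield(
        default_factory=lambda: {
            "anterior_plus_posterior_obliques": (0.0, 135.0, 225.0),
            "posterior_plus_anterior_obliques": (180.0, 45.0, 315.0),
            "single_anterior": (0.0,),
        }
    )


@dataclass
class DoseGrid:
    dose: VolumeImage  # relative units (% of prescription after normalization)

    @property
    def voxels(self) -> np.ndarray:
        return self.dose.voxels


@dataclass
class PlanResult:
    beams: List[BeamSpec]
    norm_factor: float
    plan_dose: DoseGrid
    grid: GridSpec


def _beam_direction(angle_deg: float) -> Tuple[float, float, float]:
    """Gantry angle about Z in the axial plane; 0 deg travels toward +Y
    (anterior beam, with +Y the posterior direction)."""
    rad = np.radians(angle_deg)
    return (float(np.sin(rad)), float(np.cos(rad)), 0.0)


def _rotate_axial(vol: np.ndarray, angle_deg: float, cval: float) -> np.ndarray:
    # rotating the volume by +angle brings the beam direction onto +Y
    # (scipy's positive angle turns axis 0 toward axis 1 in the (x, y) plane)
    return ndimage.rotate(
        vol, angle_deg, axes=(0, 1), reshape=False, order=1, mode="constant", cval=cval
    )


def _wepl_volume(spr_rot: np.ndarray, dy_mm: float) -> np.ndarray:
    """WEPL at each voxel center for a beam traveling along +Y (axis 1)."""
    cum = np.cumsum(spr_rot, axis=1) * dy_mm
    return cum - 0.5 * spr_rot * dy_mm


def plan_beams(
    structures: StructureSet,
    spr: VolumeImage,
    arrangement: str = "anterior_plus_posterior_obliques",
    config: Optional[DoseConfig] = None,
) -> List[BeamSpec]:
    """Aim a beam preset at the union CTV and set per-beam distal ranges.

    Each beam's range is the maximum WEPL over the target in the planning SPR
    plus a distal margin, so the whole target sits on the dose plateau; the
    aperture is the beam's-eye-view projection of the target plus a lateral
    margin.  Beam weights are equal and sum to one.
    """
    config = config or DoseConfig()
    if arrangement not in config.arrangements:
        raise ValueError(f"unknown arrangement '{arrangement}'")
    ctvs = {**structures.by_role(StructureRole.CTV_HIGH), **structures.by_role(StructureRole.CTV_STANDARD)}
    if not ctvs:
        raise GeometryError("no CTV structures to plan on")
    target = np.zeros(structures.grid.shape, dtype=bool)
    for m in ctvs.values():
        target |= m
    if not target.any():
        raise GeometryError("empty target union")
    angles = config.arrangements[arrangement]
    sx, sy, sz = spr.spacing
    beams: List[BeamSpec] = []
    for ang in angles:
        spr_rot = _rotate_axial(spr.voxels, ang, cval=0.001)
        tgt_rot = _rotate_axial(target.astype(np.float64), ang, cval=0.0) >= 0.5
        wepl = _wepl_volume(spr_rot, sy)
        if not tgt_rot.any():
            raise GeometryError("target rotated out of the grid; enlarge the grid")
        ap = tgt_rot.any(axis=1)
        # per-ray distal range: deepest target WEPL along each (x, z) ray
        rng_map = np.where(ap, np.max(np.where(tgt_rot, wepl, -np.inf), axis=1), 0.0)
        rng_map = np.where(ap, rng_map + config.distal_margin_mm, 0.0)
        # extend ranges into the lateral margin with the nearest in-aperture ray
        dist, (ix, iz) = ndimage.distance_transform_edt(
            ~ap, sampling=(sx, sz), return_indices=True
        )
        ap_marg = dist <= config.aperture_margin_mm
        rng_full = rng_map[ix, iz]
        beams.append(
            BeamSpec(
                angle_deg=float(ang),
                direction=_beam_direction(ang),
                aperture=ap | ap_marg,
                range_map_mm=np.where(ap, rng_map, np.where(ap_marg, rng_full, 0.0)),
                range_mm=float(rng_map[ap].max()),
                weight=1.0 / len(angles),
            )
        )
    return beams


def _depth_dose(wepl: np.ndarray, range_mm: float, falloff_mm: float) -> np.ndarray:
    """Flat plateau to the planned range, linear distal falloff, zero beyond."""
    return np.clip((range_mm + falloff_mm - wepl) / falloff_mm, 0.0, 1.0)


def compute_dose_proxy(
    spr: VolumeImage,
    beams: Sequence[BeamSpec],
    config: Optional[DoseConfig] = None,
    norm_factor: float = 1.0,
) -> DoseGrid:
    """Deposit the weighted per-beam depth doses on the SPR volume's grid."""
    config = config or DoseConfig()
    sy = spr.spacing[1]
    total = np.zeros(spr.voxels.shape, dtype=np.float64)
    for beam in beams:
        spr_rot = _rotate_axial(spr.voxels, beam.angle_deg, cval=0.001)
        wepl = _wepl_volume(spr_rot, sy)
        dose_rot = _depth_dose(wepl, beam.range_map_mm[:, None, :], config.falloff_mm)
        dose_rot *= beam.aperture[:, None, :]
        total += beam.weight * ndimage.rotate(
            dose_rot, -beam.angle_deg, axes=(0, 1), reshape=False, order=1, mode="constant", cval=0.0
        )
    total = np.maximum(total * norm_factor, 0.0)
    return DoseGrid(VolumeImage(total, spr.spacing, spr.origin, IntensityKind.DOSE))


def make_plan(
    structures: StructureSet,
    spr: VolumeImage,
    arrangement: str = "anterior_plus_posterior_obliques",
    config: Optional[DoseConfig] = None,
) -> PlanResult:
    """Plan beams on the planning SPR and normalize D99(CTV high) to 100 %."""
    config = config or DoseConfig()
    beams = plan_beams(structures, spr, arrangement, config)
    raw = compute_dose_proxy(spr, beams, config)
    ctv_high = structures.first(StructureRole.CTV_HIGH)
    d99 = d_metric(compute_dvh(raw, ctv_high), 0.99)
    if d99 <= 0:
        raise GeometryError("planning dose does not cover the high-risk CTV")
    norm = 100.0 / d99
    plan_dose = DoseGrid(raw.dose.with_voxels(raw.voxels * norm))
    return PlanResult(beams=beams, norm_factor=norm, plan_dose=plan_dose, grid=spr.grid)


def evaluate_dose(plan: PlanResult, spr: VolumeImage, config: Optional[DoseConfig] = None) -> DoseGrid:
    """Recompute the plan's dose on another image set's SPR (same beams,
    ranges and normalization, so coverage change isolates anatomy change)."""
    if tuple(spr.grid.shape) != tuple(plan.grid.shape):
        raise GeometryError("evaluation SPR must be on the planning grid")
    return compute_dose_proxy(spr, plan.beams, config, norm_factor=plan.norm_factor)


# ---------------------------------------------------------------------------
# DVH / D-metrics
# ---------------------------------------------------------------------------


@dataclass
class DVH:
    """Cumulative dose-volume histogram of one structure."""

    doses_desc: np.ndarray  # in-mask voxel doses, sorted descending

    @property
    def n(self) -> int:
        return self.doses_desc.size

    def volume_fraction(self, dose) -> np.ndarray:
        """V(d): fraction of the structure receiving at least dose d."""
        dose = np.asarray(dose, dtype=float)
        asc = self.doses_desc[::-1]
        return 1.0 - np.searchsorted(asc, dose, side="left") / self.n


def compute_dvh(dose: DoseGrid, mask: np.ndarray) -> DVH:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dose.voxels.shape:
        raise GeometryError("dose grid and mask shapes differ")
    if not mask.any():
        raise GeometryError("DVH of an empty mask")
    return DVH(np.sort(dose.voxels[mask])[::-1])


def d_metric(dvh: DVH, volume_fraction: float) -> float:
    """D_v: the largest dose d with V(d) >= v (lower-quantile convention).

    ``d_metric(dvh, 0.99)`` is D99, the minimum dose received by the
    best-covered 99 % of the structure.
    """
    if not 0.0 < volume_fraction < 1.0:
        raise ValueError("volume_fraction must be in (0, 1)")
    k = int(np.ceil(volume_fraction * dvh.n)) - 1
    return float(dvh.doses_desc[k])
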