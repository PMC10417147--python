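"""Rigid and deformable image registration with a focused-region contract.

The deformable step mirrors the clinical constraint that a CBCT has a smaller
field of view than the planning CT: the registration is restricted to a focus
region (the FOV retracted by a margin, 20 mm by default) and the displacement
field is identically zero outside it.  The deformable engine is a
multi-resolution symmetric-forces demons registration; when a CT is registered
to a CBCT the CBCT must first be converted to HU so the intensity metric
compares commensurate values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .core_images import (
    GeometryError,
    GridSpec,
    IntensityKind,
    StructureSet,
    VolumeImage,
    fov_distance_mm,
)

log = logging.getLogger("cbctsct")

__all__ = [
    "DeformationField",
    "DirConfig",
    "RigidResult",
    "RegistrationError",
    "ConvergenceError",
    "rigid_align",
    "deform",
    "warp_image",
    "map_contours",
    "invert_field",
]


class RegistrationError(RuntimeError):
    """Registration could not be set up or failed outright."""


class ConvergenceError(RegistrationError):
    """Similarity did not improve; carries the iteration trace."""

    def __init__(self, message: str, trace: Optional[list] = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass
class DeformationField:
    """Per-voxel displacement vectors (mm, pull-back convention).

    ``displacement[ix, iy, iz]`` is the vector added to the physical position
    of an output voxel to find where it samples the moving image.  When
    ``domain_mask`` is set the field is identically zero outside it.
    """

    displacement: np.ndarray  # (nx, ny, nz, 3) mm
    grid: GridSpec
    domain_mask: Optional[np.ndarray] = None
    info: Dict = dfield(default_factory=dict)

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=np.float64)
        if self.displacement.shape != tuple(self.grid.shape) + (3,):
            raise GeometryError(
                f"displacement shape {self.displacement.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.displacement)):
            raise GeometryError("displacement vectors must be finite")
        if self.domain_mask is not None:
            outside = ~np.asarray(self.domain_mask, dtype=bool)
            if np.any(np.abs(self.displacement[outside]) > 1e-9):
                raise GeometryError("field must be identity outside its domain mask")

    @property
    def magnitude_mm(self) -> np.ndarray:
        return np.linalg.norm(self.displacement, axis=-1)

    @classmethod
    def identity(cls, grid: GridSpec, domain_mask: Optional[np.ndarray] = None) -> "DeformationField":
        return cls(np.zeros(tuple(grid.shape) + (3,)), grid, domain_mask)


@dataclass
class DirConfig:
    """Deformable-registration settings (all resolutions/iterations fixed, so
    registration is deterministic)."""

    # single full-resolution level by default: the demons forces are anchored
    # by fine soft-tissue texture that coarse pyramid levels smooth away,
    # after which flat-region displacements drift under residual intensity
    # offsets.  Multi-level schedules remain available for large motions.
    shrink_factors: Tuple[int, ...] = (1,)
    iterations: Tuple[int, ...] = (60,)
    smoothing_sigma_px: float = 2.0  # demons field smoothing, voxel units
    # intensity differences below this exert no demons force: residual
    # shading / conversion error of a corrected CBCT is of this order and
    # would otherwise drift flat regions, while real tissue-interface
    # mismatches are hundreds of HU
    intensity_difference_threshold: float = 20.0
    # estimate and remove the dominant global translation (daily setup error)
    # by windowed phase correlation before the demons refinement
    translation_init: bool = True
    feather_mm: float = 8.0  # transition from full field to identity at focus edge
    focus_margin_mm: float = 20.0  # FOV retraction used by callers


@dataclass
class RigidResult:
    translation_mm: np.ndarray  # content shift of moving relative to fixed
    rotation_deg: np.ndarray
    resampled: VolumeImage
    mse_before: float
    mse_after: float
    transform: sitk.Euler3DTransform


# ---------------------------------------------------------------------------
# numpy <-> SimpleITK bridging (arrays are (x, y, z); sitk wants (z, y, x))
# ---------------------------------------------------------------------------


def _to_sitk(img: VolumeImage) -> sitk.Image:
    s = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(img.voxels, (2, 1, 0))).astype(np.float64))
    s.SetSpacing(img.spacing)
    s.SetOrigin(img.origin)
    return s


def _field_from_sitk(disp: sitk.Image) -> np.ndarray:
    arr = sitk.GetArrayFromImage(disp)  # (z, y, x, 3), components already (dx, dy, dz)
    return np.transpose(arr, (2, 1, 0, 3))


def rigid_align(moving: VolumeImage, fixed: VolumeImage) -> RigidResult:
    """Intensity-based rigid alignment (translation + rotation).

    Optimizes mean-squared intensity difference with a multi-resolution
    regular-step gradient descent over a centered Euler transform.  The
    returned translation is the physical shift of the moving image's content
    relative to the fixed image.
    """
    for a in range(3):
        lo_m = moving.origin[a]
        hi_m = moving.origin[a] + moving.grid.extent_mm[a]
        lo_f = fixed.origin[a]
        hi_f = fixed.origin[a] + fixed.grid.extent_mm[a]
        if hi_m <= lo_f or hi_f <= lo_m:
            raise RegistrationError(
                f"no spatial overlap on axis {a}: moving [{lo_m}, {hi_m}] vs fixed [{lo_f}, {hi_f}]"
            )
    f_img, m_img = _to_sitk(fixed), _to_sitk(moving)
    initial = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.Euler3DTransform(), sitk.CenteredTransformInitializerFilter.GEOMETRY
    )
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetMetricSamplingStrategy(reg.NONE)  # full sampling: deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=2.0, minStep=1e-4, numberOfIterations=150, relaxationFactor=0.6
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.SetInitialTransform(initial, inPlace=True)
    transform = sitk.Euler3DTransform(reg.Execute(f_img, m_img))

    resampled = sitk.Resample(m_img, f_img, transform, sitk.sitkLinear, -1000.0)
    out = VolumeImage(
        np.transpose(sitk.GetArrayFromImage(resampled), (2, 1, 0)),
        fixed.spacing,
        fixed.origin,
        moving.intensity_kind,
    )
    naive = sitk.GetArrayFromImage(
        sitk.Resample(m_img, f_img, sitk.Transform(3, sitk.sitkIdentity), sitk.sitkLinear, -1000.0)
    )
    mse_before = float(np.mean((np.transpose(naive, (2, 1, 0)) - fixed.voxels) ** 2))
    mse_after = float(np.mean((out.voxels - fixed.voxels) ** 2))
    if mse_after > mse_before:
        raise RegistrationError(
            f"rigid registration diverged: MSE {mse_before:.1f} -> {mse_after:.1f}"
        )
    # the resampling transform maps fixed-space points to moving-space points;
    # its translation equals the physical shift applied to the content.
    params = np.asarray(transform.GetParameters())
    translation = params[3:6]
    return RigidResult(
        translation_mm=translation,
        rotation_deg=np.degrees(params[:3]),
        resampled=out,
        mse_before=mse_before,
        mse_after=mse_after,
        transform=transform,
    )


def _phase_correlation_shift(
    fixed: np.ndarray, moving: np.ndarray, weight: np.ndarray, spacing: Sequence[float]
) -> np.ndarray:
    """Dominant translation (mm) of the fixed content relative to the moving
    content, from the phase-correlation peak of the windowed images."""
    f = np.fft.fftn((fixed - fixed.mean()) * weight)
    m = np.fft.fftn((moving - moving.mean()) * weight)
    cross = f * np.conj(m)
    denom = np.abs(cross)
    corr = np.real(np.fft.ifftn(cross / np.maximum(denom, 1e-12)))
    idx = np.unravel_index(np.argmax(corr), corr.shape)
    peak = np.array(idx, dtype=float)
    # parabolic sub-voxel refinement along each axis (cyclic neighbors)
    for a in range(3):
        lo = list(idx)
        hi = list(idx)
        lo[a] = (idx[a] - 1) % corr.shape[a]
        hi[a] = (idx[a] + 1) % corr.shape[a]
        c0, c1, c2 = corr[tuple(lo)], corr[idx], corr[tuple(hi)]
        denom_a = c0 - 2 * c1 + c2
        if denom_a < 0:
            peak[a] += float(np.clip(0.5 * (c0 - c2) / denom_a, -0.5, 0.5))
    shape = np.array(corr.shape, dtype=float)
    peak = np.where(peak > shape / 2, peak - shape, peak)  # wrap to signed shift
    return peak * np.asarray(spacing)


def estimate_translation(
    fixed: VolumeImage, moving: VolumeImage, focus: np.ndarray, feather_mm: float = 8.0
) -> np.ndarray:
    """Dominant global translation (mm) of the fixed content relative to the
    moving content inside the focus window (phase correlation)."""
    w = _focus_weight(np.asarray(focus, dtype=bool), fixed.spacing, feather_mm)
    return _phase_correlation_shift(fixed.voxels, moving.voxels, w, fixed.spacing)


def _focus_weight(focus: np.ndarray, spacing: Sequence[float], feather_mm: float) -> np.ndarray:
    if feather_mm <= 0:
        return focus.astype(np.float64)
    d = fov_distance_mm(focus, spacing)
    return np.clip(d / feather_mm, 0.0, 1.0)


def deform(
    moving: VolumeImage,
    fixed: VolumeImage,
    focus: np.ndarray,
    config: Optional[DirConfig] = None,
    fixed_valid: Optional[np.ndarray] = None,
) -> DeformationField:
    """Deformable registration of ``moving`` onto ``fixed`` within ``focus``.

    Symmetric-forces demons after a global-translation pre-alignment; the
    resulting displacement is feathered to exactly zero outside the focus
    region.  Both images must be on the same grid and carry commensurate
    intensities (convert a CBCT to HU first).  When ``fixed_valid`` is given
    (typically the CBCT field of view), the fixed image outside it is
    replaced by the pre-aligned moving image so the truncation boundary
    exerts no registration forces.  Raises :class:`ConvergenceError` if
    similarity inside the focus worsens.
    """
    config = config or DirConfig()
    if not moving.same_grid_as(fixed):
        raise GeometryError("deform requires moving and fixed on a common grid")
    focus = np.asarray(focus, dtype=bool)
    if focus.shape != moving.voxels.shape:
        raise GeometryError("focus mask grid mismatch")
    if not focus.any():
        raise GeometryError("empty focus region")

    trace: List[Dict] = []
    # global-translation pre-alignment: estimate the dominant setup shift by
    # windowed phase correlation, pre-shift the moving image, and add the
    # constant back after the demons refinement.  (Seeding demons with a
    # constant initial field instead would let its zero-boundary field
    # smoothing erode the constant toward zero.)
    u_const = np.zeros(3)
    moving_reg = moving
    if config.translation_init:
        w_init = _focus_weight(focus, fixed.spacing, config.feather_mm)
        t_mm = _phase_correlation_shift(fixed.voxels, moving.voxels, w_init, fixed.spacing)
        if np.any(np.abs(t_mm) > 0.25 * min(fixed.spacing)):
            u_const = -t_mm  # pull-back: content moved +t samples at -t
            shift_field = DeformationField(
                np.broadcast_to(u_const, tuple(fixed.grid.shape) + (3,)).copy(), fixed.grid
            )
            moving_reg = warp_image(moving, shift_field, "linear")
            trace.append({"translation_init_mm": t_mm.tolist()})
    fixed_reg = fixed
    if fixed_valid is not None:
        wv = _focus_weight(np.asarray(fixed_valid, dtype=bool), fixed.spacing, config.feather_mm)
        fixed_reg = fixed.with_voxels(wv * fixed.voxels + (1.0 - wv) * moving_reg.voxels)
    f_img, m_img = _to_sitk(fixed_reg), _to_sitk(moving_reg)
    disp: Optional[sitk.Image] = None
    for shrink, iters in zip(config.shrink_factors, config.iterations):
        if shrink > 1:
            f_l = sitk.SmoothingRecursiveGaussian(f_img, [shrink * s / 2.0 for s in fixed.spacing])
            f_l = sitk.Shrink(f_l, [shrink] * 3)
            m_l = sitk.SmoothingRecursiveGaussian(m_img, [shrink * s / 2.0 for s in moving.spacing])
            m_l = sitk.Shrink(m_l, [shrink] * 3)
        else:
            f_l, m_l = f_img, m_img
        demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        demons.SetNumberOfIterations(int(iters))
        demons.SetSmoothDisplacementField(True)
        demons.SetStandardDeviations(config.smoothing_sigma_px)
        demons.SetIntensityDifferenceThreshold(config.intensity_difference_threshold)
        if disp is None:
            disp = demons.Execute(f_l, m_l)
        else:
            disp = demons.Execute(f_l, m_l, sitk.Resample(disp, f_l))
        trace.append({"shrink": shrink, "iterations": int(iters), "metric": float(demons.GetMetric())})
    disp = sitk.Resample(disp, f_img)

    u = _field_from_sitk(disp) + u_const
    u *= _focus_weight(focus, fixed.spacing, config.feather_mm)[..., None]
    grid = fixed.grid
    out = DeformationField(u, grid, domain_mask=focus)

    warped = warp_image(moving, out, "linear")
    # similarity judged on lightly smoothed images so an irreducible noise
    # floor cannot mask genuine anatomical improvement
    fix_s = ndimage.gaussian_filter(fixed.voxels, 1.0)
    mse_before = float(
        np.mean((ndimage.gaussian_filter(moving.voxels, 1.0)[focus] - fix_s[focus]) ** 2)
    )
    mse_after = float(
        np.mean((ndimage.gaussian_filter(warped.voxels, 1.0)[focus] - fix_s[focus]) ** 2)
    )
    # a true divergence blows the similarity up by far more than 5 %; images
    # that were already well aligned can wobble by interpolation effects
    # alone, so the worsening must also be non-negligible against the scene
    # contrast (1 % of the fixed image's in-focus variance) to abort
    floor = 0.01 * float(np.var(fix_s[focus]))
    if mse_after > 1.05 * mse_before + floor and mse_before > 0:
        raise ConvergenceError(
            f"deformable registration diverged inside focus: MSE {mse_before:.1f} -> {mse_after:.1f}",
            trace=trace,
        )
    inv = invert_field(out, iterations=6)
    comp = _compose_displacement(out, inv)
    ic_err = float(np.mean(np.linalg.norm(comp, axis=-1)[focus]))
    out.info = {
        "trace": trace,
        "mse_before": mse_before,
        "mse_after": mse_after,
        "inverse_consistency_mm": ic_err,
    }
    return out


def _index_coords(grid: GridSpec, displacement: np.ndarray) -> np.ndarray:
    idx = np.indices(grid.shape, dtype=np.float64)
    for a in range(3):
        idx[a] += displacement[..., a] / grid.spacing[a]
    return idx


def warp_image(img: VolumeImage, field: DeformationField, interpolation: str = "linear") -> VolumeImage:
    """Pull-back warp: output voxel at x samples the input at x + u(x)."""
    if not img.same_grid_as(field.grid):
        raise GeometryError("warp_image requires the field grid to match the image grid")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation '{interpolation}'")
    from .core_images import _DEFAULT_PADDING  # local import to avoid exposing the table

    coords = _index_coords(field.grid, field.displacement)
    out = ndimage.map_coordinates(
        img.voxels.astype(np.float64),
        coords,
        order=1 if interpolation == "linear" else 0,
        mode="constant",
        cval=_DEFAULT_PADDING[img.intensity_kind],
    )
    return img.with_voxels(out)


def warp_mask(mask: np.ndarray, field: DeformationField) -> np.ndarray:
    """Warp a binary mask with the partial-volume rule: the indicator is
    anti-aliased (Gaussian, 0.6 voxel), linearly interpolated at the warped
    positions and thresholded at 0.5.  Interpolating the raw binary lattice
    would park the half-level surface between voxel centers and swallow
    sub-voxel boundary motion; the anti-aliased indicator keeps warped
    volumes consistent with the continuum deformation."""
    mask = np.asarray(mask)
    if not field.displacement.any():
        return mask.astype(bool).copy()
    coords = _index_coords(field.grid, field.displacement)
    smooth = ndimage.gaussian_filter(mask.astype(np.float64), 0.6)
    frac = ndimage.map_coordinates(smooth, coords, order=1, mode="constant", cval=0.0)
    return frac >= 0.5


def map_contours(structures: StructureSet, field: DeformationField) -> StructureSet:
    """Deformable contour mapping: every mask warped, roles preserved."""
    masks, roles = {}, {}
    for name, mask, role in structures.items():
        warped = warp_mask(mask, field)
        if mask.any() and not warped.any():
            log.warning("structure '%s' became empty after contour mapping", name)
        masks[name] = warped
        roles[name] = role
    return StructureSet(masks, roles, field.grid, require_nonempty_ctv=False)


def invert_field(field: DeformationField, iterations: int = 8) -> DeformationField:
    """Fixed-point numerical inverse: v(x) = -u(x + v(x))."""
    grid = field.grid
    v = np.zeros_like(field.displacement)
    for _ in range(iterations):
        coords = _index_coords(grid, v)
        sampled = np.stack(
            [
                ndimage.map_coordinates(field.displacement[..., a], coords, order=1, mode="nearest")
                for a in range(3)
            ],
            axis=-1,
        )
        v = -sampled
    return DeformationField(v, grid, domain_mask=None, info={"inverse_of": "numeric"})


def _compose_displacement(a: DeformationField, b: DeformationField) -> np.ndarray:
    """Displacement of applying a then b: c(x) = a(x) + b(x + a(x))."""
    coords = _index_coords(a.grid, a.displacement)
    sampled = np.stack(
        [
            ndimage.map_coordinates(b.displacement[..., k], coords, order=1, mode="nearest")
            for k in range(3)
        ],
        axis=-1,
    )
    return a.displacement + sampled
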