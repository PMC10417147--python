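"""CBCT-based synthetic-CT generation.

Three image products are built from a planning CT (pCT), a same-day CBCT and,
when available, a verification CT (vfCT):

* **corrCBCT** — the CBCT with gray values mapped to CT numbers through a
  piecewise-linear conversion fitted on a joint pCT/CBCT histogram, plus a
  low-frequency artifact correction (low-pass-filtered difference map against
  the deformed pCT).  Conversion and artifact correction iterate to
  convergence; outside the CBCT field of view the image is extended with the
  deformed pCT through a feathered transition band.
* **virtCT** — the pCT deformed to the CBCT, with voxels overridden from the
  corrCBCT wherever the two disagree in mass density by more than
  0.3 g/cm^3 and at least one of them is below 0.6 g/cm^3 (low-density
  masking: captures nasal filling / air-cavity change without duplicating
  high-density structures).
* **gtCT** — the vfCT deformed to the same-day CBCT; being diagnostic-quality
  anatomy at the treatment position it serves as the dosimetric reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, signal

from .core_images import (
    GeometryError,
    GridSpec,
    IntensityKind,
    VolumeImage,
    fov_distance_mm,
    retract_fov,
)
from .registration import (
    DeformationField,
    DirConfig,
    deform,
    estimate_translation,
    warp_image,
)

log = logging.getLogger("cbctsct")

__all__ = [
    "JointHistogram",
    "ConversionFunction",
    "ArtifactMap",
    "CorrCbctConfig",
    "CorrCbctResult",
    "DegenerateHistogramError",
    "HU_CLAMP",
    "DEFAULT_DENSITY_TABLE",
    "build_joint_histogram",
    "identify_tissue_classes",
    "fit_conversion_function",
    "estimate_artifact_map",
    "make_corrcbct",
    "naive_rescale",
    "low_density_override_mask",
    "to_density",
    "make_virtct",
    "make_gtct",
]

HU_CLAMP = (-1024.0, 3071.0)

#: piecewise-linear HU -> mass density (g/cm^3) anchors
DEFAULT_DENSITY_TABLE: Tuple[Tuple[float, float], ...] = (
    (-1000.0, 0.001),
    (0.0, 1.0),
    (1500.0, 1.85),
)


class DegenerateHistogramError(RuntimeError):
    """Fewer than two separable tissue modes; fall back to an identity-slope
    map through the single mode."""


# ---------------------------------------------------------------------------
# Joint histogram and tissue classes
# ---------------------------------------------------------------------------


@dataclass
class JointHistogram:
    counts: np.ndarray  # (n_hu_bins, n_gray_bins)
    hu_edges: np.ndarray
    gray_edges: np.ndarray
    n_voxels: int

    @property
    def gray_centers(self) -> np.ndarray:
        return 0.5 * (self.gray_edges[:-1] + self.gray_edges[1:])

    @property
    def hu_centers(self) -> np.ndarray:
        return 0.5 * (self.hu_edges[:-1] + self.hu_edges[1:])


def build_joint_histogram(
    pct_deformed: VolumeImage,
    cbct: VolumeImage,
    mask: np.ndarray,
    bins: Tuple[int, int] = (128, 128),
) -> JointHistogram:
    """2D (pCT HU x CBCT gray) histogram over the masked voxels."""
    if not pct_deformed.same_grid_as(cbct):
        raise GeometryError("joint histogram requires both images on the CBCT grid")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise GeometryError("joint histogram over an empty mask")
    hu = pct_deformed.voxels[mask].ravel()
    gray = cbct.voxels[mask].ravel()
    counts, hu_edges, gray_edges = np.histogram2d(hu, gray, bins=bins)
    return JointHistogram(counts, hu_edges, gray_edges, int(mask.sum()))


def identify_tissue_classes(
    hist: JointHistogram,
    max_classes: int = 4,
    smooth_bins: float = 2.0,
) -> List[Tuple[float, float]]:
    """Locate tissue-class points (gray, HU) on the joint histogram.

    Modes of the smoothed gray-value marginal define the classes; each class
    HU is the median of the conditional HU distribution over the mode's gray
    window.  At least an air-like and a soft-tissue-like point are returned,
    ordered by gray value.
    """
    if hist.n_voxels == 0 or hist.counts.sum() == 0:
        raise GeometryError("empty joint histogram")
    marginal = hist.counts.sum(axis=0)
    smoothed = ndimage.gaussian_filter1d(marginal.astype(float), smooth_bins)
    # peak finding in the log domain: the air mode dwarfs soft tissue and bone
    # by orders of magnitude, so prominence on the raw counts would miss them.
    logm = np.log1p(smoothed)
    # zero-pad so modes at the histogram edges (air is usually the first bin)
    # are detectable as peaks
    padded = np.concatenate([[0.0], logm, [0.0]])
    # a mode must contain at least one actual count
    peaks, props = signal.find_peaks(padded, prominence=0.05 * logm.max(), height=np.log1p(1.0))
    peaks = peaks - 1

    centers = hist.gray_centers
    total = marginal.sum()

    def _windows(pk):
        return np.concatenate([[-np.inf], 0.5 * (centers[pk[:-1]] + centers[pk[1:]]), [np.inf]])

    # adjacent "peaks" with no real valley between them are one mode: merge
    # unless the dip falls below half the smaller peak (true bimodality)
    changed = True
    while changed and peaks.size >= 2:
        changed = False
        for i in range(peaks.size - 1):
            lo, hi = peaks[i], peaks[i + 1]
            valley = smoothed[lo : hi + 1].min()
            if valley > 0.5 * min(smoothed[lo], smoothed[hi]):
                drop = i if smoothed[lo] <= smoothed[hi] else i + 1
                peaks = np.delete(peaks, drop)
                changed = True
                break

    # a genuine tissue class holds a non-negligible share of the voxels;
    # log-domain tail wiggles of a broad mode do not
    if peaks.size >= 2:
        b = _windows(peaks)
        mass = np.array(
            [marginal[(centers >= b[i]) & (centers < b[i + 1])].sum() for i in range(peaks.size)]
        )
        keep = mass >= 0.01 * total
        peaks, mass = peaks[keep], mass[keep]
        if peaks.size > max_classes:
            order = np.sort(np.argsort(mass)[-max_classes:])
            peaks = peaks[order]
    if peaks.size < 2:
        raise DegenerateHistogramError(
            f"only {peaks.size} separable gray-value mode(s); "
            "fall back to an identity-slope map through the single mode"
        )
    # gray windows: midpoints between neighboring kept peaks
    bounds = _windows(peaks)
    points: List[Tuple[float, float]] = []
    for i, p in enumerate(peaks):
        in_win = (centers >= bounds[i]) & (centers < bounds[i + 1])
        w = marginal[in_win].astype(float)
        if w.sum() == 0:
            continue
        gray_hat = float(np.average(centers[in_win], weights=w))
        cond = ndimage.gaussian_filter1d(hist.counts[:, in_win].sum(axis=1), 1.0)
        # conditional mode with parabolic sub-bin refinement: robust to the
        # partial-volume tail toward the neighboring class, which skews a
        # median, while a raw bin center quantizes by half a bin width
        j = int(np.argmax(cond))
        hu_hat = float(hist.hu_centers[j])
        if 0 < j < cond.size - 1:
            denom = cond[j - 1] - 2 * cond[j] + cond[j + 1]
            if denom < 0:
                shift = 0.5 * (cond[j - 1] - cond[j + 1]) / denom
                hu_hat += float(np.clip(shift, -0.5, 0.5)) * float(
                    hist.hu_centers[1] - hist.hu_centers[0]
                )
        points.append((gray_hat, hu_hat))
    points.sort(key=lambda t: t[0])
    if len(points) < 2:
        raise DegenerateHistogramError("fewer than two usable tissue classes")
    return points


# ---------------------------------------------------------------------------
# Conversion function
# ---------------------------------------------------------------------------


def _pava_nondecreasing(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: closest non-decreasing sequence (L2)."""
    y = np.asarray(y, dtype=float)
    out_vals, out_wts, out_len = [], [], []
    for v in y:
        out_vals.append(float(v))
        out_wts.append(1.0)
        out_len.append(1)
        while len(out_vals) > 1 and out_vals[-2] > out_vals[-1]:
            v2, w2, l2 = out_vals.pop(), out_wts.pop(), out_len.pop()
            v1, w1, l1 = out_vals.pop(), out_wts.pop(), out_len.pop()
            out_vals.append((v1 * w1 + v2 * w2) / (w1 + w2))
            out_wts.append(w1 + w2)
            out_len.append(l1 + l2)
    result = np.concatenate([np.full(l, v) for v, l in zip(out_vals, out_len)])
    return result


@dataclass
class ConversionFunction:
    """Monotone piecewise-linear map from CBCT gray values to CT numbers.

    Defined by junction points; linear extrapolation continues the terminal
    segment slopes, clamped to the representable HU range.
    """

    junctions: Tuple[Tuple[float, float], ...]  # (gray, HU), gray strictly increasing
    clamp: Tuple[float, float] = HU_CLAMP

    def __post_init__(self) -> None:
        g = np.array([j[0] for j in self.junctions], dtype=float)
        h = np.array([j[1] for j in self.junctions], dtype=float)
        if len(g) < 2:
            raise ValueError("a conversion function needs at least two junction points")
        if not np.all(np.diff(g) > 0):
            raise ValueError("junction gray values must be strictly increasing")
        if np.any(np.diff(h) < 0):
            raise ValueError("junction HU values must be non-decreasing (monotone map)")
        self._g, self._h = g, h

    def __call__(self, gray) -> np.ndarray:
        gray = np.asarray(gray, dtype=float)
        g, h = self._g, self._h
        out = np.interp(gray, g, h)
        lo_slope = (h[1] - h[0]) / (g[1] - g[0])
        hi_slope = (h[-1] - h[-2]) / (g[-1] - g[-2])
        below = gray < g[0]
        above = gray > g[-1]
        out = np.where(below, h[0] + lo_slope * (gray - g[0]), out)
        out = np.where(above, h[-1] + hi_slope * (gray - g[-1]), out)
        return np.clip(out, self.clamp[0], self.clamp[1])

    def derivative(self, gray) -> np.ndarray:
        """Local slope dHU/dgray (terminal slopes outside the junction range)."""
        gray = np.asarray(gray, dtype=float)
        g, h = self._g, self._h
        slopes = np.diff(h) / np.diff(g)
        seg = np.clip(np.searchsorted(g, gray, side="right") - 1, 0, len(slopes) - 1)
        return slopes[seg]

    def to_dict(self) -> dict:
        return {"junctions": [list(j) for j in self.junctions], "clamp": list(self.clamp)}

    @classmethod
    def from_dict(cls, d: dict) -> "ConversionFunction":
        return cls(tuple(tuple(j) for j in d["junctions"]), tuple(d.get("clamp", HU_CLAMP)))


def fit_conversion_function(class_points: Sequence[Tuple[float, float]]) -> ConversionFunction:
    """Piecewise-linear conversion through the tissue-class junction points.

    A non-monotone HU sequence (possible with noisy mode estimates) is
    monotonized by isotonic adjustment and logged.
    """
    pts = sorted(class_points, key=lambda t: t[0])
    if len(pts) < 2:
        raise ValueError("need at least two class points with distinct gray values")
    g = np.array([p[0] for p in pts], dtype=float)
    if np.any(np.diff(g) <= 0):
        raise ValueError("class points must have distinct gray values")
    h = np.array([p[1] for p in pts], dtype=float)
    if np.any(np.diff(h) < 0):
        log.warning("non-monotone HU sequence in class points; applying isotonic adjustment")
        h = _pava_nondecreasing(h)
    return ConversionFunction(tuple(zip(g.tolist(), h.tolist())))


# ---------------------------------------------------------------------------
# Artifact map
# ---------------------------------------------------------------------------


@dataclass
class ArtifactMap:
    """Additive low-frequency correction volume (HU) with its filter settings."""

    volume: np.ndarray
    grid: GridSpec
    sigma_mm: float
    units: str = "HU"

    def spectral_lowfreq_ratio(self, cutoff_cycles_per_mm: Optional[float] = None) -> float:
        """Fraction of spectral power at spatial frequencies below the cutoff
        (default: the filter's own half-power point)."""
        if cutoff_cycles_per_mm is None:
            cutoff_cycles_per_mm = np.sqrt(np.log(2) / 2.0) / (np.pi * self.sigma_mm)
        f = np.fft.fftn(self.volume)
        power = np.abs(f) ** 2
        freqs = np.meshgrid(
            *[np.fft.fftfreq(n, d=s) for n, s in zip(self.grid.shape, self.grid.spacing)],
            indexing="ij",
        )
        radial = np.sqrt(sum(fr**2 for fr in freqs))
        total = power.sum()
        return float(power[radial <= cutoff_cycles_per_mm].sum() / total) if total > 0 else 1.0


def estimate_artifact_map(
    converted_cbct: VolumeImage,
    pct_deformed: VolumeImage,
    mask: np.ndarray,
    sigma_mm: float = 25.0,
    feather_mm: float = 10.0,
    outlier_clip_hu: float = 150.0,
) -> ArtifactMap:
    """Low-frequency artifact estimate: low-pass of the HU difference map.

    The difference (converted CBCT minus deformed pCT) is Gaussian-filtered
    with a physical-units standard deviation (the operational meaning of
    "low-frequency"), using normalized convolution against the feathered mask
    so the estimate is unbiased near the region edge, then feathered smoothly
    to zero at the mask boundary.  Voxels whose difference exceeds
    ``outlier_clip_hu`` are excluded from the estimate: such differences are
    anatomy (an air cavity that filled, a registration miss at a bone edge),
    not shading, and would otherwise bleed into the correction.
    """
    if not converted_cbct.same_grid_as(pct_deformed):
        raise GeometryError("artifact estimation requires a common grid")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise GeometryError("artifact estimation over an empty mask")
    spacing = converted_cbct.spacing
    w = np.clip(fov_distance_mm(mask, spacing) / max(feather_mm, 1e-6), 0.0, 1.0)
    diff = converted_cbct.voxels - pct_deformed.voxels
    w_est = w * (np.abs(diff) <= outlier_clip_hu)
    sigma_vox = [sigma_mm / s for s in spacing]
    num = ndimage.gaussian_filter(diff * w_est, sigma_vox)
    den = ndimage.gaussian_filter(w_est, sigma_vox)
    lp = np.where(den > 1e-6, num / np.maximum(den, 1e-6), 0.0)
    return ArtifactMap(lp * w, converted_cbct.grid, sigma_mm)


# ---------------------------------------------------------------------------
# corrCBCT
# ---------------------------------------------------------------------------


@dataclass
class CorrCbctConfig:
    bins: Tuple[int, int] = (128, 128)
    max_classes: int = 4
    filter_sigma_mm: float = 25.0
    fov_feather_mm: float = 10.0
    convergence_tol_hu: float = 2.0  # mean |dHU| between iterations
    max_iterations: int = 5
    focus_margin_mm: float = 20.0
    redo_registration: bool = False  # re-run DIR every iteration instead of once
    dir: DirConfig = dfield(default_factory=DirConfig)


@dataclass
class CorrCbctResult:
    corrcbct: VolumeImage
    conversion: ConversionFunction
    artifact: ArtifactMap
    field: DeformationField
    converged: bool
    trace: List[Dict]
    pct_deformed: VolumeImage


def _initial_conversion(
    pct: VolumeImage, cbct: VolumeImage, mask: np.ndarray, config: CorrCbctConfig
) -> ConversionFunction:
    """Bootstrap conversion before any deformation: quantile matching of the
    two masked intensity distributions at fixed probability levels."""
    qs = np.array([0.02, 0.25, 0.5, 0.75, 0.98])
    gray_q = np.quantile(cbct.voxels[mask], qs)
    hu_q = np.quantile(pct.voxels[mask], qs)
    gray_q, idx = np.unique(np.round(gray_q, 6), return_index=True)
    hu_q = np.maximum.accumulate(hu_q[idx])
    if gray_q.size < 2:
        raise DegenerateHistogramError("CBCT intensity distribution is degenerate")
    return ConversionFunction(tuple(zip(gray_q.tolist(), hu_q.tolist())))


def naive_rescale(cbct: VolumeImage, fov: np.ndarray) -> VolumeImage:
    """Nominal two-point rescale of a CBCT: the gray-value air and
    soft-tissue modes are mapped to -1000 and 0 HU (water).

    This is the calibration-insert-style conversion a clinic would apply
    without any patient-specific joint-histogram fitting or artifact
    correction; it serves as the baseline the corrected CBCT is compared
    against.
    """
    fov = np.asarray(fov, dtype=bool)
    vals = cbct.voxels[fov]
    counts, edges = np.histogram(vals, bins=256)
    centers = 0.5 * (edges[:-1] + edges[1:])
    sm = ndimage.gaussian_filter1d(counts.astype(float), 2.0)
    padded = np.concatenate([[0.0], np.log1p(sm), [0.0]])
    peaks, props = signal.find_peaks(padded, prominence=0.05 * np.log1p(sm).max())
    peaks = np.sort(peaks - 1)
    if peaks.size < 2:
        raise DegenerateHistogramError("cannot locate air and soft-tissue gray modes")
    g_air = float(centers[peaks[0]])
    # soft tissue: the most prominent non-air mode
    rest = peaks[1:]
    g_soft = float(centers[rest[np.argmax(sm[rest])]])
    slope = 1000.0 / (g_soft - g_air)
    hu = -1000.0 + slope * (cbct.voxels - g_air)
    return cbct.with_voxels(np.clip(hu, *HU_CLAMP), IntensityKind.HU)


def make_corrcbct(
    pct: VolumeImage,
    cbct: VolumeImage,
    fov: np.ndarray,
    config: Optional[CorrCbctConfig] = None,
) -> CorrCbctResult:
    """Iterative intensity conversion + artifact correction of a CBCT.

    The pCT is deformably registered to the CBCT inside the retracted-FOV
    focus region (after a bootstrap intensity conversion so the similarity
    metric compares HU with HU).  The conversion function is then refitted on
    the joint histogram and a low-frequency artifact map subtracted; these two
    steps repeat until the corrected image changes by less than the tolerance
    or the iteration cap is reached.  Outside the FOV the anatomy is extended
    with the deformed pCT through a feathered transition band.
    """
    config = config or CorrCbctConfig()
    if cbct.intensity_kind != IntensityKind.CBCT_GRAY:
        raise ValueError("cbct must carry CBCT_GRAY intensities")
    if not pct.same_grid_as(cbct):
        raise GeometryError("pCT must be resampled to the CBCT grid first")
    fov = np.asarray(fov, dtype=bool)
    focus = retract_fov(fov, cbct.spacing, config.focus_margin_mm)

    conversion = _initial_conversion(pct, cbct, focus, config)
    field: Optional[DeformationField] = None
    pct_def = pct
    corrected_prev: Optional[np.ndarray] = None
    artifact: Optional[ArtifactMap] = None
    trace: List[Dict] = []
    converged = False

    shading_gray = np.zeros(cbct.voxels.shape)  # accumulated artifact, gray units
    wf = np.clip(fov_distance_mm(fov, cbct.spacing) / config.fov_feather_mm, 0.0, 1.0)
    for it in range(config.max_iterations):
        # refit the conversion on gray values with the artifact estimate so
        # far removed: a shading-contaminated histogram skews the junctions,
        # so conversion and artifact correction must relax jointly.  The
        # class modes are robust to the residual anatomy mismatch of the
        # (iteration 0) undeformed pCT.
        gray_corr = cbct.voxels - shading_gray
        hist = build_joint_histogram(pct_def, cbct.with_voxels(gray_corr), focus, config.bins)
        try:
            points = identify_tissue_classes(hist, config.max_classes)
            conversion = fit_conversion_function(points)
        except DegenerateHistogramError as exc:
            log.warning("degenerate histogram at iteration %d: %s", it, exc)
        converted = cbct.with_voxels(conversion(gray_corr), IntensityKind.HU)
        artifact = estimate_artifact_map(
            converted, pct_def, fov, config.filter_sigma_mm, config.fov_feather_mm
        )
        corrected = converted.voxels - artifact.volume
        # fold the residual back into the gray-space running estimate; the
        # low-pass recovers only part of the shading per pass (it is damped
        # near the region edge), so the loop converges geometrically
        slope = np.maximum(conversion.derivative(gray_corr), 0.05)
        shading_gray = shading_gray + artifact.volume / slope
        if field is None or config.redo_registration:
            # register against the corrected CBCT: the demons metric assumes
            # intensity constancy, so low-frequency shading must be removed
            # first; outside the FOV the registration composites in the
            # (pre-aligned) pCT so the truncation boundary exerts no forces
            reg_target = converted.with_voxels(corrected)
            field = deform(pct, reg_target, focus, config.dir, fixed_valid=fov)
            pct_def = warp_image(pct, field, "linear")
        if corrected_prev is not None:
            delta = float(np.mean(np.abs(corrected - corrected_prev)[fov]))
            trace.append({"iteration": it, "mean_abs_change_hu": delta})
            if delta < config.convergence_tol_hu:
                corrected_prev = corrected
                converged = True
                break
        else:
            trace.append({"iteration": it, "mean_abs_change_hu": None})
        corrected_prev = corrected

    assert corrected_prev is not None and artifact is not None and field is not None
    composite = wf * corrected_prev + (1.0 - wf) * pct_def.voxels
    out = VolumeImage(composite, cbct.spacing, cbct.origin, IntensityKind.HU)
    # report the total accumulated correction (conversion of the raw gray
    # values minus the corrected image), not just the last pass's residual
    total = ArtifactMap(
        conversion(cbct.voxels) - corrected_prev, cbct.grid, config.filter_sigma_mm
    )
    if not converged:
        log.warning("corrCBCT did not converge in %d iterations", config.max_iterations)
    return CorrCbctResult(out, conversion, total, field, converged, trace, pct_def)


# ---------------------------------------------------------------------------
# Density, virtCT, gtCT
# ---------------------------------------------------------------------------


def _piecewise_with_terminal_slopes(x: np.ndarray, table: Sequence[Tuple[float, float]]) -> np.ndarray:
    xs = np.array([t[0] for t in table], dtype=float)
    ys = np.array([t[1] for t in table], dtype=float)
    if np.any(np.diff(xs) <= 0) or np.any(np.diff(ys) <= 0):
        raise ValueError("calibration table must be strictly monotone")
    out = np.interp(x, xs, ys)
    lo = (ys[1] - ys[0]) / (xs[1] - xs[0])
    hi = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
    out = np.where(x < xs[0], ys[0] + lo * (x - xs[0]), out)
    out = np.where(x > xs[-1], ys[-1] + hi * (x - xs[-1]), out)
    return out


def to_density(
    img: VolumeImage, calibration: Sequence[Tuple[float, float]] = DEFAULT_DENSITY_TABLE
) -> VolumeImage:
    """Piecewise-linear HU -> mass density (g/cm^3), floored at zero."""
    if img.intensity_kind != IntensityKind.HU:
        raise ValueError("to_density expects an HU image")
    rho = np.maximum(_piecewise_with_terminal_slopes(img.voxels, calibration), 0.0)
    return img.with_voxels(rho, IntensityKind.DENSITY)


def low_density_override_mask(
    rho_a: np.ndarray,
    rho_b: np.ndarray,
    delta_rho: float = 0.3,
    low_rho: float = 0.6,
) -> np.ndarray:
    """The virtCT masking rule on two density volumes.

    True where the densities disagree by more than ``delta_rho`` AND the
    smaller of the two is below ``low_rho``; both comparisons are strict, so
    a disagreement of exactly 0.3 g/cm^3 or a density of exactly 0.6 g/cm^3
    does not override.
    """
    return (np.abs(rho_a - rho_b) > delta_rho) & (np.minimum(rho_a, rho_b) < low_rho)


def make_virtct(
    pct: VolumeImage,
    corrcbct: VolumeImage,
    field: DeformationField,
    fov: np.ndarray,
    delta_rho: float = 0.3,
    low_rho: float = 0.6,
    calibration: Sequence[Tuple[float, float]] = DEFAULT_DENSITY_TABLE,
) -> Tuple[VolumeImage, np.ndarray]:
    """Virtual CT: deformed pCT with low-density masking from the corrCBCT.

    A voxel inside the FOV is overridden with the corrCBCT CT number when the
    density disagreement exceeds ``delta_rho`` (strict >) and the lower of the
    two densities is below ``low_rho`` (strict <); both densities come from
    the same HU calibration so the comparison is commensurate.  Returns the
    virtCT and the boolean override mask.
    """
    base = warp_image(pct, field, "linear")
    if not base.same_grid_as(corrcbct):
        raise GeometryError("virtCT requires corrCBCT and deformed pCT on one grid")
    fov = np.asarray(fov, dtype=bool)
    rho_virt = to_density(base, calibration).voxels
    rho_corr = to_density(corrcbct, calibration).voxels
    override = low_density_override_mask(rho_virt, rho_corr, delta_rho, low_rho) & fov
    voxels = np.where(override, corrcbct.voxels, base.voxels)
    return base.with_voxels(voxels, IntensityKind.HU), override


def make_gtct(
    vfct: VolumeImage,
    cbct: VolumeImage,
    fov: np.ndarray,
    config: Optional[CorrCbctConfig] = None,
) -> Tuple[VolumeImage, DeformationField]:
    """Ground-truth CT: the vfCT deformed to the same-day CBCT.

    The CBCT is first converted to HU (same histogram machinery as the
    corrCBCT, fitted against the vfCT) so the deformable registration compares
    commensurate intensities; the returned image is the warped vfCT.
    """
    config = config or CorrCbctConfig()
    if not vfct.same_grid_as(cbct):
        raise GeometryError("vfCT must be resampled to the CBCT grid first")
    fov = np.asarray(fov, dtype=bool)
    focus = retract_fov(fov, cbct.spacing, config.focus_margin_mm)
    conversion = _initial_conversion(vfct, cbct, focus, config)
    converted = cbct.with_voxels(conversion(cbct.voxels), IntensityKind.HU)
    hist = build_joint_histogram(vfct, cbct, focus, config.bins)
    try:
        conversion = fit_conversion_function(identify_tissue_classes(hist, config.max_classes))
        converted = cbct.with_voxels(conversion(cbct.voxels), IntensityKind.HU)
    except DegenerateHistogramError:
        pass
    # remove low-frequency shading before registering (intensity-constancy);
    # the difference map is taken against the setup-aligned vfCT, otherwise
    # shift-correlated edge differences leak into the correction and bias the
    # registration equilibrium toward the unshifted anatomy
    t_mm = estimate_translation(converted, vfct, focus, config.dir.feather_mm)
    vf_aligned = vfct
    if np.any(np.abs(t_mm) > 0.25 * min(cbct.spacing)):
        shift_field = DeformationField(
            np.broadcast_to(-t_mm, tuple(vfct.grid.shape) + (3,)).copy(), vfct.grid
        )
        vf_aligned = warp_image(vfct, shift_field, "linear")
    pre = estimate_artifact_map(converted, vf_aligned, fov, config.filter_sigma_mm, config.fov_feather_mm)
    reg_target = converted.with_voxels(converted.voxels - pre.volume)
    field = deform(vfct, reg_target, focus, config.dir, fixed_valid=fov)
    gtct = warp_image(vfct, field, "linear")
    return gtct, field
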