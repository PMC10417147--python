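"""Volumetric image / structure data model shared by the whole pipeline.

Conventions
-----------
* Voxel arrays are indexed ``voxels[ix, iy, iz]`` with axes X (right-left),
  Y (anterior-posterior, +Y posterior) and Z (inferior-superior, +Z superior).
* Voxel indices are 0-based; the physical position of index ``i`` along an
  axis is ``origin + i * spacing`` (mm). Grids are axis-aligned.
* CT-class images carry Hounsfield units; CBCT images carry uncalibrated
  gray values and must never be mixed with HU before conversion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Dict, Iterator, Mapping, Optional, Sequence, Tuple

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

log = logging.getLogger("cbctsct")

__all__ = [
    "IntensityKind",
    "StructureRole",
    "GridSpec",
    "VolumeImage",
    "StructureSet",
    "FormatError",
    "GeometryError",
    "read_volume",
    "write_volume",
    "read_structures",
    "write_structures",
    "resample_to_grid",
    "retract_fov",
    "mask_centroid_mm",
]


class FormatError(RuntimeError):
    """Unreadable or dimensionally wrong volumetric file."""


class GeometryError(ValueError):
    """Inconsistent grids, empty regions, invalid spacings."""


class IntensityKind(str, Enum):
    HU = "HU"
    CBCT_GRAY = "CBCT_GRAY"
    DOSE = "DOSE"
    DENSITY = "DENSITY"


class StructureRole(str, Enum):
    CTV_HIGH = "CTV_HIGH"
    CTV_STANDARD = "CTV_STANDARD"
    FOV = "FOV"
    EXTERNAL = "EXTERNAL"
    OTHER = "OTHER"


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned sampling grid: shape (voxels), spacing and origin in mm."""

    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise GeometryError(f"shape must be three positive integers, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be three positive lengths, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def extent_mm(self) -> Tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def coordinate_axes(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates of voxel centers along each axis."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)
        )

    def to_dict(self) -> dict:
        return {"shape": list(self.shape), "spacing": list(self.spacing), "origin": list(self.origin)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "GridSpec":
        return cls(tuple(d["shape"]), tuple(d["spacing"]), tuple(d.get("origin", (0, 0, 0))))


@dataclass
class VolumeImage:
    """A 3D scalar grid with physical geometry and a declared intensity kind."""

    voxels: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    intensity_kind: IntensityKind = IntensityKind.HU

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise FormatError(f"expected 3D voxel data, got {self.voxels.ndim}D")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        if np.issubdtype(self.voxels.dtype, np.floating) and not np.all(np.isfinite(self.voxels)):
            raise GeometryError("voxel values must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.intensity_kind = IntensityKind(self.intensity_kind)

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.voxels.shape, self.spacing, self.origin)

    def with_voxels(self, voxels: np.ndarray, kind: Optional[IntensityKind] = None) -> "VolumeImage":
        return VolumeImage(voxels, self.spacing, self.origin, kind or self.intensity_kind)

    def same_grid_as(self, other: "VolumeImage | GridSpec", tol: float = 1e-6) -> bool:
        g = other if isinstance(other, GridSpec) else other.grid
        return (
            self.voxels.shape == tuple(g.shape)
            and np.allclose(self.spacing, g.spacing, atol=tol)
            and np.allclose(self.origin, g.origin, atol=tol)
        )


@dataclass
class StructureSet:
    """Named binary masks sharing one reference grid, each with a clinical role."""

    masks: Dict[str, np.ndarray]
    roles: Dict[str, StructureRole]
    grid: GridSpec
    # derived sets (e.g. contours mapped through a deformation) may legally
    # end up with an empty CTV; primary sets must not
    require_nonempty_ctv: bool = True

    def __post_init__(self) -> None:
        for name, m in self.masks.items():
            m = np.asarray(m)
            if m.shape != tuple(self.grid.shape):
                raise GeometryError(
                    f"mask '{name}' shape {m.shape} does not match reference grid {self.grid.shape}"
                )
            self.masks[name] = m.astype(bool)
            self.roles.setdefault(name, StructureRole.OTHER)
        for name, role in self.roles.items():
            if name not in self.masks:
                raise GeometryError(f"role given for unknown structure '{name}'")
            if (
                self.require_nonempty_ctv
                and role in (StructureRole.CTV_HIGH, StructureRole.CTV_STANDARD)
                and not self.masks[name].any()
            ):
                raise GeometryError(f"CTV mask '{name}' is empty")

    def by_role(self, role: StructureRole) -> Dict[str, np.ndarray]:
        return {n: self.masks[n] for n, r in self.roles.items() if r == role}

    def first(self, role: StructureRole) -> np.ndarray:
        found = self.by_role(role)
        if not found:
            raise KeyError(f"no structure with role {role.value}")
        return next(iter(found.values()))

    def items(self) -> Iterator[Tuple[str, np.ndarray, StructureRole]]:
        for n, m in self.masks.items():
            yield n, m, self.roles[n]


# ---------------------------------------------------------------------------
# I/O — NIfTI / MetaImage via SimpleITK; arrays are transposed so that our
# (x, y, z) index order maps onto the file's (x, y, z) physical axes.
# ---------------------------------------------------------------------------

_RECOGNIZED = (".nii", ".nii.gz", ".mha", ".mhd")


def _check_path(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(ext) for ext in _RECOGNIZED):
        raise FormatError(f"unrecognized volume format: {path} (expected .nii[.gz]/.mha/.mhd)")


def read_volume(path, intensity_kind: IntensityKind = IntensityKind.HU) -> VolumeImage:
    """Read a NIfTI or MetaImage volume; voxel values are returned as stored."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such volume file: {path}")
    _check_path(path)
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # sitk raises bare RuntimeError
        raise FormatError(f"could not read volume {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise FormatError(f"{path}: expected 3D data, got {img.GetDimension()}D")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    voxels = np.transpose(arr, (2, 1, 0))
    return VolumeImage(voxels, tuple(img.GetSpacing()), tuple(img.GetOrigin()), intensity_kind)


def write_volume(img: VolumeImage, path) -> Path:
    path = Path(path)
    _check_path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    s = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(img.voxels, (2, 1, 0))))
    s.SetSpacing(img.spacing)
    s.SetOrigin(img.origin)
    sitk.WriteImage(s, str(path))
    return path


def write_structures(structures: StructureSet, label_path, sidecar_path=None) -> Tuple[Path, Path]:
    """Store masks as one labeled integer volume + JSON sidecar (label -> name/role).

    Overlapping masks are written to separate bit-planes of an int32 label image
    (bit k set <=> structure k present), so overlap survives the round trip.
    """
    label_path = Path(label_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else label_path.with_suffix("").with_suffix(".json")
    names = list(structures.masks)
    if len(names) > 31:
        raise GeometryError("more than 31 structures cannot be bit-packed into int32 labels")
    labels = np.zeros(structures.grid.shape, dtype=np.int32)
    for k, n in enumerate(names):
        labels |= structures.masks[n].astype(np.int32) << k
    vol = VolumeImage(labels, structures.grid.spacing, structures.grid.origin, IntensityKind.HU)
    write_volume(vol, label_path)
    sidecar = {
        "encoding": "bitplane",
        "grid": structures.grid.to_dict(),
        "structures": [
            {"bit": k, "name": n, "role": structures.roles[n].value} for k, n in enumerate(names)
        ],
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return label_path, sidecar_path


def read_structures(label_path, sidecar_path=None) -> StructureSet:
    label_path = Path(label_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else label_path.with_suffix("").with_suffix(".json")
    vol = read_volume(label_path)
    meta = json.loads(Path(sidecar_path).read_text())
    labels = vol.voxels.astype(np.int64)
    masks, roles = {}, {}
    for entry in meta["structures"]:
        masks[entry["name"]] = (labels >> entry["bit"]) & 1 > 0
        roles[entry["name"]] = StructureRole(entry["role"])
    return StructureSet(masks, roles, vol.grid)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

_DEFAULT_PADDING = {
    IntensityKind.HU: -1000.0,  # air surrounds the patient
    IntensityKind.CBCT_GRAY: 0.0,
    IntensityKind.DOSE: 0.0,
    IntensityKind.DENSITY: 0.001,
}


def resample_to_grid(
    img: VolumeImage,
    target: GridSpec,
    interpolation: str = "linear",
    padding: Optional[float] = None,
) -> VolumeImage:
    """Resample onto ``target``; linear for intensities, nearest for masks.

    Out-of-extent voxels receive ``padding`` (default -1000 HU for CT-class
    images, the physical air surround).
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation '{interpolation}' (use 'linear' or 'nearest')")
    if padding is None:
        padding = _DEFAULT_PADDING[img.intensity_kind]
    if img.same_grid_as(target):
        return replace(img, voxels=img.voxels.copy())
    axes = [
        (target.origin[a] + np.arange(target.shape[a]) * target.spacing[a] - img.origin[a])
        / img.spacing[a]
        for a in range(3)
    ]
    ix, iy, iz = np.meshgrid(*axes, indexing="ij")
    order = 1 if interpolation == "linear" else 0
    out = ndimage.map_coordinates(
        img.voxels.astype(np.float64),
        np.stack([ix, iy, iz]),
        order=order,
        mode="constant",
        cval=float(padding),
    )
    if interpolation == "nearest" and img.voxels.dtype == bool:
        out = out > 0.5
    return VolumeImage(out, target.spacing, target.origin, img.intensity_kind)


def fov_distance_mm(mask: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """Euclidean distance (mm) from each in-mask voxel to the mask boundary."""
    return ndimage.distance_transform_edt(mask, sampling=spacing)


def retract_fov(fov_mask: np.ndarray, spacing: Sequence[float], margin_mm: float) -> np.ndarray:
    """Erode a field-of-view mask by ``margin_mm`` in physical units.

    Uses the Euclidean distance transform with anisotropic sampling so a 2.5 mm
    slice spacing erodes correctly; result is a strict subset of the input.
    """
    fov_mask = np.asarray(fov_mask).astype(bool)
    if margin_mm < 0:
        raise ValueError("margin_mm must be non-negative")
    if not fov_mask.any():
        raise GeometryError("empty focus region: FOV mask has no voxels")
    if margin_mm == 0:
        return fov_mask.copy()
    eroded = fov_distance_mm(fov_mask, spacing) > margin_mm
    if not eroded.any():
        raise GeometryError(
            f"empty focus region: erosion by {margin_mm} mm removed the whole FOV"
        )
    return eroded


def mask_centroid_mm(mask: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Physical centroid (mm) of a binary mask."""
    idx = np.argwhere(mask)
    if idx.size == 0:
        raise GeometryError("centroid of an empty mask")
    return np.asarray(grid.origin) + idx.mean(axis=0) * np.asarray(grid.spacing)
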