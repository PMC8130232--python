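"""Core geometric data model: voxel grids, scalar images, displacement fields,
structure masks, and readers/writers for NIfTI and MetaImage.

Conventions
-----------
* World coordinates are in millimetres on fixed, axis-aligned (LPS-like) axes.
* Arrays are indexed ``[i, j, k]`` along the (x, y, z) world axes; the centre of
  voxel ``(0, 0, 0)`` sits at ``grid.origin``.
* Displacements are stored in world mm (never voxel units), so anisotropic
  grids such as 1 x 1 x 3 mm need no special casing.
* Every :class:`DisplacementField` carries an explicit ``direction`` tag:
  ``"pull"`` fields map a point x on their own grid to the sample location
  ``x + u(x)`` in the *source* image; ``"push"`` fields map source points
  forward to target points.  Operations check and propagate the tag.

Oblique (non-axis-aligned) grids and 4D volumes are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "Image3D",
    "DisplacementField",
    "StructureMask",
    "ContourSetQC",
    "GeometryError",
    "FormatError",
    "read_volume",
    "write_volume",
    "resample",
]


class GeometryError(ValueError):
    """Grids are incompatible for the requested operation."""


class FormatError(ValueError):
    """File content does not match the expected image layout."""


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice: origin (mm), per-axis spacing (mm), size.

    The world <-> index mapping is the exact affine
    ``world = origin + index * spacing`` and its inverse.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    size: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "size", tuple(int(v) for v in self.size))
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.size) != 3:
            raise GeometryError("grids are three-dimensional")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacings must be positive, got {self.spacing}")
        if any(n < 1 for n in self.size):
            raise GeometryError(f"sizes must be >= 1, got {self.size}")

    # -- mappings -----------------------------------------------------------

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (continuous) indices, shape (..., 3), to world mm."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map world points, shape (..., 3), to continuous indices."""
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def world_coords(self) -> np.ndarray:
        """Dense world coordinates of every voxel centre, shape size + (3,)."""
        axes = [
            self.origin[a] + self.spacing[a] * np.arange(self.size[a])
            for a in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.size

    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """World coordinates of the first and last voxel centres."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + (np.asarray(self.size) - 1) * np.asarray(self.spacing)
        return lo, hi

    def same_geometry(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        return (
            self.size == other.size
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
        )


def _check_values(grid: VoxelGrid, arr: np.ndarray, ncomp: int | None) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    want = grid.size if ncomp is None else grid.size + (ncomp,)
    if arr.shape != want:
        raise GeometryError(f"array shape {arr.shape} does not match grid {want}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("array contains non-finite values")
    return arr


@dataclass(frozen=True)
class Image3D:
    """Scalar intensity volume (HU) on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _check_values(self.grid, self.values, None))


@dataclass(frozen=True)
class DisplacementField:
    """Per-voxel 3-vector displacements (world mm) with a direction tag."""

    grid: VoxelGrid
    vectors: np.ndarray = field(repr=False)
    direction: str = "pull"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "vectors", _check_values(self.grid, self.vectors, 3)
        )
        if self.direction not in ("pull", "push"):
            raise ValueError(f"direction must be 'pull' or 'push', got {self.direction!r}")

    def with_direction(self, direction: str) -> "DisplacementField":
        return replace(self, direction=direction)

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)


@dataclass(frozen=True)
class StructureMask:
    """Named binary structure on a :class:`VoxelGrid`."""

    name: str
    grid: VoxelGrid
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask)
        if mask.shape != self.grid.size:
            raise GeometryError(
                f"mask shape {mask.shape} does not match grid {self.grid.size}"
            )
        if mask.dtype != bool:
            uniq = np.unique(mask)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask must be strictly binary")
            mask = mask.astype(bool)
        object.__setattr__(self, "mask", mask)

    @property
    def volume_cc(self) -> float:
        """Physical volume: voxel count x voxel volume / 1000 (mm^3 -> cc)."""
        return float(self.mask.sum()) * self.grid.voxel_volume_mm3 / 1000.0

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class ContourSetQC:
    """Per-structure inverse-consistency QC verdict for one case.

    A structure is accepted when its mean ICE does not exceed the contour
    threshold; the whole case is rejected only when *every* structure exceeds
    the case threshold.
    """

    mean_ice_mm: dict[str, float]
    max_ice_mm: dict[str, float]
    accepted: dict[str, bool]
    case_accepted: bool
    errors: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "structures": {
                name: {
                    "mean_ice_mm": self.mean_ice_mm.get(name),
                    "max_ice_mm": self.max_ice_mm.get(name),
                    "accepted": self.accepted.get(name),
                    "error": self.errors.get(name),
                }
                for name in self.mean_ice_mm
            },
            "case_accepted": self.case_accepted,
        }


# ---------------------------------------------------------------------------
# File I/O (SimpleITK backend, NIfTI + MetaImage)
# ---------------------------------------------------------------------------

_FORMAT_EXT = {"nifti": ".nii", "mha": ".mha"}


def _grid_from_sitk(img: sitk.Image) -> VoxelGrid:
    if img.GetDimension() != 3:
        raise FormatError(f"expected a 3D volume, got {img.GetDimension()}D")
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise FormatError("oblique (non-identity direction) grids are not supported")
    spacing = img.GetSpacing()
    if any(s <= 0 for s in spacing):
        raise FormatError("file is missing positive voxel spacing")
    return VoxelGrid(origin=img.GetOrigin(), spacing=spacing, size=img.GetSize())


def read_volume(
    path: str | Path, direction: str | None = None
) -> Image3D | DisplacementField:
    """Read a scalar volume or a 3-component vector field from NIfTI/MHA.

    Vector data must be tagged with a mapping ``direction`` ("pull"/"push")
    supplied by the caller; the formats themselves do not record it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = sitk.ReadImage(str(path))
    ncomp = img.GetNumberOfComponentsPerPixel()
    grid = _grid_from_sitk(img)
    arr = sitk.GetArrayFromImage(img)  # (z, y, x[, c])
    if ncomp == 1:
        return Image3D(grid=grid, values=np.ascontiguousarray(arr.T, dtype=float))
    if ncomp == 3:
        if direction is None:
            raise ValueError(
                "vector data needs an explicit direction tag ('pull' or 'push')"
            )
        vec = np.ascontiguousarray(np.transpose(arr, (2, 1, 0, 3)), dtype=float)
        return DisplacementField(grid=grid, vectors=vec, direction=direction)
    raise FormatError(f"unsupported component count {ncomp} (expected 1 or 3)")


def write_volume(obj: Image3D | DisplacementField, path: str | Path) -> Path:
    """Write a volume; the format follows the file extension (.nii/.nii.gz/.mha/.mhd)."""
    path = Path(path)
    if isinstance(obj, Image3D):
        img = sitk.GetImageFromArray(np.ascontiguousarray(obj.values.T))
    elif isinstance(obj, DisplacementField):
        img = sitk.GetImageFromArray(
            np.ascontiguousarray(np.transpose(obj.vectors, (2, 1, 0, 3))),
            isVector=True,
        )
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    img.SetOrigin(obj.grid.origin)
    img.SetSpacing(obj.grid.spacing)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))
    return path


def write_label_volume(
    masks: list[StructureMask], path: str | Path
) -> tuple[Path, dict[int, str]]:
    """Write structures as one integer label volume plus a name map.

    Later masks overwrite earlier ones where they overlap; label 0 is
    background.  Returns the path and the ``{label: name}`` map (the caller
    typically serializes it to a sidecar JSON).
    """
    if not masks:
        raise ValueError("no masks to write")
    grid = masks[0].grid
    labels = np.zeros(grid.size, dtype=np.int16)
    name_map: dict[int, str] = {}
    for i, m in enumerate(masks, start=1):
        if not m.grid.same_geometry(grid):
            raise GeometryError("all masks must share one grid")
        labels[m.mask] = i
        name_map[i] = m.name
    img = sitk.GetImageFromArray(np.ascontiguousarray(labels.T))
    img.SetOrigin(grid.origin)
    img.SetSpacing(grid.spacing)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))
    return path, name_map


def read_label_volume(
    path: str | Path, name_map: dict[int, str] | None = None
) -> list[StructureMask]:
    """Read an integer label volume back into one mask per nonzero label."""
    img = sitk.ReadImage(str(path))
    grid = _grid_from_sitk(img)
    labels = np.ascontiguousarray(sitk.GetArrayFromImage(img).T)
    out = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        name = (name_map or {}).get(int(lab), f"label_{int(lab)}")
        out.append(StructureMask(name=name, grid=grid, mask=labels == lab))
    return out


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

_ORDER = {"linear": 1, "nearest": 0}


def sample_at_world(
    values: np.ndarray,
    grid: VoxelGrid,
    pts: np.ndarray,
    interpolation: str = "linear",
    fill: float = 0.0,
) -> np.ndarray:
    """Sample a scalar array defined on ``grid`` at world points (..., 3)."""
    if interpolation not in _ORDER:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    idx = grid.world_to_index(pts)
    coords = np.moveaxis(idx, -1, 0)
    return ndimage.map_coordinates(
        values, coords, order=_ORDER[interpolation], mode="constant", cval=fill
    )


def resample(
    img: Image3D,
    target: VoxelGrid,
    interpolation: str = "linear",
    fill: float = 0.0,
) -> Image3D:
    """Resample an image onto ``target``.

    Nearest interpolation reproduces source values at coincident grid points;
    linear interpolation is exact for affine intensity ramps (inside the
    source extent).  Raises :class:`GeometryError` if no target voxel centre
    falls inside the source extent.
    """
    lo_s, hi_s = img.grid.extent()
    lo_t, hi_t = target.extent()
    if np.any(hi_t < lo_s) or np.any(lo_t > hi_s):
        raise GeometryError("target grid does not overlap the source image")
    pts = target.world_coords()
    vals = sample_at_world(img.values, img.grid, pts, interpolation, fill)
    return Image3D(grid=target, values=vals)
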