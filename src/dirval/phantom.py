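"""Synthetic digital head-and-neck phantoms with analytic ground truth.

The generator emulates the anatomy-change inventory of interfraction HN
virtual-phantom libraries: a start-of-treatment (SOT) CT volume carrying
nine named structures whose volumes match the published per-structure means
(mandible 71.8 cc ... larynx 5.1 cc), and a smooth, invertible ground-truth
deformation composed of head rotation, progressive spine flexion, per-organ
shrinkage, and a global 4-20% body-volume loss (default 10.6%).  Structures
are geometric primitives (ellipsoids and cylinders) laid out in disjoint
anatomical bands; a smooth random texture plus distinct per-organ HU values
make NCC patches informative without attempting patient realism.

World coordinates are centred on the grid; z points superiorly.  All
deformation components are defined as *push* fields (SOT point -> EOT
point); :func:`apply_gt` numerically inverts the composite to the pull field
it needs for warping, and returns both directions for ICE/TRE analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .dvf import (
    ICEVolume,
    compose,
    ice_map,
    invert_dvf,
    jacobian_determinant,
    propagate_mask,
    warp_image,
)
from .volumes import DisplacementField, Image3D, StructureMask, VoxelGrid

__all__ = [
    "TABLE_VOLUMES_CC",
    "PhantomSpec",
    "DeformationSpec",
    "GroundTruthCase",
    "build_hn_phantom",
    "build_gt_dvf",
    "apply_gt",
    "build_marker_phantom",
    "centered_grid",
]

#: Published mean volumes (cc) of the structures of interest.
TABLE_VOLUMES_CC = {
    "mandible": 71.8,
    "oral_cavity": 31.3,
    "brainstem": 29.7,
    "spinal_cord": 22.8,
    "parotid_left": 19.9,
    "parotid_right": 19.9,
    "pharyngeal_constrictors": 11.1,
    "esophagus": 6.6,
    "submandibular_left": 5.3,
    "submandibular_right": 5.3,
    "larynx": 5.1,
}

AIR_HU = -1000.0
BODY_HU = 20.0
BONE_HU = 800.0

# structure -> (kind, params, HU); ellipsoid: (center, semiaxes);
# zcylinder: (cx, cy, r, zlo, zhi).  Semi-axis products solve
# 4/3*pi*abc = V for the table volumes; cylinders solve pi*r^2*L = V.
_STRUCTURES: dict[str, tuple] = {
    "brainstem": ("ellipsoid", ((0.0, 17.0, 30.0), (17.0, 17.0, 24.53)), 40.0),
    "spinal_cord": ("zcylinder", (0.0, 20.0, 11.0, -55.0, 5.0), 45.0),
    "mandible": ("ellipsoid", ((0.0, -45.0, 8.5), (38.6, 24.0, 18.5)), BONE_HU),
    "oral_cavity": ("ellipsoid", ((0.0, -38.0, 42.0), (24.0, 22.0, 14.15)), 60.0),
    "parotid_left": ("ellipsoid", ((52.0, -5.0, 24.0), (13.5, 16.0, 22.0)), 55.0),
    "parotid_right": ("ellipsoid", ((-52.0, -5.0, 24.0), (13.5, 16.0, 22.0)), 55.0),
    "pharyngeal_constrictors": ("zcylinder", (0.0, -8.0, 8.0, -28.0, 27.2), 50.0),
    "esophagus": ("zcylinder", (0.0, -8.0, 9.36, -56.0, -33.5), 35.0),
    "submandibular_left": ("ellipsoid", ((40.0, -28.0, -16.0), (8.5, 12.0, 12.4)), 65.0),
    "submandibular_right": ("ellipsoid", ((-40.0, -28.0, -16.0), (8.5, 12.0, 12.4)), 65.0),
    "larynx": ("ellipsoid", ((0.0, -38.0, -26.0), (9.0, 9.0, 15.0)), 30.0),
}

#: Cervical vertebral column: unnamed bone feature for registration contrast.
_VERTEBRA = (0.0, 42.0, 9.0, -55.0, 0.0)


def centered_grid(
    size: tuple[int, int, int], spacing: tuple[float, float, float]
) -> VoxelGrid:
    """Grid whose world origin sits at the volume centre."""
    origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(size, spacing))
    return VoxelGrid(origin=origin, spacing=spacing, size=size)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and appearance of the SOT phantom.

    Default grid is 1 x 1 x 3 mm at 256 x 256 x 60 voxels; ``desk`` gives a
    smaller 128 x 128 x 40 grid (1.5 x 1.5 x 3 mm) covering the same anatomy
    for quick runs.  ``texture_hu`` is the amplitude of the smooth random
    texture added inside the body.
    """

    size: tuple[int, int, int] = (256, 256, 60)
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    texture_hu: float = 50.0
    texture_sigma_mm: float = 4.0
    seed: int = 0
    structures: tuple[str, ...] = tuple(_STRUCTURES)

    @classmethod
    def desk(cls, seed: int = 0, **kw) -> "PhantomSpec":
        return cls(size=(128, 128, 40), spacing=(1.5, 1.5, 3.0), seed=seed, **kw)

    def grid(self) -> VoxelGrid:
        return centered_grid(self.size, self.spacing)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))

def _body_radii(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """In-plane body semi-axes (mm): neck ~55/60 widening to head ~80/85."""
    s = _sigmoid((z - 10.0) / 12.0)
    rx = 55.0 + 25.0 * s
    return rx, rx + 5.0


def _rasterize(kind: str, params, coords: np.ndarray) -> np.ndarray:
    x, y, z = coords[..., 0], coords[..., 1], coords[..., 2]
    if kind == "ellipsoid":
        (cx, cy, cz), (a, b, c) = params
        return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0
    if kind == "zcylinder":
        cx, cy, r, zlo, zhi = params
        return (((x - cx) / r) ** 2 + ((y - cy) / r) ** 2 <= 1.0) & (z >= zlo) & (z <= zhi)
    raise ValueError(f"unknown primitive {kind!r}")


def build_hn_phantom(
    spec: PhantomSpec | None = None,
) -> tuple[Image3D, list[StructureMask]]:
    """Rasterize the SOT image and its structure masks.

    A voxel belongs to a shape when its centre is inside the analytic
    primitive.  Structures with different HU assignments must not overlap
    (spec error); the image is painted body -> vertebra -> structures and
    textured with a seeded smooth random field inside the body.
    """
    spec = spec or PhantomSpec()
    grid = spec.grid()
    coords = grid.world_coords()
    x, y, z = coords[..., 0], coords[..., 1], coords[..., 2]
    rx, ry = _body_radii(z)
    body = (x / rx) ** 2 + (y / ry) ** 2 <= 1.0

    values = np.full(grid.size, AIR_HU)
    values[body] = BODY_HU
    values[_rasterize("zcylinder", _VERTEBRA, coords) & body] = BONE_HU

    masks: list[StructureMask] = []
    claimed = np.zeros(grid.size, dtype=bool)
    claimed_hu = np.zeros(grid.size)
    for name in spec.structures:
        kind, params, hu = _STRUCTURES[name]
        m = _rasterize(kind, params, coords)
        if not np.all(body[m]):
            raise ValueError(f"structure {name!r} leaves the body")
        clash = m & claimed & (claimed_hu != hu)
        if clash.any():
            raise ValueError(f"structure {name!r} overlaps an incompatible primitive")
        claimed |= m
        claimed_hu[m] = hu
        values[m] = hu
        masks.append(StructureMask(name=name, grid=grid, mask=m))

    if spec.texture_hu > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.standard_normal(grid.size)
        sigma_vox = spec.texture_sigma_mm / np.asarray(spec.spacing)
        tex = ndimage.gaussian_filter(noise, sigma_vox, mode="nearest")
        tex *= spec.texture_hu / max(tex.std(), 1e-12)
        values = values + tex * body
    return Image3D(grid=grid, values=values), masks


# ---------------------------------------------------------------------------
# Ground-truth deformation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DeformationSpec:
    """Magnitudes of the composed anatomy-change components.

    head_rotation_deg: axial head turn, blended in smoothly above the neck.
    flexion_deg_per_cm: progressive spine bend (rotation about x) per cm of
    height above the flexion pivot.
    shrink_fractions: per-structure volume-loss fraction (uniform scaling
    about the structure centre with a smooth falloff outside it).
    body_loss_fraction: global body-volume loss via uniform in-plane
    contraction toward the body axis (push scale sqrt(1 - f) per axis).
    """

    head_rotation_deg: float = 3.0
    head_pivot: tuple[float, float, float] = (0.0, 20.0, -10.0)
    head_blend_z0: float = 10.0
    head_blend_width: float = 10.0
    flexion_deg_per_cm: float = 0.3
    flexion_pivot: tuple[float, float, float] = (0.0, 20.0, -20.0)
    shrink_fractions: dict[str, float] = dc_field(
        default_factory=lambda: {
            "parotid_left": 0.15,
            "parotid_right": 0.15,
            "oral_cavity": 0.10,
        }
    )
    body_loss_fraction: float = 0.106
    min_jacobian: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.body_loss_fraction < 1.0:
            raise ValueError("body_loss_fraction must be in [0, 1)")


def _field_from_map(grid: VoxelGrid, mapped: np.ndarray) -> DisplacementField:
    return DisplacementField(
        grid=grid, vectors=mapped - grid.world_coords(), direction="push"
    )


def _head_rotation_field(spec: DeformationSpec, grid: VoxelGrid) -> DisplacementField:
    coords = grid.world_coords()
    th = np.deg2rad(spec.head_rotation_deg)
    c = np.asarray(spec.head_pivot)
    w = _sigmoid((coords[..., 2] - spec.head_blend_z0) / spec.head_blend_width)
    rel = coords - c
    rot = np.empty_like(rel)
    rot[..., 0] = np.cos(th) * rel[..., 0] - np.sin(th) * rel[..., 1]
    rot[..., 1] = np.sin(th) * rel[..., 0] + np.cos(th) * rel[..., 1]
    rot[..., 2] = rel[..., 2]
    return DisplacementField(
        grid=grid, vectors=w[..., None] * (rot - rel), direction="push"
    )


def _flexion_field(spec: DeformationSpec, grid: VoxelGrid) -> DisplacementField:
    coords = grid.world_coords()
    c = np.asarray(spec.flexion_pivot)
    height_cm = np.maximum(coords[..., 2] - c[2], 0.0) / 10.0
    a = np.deg2rad(spec.flexion_deg_per_cm) * height_cm
    rel_y = coords[..., 1] - c[1]
    rel_z = coords[..., 2] - c[2]
    vec = np.zeros_like(coords)
    vec[..., 1] = np.cos(a) * rel_y - np.sin(a) * rel_z - rel_y
    vec[..., 2] = np.sin(a) * rel_y + np.cos(a) * rel_z - rel_z
    return DisplacementField(grid=grid, vectors=vec, direction="push")


def _shrink_field(
    name: str, fraction: float, grid: VoxelGrid
) -> DisplacementField:
    kind, params, _hu = _STRUCTURES[name]
    if kind == "ellipsoid":
        center, semi = params
    else:
        cx, cy, r, zlo, zhi = params
        center = (cx, cy, 0.5 * (zlo + zhi))
        semi = (r, r, 0.5 * (zhi - zlo))
    coords = grid.world_coords()
    rel = coords - np.asarray(center)
    rtil = np.sqrt(((rel / np.asarray(semi)) ** 2).sum(axis=-1))
    # uniform scaling inside the structure (exact volume prediction), smooth
    # Gaussian falloff outside it
    k = 1.0 - (1.0 - fraction) ** (1.0 / 3.0)
    w = np.where(rtil <= 1.0, 1.0, np.exp(-((rtil - 1.0) ** 2) / (2 * 0.5**2)))
    return DisplacementField(
        grid=grid, vectors=-k * w[..., None] * rel, direction="push"
    )


def _body_loss_field(fraction: float, grid: VoxelGrid) -> DisplacementField:
    kxy = np.sqrt(1.0 - fraction)
    coords = grid.world_coords()
    vec = np.zeros_like(coords)
    vec[..., 0] = (kxy - 1.0) * coords[..., 0]
    vec[..., 1] = (kxy - 1.0) * coords[..., 1]
    return DisplacementField(grid=grid, vectors=vec, direction="push")


def build_gt_dvf(
    spec: DeformationSpec | None = None, grid: VoxelGrid | None = None
) -> DisplacementField:
    """Compose the ground-truth push field on ``grid``.

    Application order (innermost first): body contraction, organ shrinkage,
    spine flexion, head rotation.  Raises if the composite folds (Jacobian
    determinant below ``min_jacobian`` anywhere on the body).
    """
    spec = spec or DeformationSpec()
    grid = grid or PhantomSpec().grid()
    total = _body_loss_field(spec.body_loss_fraction, grid)
    for name, frac in sorted(spec.shrink_fractions.items()):
        if frac != 0.0:
            total = compose(_shrink_field(name, frac, grid), total)
    if spec.flexion_deg_per_cm != 0.0:
        total = compose(_flexion_field(spec, grid), total)
    if spec.head_rotation_deg != 0.0:
        total = compose(_head_rotation_field(spec, grid), total)

    coords = grid.world_coords()
    rx, ry = _body_radii(coords[..., 2])
    body = (coords[..., 0] / rx) ** 2 + (coords[..., 1] / ry) ** 2 <= 1.0
    jmin = float(jacobian_determinant(total)[body].min())
    if jmin <= spec.min_jacobian:
        raise ValueError(
            f"deformation folds on the body (min Jacobian {jmin:.3f} <= "
            f"{spec.min_jacobian}); reduce component magnitudes"
        )
    return total


@dataclass
class GroundTruthCase:
    """One synthetic case: sEOT image, ground-truth EOT masks, both field
    directions, and the inverse-consistency map of the pair."""

    seot: Image3D
    eot_masks: list[StructureMask]
    fwd: DisplacementField  # push, SOT -> EOT
    inv: DisplacementField  # pull on the EOT grid
    ice: ICEVolume
    max_displacement_mm: float


def apply_gt(
    sot: Image3D,
    masks: list[StructureMask],
    fwd: DisplacementField,
    inv_tol: float = 1e-4,
    inv_max_iter: int = 200,
) -> GroundTruthCase:
    """Generate the sEOT image and ground-truth EOT contours.

    The push field is numerically inverted (fixed point) to the pull field
    used for warping; image warped with linear interpolation and air fill,
    masks propagated with the 0.5-threshold convention.
    """
    if fwd.direction == "push":
        inv = invert_dvf(fwd, tol=inv_tol, max_iter=inv_max_iter)
    else:
        inv, fwd = fwd, invert_dvf(fwd, tol=inv_tol, max_iter=inv_max_iter)
    seot = warp_image(sot, inv, fill=AIR_HU)
    eot_masks = [propagate_mask(m, inv) for m in masks]
    ice = ice_map(fwd, inv)
    return GroundTruthCase(
        seot=seot,
        eot_masks=eot_masks,
        fwd=fwd,
        inv=inv,
        ice=ice,
        max_displacement_mm=float(fwd.magnitude().max()),
    )


# ---------------------------------------------------------------------------
# Marker phantom
# ---------------------------------------------------------------------------

_MARKER_OFFSETS = np.array(
    [[12.0, 4.0, -8.0], [-10.0, 9.0, 6.0], [3.0, -12.0, 10.0]]
)


def build_marker_phantom(
    translation_mm: tuple[float, float, float],
    grid: VoxelGrid | None = None,
    marker_diameter_mm: float = 2.0,
    marker_hu: float = 1200.0,
    edge_mm: float = 0.5,
) -> tuple[Image3D, Image3D]:
    """Translation phantom: three 2-mm spherical markers on a uniform
    background, noncoplanar with the grid centre, plus a copy translated by
    ``translation_mm``.

    Both volumes are rasterized analytically with an erf edge profile
    (band-limited, no aliasing), so intensity-weighted marker centroids sit
    at the analytic centres to well under the voxel size.
    """
    grid = grid or centered_grid((64, 64, 64), (1.0, 1.0, 1.0))
    t = np.asarray(translation_mm, dtype=float)
    center = np.mean(grid.extent(), axis=0)
    centers = center + _MARKER_OFFSETS
    if abs(np.linalg.det(_MARKER_OFFSETS)) < 1e-6:
        raise ValueError("markers are coplanar with the grid centre")
    lo, hi = grid.extent()
    r = marker_diameter_mm / 2.0
    for c in np.vstack([centers, centers + t]):
        if np.any(c - r < lo) or np.any(c + r > hi):
            raise ValueError(f"marker at {c} leaves the grid")

    coords = grid.world_coords()

    def paint(marker_centers: np.ndarray) -> np.ndarray:
        vals = np.zeros(grid.size)
        for c in marker_centers:
            d = np.linalg.norm(coords - c, axis=-1)
            vals += marker_hu * 0.5 * (1.0 + erf((r - d) / (edge_mm * np.sqrt(2))))
        return vals

    fixed = Image3D(grid=grid, values=paint(centers))
    moving = Image3D(grid=grid, values=paint(centers + t))
    return fixed, moving
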