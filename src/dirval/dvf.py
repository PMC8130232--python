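"""Displacement-field operations: warping, composition, fixed-point inversion,
inverse-consistency error (ICE), and the contour-level QC filter.

Direction contract: :func:`warp_image` and :func:`propagate_mask` require a
*pull* field (the field lives on the target grid and points to the sample
location in the moving image).  A push field must be inverted first with
:func:`invert_dvf`, which flips the tag.

ICE is defined per voxel of the forward field's grid as
``ice(x) = || inv(x + fwd(x)) + fwd(x) ||`` with linear interpolation of the
inverse field.  Voxels whose composed sample point leaves the grid are
excluded from the statistics (edge extrapolation would poison the mean) and
counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import (
    ContourSetQC,
    DisplacementField,
    GeometryError,
    Image3D,
    StructureMask,
    VoxelGrid,
)

__all__ = [
    "DirectionError",
    "ConvergenceError",
    "ICEVolume",
    "warp_image",
    "propagate_mask",
    "compose",
    "invert_dvf",
    "ice_map",
    "qc_filter",
    "jacobian_determinant",
]


class DirectionError(ValueError):
    """A field with the wrong pull/push tag was supplied."""


class ConvergenceError(RuntimeError):
    """Fixed-point DVF inversion failed to reach tolerance."""

    def __init__(self, msg: str, worst_residual_mm: float):
        super().__init__(msg)
        self.worst_residual_mm = worst_residual_mm


@dataclass(frozen=True)
class ICEVolume:
    """Per-voxel inverse-consistency residual magnitude in mm.

    ``valid`` marks voxels whose forward-mapped point stayed inside the grid;
    only those enter QC statistics.
    """

    grid: VoxelGrid
    ice: np.ndarray = field(repr=False)
    valid: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.ice.shape != self.grid.size or self.valid.shape != self.grid.size:
            raise GeometryError("ICE arrays must match the grid")
        if np.any(self.ice < 0):
            raise ValueError("ICE is a magnitude and cannot be negative")

    @property
    def n_out_of_domain(self) -> int:
        return int((~self.valid).sum())


def _sample_vectors(
    fld: DisplacementField, pts: np.ndarray, order: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a vector field at world points; returns (vectors, inside_mask)."""
    idx = fld.grid.world_to_index(pts)
    coords = np.moveaxis(idx, -1, 0)
    out = np.stack(
        [
            ndimage.map_coordinates(
                fld.vectors[..., c], coords, order=order, mode="nearest"
            )
            for c in range(3)
        ],
        axis=-1,
    )
    hi = np.asarray(fld.grid.size) - 1
    inside = np.all((idx >= 0) & (idx <= hi), axis=-1)
    return out, inside


def warp_image(
    moving: Image3D,
    fld: DisplacementField,
    interpolation: str = "linear",
    fill: float = 0.0,
) -> Image3D:
    """Warp ``moving`` onto the field's grid: out(x) = moving(x + u(x)).

    Requires a pull field; out-of-domain samples take ``fill``.
    """
    if fld.direction != "pull":
        raise DirectionError("warp_image needs a pull field; invert_dvf a push field first")
    pts = fld.grid.world_coords() + fld.vectors
    from .volumes import sample_at_world

    vals = sample_at_world(moving.values, moving.grid, pts, interpolation, fill)
    return Image3D(grid=fld.grid, values=vals)


def propagate_mask(
    mask: StructureMask,
    fld: DisplacementField,
    threshold: float = 0.5,
    interpolation: str = "linear",
) -> StructureMask:
    """Propagate a contour: warp the binary mask with linear interpolation and
    binarize at ``threshold`` (nearest-neighbour available for cross-checks)."""
    warped = warp_image(
        Image3D(grid=mask.grid, values=mask.mask.astype(float)),
        fld,
        interpolation=interpolation,
        fill=0.0,
    )
    out = warped.values > threshold if interpolation == "linear" else warped.values > 0.5
    return StructureMask(name=mask.name, grid=fld.grid, mask=out)


def warped_mask_volume_cc(mask: StructureMask, fld: DisplacementField) -> float:
    """Partial-volume estimate of a propagated structure's volume.

    Sums the linearly interpolated (fractional) warped indicator instead of
    binarizing it: sub-voxel boundary displacements, invisible to a
    thresholded mask, still change this volume estimate.
    """
    warped = warp_image(
        Image3D(grid=mask.grid, values=mask.mask.astype(float)), fld, fill=0.0
    )
    return float(warped.values.sum()) * fld.grid.voxel_volume_mm3 / 1000.0


def compose(f: DisplacementField, g: DisplacementField) -> DisplacementField:
    """Compose two fields: (f o g)(x) = g(x) + f(x + g(x)).

    Both fields must carry the same direction tag.  For pull fields the
    composite warps through g first then f when used with :func:`warp_image`
    semantics ``x -> x + g(x) -> x + g(x) + f(x + g(x))``.
    """
    if f.direction != g.direction:
        raise DirectionError("composed fields must share a direction tag")
    if not f.grid.same_geometry(g.grid, tol=1e-3):
        raise GeometryError("compose requires matching grids")
    pts = g.grid.world_coords() + g.vectors
    f_at, _ = _sample_vectors(f, pts)
    return DisplacementField(grid=g.grid, vectors=g.vectors + f_at, direction=f.direction)


def invert_dvf(
    fld: DisplacementField, tol: float = 1e-3, max_iter: int = 50
) -> DisplacementField:
    """Invert a displacement field by fixed-point iteration.

    Solves v(x) = -u(x + v(x)) starting from v0 = -u(x), stopping when the
    largest update falls below ``tol`` (mm).  Converges when the map is
    contractive (max |grad u| < 1 is the usual sufficient condition).  The
    direction tag is flipped.
    """
    x = fld.grid.world_coords()
    v = -fld.vectors.copy()
    worst = np.inf
    for _ in range(max_iter):
        u_at, _ = _sample_vectors(fld, x + v)
        v_new = -u_at
        worst = float(np.max(np.linalg.norm(v_new - v, axis=-1)))
        v = v_new
        if worst < tol:
            break
    else:
        raise ConvergenceError(
            f"DVF inversion did not reach {tol} mm in {max_iter} iterations "
            f"(worst residual {worst:.3g} mm)",
            worst_residual_mm=worst,
        )
    flipped = "push" if fld.direction == "pull" else "pull"
    return DisplacementField(grid=fld.grid, vectors=v, direction=flipped)


def ice_map(fwd: DisplacementField, inv: DisplacementField) -> ICEVolume:
    """Inverse-consistency error of a putative (forward, inverse) pair.

    ice(x) = ||inv(x + fwd(x)) + fwd(x)||; the two fields must carry opposite
    direction tags and share a grid.
    """
    if fwd.direction == inv.direction:
        raise DirectionError("ICE needs one field of each direction")
    if not fwd.grid.same_geometry(inv.grid, tol=1e-3):
        raise GeometryError("ICE requires matching grids")
    pts = fwd.grid.world_coords() + fwd.vectors
    inv_at, inside = _sample_vectors(inv, pts)
    residual = np.linalg.norm(inv_at + fwd.vectors, axis=-1)
    return ICEVolume(grid=fwd.grid, ice=residual, valid=inside)


def qc_filter(
    ice: ICEVolume,
    structures: list[StructureMask],
    contour_thresh: float = 0.2,
    case_thresh: float = 0.5,
) -> ContourSetQC:
    """Apply the contour-level inverse-consistency QC.

    A structure is excluded when its mean ICE exceeds ``contour_thresh``
    (0.2 mm); the whole case is excluded when every structure's mean ICE
    exceeds ``case_thresh`` (0.5 mm).  Empty masks are flagged per structure,
    never fatal for the case.
    """
    mean_ice: dict[str, float] = {}
    max_ice: dict[str, float] = {}
    accepted: dict[str, bool] = {}
    errors: dict[str, str] = {}
    for s in structures:
        if not s.grid.same_geometry(ice.grid, tol=1e-3):
            raise GeometryError(f"structure {s.name!r} is not on the ICE grid")
        sel = s.mask & ice.valid
        if not sel.any():
            mean_ice[s.name] = float("nan")
            max_ice[s.name] = float("nan")
            accepted[s.name] = False
            errors[s.name] = "empty mask (or fully out of domain)"
            continue
        vals = ice.ice[sel]
        mean_ice[s.name] = float(vals.mean())
        max_ice[s.name] = float(vals.max())
        accepted[s.name] = mean_ice[s.name] <= contour_thresh
    finite = [v for v in mean_ice.values() if np.isfinite(v)]
    case_accepted = bool(finite) and not all(v > case_thresh for v in finite)
    return ContourSetQC(
        mean_ice_mm=mean_ice,
        max_ice_mm=max_ice,
        accepted=accepted,
        case_accepted=case_accepted,
        errors=errors,
    )


def jacobian_determinant(fld: DisplacementField) -> np.ndarray:
    """Determinant of the Jacobian of the mapping x -> x + u(x), per voxel.

    Computed with central differences in world units; reported for QC only
    (no folding repair is attempted).
    """
    jac = np.empty(fld.grid.size + (3, 3))
    for c in range(3):
        for a in range(3):
            jac[..., c, a] = np.gradient(fld.vectors[..., c], fld.grid.spacing[a], axis=a)
        jac[..., c, c] += 1.0
    return np.linalg.det(jac)
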