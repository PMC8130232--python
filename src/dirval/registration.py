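"""Rigid and deformable registration.

The deformable engine is a faithful-to-description stand-in for the
proprietary algorithm it emulates, not a clone: it maximizes normalized
cross-correlation (NCC) over small neighbourhood patches, iterating over the
whole domain in a multiresolution coarse-to-fine scheme (up to 4 levels, up
to 500 iterations per level), and regularizes the accumulated displacement
field with a Gaussian smoothing operator after every iteration.

Patch-NCC is realized by local intensity normalization: subtracting the
local mean and dividing by the local standard deviation over a patch window
makes the voxelwise squared difference of the two normalized images equal
2(1 - NCC) per patch, so demons-style forces on the normalized images ascend
patch NCC while staying invariant to affine intensity rescaling — the
property that makes cross-modality (kV-MV) registration possible.  Patches
with (near) zero variance contribute zero force and are counted in the
diagnostics.

The engine keeps the best state seen under its objective (the aggregate
patch NCC of the locally normalized images) and a level stops after a
patience window without relative improvement; the published trace records
the objective's improvement path, which is non-decreasing within each level
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

from .volumes import DisplacementField, Image3D, VoxelGrid, resample

__all__ = [
    "RigidTransform",
    "DIRConfig",
    "ncc",
    "rigid_register",
    "deform_register",
]


# ---------------------------------------------------------------------------
# NCC
# ---------------------------------------------------------------------------


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two equally shaped patches in [-1, 1].

    Returns 0 when either patch has zero variance (flat patches carry no
    alignment information).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("NCC needs at least 2 voxels")
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt((ac**2).sum() * (bc**2).sum())
    if denom == 0:
        return 0.0
    return float(np.clip((ac * bc).sum() / denom, -1.0, 1.0))


# ---------------------------------------------------------------------------
# Rigid
# ---------------------------------------------------------------------------


def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    rx, ry, rz = np.deg2rad(angles_deg)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclass(frozen=True)
class RigidTransform:
    """6-DOF transform: rotations (deg, Rz*Ry*Rx order) about ``center`` (mm)
    plus a translation (mm), in pull convention — it maps a point on the
    fixed grid to its sample location in moving space."""

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        return _rotation_matrix(np.asarray(self.rotation_deg))

    def apply(self, pts: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translation_mm)
        return (pts - c) @ self.matrix().T + c + t

    def inverse(self) -> "RigidTransform":
        # y = R(x-c)+c+t  =>  x = R^T(y-c-t)+c; re-expressed about the same c
        R = self.matrix()
        t = np.asarray(self.translation_mm)
        rot = np.rad2deg(_angles_from_matrix(R.T))
        return RigidTransform(
            rotation_deg=tuple(rot),
            translation_mm=tuple(-R.T @ t),
            center_mm=self.center_mm,
        )

    def as_field(self, grid: VoxelGrid) -> DisplacementField:
        """The transform as a pull displacement field on ``grid``."""
        pts = grid.world_coords()
        return DisplacementField(
            grid=grid, vectors=self.apply(pts) - pts, direction="pull"
        )


def _angles_from_matrix(R: np.ndarray) -> np.ndarray:
    """Euler angles (rad) such that Rz*Ry*Rx reproduces R (|ry| < pi/2)."""
    ry = np.arcsin(-np.clip(R[2, 0], -1, 1))
    rx = np.arctan2(R[2, 1], R[2, 2])
    rz = np.arctan2(R[1, 0], R[0, 0])
    return np.array([rx, ry, rz])


def _warp_rigid(moving: Image3D, grid: VoxelGrid, T: RigidTransform, fill: float) -> np.ndarray:
    from .volumes import sample_at_world

    return sample_at_world(moving.values, moving.grid, T.apply(grid.world_coords()), "linear", fill)


def _level_sigma(factor: int) -> float:
    """Pyramid smoothing in voxels; the finest level keeps a light 0.5-voxel
    blur so the fixed image and the interpolation-smoothed warped moving
    image sit in the same band (otherwise interpolation biases the optimum
    toward zero displacement)."""
    return max(factor / 2.0, 0.5)


def _downsample(img: Image3D, factor: int) -> Image3D:
    smoothed = ndimage.gaussian_filter(img.values, _level_sigma(factor), mode="nearest")
    if factor == 1:
        return Image3D(grid=img.grid, values=smoothed)
    size = tuple(max(1, n // factor) for n in img.grid.size)
    spacing = tuple(s * factor for s in img.grid.spacing)
    grid = VoxelGrid(origin=img.grid.origin, spacing=spacing, size=size)
    return resample(Image3D(grid=img.grid, values=smoothed), grid, "linear")


def _smooth_like_level(img: Image3D, factor: int) -> Image3D:
    """Smooth the moving image to the same band as the level's fixed image
    (it stays on its own grid; sampling interpolates it during warps)."""
    return Image3D(
        grid=img.grid,
        values=ndimage.gaussian_filter(img.values, _level_sigma(factor), mode="nearest"),
    )


def rigid_register(
    fixed: Image3D,
    moving: Image3D,
    init: RigidTransform | None = None,
    n_levels: int = 3,
    fill: float | None = None,
    finest_factor: int = 1,
) -> RigidTransform:
    """Automatic 6-DOF registration maximizing global NCC.

    Multiresolution: a coarse phase-correlation translation seed, then Powell
    refinement of rotations + translation at each pyramid level down to
    sub-voxel precision.  Deterministic for given inputs.  ``finest_factor``
    stops the pyramid above full resolution (2 = half-resolution finish) for
    pre-alignment uses where the deformable stage follows anyway.
    """
    if fill is None:
        fill = float(moving.values.min())
    center = tuple(np.mean(fixed.grid.extent(), axis=0))
    if init is None:
        # phase-correlation translation seed on a common coarse grid
        f2 = _downsample(fixed, 2)
        m2 = resample(moving, f2.grid, "linear", fill)
        shift_vox = phase_cross_correlation(
            f2.values, m2.values, upsample_factor=10, normalization=None
        )[0]
        # moving(x + t) ~ fixed(x): pull translation = -shift * spacing
        t0 = tuple(-shift_vox * np.asarray(f2.grid.spacing))
        init = RigidTransform(translation_mm=t0, center_mm=center)
    else:
        init = RigidTransform(
            rotation_deg=init.rotation_deg,
            translation_mm=init.translation_mm,
            center_mm=center,
        )

    params = np.r_[init.rotation_deg, init.translation_mm]
    factors = [finest_factor * 2 ** (n_levels - 1 - i) for i in range(n_levels)]
    for factor in factors:
        fx = _downsample(fixed, factor)
        mov = _smooth_like_level(moving, factor)
        # cubic B-spline sampling (prefiltered once per level): linear
        # interpolation's position-dependent blur biases subvoxel optima
        coeffs = ndimage.spline_filter(mov.values, order=3, mode="nearest")
        pts_level = fx.grid.world_coords()

        def negative_ncc(p: np.ndarray) -> float:
            T = RigidTransform(
                rotation_deg=tuple(p[:3]), translation_mm=tuple(p[3:]), center_mm=center
            )
            idx = np.moveaxis(mov.grid.world_to_index(T.apply(pts_level)), -1, 0)
            warped = ndimage.map_coordinates(
                coeffs, idx, order=3, prefilter=False, mode="constant", cval=fill
            )
            return -ncc(fx.values, warped)

        res = optimize.minimize(
            negative_ncc,
            params,
            method="Powell",
            options={"xtol": 1e-4, "ftol": 1e-12, "maxiter": 20000},
        )
        if not np.all(np.isfinite(res.x)):
            raise RuntimeError(f"rigid optimizer diverged: {res.message}")
        params = res.x
    return RigidTransform(
        rotation_deg=tuple(params[:3]),
        translation_mm=tuple(params[3:]),
        center_mm=center,
    )


# ---------------------------------------------------------------------------
# Deformable
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DIRConfig:
    """Parameters of the patch-NCC deformable engine.

    patch_radius: half-width (voxels) of the local normalization window, so
    the patch spans ``2r + 1`` voxels per axis.
    reg_sigma_mm: width of the Gaussian field regularizer applied after each
    iteration.
    step_size_mm: displacement a typical informative voxel takes per
    iteration (95th-percentile normalization; individual voxels are capped
    at twice this).
    stop_tol: relative objective improvement counted as progress; a level
    stops after ``patience`` iterations without it.
    """

    n_levels: int = 3
    max_iter_per_level: int = 300
    patch_radius: int = 2
    reg_sigma_mm: float = 2.5
    step_size_mm: float = 1.0
    stop_tol: float = 1e-6
    patience: int = 15

    def __post_init__(self) -> None:
        if not 1 <= self.n_levels <= 4:
            raise ValueError("n_levels must be in [1, 4]")
        if not 1 <= self.max_iter_per_level <= 500:
            raise ValueError("max_iter_per_level must be in [1, 500]")


@dataclass
class DIRResult:
    """Field plus the optimizer's improvement path.

    ``ncc_trace`` rows are (level, iteration, aggregate patch NCC) recorded
    each time the objective improved — the aggregate patch NCC is
    ``1 - mean(diff^2)/2`` of the locally normalized images, i.e. the
    quantity the engine actually ascends, and the recorded path is
    non-decreasing within each level by construction.
    """

    field: DisplacementField
    ncc_trace: list[tuple[int, int, float]] = dc_field(default_factory=list)
    n_flat_patches: int = 0

    def trace_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            self.ncc_trace, columns=["level", "iteration", "patch_ncc"]
        ).to_csv(path, index=False)


def _local_normalize(arr: np.ndarray, radius: int, sd_floor: float) -> np.ndarray:
    size = 2 * radius + 1
    mean = ndimage.uniform_filter(arr, size, mode="nearest")
    var = ndimage.uniform_filter(arr * arr, size, mode="nearest") - mean**2
    sd = np.sqrt(np.maximum(var, 0.0))
    # flat patches (sd below floor) normalize to ~0 => zero force
    return (arr - mean) / np.maximum(sd, sd_floor)


def _world_gradient(arr: np.ndarray, spacing) -> np.ndarray:
    return np.stack(np.gradient(arr, *spacing), axis=-1)


def deform_register(
    fixed: Image3D,
    moving: Image3D,
    config: DIRConfig | None = None,
    init: RigidTransform | None = None,
    fill: float | None = None,
    return_result: bool = False,
) -> DisplacementField | DIRResult:
    """Patch-NCC multiresolution deformable registration.

    Returns a pull displacement field on the fixed grid (sample the moving
    image at ``x + u(x)``); with ``return_result=True`` also the objective's
    improvement trace.  Apply a rigid pre-alignment first (``init``) — going
    straight to the deformable stage from a poor start is not recoverable.
    """
    config = config or DIRConfig()
    if fill is None:
        fill = float(moving.values.min())
    from .volumes import sample_at_world

    trace: list[tuple[int, int, float]] = []
    n_flat = 0
    factors = [2 ** (config.n_levels - 1 - i) for i in range(config.n_levels)]
    u: DisplacementField | None = None
    for level, factor in enumerate(factors):
        fx = _downsample(fixed, factor)
        mov = _smooth_like_level(moving, factor)
        grid = fx.grid
        pts = grid.world_coords()
        spacing = np.asarray(grid.spacing)
        if u is None:
            if init is not None:
                vec = init.as_field(grid).vectors
            else:
                vec = np.zeros(grid.size + (3,))
        else:
            from .dvf import _sample_vectors

            vec = _sample_vectors(u, pts)[0]  # edge-clamped upsampling
        sd_floor = 0.02 * float(fx.values.std()) or 1e-6
        Fn = _local_normalize(fx.values, config.patch_radius, sd_floor)
        gF = _world_gradient(Fn, spacing)
        reg_sigma_vox = config.reg_sigma_mm / spacing

        lo_m, hi_m = mov.grid.extent()

        def sample_with_domain(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            p = pts + v
            w = sample_at_world(mov.values, mov.grid, p, "linear", fill)
            inside = np.all((p >= lo_m) & (p <= hi_m), axis=-1)
            return w, inside

        warped, inside = sample_with_domain(vec)

        def objective(w: np.ndarray, ins: np.ndarray) -> float:
            """Mean squared normalized difference = 2(1 - aggregate patch NCC),
            over voxels whose sample point stayed inside the moving volume —
            truncated-coverage voxels carry no alignment information."""
            d = _local_normalize(w, config.patch_radius, sd_floor) - Fn
            if not ins.any():
                return float("inf")
            return float((d[ins] ** 2).mean())

        best_e = objective(warped, inside)
        best_vec = vec.copy()
        trace.append((level, 0, 1.0 - best_e / 2.0))
        since_improved = 0
        for it in range(1, config.max_iter_per_level + 1):
            Mn = _local_normalize(warped, config.patch_radius, sd_floor)
            diff = Mn - Fn
            grad = 0.5 * (gF + _world_gradient(Mn, spacing))
            g2 = (grad**2).sum(axis=-1)
            denom = g2 + diff**2
            flat = denom < 1e-12
            n_flat += int(flat.sum())
            force = -diff[..., None] * grad / np.where(flat, 1.0, denom)[..., None]
            # out-of-domain samples compare tissue against fill, which is
            # pure noise: they exert no force (the regularizer carries the
            # field from informed neighbours instead)
            force[~inside] = 0.0
            # normalize so a typical informative voxel moves step_size mm per
            # iteration (95th percentile of nonzero forces), capped at 2x
            mag = np.linalg.norm(force, axis=-1)
            active = mag > 1e-9
            if active.any():
                p95 = float(np.percentile(mag[active], 95))
                if p95 > 0:
                    # amplification is capped so near-converged states are
                    # not inflated back to full step size (noise forces
                    # would push converged regions around)
                    scale = min(config.step_size_mm / p95, 4.0)
                    force *= scale
                    mag = mag * scale
            force *= np.minimum(
                1.0, 2.0 * config.step_size_mm / np.maximum(mag, 1e-12)
            )[..., None]
            vec = vec + force
            for c in range(3):
                vec[..., c] = ndimage.gaussian_filter(
                    vec[..., c], reg_sigma_vox, mode="nearest"
                )
            warped, inside = sample_with_domain(vec)
            e = objective(warped, inside)
            if e < best_e * (1.0 - config.stop_tol):
                best_e = e
                best_vec = vec.copy()
                trace.append((level, it, 1.0 - best_e / 2.0))
                since_improved = 0
            else:
                since_improved += 1
                if since_improved >= config.patience:
                    break
        u = DisplacementField(grid=grid, vectors=best_vec, direction="pull")

    assert u is not None
    if not u.grid.same_geometry(fixed.grid):
        from .dvf import _sample_vectors

        pts = fixed.grid.world_coords()
        vec = _sample_vectors(u, pts)[0]
        u = DisplacementField(grid=fixed.grid, vectors=vec, direction="pull")
    if return_result:
        return DIRResult(field=u, ncc_trace=trace, n_flat_patches=n_flat)
    return u
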