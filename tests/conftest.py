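import numpy as np
import pytest

from dirval.volumes import Image3D, StructureMask, VoxelGrid


@pytest.fixture
def grid8() -> VoxelGrid:
    return VoxelGrid(origin=(0.0, 0.0, 0.0), spacing=(1.0, 1.0, 1.0), size=(8, 8, 8))


@pytest.fixture
def aniso_grid() -> VoxelGrid:
    """Clinical-style anisotropic grid (thick slices along z)."""
    return VoxelGrid(origin=(-10.0, -10.0, -15.0), spacing=(1.0, 1.0, 3.0), size=(21, 21, 11))


def make_sphere_mask(grid: VoxelGrid, center, radius_mm: float, name: str = "sphere") -> StructureMask:
    d = np.linalg.norm(grid.world_coords() - np.asarray(center, dtype=float), axis=-1)
    return StructureMask(name=name, grid=grid, mask=d <= radius_mm)


def make_ramp_image(grid: VoxelGrid, direction=(1.0, 0.0, 0.0), offset: float = 0.0) -> Image3D:
    vals = grid.world_coords() @ np.asarray(direction, dtype=float) + offset
    return Image3D(grid=grid, values=vals)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------


def oracle_surface_indices(mask: np.ndarray) -> np.ndarray:
    """Exhaustive six-neighbour check; grid edge counts as background."""
    out = []
    nx, ny, nz = mask.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not mask[i, j, k]:
                    continue
                boundary = False
                for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    ii, jj, kk = i + di, j + dj, k + dk
                    if not (0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz) or not mask[ii, jj, kk]:
                        boundary = True
                        break
                if boundary:
                    out.append((i, j, k))
    return np.asarray(out, dtype=float)


def oracle_mda(a: StructureMask, b: StructureMask) -> float:
    """All-pairs nearest-neighbour symmetric mean surface distance."""
    pa = a.grid.index_to_world(oracle_surface_indices(a.mask))
    pb = b.grid.index_to_world(oracle_surface_indices(b.mask))
    d_ab = np.array([np.min(np.linalg.norm(pb - p, axis=1)) for p in pa])
    d_ba = np.array([np.min(np.linalg.norm(pa - p, axis=1)) for p in pb])
    return float((d_ab.mean() + d_ba.mean()) / 2.0)


def oracle_dsc(a: StructureMask, b: StructureMask) -> float:
    inter = 0
    na = nb = 0
    for va, vb in zip(a.mask.ravel(), b.mask.ravel()):
        na += bool(va)
        nb += bool(vb)
        inter += bool(va) and bool(vb)
    if na + nb == 0:
        return 1.0
    return 2.0 * inter / (na + nb)


def oracle_wilcoxon_exact(x, y) -> float:
    """Two-sided signed-rank p by brute force over all sign assignments."""
    from itertools import product

    from scipy.stats import rankdata

    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in product((0, 1), repeat=n):
        ws.append(sum(r for s, r in zip(signs, ranks) if s))
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))
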