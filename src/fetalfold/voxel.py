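"""Binary voxel grids: mesh voxelisation and Euclidean-ball morphology.

The closing operation underlying the gyrification index uses the exact
Euclidean distance transform, which is equivalent to dilation/erosion with
the discrete Euclidean ball (the set of voxel offsets whose centre distance
is at most the radius) but runs in linear time in the number of voxels.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .mesh import TriMesh

__all__ = ["VoxelGrid", "voxelize", "morphological_closing", "ball_footprint"]


@dataclasses.dataclass
class VoxelGrid:
    """Binary occupancy on a regular isotropic grid.

    ``origin`` is the world coordinate (mm) of the centre of voxel
    (0, 0, 0); ``spacing`` is the edge length of a voxel in mm.
    """

    occupancy: np.ndarray  # bool, 3D
    spacing: float
    origin: np.ndarray  # (3,) mm

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        self.origin = np.asarray(self.origin, dtype=np.float64).ravel()
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be 3D")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Nearest voxel index for world points (no bounds check)."""
        return np.round((np.asarray(points) - self.origin) / self.spacing).astype(int)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, dtype=float) * self.spacing + self.origin

    def occupied_volume(self) -> float:
        """Total occupied volume, mm³."""
        return float(self.occupancy.sum()) * self.spacing**3

    def border_margin(self) -> int:
        """Smallest number of empty voxel layers between occupancy and the
        array border."""
        occ = self.occupancy
        if not occ.any():
            return min(occ.shape)
        idx = np.argwhere(occ)
        lo = idx.min(axis=0)
        hi = np.array(occ.shape) - 1 - idx.max(axis=0)
        return int(min(lo.min(), hi.min()))


def ball_footprint(radius_mm: float, spacing: float) -> np.ndarray:
    """Discrete Euclidean ball: offsets with ||offset|| * spacing <= radius."""
    r = int(np.floor(radius_mm / spacing + 1e-9))
    ax = np.arange(-r, r + 1)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    return (X**2 + Y**2 + Z**2) * spacing**2 <= radius_mm**2 + 1e-9


def voxelize(
    mesh: TriMesh,
    spacing: float,
    pad_mm: float = 9.0,
    origin: np.ndarray | None = None,
    shape: tuple[int, int, int] | None = None,
) -> VoxelGrid:
    """Occupy every voxel whose centre lies inside the closed mesh.

    Inside/outside is decided by ray-crossing parity along the z axis,
    evaluated exactly against the mesh triangles.  The grid is padded by
    ``pad_mm`` on every side so that a subsequent closing with a kernel of
    radius <= pad_mm - spacing cannot touch the border.  Passing ``origin``
    and ``shape`` rasterises onto an existing grid frame instead (used to
    voxelise a hull onto its brain's grid).
    """
    if not mesh.closed:
        raise ValueError("voxelize requires a closed mesh")
    lo, hi = mesh.bounds()
    if origin is None:
        npad = int(np.ceil(pad_mm / spacing)) + 1
        origin = lo - npad * spacing
        shape = tuple(np.ceil((hi - origin) / spacing).astype(int) + npad + 1)
    else:
        origin = np.asarray(origin, dtype=float)
        if shape is None:
            raise ValueError("shape is required when origin is given")
    # parity rays are offset from voxel centres by an irrational-ish fraction
    # of a voxel so they never pass through mesh vertices or edges, including
    # marching-cubes meshes whose vertices lie exactly on grid planes
    delta = 0.0137 * spacing

    nx, ny, nz = shape
    toggle = np.zeros(shape, dtype=np.int64)
    v, f = mesh.vertices, mesh.faces
    # metrologically-negligible deterministic jitter removes exact ray/edge
    # coincidences (marching-cubes meshes have vertices on grid planes, where
    # adjacent triangles would otherwise double-count a shared-edge crossing)
    rng = np.random.default_rng(7)
    v = v + (rng.random(v.shape) - 0.5) * (2e-7 * spacing)
    tv = v[f]  # (m, 3, 3)
    t0, t1, t2 = tv[:, 0], tv[:, 1], tv[:, 2]
    # candidate columns per face: the xy bounding box, enumerated flat so the
    # barycentric crossing test runs vectorised over every (face, column) pair
    xy_min = np.minimum(np.minimum(t0[:, :2], t1[:, :2]), t2[:, :2])
    xy_max = np.maximum(np.maximum(t0[:, :2], t1[:, :2]), t2[:, :2])
    i0 = np.maximum(np.ceil((xy_min[:, 0] - origin[0] - delta) / spacing), 0).astype(int)
    i1 = np.minimum(np.floor((xy_max[:, 0] - origin[0] - delta) / spacing), nx - 1).astype(int)
    j0 = np.maximum(np.ceil((xy_min[:, 1] - origin[1] - delta) / spacing), 0).astype(int)
    j1 = np.minimum(np.floor((xy_max[:, 1] - origin[1] - delta) / spacing), ny - 1).astype(int)
    wi = np.maximum(i1 - i0 + 1, 0)
    wj = np.maximum(j1 - j0 + 1, 0)
    ncand = wi * wj
    keep = ncand > 0
    t0, t1, t2 = t0[keep], t1[keep], t2[keep]
    i0, j0, wi, wj, ncand = i0[keep], j0[keep], wi[keep], wj[keep], ncand[keep]
    if len(ncand):
        face = np.repeat(np.arange(len(ncand)), ncand)
        start = np.concatenate([[0], np.cumsum(ncand)[:-1]])
        offset = np.arange(int(ncand.sum())) - start[face]
        di = offset // wj[face]
        dj = offset - di * wj[face]
        X = origin[0] + delta + spacing * (i0[face] + di)
        Y = origin[1] + delta + spacing * (j0[face] + dj)
        a0, a1_, a2 = t0[face], t1[face], t2[face]
        d = (a1_[:, 0] - a0[:, 0]) * (a2[:, 1] - a0[:, 1]) - (
            a2[:, 0] - a0[:, 0]
        ) * (a1_[:, 1] - a0[:, 1])
        with np.errstate(divide="ignore", invalid="ignore"):
            wa = ((a1_[:, 0] - X) * (a2[:, 1] - Y) - (a2[:, 0] - X) * (a1_[:, 1] - Y)) / d
            wb = ((a2[:, 0] - X) * (a0[:, 1] - Y) - (a0[:, 0] - X) * (a2[:, 1] - Y)) / d
        wc = 1.0 - wa - wb
        # half-open rule keeps shared-edge crossings counted once; triangles
        # vertical in z (d ~ 0) are zero-measure for the offset rays
        inside = (
            ((wa >= 0) & (wb >= 0) & (wc > 0) | (wa > 0) & (wb > 0) & (wc >= 0))
            & (np.abs(d) > 1e-300)
        )
        zhit = wa * a0[:, 2] + wb * a1_[:, 2] + wc * a2[:, 2]
        # the -1e-5 (larger than the vertex jitter in index units) makes exact
        # surface/centre-plane ties resolve consistently, so grid-aligned
        # faces (e.g. an axis-aligned box) land wholly on one side
        kk = np.ceil((zhit[inside] - origin[2]) / spacing - 1e-5).astype(int)
        ok = (kk >= 0) & (kk < nz)
        ii = (i0[face] + di)[inside][ok]
        jj = (j0[face] + dj)[inside][ok]
        np.add.at(toggle, (ii, jj, kk[ok]), 1)
    # centre k is inside iff an odd number of crossings lie strictly above it:
    # exclusive suffix sum of the crossing toggles
    cs = np.cumsum(toggle[:, :, ::-1], axis=2)[:, :, ::-1]
    occ = ((cs - toggle) % 2).astype(bool)
    return VoxelGrid(occ, spacing, origin)


def morphological_closing(grid: VoxelGrid, diameter: float = 15.0) -> VoxelGrid:
    """Binary closing with a Euclidean ball of the given diameter (mm).

    Extensive (output contains input) and idempotent.  Raises if the grid
    padding is smaller than the kernel radius, rather than silently
    truncating the dilation at the border.
    """
    radius = diameter / 2.0
    r_vox = int(np.floor(radius / grid.spacing + 1e-9))
    if grid.border_margin() < r_vox + 1:
        raise ValueError(
            f"insufficient padding for closing: margin {grid.border_margin()} "
            f"voxels < kernel radius {r_vox} + 1"
        )
    occ = grid.occupancy
    # dilation: voxels within `radius` of an occupied centre
    d_to_occ = ndimage.distance_transform_edt(~occ, sampling=grid.spacing)
    dilated = d_to_occ <= radius + 1e-9
    # erosion of the dilated set
    d_to_bg = ndimage.distance_transform_edt(dilated, sampling=grid.spacing)
    closed = d_to_bg > radius + 1e-9
    closed |= occ  # guard against isolated voxels thinner than the kernel
    return VoxelGrid(closed, grid.spacing, grid.origin.copy())
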