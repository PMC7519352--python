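"""Voxelized optical media, fluorophore maps, and digital-phantom constructors.

Coordinate conventions used throughout the package:

* z = 0 is the tissue surface; z increases into the medium.
* x is the stage-scan direction (the sample moves perpendicular to the
  illumination line), y runs along the illumination line.
* Voxels are isotropic cubes of edge ``voxel_size`` (mm).  Voxel ``i`` spans
  the half-open interval ``[i * voxel_size, (i + 1) * voxel_size)`` and its
  center sits at ``(i + 0.5) * voxel_size``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Refractive index of the ambient medium above the surface (air).
AMBIENT_INDEX = 1.0


@dataclass(frozen=True)
class VoxelGrid:
    """Regular isotropic voxel grid with z = 0 at the tissue surface."""

    nx: int
    ny: int
    nz: int
    voxel_size: float  # mm, isotropic

    def __post_init__(self) -> None:
        for name in ("nx", "ny", "nz"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if not (self.voxel_size > 0):
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical extent (mm) along x, y, z."""
        h = self.voxel_size
        return (self.nx * h, self.ny * h, self.nz * h)

    @property
    def voxel_volume(self) -> float:
        return self.voxel_size**3

    @property
    def x_centers(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.voxel_size

    @property
    def y_centers(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.voxel_size

    @property
    def z_centers(self) -> np.ndarray:
        return (np.arange(self.nz) + 0.5) * self.voxel_size


def _as_field(grid: VoxelGrid, value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=np.float64)
    if arr.ndim == 0:
        arr = np.full(grid.shape, float(arr))
    if arr.shape != grid.shape:
        raise ValueError(f"{name} has shape {arr.shape}, expected {grid.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class OpticalMedium:
    """Per-voxel absorption / scattering / anisotropy / refractive index.

    ``mua`` and ``mus`` are in mm^-1; ``g`` is the Henyey-Greenstein
    anisotropy; ``n`` the refractive index.  ``exterior`` marks voxels above a
    curved surface (no interaction, ambient index); it is None for plain
    slabs.
    """

    grid: VoxelGrid
    mua: np.ndarray
    mus: np.ndarray
    g: np.ndarray
    n: np.ndarray
    exterior: np.ndarray | None = None
    allow_zero_scatter: bool = False

    def __post_init__(self) -> None:
        self.mua = _as_field(self.grid, self.mua, "mua")
        self.mus = _as_field(self.grid, self.mus, "mus")
        self.g = _as_field(self.grid, self.g, "g")
        self.n = _as_field(self.grid, self.n, "n")
        if np.any(self.mua < 0):
            raise ValueError("mua must be >= 0 everywhere")
        interior = np.ones(self.grid.shape, dtype=bool)
        if self.exterior is not None:
            ext = np.asarray(self.exterior, dtype=bool)
            if ext.shape != self.grid.shape:
                raise ValueError("exterior mask shape mismatch")
            self.exterior = ext
            interior = ~ext
        if np.any(self.mus[interior] < 0):
            raise ValueError("mus must be >= 0")
        if not self.allow_zero_scatter and np.any(self.mus[interior] <= 0):
            raise ValueError(
                "mus must be > 0 wherever photons propagate "
                "(pass allow_zero_scatter=True for analytic-limit tests)"
            )
        if np.any(np.abs(self.g) >= 1):
            raise ValueError("g must satisfy -1 < g < 1")
        if np.any(self.n[interior] < 1):
            raise ValueError("n must be >= 1")

    @property
    def is_homogeneous(self) -> bool:
        if self.exterior is not None and self.exterior.any():
            return False
        return all(
            np.ptp(a) == 0 for a in (self.mua, self.mus, self.g, self.n)
        )

    def homogeneous_values(self) -> tuple[float, float, float, float]:
        if not self.is_homogeneous:
            raise ValueError("medium is not homogeneous")
        return (
            float(self.mua.flat[0]),
            float(self.mus.flat[0]),
            float(self.g.flat[0]),
            float(self.n.flat[0]),
        )


@dataclass
class FluorophoreMap:
    """Per-voxel nonnegative fluorescence yield O(r') on the medium grid."""

    grid: VoxelGrid
    yield_: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.yield_ = _as_field(self.grid, self.yield_, "yield")
        if np.any(self.yield_ < 0):
            raise ValueError("fluorophore yield must be >= 0 everywhere")

    @classmethod
    def empty(cls, grid: VoxelGrid) -> "FluorophoreMap":
        return cls(grid, np.zeros(grid.shape))

    def total_yield(self) -> float:
        """Integrated yield (yield units x mm^3)."""
        return float(self.yield_.sum()) * self.grid.voxel_volume


def make_homogeneous_medium(
    grid: VoxelGrid,
    mua: float,
    mus: float,
    g: float,
    n: float,
    allow_zero_scatter: bool = False,
) -> OpticalMedium:
    """Uniform slab, e.g. the intralipid phantom (mua=0.01, mus=15, g=0.9, n=1.33)."""
    if mua < 0:
        raise ValueError(f"mua must be >= 0, got {mua}")
    if mus < 0 or (mus == 0 and not allow_zero_scatter):
        raise ValueError(f"mus must be > 0, got {mus}")
    if not (-1 < g < 1):
        raise ValueError(f"g must be in (-1, 1), got {g}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return OpticalMedium(
        grid,
        np.full(grid.shape, float(mua)),
        np.full(grid.shape, float(mus)),
        np.full(grid.shape, float(g)),
        np.full(grid.shape, float(n)),
        allow_zero_scatter=allow_zero_scatter,
    )


def capillary_axis_depth(x_mm, entry_x: float, tilt_deg: float):
    """Depth (mm) of the capillary axis at scan position x (vectorized).

    The axis is a straight line in the x-z plane entering the surface at
    ``entry_x`` and descending at ``tilt_deg`` toward +x.
    """
    return (np.asarray(x_mm, dtype=float) - entry_x) * math.tan(
        math.radians(tilt_deg)
    )


def embed_capillary(
    fmap: FluorophoreMap,
    inner_diameter: float,
    tilt_deg: float,
    entry: tuple[float, float],
    value: float,
    outer_diameter: float | None = None,
) -> FluorophoreMap:
    """Insert a straight fluorophore-filled capillary into a map.

    The axis lies in the x-z plane at y = entry[1], entering the surface at
    x = entry[0] and descending at ``tilt_deg`` (degrees from the surface)
    toward +x.  Every voxel whose center lies within ``inner_diameter / 2``
    of the axis is set to ``value``; the glass wall is not modeled
    (``outer_diameter`` is recorded in metadata only).
    """
    if inner_diameter <= 0:
        raise ValueError(f"inner_diameter must be > 0, got {inner_diameter}")
    if not (0 < tilt_deg < 90):
        raise ValueError(f"tilt_deg must be in (0, 90), got {tilt_deg}")
    grid = fmap.grid
    x0, y0 = entry
    ex, ey, _ = grid.extent
    if not (0 <= x0 < ex and 0 <= y0 < ey):
        raise ValueError("capillary entry point outside the grid footprint")
    theta = math.radians(tilt_deg)
    # axis direction (unit): descends toward +x
    ux, uz = math.cos(theta), math.sin(theta)
    # reject axes that never cross the grid volume
    z_at_x0, z_at_x1 = capillary_axis_depth([0.0, ex], x0, tilt_deg)
    if max(z_at_x0, z_at_x1) < -inner_diameter or min(z_at_x0, z_at_x1) > grid.extent[2] + inner_diameter:
        raise ValueError("capillary axis entirely outside the grid")

    xs = grid.x_centers[:, None, None]
    ys = grid.y_centers[None, :, None]
    zs = grid.z_centers[None, None, :]
    # vector from axis point (x0, y0, 0) to voxel center, minus axial component
    dx = xs - x0
    dy = ys - y0
    dz = zs
    t = dx * ux + dz * uz
    px = dx - t * ux
    pz = dz - t * uz
    dist2 = px**2 + dy**2 + pz**2
    mask = dist2 <= (inner_diameter / 2) ** 2
    new = fmap.yield_.copy()
    new[mask] = value
    meta = dict(fmap.meta)
    meta["capillary"] = {
        "inner_diameter_mm": inner_diameter,
        "outer_diameter_mm": outer_diameter,
        "tilt_deg": tilt_deg,
        "entry_x_mm": x0,
        "entry_y_mm": y0,
        "value": value,
    }
    return FluorophoreMap(grid, new, meta)


def brain_like_medium(
    grid: VoxelGrid,
    mua: float,
    mus: float,
    g: float,
    n: float,
    surface_height: np.ndarray | None = None,
) -> OpticalMedium:
    """Uniform brain-analog slab, optionally with a curved surface.

    ``surface_height[x, y]`` gives the depth (mm, >= 0) at which the tissue
    surface sits below the z = 0 plane; voxels above it are exterior (no
    scattering or absorption, ambient index).  A flat (zero) height field
    reproduces :func:`make_homogeneous_medium` exactly.
    """
    med = make_homogeneous_medium(grid, mua, mus, g, n)
    if surface_height is None:
        return med
    hfield = np.asarray(surface_height, dtype=float)
    if hfield.shape != (grid.nx, grid.ny):
        raise ValueError(
            f"surface_height has shape {hfield.shape}, expected {(grid.nx, grid.ny)}"
        )
    exterior = grid.z_centers[None, None, :] < hfield[:, :, None]
    if not exterior.any():
        return med
    mua_f = med.mua
    mus_f = med.mus
    n_f = med.n
    mua_f[exterior] = 0.0
    mus_f[exterior] = 0.0
    n_f[exterior] = AMBIENT_INDEX
    return OpticalMedium(
        grid, mua_f, mus_f, med.g, n_f, exterior=exterior, allow_zero_scatter=True
    )
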