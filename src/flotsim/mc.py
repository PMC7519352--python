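"""Monte Carlo photon transport: excitation fluence and emission Green's functions.

The forward physics of the tomographic model is the first-order Born
integral: the signal at detector position ``r_d`` for a source at ``r_s``
is the voxel sum of ``G(r_d - r') * O(r') * Phi(r' - r_s)``, where ``Phi``
is the excitation fluence and ``G`` the escape (detection) probability
density.  Both fields are computed here by voxel Monte Carlo; ``G`` is
obtained by reciprocity, launching adjoint photons from the detector pixel
with cosine-weighted directions restricted to the escape cone and weighted
by the Fresnel transmission of the reversed ray.

Excitation (690 nm) and emission (~700-735 nm) share one set of optical
properties (single-wavelength optics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .medium import AMBIENT_INDEX, OpticalMedium, VoxelGrid


@dataclass(frozen=True)
class SourceSpec:
    """Illumination geometry.

    ``incidence_deg`` is the angle between the beam and the surface plane
    (135 deg means 45 deg from the surface normal, tilting the refracted
    beam toward +x).  ``line_fwhm`` is the Gaussian full width at half
    maximum of the line profile across the line (the x direction), in mm.
    """

    kind: str = "line"  # "pencil" | "line"
    position: tuple[float, float] = (0.0, 0.0)  # (x, y) mm on the surface
    incidence_deg: float = 135.0
    line_fwhm: float = 0.02
    wavelength_nm: float = 690.0  # metadata only

    def __post_init__(self) -> None:
        if self.kind not in ("pencil", "line"):
            raise ValueError(f"unknown source kind {self.kind!r}")
        if not (self.line_fwhm > 0):
            raise ValueError("line FWHM must be > 0")
        if not (90.0 < self.incidence_deg < 180.0):
            raise ValueError("incidence angle must be in (90, 180) degrees")

    @property
    def sigma_x(self) -> float:
        """Gaussian sigma of the beam profile on the surface (mm)."""
        return self.line_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    @property
    def air_direction(self) -> tuple[float, float, float]:
        """Unit propagation direction on the air side (az > 0 into tissue)."""
        theta = math.radians(self.incidence_deg - 90.0)  # from the normal
        return (math.sin(theta), 0.0, math.cos(theta))


@dataclass(frozen=True)
class DetectorSpec:
    """A surface camera pixel: position and (metadata) footprint.

    The camera is normal to the surface; acceptance is cosine-weighted over
    the escape cone (collection NA unspecified by the acquisition geometry).
    """

    position: tuple[float, float]  # (x, y) mm
    footprint_mm: float = 0.0029


@dataclass
class FluenceField:
    """Excitation fluence per launched photon (mm^-2), grid-shaped."""

    grid: VoxelGrid
    phi: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.phi.shape != self.grid.shape:
            raise ValueError("fluence shape does not match grid")
        if not np.all(np.isfinite(self.phi)) or np.any(self.phi < 0):
            raise ValueError("fluence must be nonnegative and finite")


@dataclass
class GreenField:
    """Escape probability density from each voxel to one detector pixel."""

    grid: VoxelGrid
    green: np.ndarray
    detector: DetectorSpec | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.green.shape != self.grid.shape:
            raise ValueError("green field shape does not match grid")
        if not np.all(np.isfinite(self.green)) or np.any(self.green < 0):
            raise ValueError("green field must be nonnegative and finite")


def _check_medium(medium: OpticalMedium, n_photons: int) -> None:
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    mt = medium.mua + medium.mus
    if not np.any(mt > 0):
        raise ValueError("medium has zero mu_t everywhere; photons never interact")


def _tally_meta(tal: np.ndarray, n_photons: int, seed: int) -> dict:
    return {
        "n_photons": int(n_photons),
        "seed": int(seed),
        "absorbed": float(tal[K.T_ABSORBED]),
        "escaped_top": float(tal[K.T_ESCAPED]),
        "terminated": float(tal[K.T_TERMINATED]),
        "specular": float(tal[K.T_SPECULAR]),
        "rr_killed": float(tal[K.T_RR_KILLED]),
        "rr_gain": float(tal[K.T_RR_GAIN]),
        "energy_balance_error": float(K.energy_balance_error(tal)),
    }


def simulate_fluence(
    medium: OpticalMedium,
    source: SourceSpec,
    n_photons: int,
    seed: int,
) -> FluenceField:
    """Excitation fluence of a pencil (or single-point line) source.

    Accumulates sum(weight x path) / (n_photons x voxel volume) per voxel.
    """
    _check_medium(medium, n_photons)
    grid = medium.grid
    ax, ay, az = source.air_direction
    x0, y0 = source.position
    fl, _, tal = K.mc_voxel(
        medium.mua,
        medium.mus,
        medium.g,
        medium.n,
        grid.voxel_size,
        AMBIENT_INDEX,
        K.MODE_PENCIL,
        x0,
        y0,
        source.sigma_x if source.kind == "pencil" else 0.0,
        ax,
        ay,
        az,
        0.0,
        0.0,
        0.0,
        int(n_photons),
        int(seed),
    )
    phi = fl / (n_photons * grid.voxel_volume)
    meta = _tally_meta(tal, n_photons, seed)
    meta["disabled_scatter"] = bool(np.any(medium.mus == 0))
    meta["source"] = {"kind": source.kind, "position": source.position,
                      "incidence_deg": source.incidence_deg}
    return FluenceField(grid, phi, meta)


def line_source_fluence(
    medium: OpticalMedium,
    source: SourceSpec,
    n_photons: int,
    seed: int,
) -> FluenceField:
    """Fluence of a line beam extended along the full y extent of the grid."""
    _check_medium(medium, n_photons)
    if source.kind != "line":
        raise ValueError("line_source_fluence requires a line source")
    grid = medium.grid
    ax, ay, az = source.air_direction
    x0, _ = source.position
    fl, _, tal = K.mc_voxel(
        medium.mua,
        medium.mus,
        medium.g,
        medium.n,
        grid.voxel_size,
        AMBIENT_INDEX,
        K.MODE_LINE,
        x0,
        0.0,
        source.sigma_x,
        ax,
        ay,
        az,
        0.0,
        grid.extent[1],
        0.0,
        int(n_photons),
        int(seed),
    )
    phi = fl / (n_photons * grid.voxel_volume)
    meta = _tally_meta(tal, n_photons, seed)
    meta["disabled_scatter"] = bool(np.any(medium.mus == 0))
    return FluenceField(grid, phi, meta)


def emission_green(
    medium: OpticalMedium,
    detector: DetectorSpec,
    n_photons: int,
    seed: int,
) -> GreenField:
    """Adjoint (reciprocity) Green's function for one surface detector pixel."""
    _check_medium(medium, n_photons)
    grid = medium.grid
    x0, y0 = detector.position
    ex, ey, _ = grid.extent
    if not (0 <= x0 < ex and 0 <= y0 < ey):
        raise ValueError("detector pixel must lie on the grid surface")
    fl, _, tal = K.mc_voxel(
        medium.mua,
        medium.mus,
        medium.g,
        medium.n,
        grid.voxel_size,
        AMBIENT_INDEX,
        K.MODE_COSINE,
        x0,
        y0,
        0.0,
        0.0,
        0.0,
        1.0,
        0.0,
        0.0,
        0.0,
        int(n_photons),
        int(seed),
    )
    green = fl / (n_photons * grid.voxel_volume)
    meta = _tally_meta(tal, n_photons, seed)
    return GreenField(grid, green, detector, meta)


# ---------------------------------------------------------------------------
# Translation-invariant slab response fields (pipeline fast path)
# ---------------------------------------------------------------------------


@dataclass
class SlabKernels:
    """Translation-invariant MC response fields of a homogeneous slab.

    ``phi_line[u, z]``: y-marginal excitation field of the oblique line
    beam, sampled at lateral displacements u = -nu_half..nu_half voxels
    from the nominal beam center (equivalently the fluence of an infinite
    line source).  ``green[dx, dy, z]``: adjoint detection field of a
    surface pixel at displacement (dx, dy) voxels, dx in
    [-(nfx-1), nfx-1], dy in [-(nfy-1), nfy-1], already unfolded from the
    mirror-symmetric tally.
    """

    voxel_size: float
    nu_half: int
    phi_line: np.ndarray  # (2*nu_half+1, nz)
    green: np.ndarray  # (2*nfx-1, 2*nfy-1, nz)
    meta: dict = field(default_factory=dict)

    @property
    def nz(self) -> int:
        return self.phi_line.shape[1]

    @property
    def nfx(self) -> int:
        return (self.green.shape[0] + 1) // 2

    @property
    def nfy(self) -> int:
        return (self.green.shape[1] + 1) // 2

    def green_at(self, dx: int, dy: int, z: int) -> float:
        return float(
            self.green[dx + self.nfx - 1, dy + self.nfy - 1, z]
        )


def _unfold(folded: np.ndarray) -> np.ndarray:
    """Expand a (|dx|, |dy|, z) tally to (dx, dy, z) with multiplicity."""
    nfx, nfy, nz = folded.shape
    mult_x = np.where(np.arange(nfx) == 0, 1.0, 2.0)
    mult_y = np.where(np.arange(nfy) == 0, 1.0, 2.0)
    est = folded / (mult_x[:, None, None] * mult_y[None, :, None])
    full = np.zeros((2 * nfx - 1, 2 * nfy - 1, nz))
    for sx in (-1, 1):
        for sy in (-1, 1):
            xs = slice(nfx - 1, None) if sx > 0 else slice(nfx - 1, None, -1)
            ys = slice(nfy - 1, None) if sy > 0 else slice(nfy - 1, None, -1)
            full[xs, ys, :] = est
    return full


def slab_response_kernels(
    medium: OpticalMedium,
    source: SourceSpec,
    n_photons: int,
    seed: int,
    nu_half: int,
    nfx: int,
    nfy: int,
    nz: int | None = None,
    kill_margin_mm: float = 0.6,
) -> SlabKernels:
    """Run the two slab MC passes (excitation line + adjoint detector).

    Requires a homogeneous medium.  ``n_photons`` is the budget per pass.
    The slab is laterally unbounded; photons are killed ``kill_margin_mm``
    beyond the scoring box (matched-boundary truncation).
    """
    _check_medium(medium, n_photons)
    mua, mus, g, n = medium.homogeneous_values()
    if mus <= 0:
        raise ValueError("slab response kernels require a scattering medium")
    grid = medium.grid
    h = grid.voxel_size
    nz = grid.nz if nz is None else nz
    ax, _, az = source.air_direction
    ss = np.random.SeedSequence(int(seed))
    seed_phi, seed_g = (int(s) % (2**31) for s in ss.generate_state(2))

    kill_x = (max(nu_half, nfx) + 0.5) * h + kill_margin_mm
    kill_y = (nfy + 0.5) * h + kill_margin_mm
    kill_z = nz * h + kill_margin_mm

    phi2d, _, tal_phi = K.mc_slab_response(
        mua, mus, g, n, AMBIENT_INDEX, h,
        K.MODE_PENCIL, source.sigma_x, ax, az,
        False, nu_half, 1, 1, nz,
        kill_x, kill_y, kill_z, int(n_photons), seed_phi,
    )
    _, g3d, tal_g = K.mc_slab_response(
        mua, mus, g, n, AMBIENT_INDEX, h,
        K.MODE_COSINE, 0.0, 0.0, 1.0,
        True, 1, nfx, nfy, nz,
        kill_x, kill_y, kill_z, int(n_photons), seed_g,
    )
    # collision-estimator normalization: fluence = collisions / (N V mu_t)
    mt = mua + mus
    phi_line = phi2d / (n_photons * h * h * mt)
    green = _unfold(g3d) / (n_photons * h**3 * mt)
    meta = {
        "mua": mua, "mus": mus, "g": g, "n": n,
        "seed": int(seed), "n_photons": int(n_photons),
        "phi_tally": _tally_meta(tal_phi, n_photons, seed_phi),
        "green_tally": _tally_meta(tal_g, n_photons, seed_g),
        "incidence_deg": source.incidence_deg,
        "line_fwhm": source.line_fwhm,
    }
    return SlabKernels(h, nu_half, phi_line, green, meta)


def surface_escape_map(
    medium: OpticalMedium,
    position: tuple[float, float, float],
    n_photons: int,
    seed: int,
) -> tuple[np.ndarray, dict]:
    """Escape map of an interior isotropic emitter (forward emission MC).

    Launches isotropic photons from ``position`` (x, y, z in mm) and
    tallies, per surface bin, the cosine-weighted transmitted weight — the
    signal a surface-normal camera collects.  By reciprocity the map over
    emitter positions for a fixed bin is proportional to the adjoint
    Green's function of that bin, which makes this the independent forward
    route for reciprocity checks.
    """
    _check_medium(medium, n_photons)
    grid = medium.grid
    x0, y0, z0 = position
    ex, ey, ez = grid.extent
    if not (0 <= x0 < ex and 0 <= y0 < ey and 0 <= z0 < ez):
        raise ValueError("emitter position must lie inside the grid")
    _, esc, tal = K.mc_voxel(
        medium.mua,
        medium.mus,
        medium.g,
        medium.n,
        grid.voxel_size,
        AMBIENT_INDEX,
        K.MODE_ISOTROPIC,
        x0,
        y0,
        0.0,
        0.0,
        0.0,
        1.0,
        0.0,
        0.0,
        z0,
        int(n_photons),
        int(seed),
    )
    return esc / n_photons, _tally_meta(tal, n_photons, seed)
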