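"""Forward simulation of the line-scan acquisition (the oblique stack).

The scan geometry: a 20-um-FWHM line beam hits the surface at 135 deg, the
camera (2.9-um pixels, 12-bit) views the surface from above, and a
motorized stage moves the sample perpendicular to the line, collecting 300
frames.  Each frame records the fluorescence at all source-detector
separations at once; the illuminated line itself appears as a bright
leakage column that downstream stages treat as the registered surface
position and mask from all metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .forward import SlabForwardModel
from .mc import SlabKernels, SourceSpec, slab_response_kernels
from .medium import (
    FluorophoreMap,
    OpticalMedium,
    VoxelGrid,
    embed_capillary,
    make_homogeneous_medium,
)

_BIT_DEPTHS = (8, 12, 16)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Line-scan acquisition parameters and CCD noise model.

    Noise model: counts -> Poisson(photon_scale * counts) / photon_scale
    + Normal(0, read_noise) + dark_level, then quantized to the bit depth.
    ``photon_scale`` is the number of detected photons per camera count
    (np.inf disables shot noise).
    """

    n_positions: int = 300
    stage_step: float = 0.0106667  # mm per stage position
    pixel_pitch: float = 0.0029  # mm on-sample per camera pixel
    n_offset_px: int = 414  # frame size perpendicular to the line
    n_along_px: int = 110  # frame size along the line
    bit_depth: int = 12
    photon_scale: float = 1.0
    read_noise: float = 5.0  # counts RMS
    dark_level: float = 100.0  # counts
    incidence_deg: float = 135.0
    line_fwhm: float = 0.02  # mm
    oblique_deg: float = 30.0  # effective stack obliquity for shear correction
    max_offset: float = 1.2  # mm, largest usable source-detector separation
    leak_amp: float = 10.0  # leakage column amplitude vs brightest pixel
    peak_fraction: float = 0.5  # brightest noiseless signal vs full scale

    def __post_init__(self) -> None:
        if self.n_positions < 1:
            raise ValueError("n_positions must be >= 1")
        if not (self.stage_step > 0 and self.pixel_pitch > 0):
            raise ValueError("stage_step and pixel_pitch must be > 0")
        if self.bit_depth not in _BIT_DEPTHS:
            raise ValueError(f"bit_depth must be one of {_BIT_DEPTHS}")
        if self.read_noise < 0 or self.dark_level < 0 or not self.photon_scale > 0:
            raise ValueError("noise parameters must be nonnegative (photon_scale > 0)")

    @property
    def full_scale(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def stage_positions(self) -> np.ndarray:
        """Source-line x positions (mm)."""
        return (np.arange(self.n_positions) + 0.5) * self.stage_step

    @property
    def offset_positions(self) -> np.ndarray:
        """Detector pixel offsets from the source line (mm), offset axis."""
        return np.arange(self.n_offset_px) * self.pixel_pitch

    @property
    def along_positions(self) -> np.ndarray:
        """Detector pixel y positions (mm), along-line axis."""
        return (np.arange(self.n_along_px) + 0.5) * self.pixel_pitch

    def source(self) -> SourceSpec:
        return SourceSpec(
            kind="line", incidence_deg=self.incidence_deg, line_fwhm=self.line_fwhm
        )


@dataclass
class MeasurementStack:
    """n_positions x n_offset x n_along camera frames plus geometry.

    ``source_col`` is the frame column registered as the surface source
    line (the leakage column); offsets are measured from it toward +x.
    """

    frames: np.ndarray
    acq: AcquisitionSpec
    source_col: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 3:
            raise ValueError("frames must be (n_positions, n_offset, n_along)")
        if f.shape[0] != self.acq.n_positions:
            raise ValueError(
                f"frame count {f.shape[0]} != n_positions {self.acq.n_positions}"
            )
        if f.min() < 0 or f.max() > self.acq.full_scale:
            raise ValueError("frame values outside the camera bit depth range")
        self.frames = f

    @property
    def n_positions(self) -> int:
        return self.frames.shape[0]


def _quantize(frames: np.ndarray, acq: AcquisitionSpec) -> np.ndarray:
    return np.clip(np.rint(frames), 0, acq.full_scale).astype(np.uint16)


def add_noise(
    frames: np.ndarray, acq: AcquisitionSpec, seed: int, quantize: bool = True
) -> np.ndarray:
    """Apply the CCD noise model to noiseless frames (counts, >= 0)."""
    rng = np.random.default_rng(seed)
    out = np.asarray(frames, dtype=np.float64)
    if np.isfinite(acq.photon_scale):
        out = rng.poisson(np.maximum(out, 0.0) * acq.photon_scale) / acq.photon_scale
    if acq.read_noise > 0:
        out = out + rng.normal(0.0, acq.read_noise, size=out.shape)
    out = out + acq.dark_level
    return _quantize(out, acq) if quantize else out


def default_offsets_vox(acq: AcquisitionSpec, h: float, spacing_vox: int = 1) -> np.ndarray:
    """Detector offsets (voxel units) used by the forward model."""
    dmax = int(math.floor(acq.max_offset / h + 1.0e-9))
    return np.arange(spacing_vox, dmax + 1, spacing_vox, dtype=int)


def render_frames(
    model: SlabForwardModel, fmap: FluorophoreMap, acq: AcquisitionSpec
) -> np.ndarray:
    """Noiseless camera frames (signal units) from the Born forward model.

    The Born sum is evaluated on the voxel lattice (source positions at
    voxel x centers, offsets at voxel pitch, detector y at voxel centers)
    and interpolated to the stage positions and 2.9-um camera pixels.
    """
    grid = model.grid
    h = grid.voxel_size
    offs = default_offsets_vox(acq, h)
    sig = model.forward_offsets(fmap.yield_, offs)  # (nx, nd, ny)
    # lattice coordinates
    s_mm = grid.x_centers
    d_mm = offs * h
    y_mm = grid.y_centers
    interp = RegularGridInterpolator(
        (s_mm, d_mm, y_mm), sig, bounds_error=False, fill_value=None
    )
    sp = np.clip(acq.stage_positions, s_mm[0], s_mm[-1])
    op = np.clip(acq.offset_positions, d_mm[0], d_mm[-1])
    yp = np.clip(acq.along_positions, y_mm[0], y_mm[-1])
    pts = np.stack(np.meshgrid(sp, op, yp, indexing="ij"), axis=-1)
    out = interp(pts)
    return np.maximum(out, 0.0)


def simulate_scan(
    medium: OpticalMedium,
    fmap: FluorophoreMap,
    acq: AcquisitionSpec,
    mc_budget: int,
    seed: int,
    kernels: SlabKernels | None = None,
) -> MeasurementStack:
    """Simulate the full line-scan acquisition of a homogeneous slab.

    One MC response pair (seeded by ``seed``) is reused for every stage
    position; frames are scaled so the brightest noiseless pixel sits at
    ``peak_fraction`` of full scale, the leakage column is painted at
    offset 0, CCD noise is applied, and the result is quantized.
    """
    if medium.grid != fmap.grid:
        raise ValueError("medium and fluorophore map are on different grids")
    grid = medium.grid
    scan_extent = acq.n_positions * acq.stage_step
    if scan_extent > grid.extent[0] + grid.voxel_size:
        raise ValueError(
            f"scan extent {scan_extent:.3f} mm exceeds grid x extent "
            f"{grid.extent[0]:.3f} mm"
        )
    ss = np.random.SeedSequence(int(seed))
    mc_seed, noise_seed = (int(s) % (2**31) for s in ss.generate_state(2))

    if np.any(fmap.yield_ > 0):
        if not medium.is_homogeneous:
            raise ValueError(
                "simulate_scan supports homogeneous media (slab fast path)"
            )
        if kernels is None:
            kernels = phantom_slab_kernels(medium, acq, mc_budget, mc_seed)
        model = SlabForwardModel(kernels, grid, default_offsets_vox(acq, grid.voxel_size))
        noiseless = render_frames(model, fmap, acq)
    else:
        noiseless = np.zeros(
            (acq.n_positions, acq.n_offset_px, acq.n_along_px)
        )

    peak = float(noiseless.max())
    if peak > 0:
        counts_per_signal = acq.peak_fraction * acq.full_scale / peak
    else:
        counts_per_signal = 1.0
    counts = noiseless * counts_per_signal
    # source-line leakage: bright column at offset 0
    leak = min(acq.leak_amp * counts.max(), float(acq.full_scale)) if counts.max() > 0 else float(acq.full_scale)
    counts[:, 0, :] = leak
    frames = add_noise(counts, acq, noise_seed)
    meta = {
        "seed": int(seed),
        "mc_seed": mc_seed,
        "noise_seed": noise_seed,
        "mc_budget": int(mc_budget),
        "counts_per_signal": counts_per_signal,
        "kernel_meta": kernels.meta if kernels is not None else None,
    }
    return MeasurementStack(frames, acq, source_col=0, meta=meta)


def phantom_slab_kernels(
    medium: OpticalMedium, acq: AcquisitionSpec, mc_budget: int, seed: int
) -> SlabKernels:
    """MC response pair sized for this acquisition's offset range."""
    grid = medium.grid
    h = grid.voxel_size
    dmax = int(math.floor(acq.max_offset / h + 1.0e-9))
    nu_half = dmax  # excitation support matches the usable offset range
    nfx = nu_half + dmax + 1
    nfy = grid.ny
    return slab_response_kernels(
        medium, acq.source(), mc_budget, seed, nu_half, nfx, nfy, grid.nz
    )


# ---------------------------------------------------------------------------
# Phantom recipes
# ---------------------------------------------------------------------------

RECIPES = ("paper_phantom", "paper_exvivo_analog")


def phantom_recipe(
    name: str, **overrides
) -> tuple[OpticalMedium, FluorophoreMap, AcquisitionSpec]:
    """Fully parameterized digital phantoms.

    ``paper_phantom``: intralipid slab (mua = 0.01, mus = 15 mm^-1, g = 0.9,
    n = 1.33, i.e. mus' = 1.5 mm^-1 at 690 nm) with a 100-um-ID capillary
    of fluorophore (yield 2.5, a 2.5-uM photosensitizer equivalent) tilted
    23.5 deg from the surface.  ``paper_exvivo_analog``: a uniform
    brain-like slab (user-set mus, default 20 mm^-1) with a 150-um-ID
    capillary.  Overrides: grid shape/voxel, optical properties, capillary
    geometry, acquisition fields.
    """
    if name not in RECIPES:
        raise ValueError(f"unknown recipe {name!r}; known recipes: {RECIPES}")
    if name == "paper_phantom":
        p = dict(
            nx=160, ny=16, nz=66, voxel_size=0.02,
            mua=0.01, mus=15.0, g=0.9, n=1.33,
            capillary_id=0.10, capillary_od=0.17, tilt_deg=23.5,
            entry_x=0.1, yield_value=2.5,
        )
    else:
        p = dict(
            nx=160, ny=16, nz=56, voxel_size=0.02,
            mua=0.02, mus=20.0, g=0.9, n=1.37,
            capillary_id=0.15, capillary_od=0.20, tilt_deg=23.5,
            entry_x=0.1, yield_value=2.5,
        )
    acq_over = {
        k: overrides.pop(k)
        for k in list(overrides)
        if k in AcquisitionSpec.__dataclass_fields__
    }
    unknown = set(overrides) - set(p)
    if unknown:
        raise ValueError(f"unknown recipe overrides: {sorted(unknown)}")
    p.update(overrides)

    grid = VoxelGrid(p["nx"], p["ny"], p["nz"], p["voxel_size"])
    medium = make_homogeneous_medium(grid, p["mua"], p["mus"], p["g"], p["n"])
    fmap = embed_capillary(
        FluorophoreMap.empty(grid),
        inner_diameter=p["capillary_id"],
        tilt_deg=p["tilt_deg"],
        entry=(p["entry_x"], grid.extent[1] / 2),
        value=p["yield_value"],
        outer_diameter=p["capillary_od"],
    )
    n_positions = acq_over.pop("n_positions", 300)
    stage_step = acq_over.pop("stage_step", grid.extent[0] / n_positions)
    pitch = acq_over.get("pixel_pitch", 0.0029)
    max_offset = acq_over.pop("max_offset", min(1.2, grid.extent[2] - 0.1))
    n_offset_px = acq_over.pop("n_offset_px", int(round(max_offset / pitch)))
    n_along_px = acq_over.pop("n_along_px", int(round(grid.extent[1] / pitch)))
    acq = AcquisitionSpec(
        n_positions=n_positions,
        stage_step=stage_step,
        n_offset_px=n_offset_px,
        n_along_px=n_along_px,
        max_offset=max_offset,
        **acq_over,
    )
    return medium, fmap, acq
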