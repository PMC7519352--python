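"""Quantification: FWHM resolution, depth-decay curves, 1/e depths,
exponential decay fits, the N+3sigma limit of detection, and the
tomography-vs-MIP comparison report.

Depth-decay curves follow the standard protocol: the peak signal of the
capillary is extracted at each scan position, indexed by the ground-truth
depth of the capillary axis there, and normalized to the value at the
surface (Z ~ 0).  The 2-D comparator decays as I(z) = I0 exp(-z mu_eff);
the tomographic reconstruction compensates attenuation and decays more
slowly, which is summarized by the depth at which each curve first falls
to 1/e of its surface value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .acquisition import MeasurementStack
from .medium import FluorophoreMap, VoxelGrid, capillary_axis_depth
from .projections import mip, orthogonal_stack
from .reconstruction import ReconstructionVolume

#: common depth grid step for curve comparison (um)
RESAMPLE_STEP_UM = 10.0


# ---------------------------------------------------------------------------
# curve containers
# ---------------------------------------------------------------------------


@dataclass
class DecayCurve:
    """Normalized intensity vs depth (um); first sample is 1 by construction."""

    depth_um: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.depth_um, dtype=float)
        v = np.asarray(self.intensity, dtype=float)
        if d.ndim != 1 or d.shape != v.shape or len(d) < 1:
            raise ValueError("depth and intensity must be matching 1-D arrays")
        if np.any(np.diff(d) <= 0):
            raise ValueError("depth samples must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("intensities must be nonnegative")
        self.depth_um = d
        self.intensity = v

    @classmethod
    def from_samples(cls, depth_um, values, meta=None) -> "DecayCurve":
        """Normalize raw peak values to the shallowest (Z ~ 0) sample."""
        d = np.asarray(depth_um, dtype=float)
        v = np.asarray(values, dtype=float)
        order = np.argsort(d)
        d, v = d[order], v[order]
        if v[0] <= 0:
            raise ValueError("surface sample must be positive for normalization")
        return cls(d, np.maximum(v, 0.0) / v[0], meta or {})

    @property
    def is_normalized(self) -> bool:
        return bool(np.isclose(self.intensity[0], 1.0, atol=1.0e-9))

    def at(self, depth_um: float) -> float:
        return float(np.interp(depth_um, self.depth_um, self.intensity))

    def resampled(self, step_um: float = RESAMPLE_STEP_UM) -> "DecayCurve":
        lo, hi = self.depth_um[0], self.depth_um[-1]
        d = np.arange(lo, hi + 0.5 * step_um, step_um)
        return DecayCurve(d, np.interp(d, self.depth_um, self.intensity), dict(self.meta))


@dataclass(frozen=True)
class ResolutionProfile:
    depth_um: float
    fwhm_um: float
    axis: str  # "XY" | "XZ"
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.fwhm_um > 0):
            raise ValueError("FWHM must be > 0")
        if self.depth_um < 0:
            raise ValueError("depth must be >= 0")


@dataclass(frozen=True)
class DetectionLimit:
    """Blank statistics: threshold = N + 3 sigma."""

    N: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def threshold(self) -> float:
        return self.N + 3.0 * self.sigma


@dataclass(frozen=True)
class OneOverEDepth:
    depth_um: float
    reached: bool  # False: curve never fell to 1/e; depth is the deepest sample


# ---------------------------------------------------------------------------
# ground-truth capillary track
# ---------------------------------------------------------------------------


@dataclass
class CapillaryTrack:
    """Per-scan-position expected (y, z) of the capillary axis (mm)."""

    x_mm: np.ndarray
    z_mm: np.ndarray
    y_mm: np.ndarray

    @classmethod
    def from_map(cls, fmap: FluorophoreMap) -> "CapillaryTrack":
        cap = fmap.meta.get("capillary")
        if cap is None:
            raise ValueError("fluorophore map has no capillary metadata")
        grid = fmap.grid
        x = grid.x_centers
        z = capillary_axis_depth(x, cap["entry_x_mm"], cap["tilt_deg"])
        y = np.full_like(x, cap["entry_y_mm"])
        keep = (z >= 0) & (z < grid.extent[2])
        return cls(x[keep], z[keep], y[keep])


# ---------------------------------------------------------------------------
# profile / curve extraction
# ---------------------------------------------------------------------------


def _grid_index(coord: float, h: float, n: int) -> int:
    return int(np.clip(math.floor(coord / h), 0, n - 1))


def depth_profile(
    volume,
    track: CapillaryTrack,
    window_mm: float = 0.1,
    min_depth_mm: float = 0.05,
    grid: VoxelGrid | None = None,
) -> DecayCurve:
    """Peak-intensity depth-decay curve of a reconstructed volume.

    For each scan position on the track (restricted to axis depths >=
    ``min_depth_mm``, where the capillary is fully submerged), records the
    maximum intensity in a (y, z) window of half-width ``window_mm``
    around the expected axis position, then normalizes to the shallowest
    sample.  Track points outside the volume are truncated (flagged in
    the metadata).
    """
    if isinstance(volume, ReconstructionVolume):
        data, grid = volume.values, volume.grid
    else:
        data = np.asarray(volume)
        if grid is None:
            raise ValueError("grid required for a bare array volume")
    if np.any(data < 0):
        raise ValueError("volume must be nonnegative")
    h = grid.voxel_size
    wv = max(1, int(round(window_mm / h)))
    depths, values = [], []
    truncated = False
    for x, z, y in zip(track.x_mm, track.z_mm, track.y_mm):
        if z < min_depth_mm:
            continue
        if z >= grid.extent[2]:
            truncated = True
            continue
        ix = _grid_index(x, h, grid.nx)
        iy = _grid_index(y, h, grid.ny)
        iz = _grid_index(z, h, grid.nz)
        sub = data[
            ix,
            max(0, iy - wv) : iy + wv + 1,
            max(0, iz - wv) : iz + wv + 1,
        ]
        depths.append(z * 1000.0)
        values.append(float(sub.max()))
    if not depths:
        raise ValueError("track does not intersect the volume")
    return DecayCurve.from_samples(
        depths, values, {"source": "reconstruction", "truncated": truncated}
    )


def stack_decay_curve(
    stack: MeasurementStack,
    track: CapillaryTrack,
    background: float | None = None,
    min_depth_mm: float = 0.05,
) -> DecayCurve:
    """Depth-decay curve of the MIP comparator from the raw oblique stack.

    MIP of the orthogonally stacked frames along y, background-subtracted
    peak per stage position, indexed by the ground-truth axis depth at
    that position.
    """
    vol = orthogonal_stack(stack, shear_correct=False)
    img = mip(vol, "y")  # (n_positions, n_offset)
    if background is None:
        tail = img[:, -max(1, img.shape[1] // 10):]
        background = float(np.median(tail))
    sig = np.maximum(img - background, 0.0)
    sx = stack.acq.stage_positions
    zx = np.interp(sx, track.x_mm, track.z_mm, left=np.nan, right=np.nan)
    keep = np.isfinite(zx) & (zx >= min_depth_mm)
    if not keep.any():
        raise ValueError("track does not overlap the scan")
    depths = zx[keep] * 1000.0
    values = sig[keep].max(axis=1)
    # collapse duplicate depths (several stage positions per depth sample)
    return DecayCurve.from_samples(
        depths, values, {"source": "mip", "background": background}
    )


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------


def one_over_e_depth(curve: DecayCurve) -> OneOverEDepth:
    """First depth where the normalized curve falls to 1/e (linear interp)."""
    if not curve.is_normalized:
        raise ValueError("curve must be normalized (first sample = 1)")
    target = 1.0 / math.e
    v = curve.intensity
    d = curve.depth_um
    below = np.nonzero(v <= target)[0]
    if len(below) == 0:
        return OneOverEDepth(float(d[-1]), False)
    j = below[0]
    if j == 0:
        return OneOverEDepth(float(d[0]), True)
    d0, d1 = d[j - 1], d[j]
    v0, v1 = v[j - 1], v[j]
    t = (v0 - target) / (v0 - v1)
    return OneOverEDepth(float(d0 + t * (d1 - d0)), True)


@dataclass(frozen=True)
class ExpFit:
    I0: float
    mu_eff_per_mm: float
    r2: float


def fit_exponential(curve: DecayCurve) -> ExpFit:
    """Least-squares fit of I(z) = I0 exp(-z mu_eff) on log intensities.

    Nonpositive samples are excluded from the log-linear fit; an
    all-nonpositive curve is rejected.
    """
    v = curve.intensity
    z = curve.depth_um / 1000.0  # mm
    ok = v > 0
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive samples for an exponential fit")
    if len(v) < 3:
        raise ValueError("need >= 3 samples")
    ly = np.log(v[ok])
    A = np.vstack([np.ones(ok.sum()), -z[ok]]).T
    coef, *_ = np.linalg.lstsq(A, ly, rcond=None)
    pred = A @ coef
    ss_res = float(((ly - pred) ** 2).sum())
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ExpFit(float(np.exp(coef[0])), float(coef[1]), r2)


def fwhm(coords_um: np.ndarray, profile: np.ndarray) -> float:
    """Full width at half maximum by interpolated half-crossings.

    The background (minimum of the two profile tails) is subtracted
    before halving; a profile whose half level is never crossed on one
    side is rejected as truncated.
    """
    x = np.asarray(coords_um, dtype=float)
    y = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.shape != y.shape or len(x) < 3:
        raise ValueError("profile must be 1-D with >= 3 samples")
    bg = min(y[0], y[-1])
    y = y - bg
    imax = int(np.argmax(y))
    peak = y[imax]
    if peak <= 0:
        raise ValueError("profile has no peak above background")
    half = 0.5 * peak
    left = None
    for i in range(imax, 0, -1):
        if y[i - 1] <= half <= y[i]:
            t = (y[i] - half) / (y[i] - y[i - 1]) if y[i] != y[i - 1] else 0.0
            left = x[i] - t * (x[i] - x[i - 1])
            break
    right = None
    for i in range(imax, len(y) - 1):
        if y[i + 1] <= half <= y[i]:
            t = (y[i] - half) / (y[i] - y[i + 1]) if y[i] != y[i + 1] else 0.0
            right = x[i] + t * (x[i + 1] - x[i])
            break
    if left is None or right is None:
        raise ValueError("half maximum not crossed on both sides (truncated profile)")
    return float(right - left)


def limit_of_detection(blank_stack: MeasurementStack) -> DetectionLimit:
    """N + 3 sigma from a blank (no capillary) acquisition.

    N is the mean of the blank stack and sigma the standard deviation of
    a single blank frame, both with the leakage column masked.
    """
    frames = blank_stack.frames.astype(np.float64)
    mask = np.ones(frames.shape[1], dtype=bool)
    mask[blank_stack.source_col] = False
    vals = frames[:, mask, :]
    if vals.size == 0:
        raise ValueError("empty mask: no blank pixels available")
    N = float(vals.mean())
    sigma = float(vals[len(vals) // 2].std())
    return DetectionLimit(N, sigma)


def max_detectable_depth(
    curve: DecayCurve, surface_counts: float, lod: DetectionLimit
) -> float:
    """Deepest depth (um) at which the signal stays above N + 3 sigma.

    ``surface_counts`` anchors the normalized curve back to camera counts
    (peak signal above background at the surface); the detectability
    condition is curve(z) * surface_counts >= 3 sigma.
    """
    if surface_counts <= 0:
        raise ValueError("surface_counts must be > 0")
    thresh = (lod.threshold - lod.N) / surface_counts
    v = curve.intensity
    d = curve.depth_um
    above = np.nonzero(v >= thresh)[0]
    if len(above) == 0:
        return 0.0
    j = int(above[-1])
    if j == len(v) - 1:
        return float(d[-1])
    v0, v1 = v[j], v[j + 1]
    t = (v0 - thresh) / (v0 - v1) if v0 != v1 else 0.0
    return float(d[j] + t * (d[j + 1] - d[j]))


# ---------------------------------------------------------------------------
# resolution extraction from a reconstruction
# ---------------------------------------------------------------------------


def _track_indices(grid: VoxelGrid, track: CapillaryTrack):
    h = grid.voxel_size
    ix = np.clip(np.floor(track.x_mm / h).astype(int), 0, grid.nx - 1)
    iy = np.clip(np.floor(track.y_mm / h).astype(int), 0, grid.ny - 1)
    iz = np.clip(np.floor(track.z_mm / h).astype(int), 0, grid.nz - 1)
    return ix, iy, iz


def xy_resolution(
    recon: ReconstructionVolume,
    track: CapillaryTrack,
    depth_um: float = 80.0,
    x_halfwidth: int = 2,
) -> ResolutionProfile:
    """FWHM of the capillary across y in the XY plane near the surface."""
    grid = recon.grid
    k = int(np.argmin(np.abs(track.z_mm * 1000.0 - depth_um)))
    ix, iy, iz = _track_indices(grid, track)
    sl = recon.values[
        max(0, ix[k] - x_halfwidth) : ix[k] + x_halfwidth + 1, :, iz[k]
    ].mean(axis=0)
    w = fwhm(grid.y_centers * 1000.0, sl)
    return ResolutionProfile(
        float(track.z_mm[k] * 1000.0), w, "XY", {"x_index": int(ix[k])}
    )


def xz_resolution(
    recon: ReconstructionVolume,
    track: CapillaryTrack,
    depth_um: float,
    x_halfwidth: int = 2,
    y_halfwidth: int = 1,
) -> ResolutionProfile:
    """FWHM of the capillary along z in the XZ plane at a given axis depth."""
    grid = recon.grid
    k = int(np.argmin(np.abs(track.z_mm * 1000.0 - depth_um)))
    ix, iy, iz = _track_indices(grid, track)
    sl = recon.values[
        max(0, ix[k] - x_halfwidth) : ix[k] + x_halfwidth + 1,
        max(0, iy[k] - y_halfwidth) : iy[k] + y_halfwidth + 1,
        :,
    ].mean(axis=(0, 1))
    w = fwhm(grid.z_centers * 1000.0, sl)
    return ResolutionProfile(
        float(track.z_mm[k] * 1000.0), w, "XZ", {"x_index": int(ix[k])}
    )


# ---------------------------------------------------------------------------
# comparison report
# ---------------------------------------------------------------------------


def compare_flot_mip(
    flot_curve: DecayCurve,
    mip_curve: DecayCurve,
    replicates: list[tuple[DecayCurve, DecayCurve]] | None = None,
) -> dict:
    """Head-to-head report of the tomographic and MIP depth-decay curves.

    Curves are resampled to a common 10-um depth grid over their
    overlapping range.  The report carries both 1/e depths and their
    ratio, both exponential-decay fits, the depth range where the
    tomographic curve dominates, and replicate mean +/- sample SD when
    replicate curve pairs are provided.
    """
    lo = max(flot_curve.depth_um[0], mip_curve.depth_um[0])
    hi = min(flot_curve.depth_um[-1], mip_curve.depth_um[-1])
    if hi <= lo:
        raise ValueError("curves cover disjoint depth ranges")
    d = np.arange(lo, hi + 0.5 * RESAMPLE_STEP_UM, RESAMPLE_STEP_UM)
    f = np.interp(d, flot_curve.depth_um, flot_curve.intensity)
    m = np.interp(d, mip_curve.depth_um, mip_curve.intensity)
    fe = one_over_e_depth(flot_curve)
    me = one_over_e_depth(mip_curve)
    dominate = d[f >= m]
    report = {
        "flot_one_over_e_um": fe.depth_um,
        "flot_one_over_e_reached": fe.reached,
        "mip_one_over_e_um": me.depth_um,
        "mip_one_over_e_reached": me.reached,
        "one_over_e_ratio": fe.depth_um / me.depth_um if me.depth_um > 0 else np.inf,
        "flot_fit": fit_exponential(flot_curve).__dict__,
        "mip_fit": fit_exponential(mip_curve).__dict__,
        "flot_dominates_from_um": float(dominate[0]) if len(dominate) else None,
        "flot_dominates_to_um": float(dominate[-1]) if len(dominate) else None,
    }
    if replicates:
        fes = [one_over_e_depth(fc).depth_um for fc, _ in replicates]
        mes = [one_over_e_depth(mc).depth_um for _, mc in replicates]
        report["replicates"] = {
            "n": len(replicates),
            "flot_one_over_e_um_mean": float(np.mean(fes)),
            "flot_one_over_e_um_sd": float(np.std(fes, ddof=1)) if len(fes) > 1 else 0.0,
            "mip_one_over_e_um_mean": float(np.mean(mes)),
            "mip_one_over_e_um_sd": float(np.std(mes, ddof=1)) if len(mes) > 1 else 0.0,
        }
    return report
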