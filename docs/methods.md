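# Methods

## Geometry and conventions

The tissue surface is the plane z = 0 with z increasing into the medium;
x is the stage-scan direction and y runs along the illumination line.
Voxels are isotropic cubes (anisotropic voxels are rejected); voxel *i*
spans the half-open interval [i·h, (i+1)·h) and its center sits at
(i+0.5)·h.  The digital phantom is a homogeneous slab (µa = 0.01 mm⁻¹,
µs = 15 mm⁻¹, g = 0.9, n = 1.33; µs′ = 1.5 mm⁻¹) with a capillary of
fluorophore (inner diameter 0.10 mm, yield 2.5 in
concentration-proportional units) whose axis lies in the x–z plane and
descends at 23.5° from the surface.  The capillary is fluorophore-only:
the glass wall is not modeled and its outer diameter (0.17 mm) is kept
in metadata.  The default grid is 160×16×66 voxels at h = 0.02 mm
(3.2 × 0.32 × 1.32 mm), sized so the capillary descends from the surface
past 1.2 mm within the scanned range.

## Monte Carlo transport

Photon steps are sampled from the exponential distribution with
µt = µa + µs; absorption uses continuous weighting (the photon deposits
µa/µt of its weight per interaction and survives with the albedo);
scattering angles follow Henyey–Greenstein with anisotropy g; the z = 0
interface applies unpolarized Fresnel reflection/refraction between the
medium index and ambient air (n = 1), including total internal
reflection.  Russian roulette starts below weight 10⁻⁴ with survival
probability 0.1.  A bookkeeping audit accumulated during transport
(launched = specular + absorbed + escaped + terminated + roulette-killed
− roulette-gained) closes to floating-point rounding on every run.
Kernels are single-threaded and bit-reproducible for a fixed seed.

Two estimators are used.  The bounded-grid kernel scores fluence with
the path-length estimator (Σ w·ℓ / N·V), which the analytic-limit tests
rely on (a µs = 0 medium reproduces Beer–Lambert attenuation; a pencil
source on the phantom medium matches the semi-infinite
diffusion-approximation dipole with extrapolated boundary to within 7%
at z = 3 mm).  The homogeneous-slab response kernels used by the
pipeline score with the collision estimator (Σ w/µt per interaction
site), which is unbiased and several times faster at the phantom's
collision density (mean free path 67 µm vs 20-µm voxels).

The detector model launches adjoint photons from the pixel with
cosine-weighted directions restricted to the escape cone, weighted by
the Fresnel transmission of the reversed escaping ray: the collection
numerical aperture of the objective is not part of the acquisition
geometry, so the camera is taken to accept everything that escapes
toward it.  Reciprocity of this adjoint is verified against an
independent forward route (isotropic emission from an interior voxel,
cosine-weighted escape tally at the surface).

The slab is laterally unbounded; photons are terminated 0.6 mm beyond
the scoring box (a matched-boundary truncation).  Photons leaving the
bounded grid of the general kernel terminate at the faces.

## Translation-invariant forward model

In a homogeneous slab the line-source excitation field Φ(u, z) and the
pixel detection field G(Δx, Δy, z) depend only on displacements, so the
Born sum is a cross-correlation of the volume with the per-offset kernel
K_d[u, v, z] = Φ[u, z]·G[d−u, v, z]·h³, evaluated with FFTs over (x, y).
The excitation field is tallied as a y-marginal (equivalent to an
infinite line by superposition); the detection field is tallied folded
over its x and y mirror symmetries and unfolded with the multiplicity
correction, which quarters its variance.  Kernel entries below 10⁻⁶ of
the maximum are zeroed: Monte Carlo shot noise in deep, weakly sensitive
voxels otherwise leaks into the inversion.

Measurements are indexed (stage position, detector offset, y bin) on the
voxel lattice.  The acquisition itself is finer — 300 stage positions at
10.7 µm and 2.9-µm camera pixels — so frames are rendered by
interpolating the lattice forward model to the camera sampling, and
reconstruction rebins the frames back onto the lattice by averaging (the
leakage column excluded).  Detector offsets run one-sided toward +x (the
direction the refracted beam tilts) up to 1.2 mm; the pipeline uses
every second lattice offset (40-µm bins) for the sensitivity operator
and all of them for frame rendering.

## Camera and noise model

Counts = Poisson(photon_scale · signal)/photon_scale + N(0, σ_read) +
N₀, quantized to the bit depth (12 bits).  Defaults: photon_scale 1
(counts are detected photons), σ_read = 5 counts, dark level N₀ = 100
counts — a mid-grade scientific CCD operating point.  The brightest
noiseless pixel is scaled to 50% of full scale so quantization never
dominates.  The source line leaks onto the camera and is painted as a
saturating bright column at offset 0; it registers the surface position
and is masked from every metric.  The dark pedestal carries no shot
noise (it is a bias level, not a photon background), so the blank noise
is read noise alone.

## Inversion

`tikhonov_solve` minimizes ‖W·x − ΔF‖² + λ²‖x‖² with damped LSMR at
relative tolerance 10⁻⁸ (default iteration cap 4·min(m, n), well above
scipy's default, which truncates damped systems early).  λ = 0 on a
rank-deficient system returns the minimum-norm least-squares solution
with a warning flag.  The L-curve sweep solves largest-λ first with warm
starts; near-duplicate sweep points (the plateau where λ is below every
relevant singular value) are collapsed before curvature estimation,
since duplicated points otherwise fabricate curvature at the plateau.
Curvature is computed by central finite differences on the pruned
(log ρ, log η) points; ties break toward larger λ.  The default grid is
20 log-spaced points over [10⁻⁴, 10²]·σmax(W) (the pipeline uses 12 over
[10⁻⁴, 10]·σmax — the corner of the phantom problem sits near
2·10⁻³·σmax).  Negative voxels are clipped after the solve; the count of
clipped voxels is reported in the diagnostics.

The corner criterion is validated on a mildly ill-conditioned 1-D
exponential smoothing problem (32 unknowns, 1% noise), where the corner
solution's error stays within 2× of the sweep minimum.  On severely
ill-posed kernels (e.g. wide Gaussian blur) the L-curve corner is known
to over- or under-smooth by larger factors; that is a property of the
criterion, not of this implementation.

Depth compensation scales the columns of W per depth layer with
M(A_l)^γ, where M(A_l) is the largest singular value of the submatrix of
layers 1..l (surface = layer 1) and γ ∈ [0, 3]; γ = 0 leaves W
untouched, and the reconstruction maps the scaled solution back to
yield units.  Because M(A_l) is nondecreasing in l, deep layers are
up-weighted.  The pipeline default is γ = 0 (plain Tikhonov).

## Metrics

Depth-decay curves record, per scan position, the peak intensity in a
100-µm window around the ground-truth capillary axis, indexed by the
axis depth there, normalized to the shallowest sample with the axis
fully submerged (depth ≥ 50 µm ≈ one radius).  The MIP comparator is
extracted from the raw orthogonally stacked frames (no shear
correction), background-subtracted, maximum per stage position.  1/e
depths are located by linear interpolation; exponential fits are
log-linear least squares excluding nonpositive samples; FWHM uses
interpolated half-maximum crossings after subtracting the smaller tail
(a Gaussian-fit variant is deliberately not the default — the crossings
make no shape assumption).  Curves are resampled to a common 10-µm depth
grid for comparison.  The N+3σ limit of detection uses the blank-stack
mean and single-frame standard deviation with the leakage column masked;
the detectability of the reconstruction is assessed by anchoring its
normalized curve to the measured surface peak counts, so the condition
becomes curve(z)·S₀ ≥ 3σ.

Because the MIP curve value is a maximum over a frame, its blank-level
pedestal is the extreme value of the noise (≈ 4σ over ~4·10⁴ pixels),
not 3σ; the pipeline measures this pedestal directly by applying the
same peak extraction to the blank stack, and curve-domination
comparisons are restricted to depths where the MIP value exceeds twice
that pedestal.

## What the synthetic data does and does not emulate

Emulated: the line-scan acquisition geometry (300 positions, 135°
illumination, 20-µm line FWHM, 2.9-µm pixels, 12-bit quantization,
source-line leakage), exact voxel MC transport in the slab, Born-linear
fluorescence generation, shot/read/dark camera noise, and the
inverse-crime separation between the data-generating and
reconstruction Monte Carlo.

Not emulated: the glass capillary wall (refraction at the wall and the
35-µm fluorophore-free annulus), the objective's point-spread function
and collection NA, wavelength-dependent optical properties between
excitation and emission, and any lateral heterogeneity of the medium.
These omissions matter most within the first one or two scattering mean
free paths of the surface: the ideal model has a strong quasi-ballistic
excitation core and a near-field detection peak there, so the simulated
depth-decay curves fall steeply over the first ~150 µm before settling
onto the diffuse decay (tail µ_eff ≈ 1.5 mm⁻¹ for the MIP comparator).
A physical system suppresses that near-surface spike, which shifts its
normalized curves upward at all depths and extends its measured 1/e
depths; passing the ordering and domination tests here therefore
demonstrates the *relative* depth-compensation property of the
tomographic reconstruction, not absolute agreement of near-surface
normalization with a physical instrument.  The plain-Tikhonov
reconstruction also carries a systematic shallow bias of roughly two
voxels (~40 µm) in peak depth, the textbook consequence of depth-decaying
sensitivity at γ = 0.

## Problem sizes

Defaults used by the pipeline and the acceptance script: grid 160×16×66
at 20 µm, 300 stage positions, 1.5·10⁶ photons per data response field
and 10⁶ per sensitivity field, 12-point λ sweep, three seeded
replicates.  The test suite exercises the same pipeline at reduced
photon budgets (6·10⁵/4·10⁵) across five replicates, and the single
voxel localization check runs on 40-µm voxels, comparable to the
system's point-spread scale.  All of these are the package's chosen
desk-scale operating points; every stage accepts larger budgets
unchanged.

## Known limitations

* Heterogeneous media are transported exactly by the bounded-grid kernel
  but the scan simulator and convolutional sensitivity assembly require
  a homogeneous slab; per-position Monte Carlo for heterogeneous W is
  structurally possible through the explicit sparse backend but not
  optimized.
* The effective obliquity of the stacked frames is a parameter
  (default 30°); the acquisition geometry implies a 45° air-side angle
  and ~32° in-tissue after refraction, and the shear correction accepts
  either convention.
* Curved-surface media mark exterior voxels as vacuum but do not refract
  at the interior tissue interface.
* The ex vivo brain analog is a uniform slab with user-set scattering;
  layered brain optics and mesh geometries are out of scope.
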