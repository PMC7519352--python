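# flotsim

Fluorescence laminar optical tomography (FLOT) at desk scale: simulate a
line-scan fluorescence acquisition of a photosensitizer-filled capillary
in a scattering medium, reconstruct the 3-D fluorophore distribution from
the surface measurements, and quantify how much better the tomographic
image compensates depth attenuation than plain 2-D
maximum-intensity-projection (MIP) imaging.

The package is aimed at mesoscopic-imaging researchers who want a fully
seeded, end-to-end digital twin of a line-scan FLOT experiment — phantom,
camera, photon transport, inversion, and metrics — with every stage
testable against analytic oracles.

## The model

A line beam (20-µm FWHM, incident 135° to the surface) excites a
fluorophore distribution *O*(r′) inside a turbid slab; a camera normal to
the surface (2.9-µm pixels, 12-bit) records the emitted light at all
source–detector separations at once while a stage steps the sample
perpendicular to the line (300 positions).  Under the first-order Born
approximation the background-subtracted measurement is

    ΔF(r_s, r_d) = Σ_{r′} G(r_d − r′) · O(r′) · Φ(r′ − r_s) · ΔV
                 = W · ΔO,

where Φ is the excitation fluence of the line source and G the
probability that emission from r′ reaches the detector pixel.  Both
fields are computed by voxel Monte Carlo (Henyey–Greenstein scattering,
continuous absorption weighting, Fresnel boundary at the surface, Russian
roulette); G is obtained by reciprocity from adjoint launches at the
detector.  In a homogeneous slab W is block-convolutional — one MC pair
serves all 300 stage positions — and the inverse problem

    min ‖W·ΔO − ΔF‖² + λ²‖ΔO‖²

is solved with damped LSMR, with λ chosen at the maximum-curvature corner
of the L-curve.  Depth compensation (per-layer column weighting with
exponent γ ∈ [0, 3], built from cumulative maximum singular values) is
available and off by default.

Metrics mirror the standard characterization of such systems: FWHM
resolution profiles of the reconstructed capillary, normalized
depth-decay curves for the reconstruction and the MIP comparator, their
1/e depths, exponential-decay fits I(z) = I₀·exp(−μ_eff·z), and the
N + 3σ limit of detection from a blank acquisition.

## Worked example

```python
from flotsim import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(data_seed=1, w_seed=2))
r = result.report
print(r["comparison"]["mip_one_over_e_um"])   # 92.4
print(r["comparison"]["flot_one_over_e_um"])  # 199.4
print(r["resolution"]["xy_surface"]["fwhm_um"])  # 94.5
print(r["detection"]["max_detectable_depth_um"])  # 1041.0
```

This simulates the intralipid phantom (µa = 0.01 mm⁻¹, µs = 15 mm⁻¹,
g = 0.9, n = 1.33, i.e. µs′ = 1.5 mm⁻¹) containing a 100-µm-ID capillary
of fluorophore tilted 23.5° from the surface, builds the sensitivity
operator with an independent Monte Carlo seed (the inverse-crime guard
rejects equal seeds), reconstructs, and reports:

* the MIP depth-decay curve falls to 1/e of its surface value at
  **92 µm** and the tomographic reconstruction at **199 µm** — the
  reconstruction compensates attenuation and always outlives the 2-D
  comparator (every seeded replicate preserves this ordering);
* the reconstructed capillary is **94.5 µm** wide (FWHM) across the line
  direction near the surface — the true capillary is 100 µm;
* the capillary stays above the N + 3σ detection limit down to
  **1.04 mm**.

Both curves have a steep near-surface knee produced by the
quasi-ballistic excitation core and near-field detection of the ideal
model; beyond that region the MIP curve decays with
µ_eff ≈ 1.5 mm⁻¹, see `docs/methods.md` for what this does and does not
say about a physical system.

The same pipeline is scriptable from the shell:

```bash
flot simulate --recipe paper_phantom --seed 1 --photons 1000000 --out stack.tif
flot reconstruct --stack stack.tif --w-seed 2 --out recon.h5
flot mip --stack stack.tif --out mip.tif
flot run --data-seed 1 --w-seed 2 --out-dir out/
flot provenance out/stack.tif
```

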