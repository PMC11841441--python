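# vasckit

Quantitative toolkit for **perfusable vascularized hydrogel constructs** —
the kind of 3D-bioprinted tumor-niche model in which a sacrificial ink
leaves a hollow vascular channel inside a cell-laden GelMA matrix, an
endothelium is grown on the channel wall, and the construct is kept alive
under continuous perfusion.

It is written for the people who build and characterize such systems:
tissue engineers and bioprinting labs who need the *numbers* behind the
platform — how fast solutes move through the gel, what shear the
endothelium feels, how faithful the printed geometry is, how leaky the
vascular barrier is — without a commercial FEM license or a pile of
one-off ImageJ macros.

## What it computes

**Reduced-order transport model.**  Steady laminar flow in a cylindrical
channel (radius R) coupled to Brinkman/Darcy seepage in the porous GelMA
annulus, solved as a two-domain radial finite-volume problem.  Wall shear
stress τ_w = μ|du/dr| at r = R agrees with the Poiseuille closed form
4μQ/(πR³) to better than 1% at the default grid.  A transient
advection–diffusion solver (effective matrix diffusivity D_eff = ε·D_s)
reports t*, the time for the volume-averaged matrix concentration to reach
a target fraction of the inlet value; its slab limit matches the erfc
similarity solution within 2%.

**Image-derived metrics**, each validated against synthetic ground truth:

| Metric | Definition | Guarantee |
|---|---|---|
| FRAP diffusion coefficient | D = c·r²/τ½, τ½ from an exponential recovery fit | within 10% of truth (disk-bleach prefactor c = 0.224) |
| Printability | Pr = p²/(16A) per enclosed grid pore | 1.00 ± 0.02 on squares, π/4 ± 0.02 on circles |
| Porosity / pore sizes | Otsu + connected components, r = √(A/π) | porosity ±0.02 abs, radii within 1 px |
| Viability | live/dead blob counts | exact on clean fields |
| Vascular permeability | P = (I_t−I_0)/(t(I_0−I_b))·d/4 (cm/s) | exact on linear leak series |
| Network metrics | skeleton length + circuit-rank mesh count | length within 5%, meshes exact |

**Synthetic data generators** for all six input kinds (FRAP stacks, dextran
leak series, pore textures, printed grids, nuclei fields, network masks),
fully seeded and emitting exact ground truth alongside each TIFF.

## Worked example

One command regenerates every synthetic experiment, runs every analysis
stage plus both simulations, and writes a report:

```bash
vasckit demo --seed 1 --out demo_out
```

`demo_out/report.json` (abridged, actual output):

```json
"frap": {
  "cases": [
    {"D_true": 5.0,  "D_est": 5.30,  "rel_error": 0.059},
    {"D_true": 13.2, "D_est": 13.95, "rel_error": 0.056},
    {"D_true": 28.2, "D_est": 29.53, "rel_error": 0.047}],
  "ordering_preserved": true, "passed": true },
"flow": {
  "calibrated_radius_m": 5.49e-4,
  "tau_w_10_pa": 8.91e-4, "tau_w_90_pa": 8.02e-3,
  "linearity_r2": 1.0, "passed": true },
"permeability": { "ratio": 5.0, "percent_reduction": 80.0, "passed": true },
"transport": { "time_to_target_min": 117.3, "target_fraction": 0.9 }
```

Reading it: the FRAP pipeline recovers the generating diffusion
coefficients of the three dextran surrogates (5, 13.2, 28.2 µm²/s) within
6% and preserves their ordering; calibrating the channel radius so that
τ_w = 0.89×10⁻³ Pa at 10 µL/min yields R ≈ 0.55 mm, and the shear sweep is
exactly linear up to 8.0×10⁻³ Pa at 90 µL/min; a synthetic endothelialized
channel with one-fifth the leak slope shows the expected 80% permeability
reduction; and with the default geometry the matrix reaches 90% of the
inlet concentration after ~117 min of perfusion at 30 µL/min.

The same stages are exposed individually (`vasckit synth`, `vasckit
simulate flow|sweep|transport`, `vasckit frap`, `vasckit metrics`,
`vasckit network`) and as a Python API:

```python
from vasckit import (SynthSpec, generate_frap_stack, frap_pipeline,
                     SOUMPASIS_PREFACTOR)

spec = SynthSpec(kind="frap", seed=7, shape=(96, 96), frame_interval=0.25,
                 params={"D_true": 13.2, "roi_radius": 10.0})
stack, truth = generate_frap_stack(spec)
est = frap_pipeline(stack, truth.data["roi_center_px"], 10.0,
                    truth.data["bleach_frame"], prefactor=SOUMPASIS_PREFACTOR)
print(f"D = {est.D:.1f} um^2/s (tau_1/2 = {est.tau_half:.2f} s)")
# D = 13.9 um^2/s (tau_1/2 = 1.61 s)
```

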