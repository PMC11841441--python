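# Methods

`vasckit` reimplements, as a tested pipeline, the quantitative backbone of a
perfusable vascularized tumor-niche platform: a reduced-order model of flow
and solute transport in a cylindrical vascular channel embedded in porous
GelMA, and the image-derived measurements used to characterize such
constructs.  Raw microscopy is replaced by synthetic generators with exact
ground truth, so every stage is benchmarked end to end.

## Reduced-order flow model

Culture medium is pumped through a channel of radius R embedded in a GelMA
annulus of outer radius R_out.  At perfusion flow rates (tens of µL/min in a
~1 mm channel) the Reynolds number is ≪ 1 and the axial momentum balance is
fully developed, so the velocity reduces to a two-domain radial ODE:
Stokes flow in the lumen, the Brinkman equation (Darcy drag μ_f/κ plus an
effective viscous term) in the matrix, with continuity of velocity and
viscous stress at r = R, symmetry at the axis and no slip at R_out.  The
problem is linear, so it is solved once for a unit pressure gradient on a
flux-conservative finite-volume grid and rescaled so the lumen carries the
prescribed flow rate Q.  Wall shear stress is τ_w = μ_f |du/dr| at r = R,
evaluated by quadratic extrapolation from the three lumen cells nearest the
wall — exact for the quadratic lumen profile, so the discretization error
comes only from the interface coupling.

Two modelling reductions deserve comment:

* **Forchheimer drag is omitted.**  The inertial correction to Darcy drag
  scales with the pore-scale Reynolds number, which is vanishingly small
  here, and no inertial coefficient is available for this hydrogel.
* **Effective Brinkman viscosity.**  The hydrogel's own dynamic viscosity
  (100 Pa·s) is used as the effective viscosity of the Brinkman viscous
  term; the Darcy term keeps the permeating fluid's viscosity.  With the
  tabulated permeability κ = 1e-7 m² the alternative choice (fluid viscosity
  in both terms) would let the matrix conduct a volumetric flux comparable
  to the channel's and put a slip velocity of the same order as the
  centerline velocity at the wall — physically implausible for a hydrogel
  whose channel walls support an endothelium, and incompatible with the
  near-Poiseuille channel behaviour the model is meant to reproduce.  With
  the default, the matrix is essentially stagnant and the channel solution
  collapses onto Poiseuille flow (verified to < 1% at the default grid).
  The choice is a parameter (`dynamic_viscosity_matrix`), not a hard-coded
  assumption.

The radial grid is piecewise uniform with a cell face exactly on the
interface; `n_r` cells are split between the domains in proportion to their
widths (minimum 8 per domain), and `n_r_matrix` can pin the matrix
resolution for thin-annulus studies.  Halving the spacing changes τ_w by
< 1% at the default `n_r = 64`.

Channel radius is rarely reported for such platforms; `calibrate_radius`
inverts the numerical shear-flow relation by bisection (τ_w ∝ R⁻³) so an
operating point (τ_w, Q) fixes the geometry.  Calibrating to
τ_w = 0.89×10⁻³ Pa at 10 µL/min gives R ≈ 0.55 mm, and the sweep to
90 µL/min then reproduces the reported upper endpoint 7.90×10⁻³ Pa within
~1.5% (the model is exactly linear in Q; the reported endpoints depart from
perfect 9× linearity by ~1.4%).

## Solute transport

Transport of a diluted species (oxygen/nutrients, normalized to the inlet
concentration) combines upwind axial advection in the lumen — velocity
profile from the flow solve — with Fickian diffusion: free diffusivity
D_s = 3×10⁻⁹ m²/s in the lumen and effective diffusivity D_eff = ε·D_s in
the matrix.  The porosity scaling is itself a convention (the source table
does not state whether its diffusivity is free or effective); it is the
default, not a claim.  Time stepping is explicit with internal substepping
at 0.8× the combined diffusive+CFL bound; the scheme, step and channel
model are recorded in the result.  The readout is t*, the first time the
volume-averaged matrix concentration crosses a target fraction (default
0.9), interpolated linearly between steps; a target not reached by `t_max`
returns `+inf` with a warning rather than raising.

A `saturated` channel model holds the lumen at the inlet value from t = 0,
with the Dirichlet condition applied at the interface face itself.  This is
the no-flow/fast-perfusion idealization used for the closed-form benchmark:
in a thin, large-radius annulus the radial profile must follow the
half-space similarity solution c = erfc(x/√(4 D_eff t)), and does so within
2% (L∞) at the test resolution.  Pure-diffusion scaling t* ∝ 1/D_eff holds
within the interpolation error (< 1%).

With the calibrated geometry (R ≈ 0.55 mm, R_out = 3 mm, L = 10 mm) at the
nominal 30 µL/min, t*(0.9) ≈ 117 min, i.e. a diffusion length
√(D_s·t*) ≈ 4.6 mm.  Reported homogenization times of roughly 45 min for
perfused GelMA constructs correspond to a diffusion length of ≈2.8 mm at
the tabulated diffusivity — the same order of magnitude, consistent with a
somewhat thinner matrix shell than the default geometry.  Absent published
construct dimensions, such figures are reproducible only to order of
magnitude; all geometry is configuration.

## FRAP

The generator simulates a uniformly bleached disk in a uniform fluorophore
field by explicit (FTCS) finite differences on the pixel grid with a
Dirichlet far-field boundary — a deliberately independent numerical route
from the analysis.  The stability bound dt ≤ dx²/(4D) is enforced: an
explicitly requested unstable step is refused, never silently substepped
(the default step, 0.4× the bound, is recorded in the ground truth).

Analysis normalizes the ROI mean to F = 0 at the first post-bleach frame
and F = 1 at the single pre-bleach frame, fits F(t) = A(1 − e^(−t/τ)) and
reports τ½ = τ ln 2, falling back to linear interpolation of the raw curve
when the fit R² < 0.8 (the method used is recorded).  The diffusion
coefficient is D = c·r²/τ½.  The half-time convention c = 2 is the default;
for a uniformly bleached disk measured over the same disk the physically
calibrated prefactor is the Soumpasis value c ≈ 0.224, exposed as
`SOUMPASIS_PREFACTOR` and used in all parameter-recovery benchmarks.  With
it, end-to-end recovery on noise-free synthetic stacks at D ∈ {5, 13.2,
28.2} µm²/s is within ~6% (tolerance 10%), and the D ordering survives 5%
additive noise across seeds.  Single-exponential recovery is itself an
approximation to the true disk-bleach kinetics (long 1/t tail); it
contributes a few percent of the residual bias, which is why the plateau
check acquires tens of characteristic times.

## Printability

Pr = p²/(16A) per enclosed pore of a printed grid: Otsu binarization,
border-touching background removed, area by pixel count, perimeter by
marching-squares boundary tracing followed by a Douglas-Peucker
simplification with 1 px tolerance.  The simplification is what makes the
estimator usable at this tolerance: raw traced (or pixel-edge) perimeters
overestimate a digital circle by ~12–15%, while DP preserves square corners
exactly and removes the staircase, giving mean Pr = 0.990 on 100 px square
pores and 0.793 on circles (π/4 ≈ 0.785), both within the ±0.02 band.
Features larger than the 1 px tolerance — e.g. star points — survive, so
jagged pores correctly yield Pr > 1.

## Porosity, viability, permeability

* **Porosity**: Otsu threshold, connected components on the dark phase,
  equivalent-circle radii r = √(A/π), areal porosity as the pore-pixel
  fraction, 1 µm histogram bins over 0–20 µm.  On generated textures
  spanning the realistic 5–14 µm pore-radius regime, porosity is recovered
  within 2 points absolute and radii within one pixel-equivalent.
* **Viability**: per-channel blob counting (Gaussian smoothing σ = 2 px,
  Otsu floor, local maxima with minimum separation).  Counts are exact on
  well-separated noise-free fields; viability = n_live/(n_live+n_dead), and
  an empty field is flagged undefined rather than defaulting to a number.
* **Permeability**: P = (I_t − I_0)/(t (I_0 − I_b)) · d/4 in cm/s, with the
  channel diameter converted to cm.  The default estimator uses the
  least-squares slope of the flanking-ROI mean over all post-perfusion
  frames (recorded as method `slope`), which is exact to floating point on
  a linear series; a single-endpoint form is available.  The measurement
  ROI defaults to two full-height rectangles, one channel-radius wide,
  one channel-radius away from either channel edge — placement the source
  protocol leaves unspecified, recorded in provenance.  Decreasing
  intensity yields a negative P with a warning (photobleaching artifact)
  rather than an error.

## Network metrics

Masks are skeletonized; the skeleton's pixel graph (8-connected, with
diagonal shortcuts across orthogonal pairs removed) is reduced to a spatial
graph whose nodes are junctions and endpoints; junction pixels within 3 px
merge into one node, and self-loops shorter than 5 px are treated as
junction artifacts.  Mesh count is the circuit rank E − N + C, exact by
construction.  Branch lengths resample each pixel chain every 4 px and sum
the polyline — chain-code weights were rejected because (1,√2) weights
overestimate oblique segments by up to 8% and corrected (Kulpa-type)
weights underestimate axis-aligned ones by 5%; resampling keeps both a
straight 100 µm segment and random trees within a few percent.  Free ends
still lose roughly half a stroke width to skeletonization, the dominant
residual bias (~1–2% on the default tree).

## Synthetic data: what it does and does not emulate

Generators emit 16-bit grayscale stacks with signal at 80% of the dynamic
range and optional additive Gaussian noise; all randomness flows from the
spec seed (bit-identical reruns).  Object placement uses rejection sampling
capped at 10⁴ attempts, erroring on packing failure rather than degrading.
The random-tree generator enforces a planar, overlap-free embedding
(segment clearance, minimum sibling-edge angle) so the rasterized mask has
exactly the tree's topology — the abstract circuit rank is the ground
truth, and crossing strokes would silently create real loops.

Deliberately not modelled: point-spread-function blur, acquisition
photobleaching, stage drift, uneven illumination, autofluorescence and
segmentation-confounding cell clutter.  Passing benchmarks therefore
demonstrate correctness of the estimators on clean, well-posed inputs and
their stability under additive noise — not robustness to every real
microscopy artifact.

## Defaults chosen where the source is silent

| Quantity | Default | Why |
|---|---|---|
| Pixel size | 1 µm/px | typical 10× fluorescence scale; configuration, not a claim |
| FRAP frame interval | 0.5 s | resolves τ½ of the fastest realistic D |
| Leak frame interval | 30 s | stated acquisition cadence |
| Medium viscosity | 0.7×10⁻³ Pa·s | aqueous medium at 37 °C |
| Geometry | R_out = 3 mm, L = 10 mm | mm-scale construct; all geometry configurable |
| Target fraction | 0.9 | "target concentration" never defined; exposed as a flag |
| Transport t_max (demo) | 4 h | covers t* for the default geometry |

## Problem sizes

Benchmarks are sized for interactive runs: FRAP stacks 96×96 px with
~100–200 frames (a few thousand FTCS steps each), textures and grids
512×512 px, flow grids 64 radial cells, transport runs 10³–10⁴ explicit
steps on ≤ 80×32 cells.  The full demo (`vasckit demo`) completes in under
a minute on one core.
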