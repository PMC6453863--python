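# Methods

This note records the models, assumptions, parameter choices and numerical
methods behind `strutflow`, and the limitations that follow from them. Every
number quoted here is either a model parameter or a quantity the test suite /
`scripts/acceptance.py` computes.

## 1. Geometry and imaging model

**Vessel phantoms.** Analytic centerlines (straight, or circular-helix with
torsion set to half the curvature so no projection plane contains the curve),
arc-length parametrized, with a circular lumen of optionally tapering radius.
A side-branch landmark with a seeded angle sits in the proximal native
segment and fixes the absolute rotation during fusion.

**OCT pullback.** Frames every 200 µm (configurable), contours sampled at 1°
in catheter-centred polar form. Strut rings are placed at the design pitch
(inter-strut gap + strut width); six struts per ring, alternate rings rotated
by half a strut period. Each strut footprint carries its adluminal and
abluminal radii; the generator stores the true protrusion depth and
malapposition flag per strut, which is what makes sub-micron round-trip tests
possible.

**Measurement conventions.**

- *Protrusion distance* = interpolated wall radius under the strut centre
  minus the adluminal radius, floored at 0. The wall under a strut is
  linearly interpolated between the contour points flanking the footprint.
- *Malapposition* = abluminal gap strictly greater than 20 µm (at or below is
  treated as apposed — the imaging resolution limit). Malapposed struts are
  excluded from protrusion statistics.
- *Flow-area contour* = lumen contour with the trace inside each strut span
  replaced by the strut's adluminal edge. Inverted geometry (adluminal edge
  outside the wall) and overlapping spans are rejected, not repaired.
- Aggregation averages struts within half-open 200 µm intervals first; the
  device-level mean is the mean of interval means, and the protrusion
  fraction is that mean as an integer percent of strut thickness.

**Fusion.** Two orthographic projections at known gantry angles, at least 25°
apart (effective separation folds near 180°, where the system is equally
ill-conditioned). Corresponding points are paired at equal normalized arc
length; each pair gives a 2×2 linear solve for the transverse coordinates
(determinant = sin Δθ). Frames along the recovered centerline are
rotation-minimizing (double-reflection method), so no spurious axial twist is
introduced; the absolute rotation comes from the circular mean of landmark
angle pairs. Contours are mounted perpendicularly at 100 µm steps in the
scaffolded segment and 400 µm in native segments, by linear interpolation of
the frame radius profiles; placement is rigid (no scaling). Interpolation
finer than a quarter of the frame spacing is refused.

## 2. Hemodynamics

**Model.** Steady incompressible Navier-Stokes in an axisymmetric (z, r)
lumen. Blood is Newtonian with µ = 0.0035 Pa·s and ρ = 1050 kg/m³. Inlet:
parabolic (default) or flat profile at a prescribed mean velocity (default
0.13 m/s; `estimate_inlet_velocity` converts contrast-transit counts to a
mean velocity as volume × frame rate / frames / area). Outlet: zero reference
pressure. Flat inlets get an entrance extension of ten lumen diameters that
is cropped from the returned solution. Solves with inlet Reynolds number
above 2000 are rejected as outside laminar validity.

**Discretization.** Staggered MAC grid; explicit first-order upwind
convection with central diffusion; half-cell no-slip corrections at walls and
strut faces; incremental Chorin projection with a direct (sparse LU) solve of
the axisymmetric pressure Poisson equation — mass conservation is therefore
exact to round-off (the acceptance JSON reports flux mismatches of order
1e-16). Struts are rectangular rings resolved by blanking cells; the radial
grid is chosen so the wall and strut faces are grid-aligned. Target edge
length is strut thickness / 5 near the reference resolution; desk-scale runs
default to a 2× coarsening, which is logged. The mesher fails explicitly when
the cell budget would be exceeded rather than silently degrading.

**Convergence and validation.** Pseudo-time marching from a Poiseuille
initial state; convergence is declared when the windowed maximum velocity
change relative to the inlet mean falls below 1e-4. Wall shear stress uses a
one-sided second-order gradient, τ = µ(9u₁ − u₂)/(3Δr), with the signed axial
component retained so recirculation is visible. The strut-free cylinder
reproduces τ = 4µv/R within 1.3% at the default desk mesh (1.418 Pa vs
1.4 Pa at R = 1.5 mm, v = 0.15 m/s), and WSS is exactly linear in viscosity
on a fixed converged field.

## 3. ESS mapping

Wall elements are binned into 5° sectors × 200 µm axial intervals (half-open
bins; 72 sectors). Cell values are area-weighted means; uncovered cells are
masked, never imputed as zero, and all fractions are over covered cells.
Axisymmetric solutions are spread around the circumference with 1/72 of each
element's area per sector. Thresholds are strict: low ESS < 1.0 Pa, very low
< 0.5 Pa (very-low cells are a subset of low cells). Summaries exist at the
device, segment and cross-section (per-interval) levels.

## 4. Statistics

**Model.** ESS per sector = intercept + scaffold-type effect + centred
cross-sectional area + type × area interaction + nested random intercepts for
animal, scaffold-within-animal and cross-section-within-scaffold + sector
noise. Nesting is validated, not assumed.

**Fitter.** The fixed effects and residual variance are profiled out
analytically; only the three variance ratios are optimized (Nelder-Mead on
square-root coordinates, multiple starts). Per-animal Woodbury identities on
the low-rank random-effect design reduce each likelihood evaluation to small
dense solves, which is what makes a 200-replicate calibration study at full
study scale run in a few minutes. REML is the default for inference: with
few upper-level clusters (9 animals, 12 scaffolds in the reference layout)
plain ML biases the variance components down and makes the type test
anti-conservative — the suite's calibration run measures a type-I error rate
of 0.090 under ML and 0.045–0.060 under REML against the nominal 0.05.
Model selection across fixed-effect structures requires ML fits (`select_model`
refuses REML candidates); candidates are ranked by log-likelihood/AIC with
likelihood-ratio tests for nested pairs. Satterthwaite-style degrees of
freedom come from the delta method on the numeric Hessian of the variance
parameters, falling back to the normal approximation when the Hessian is not
positive definite (this happens when a variance component sits on the zero
boundary). The fitter is verified against `statsmodels.MixedLM` (ML and REML)
on the same data in the test suite; in the degenerate case of zero group
variances it reproduces OLS to machine precision.

**Generator fidelity.** The hierarchical generator draws exactly the model
above, with type assigned at the animal level — so type is confounded with
animal random effects in any single realization, exactly as in a real
animal study; the standard error prices this (single-realization estimates
can sit 1–2 SE from the injected effect without any bias). The reference
layout is 9 animals (6 with one thick-strut scaffold, 3 with two thin-strut
scaffolds), 38 cross-sections per scaffold, 72 sectors per cross-section;
default standard deviations 0.2 / 0.1 / 0.1 Pa for animal / scaffold /
cross-section intercepts and 0.5 Pa sector noise, grand mean 0.73 Pa,
injected type effect 0.79 Pa.

**Univariate companions.** Mann-Whitney (asymptotic, no continuity
correction), Kruskal-Wallis, χ² without Yates correction (expected counts
below 1 rejected), and a KS test against a normal with the sample's moments.

## 5. Parameters at a glance

| quantity | value |
|---|---|
| blood viscosity / density | 0.0035 Pa·s / 1050 kg/m³ |
| default inlet mean velocity | 0.13 m/s |
| low / very-low ESS | < 1.0 Pa / < 0.5 Pa (strict) |
| malapposition tolerance | 20 µm (strict >) |
| ESS grid | 5° × 200 µm, 72 sectors |
| contour mounting steps | 100 µm scaffolded / 400 µm native |
| minimum projection separation | 25° (folded near 180°) |
| mesh edge | thickness/5 × coarsening (default 2×) |
| thick preset (`absorb_like`) | 157 × 176 µm struts, 1.0 mm gaps |
| thin preset (`arteriosorb_like`) | 95 × 170 µm struts, 1.4 mm gaps |
| spacing rule of thumb | gap ≥ 6 × strut thickness |

## 6. Limitations

**Axisymmetric surrogate and the 6× recovery rule.** The flow stage models
every strut as a full annular ring. This is deliberate — it makes the solves
cheap, deterministic and grid-aligned, and it preserves the design ranking
(the thin, widely spaced design shows roughly double the inter-strut ESS and
half the very-low-ESS burden of the thick one under identical inflow). But it
exaggerates inter-strut shielding: the gap between two annular fences is a
closed cavity with a captive recirculation, so the WSS at the gap *midpoint*
stays low regardless of spacing (≈ 22% of the strut-free value at 3×
thickness spacing and ≈ 16% at 6× — not even monotone in spacing, because
the midpoint sits at different points of the cavity vortex). Downstream of an
*isolated* ring, where no second fence encloses the probe, recovery behaves
as the rule of thumb expects: ≈ 20% at 3 thicknesses, 65% at 6, 76% at 8 and
94% at 20 (all in the acceptance JSON). An 80% midpoint recovery at 6×
spacing is therefore unattainable in this geometry class, and the
corresponding acceptance assertion fails honestly rather than being weakened;
a discrete-strut 3-D solver would be required to test that clause faithfully.

**Other simplifications.**

- Steady flow only: no pulsatility, so oscillatory indices (OSI, RRT) are out
  of scope; the signed axial WSS is the only directionality retained.
- Newtonian blood; shear-thinning effects at the low inter-strut shear rates
  are not modelled.
- The lumen in the flow stage is straight and circular; curvature-induced
  secondary flow is not represented (the reconstruction stage does carry full
  3-D geometry, but `domain_from_surface` collapses it to mean radii).
- First-order upwinding adds numerical diffusion; the Poiseuille benchmark
  and the resolution consistency of the recovery curves bound its effect at
  the default meshes.
- OCT simulation has no catheter eccentricity, NURD, or segmentation noise
  beyond optional ovality; protrusion round-trip accuracy on clean synthetic
  contours is therefore an upper bound on real-data performance.
- The mixed model assumes Gaussian random effects and residuals and a common
  residual variance across types; the generator draws from the same family,
  so model misspecification is not exercised.
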