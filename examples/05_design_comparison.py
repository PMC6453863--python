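"""Head-to-head hemodynamic comparison of a thick-strut and a thin-strut
scaffold design under identical inlet flow.

The thick design (157 um struts, 1.0 mm gaps, 97% protrusion) shields the
inter-strut wall more than the thin one (95 um, 1.4 mm, 88%), so it shows a
lower mean inter-strut ESS and a larger low-ESS burden.  Also checks each
design against the six-thicknesses spacing rule of thumb and measures the
actual midpoint recovery in the axisymmetric surrogate.
"""

from strutflow.core import SEGMENT_SCAFFOLDED, SURFACE_WALL
from strutflow.ess import classify_ess, replicate_axisymmetric, sectorize
from strutflow.hemodynamics import (
    FlowConditions,
    compute_wss,
    downstream_recovery,
    generate_mesh,
    midpoint_recovery,
    scaffold_domain,
    solve_steady_flow,
)
from strutflow.oct import interstrut_recovery_check
from strutflow.synthetic import make_scaffold_design

conditions = FlowConditions()

for preset, fraction in [("absorb_like", 0.97), ("arteriosorb_like", 0.88)]:
    design = make_scaffold_design(preset)
    ok, margin = interstrut_recovery_check(design)
    print(f"\n{design.name}: {design.strut_thickness_um:.0f} um struts, "
          f"{design.inter_strut_distance_max_mm} mm gaps, "
          f"{100 * fraction:.0f}% protrusion")
    print(f"  6x-thickness spacing rule: "
          f"{'met' if ok else 'violated'} (margin {margin:+.0f} um)")

    domain = scaffold_domain(design, lumen_radius_mm=1.5,
                             protrusion_fraction=fraction, n_rings=8)
    mesh = generate_mesh(domain, design.strut_thickness_um, coarsening=2.0)
    sol = solve_steady_flow(mesh, conditions)
    wss = compute_wss(sol)
    inter = wss[(wss.segment == SEGMENT_SCAFFOLDED)
                & (wss.label == SURFACE_WALL)]
    s0, s1 = domain.scaffold_bounds_m
    emap = sectorize(replicate_axisymmetric(inter),
                     segment_bounds_um=(s0 * 1e6, s1 * 1e6))
    _, frac_low, frac_very_low = classify_ess(emap)
    print(f"  mean inter-strut ESS {inter.wss_pa.mean():.2f} Pa; "
          f"low (< 1 Pa) {100 * frac_low:.0f}% of cells, "
          f"very low (< 0.5 Pa) {100 * frac_very_low:.0f}%")
    print(f"  recirculating wall elements: "
          f"{(inter.signed_wss_pa < 0).sum()} of {len(inter)}")

print("\nmidpoint WSS recovery between square struts (157 um), relative to a "
      "strut-free wall:")
for mult in (3.0, 6.0):
    r = midpoint_recovery(157.0, mult)
    print(f"  spacing {mult:.0f}x thickness: {100 * r:.0f}%")

print("recovery downstream of a single isolated ring (no neighbour "
      "shielding the probe):")
for mult in (3.0, 6.0, 8.0, 20.0):
    r = downstream_recovery(157.0, mult)
    print(f"  {mult:.0f}x thickness downstream: {100 * r:.0f}%")
print("note: in the ring array every gap is a closed cavity between two "
      "annular fences, so midpoint recovery stays low regardless of spacing; "
      "the isolated-ring curve climbs toward the strut-free value as the "
      "rule of thumb expects (see docs/methods.md).")
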