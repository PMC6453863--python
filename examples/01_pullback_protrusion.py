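"""Simulate an OCT pullback over a scaffolded vessel and measure strut
protrusion through the analysis pipeline.

The generator plants struts with a known protrusion depth; the measurement
side only sees the contours and strut footprints, so the printed numbers are a
genuine round trip through the interpolation and classification code.
"""

from strutflow.oct import LEVEL_INTERVAL, aggregate_protrusion, measure_struts
from strutflow.synthetic import make_phantom, make_scaffold_design, simulate_pullback

phantom = make_phantom(length_mm=20.0, radius_mm=1.5, seed=1)
design = make_scaffold_design("absorb_like")
pullback = simulate_pullback(phantom, design, protrusion_fraction=0.97, seed=1)

print(f"pullback: {pullback.n_frames} frames at "
      f"{pullback.frame_spacing_um:.0f} um, {len(pullback.struts)} struts")

measured = measure_struts(pullback)
err = (measured.protrusion_um
       - pullback.struts.true_protrusion_um.to_numpy()).abs().max()
print(f"max |measured - true| protrusion: {err:.3f} um "
      "(sub-micron round trip)")
print("apposition labels:", measured.apposition.value_counts().to_dict())

device = aggregate_protrusion(pullback)
print(f"device level: mean protrusion {device.mean_um:.1f} um over "
      f"{device.n_struts} struts = {device.protrusion_fraction_pct}% of the "
      f"{design.strut_thickness_um:.0f} um strut thickness")
print(f"protrusion-to-lumen-diameter ratio: "
      f"{device.protrusion_to_lumen_ratio:.3f}")

per_interval = aggregate_protrusion(pullback, LEVEL_INTERVAL)
print(f"per-200um-interval means span "
      f"{per_interval['mean'].min():.1f}-{per_interval['mean'].max():.1f} um "
      f"across {len(per_interval)} intervals")
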