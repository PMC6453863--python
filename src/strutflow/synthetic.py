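"""Synthetic phantoms, pullbacks, projections and hierarchical ESS datasets.

Every generator is deterministic for a given seed, and every generated object
carries enough ground truth that the downstream stage can be validated by a
round trip (e.g. stored per-strut protrusion vs. protrusion re-measured on the
generated contours).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    SEGMENT_DISTAL,
    SEGMENT_PROXIMAL,
    SEGMENT_SCAFFOLDED,
    STRUT_COLUMNS,
    Contour,
    HierarchySpec,
    ProjectionPair,
    Pullback,
    ScaffoldDesign,
    VesselPhantom,
)

ABSORB_LIKE = "absorb_like"
ARTERIOSORB_LIKE = "arteriosorb_like"

#: device-family presets: quadratic (rectangular-section) strut scaffolds.
#: Absorb-like: 157 um thick, 176 um wide, 1.0 mm max inter-strut gap, 27%
#: vessel coverage.  ArterioSorb-like: 95 um thick, 170 um wide, 1.4 mm gap,
#: 29% coverage.
_PRESETS = {
    ABSORB_LIKE: dict(
        name=ABSORB_LIKE,
        strut_thickness_um=157.0,
        strut_width_um=176.0,
        inter_strut_distance_max_mm=1.0,
        coverage_ratio=0.27,
        n_rings=12,
        struts_per_ring=6,
    ),
    ARTERIOSORB_LIKE: dict(
        name=ARTERIOSORB_LIKE,
        strut_thickness_um=95.0,
        strut_width_um=170.0,
        inter_strut_distance_max_mm=1.4,
        coverage_ratio=0.29,
        n_rings=9,
        struts_per_ring=6,
    ),
}


def make_scaffold_design(preset: str, **overrides) -> ScaffoldDesign:
    """Return a fully populated scaffold design.

    ``preset`` is one of ``absorb_like``, ``arteriosorb_like`` or ``custom``;
    ``custom`` requires the geometric parameters to be passed explicitly.
    """
    if preset in _PRESETS:
        params = dict(_PRESETS[preset])
        params.update(overrides)
        return ScaffoldDesign(**params)
    if preset == "custom":
        missing = {"strut_thickness_um", "strut_width_um",
                   "inter_strut_distance_max_mm"} - set(overrides)
        if missing:
            raise ValueError(f"custom design requires {sorted(missing)}")
        overrides.setdefault("name", "custom")
        return ScaffoldDesign(**overrides)
    raise ValueError(f"unknown preset {preset!r}; "
                     f"choose from {sorted(_PRESETS)} or 'custom'")


def make_phantom(
    length_mm: float,
    radius_mm: float,
    curvature: float = 0.0,
    seed: int = 0,
    n_points: int = 400,
    native_margin_mm: float = 3.0,
    taper: float = 0.0,
) -> VesselPhantom:
    """Analytic vessel phantom with exact arc-length parametrization.

    ``curvature`` (1/mm) is the centerline curvature; zero gives a straight
    cylinder along z.  Nonzero curvature produces a gentle helix (torsion set
    to half the curvature) so that neither standard projection plane contains
    the curve.  ``taper`` is the fractional radius decrease from the proximal
    to the distal end.  One side-branch landmark is placed in the proximal
    native segment with a seeded angle.
    """
    if length_mm <= 0 or radius_mm <= 0 or curvature < 0:
        raise ValueError("length/radius must be positive, curvature >= 0")
    if not 0 <= taper < 1:
        raise ValueError("taper must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    s = np.linspace(0.0, length_mm, n_points)
    if curvature == 0.0:
        pts = np.column_stack([np.zeros_like(s), np.zeros_like(s), s])
    else:
        # circular helix: radius a, pitch slope b; curvature = a/(a^2+b^2),
        # torsion = b/(a^2+b^2); b = a/2 gives torsion = curvature/2.
        a = 0.8 / curvature
        b = 0.4 / curvature
        c = np.hypot(a, b)          # ds/dt
        t = s / c
        pts = np.column_stack([a * (1.0 - np.cos(t)), a * np.sin(t) - 0.0, b * t])
        # rotate so the initial tangent points along +z
        t0 = np.array([0.0, a, b]) / c
        z = np.array([0.0, 0.0, 1.0])
        v = np.cross(t0, z)
        sv = np.linalg.norm(v)
        if sv > 1e-12:
            cv = float(np.dot(t0, z))
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            rot = np.eye(3) + vx + vx @ vx * ((1 - cv) / sv**2)
            pts = pts @ rot.T
    radii = radius_mm * (1.0 - taper * s / length_mm)
    margin = min(native_margin_mm, length_mm / 4.0)
    bounds = {
        SEGMENT_PROXIMAL: (0.0, margin),
        SEGMENT_SCAFFOLDED: (margin, length_mm - margin),
        SEGMENT_DISTAL: (length_mm - margin, length_mm),
    }
    landmark_angle = float(rng.uniform(0.0, 360.0))
    landmarks = [(0.5 * margin, landmark_angle)]
    return VesselPhantom(
        centerline_mm=pts,
        arc_length_mm=s,
        lumen_radius_mm=radii,
        landmarks=landmarks,
        segment_bounds=bounds,
    )


def _ring_positions_um(design: ScaffoldDesign, scaffold_bounds_um: tuple) -> np.ndarray:
    """Axial centres of strut rings placed at the design pitch."""
    s0, s1 = scaffold_bounds_um
    pitch = design.ring_pitch_mm * 1000.0
    w = design.strut_width_um
    first = s0 + w / 2.0
    n_fit = int(np.floor((s1 - s0 - w) / pitch)) + 1
    n = min(design.n_rings, max(n_fit, 0))
    return first + pitch * np.arange(n)


def simulate_pullback(
    phantom: VesselPhantom,
    design: ScaffoldDesign,
    protrusion_fraction: float,
    frame_spacing_um: float = 200.0,
    seed: int = 0,
    strut_angular_span_deg: float = 25.0,
    ovality: float = 0.0,
    angular_step_deg: float = 1.0,
) -> Pullback:
    """Simulate an OCT pullback over a scaffolded phantom.

    Struts are placed on rings at the design pitch inside the scaffolded
    segment; each strut's adluminal edge sits at
    ``wall_radius - protrusion_fraction * strut_thickness``.  Fractions above
    1 produce malapposed struts (abluminal edge clear of the wall); the
    generated ground truth flags them.  ``ovality`` adds a small elliptic
    perturbation to each frame (fractional radius amplitude).
    """
    if not 0.0 <= protrusion_fraction <= 1.2:
        raise ValueError("protrusion_fraction must lie in [0, 1.2]")
    if frame_spacing_um <= 0:
        raise ValueError("frame_spacing_um must be positive")
    rng = np.random.default_rng(seed)
    t_um = design.strut_thickness_um
    depth = protrusion_fraction * t_um
    if depth >= phantom.lumen_radius_mm.min() * 1000.0:
        raise ValueError("protrusion deeper than the lumen radius")

    length_um = phantom.length_mm * 1000.0
    n_frames = int(np.floor(length_um / frame_spacing_um)) + 1
    angles = np.arange(0.0, 360.0, angular_step_deg)
    oval_phase = float(rng.uniform(0.0, 2 * np.pi))

    s0_mm, s1_mm = phantom.segment_bounds[SEGMENT_SCAFFOLDED]
    scaffold_bounds_um = (s0_mm * 1000.0, s1_mm * 1000.0)
    rings = _ring_positions_um(design, scaffold_bounds_um)
    w = design.strut_width_um

    contours = []
    strut_rows = []
    for k in range(n_frames):
        z = k * frame_spacing_um
        wall = phantom.radius_at(z / 1000.0) * 1000.0
        radii = wall * (1.0 + ovality * np.cos(2 * np.deg2rad(angles) + oval_phase))
        contours.append(Contour(k, z, angles.copy(), radii))

        hits = np.flatnonzero(np.abs(rings - z) <= w / 2.0)
        for ring_idx in hits:
            offset = 0.0 if ring_idx % 2 == 0 else 180.0 / design.struts_per_ring
            centers = (offset + 360.0 * np.arange(design.struts_per_ring)
                       / design.struts_per_ring) % 360.0
            for ang in np.sort(centers):
                wall_here = float(
                    np.interp(ang % 360.0,
                              np.concatenate([angles, [360.0]]),
                              np.concatenate([radii, [radii[0]]]))
                )
                adl = wall_here - depth
                strut_rows.append(dict(
                    frame_index=k,
                    angle_center_deg=float(ang),
                    angular_span_deg=strut_angular_span_deg,
                    adluminal_radius_um=adl,
                    abluminal_radius_um=adl + t_um,
                    true_protrusion_um=depth,
                    true_malapposed=bool(protrusion_fraction > 1.0),
                ))

    struts = pd.DataFrame(strut_rows, columns=STRUT_COLUMNS)
    return Pullback(
        contours=contours,
        struts=struts,
        frame_spacing_um=frame_spacing_um,
        scaffold_bounds_um=scaffold_bounds_um,
        design=design,
        protrusion_fraction=protrusion_fraction,
        meta=dict(seed=seed, ovality=ovality,
                  strut_angular_span_deg=strut_angular_span_deg,
                  landmarks=list(phantom.landmarks)),
    )


def project_centerline(
    phantom: VesselPhantom,
    angle_a_deg: float,
    angle_b_deg: float,
    calibration_mm_per_px: float = 0.08,
) -> ProjectionPair:
    """Orthographic biplane projections of the phantom centerline.

    Gantry angle ``theta`` views along the direction
    ``(cos theta, sin theta, 0)``; the projected 2D coordinates are
    ``(p . u(theta), p . z)`` with in-plane axis
    ``u(theta) = (-sin theta, cos theta, 0)``.
    """
    d = abs(angle_a_deg - angle_b_deg) % 180.0
    if min(d, 180.0 - d) < 1e-9:
        raise ValueError("degenerate projection pair: identical viewing axes")

    def _project(theta_deg: float) -> np.ndarray:
        th = np.deg2rad(theta_deg)
        u = np.array([-np.sin(th), np.cos(th), 0.0])
        pts = phantom.centerline_mm
        return np.column_stack([pts @ u, pts[:, 2]])

    return ProjectionPair(
        polyline_a_mm=_project(angle_a_deg),
        polyline_b_mm=_project(angle_b_deg),
        angle_a_deg=angle_a_deg,
        angle_b_deg=angle_b_deg,
        calibration_mm_per_px=calibration_mm_per_px,
    )


def paper_hierarchy_spec(**overrides) -> HierarchySpec:
    """Study-scale hierarchy: 9 animals, 12 scaffolds (6 animals with one
    Absorb-like device, 3 animals with two ArterioSorb-like devices),
    ~38 cross-sections per scaffold and 72 five-degree sectors each."""
    allocation = tuple(
        [(ABSORB_LIKE,)] * 6 + [(ARTERIOSORB_LIKE, ARTERIOSORB_LIKE)] * 3
    )
    params = dict(n_animals=9, allocation=allocation)
    params.update(overrides)
    return HierarchySpec(**params)


def simulate_hierarchical_ess(spec: HierarchySpec):
    """Draw sector-level ESS records from the nested generative model.

    Returns ``(records, truth)`` where ``records`` is a long-format DataFrame
    (one row per 5-degree sector) and ``truth`` holds the drawn random effects
    and the fixed-effect parameters actually used.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.allocation is not None:
        alloc = [list(a) for a in spec.allocation]
        if len(alloc) != spec.n_animals:
            raise ValueError("allocation length must equal n_animals")
    else:
        # type assigned at animal level, first half absorb-like
        n_abs = (spec.n_animals + 1) // 2
        alloc = [
            [ABSORB_LIKE if i < n_abs else ARTERIOSORB_LIKE] * spec.scaffolds_per_animal
            for i in range(spec.n_animals)
        ]

    rows = []
    animal_effects = {}
    scaffold_effects = {}
    scaffold_id = 0
    n_sec = spec.sectors_per_cross_section
    cs_id = 0
    for i, types in enumerate(alloc):
        a_eff = rng.normal(0.0, spec.sd_animal_pa)
        animal_effects[i] = a_eff
        for typ in types:
            s_eff = rng.normal(0.0, spec.sd_scaffold_pa)
            scaffold_effects[scaffold_id] = s_eff
            delta = spec.fixed_effect_delta_pa if typ == ARTERIOSORB_LIKE else 0.0
            for _ in range(spec.cross_sections_per_scaffold):
                c_eff = rng.normal(0.0, spec.sd_cross_section_pa)
                csa = rng.normal(spec.csa_mean_mm2, spec.csa_sd_mm2)
                noise = rng.normal(0.0, spec.sd_sector_pa, size=n_sec)
                ess = spec.grand_mean_pa + delta + a_eff + s_eff + c_eff + noise
                rows.append(pd.DataFrame({
                    "animal_id": i,
                    "scaffold_id": scaffold_id,
                    "cross_section_id": cs_id,
                    "sector_id": np.arange(n_sec),
                    "scaffold_type": typ,
                    "cross_sectional_area": csa,
                    "ess": ess,
                }))
                cs_id += 1
            scaffold_id += 1
    records = pd.concat(rows, ignore_index=True)
    truth = dict(
        grand_mean_pa=spec.grand_mean_pa,
        fixed_effect_delta_pa=spec.fixed_effect_delta_pa,
        animal_effects=animal_effects,
        scaffold_effects=scaffold_effects,
        sd_animal_pa=spec.sd_animal_pa,
        sd_scaffold_pa=spec.sd_scaffold_pa,
        sd_cross_section_pa=spec.sd_cross_section_pa,
        sd_sector_pa=spec.sd_sector_pa,
    )
    return records, truth


# ---------------------------------------------------------------------------
# plain-text export/import (hand-editable dialect, also usable for real data)
# ---------------------------------------------------------------------------

def write_pullback(pullback: Pullback, out_dir) -> None:
    """Write a pullback as JSON metadata + two CSVs (contour points, struts)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for c in pullback.contours:
        rows.append(pd.DataFrame({
            "frame": c.frame_index,
            "angle_deg": c.angles_deg,
            "radius_um": c.radii_um,
        }))
    pd.concat(rows, ignore_index=True).to_csv(out / "contours.csv", index=False)
    pullback.struts.to_csv(out / "struts.csv", index=False)
    design = pullback.design
    meta = dict(
        frame_spacing_um=pullback.frame_spacing_um,
        scaffold_bounds_um=list(pullback.scaffold_bounds_um),
        protrusion_fraction=pullback.protrusion_fraction,
        design=None if design is None else dict(
            name=design.name,
            strut_thickness_um=design.strut_thickness_um,
            strut_width_um=design.strut_width_um,
            inter_strut_distance_max_mm=design.inter_strut_distance_max_mm,
            n_rings=design.n_rings,
            struts_per_ring=design.struts_per_ring,
            coverage_ratio=design.coverage_ratio,
        ),
        meta={k: v for k, v in pullback.meta.items() if k != "landmarks"},
        landmarks=[list(lm) for lm in pullback.meta.get("landmarks", [])],
    )
    (out / "pullback.json").write_text(json.dumps(meta, indent=2))


def read_pullback(in_dir) -> Pullback:
    src = Path(in_dir)
    meta = json.loads((src / "pullback.json").read_text())
    pts = pd.read_csv(src / "contours.csv")
    struts = pd.read_csv(src / "struts.csv")
    spacing = float(meta["frame_spacing_um"])
    contours = []
    for k, grp in pts.groupby("frame", sort=True):
        contours.append(Contour(int(k), int(k) * spacing,
                                grp["angle_deg"].to_numpy(),
                                grp["radius_um"].to_numpy()))
    design = None
    if meta.get("design"):
        design = ScaffoldDesign(**meta["design"])
    pb_meta = dict(meta.get("meta", {}))
    pb_meta["landmarks"] = [tuple(lm) for lm in meta.get("landmarks", [])]
    return Pullback(
        contours=contours,
        struts=struts,
        frame_spacing_um=spacing,
        scaffold_bounds_um=tuple(meta["scaffold_bounds_um"]),
        design=design,
        protrusion_fraction=meta.get("protrusion_fraction"),
        meta=pb_meta,
    )


def write_projection_pair(pair: ProjectionPair, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for tag, poly in [("a", pair.polyline_a_mm), ("b", pair.polyline_b_mm)]:
        pd.DataFrame(poly, columns=["u_mm", "z_mm"]).to_csv(
            out / f"projection_{tag}.csv", index=False)
    (out / "projections.json").write_text(json.dumps(dict(
        angle_a_deg=pair.angle_a_deg,
        angle_b_deg=pair.angle_b_deg,
        calibration_mm_per_px=pair.calibration_mm_per_px,
    ), indent=2))


def read_projection_pair(in_dir) -> ProjectionPair:
    src = Path(in_dir)
    meta = json.loads((src / "projections.json").read_text())
    a = pd.read_csv(src / "projection_a.csv").to_numpy()
    b = pd.read_csv(src / "projection_b.csv").to_numpy()
    return ProjectionPair(polyline_a_mm=a, polyline_b_mm=b, **meta)
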