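"""Flow-area contour construction and strut protrusion morphometry.

The lumen contour traced between struts is the vessel wall; inside a strut's
angular footprint the flow boundary is the strut's adluminal (lumen-facing)
edge.  Protrusion is the radial distance between the wall — linearly
interpolated across the hidden footprint from the flanking contour samples —
and the adluminal edge.  Malapposition is an abluminal-edge-to-wall gap larger
than a tolerance (default 20 µm, about the axial OCT resolution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    APPOSITION_EMBEDDED,
    APPOSITION_MALAPPOSED,
    APPOSITION_PROTRUDING,
    Contour,
    Pullback,
    ScaffoldDesign,
    StrutObservation,
)

MALAPPOSITION_TOLERANCE_UM = 20.0

LEVEL_INTERVAL = "interval_200um"
LEVEL_CROSS_SECTION = "cross_section"
LEVEL_DEVICE = "device"

INTERVAL_UM = 200.0


@dataclass
class ProtrusionSummary:
    level: str
    n_struts: int
    mean_um: float
    sd_um: float
    protrusion_fraction_pct: int
    protrusion_to_lumen_ratio: float

    def __post_init__(self) -> None:
        if self.n_struts < 1:
            raise ValueError("summary requires at least one strut")


def _span_bounds(strut: StrutObservation) -> tuple:
    half = strut.angular_span_deg / 2.0
    return strut.angle_center_deg - half, strut.angle_center_deg + half


def _in_span(angles_deg: np.ndarray, strut: StrutObservation) -> np.ndarray:
    """Membership of angles in the strut footprint, handling 0/360 wrap."""
    lo, hi = _span_bounds(strut)
    a = np.asarray(angles_deg) % 360.0
    lo %= 360.0
    hi %= 360.0
    if lo <= hi:
        return (a >= lo) & (a < hi)
    return (a >= lo) | (a < hi)


def _spans_overlap(struts) -> bool:
    ivals = []
    for s in struts:
        lo, hi = _span_bounds(s)
        lo %= 360.0
        hi %= 360.0
        if lo <= hi:
            ivals.append((lo, hi))
        else:
            ivals.append((lo, 360.0))
            ivals.append((0.0, hi))
    ivals.sort()
    for (l1, h1), (l2, _) in zip(ivals, ivals[1:]):
        if l2 < h1 - 1e-9:
            return True
    return False


def _wall_radius_under(strut: StrutObservation, contour: Contour,
                       angle_deg: float) -> float:
    """Wall radius at ``angle_deg`` by linear interpolation between the two
    contour samples flanking the strut footprint (the wall under the strut is
    shadowed in OCT, so only the flanks are trusted)."""
    lo, hi = _span_bounds(strut)
    step = float(np.median(np.diff(contour.angles_deg)))
    span = hi - lo
    if span > 360.0 - 2 * step:
        raise ValueError("contour gap wider than strut span; cannot interpolate")
    r_lo = float(contour.radius_at(lo))
    r_hi = float(contour.radius_at(hi))
    # unwrap the query angle relative to the span start
    ang = (angle_deg - lo) % 360.0
    frac = np.clip(ang / span, 0.0, 1.0)
    return r_lo + (r_hi - r_lo) * float(frac)


def build_flow_area_contour(contour: Contour, struts) -> Contour:
    """Replace the wall trace inside each strut footprint with the strut's
    adluminal edge, yielding the flow-area contour."""
    if _spans_overlap(struts):
        raise ValueError("strut angular spans overlap")
    radii = contour.radii_um.copy()
    for s in struts:
        mask = _in_span(contour.angles_deg, s)
        if np.any(radii[mask] < s.adluminal_radius_um - 1e-9):
            raise ValueError(
                "inverted geometry: adluminal radius exceeds the wall radius "
                f"inside the span of strut at {s.angle_center_deg:.1f} deg"
            )
        radii[mask] = s.adluminal_radius_um
    return Contour(contour.frame_index, contour.axial_position_um,
                   contour.angles_deg.copy(), radii)


def protrusion_distance(strut: StrutObservation, contour: Contour) -> float:
    """Radial protrusion of the strut above the interpolated wall, in µm,
    floored at zero (struts embedded below the wall protrude 0)."""
    wall = _wall_radius_under(strut, contour, strut.angle_center_deg)
    return max(wall - strut.adluminal_radius_um, 0.0)


def classify_apposition(
    strut: StrutObservation,
    contour: Contour,
    strut_thickness_um: float,
    tolerance_um: float = MALAPPOSITION_TOLERANCE_UM,
) -> str:
    """Label a strut embedded / protruding / malapposed.

    Malapposed iff the abluminal edge stands clear of the wall by strictly
    more than ``tolerance_um``; gaps at or below the tolerance are treated as
    apposed (resolution-limited).
    """
    wall = _wall_radius_under(strut, contour, strut.angle_center_deg)
    gap = wall - strut.abluminal_radius_um
    if gap > tolerance_um:
        return APPOSITION_MALAPPOSED
    if protrusion_distance(strut, contour) > 0.0:
        return APPOSITION_PROTRUDING
    return APPOSITION_EMBEDDED


def measure_struts(pullback: Pullback,
                   tolerance_um: float = MALAPPOSITION_TOLERANCE_UM) -> pd.DataFrame:
    """Per-strut table with measured protrusion, apposition label, axial
    position and the 200 µm interval index (0-based from the first scaffolded
    frame, half-open bins)."""
    t_um = pullback.design.strut_thickness_um if pullback.design else np.nan
    s0 = pullback.scaffold_bounds_um[0]
    rows = []
    for c in pullback.contours:
        struts = pullback.struts_for_frame(c.frame_index)
        for s in struts:
            p = protrusion_distance(s, c)
            label = classify_apposition(s, c, t_um, tolerance_um)
            rows.append(dict(
                frame_index=c.frame_index,
                axial_position_um=c.axial_position_um,
                interval=int(np.floor((c.axial_position_um - s0) / INTERVAL_UM)),
                angle_center_deg=s.angle_center_deg,
                protrusion_um=p,
                apposition=label,
                lumen_diameter_um=2.0 * float(np.mean(c.radii_um)),
            ))
    cols = ["frame_index", "axial_position_um", "interval", "angle_center_deg",
            "protrusion_um", "apposition", "lumen_diameter_um"]
    return pd.DataFrame(rows, columns=cols)


def _summarize(df: pd.DataFrame, level: str, thickness_um: float) -> ProtrusionSummary:
    mean = float(df["mean"].mean())
    sd = float(df["mean"].std(ddof=1)) if len(df) > 1 else 0.0
    n = int(df["n"].sum())
    lumen = float(df["lumen_diameter_um"].mean())
    return ProtrusionSummary(
        level=level,
        n_struts=n,
        mean_um=mean,
        sd_um=sd,
        protrusion_fraction_pct=protrusion_fraction(mean, thickness_um),
        protrusion_to_lumen_ratio=mean / lumen,
    )


def aggregate_protrusion(pullback: Pullback, level: str = LEVEL_DEVICE,
                         tolerance_um: float = MALAPPOSITION_TOLERANCE_UM):
    """Protrusion statistics at the requested level.

    Malapposed struts are excluded.  Struts are first averaged within each
    200 µm half-open interval; ``cross_section`` returns per-frame statistics,
    ``interval_200um`` per-interval statistics (both as DataFrames), and
    ``device`` a single :class:`ProtrusionSummary` over interval means.
    """
    if level not in (LEVEL_INTERVAL, LEVEL_CROSS_SECTION, LEVEL_DEVICE):
        raise ValueError(f"unknown level {level!r}")
    measured = measure_struts(pullback, tolerance_um)
    apposed = measured[measured["apposition"] != APPOSITION_MALAPPOSED]
    if apposed.empty:
        raise ValueError("no apposed struts at the requested level")
    t_um = pullback.design.strut_thickness_um if pullback.design else np.nan

    key = "frame_index" if level == LEVEL_CROSS_SECTION else "interval"
    grouped = apposed.groupby(key).agg(
        mean=("protrusion_um", "mean"),
        sd=("protrusion_um", lambda x: x.std(ddof=1) if len(x) > 1 else 0.0),
        n=("protrusion_um", "size"),
        lumen_diameter_um=("lumen_diameter_um", "mean"),
    ).reset_index()
    if level == LEVEL_DEVICE:
        return _summarize(grouped, LEVEL_DEVICE, t_um)
    grouped["protrusion_fraction_pct"] = [
        protrusion_fraction(m, t_um) for m in grouped["mean"]
    ]
    grouped["protrusion_to_lumen_ratio"] = grouped["mean"] / grouped["lumen_diameter_um"]
    return grouped


def protrusion_fraction(mean_protrusion_um: float, strut_thickness_um: float) -> int:
    """Protrusion as an integer percent of the strut thickness."""
    if strut_thickness_um <= 0:
        raise ValueError("strut thickness must be positive")
    return int(round(100.0 * mean_protrusion_um / strut_thickness_um))


def interstrut_recovery_check(design: ScaffoldDesign) -> tuple:
    """Design rule: the inter-strut distance should be at least six times the
    strut thickness for the laminar profile to recover between struts.

    Returns ``(passes, margin_um)`` where the margin is the gap minus six
    thicknesses.
    """
    gap_um = design.inter_strut_distance_max_mm * 1000.0
    required = 6.0 * design.strut_thickness_um
    margin = gap_um - required
    return margin >= 0.0, margin
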