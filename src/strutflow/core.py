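"""Shared data containers for the scaffold shear-stress pipeline.

Unit conventions
----------------
Strut- and contour-scale quantities are carried in micrometres (µm), vessel-
scale geometry in millimetres (mm).  The flow solver works in SI internally;
conversions happen at module boundaries.  Angles are degrees externally,
radians inside numerical routines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

APPOSITION_EMBEDDED = "embedded"
APPOSITION_PROTRUDING = "protruding"
APPOSITION_MALAPPOSED = "malapposed"

SEGMENT_SCAFFOLDED = "scaffolded"
SEGMENT_PROXIMAL = "proximal_native"
SEGMENT_DISTAL = "distal_native"

SURFACE_NATIVE = "native"
SURFACE_WALL = "inter_strut_wall"
SURFACE_STRUT = "strut_adluminal"


@dataclass(frozen=True)
class ScaffoldDesign:
    """Strut geometry and spacing parameters defining a device family.

    ``inter_strut_distance_max_mm`` is the largest wall exposure (gap)
    between the edges of consecutive strut rings; it governs how far the
    laminar profile can recover between struts.
    """

    name: str
    strut_thickness_um: float
    strut_width_um: float
    inter_strut_distance_max_mm: float
    n_rings: int = 10
    struts_per_ring: int = 6
    coverage_ratio: float = 0.25

    def __post_init__(self) -> None:
        if self.strut_thickness_um <= 0:
            raise ValueError("strut_thickness_um must be positive")
        if self.strut_width_um <= 0:
            raise ValueError("strut_width_um must be positive")
        if self.inter_strut_distance_max_mm * 1000.0 <= self.strut_width_um:
            raise ValueError(
                "inter-strut distance must exceed the strut width "
                f"({self.inter_strut_distance_max_mm} mm vs "
                f"{self.strut_width_um} um)"
            )
        if not 0.0 < self.coverage_ratio < 1.0:
            raise ValueError("coverage_ratio must lie in (0, 1)")
        if self.n_rings < 1 or self.struts_per_ring < 1:
            raise ValueError("ring counts must be >= 1")

    @property
    def ring_pitch_mm(self) -> float:
        """Centre-to-centre axial spacing of consecutive strut rings."""
        return self.inter_strut_distance_max_mm + self.strut_width_um / 1000.0


@dataclass
class Contour:
    """A closed lumen (or flow-area) contour in catheter-centred polar form."""

    frame_index: int
    axial_position_um: float
    angles_deg: np.ndarray
    radii_um: np.ndarray

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.radii_um = np.asarray(self.radii_um, dtype=float)
        if self.angles_deg.ndim != 1 or self.angles_deg.shape != self.radii_um.shape:
            raise ValueError("angles and radii must be matching 1-D arrays")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("contour angles must be strictly increasing")
        if self.angles_deg[0] < 0 or self.angles_deg[-1] >= 360.0:
            raise ValueError("contour angles must cover [0, 360) once")
        if np.any(self.radii_um <= 0):
            raise ValueError("contour radii must be positive")

    def points_xy_um(self) -> np.ndarray:
        a = np.deg2rad(self.angles_deg)
        return np.column_stack([self.radii_um * np.cos(a), self.radii_um * np.sin(a)])

    def area_um2(self) -> float:
        """Enclosed area by the shoelace rule on the closed polygon."""
        p = self.points_xy_um()
        x, y = p[:, 0], p[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    def is_simple(self) -> bool:
        from shapely.geometry import Polygon

        return Polygon(self.points_xy_um()).is_valid

    def radius_at(self, angle_deg: float | np.ndarray) -> np.ndarray:
        """Wall radius at arbitrary angles by periodic linear interpolation."""
        ang = np.asarray(angle_deg, dtype=float) % 360.0
        xp = np.concatenate([self.angles_deg, [self.angles_deg[0] + 360.0]])
        fp = np.concatenate([self.radii_um, [self.radii_um[0]]])
        return np.interp(ang, xp, fp)


@dataclass
class StrutObservation:
    """One strut footprint in one OCT frame."""

    frame_index: int
    angle_center_deg: float
    angular_span_deg: float
    adluminal_radius_um: float
    abluminal_radius_um: float
    apposition: Optional[str] = None
    protrusion_distance_um: Optional[float] = None

    def __post_init__(self) -> None:
        if self.abluminal_radius_um < self.adluminal_radius_um:
            raise ValueError("abluminal radius must be >= adluminal radius")
        if not 0 < self.angular_span_deg < 360:
            raise ValueError("angular span must lie in (0, 360)")


#: column layout of the per-strut table carried by a :class:`Pullback`
STRUT_COLUMNS = [
    "frame_index",
    "angle_center_deg",
    "angular_span_deg",
    "adluminal_radius_um",
    "abluminal_radius_um",
    "true_protrusion_um",
    "true_malapposed",
]


@dataclass
class Pullback:
    """Ordered per-frame lumen contours with strut annotations.

    ``struts`` is a long-format table (one row per strut observation, see
    :data:`STRUT_COLUMNS`); synthetic pullbacks additionally carry the
    generator ground truth per strut for recovery tests.
    """

    contours: list
    struts: pd.DataFrame
    frame_spacing_um: float
    scaffold_bounds_um: tuple
    design: Optional[ScaffoldDesign] = None
    protrusion_fraction: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ["frame_index", "angle_center_deg", "angular_span_deg",
                    "adluminal_radius_um", "abluminal_radius_um"]:
            if col not in self.struts.columns:
                raise ValueError(f"strut table missing column {col!r}")

    @property
    def n_frames(self) -> int:
        return len(self.contours)

    def contour_for_frame(self, frame_index: int) -> Contour:
        return self.contours[frame_index]

    def struts_for_frame(self, frame_index: int) -> list:
        rows = self.struts[self.struts["frame_index"] == frame_index]
        return [
            StrutObservation(
                frame_index=int(r.frame_index),
                angle_center_deg=float(r.angle_center_deg),
                angular_span_deg=float(r.angular_span_deg),
                adluminal_radius_um=float(r.adluminal_radius_um),
                abluminal_radius_um=float(r.abluminal_radius_um),
            )
            for r in rows.itertuples()
        ]

    def segment_of(self, axial_position_um: float) -> str:
        s0, s1 = self.scaffold_bounds_um
        if axial_position_um < s0:
            return SEGMENT_PROXIMAL
        if axial_position_um < s1:
            return SEGMENT_SCAFFOLDED
        return SEGMENT_DISTAL


@dataclass
class VesselPhantom:
    """Analytic ground-truth vessel used to exercise the pipeline."""

    centerline_mm: np.ndarray          # (N, 3), ordered proximal -> distal
    arc_length_mm: np.ndarray          # (N,), strictly increasing from 0
    lumen_radius_mm: np.ndarray        # (N,), radius per arc-length sample
    landmarks: list                    # [(arc_length_mm, angle_deg), ...]
    segment_bounds: dict               # segment label -> (s0_mm, s1_mm)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.arc_length_mm) <= 0):
            raise ValueError("arc length must be strictly increasing")
        if np.any(self.lumen_radius_mm <= 0):
            raise ValueError("lumen radii must be positive")
        s0, s1 = self.segment_bounds[SEGMENT_SCAFFOLDED]
        if s0 < self.arc_length_mm[0] - 1e-9 or s1 > self.arc_length_mm[-1] + 1e-9:
            raise ValueError("scaffolded range must lie inside the phantom")

    @property
    def length_mm(self) -> float:
        return float(self.arc_length_mm[-1])

    def radius_at(self, s_mm: float | np.ndarray) -> np.ndarray:
        return np.interp(s_mm, self.arc_length_mm, self.lumen_radius_mm)

    def point_at(self, s_mm: float | np.ndarray) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s_mm, dtype=float))
        out = np.column_stack([
            np.interp(s, self.arc_length_mm, self.centerline_mm[:, k])
            for k in range(3)
        ])
        return out[0] if np.isscalar(s_mm) else out


@dataclass
class ProjectionPair:
    """Two orthographic projections of a 3D centerline at known gantry angles."""

    polyline_a_mm: np.ndarray
    polyline_b_mm: np.ndarray
    angle_a_deg: float
    angle_b_deg: float
    calibration_mm_per_px: float = 0.08

    def separation_deg(self) -> float:
        d = abs(self.angle_a_deg - self.angle_b_deg) % 360.0
        return min(d, 360.0 - d)


@dataclass
class Centerline3D:
    points_mm: np.ndarray
    arc_length_mm: np.ndarray
    tangents: Optional[np.ndarray] = None
    normals: Optional[np.ndarray] = None
    binormals: Optional[np.ndarray] = None
    residual_mm: Optional[float] = None

    @property
    def length_mm(self) -> float:
        return float(self.arc_length_mm[-1])


@dataclass
class LumenSurface:
    """Triangulated lumen surface with per-vertex provenance labels."""

    vertices_mm: np.ndarray            # (V, 3)
    faces: np.ndarray                  # (F, 3) int
    labels: np.ndarray                 # (V,) str in {native, inter_strut_wall, strut_adluminal}
    axial_um: np.ndarray               # (V,) axial position along the pullback
    sector_angle_deg: np.ndarray       # (V,) mounted-frame angle in [0, 360)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices_mm)


@dataclass(frozen=True)
class HierarchySpec:
    """Generative twin of the three-level study hierarchy.

    ESS per 5-degree sector = grand mean + scaffold-type effect + nested
    random intercepts (animal / scaffold / cross-section) + sector noise.
    """

    n_animals: int = 9
    scaffolds_per_animal: int = 1
    cross_sections_per_scaffold: int = 38
    sectors_per_cross_section: int = 72
    sd_animal_pa: float = 0.2
    sd_scaffold_pa: float = 0.1
    sd_cross_section_pa: float = 0.1
    sd_sector_pa: float = 0.5
    fixed_effect_delta_pa: float = 0.79
    grand_mean_pa: float = 0.73
    csa_mean_mm2: float = 7.5
    csa_sd_mm2: float = 1.0
    seed: int = 0
    # optional explicit per-animal allocation: list of lists of scaffold types,
    # e.g. the study layout 6 x ["absorb_like"] + 3 x 2*["arteriosorb_like"]
    allocation: Optional[tuple] = None

    def __post_init__(self) -> None:
        for f in ["sd_animal_pa", "sd_scaffold_pa", "sd_cross_section_pa", "sd_sector_pa"]:
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        for f in ["n_animals", "scaffolds_per_animal", "cross_sections_per_scaffold",
                  "sectors_per_cross_section"]:
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")
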