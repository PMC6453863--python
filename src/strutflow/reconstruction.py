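"""3D lumen reconstruction from biplane projections and OCT contours.

The centerline is recovered from two orthographic projections with at least
25 degrees of angular separation, point correspondence being established by
normalized arc length along the two polylines.  OCT flow-area contours are
then mounted perpendicularly onto the centerline using rotation-minimizing
frames; a single global rotation, estimated from side-branch landmarks seen
in both modalities, fixes the absolute orientation.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .core import (
    SEGMENT_SCAFFOLDED,
    SURFACE_NATIVE,
    SURFACE_STRUT,
    SURFACE_WALL,
    Centerline3D,
    Contour,
    LumenSurface,
    ProjectionPair,
    Pullback,
)
from .oct import _in_span, build_flow_area_contour

MIN_PROJECTION_SEPARATION_DEG = 25.0


def _polyline_arclength(poly: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _resample_polyline(poly: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    s = _polyline_arclength(poly)
    target = fractions * s[-1]
    return np.column_stack([np.interp(target, s, poly[:, k]) for k in range(poly.shape[1])])


def reconstruct_centerline_3d(
    pair: ProjectionPair,
    step_mm: float = 0.1,
    n_stations: int = 400,
) -> Centerline3D:
    """Recover the 3D luminal centerline from a biplane projection pair.

    Corresponding points on the two polylines are paired at equal normalized
    arc length; each pair yields a 2x2 linear system for the transverse (x, y)
    coordinates while the longitudinal coordinate is shared.  The result is
    resampled to a uniform arc-length step and the mean back-projection
    residual is stored.
    """
    sep = pair.separation_deg()
    eff = min(sep, 180.0 - min(sep, 180.0)) if sep > 90.0 else sep
    # fold: separations near 0 or near 180 both give ill-conditioned systems
    if eff < MIN_PROJECTION_SEPARATION_DEG:
        raise ValueError(
            f"projection angles only {sep:.1f} deg apart (effective {eff:.1f}); "
            f"at least {MIN_PROJECTION_SEPARATION_DEG} deg required"
        )
    la = _polyline_arclength(pair.polyline_a_mm)[-1]
    lb = _polyline_arclength(pair.polyline_b_mm)[-1]
    if abs(la - lb) > 0.2 * max(la, lb):
        raise ValueError(
            f"projected polyline lengths differ by more than 20% "
            f"({la:.2f} vs {lb:.2f} mm); check calibration/ordering"
        )

    fr = np.linspace(0.0, 1.0, n_stations)
    a = _resample_polyline(pair.polyline_a_mm, fr)
    b = _resample_polyline(pair.polyline_b_mm, fr)

    tha, thb = np.deg2rad(pair.angle_a_deg), np.deg2rad(pair.angle_b_deg)
    m = np.array([[-np.sin(tha), np.cos(tha)],
                  [-np.sin(thb), np.cos(thb)]])
    xy = np.linalg.solve(m, np.column_stack([a[:, 0], b[:, 0]]).T).T
    z = 0.5 * (a[:, 1] + b[:, 1])
    pts = np.column_stack([xy, z])

    # back-projection residual (in-plane coordinate mismatch)
    ua = pts[:, :2] @ np.array([-np.sin(tha), np.cos(tha)])
    ub = pts[:, :2] @ np.array([-np.sin(thb), np.cos(thb)])
    residual = float(np.mean(np.hypot(ua - a[:, 0], ub - b[:, 0])))

    s = _polyline_arclength(pts)
    n_out = max(int(np.round(s[-1] / step_mm)) + 1, 2)
    s_out = np.linspace(0.0, s[-1], n_out)
    pts_out = np.column_stack([np.interp(s_out, s, pts[:, k]) for k in range(3)])
    return Centerline3D(points_mm=pts_out, arc_length_mm=s_out, residual_mm=residual)


def compute_local_frames(centerline: Centerline3D) -> Centerline3D:
    """Attach rotation-minimizing orthonormal frames (double-reflection method).

    Tangents come from central differences; the normal is propagated with the
    double-reflection rule so consecutive frames carry no spurious axial twist.
    A straight centerline gets constant frames.
    """
    pts = centerline.points_mm
    if len(pts) < 3:
        raise ValueError("need at least three centerline points")
    if np.any(np.linalg.norm(np.diff(pts, axis=0), axis=1) < 1e-12):
        raise ValueError("duplicate consecutive centerline points")

    tangents = np.gradient(pts, centerline.arc_length_mm, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)

    normals = np.empty_like(pts)
    # initial normal: project the least-aligned coordinate axis
    axis = np.eye(3)[np.argmin(np.abs(tangents[0]))]
    n0 = axis - np.dot(axis, tangents[0]) * tangents[0]
    normals[0] = n0 / np.linalg.norm(n0)
    for i in range(len(pts) - 1):
        # double reflection (Wang et al.): reflect across the chord bisector,
        # then across the bisector of the reflected and next tangent
        v1 = pts[i + 1] - pts[i]
        c1 = float(np.dot(v1, v1))
        rl = normals[i] - (2.0 / c1) * np.dot(v1, normals[i]) * v1
        tl = tangents[i] - (2.0 / c1) * np.dot(v1, tangents[i]) * v1
        v2 = tangents[i + 1] - tl
        c2 = float(np.dot(v2, v2))
        n = rl if c2 < 1e-14 else rl - (2.0 / c2) * np.dot(v2, rl) * v2
        n = n - np.dot(n, tangents[i + 1]) * tangents[i + 1]
        normals[i + 1] = n / np.linalg.norm(n)
    binormals = np.cross(tangents, normals)
    return Centerline3D(
        points_mm=pts,
        arc_length_mm=centerline.arc_length_mm,
        tangents=tangents,
        normals=normals,
        binormals=binormals,
        residual_mm=centerline.residual_mm,
    )


def landmark_rotation_deg(landmarks) -> float:
    """Single global rotation (degrees) minimizing the circular mismatch of
    (oct_angle, angiographic_angle) landmark pairs; closed form for one pair."""
    if not landmarks:
        return 0.0
    diffs = np.deg2rad([(ref - obs) for obs, ref in landmarks])
    return float(np.rad2deg(np.arctan2(np.mean(np.sin(diffs)), np.mean(np.cos(diffs))))) % 360.0


def _frame_radius_profiles(pullback: Pullback):
    """Flow-area radius per frame on the common angular grid, plus per-angle
    surface labels."""
    profiles, labels, axial = [], [], []
    for c in pullback.contours:
        struts = pullback.struts_for_frame(c.frame_index)
        flow = build_flow_area_contour(c, struts)
        lab = np.full(len(c.angles_deg), SURFACE_NATIVE, dtype=object)
        if pullback.segment_of(c.axial_position_um) == SEGMENT_SCAFFOLDED:
            lab[:] = SURFACE_WALL
            for s in struts:
                lab[_in_span(c.angles_deg, s)] = SURFACE_STRUT
        profiles.append(flow.radii_um)
        labels.append(lab)
        axial.append(c.axial_position_um)
    return np.asarray(axial), np.vstack(profiles), np.vstack(labels)


def mount_contours(
    pullback: Pullback,
    centerline: Centerline3D,
    landmarks=None,
    scaffold_step_um: float = 100.0,
    native_step_um: float = 400.0,
) -> LumenSurface:
    """Mount flow-area contours perpendicularly onto the centerline.

    Contours are resampled axially to 100 µm in the scaffolded segment and
    400 µm in the native segments by linear interpolation of the available
    frames; placement is rigid (no scaling).  ``landmarks`` is a list of
    ``(oct_angle_deg, angiographic_angle_deg)`` pairs fixing the absolute
    rotation; without any landmark the rotation defaults to 0 with a warning.
    """
    if centerline.normals is None:
        centerline = compute_local_frames(centerline)
    length_um = pullback.contours[-1].axial_position_um
    cl_um = centerline.length_mm * 1000.0
    # chord-length resampling can shorten the recovered centerline by a
    # fraction of a frame; tolerate up to one frame spacing and clamp
    if length_um > cl_um + pullback.frame_spacing_um:
        raise ValueError("pullback extends beyond the centerline arc length")
    length_um = min(length_um, cl_um)
    if min(scaffold_step_um, native_step_um) < pullback.frame_spacing_um / 4.0:
        raise ValueError(
            "requested contour spacing finer than a quarter of the frame "
            "spacing; interpolation refused"
        )
    if landmarks is None:
        landmarks = []
    if not landmarks:
        warnings.warn("no landmarks given; absolute rotation defaults to 0 deg",
                      stacklevel=2)
    rot_deg = landmark_rotation_deg(landmarks)

    axial, profiles, labels = _frame_radius_profiles(pullback)
    angles = pullback.contours[0].angles_deg
    s0, s1 = pullback.scaffold_bounds_um

    stations = np.concatenate([
        np.arange(0.0, s0, native_step_um),
        np.arange(s0, s1, scaffold_step_um),
        np.arange(s1, length_um + 1e-9, native_step_um),
    ])
    stations = np.unique(stations)

    n_ang = len(angles)
    verts, vert_labels, vert_axial, vert_angle = [], [], [], []
    alpha = np.deg2rad((angles + rot_deg) % 360.0)
    for s_um in stations:
        # linear interpolation of the radius profile between flanking frames
        i1 = int(np.clip(np.searchsorted(axial, s_um), 1, len(axial) - 1))
        i0 = i1 - 1
        w = (s_um - axial[i0]) / (axial[i1] - axial[i0])
        w = float(np.clip(w, 0.0, 1.0))
        radii = (1.0 - w) * profiles[i0] + w * profiles[i1]
        # label from nearest available frame
        lab = labels[i0 if w < 0.5 else i1]
        s_mm = s_um / 1000.0
        idx = np.searchsorted(centerline.arc_length_mm, s_mm)
        idx = np.clip(idx, 0, len(centerline.arc_length_mm) - 1)
        # interpolate centre and frame between samples
        c = np.array([np.interp(s_mm, centerline.arc_length_mm, centerline.points_mm[:, k2])
                      for k2 in range(3)])
        n_vec = centerline.normals[idx]
        b_vec = centerline.binormals[idx]
        ring = (c[None, :]
                + (radii[:, None] / 1000.0)
                * (np.cos(alpha)[:, None] * n_vec[None, :]
                   + np.sin(alpha)[:, None] * b_vec[None, :]))
        verts.append(ring)
        vert_labels.append(lab)
        vert_axial.append(np.full(n_ang, s_um))
        vert_angle.append((angles + rot_deg) % 360.0)

    vertices = np.vstack(verts)
    labels_out = np.concatenate(vert_labels)
    axial_out = np.concatenate(vert_axial)
    angle_out = np.concatenate(vert_angle)

    faces = []
    n_rings = len(stations)
    for r in range(n_rings - 1):
        base0 = r * n_ang
        base1 = (r + 1) * n_ang
        j = np.arange(n_ang)
        jn = (j + 1) % n_ang
        faces.append(np.column_stack([base0 + j, base0 + jn, base1 + j]))
        faces.append(np.column_stack([base0 + jn, base1 + jn, base1 + j]))
    faces = np.vstack(faces)
    return LumenSurface(
        vertices_mm=vertices,
        faces=faces,
        labels=labels_out,
        axial_um=axial_out,
        sector_angle_deg=angle_out,
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

_LABEL_CODES = {SURFACE_NATIVE: 0, SURFACE_WALL: 1, SURFACE_STRUT: 2}


def save_surface_ply(surface: LumenSurface, path) -> None:
    import trimesh

    mesh = trimesh.Trimesh(vertices=surface.vertices_mm, faces=surface.faces,
                           process=False)
    mesh.export(str(path), file_type="ply", encoding="ascii")
    meta = Path(str(path)).with_suffix(".labels.json")
    meta.write_text(json.dumps(dict(
        label_codes=_LABEL_CODES,
        labels=[_LABEL_CODES[l] for l in surface.labels],
    )))


def save_surface_vtk(surface: LumenSurface, path) -> None:
    """Legacy-ASCII VTK PolyData with per-vertex label/axial/angle arrays."""
    v = surface.vertices_mm
    f = surface.faces
    lines = [
        "# vtk DataFile Version 3.0",
        "lumen surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(v)} float",
    ]
    lines += [f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}" for p in v]
    lines.append(f"POLYGONS {len(f)} {4 * len(f)}")
    lines += [f"3 {a} {b} {c}" for a, b, c in f]
    lines.append(f"POINT_DATA {len(v)}")
    lines.append("SCALARS label int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(_LABEL_CODES[l]) for l in surface.labels]
    lines.append("SCALARS axial_um float 1")
    lines.append("LOOKUP_TABLE default")
    lines += [f"{x:.3f}" for x in surface.axial_um]
    Path(str(path)).write_text("\n".join(lines) + "\n")


def save_centerline_csv(centerline: Centerline3D, path) -> None:
    import pandas as pd

    df = pd.DataFrame(centerline.points_mm, columns=["x_mm", "y_mm", "z_mm"])
    df.insert(0, "arc_length_mm", centerline.arc_length_mm)
    df.to_csv(path, index=False)
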