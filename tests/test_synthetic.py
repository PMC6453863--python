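"""Generators: determinism, analytic oracles and ground-truth bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from strutflow.core import SEGMENT_SCAFFOLDED, HierarchySpec
from strutflow.synthetic import (
    make_phantom,
    make_scaffold_design,
    paper_hierarchy_spec,
    project_centerline,
    read_projection_pair,
    read_pullback,
    simulate_hierarchical_ess,
    simulate_pullback,
    write_projection_pair,
    write_pullback,
)


class TestDesignPresets:
    def test_absorb_like_geometry(self, absorb_design):
        assert absorb_design.strut_thickness_um == 157.0
        assert absorb_design.strut_width_um == 176.0
        assert absorb_design.inter_strut_distance_max_mm == 1.0

    def test_arteriosorb_like_geometry(self, arterio_design):
        assert arterio_design.strut_thickness_um == 95.0
        assert arterio_design.strut_width_um == 170.0
        assert arterio_design.inter_strut_distance_max_mm == 1.4

    def test_custom_requires_geometry(self):
        with pytest.raises(ValueError, match="custom design requires"):
            make_scaffold_design("custom", strut_thickness_um=100.0)

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="unknown preset"):
            make_scaffold_design("steel")


class TestPhantom:
    def test_straight_centerline_is_axis(self, straight_phantom):
        pts = straight_phantom.centerline_mm
        assert np.allclose(pts[:, :2], 0.0)
        assert np.allclose(pts[:, 2], straight_phantom.arc_length_mm)

    def test_curved_arc_length_parametrization(self):
        ph = make_phantom(20.0, 1.5, curvature=0.05, n_points=2000)
        chord = np.linalg.norm(np.diff(ph.centerline_mm, axis=0), axis=1)
        # chord sums must reproduce the declared arc length to high accuracy
        assert np.cumsum(chord)[-1] == pytest.approx(ph.length_mm, rel=1e-4)
        assert np.allclose(np.cumsum(chord), ph.arc_length_mm[1:], atol=2e-3)

    def test_curved_initial_tangent_along_z(self):
        ph = make_phantom(20.0, 1.5, curvature=0.05)
        t0 = ph.centerline_mm[1] - ph.centerline_mm[0]
        t0 /= np.linalg.norm(t0)
        assert t0[2] == pytest.approx(1.0, abs=1e-4)

    def test_taper(self):
        ph = make_phantom(10.0, 2.0, taper=0.25)
        assert ph.radius_at(0.0) == pytest.approx(2.0)
        assert ph.radius_at(10.0) == pytest.approx(1.5)

    def test_seed_controls_landmark_angle(self):
        a = make_phantom(10.0, 1.5, seed=1).landmarks[0][1]
        b = make_phantom(10.0, 1.5, seed=2).landmarks[0][1]
        assert a != b

    def test_validation(self):
        with pytest.raises(ValueError):
            make_phantom(-1.0, 1.5)
        with pytest.raises(ValueError):
            make_phantom(10.0, 1.5, taper=1.0)


class TestSimulatePullback:
    def test_deterministic_for_fixed_seed(self, straight_phantom, absorb_design):
        a = simulate_pullback(straight_phantom, absorb_design, 0.97, seed=7)
        b = simulate_pullback(straight_phantom, absorb_design, 0.97, seed=7)
        pd.testing.assert_frame_equal(a.struts, b.struts)
        assert all(np.array_equal(x.radii_um, y.radii_um)
                   for x, y in zip(a.contours, b.contours))

    def test_struts_confined_to_scaffolded_segment(self, absorb_pullback):
        s0, s1 = absorb_pullback.scaffold_bounds_um
        z = absorb_pullback.struts.frame_index * absorb_pullback.frame_spacing_um
        assert ((z >= s0) & (z < s1)).all()

    def test_strut_count_per_frame_with_ring(self, absorb_pullback):
        counts = absorb_pullback.struts.groupby("frame_index").size()
        assert (counts == absorb_pullback.design.struts_per_ring).all()

    def test_ground_truth_depth(self, absorb_pullback):
        depth = 0.97 * 157.0
        assert np.allclose(absorb_pullback.struts.true_protrusion_um, depth)
        assert not absorb_pullback.struts.true_malapposed.any()

    def test_malapposed_generation(self, straight_phantom, absorb_design):
        pb = simulate_pullback(straight_phantom, absorb_design, 1.1, seed=0)
        assert pb.struts.true_malapposed.all()
        # abluminal edge stands clear of the wall by 0.1 thickness
        gap = 0.1 * 157.0
        frame0 = int(pb.struts.frame_index.iloc[0])
        wall = pb.contours[frame0].radii_um[0]
        row = pb.struts.iloc[0]
        assert wall - row.abluminal_radius_um == pytest.approx(gap, abs=1e-6)

    def test_rejects_fraction_out_of_range(self, straight_phantom, absorb_design):
        with pytest.raises(ValueError):
            simulate_pullback(straight_phantom, absorb_design, 1.3)

    def test_alternate_rings_are_offset(self, straight_phantom, absorb_design):
        pb = simulate_pullback(straight_phantom, absorb_design, 0.97, seed=0)
        frames = sorted(pb.struts.frame_index.unique())
        a = set(pb.struts[pb.struts.frame_index == frames[0]].angle_center_deg)
        b = set(pb.struts[pb.struts.frame_index == frames[1]].angle_center_deg)
        assert a.isdisjoint(b)


class TestProjection:
    def test_straight_phantom_projects_to_straight_lines(self, straight_phantom):
        pair = project_centerline(straight_phantom, 30.0, 120.0)
        assert np.allclose(pair.polyline_a_mm[:, 0], 0.0, atol=1e-12)
        assert np.allclose(np.diff(pair.polyline_a_mm[:, 1]) > 0, True)

    def test_degenerate_angles_rejected(self, straight_phantom):
        with pytest.raises(ValueError):
            project_centerline(straight_phantom, 30.0, 30.0)


class TestHierarchicalGenerator:
    def test_paper_layout(self):
        spec = paper_hierarchy_spec(seed=0)
        rec, _ = simulate_hierarchical_ess(spec)
        assert rec.animal_id.nunique() == 9
        assert rec.scaffold_id.nunique() == 12
        assert rec.groupby("cross_section_id").size().eq(72).all()
        by_animal = rec.groupby("animal_id").scaffold_type.nunique()
        assert (by_animal == 1).all()   # type assigned at the animal level

    def test_moments_and_injected_delta(self):
        spec = HierarchySpec(n_animals=40, scaffolds_per_animal=1,
                             cross_sections_per_scaffold=10,
                             sectors_per_cross_section=72,
                             sd_animal_pa=0.01, sd_scaffold_pa=0.01,
                             sd_cross_section_pa=0.01, sd_sector_pa=0.5,
                             fixed_effect_delta_pa=0.79, seed=5)
        rec, _ = simulate_hierarchical_ess(spec)
        g = rec.groupby("scaffold_type").ess.mean()
        assert g["arteriosorb_like"] - g["absorb_like"] == pytest.approx(0.79, abs=0.03)
        resid_sd = rec.groupby("cross_section_id").ess.transform("mean")
        assert (rec.ess - resid_sd).std() == pytest.approx(0.5, rel=0.05)

    def test_allocation_must_match_animals(self):
        spec = HierarchySpec(n_animals=3, allocation=(("absorb_like",),))
        with pytest.raises(ValueError, match="allocation"):
            simulate_hierarchical_ess(spec)

    def test_truth_contains_drawn_effects(self):
        rec, truth = simulate_hierarchical_ess(HierarchySpec(seed=1))
        assert len(truth["animal_effects"]) == rec.animal_id.nunique()
        assert truth["fixed_effect_delta_pa"] == 0.79


class TestPlainTextIO:
    def test_pullback_round_trip(self, tmp_path, absorb_pullback):
        write_pullback(absorb_pullback, tmp_path / "pb")
        back = read_pullback(tmp_path / "pb")
        assert back.n_frames == absorb_pullback.n_frames
        assert back.frame_spacing_um == absorb_pullback.frame_spacing_um
        assert back.scaffold_bounds_um == absorb_pullback.scaffold_bounds_um
        pd.testing.assert_frame_equal(
            back.struts.reset_index(drop=True),
            absorb_pullback.struts.reset_index(drop=True),
            check_dtype=False,
        )
        for a, b in zip(back.contours, absorb_pullback.contours):
            assert np.allclose(a.radii_um, b.radii_um)
            assert a.axial_position_um == pytest.approx(b.axial_position_um)

    def test_projection_round_trip(self, tmp_path, straight_phantom):
        pair = project_centerline(straight_phantom, 30.0, 120.0)
        write_projection_pair(pair, tmp_path / "proj")
        back = read_projection_pair(tmp_path / "proj")
        assert back.angle_a_deg == pair.angle_a_deg
        assert np.allclose(back.polyline_b_mm, pair.polyline_b_mm)
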