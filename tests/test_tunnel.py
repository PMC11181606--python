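"""Tunnel geometry against the closed-form prism oracle and invariants."""

import math
from dataclasses import replace

import numpy as np
import pytest

from conftest import random_rigid_transform
from pcltunnel.geometry import AnatomicalFrame, Contour, PlateauPlane, plateau_plane_from_mesh
from pcltunnel.synthetic import (
    PrismSpec,
    TibiaParams,
    generate_tibia,
    mirror_x,
    prism_expected,
    prism_tibia,
    sample_cohort,
    PopulationConfig,
)
from pcltunnel.tunnel import (
    ObliqueSection,
    SectionError,
    crest_point,
    cut_section,
    entry_points,
    measure_tunnel,
    section_plane,
    simulate_knee,
)

FRAME = AnatomicalFrame()


def run_prism(mesh, lm, tta, offset=20.0, mode="arc"):
    plateau = plateau_plane_from_mesh(mesh, lm.frame)
    point, normal = section_plane(plateau, lm.pcl_attachment, tta, lm.frame)
    section = cut_section(mesh, point, normal, tta=tta)
    crest_point(section, lm.frame)
    am, al = entry_points(section, lm.frame, offset_mm=offset, mode=mode)
    m_am = measure_tunnel(am, lm.pcl_attachment, plateau, tta, "AM")
    m_al = measure_tunnel(al, lm.pcl_attachment, plateau, tta, "AL")
    return m_am, m_al


class TestSectionPlane:
    def test_prism_45_degree_plane_closed_form(self, prism):
        """On the prism the 45-degree plane through E = (0,-40,-10) is
        z = -10 - (y + 40)."""
        mesh, lm, _ = prism
        plateau = plateau_plane_from_mesh(mesh, lm.frame)
        point, normal = section_plane(plateau, lm.pcl_attachment, 45.0, lm.frame)
        for y in (-40.0, 0.0, 30.0):
            p = np.array([5.0, y, -10.0 - (y + 40.0)])
            assert abs((p - point) @ normal) < 1e-9

    @pytest.mark.parametrize("tta", [30.0, 60.0])
    def test_dihedral_angle_recovered_from_normal(self, prism, tta):
        mesh, lm, _ = prism
        plateau = plateau_plane_from_mesh(mesh, lm.frame)
        _, normal = section_plane(plateau, lm.pcl_attachment, tta, lm.frame)
        cos = abs(float(normal @ plateau.unit_normal))
        assert math.degrees(math.acos(min(cos, 1.0))) == pytest.approx(tta, abs=1e-9)

    @pytest.mark.parametrize("tta", [0.0, -5.0, 90.0, 120.0])
    def test_out_of_range_angle_rejected(self, prism, tta):
        mesh, lm, _ = prism
        plateau = plateau_plane_from_mesh(mesh, lm.frame)
        with pytest.raises(SectionError):
            section_plane(plateau, lm.pcl_attachment, tta, lm.frame)

    def test_plane_descends_anteriorly(self, prism):
        mesh, lm, _ = prism
        plateau = plateau_plane_from_mesh(mesh, lm.frame)
        point, normal = section_plane(plateau, lm.pcl_attachment, 50.0, lm.frame)
        # moving anterior within the plane must go distal
        anterior_in_plane = np.array([0, 1, 0]) - normal[1] * normal
        assert anterior_in_plane[2] < 0


class TestCutSection:
    def test_contour_is_planar(self, prism):
        mesh, lm, _ = prism
        plateau = plateau_plane_from_mesh(mesh, lm.frame)
        point, normal = section_plane(plateau, lm.pcl_attachment, 45.0, lm.frame)
        section = cut_section(mesh, point, normal)
        d = (section.contour.points - point) @ normal
        assert np.abs(d).max() < 1e-6

    def test_plane_missing_mesh_raises(self, prism):
        mesh, _, _ = prism
        with pytest.raises(SectionError):
            cut_section(mesh, [0, 0, 100.0], [0, 0, 1.0])

    def test_prism_45_contour_matches_analytic_quadrilateral(self, prism):
        mesh, lm, spec = prism
        plateau = plateau_plane_from_mesh(mesh, lm.frame)
        point, normal = section_plane(plateau, lm.pcl_attachment, 45.0, lm.frame)
        section = cut_section(mesh, point, normal)
        pts = section.contour.points
        # analytic cut of the box by z = -10 - (y + 40): anterior edge at
        # (x, 30, -80), posterior edge at (x, -50, 0)
        assert pts[:, 1].max() == pytest.approx(spec.y_anterior, abs=1e-6)
        assert pts[pts[:, 1] > 29.9][:, 2].max() == pytest.approx(-80.0, abs=1e-6)
        assert pts[:, 0].min() == pytest.approx(-spec.half_width, abs=1e-6)
        assert pts[:, 0].max() == pytest.approx(spec.half_width, abs=1e-6)


class TestCrestAndEntries:
    def test_crest_point_mid_anterior_on_prism(self, prism):
        mesh, lm, _ = prism
        plateau = plateau_plane_from_mesh(mesh, lm.frame)
        point, normal = section_plane(plateau, lm.pcl_attachment, 45.0, lm.frame)
        section = cut_section(mesh, point, normal)
        crest = crest_point(section, lm.frame)
        assert np.allclose(crest, [0.0, 30.0, -80.0], atol=1e-9)

    def test_flat_edge_tie_break_returns_middle_vertex(self):
        xs = np.linspace(-5, 5, 11)
        top = np.stack([xs, np.full_like(xs, 8.0), np.zeros_like(xs)], axis=1)
        bottom = np.stack([xs[::-1], np.full_like(xs, -8.0), np.zeros_like(xs)], axis=1)
        section = ObliqueSection(
            plane_point=np.zeros(3),
            plane_normal=np.array([0.0, 0.0, 1.0]),
            contour=Contour(points=np.vstack([top, bottom])),
            tta=50.0,
        )
        crest = crest_point(section, FRAME)
        assert crest[0] == pytest.approx(0.0, abs=1e-9)

    def test_zero_offset_entries_equal_crest(self, prism):
        mesh, lm, _ = prism
        plateau = plateau_plane_from_mesh(mesh, lm.frame)
        point, normal = section_plane(plateau, lm.pcl_attachment, 45.0, lm.frame)
        section = cut_section(mesh, point, normal)
        crest = crest_point(section, lm.frame)
        am, al = entry_points(section, lm.frame, offset_mm=0.0)
        assert np.allclose(am, crest) and np.allclose(al, crest)

    def test_entries_20mm_arc_on_prism(self, prism):
        mesh, lm, _ = prism
        m_am, m_al = run_prism(mesh, lm, 45.0)
        assert np.allclose(m_am.entry, [-20.0, 30.0, -80.0], atol=1e-6)
        assert np.allclose(m_al.entry, [20.0, 30.0, -80.0], atol=1e-6)

    def test_arc_and_chord_modes_coincide_on_flat_face(self, prism):
        mesh, lm, _ = prism
        arc_am, arc_al = run_prism(mesh, lm, 45.0, mode="arc")
        ch_am, ch_al = run_prism(mesh, lm, 45.0, mode="chord")
        assert np.allclose(arc_am.entry, ch_am.entry, atol=1e-6)
        assert np.allclose(arc_al.entry, ch_al.entry, atol=1e-6)

    def test_offset_longer_than_contour_rejected(self, prism):
        mesh, lm, _ = prism
        plateau = plateau_plane_from_mesh(mesh, lm.frame)
        point, normal = section_plane(plateau, lm.pcl_attachment, 45.0, lm.frame)
        section = cut_section(mesh, point, normal)
        with pytest.raises(SectionError):
            entry_points(section, lm.frame, offset_mm=1e4)


class TestMeasureTunnel:
    def test_simple_distances(self):
        plane = PlateauPlane(
            point_on_plane=[0, 0, 0], unit_normal=[0, 0, 1],
            p_anterior=[0, 1, 0], p_medial=[-1, 0, 0], p_posterior=[0, -1, 0],
        )
        m = measure_tunnel([0, 0, 0], [0, 0, 10], plane)
        assert m.ttl == pytest.approx(10.0)
        assert m.tth == pytest.approx(0.0)

    def test_coincident_entry_exit_rejected(self):
        plane = PlateauPlane(
            point_on_plane=[0, 0, 0], unit_normal=[0, 0, 1],
            p_anterior=[0, 1, 0], p_medial=[-1, 0, 0], p_posterior=[0, -1, 0],
        )
        with pytest.raises(ValueError):
            measure_tunnel([1, 2, 3], [1, 2, 3], plane)


class TestPrismAgainstClosedForm:
    @pytest.mark.parametrize("tta", [40.0, 45.0, 50.0, 55.0, 60.0])
    @pytest.mark.parametrize("offset", [10.0, 20.0])
    def test_ttl_tth_match_trigonometry(self, prism, tta, offset):
        mesh, lm, spec = prism
        exp = prism_expected(spec, tta, offset)
        m_am, m_al = run_prism(mesh, lm, tta, offset)
        assert m_am.ttl == pytest.approx(exp["ttl_am"], abs=0.1)
        assert m_al.ttl == pytest.approx(exp["ttl_al"], abs=0.1)
        assert m_am.tth == pytest.approx(exp["tth"], abs=0.1)
        assert m_al.tth == pytest.approx(exp["tth"], abs=0.1)

    def test_finer_mesh_does_not_degrade_accuracy(self):
        spec = PrismSpec()
        exp = prism_expected(spec, 45.0, 20.0)
        errs = []
        for edge in (8.0, 4.0, 2.0):
            mesh, lm = prism_tibia(spec, max_edge=edge)
            m_am, _ = run_prism(mesh, lm, 45.0)
            errs.append(abs(m_am.ttl - exp["ttl_am"]))
        assert all(e < 0.1 for e in errs)
        assert errs[-1] <= errs[0] + 1e-9


class TestInvariants:
    def test_rigid_motion_invariance_of_ttl_tth(self, prism, rng):
        mesh, lm, _ = prism
        base_am, base_al = run_prism(mesh, lm, 50.0)
        m = random_rigid_transform(rng)
        moved = mesh.copy()
        moved.apply_transform(m)
        lm2 = replace_landmarks_transform(lm, m)
        got_am, got_al = run_prism(moved, lm2, 50.0)
        assert got_am.ttl == pytest.approx(base_am.ttl, abs=1e-6)
        assert got_al.ttl == pytest.approx(base_al.ttl, abs=1e-6)
        assert got_am.tth == pytest.approx(base_am.tth, abs=1e-6)

    def test_mirrored_knee_swaps_am_and_al(self, default_tibia, default_plateau):
        mesh, lm = default_tibia
        rows = simulate_knee(mesh, default_plateau, lm.pcl_attachment, lm.frame)
        mirrored, lm_m = mirror_x(mesh, lm, new_side="left")
        plateau_m = plateau_plane_from_mesh(mirrored, lm_m.frame)
        rows_m = simulate_knee(mirrored, plateau_m, lm_m.pcl_attachment, lm_m.frame)
        base = {(r.approach, r.tta): r for r in rows}
        got = {(r.approach, r.tta): r for r in rows_m}
        for (app, tta), r in base.items():
            other = "AL" if app == "AM" else "AM"
            assert got[(other, tta)].ttl == pytest.approx(r.ttl, abs=1e-6)
            assert got[(other, tta)].tth == pytest.approx(r.tth, abs=1e-6)

    def test_ttl_and_tth_strictly_increase_with_angle(self, default_tibia, default_plateau):
        mesh, lm = default_tibia
        rows = simulate_knee(mesh, default_plateau, lm.pcl_attachment, lm.frame)
        for app in ("AM", "AL"):
            seq = sorted((r.tta, r.ttl, r.tth) for r in rows if r.approach == app)
            ttls = [s[1] for s in seq]
            tths = [s[2] for s in seq]
            assert all(b > a for a, b in zip(ttls, ttls[1:]))
            assert all(b > a for a, b in zip(tths, tths[1:]))

    @pytest.mark.parametrize("subject", [0, 7, 42])
    def test_entry_depth_bound_on_ground_truthed_knees(self, subject):
        """0 < TTH - d_exit <= TTL sin(TTA): the entry lies deeper than the
        exit by at most the in-section-plane depth gain of the tunnel."""
        cohort = sample_cohort(PopulationConfig(seed=1))
        params, _ = cohort[subject]
        params = replace(params, side="right")
        mesh, lm = generate_tibia(params, level_mm=3.0, n_theta=96)
        plateau = PlateauPlane(
            point_on_plane=lm.plateau_point, unit_normal=lm.plateau_normal,
            p_anterior=[0, 1, 0], p_medial=[-1, 0, 0], p_posterior=[0, -1, 0],
        )
        d_exit = params.pcl_depth_below_plateau * params.global_scale
        rows = simulate_knee(mesh, plateau, lm.pcl_attachment, lm.frame)
        for r in rows:
            gain = r.tth - d_exit
            assert gain > 0
            assert gain <= r.ttl * math.sin(math.radians(r.tta)) + 1e-9

    def test_simulate_knee_cardinality_and_determinism(self, default_tibia, default_plateau):
        mesh, lm = default_tibia
        rows1 = simulate_knee(mesh, default_plateau, lm.pcl_attachment, lm.frame)
        rows2 = simulate_knee(mesh, default_plateau, lm.pcl_attachment, lm.frame)
        assert len(rows1) == 10  # 5 angles x 2 approaches
        for a, b in zip(rows1, rows2):
            assert a.ttl == b.ttl and a.tth == b.tth


def replace_landmarks_transform(lm, matrix):
    rot, tr = matrix[:3, :3], matrix[:3, 3]
    from pcltunnel.synthetic import GroundTruthLandmarks

    return GroundTruthLandmarks(
        plateau_point=rot @ lm.plateau_point + tr,
        plateau_normal=rot @ lm.plateau_normal,
        pcl_attachment=rot @ lm.pcl_attachment + tr,
        crest_apex_curve=lm.crest_apex_curve @ rot.T + tr,
        frame=lm.frame.transformed(matrix),
        side=lm.side,
    )
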