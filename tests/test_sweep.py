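"""Plane sweep, component tracking, and split-event detection."""

import numpy as np
import pytest

import pulpsweep as ps
from pulpsweep.phantom import CanalSpec, Leaf, PhantomSpec, Split, add_pulp_stone
from pulpsweep.sweep import anchor_slice, detect_events, detect_floor_contact, sweep

from .conftest import angle_deg


class TestAnchorSlice:
    def test_three_points_exact(self):
        pts = np.array([[0, 0, 1], [2, 0, 1], [0, 3, 1]], float)
        plane = anchor_slice(pts)
        assert plane.fit_residual == pytest.approx(0.0, abs=1e-12)

    def test_four_coplanar_points_zero_residual(self):
        pts = np.array([[0, 0, 2], [1, 0, 2], [0, 1, 2], [1, 1, 2]], float)
        assert anchor_slice(pts).fit_residual == pytest.approx(0.0, abs=1e-12)

    def test_collinear_anchors_rejected(self):
        with pytest.raises(ps.GeometryError):
            anchor_slice(np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float))

    def test_wrong_count_rejected(self):
        with pytest.raises(ps.ValidationError):
            anchor_slice(np.zeros((5, 3)))

    def test_perturbed_anchor_tilt_follows_monte_carlo_oracle(self, two_rooted):
        # bound frozen from the Monte-Carlo oracle itself (100 seeded
        # perturbations of the phantom anchors at sigma = 0.1 mm)
        A = two_rooted.gt.landmarks.anchor_array()
        ref = two_rooted.vol.pulp_centroid()
        tilts = []
        for s in range(100):
            rng = np.random.default_rng(s)
            plane = anchor_slice(A + rng.normal(0, 0.1, A.shape), apical_reference=ref)
            tilts.append(angle_deg(plane.normal, (0, 0, -1)))
        assert np.mean(tilts) <= 3.5
        assert np.max(tilts) <= 10.0


class TestSweep:
    def test_single_canal_never_exceeds_one_component(self, single_canal):
        counts = [len(s.components) for s in single_canal.res.sections]
        assert max(counts) == 1

    def test_two_canal_component_counts_bracket_the_split(self, two_rooted):
        d1 = two_rooted.spec.plan.depth
        sz = two_rooted.vol.spacing[2]
        for s in two_rooted.res.sections:
            if s.depth < d1 - sz:
                assert len(s.components) == 1
            elif s.depth > d1 + sz:
                assert len(s.components) == 2

    def test_step_below_axial_spacing_rejected(self, two_rooted):
        with pytest.raises(ps.ValidationError, match="step"):
            sweep(two_rooted.res.volume, two_rooted.res.anchor_plane, step=0.01)

    def test_anchors_below_chamber_rejected(self, two_rooted):
        vol = two_rooted.res.volume
        deep = ps.Plane((vol.origin[0], vol.origin[1],
                         two_rooted.res.anchor_plane.point[2] + 3.0), (0.0, 0.0, -1.0))
        with pytest.raises(ps.GeometryError, match="below the chamber"):
            sweep(vol, deep)

    def test_pulp_stone_is_filtered_and_counts_unchanged(self, two_rooted):
        rec = two_rooted.res.orifices[0]
        center = np.asarray(two_rooted.res.transform.invert(np.asarray(rec.centroid))[0])
        vol_stone = add_pulp_stone(two_rooted.vol, center + np.array([0.6, 0.0, 0.0]), 3)
        res = ps.run_pipeline(vol_stone, two_rooted.lms,
                              two_rooted.spec.arch, two_rooted.spec.side)
        base_counts = [len(s.components) for s in two_rooted.res.sections]
        stone_counts = [len(s.components) for s in res.sections]
        assert stone_counts == base_counts

    def test_increasing_min_area_never_adds_events(self, two_rooted):
        vol, plane = two_rooted.res.volume, two_rooted.res.anchor_plane
        n_events = []
        for min_area in (4, 16, 64, 256):
            sections = sweep(vol, plane, min_area=min_area)
            n_events.append(len(detect_events(sections).events()))
        assert all(a >= b for a, b in zip(n_events, n_events[1:]))


class TestDetectEvents:
    def test_two_rooted_single_bifurcation_within_a_step(self, two_rooted):
        events = two_rooted.res.tree.events()
        assert len(events) == 1 and events[0].kind == "bifurcation"
        d1 = two_rooted.spec.plan.depth
        step = two_rooted.vol.spacing[2]
        assert abs(events[0].depth - d1) <= step

    def test_radix_orders_events_mesial_then_distal(self, radix):
        events = radix.res.tree.events()
        assert len(events) == 2
        assert events[0].depth < events[1].depth
        # the deeper event separates exactly two children (D vs DL)
        assert events[1].kind == "bifurcation"

    def test_true_trifurcation_is_one_event_with_three_children(self):
        canals = (CanalSpec("P", (-1.0, 0), (-1.2, 0), 0.45, 0.3, 4.2),
                  CanalSpec("MB", (0.9, 0.75), (1.0, 0.9), 0.35, 0.2, 4.2),
                  CanalSpec("DB", (0.9, -0.75), (1.0, -0.9), 0.35, 0.2, 4.2))
        spec = PhantomSpec(arch="maxillary", side="left", canals=canals,
                           plan=Split(1.7, (Leaf(("P",)), Leaf(("MB",)), Leaf(("DB",)))))
        vol, gt = ps.build_phantom(spec)
        res = ps.run_pipeline(vol, ps.render_landmarks(gt), "maxillary", "left")
        events = res.tree.events()
        assert len(events) == 1
        assert events[0].kind == "trifurcation"
        assert len(events[0].child_components) == 3

    def test_merge_guard_suppresses_flicker_splits(self):
        # dumbbell pulp: splits for 0.1 mm then re-merges
        arr = np.zeros((24, 24, 14), dtype=np.uint8)
        bar = np.zeros((24, 24), dtype=bool)
        bar[6:18, 8:16] = True
        halves = np.zeros((24, 24), dtype=bool)
        halves[6:11, 8:16] = True
        halves[13:18, 8:16] = True
        for k in range(12):
            arr[:, :, k][bar if k not in (4, 5) else halves] = 3
        vol = ps.LabeledVolume(arr, (0.05, 0.05, 0.05))
        plane = ps.Plane((0.0, 0.0, 0.0), (0.0, 0.0, -1.0))
        sections = sweep(vol, plane)
        guarded = detect_events(sections, merge_guard=0.2)
        unguarded = detect_events(sections, merge_guard=0.0)
        assert len(guarded.events()) == 0
        assert len(unguarded.events()) == 1
        # the apical re-merge never creates additional events either way
        assert len(unguarded.leaves()) == 2


class TestSaddle:
    def test_symmetric_two_canal_saddle_on_the_midline(self):
        canals = (CanalSpec("M", (0.0, 1.1), (0.0, 1.1), 0.45, 0.25, 4.2),
                  CanalSpec("D", (0.0, -1.1), (0.0, -1.1), 0.45, 0.25, 4.2))
        spec = PhantomSpec(arch="mandibular", side="right",
                           chamber_half_widths=(1.4, 1.8), canals=canals,
                           plan=Split(2.0, (Leaf(("M",)), Leaf(("D",)))))
        vol, gt = ps.build_phantom(spec)
        res = ps.run_pipeline(vol, ps.render_landmarks(gt), "mandibular", "right")
        saddle = res.transform.invert(np.asarray(res.tree.events()[0].saddle))[0]
        cy = (vol.shape[1] - 1) * vol.spacing[1] / 2
        assert abs(saddle[1] - cy) <= vol.spacing[1]

    def test_asymmetric_radii_saddle_matches_generator_oracle(self):
        canals = (CanalSpec("M", (0.0, 1.1), (0.0, 1.1), 0.5, 0.3, 4.2),
                  CanalSpec("D", (0.0, -1.1), (0.0, -1.1), 0.3, 0.2, 4.2))
        spec = PhantomSpec(arch="mandibular", side="right",
                           chamber_half_widths=(1.4, 1.8), canals=canals,
                           plan=Split(2.0, (Leaf(("M",)), Leaf(("D",)))))
        vol, gt = ps.build_phantom(spec)
        res = ps.run_pipeline(vol, ps.render_landmarks(gt), "mandibular", "right")
        det = res.transform.invert(np.asarray(res.tree.events()[0].saddle))[0]
        true = np.asarray(gt.split_events[0].saddle)
        assert np.hypot(*(det[:2] - true[:2])) <= 2 * max(vol.spacing[:2])


class TestFloorContact:
    def test_floor_contact_agrees_with_split_detector(self, two_rooted, radix):
        for run in (two_rooted, radix):
            s_contact = detect_floor_contact(run.res.volume, run.res.anchor_plane)
            first_split = run.res.tree.events()[0].depth
            step = run.vol.spacing[2]
            assert s_contact is not None
            assert abs(s_contact - first_split) <= 2 * step, run.name
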