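"""Orifice assignment, anatomical labelling, and exact pulp partitioning."""

import numpy as np
import pytest

import pulpsweep as ps
from pulpsweep.geometry import build_frame
from pulpsweep.partition import OrificeRecord, label_canals
from pulpsweep.sweep import BranchNode


def _fake_record(centroid, area=1.0, depth=2.0):
    return OrificeRecord(leaf=BranchNode(trail=[(0, 0)]), depth=depth,
                         contour=np.zeros((4, 2)), area_mm2=area, centroid=centroid)


class TestOrificeRule:
    def test_two_rooted_both_canals_at_the_single_event(self, two_rooted):
        recs = two_rooted.res.orifices
        assert len(recs) == 2
        event_depth = two_rooted.res.tree.events()[0].depth
        assert all(r.depth == event_depth for r in recs)

    def test_radix_mesial_first_distals_second(self, radix):
        by_name = {r.name: r for r in radix.res.orifices}
        e1, e2 = [e.depth for e in radix.res.tree.events()]
        assert by_name["M"].depth == e1
        assert by_name["D"].depth == e2
        assert by_name["DL"].depth == e2

    def test_three_rooted_palatal_shallow_buccals_deep(self, three_rooted):
        by_name = {r.name: r for r in three_rooted.res.orifices}
        e1, e2 = [e.depth for e in three_rooted.res.tree.events()]
        assert by_name["P"].depth == e1
        assert by_name["MB"].depth == e2
        assert by_name["DB"].depth == e2

    def test_c_shape_one_shared_record_plus_separate_palatal(self, c_shape):
        recs = c_shape.res.orifices
        shared = [r for r in recs if r.shared]
        assert len(recs) == 2
        assert len(shared) == 1 and sorted(shared[0].labels) == ["DB", "MB"]
        assert [r.labels for r in recs if not r.shared] == [["P"]]

    def test_single_canal_orifice_at_cej_plane(self, single_canal):
        recs = single_canal.res.orifices
        assert len(recs) == 1 and recs[0].event is None
        assert recs[0].depth == 0.0
        assert single_canal.res.report.notes == ["single canal; orifice at CEJ plane"]

    def test_orifice_area_matches_analytic_tube_section(self, two_rooted):
        # at the chamber floor the tapered canal still has its start radius
        radii = {c.label: c.start_radius for c in two_rooted.spec.canals}
        for r in two_rooted.res.orifices:
            analytic = np.pi * radii[r.name] ** 2
            assert abs(r.area_mm2 - analytic) / analytic < 0.10


class TestPartition:
    @pytest.mark.parametrize("fixture", ["two_rooted", "radix", "c_shape", "single_canal"])
    def test_partition_conserves_every_pulp_voxel(self, fixture, request):
        run = request.getfixturevalue(fixture)
        part = run.res.partition
        total = int((run.res.volume.voxels == 3).sum())
        assert sum(part.counts().values()) == total
        assert int((part.region_of > 0).sum()) == total

    def test_radix_shared_region_between_the_two_events(self, radix):
        part = radix.res.partition
        shared_names = [n for n, k in zip(part.names, part.kinds) if k == "shared"]
        assert shared_names == ["shared:D+DL"]
        detected = part.counts()["shared:D+DL"]
        true = radix.gt.region_counts["shared:D+DL"]
        assert detected > 0
        assert abs(detected - true) / true < 0.25  # event planes are quantized

    def test_chamber_volume_matches_ground_truth(self, two_rooted):
        det = two_rooted.res.partition.counts()["chamber"]
        true = two_rooted.gt.region_counts["chamber"]
        assert abs(det - true) / true < 0.05

    def test_single_canal_partition_is_chamber_plus_canal(self, single_canal):
        part = single_canal.res.partition
        assert sorted(part.kinds) == ["canal", "chamber"]


class TestLabelCanals:
    def _frame(self, arch, side):
        return build_frame(np.array([0.0, 0.0, -1.0]), np.array([1.0, 0.0, 0.0]),
                           arch, side)

    def test_labels_match_generator_on_presets(self, two_rooted, radix, three_rooted):
        assert two_rooted.res.report.configuration == "M D"
        assert radix.res.report.configuration == "M D DL"
        assert three_rooted.res.report.configuration == "MB DB P"

    def test_mirrored_side_flips_mesial_distal(self):
        frame_r = self._frame("mandibular", "right")
        frame_l = self._frame("mandibular", "left")
        recs = [_fake_record((0.0, 1.0, 0.0)), _fake_record((0.0, -1.0, 0.0))]
        label_canals(recs, frame_r, "mandibular", "right")
        right = [r.labels[0] for r in recs]
        label_canals(recs, frame_l, "mandibular", "left")
        left = [r.labels[0] for r in recs]
        assert right == left[::-1]

    def test_radix_third_leaf_is_disto_lingual(self, radix):
        names = {r.name for r in radix.res.orifices}
        assert "DL" in names
        dl = next(r for r in radix.res.orifices if r.name == "DL")
        # DL sits lingually: negative along the buccal axis
        rel = np.asarray(dl.centroid) - np.mean(
            [r.centroid for r in radix.res.orifices], axis=0)
        assert rel @ radix.res.frame.buccal < 0

    def test_unexpected_branch_count_gets_generic_labels(self):
        frame = self._frame("mandibular", "right")
        recs = [_fake_record((0.0, float(y), 0.0)) for y in range(4)]
        label_canals(recs, frame, "mandibular", "right")
        assert sorted(r.labels[0] for r in recs) == ["C1", "C2", "C3", "C4"]


class TestSummarize:
    def test_c_shape_configuration_uses_double_slash(self, c_shape):
        assert "MB//DB" in c_shape.res.report.configuration

    def test_two_rooted_report_shape(self, two_rooted):
        rep = two_rooted.res.report
        assert len(rep.canals) == 2
        assert len(rep.events) == 1
        assert not any(c.shared_with for c in rep.canals)
        total = rep.total_pulp_volume_mm3()
        direct = int((two_rooted.res.volume.voxels == 3).sum()) * two_rooted.vol.voxel_volume
        assert total == pytest.approx(direct, rel=1e-9)

    def test_depths_are_reported_below_the_cej_plane(self, two_rooted):
        rep = two_rooted.res.report
        d1 = two_rooted.spec.plan.depth
        for c in rep.canals:
            assert abs(c.orifice_depth_mm - d1) <= 2 * two_rooted.vol.spacing[2]
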