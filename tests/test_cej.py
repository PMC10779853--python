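"""CEJ curve extraction, total-least-squares plane fit, re-orientation."""

import numpy as np
import pytest

import pulpsweep as ps
from pulpsweep.cej import resample_rigid
from pulpsweep.geometry import RigidTransform, rotation_about

from ._oracles import brute_force_plane
from .conftest import angle_deg


class TestFitPlane:
    def test_exact_three_point_plane(self):
        plane = ps.fit_plane(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float))
        assert plane.fit_residual == pytest.approx(0.0, abs=1e-12)
        assert abs(np.asarray(plane.normal)[2]) == pytest.approx(1.0, abs=1e-12)

    def test_coplanar_cloud_has_zero_residual(self):
        rng = np.random.default_rng(0)
        uv = rng.normal(size=(10, 2))
        basis = np.array([[1.0, 0.0, 0.3], [0.0, 1.0, -0.2]])
        pts = uv @ basis + np.array([5.0, -2.0, 1.0])
        assert ps.fit_plane(pts).fit_residual < 1e-12

    def test_matches_brute_force_oracle(self):
        # frozen example: unit square corners plus one lifted corner
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 1]], float)
        plane = ps.fit_plane(pts)
        n_o, res_o = brute_force_plane(pts)
        assert abs(plane.fit_residual - res_o) < 1e-6
        assert angle_deg(plane.normal, n_o) < np.degrees(1e-4)

    def test_random_clouds_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            pts = rng.normal(size=(rng.integers(4, 50), 3)) * [3.0, 2.0, 0.4]
            plane = ps.fit_plane(pts)
            n_o, res_o = brute_force_plane(pts)
            assert abs(plane.fit_residual - res_o) < 1e-6
            assert angle_deg(plane.normal, n_o) < np.degrees(1e-4)

    def test_normal_oriented_away_from_apical_reference(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        plane = ps.fit_plane(pts, apical_reference=np.array([0.0, 0.0, 5.0]))
        assert np.asarray(plane.normal)[2] < 0

    def test_collinear_and_underdetermined_rejected(self):
        with pytest.raises(ps.GeometryError, match="collinear"):
            ps.fit_plane(np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2]], float))
        with pytest.raises(ps.ValidationError):
            ps.fit_plane(np.array([[0, 0, 0], [1, 0, 0]], float))


class TestExtractCejCurve:
    def test_curve_lies_on_the_generated_cej_plane(self, two_rooted):
        pts = ps.extract_cej_curve(two_rooted.vol)
        z0 = two_rooted.gt.cej_plane.point[2]
        sz = two_rooted.vol.spacing[2]
        assert len(pts) > 50
        assert np.all(np.abs(pts[:, 2] - z0) <= sz + 1e-9)

    def test_rotation_about_z_rotates_the_curve(self, two_rooted):
        vol = two_rooted.vol
        pts = ps.extract_cej_curve(vol)
        rot = ps.LabeledVolume(np.rot90(vol.voxels, axes=(0, 1)).copy(),
                               vol.spacing, vol.origin)
        pts_r = ps.extract_cej_curve(rot)
        assert len(pts_r) == len(pts)
        # the curve's plane is unchanged by an in-plane rotation
        assert ps.fit_plane(pts_r).point[2] == pytest.approx(ps.fit_plane(pts).point[2],
                                                             abs=vol.spacing[2] / 2)

    def test_missing_enamel_rejected(self):
        arr = np.full((6, 6, 6), 2, dtype=np.uint8)
        arr[2:4, 2:4, 2:4] = 3
        with pytest.raises(ps.ValidationError, match="enamel"):
            ps.extract_cej_curve(ps.LabeledVolume(arr, (0.05,) * 3))

    def test_solid_block_without_background_contact_flagged(self):
        arr = np.full((6, 6, 6), 2, dtype=np.uint8)
        arr[:, :, :2] = 1  # enamel buried under nothing: no background anywhere
        with pytest.raises(ps.GeometryError, match="surface"):
            ps.extract_cej_curve(ps.LabeledVolume(arr, (0.05,) * 3))


class TestReorient:
    def test_axis_aligned_plane_preserves_labels_exactly(self, two_rooted):
        vol = two_rooted.vol
        plane = ps.Plane((1.0, 1.0, 2.4), (0.0, 0.0, -1.0))
        out, _ = ps.reorient(vol, plane)
        got, want = out.label_counts(), vol.label_counts()
        assert {k: got[k] for k in (1, 2, 3)} == {k: want[k] for k in (1, 2, 3)}

    def test_reorient_is_idempotent_up_to_resampling_jitter(self, two_rooted):
        plane = ps.Plane((1.0, 1.0, 2.4), (0.0, 0.0, -1.0))
        once, _ = ps.reorient(two_rooted.vol, plane)
        twice, _ = ps.reorient(once, plane)
        c1, c2 = once.label_counts(), twice.label_counts()
        for lab in (1, 2, 3):
            assert abs(c2[lab] - c1[lab]) <= 0.005 * c1[lab] + 1

    def test_rotated_volume_label_counts_within_two_percent(self, two_rooted):
        vol = two_rooted.vol
        R = rotation_about(np.array([1.0, 0.0, 0.0]), np.deg2rad(15))
        t = RigidTransform(R, np.asarray(vol.world(np.array(vol.shape) / 2)))
        out = resample_rigid(vol, t, pad_mm=0.4)
        c0, c1 = vol.label_counts(), out.label_counts()
        for lab in (1, 2, 3):
            assert abs(c1[lab] - c0[lab]) / c0[lab] < 0.02

    def test_rotated_phantom_recovers_furcation_depth_within_one_slice(self, two_rooted):
        vol, lms = two_rooted.vol, two_rooted.lms
        R = rotation_about(np.array([1.0, 0.0, 0.0]), np.deg2rad(15))
        t = RigidTransform(R, np.asarray(vol.world(np.array(vol.shape) / 2)))
        vol_r = resample_rigid(vol, t, pad_mm=0.4)
        res_r = ps.run_pipeline(vol_r, lms.transformed(t.apply),
                                two_rooted.spec.arch, two_rooted.spec.side)
        d0 = two_rooted.res.tree.events()[0].depth
        d1 = res_r.tree.events()[0].depth
        assert abs(d0 - d1) <= vol.spacing[2]
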