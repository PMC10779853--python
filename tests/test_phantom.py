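"""Phantom generator: determinism, topology, and ground-truth contracts."""

import numpy as np
import pytest
from scipy import ndimage

import pulpsweep as ps
from pulpsweep.phantom import CanalSpec, Leaf, PhantomSpec, Split


def test_build_is_deterministic_bit_identical():
    spec = ps.preset("mand_radix", 3)
    vol1, _ = ps.build_phantom(spec)
    vol2, _ = ps.build_phantom(spec)
    assert np.array_equal(vol1.voxels, vol2.voxels)


def test_preset_is_deterministic_under_seed():
    assert ps.preset("mand_two_rooted", 1) == ps.preset("mand_two_rooted", 1)
    assert ps.preset("mand_two_rooted", 1) != ps.preset("mand_two_rooted", 2)


def test_unknown_preset_lists_valid_names():
    with pytest.raises(ps.PhantomSpecError, match="mand_two_rooted"):
        ps.preset("no_such_tooth")


def test_ground_truth_depths_copy_the_split_plan(radix):
    plan = radix.spec.plan
    depths = sorted(e.depth for e in radix.gt.split_events)
    assert depths[0] == plan.depth
    assert depths[1] == plan.children[1].depth
    # second event separates the two distal canals
    second = max(radix.gt.split_events, key=lambda e: e.depth)
    assert sorted(g[0] for g in second.child_groups) == ["D", "DL"]


def test_pulp_is_single_26_connected_component(two_rooted, radix, c_shape):
    for run in (two_rooted, radix, c_shape):
        _, n = ndimage.label(run.vol.pulp_mask(), structure=np.ones((3, 3, 3)))
        assert n == 1, run.name


def test_slice_counting_oracle_matches_split_plan(radix):
    """Independent per-slice 2D component count against the declared plan."""
    spec, vol = radix.spec, radix.vol
    d1 = spec.plan.depth
    d2 = spec.plan.children[1].depth
    sz = spec.spacing[2]
    for depth, expected in [(d1 - 0.2, 1), ((d1 + d2) / 2, 2), (d2 + 0.2, 3)]:
        k = int(round((spec.cej_z + depth) / sz))
        _, n = ndimage.label(vol.voxels[:, :, k] == 3, structure=np.ones((3, 3)))
        assert n == expected, f"depth {depth}"


def test_region_counts_conserve_pulp_voxels(three_rooted):
    gt, vol = three_rooted.gt, three_rooted.vol
    assert sum(gt.region_counts.values()) == vol.label_counts()[3]
    for i, name in enumerate(gt.region_names):
        assert gt.region_counts[name] == int((gt.region_map == i + 1).sum())


def test_mandibular_anchor_scheme(two_rooted):
    anchors = two_rooted.gt.landmarks.anchors()
    assert len(anchors) == 4
    surfaces = sorted(p.surface for p in anchors)
    assert surfaces == ["buccal", "buccal", "lingual", "lingual"]


def test_maxillary_standard_has_three_anchors(three_rooted):
    assert len(three_rooted.gt.landmarks.anchors()) == 3


def test_dipping_palatal_cej_gets_paired_anchors():
    spec = ps.preset("max_fused", 0)
    _, gt = ps.build_phantom(spec)
    anchors = gt.landmarks.anchors()
    assert len(anchors) == 4
    assert sum(p.surface == "palatal" for p in anchors) == 2


def test_zero_noise_landmarks_equal_ground_truth(two_rooted):
    lms = ps.render_landmarks(two_rooted.gt, noise_sigma=0.0)
    np.testing.assert_array_equal(lms.anchor_array(), two_rooted.gt.landmarks.anchor_array())
    noisy1 = ps.render_landmarks(two_rooted.gt, noise_sigma=0.05, seed=7)
    noisy2 = ps.render_landmarks(two_rooted.gt, noise_sigma=0.05, seed=7)
    np.testing.assert_array_equal(noisy1.anchor_array(), noisy2.anchor_array())
    assert not np.array_equal(noisy1.anchor_array(), two_rooted.gt.landmarks.anchor_array())


def test_c_shape_preset_has_ribbon_and_separate_palatal():
    spec = ps.preset("max_c_shape", 7)
    assert spec.c_shape_ribbon
    ribbon = spec.plan.children[0]
    assert isinstance(ribbon, Leaf) and ribbon.ribbon and set(ribbon.labels) == {"MB", "DB"}
    assert spec.plan.children[1].labels == ("P",)


def test_apical_dp_preset_splits_mesially_first():
    spec = ps.preset("max_apical_dp", 3)
    d1 = spec.plan.depth
    inner = spec.plan.children[1]
    assert isinstance(inner, Split) and inner.depth > d1
    assert set(ps.phantom._leaf_labels(inner)) == {"DB", "P"}


@pytest.mark.parametrize("name", ps.PRESETS)
def test_preset_jitter_keeps_specs_valid(name):
    for seed in range(8):
        ps.preset(name, seed).validate()


def test_geometrically_inconsistent_spec_rejected_with_pair():
    bad = PhantomSpec(
        arch="mandibular", side="right",
        canals=(CanalSpec("M", (0, 0.15), (0, 0.15), 0.45, 0.3, 4.0),
                CanalSpec("D", (0, -0.15), (0, -0.15), 0.45, 0.3, 4.0)),
        plan=Split(2.0, (Leaf(("M",)), Leaf(("D",)))),
    )
    with pytest.raises(ps.PhantomSpecError, match="merge below"):
        ps.build_phantom(bad)


def test_decreasing_split_depths_rejected():
    bad = PhantomSpec(
        arch="mandibular", side="right",
        canals=(CanalSpec("M", (0, 1.1), (0, 1.1), 0.4, 0.3, 4.0),
                CanalSpec("D", (0.45, -1.0), (0.45, -1.0), 0.35, 0.2, 4.0),
                CanalSpec("DL", (-0.55, -1.0), (-0.55, -1.0), 0.3, 0.2, 4.0)),
        plan=Split(2.0, (Leaf(("M",)), Split(1.5, (Leaf(("D",)), Leaf(("DL",)))))),
    )
    with pytest.raises(ps.PhantomSpecError, match="strictly increase"):
        bad.validate()
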