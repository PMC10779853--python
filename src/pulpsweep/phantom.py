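"""Parametric voxel tooth phantoms with known furcation ground truth.

Each phantom is a labeled volume (background / enamel / dentine / pulp)
built in a canonical frame: axis 0 points buccally, axis 2 apically, and
the CEJ plane sits at a fixed z.  The pulp is a chamber solid (a
superellipse prism capped occlusally by dentine) joined to tapered
circular canals; canals that separate deeper than the chamber floor stay
connected through stadium-shaped bridges until their declared split
depth, and a C-shaped ribbon is a swept crescent that never splits.
Dentine is an equal-thickness shell around the pulp (computed from a 3D
Euclidean distance transform), and enamel is a second shell restricted to
above the CEJ plane — so the CEJ curve is recoverable as the apical rim
of the enamel label.  An optional apically-dipping CEJ sector emulates
teeth whose palatal CEJ extends toward the root.

The generator emits a :class:`GroundTruth` carrying the CEJ plane, the
slice-anchor landmarks A-D, every split event (depth, saddle, child
groups — the anatomical landmarks D/E/F), the true orifice plane of every
canal, and exact per-region voxel counts, so the whole downstream
pipeline can be validated without scans.

Presets cover the morphology catalogue: two- and three-rooted mandibular
molars (the latter with a disto-lingual Radix Entomolaris root),
maxillary molars with three separate roots, with an apically displaced
disto-palatal bifurcation, with fused roots and a dipping palatal CEJ,
with a C-shaped shared MB/DB ribbon, and a mesotaurodont form with a
deep chamber floor.  Preset dimensions are plausible literature-scale
values for first permanent molars; they are synthetic, not measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import PhantomSpecError
from .geometry import Plane, build_frame
from .volume import (
    ANCHOR_TAG,
    BACKGROUND,
    CEJ_TAG,
    DENTINE,
    ENAMEL,
    PULP,
    LabeledVolume,
    Landmark,
    LandmarkSet,
)

PRESETS = (
    "mand_two_rooted",
    "mand_radix",
    "max_three_rooted",
    "max_apical_dp",
    "max_fused",
    "max_c_shape",
    "max_taurodont",
)

_N26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class CanalSpec:
    """A tapered circular canal.  Offsets are (buccal, mesial) mm from the
    chamber axis; depths are mm below the CEJ plane, positive apically."""

    label: str
    floor_offset: tuple[float, float]
    apex_offset: tuple[float, float]
    start_radius: float
    apex_radius: float
    apex_depth: float


@dataclass(frozen=True)
class Leaf:
    """A terminal branch: one canal, or several confluent canals forming a
    C-shaped ribbon that never separates."""

    labels: tuple[str, ...]
    ribbon: bool = False

    @property
    def name(self) -> str:
        return "//".join(self.labels)


@dataclass(frozen=True)
class Split:
    """A furcation: ``children`` separate from each other at ``depth``."""

    depth: float
    children: tuple  # of Leaf | Split


def _leaf_labels(node) -> tuple[str, ...]:
    if isinstance(node, Leaf):
        return node.labels
    out: tuple[str, ...] = ()
    for c in node.children:
        out += _leaf_labels(c)
    return out


@dataclass(frozen=True)
class PhantomSpec:
    arch: str
    side: str
    shape: tuple[int, int, int] = (120, 120, 160)
    spacing: tuple[float, float, float] = (0.05, 0.05, 0.05)
    cej_z: float = 2.4  # mm from the occlusal grid face
    chamber_half_widths: tuple[float, float] = (1.5, 1.5)  # (buccal, mesial) mm
    chamber_occlusal_height: float = 1.2  # chamber extent above the CEJ plane, mm
    chamber_floor_depth: float | None = None  # below CEJ; defaults to first split depth
    dentine_thickness: float = 0.6
    enamel_thickness: float = 0.35
    canals: tuple[CanalSpec, ...] = ()
    plan: Leaf | Split = Leaf(("C1",))
    bridge_width_factor: float = 0.8  # bridge half-width as a fraction of member radius
    cej_dip: tuple[float, float, float] | None = None  # (amplitude mm, direction deg, half-width deg)
    fused_pair: bool = False
    c_shape_ribbon: bool = False
    taurodont: bool = False
    apical_dp_bifurcation: bool = False
    seed: int = 0

    def first_split_depth(self) -> float | None:
        return self.plan.depth if isinstance(self.plan, Split) else None

    def floor_depth(self) -> float:
        d = self.first_split_depth()
        if d is not None:
            return d
        if self.chamber_floor_depth is None:
            raise PhantomSpecError("single-canal spec needs an explicit chamber_floor_depth")
        return self.chamber_floor_depth

    def validate(self) -> None:
        if self.arch not in ("maxillary", "mandibular"):
            raise PhantomSpecError(f"unknown arch {self.arch!r}")
        labels = _leaf_labels(self.plan)
        if len(set(labels)) != len(labels):
            raise PhantomSpecError("a canal label appears in more than one leaf")
        if set(labels) != {c.label for c in self.canals}:
            raise PhantomSpecError("split plan labels do not match the canal list")
        self._check_depths(self.plan, parent=0.0)
        vmax = 2.0 * max(self.spacing[0], self.spacing[1])
        by_label = {c.label: c for c in self.canals}
        nz_mm = self.shape[2] * self.spacing[2]
        for c in self.canals:
            if c.start_radius <= 0 or c.apex_radius <= 0:
                raise PhantomSpecError(f"canal {c.label}: radii must be positive")
            if c.start_radius < vmax:
                raise PhantomSpecError(
                    f"canal {c.label}: start radius {c.start_radius} mm is below the "
                    f"2-voxel minimum ({vmax} mm)"
                )
            apex_z = self.cej_z + c.apex_depth
            if apex_z + self.dentine_thickness >= nz_mm:
                raise PhantomSpecError(f"canal {c.label}: apex (+dentine margin) leaves the grid")
        # every bridged member must outlive its group's split depth
        self._check_apices(self.plan, by_label)

    def _check_depths(self, node, parent: float) -> None:
        if isinstance(node, Split):
            if node.depth <= parent:
                raise PhantomSpecError(
                    f"split depths must strictly increase along a path "
                    f"({node.depth} <= {parent})"
                )
            if len(node.children) < 2:
                raise PhantomSpecError("a split needs >= 2 children")
            for c in node.children:
                self._check_depths(c, node.depth)

    def _check_apices(self, node, by_label) -> None:
        if isinstance(node, Split):
            for c in node.children:
                for lab in _leaf_labels(c):
                    if by_label[lab].apex_depth <= node.depth:
                        raise PhantomSpecError(
                            f"canal {lab} ends above its split depth {node.depth}"
                        )
                self._check_apices(c, by_label)


@dataclass(frozen=True)
class SplitEvent:
    depth: float  # mm below the CEJ plane
    saddle: tuple[float, float, float]  # world mm (the landmark D/E/F position)
    parent_labels: tuple[str, ...]
    child_groups: tuple[tuple[str, ...], ...]


@dataclass
class GroundTruth:
    """Generative ground truth for one phantom."""

    arch: str
    side: str
    cej_plane: Plane
    landmarks: LandmarkSet  # noise-free CEJ ring + slice anchors
    split_events: list[SplitEvent]
    orifice_depths: dict[str, float]  # per leaf name ("M", "MB//DB", ...)
    shared_groups: list[tuple[str, ...]]
    region_counts: dict[str, int]
    region_map: np.ndarray = field(repr=False)  # 0 = non-pulp, i+1 = region_names[i]
    region_names: list[str] = field(default_factory=list)
    canal_floor_points: dict[str, tuple[float, float, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry helpers


def _superellipse_mask(xs, ys, cx, cy, ax, ay, p=2.5):
    return (np.abs((xs - cx) / ax) ** p + np.abs((ys - cy) / ay) ** p) <= 1.0


def _superellipse_radius(ux, uy, ax, ay, p=2.5):
    return (np.abs(ux / ax) ** p + np.abs(uy / ay) ** p) ** (-1.0 / p)


def _disk(xs, ys, cx, cy, r):
    return (xs - cx) ** 2 + (ys - cy) ** 2 <= r * r


def _stadium(xs, ys, p0, p1, w):
    """Points within distance w of the segment p0-p1."""
    d = np.asarray(p1, dtype=float) - np.asarray(p0, dtype=float)
    L2 = float(d @ d)
    px, py = xs - p0[0], ys - p0[1]
    if L2 < 1e-12:
        return px * px + py * py <= w * w
    t = np.clip((px * d[0] + py * d[1]) / L2, 0.0, 1.0)
    qx, qy = px - t * d[0], py - t * d[1]
    return qx * qx + qy * qy <= w * w


class _Branch:
    """An active node of the split plan with its slice-mask renderer."""

    def __init__(self, node, spec: PhantomSpec, by_label, to_world, parent_depth: float):
        self.node = node
        self.parent_depth = parent_depth
        self.spec = spec
        self.by_label = by_label
        self.to_world = to_world
        self.labels = _leaf_labels(node)
        if isinstance(node, Leaf):
            self.name = node.name
            self.end_depth = max(by_label[l].apex_depth for l in node.labels)
        else:
            self.name = "shared:" + "+".join(sorted(self.labels))
            self.end_depth = node.depth

    def canal_center(self, label: str, s: float) -> np.ndarray:
        c = self.by_label[label]
        floor = self.spec.floor_depth()
        t = 0.0 if c.apex_depth <= floor else np.clip((s - floor) / (c.apex_depth - floor), 0, 1)
        off = (1 - t) * np.asarray(c.floor_offset) + t * np.asarray(c.apex_offset)
        return self.to_world(off)

    def canal_radius(self, label: str, s: float) -> float:
        c = self.by_label[label]
        floor = self.spec.floor_depth()
        t = 0.0 if c.apex_depth <= floor else np.clip((s - floor) / (c.apex_depth - floor), 0, 1)
        return float((1 - t) * c.start_radius + t * c.apex_radius)

    def mask(self, xs, ys, s: float) -> np.ndarray:
        node = self.node
        if isinstance(node, Leaf) and node.ribbon:
            return self._ribbon_mask(xs, ys, s)
        m = np.zeros(xs.shape, dtype=bool)
        active = [l for l in self.labels if self.by_label[l].apex_depth >= s]
        for lab in active:
            cx, cy = self.canal_center(lab, s)
            m |= _disk(xs, ys, cx, cy, self.canal_radius(lab, s))
        if isinstance(node, Split) and len(active) >= 2:
            # keep the pending group confluent until its split depth
            w = self.spec.bridge_width_factor * min(self.canal_radius(l, s) for l in active)
            reps = [self._group_rep(c, s) for c in node.children]
            reps = [r for r in reps if r is not None]
            for a, b in zip(reps[:-1], reps[1:]):
                m |= _stadium(xs, ys, a, b, w)
        return m

    def _group_rep(self, child, s):
        labs = [l for l in _leaf_labels(child) if self.by_label[l].apex_depth >= s]
        if not labs:
            return None
        pts = np.array([self.canal_center(l, s) for l in labs])
        return pts.mean(axis=0)

    def _ribbon_mask(self, xs, ys, s: float) -> np.ndarray:
        labs = list(self.node.labels)
        if s > self.end_depth:
            return np.zeros(xs.shape, dtype=bool)
        pts = [self.canal_center(l, s) for l in labs]
        w = min(self.canal_radius(l, s) for l in labs)
        # bow the ribbon buccally (+x in the canonical frame) into a crescent
        mid = 0.5 * (np.asarray(pts[0]) + np.asarray(pts[-1]))
        chord = np.linalg.norm(np.asarray(pts[-1]) - np.asarray(pts[0]))
        bow = mid + np.array([0.35 * chord, 0.0]) * np.sign(mid[0] - 0.0 + 1e-9)
        m = np.zeros(xs.shape, dtype=bool)
        poly = [pts[0], bow, pts[-1]]
        for a, b in zip(poly[:-1], poly[1:]):
            m |= _stadium(xs, ys, a, b, w)
        return m


def _active_branches(spec: PhantomSpec, by_label, to_world, s: float) -> list[_Branch]:
    """Branches whose cross-sections exist at depth s (below the floor)."""
    out: list[_Branch] = []

    def walk(node, parent_depth):
        if isinstance(node, Leaf):
            br = _Branch(node, spec, by_label, to_world, parent_depth)
            if parent_depth <= s <= br.end_depth:
                out.append(br)
            return
        if s < node.depth:
            if parent_depth <= s:
                out.append(_Branch(node, spec, by_label, to_world, parent_depth))
            return
        for c in node.children:
            walk(c, node.depth)

    root_depth = spec.floor_depth()
    walk(spec.plan, root_depth)
    return out


# ---------------------------------------------------------------------------
# the generator


def build_phantom(spec: PhantomSpec) -> tuple[LabeledVolume, GroundTruth]:
    """Render a spec into a labeled volume plus its ground truth.

    Deterministic: the same spec always yields bit-identical voxels.
    Raises :class:`PhantomSpecError` when canal tubes would merge below
    their declared split depth (the spec is geometrically inconsistent).
    """
    spec.validate()
    nx, ny, nz = spec.shape
    sx, sy, sz = spec.spacing
    cx, cy = (nx - 1) * sx / 2.0, (ny - 1) * sy / 2.0
    frame = build_frame(np.array([0.0, 0.0, -1.0]), np.array([1.0, 0.0, 0.0]),
                        spec.arch, spec.side)
    mesial_y = float(frame.mesial[1])  # +-1: canonical mesial direction along y

    def to_world(offset_bm) -> np.ndarray:
        b, m = offset_bm
        return np.array([cx + b, cy + m * mesial_y])

    by_label = {c.label: c for c in spec.canals}
    xs = (np.arange(nx) * sx)[:, None] * np.ones((1, ny))
    ys = np.ones((nx, 1)) * (np.arange(ny) * sy)[None, :]
    ax, ay = spec.chamber_half_widths
    chamber2d = _superellipse_mask(xs, ys, cx, cy, ax, ay)

    floor = spec.floor_depth()
    pulp = np.zeros((nx, ny, nz), dtype=bool)
    region = np.zeros((nx, ny, nz), dtype=np.int16)
    region_names: list[str] = ["chamber"]

    def region_id(name: str) -> int:
        if name not in region_names:
            region_names.append(name)
        return region_names.index(name) + 1

    slice_branches: dict[int, list[tuple[str, np.ndarray]]] = {}
    for k in range(nz):
        s = k * sz - spec.cej_z  # depth below the CEJ plane
        masks: list[tuple[str, np.ndarray]] = []
        if -spec.chamber_occlusal_height <= s < floor:
            masks.append(("chamber", chamber2d))
        elif s >= floor:
            for br in _active_branches(spec, by_label, to_world, s):
                m = br.mask(xs, ys, s)
                if m.any():
                    masks.append((br.name, m))
        if not masks:
            continue
        slice_branches[k] = masks
        for name, m in masks:
            pulp[:, :, k] |= m
            rid = region_id(name)
            sel = m & (region[:, :, k] == 0)
            region[:, :, k][sel] = rid

    _check_topology(spec, pulp, slice_branches, sz)

    # dentine / enamel shells from the 3D distance to pulp
    dist = ndimage.distance_transform_edt(~pulp, sampling=spec.spacing)
    t_d = spec.dentine_thickness * (1.3 if spec.fused_pair else 1.0)
    t_e = spec.enamel_thickness
    zmm = np.arange(nz) * sz
    s_of_z = zmm - spec.cej_z
    dip = _dip_profile(spec, xs, ys, cx, cy)  # (nx, ny) apical CEJ extension, mm >= 0
    vox = np.zeros((nx, ny, nz), dtype=np.uint8)
    vox[(dist > 0) & (dist <= t_d)] = DENTINE
    enamel_shell = (dist > t_d) & (dist <= t_d + t_e)
    above_cej = s_of_z[None, None, :] < dip[:, :, None]
    vox[enamel_shell & above_cej] = ENAMEL
    vox[pulp] = PULP

    if vox[0, :, :].any() or vox[-1, :, :].any() or vox[:, 0, :].any() or vox[:, -1, :].any() \
            or vox[:, :, 0].any() or vox[:, :, -1].any():
        raise PhantomSpecError("tooth touches the grid boundary; enlarge the grid")

    vol = LabeledVolume(vox, spec.spacing, (0.0, 0.0, 0.0),
                        {"phantom": True, "arch": spec.arch, "side": spec.side})
    gt = _ground_truth(spec, vol, region, region_names, slice_branches,
                       frame, cx, cy, to_world)
    return vol, gt


def _dip_profile(spec: PhantomSpec, xs, ys, cx, cy) -> np.ndarray:
    if spec.cej_dip is None:
        return np.zeros(xs.shape)
    amp, direction_deg, half_width_deg = spec.cej_dip
    theta = np.arctan2(ys - cy, xs - cx)
    delta = np.angle(np.exp(1j * (theta - np.deg2rad(direction_deg))))
    hw = np.deg2rad(half_width_deg)
    bump = np.clip(1.0 - (delta / hw) ** 2, 0.0, None)
    return amp * bump


def _check_topology(spec, pulp, slice_branches, sz) -> None:
    """Independent checks that the rendered pulp realizes the split plan."""
    _, ncomp = ndimage.label(pulp, structure=_N26)
    if ncomp != 1:
        raise PhantomSpecError(
            f"pulp is not a single 26-connected component ({ncomp} found); "
            "a canal is disconnected from the chamber"
        )
    struct2d = np.ones((3, 3), dtype=bool)
    for k, masks in slice_branches.items():
        expected = len(masks)
        merged = np.zeros(pulp.shape[:2], dtype=bool)
        for _, m in masks:
            merged |= m
        _, n = ndimage.label(merged, structure=struct2d)
        if n < expected:
            pair = _find_touching_pair(masks, struct2d)
            raise PhantomSpecError(
                f"canal tubes merge below their declared split depth at slice {k} "
                f"(depth {k * sz - spec.cej_z:.3f} mm): offending pair {pair}"
            )


def _find_touching_pair(masks, struct2d):
    for i in range(len(masks)):
        di = ndimage.binary_dilation(masks[i][1], structure=struct2d)
        for j in range(i + 1, len(masks)):
            if (di & masks[j][1]).any():
                return (masks[i][0], masks[j][0])
    return ("?", "?")


def _leaves(node):
    if isinstance(node, Leaf):
        return [node]
    out = []
    for c in node.children:
        out += _leaves(c)
    return out


def _ground_truth(spec, vol, region, region_names, slice_branches, frame, cx, cy, to_world):
    sx, sy, sz = spec.spacing
    cej_plane = Plane((cx, cy, spec.cej_z), (0.0, 0.0, -1.0))

    # split events, walking the plan
    events: list[SplitEvent] = []

    def walk(node):
        if isinstance(node, Leaf):
            return
        child_groups = tuple(tuple(_leaf_labels(c)) for c in node.children)
        saddle = _true_saddle(spec, region, region_names, node, sz)
        events.append(SplitEvent(node.depth, saddle, _leaf_labels(node), child_groups))
        for c in node.children:
            walk(c)

    walk(spec.plan)
    events.sort(key=lambda e: e.depth)

    orifice_depths: dict[str, float] = {}
    shared_groups: list[tuple[str, ...]] = []

    def assign(node, parent_depth):
        if isinstance(node, Leaf):
            orifice_depths[node.name] = parent_depth
            if len(node.labels) > 1:
                shared_groups.append(node.labels)
            return
        for c in node.children:
            assign(c, node.depth)

    # a tooth with no splits keeps its orifice at the CEJ plane (depth 0)
    assign(spec.plan, spec.first_split_depth() or 0.0)
    if not isinstance(spec.plan, Split):
        orifice_depths[spec.plan.name] = 0.0

    counts = {name: int((region == i + 1).sum()) for i, name in enumerate(region_names)}
    landmarks = _true_landmarks(spec, frame, cx, cy)
    floor_pts = {
        c.label: tuple(np.r_[to_world(c.floor_offset), spec.cej_z + spec.floor_depth()])
        for c in spec.canals
    }
    return GroundTruth(
        arch=spec.arch, side=spec.side, cej_plane=cej_plane, landmarks=landmarks,
        split_events=events, orifice_depths=orifice_depths, shared_groups=shared_groups,
        region_counts=counts, region_map=region, region_names=list(region_names),
        canal_floor_points=floor_pts,
    )


def _true_saddle(spec, region, region_names, node: Split, sz) -> tuple[float, float, float]:
    """Midpoint of the shortest inter-child gap at the first separated
    slice (the near-minimal-pair average shared with the detector)."""
    from .sweep import saddle_between

    k = int(np.ceil((spec.cej_z + node.depth) / sz - 1e-9))
    child_masks = []
    for c in node.children:
        names = {br.name for br in _leaves_branch_names(c)}
        ids = [i + 1 for i, n in enumerate(region_names) if n in names]
        m = np.isin(region[:, :, k], ids)
        if m.any():
            child_masks.append(m)
    if len(child_masks) < 2:  # pragma: no cover - guarded by topology check
        raise PhantomSpecError(f"split at {node.depth} mm has no separated slice")
    x, y = saddle_between(child_masks, spec.spacing[:2], (0.0, 0.0))
    return (x, y, float(spec.cej_z + node.depth))


def _leaves_branch_names(node):
    class _N:  # tiny adapter exposing .name like _Branch
        def __init__(self, name):
            self.name = name

    out = [_N(l.name) for l in _leaves(node)]
    if isinstance(node, Split):
        out.append(_N("shared:" + "+".join(sorted(_leaf_labels(node)))))
        for c in node.children:
            if isinstance(c, Split):
                out += _leaves_branch_names(c)
    return out


def _true_landmarks(spec: PhantomSpec, frame, cx, cy) -> LandmarkSet:
    ax, ay = spec.chamber_half_widths
    t_d = spec.dentine_thickness * (1.3 if spec.fused_pair else 1.0)
    mesial_y = float(frame.mesial[1])

    def ring_point(direction_bm, name, tag, anat=None, surface=None) -> Landmark:
        b, m = direction_bm
        ux, uy = b, m * mesial_y
        n = np.hypot(ux, uy)
        ux, uy = ux / n, uy / n
        r = _superellipse_radius(ux, uy, ax, ay) + t_d
        x, y = cx + r * ux, cy + r * uy
        z = spec.cej_z + _dip_profile(spec, np.array([[x]]), np.array([[y]]), cx, cy)[0, 0]
        return Landmark(name, (x, y, z), tag, anat, surface)

    pts: list[Landmark] = []
    for i, th in enumerate(np.linspace(0, 2 * np.pi, 16, endpoint=False)):
        pts.append(ring_point((np.cos(th), np.sin(th)), f"cej_{i:02d}", CEJ_TAG))

    if spec.arch == "mandibular":
        anchors = [
            (("A", "buccal"), (1.0, 0.7)),
            (("B", "buccal"), (1.0, -0.7)),
            (("C", "lingual"), (-1.0, -0.7)),
            (("D", "lingual"), (-1.0, 0.7)),
        ]
    elif spec.cej_dip is not None:
        # paired landmarks either side of the apically-dipping palatal CEJ
        _, direction_deg, half_width_deg = spec.cej_dip
        edge = np.deg2rad(direction_deg)
        hw = np.deg2rad(half_width_deg)
        anchors = [
            (("A", "buccal"), (np.cos(0.5), np.sin(0.5))),
            (("B", "buccal"), (np.cos(-0.5), np.sin(-0.5))),
            (("C", "palatal"), (np.cos(edge - hw), np.sin(edge - hw))),
            (("D", "palatal"), (np.cos(edge + hw), np.sin(edge + hw))),
        ]
        # buccal anchors expressed directly in canonical xy, not (buccal, mesial)
        pts += [
            Landmark(nm, _ring_xy(spec, cx, cy, ux, uy, t_d), ANCHOR_TAG, nm, surf)
            for (nm, surf), (ux, uy) in anchors
        ]
        return LandmarkSet(pts)
    else:
        anchors = [
            (("A", "buccal"), (1.0, 0.75)),
            (("B", "buccal"), (1.0, -0.75)),
            (("C", "palatal"), (-1.0, 0.0)),
        ]
    for (nm, surf), d in anchors:
        pts.append(ring_point(d, nm, ANCHOR_TAG, nm, surf))
    return LandmarkSet(pts)


def _ring_xy(spec, cx, cy, ux, uy, t_d) -> tuple[float, float, float]:
    n = np.hypot(ux, uy)
    ux, uy = ux / n, uy / n
    ax, ay = spec.chamber_half_widths
    r = _superellipse_radius(ux, uy, ax, ay) + t_d
    x, y = cx + r * ux, cy + r * uy
    z = spec.cej_z + _dip_profile(spec, np.array([[x]]), np.array([[y]]), cx, cy)[0, 0]
    return (float(x), float(y), float(z))


def render_landmarks(gt: GroundTruth, noise_sigma: float = 0.0, seed: int = 0) -> LandmarkSet:
    """The ground-truth landmark set, optionally with Gaussian placement
    noise of ``noise_sigma`` mm on the slice anchors (robustness tests)."""
    if noise_sigma <= 0:
        return gt.landmarks
    rng = np.random.default_rng(seed)
    pts = []
    for p in gt.landmarks.points:
        if p.tag == ANCHOR_TAG:
            xyz = tuple(np.asarray(p.xyz) + rng.normal(0.0, noise_sigma, 3))
            pts.append(replace(p, xyz=xyz))
        else:
            pts.append(p)
    return LandmarkSet(pts)


def add_pulp_stone(vol: LabeledVolume, center_world, n_voxels: int = 3) -> LabeledVolume:
    """Embed a tiny isolated pulp islet (a simplified pulp stone remnant)
    near ``center_world``; used to exercise the sweep's min-area filter."""
    out = vol.voxels.copy()
    idx = np.round(vol.index(np.asarray(center_world))).astype(int)
    placed = 0
    for off in ([0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0], [0, 0, 1]):
        if placed >= n_voxels:
            break
        i, j, k = idx + np.asarray(off)
        if out[i, j, k] == DENTINE:
            out[i, j, k] = PULP
            placed += 1
    return LabeledVolume(out, vol.spacing, vol.origin, dict(vol.meta))


# ---------------------------------------------------------------------------
# presets


def _jit(rng, v):
    return float(v * rng.uniform(0.9, 1.1))


def preset(name: str, seed: int = 0) -> PhantomSpec:
    """A PhantomSpec for one of the catalogued morphologies, with ±10%
    jitter on furcation depths and canal radii under the seed."""
    if name not in PRESETS:
        raise PhantomSpecError(f"unknown preset {name!r}; valid names: {', '.join(PRESETS)}")
    rng = np.random.default_rng(seed)

    if name == "mand_two_rooted":
        d1 = _jit(rng, 2.0)
        canals = (
            CanalSpec("M", (0.0, 1.1), (0.0, 1.3), _jit(rng, 0.45), _jit(rng, 0.25), 4.2),
            CanalSpec("D", (0.0, -1.1), (0.0, -1.3), _jit(rng, 0.45), _jit(rng, 0.28), 4.2),
        )
        return PhantomSpec(
            arch="mandibular", side="right", chamber_half_widths=(1.4, 1.8),
            canals=canals, plan=Split(d1, (Leaf(("M",)), Leaf(("D",)))), seed=seed,
        )

    if name == "mand_radix":
        d1 = _jit(rng, 1.8)
        d2 = d1 + _jit(rng, 0.8)
        canals = (
            CanalSpec("M", (0.0, 1.1), (0.0, 1.3), _jit(rng, 0.42), _jit(rng, 0.24), 4.2),
            CanalSpec("D", (0.45, -1.0), (0.55, -1.15), _jit(rng, 0.35), _jit(rng, 0.2), 4.2),
            CanalSpec("DL", (-0.55, -1.0), (-0.7, -1.15), _jit(rng, 0.3), _jit(rng, 0.18), 4.0),
        )
        plan = Split(d1, (Leaf(("M",)), Split(d2, (Leaf(("D",)), Leaf(("DL",))))))
        return PhantomSpec(
            arch="mandibular", side="right", chamber_half_widths=(1.4, 1.8),
            canals=canals, plan=plan, seed=seed,
        )

    maxilla = dict(arch="maxillary", side="left", chamber_half_widths=(1.5, 1.5))
    if name in ("max_three_rooted", "max_fused", "max_taurodont"):
        deep = name == "max_taurodont"
        d1 = _jit(rng, 3.6 if deep else 1.6)
        d2 = d1 + _jit(rng, 0.6 if deep else 0.8)
        apex = 4.8 if deep else 4.2
        canals = (
            CanalSpec("P", (-1.0, 0.0), (-1.25, 0.0), _jit(rng, 0.45), _jit(rng, 0.28), apex),
            CanalSpec("MB", (0.9, 0.75), (1.05, 0.9), _jit(rng, 0.35), _jit(rng, 0.2), apex),
            CanalSpec("DB", (0.9, -0.75), (1.05, -0.9), _jit(rng, 0.35), _jit(rng, 0.2), apex),
        )
        plan = Split(d1, (Leaf(("P",)), Split(d2, (Leaf(("MB",)), Leaf(("DB",))))))
        extra: dict = {}
        if name == "max_fused":
            extra = dict(fused_pair=True, cej_dip=(0.5, 180.0, 40.0))
        if deep:
            extra = dict(taurodont=True, cej_z=2.2, chamber_occlusal_height=0.8)
        return PhantomSpec(canals=canals, plan=plan, seed=seed, **maxilla, **extra)

    if name == "max_apical_dp":
        d1 = _jit(rng, 1.6)
        d2 = d1 + _jit(rng, 0.8)
        canals = (
            CanalSpec("P", (-1.0, 0.0), (-1.25, 0.0), _jit(rng, 0.45), _jit(rng, 0.28), 4.2),
            CanalSpec("MB", (0.9, 0.75), (1.05, 0.9), _jit(rng, 0.35), _jit(rng, 0.2), 4.2),
            CanalSpec("DB", (0.9, -0.75), (1.05, -0.9), _jit(rng, 0.35), _jit(rng, 0.2), 4.2),
        )
        # the disto-palatal separation lies deeper than the first (mesial) split
        plan = Split(d1, (Leaf(("MB",)), Split(d2, (Leaf(("DB",)), Leaf(("P",))))))
        return PhantomSpec(canals=canals, plan=plan, seed=seed,
                           apical_dp_bifurcation=True, **maxilla)

    # max_c_shape: MB and DB fused into a ribbon sharing one orifice; P separate
    d1 = _jit(rng, 1.6)
    canals = (
        CanalSpec("P", (-1.0, 0.0), (-1.25, 0.0), _jit(rng, 0.45), _jit(rng, 0.28), 4.2),
        CanalSpec("MB", (0.9, 0.75), (1.0, 0.85), _jit(rng, 0.3), _jit(rng, 0.2), 4.2),
        CanalSpec("DB", (0.9, -0.75), (1.0, -0.85), _jit(rng, 0.3), _jit(rng, 0.2), 4.2),
    )
    plan = Split(d1, (Leaf(("MB", "DB"), ribbon=True), Leaf(("P",))))
    return PhantomSpec(canals=canals, plan=plan, seed=seed, c_shape_ribbon=True, **maxilla)
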