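"""Landmark-anchored plane sweep and furcation (split-event) detection.

The cross-sectional plane anchored on landmarks A-D is translated
apically in fixed steps through the re-oriented volume.  On every slice
the pulp label is decomposed into 8-connected 2D components (small
islands below ``min_area`` — pulp stones, segmentation specks — are
discarded) and components are linked to the previous slice by maximal
pixel overlap.  A *furcation event* is the depth at which one tracked
component first maps to two (bifurcation) or three (trifurcation)
children: this is the plane-sweep operationalization of the slice
"crossing the pulp floor for the first time", and the event's saddle
point is the furcation zenith (the anatomical landmarks D/E/F).

Numerical conventions: the event depth is the midpoint between the last
single-parent slice and the first split slice (halving the worst-case
discretization error); splits whose children re-merge within
``merge_guard`` mm are treated as voxelization flicker and suppressed;
component merges (canals re-joining apically) end the absorbed branch but
never create events — the protocol stops at orifice level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure, morphology

from .errors import GeometryError, ValidationError
from .geometry import Plane, fit_plane
from .volume import DENTINE, PULP, LabeledVolume, LandmarkSet

log = logging.getLogger(__name__)

_AXIS2 = np.array([0.0, 0.0, 1.0])
_S8 = np.ones((3, 3), dtype=bool)

DEFAULT_MIN_AREA = 4  # voxels; suppresses pulp stones and noise
DEFAULT_MERGE_GUARD = 0.2  # mm; suppresses voxelization flicker at the saddle


def anchor_slice(anchors: LandmarkSet | np.ndarray, apical_reference=None) -> Plane:
    """The cross-sectional plane through the 3-4 slice-anchor landmarks.

    Three anchors give the exact plane; four give the total-least-squares
    plane.  The normal is oriented occlusally (away from
    ``apical_reference``, typically the pulp centroid) when a reference
    is supplied.
    """
    if isinstance(anchors, LandmarkSet):
        pts = anchors.anchor_array()
    else:
        pts = np.atleast_2d(np.asarray(anchors, dtype=float))
    if pts.shape[0] not in (3, 4):
        raise ValidationError(f"anchor slice needs 3 or 4 points, got {pts.shape[0]}")
    return fit_plane(pts, apical_reference=apical_reference)


@dataclass
class Component:
    """One 2D pulp cross-section component on a swept slice."""

    id: int
    parent_id: int | None
    area_mm2: float
    centroid: tuple[float, float, float]  # world mm
    contour: np.ndarray  # (n, 2) world xy polygon
    pixel_count: int
    merged_from: tuple[int, ...] = ()  # previous-slice ids absorbed into this one


@dataclass
class SliceSection:
    """All pulp components on one swept slice."""

    depth: float  # mm below the anchor plane, >= 0 apically
    k: int  # slice index along axis 2
    z_world: float
    components: list[Component]
    labeled: np.ndarray = field(repr=False)  # 2D array of global component ids
    spacing_xy: tuple[float, float] = (1.0, 1.0)
    origin_xy: tuple[float, float] = (0.0, 0.0)


def sweep(
    vol: LabeledVolume,
    plane: Plane,
    step: float | None = None,
    min_area: int = DEFAULT_MIN_AREA,
) -> list[SliceSection]:
    """Sweep the anchor plane apically; one SliceSection per step.

    Requires the volume to be re-oriented so the plane normal is
    anti-parallel to axis 2.  Stops at the first slice with no remaining
    pulp cross-section.
    """
    sx, sy, sz = vol.spacing
    n = np.asarray(plane.normal)
    angle = float(np.arccos(np.clip(-n @ _AXIS2, -1.0, 1.0)))
    if angle > 1e-6:
        raise ValidationError(
            f"volume is not re-oriented to the sweep plane (normal off axis 2 by "
            f"{np.degrees(angle):.4g} deg); call reorient() first"
        )
    step = sz if step is None else float(step)
    if step < sz - 1e-12:
        raise ValidationError(f"step {step} mm is below the axial voxel spacing {sz} mm")

    k_plane = (plane.point[2] - vol.origin[2]) / sz
    sections: list[SliceSection] = []
    next_id = 1
    prev: SliceSection | None = None
    i = 0
    while True:
        s = i * step
        k = int(round(k_plane + s / sz))
        if k >= vol.shape[2]:
            break
        mask = vol.voxels[:, :, k] == PULP
        lab, ncomp = ndimage.label(mask, structure=_S8)
        comps: list[Component] = []
        labeled = np.zeros_like(lab)
        areas = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, ncomp + 1))
        order = np.argsort(-areas)  # largest first: deterministic ids
        for li in order:
            npix = int(areas[li])
            if npix < min_area:
                continue
            m = lab == (li + 1)
            parent_id, merged = None, ()
            if prev is not None:
                overl = prev.labeled[m]
                overl = overl[overl > 0]
                if overl.size:
                    ids, cnts = np.unique(overl, return_counts=True)
                    parent_id = int(ids[np.argmax(cnts)])
                    if ids.size > 1:
                        merged = tuple(int(v) for v in ids if v != parent_id)
            cid = next_id
            next_id += 1
            labeled[m] = cid
            idx = np.argwhere(m)
            cworld = vol.world(np.array([idx[:, 0].mean(), idx[:, 1].mean(), k]))
            comps.append(Component(
                id=cid, parent_id=parent_id, area_mm2=npix * sx * sy,
                centroid=tuple(cworld), contour=_component_contour(m, vol),
                pixel_count=npix, merged_from=merged,
            ))
        if not comps:
            if i == 0:
                raise GeometryError(
                    "anchors placed below the chamber: pulp cross-section is empty "
                    "at the anchor plane"
                )
            break
        z = vol.origin[2] + k * sz
        sections.append(SliceSection(depth=s, k=k, z_world=z, components=comps,
                                     labeled=labeled, spacing_xy=(sx, sy),
                                     origin_xy=(vol.origin[0], vol.origin[1])))
        prev = sections[-1]
        i += 1
    if sections and len(sections[0].components) > 1:
        raise GeometryError(
            "anchors placed below the chamber: pulp cross-section is already split "
            "at the anchor plane"
        )
    return sections


def _component_contour(mask: np.ndarray, vol: LabeledVolume) -> np.ndarray:
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    c = max(contours, key=len) - 1.0  # undo pad; (i, j) fractional indices
    return c * np.array([vol.spacing[0], vol.spacing[1]]) + np.array(vol.origin[:2])


@dataclass
class FurcationEvent:
    """A 1 -> many split of the swept pulp cross-section."""

    kind: str  # bifurcation | trifurcation | multifurcation
    depth: float  # mm below the anchor plane (midpoint convention)
    saddle: tuple[float, float, float]  # world mm; the landmark D/E/F
    parent_component: int
    child_components: tuple[int, ...]
    section_index: int  # first split section
    refined: bool = False


@dataclass
class BranchNode:
    """A maximal single-component run of the sweep (chamber or canal)."""

    trail: list[tuple[int, int]]  # (section index, component id)
    event: FurcationEvent | None = None  # the split ending this branch
    children: list["BranchNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["BranchNode"]:
        return [self] if self.is_leaf else [lf for c in self.children for lf in c.leaves()]


@dataclass
class FurcationTree:
    root: BranchNode
    step: float

    def events(self) -> list[FurcationEvent]:
        out: list[FurcationEvent] = []

        def walk(n: BranchNode):
            if n.event is not None:
                out.append(n.event)
            for c in n.children:
                walk(c)

        walk(self.root)
        return sorted(out, key=lambda e: e.depth)

    def leaves(self) -> list[BranchNode]:
        return self.root.leaves()

    def leaf_path_events(self, leaf: BranchNode) -> list[FurcationEvent]:
        """Events on the root-to-leaf path, shallow to deep."""
        path: list[FurcationEvent] = []

        def walk(n: BranchNode, acc):
            if n is leaf:
                path.extend(acc)
                return True
            return any(walk(c, acc + [n.event]) for c in n.children)

        walk(self.root, [])
        return path


def detect_events(
    sections: list[SliceSection],
    merge_guard: float = DEFAULT_MERGE_GUARD,
) -> FurcationTree:
    """Organize swept sections into the furcation tree.

    An event is recorded at each depth where a tracked component maps to
    >= 2 children; its depth is the midpoint between the bracketing
    sections.  Splits whose children re-merge within ``merge_guard`` mm
    are suppressed as noise (a warning is logged).
    """
    if not sections:
        raise ValidationError("no sections to analyse")
    step = sections[1].depth - sections[0].depth if len(sections) > 1 else 1.0
    guard_n = int(np.ceil(merge_guard / step)) if step > 0 else 0
    by_sec: list[dict[int, Component]] = [{c.id: c for c in s.components} for s in sections]

    def kids_of(sec_i: int, cid: int) -> list[Component]:
        if sec_i + 1 >= len(sections):
            return []
        return [c for c in sections[sec_i + 1].components if c.parent_id == cid]

    def follow(cid: int, sec_i: int) -> BranchNode:
        trail = [(sec_i, cid)]
        cur, i = cid, sec_i
        while True:
            kids = kids_of(i, cur)
            if not kids:
                return BranchNode(trail=trail)
            if len(kids) == 1:
                cur = kids[0].id
                i += 1
                trail.append((i, cur))
                continue
            groups, alive = _guard_groups(kids, i + 1, guard_n, sections)
            if not alive:
                return BranchNode(trail=trail)  # all children die out: branch tip
            if len(groups) > len(alive):
                log.warning(
                    "%d of %d children at depth %.3f mm die within %.2f mm; "
                    "treated as resampling debris",
                    len(groups) - len(alive), len(groups), sections[i + 1].depth,
                    merge_guard,
                )
                groups = alive
            if len(groups) == 1:
                log.warning(
                    "split at depth %.3f mm re-merged within %.2f mm; suppressed as noise",
                    sections[i + 1].depth, merge_guard,
                )
                survivor = max(groups[0], key=lambda c: c.pixel_count)
                cur = survivor.id
                i += 1
                trail.append((i, cur))
                continue
            reps = [max(g, key=lambda c: c.pixel_count) for g in groups]
            sec = sections[i + 1]
            saddle = _contour_saddle(groups, sec, sec.spacing_xy, sec.origin_xy)
            kind = {2: "bifurcation", 3: "trifurcation"}.get(len(groups), "multifurcation")
            event = FurcationEvent(
                kind=kind,
                depth=0.5 * (sections[i].depth + sections[i + 1].depth),
                saddle=saddle,
                parent_component=cur,
                child_components=tuple(c.id for c in reps),
                section_index=i + 1,
            )
            node = BranchNode(trail=trail, event=event)
            node.children = [follow(r.id, i + 1) for r in reps]
            return node

    root = follow(sections[0].components[0].id, 0)
    return FurcationTree(root=root, step=step)


def _guard_groups(kids, sec_i, guard_n, sections):
    """Group split children over the guard window.

    Children whose descendants re-merge within the window are unified
    (union-find); the second return value lists the groups still alive
    at the end of the window — short-lived debris is not.
    """
    parent = {c.id: c.id for c in kids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    end_j = sec_i + guard_n
    beyond_sweep = end_j > len(sections) - 1
    end_j = min(end_j, len(sections) - 1)
    owner = {c.id: c.id for c in kids}  # descendant comp id -> child id
    for j in range(sec_i, end_j):
        for c in sections[j + 1].components:
            srcs = set()
            if c.parent_id in owner:
                srcs.add(owner[c.parent_id])
            for m in c.merged_from:
                if m in owner:
                    srcs.add(owner[m])
            if len(srcs) >= 2:
                srcs = list(srcs)
                for a in srcs[1:]:
                    union(srcs[0], a)
            if srcs:
                owner[c.id] = next(iter(srcs))
    groups: dict[int, list] = {}
    for c in kids:
        groups.setdefault(find(c.id), []).append(c)
    group_list = list(groups.values())
    if beyond_sweep:
        # the split sits within the guard window of the sweep's apical end:
        # children cannot demonstrate persistence, so no orifice-level event
        return group_list, []
    alive_roots = {find(owner[c.id]) for c in sections[end_j].components if c.id in owner}
    alive = [g for r, g in groups.items() if r in alive_roots]
    return group_list, alive


def _boundary_world(mask: np.ndarray, spacing, origin) -> np.ndarray:
    inner = ndimage.binary_erosion(mask, structure=_S8)
    idx = np.argwhere(mask & ~inner)
    if idx.size == 0:
        idx = np.argwhere(mask)
    return idx * np.asarray(spacing[:2]) + np.asarray(origin[:2])


def saddle_between(child_masks: list[np.ndarray], spacing, origin) -> tuple[float, float]:
    """In-plane saddle between separated child cross-sections.

    Defined as the weighted mean midpoint of boundary-point pairs, each
    pair down-weighted exponentially by how much it exceeds the shortest
    inter-child gap (length scale: two in-plane voxels).  The smooth
    weighting keeps the convention stable when the gap is degenerate
    (e.g. a palatal canal equidistant from both buccal canals) and under
    the boundary jitter of nearest-neighbour resampling, where a single
    nearest-pair pick would flip sides.  Both query directions are
    accumulated, so the result is symmetric in the children.  The
    generator and the detector share this convention.
    """
    bounds = [_boundary_world(m, spacing, origin) for m in child_masks]
    trees = [cKDTree(b) for b in bounds]
    tau = 2.0 * float(max(spacing[0], spacing[1]))
    pair_data = []
    dmin = np.inf
    for i in range(len(bounds)):
        for j in range(i + 1, len(bounds)):
            d_ij, idx_ij = trees[i].query(bounds[j])
            d_ji, idx_ji = trees[j].query(bounds[i])
            pair_data.append((d_ij, bounds[i][idx_ij], bounds[j]))
            pair_data.append((d_ji, bounds[j][idx_ji], bounds[i]))
            dmin = min(dmin, float(d_ij.min()))
    num = np.zeros(2)
    den = 0.0
    for d, a_pts, b_pts in pair_data:
        w = np.exp(-(d - dmin) / tau)
        num += (w[:, None] * 0.5 * (a_pts + b_pts)).sum(axis=0)
        den += float(w.sum())
    mid = num / den
    return float(mid[0]), float(mid[1])


def _group_masks(groups, section: SliceSection) -> list[np.ndarray]:
    return [np.isin(section.labeled, [c.id for c in g]) for g in groups]


def _contour_saddle(groups, section: SliceSection, spacing, origin) -> tuple[float, float, float]:
    x, y = saddle_between(_group_masks(groups, section), spacing, origin)
    return (x, y, section.z_world)


def locate_saddle(
    event: FurcationEvent,
    sections: list[SliceSection],
    vol: LabeledVolume | None = None,
) -> tuple[float, float, float]:
    """Refine the event saddle against the dentine gap.

    Recomputes the near-minimal-gap midpoint between the child
    components at the first split section, and (when the volume is
    available) verifies the point falls on dentine — the furcation
    zenith lies on the pulp floor between the canals.  ``event.refined``
    records whether the dentine check succeeded; the contour-based
    saddle is kept as a flagged fallback otherwise.
    """
    section = sections[event.section_index]
    masks = [section.labeled == cid for cid in event.child_components]
    masks = [m for m in masks if m.any()]
    if len(masks) < 2:
        event.refined = False
        return event.saddle
    x, y = saddle_between(masks, section.spacing_xy, section.origin_xy)
    saddle = (x, y, section.z_world)
    event.refined = True
    if vol is not None:
        i = int(round((x - vol.origin[0]) / vol.spacing[0]))
        j = int(round((y - vol.origin[1]) / vol.spacing[1]))
        i = min(max(i, 0), vol.shape[0] - 1)
        j = min(max(j, 0), vol.shape[1] - 1)
        if vol.voxels[i, j, section.k] != DENTINE:
            event.refined = False
    event.saddle = saddle
    return saddle


def detect_floor_contact(
    vol: LabeledVolume,
    plane: Plane,
    step: float | None = None,
    min_voxels: int = 4,
) -> float | None:
    """First depth at which dentine appears strictly inside the convex
    hull of the pulp cross-section — an independent reading of the slice
    "crossing the pulp floor", used as a cross-check of the split
    detector."""
    sz = vol.spacing[2]
    step = sz if step is None else float(step)
    k_plane = (plane.point[2] - vol.origin[2]) / sz
    i = 0
    while True:
        s = i * step
        k = int(round(k_plane + s / sz))
        if k >= vol.shape[2]:
            return None
        pulp = vol.voxels[:, :, k] == PULP
        if not pulp.any():
            return None
        hull = morphology.convex_hull_image(pulp)
        interior = ndimage.binary_erosion(hull, structure=_S8)
        dent_inside = interior & (vol.voxels[:, :, k] == DENTINE)
        if int(dent_inside.sum()) >= min_voxels:
            return s
        i += 1
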