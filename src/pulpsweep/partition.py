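"""Orifice assignment, pulp partitioning, and anatomical canal naming.

The orifice rule is uniform across morphologies: each canal's orifice is
the cross-section of its branch at the *deepest split on its root-to-leaf
path* — the event where it separated from its last sibling.  Canals
created together at one event share that event's plane but keep
individual contours; a branch group that never separates (a C-shaped
ribbon) receives a single shared orifice record listing all member
canals; a tooth with no splits keeps its orifice at the CEJ plane.  This
single rule reproduces the per-morphology protocols: both canals at the
bifurcation in a two-rooted mandibular molar; the mesial canal at the
first event and the two distal canals at the second in a Radix
Entomolaris; the palatal canal at the trifurcation zenith and the buccal
pair at the deeper buccal bifurcation in a three-rooted maxillary molar;
and the mirror-image rules for apically displaced variants.

The pulp is partitioned into the chamber (coronal to the first event),
inter-event shared-chamber regions (a component whose split is still
pending, e.g. the space shared by the distal canals between the first and
second mandibular bifurcations), and per-canal radicular spaces.  The
partition is exact: every pulp voxel lands in exactly one region, which
is asserted on every run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import PulpSweepError
from .geometry import AnatomicalFrame
from .io import CanalEntry, EventEntry, MorphologyReport
from .sweep import BranchNode, FurcationEvent, FurcationTree, SliceSection
from .volume import PULP, LabeledVolume

log = logging.getLogger(__name__)

# canonical display order for canal labels
_LABEL_ORDER = {"M": 0, "ML": 1, "MB": 2, "D": 3, "DB": 4, "DL": 5, "P": 6}


@dataclass
class OrificeRecord:
    """The orifice plane and contour of one terminal branch.

    ``labels`` holds one anatomical name, or several when the orifice is
    shared (``shared`` is true iff there are >= 2 labels).
    """

    leaf: BranchNode
    depth: float  # mm below the anchor plane
    contour: np.ndarray
    area_mm2: float
    centroid: tuple[float, float, float]
    event: FurcationEvent | None = None
    labels: list[str] = field(default_factory=list)

    @property
    def shared(self) -> bool:
        return len(self.labels) >= 2

    @property
    def name(self) -> str:
        return "//".join(self.labels) if self.labels else "?"


def assign_orifices(tree: FurcationTree, sections: list[SliceSection]) -> list[OrificeRecord]:
    """One orifice record per terminal branch (deepest-split-on-path rule)."""
    records: list[OrificeRecord] = []
    comp_by_sec = [{c.id: c for c in s.components} for s in sections]
    for leaf in tree.leaves():
        path = tree.leaf_path_events(leaf)
        if path:
            event = path[-1]
            sec_i, cid = leaf.trail[0]
            if sec_i != event.section_index:  # pragma: no cover - tracking invariant
                raise PulpSweepError("leaf does not start at its split section (tracking bug)")
            comp = comp_by_sec[sec_i].get(cid)
            if comp is None or comp.pixel_count == 0:
                raise PulpSweepError("leaf has an empty contour at its event plane (tracking bug)")
            records.append(OrificeRecord(
                leaf=leaf, depth=event.depth, contour=comp.contour,
                area_mm2=comp.area_mm2, centroid=comp.centroid, event=event,
            ))
        else:
            # no furcation: single canal, orifice at the anchor (CEJ) plane
            sec_i, cid = leaf.trail[0]
            comp = comp_by_sec[sec_i][cid]
            records.append(OrificeRecord(
                leaf=leaf, depth=sections[sec_i].depth, contour=comp.contour,
                area_mm2=comp.area_mm2, centroid=comp.centroid, event=None,
            ))
    return records


@dataclass
class PulpPartition:
    """Exact partition of the pulp voxel set into named regions.

    ``region_of`` holds, for every voxel, 0 (not pulp) or 1 + index into
    ``names``.  Region kinds: ``chamber``, ``shared`` (inter-event
    pending-split space), ``canal``.
    """

    region_of: np.ndarray
    names: list[str]
    kinds: list[str]
    voxel_volume: float
    node_region: dict[int, int]  # id(BranchNode) -> region index

    def counts(self) -> dict[str, int]:
        binc = np.bincount(self.region_of.ravel(), minlength=len(self.names) + 1)
        return {n: int(binc[i + 1]) for i, n in enumerate(self.names)}

    def volumes_mm3(self) -> dict[str, float]:
        return {n: c * self.voxel_volume for n, c in self.counts().items()}

    def mask(self, name: str) -> np.ndarray:
        return self.region_of == (self.names.index(name) + 1)


def partition_pulp(
    vol: LabeledVolume,
    tree: FurcationTree,
    orifices: list[OrificeRecord],
    sections: list[SliceSection],
) -> PulpPartition:
    """Assign every pulp voxel to chamber, shared region, or canal.

    Pulp voxels not covered by any tracked component (pulp stones,
    flicker islands, voxels above the anchor plane) are attached to the
    nearest assigned region; exact voxel conservation is asserted.
    """
    pulp = vol.voxels == PULP
    region_of = np.zeros(vol.shape, dtype=np.int16)
    names: list[str] = []
    kinds: list[str] = []
    node_region: dict[int, int] = {}

    def new_region(name: str, kind: str) -> int:
        names.append(name)
        kinds.append(kind)
        return len(names)

    rec_by_leaf = {id(r.leaf): r for r in orifices}

    def node_name(n: BranchNode) -> tuple[str, str]:
        if n is tree.root:
            return "chamber", "chamber"
        if n.is_leaf:
            r = rec_by_leaf[id(n)]
            return r.name, "canal"
        return "shared:" + "+".join(sorted(l_name(lf) for lf in n.leaves())), "shared"

    def l_name(leaf: BranchNode) -> str:
        return rec_by_leaf[id(leaf)].name

    comp_owner: dict[tuple[int, int], int] = {}

    def walk(n: BranchNode):
        name, kind = node_name(n)
        rid = new_region(name, kind)
        node_region[id(n)] = rid
        for sec_i, cid in n.trail:
            comp_owner[(sec_i, cid)] = rid
        for c in n.children:
            walk(c)

    if tree.root.is_leaf:
        # no furcation: the orifice sits at the anchor (CEJ) plane, so the
        # swept slices are the canal and the chamber is everything coronal
        rid_chamber = new_region("chamber", "chamber")
        node_region[id(tree.root)] = rid_chamber
        rec = rec_by_leaf[id(tree.root)]
        rid_canal = new_region(rec.name, "canal")
        for sec_i, cid in tree.root.trail:
            comp_owner[(sec_i, cid)] = rid_canal
    else:
        walk(tree.root)

    for sec_i, section in enumerate(sections):
        ids = np.unique(section.labeled)
        sl = region_of[:, :, section.k]
        for cid in ids[ids > 0]:
            rid = comp_owner.get((sec_i, int(cid)))
            if rid is not None:
                sl[(section.labeled == cid) & pulp[:, :, section.k]] = rid

    # chamber extends occlusally above the anchor plane
    k0 = sections[0].k
    chamber_rid = node_region[id(tree.root)]
    above = pulp.copy()
    above[:, :, k0:] = False
    region_of[above & (region_of == 0)] = chamber_rid

    # attach orphans (filtered islets, skipped slices) to the nearest region
    orphan = pulp & (region_of == 0)
    if orphan.any():
        n_orphan = int(orphan.sum())
        idx = ndimage.distance_transform_edt(
            region_of == 0, sampling=vol.spacing, return_distances=False, return_indices=True
        )
        region_of[orphan] = region_of[idx[0][orphan], idx[1][orphan], idx[2][orphan]]
        log.info("attached %d orphan pulp voxels to their nearest region", n_orphan)

    assigned = region_of > 0
    if (assigned != pulp).any():
        n_bad = int((assigned != pulp).sum())
        raise PulpSweepError(
            f"partition contract violated: {n_bad} voxels unassigned or assigned "
            "outside the pulp"
        )
    return PulpPartition(region_of=region_of, names=names, kinds=kinds,
                         voxel_volume=vol.voxel_volume, node_region=node_region)


def label_canals(
    orifices: list[OrificeRecord],
    frame: AnatomicalFrame,
    arch: str,
    side: str,
) -> list[OrificeRecord]:
    """Name terminal branches anatomically from their orifice centroids.

    Maxillary: the most palatal centroid (most negative along the buccal
    axis) is P; the remaining two, ordered mesially, are MB and DB — or a
    single remaining branch is the shared MB//DB pair.  Mandibular: order
    along the mesial axis gives M vs D; a second distal branch lying
    lingually is DL.  Ties are broken by larger area.  Branch counts
    incompatible with the arch fall back to generic C1..Cn labels with a
    warning.
    """
    if not orifices:
        return orifices
    cents = np.array([r.centroid for r in orifices], dtype=float)
    ref = cents.mean(axis=0)
    b = (cents - ref) @ frame.buccal
    m = (cents - ref) @ frame.mesial
    areas = np.array([r.area_mm2 for r in orifices])
    n = len(orifices)

    def key_min_b(i):
        return (b[i], -areas[i])

    def key_mesial(i):
        return (-m[i], -areas[i])

    order = list(range(n))
    if n == 1:
        orifices[0].labels = ["C1"]
    elif arch == "maxillary" and n == 3:
        p = min(order, key=key_min_b)
        rest = sorted((i for i in order if i != p), key=key_mesial)
        orifices[p].labels = ["P"]
        orifices[rest[0]].labels = ["MB"]
        orifices[rest[1]].labels = ["DB"]
    elif arch == "maxillary" and n == 2:
        p = min(order, key=key_min_b)
        other = next(i for i in order if i != p)
        orifices[p].labels = ["P"]
        orifices[other].labels = ["MB", "DB"]  # confluent buccal ribbon
    elif arch == "mandibular" and n == 2:
        first, second = sorted(order, key=key_mesial)
        orifices[first].labels = ["M"]
        orifices[second].labels = ["D"]
    elif arch == "mandibular" and n == 3:
        mi = min(order, key=lambda i: (-m[i], -areas[i]))
        rest = [i for i in order if i != mi]
        dl = min(rest, key=key_min_b)
        d = next(i for i in rest if i != dl)
        orifices[mi].labels = ["M"]
        orifices[d].labels = ["D"]
        orifices[dl].labels = ["DL"]
    else:
        log.warning("%d terminal branches is unexpected for a %s molar; using generic labels",
                    n, arch)
        for j, i in enumerate(sorted(order, key=lambda i: (orifices[i].depth, -areas[i]))):
            orifices[i].labels = [f"C{j + 1}"]
    return orifices


def summarize(
    orifices: list[OrificeRecord],
    partition: PulpPartition,
    tree: FurcationTree,
    arch: str,
    side: str,
    cej_offset: float = 0.0,
    provenance: dict | None = None,
) -> MorphologyReport:
    """Assemble the per-tooth morphology report.

    ``cej_offset`` converts sweep depths (below the anchor plane) to
    depths below the CEJ best-fit plane: it is the signed apical distance
    of the anchor plane below the CEJ plane.
    """
    volumes = partition.volumes_mm3()
    counts = partition.counts()
    chamber_vol = sum(volumes[nm] for nm, k in zip(partition.names, partition.kinds)
                      if k == "chamber")
    shared_vols = {nm: volumes[nm] for nm, k in zip(partition.names, partition.kinds)
                   if k == "shared"}

    entries: list[CanalEntry] = []
    for r in sorted(orifices, key=lambda r: min(_LABEL_ORDER.get(l, 99) for l in r.labels)):
        entries.append(CanalEntry(
            labels=list(r.labels),
            orifice_depth_mm=r.depth + cej_offset,
            centroid=tuple(r.centroid),
            area_mm2=r.area_mm2,
            shared_with=r.labels[1:] if r.shared else [],
            volume_mm3=volumes.get(r.name, 0.0),
        ))
    events = [EventEntry(e.kind, e.depth + cej_offset, tuple(e.saddle))
              for e in tree.events()]
    config = " ".join("//".join(e.labels) for e in entries)
    notes = []
    if not events:
        notes.append("single canal; orifice at CEJ plane")
    report = MorphologyReport(
        arch=arch, side=side, canals=entries, events=events,
        chamber_volume_mm3=chamber_vol,
        shared_region_volumes_mm3=shared_vols,
        configuration=config, notes=notes,
        provenance=provenance or {},
    )
    report.provenance.setdefault("region_voxel_counts", counts)
    report.validate()
    return report
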