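"""End-to-end pipeline: volume + landmarks -> morphology report.

Stages (in order): CEJ curve extraction and best-fit plane; re-orientation
of the volume so the anchor-slice normal is the sweep axis; the apical
plane sweep; split-event detection and saddle refinement; orifice
assignment; anatomical labelling; pulp partitioning; report assembly.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .cej import extract_cej_curve, reorient
from .errors import ValidationError
from .geometry import AnatomicalFrame, Plane, RigidTransform, build_frame, fit_plane
from .io import MorphologyReport
from .partition import (
    OrificeRecord,
    PulpPartition,
    assign_orifices,
    label_canals,
    partition_pulp,
    summarize,
)
from .sweep import (
    DEFAULT_MERGE_GUARD,
    DEFAULT_MIN_AREA,
    FurcationTree,
    SliceSection,
    anchor_slice,
    detect_events,
    locate_saddle,
    sweep,
)
from .volume import ANCHOR_TAG, LabeledVolume, LandmarkSet

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    report: MorphologyReport
    tree: FurcationTree
    orifices: list[OrificeRecord]
    partition: PulpPartition
    sections: list[SliceSection]
    volume: LabeledVolume  # re-oriented volume
    transform: RigidTransform  # original world -> re-oriented world
    cej_plane: Plane  # in the re-oriented frame
    anchor_plane: Plane  # in the re-oriented frame
    frame: AnatomicalFrame
    timings: dict[str, float] = field(default_factory=dict)


def _buccal_hint(landmarks: LandmarkSet) -> np.ndarray:
    anchors = landmarks.anchors()
    buccal = [p.xyz for p in anchors if p.surface == "buccal"]
    other = [p.xyz for p in anchors if p.surface in ("lingual", "palatal")]
    if not buccal or not other:
        log.warning("anchor surfaces missing; assuming +x is buccal")
        return np.array([1.0, 0.0, 0.0])
    return np.mean(buccal, axis=0) - np.mean(other, axis=0)


def run_pipeline(
    vol: LabeledVolume,
    landmarks: LandmarkSet,
    arch: str,
    side: str,
    step: float | None = None,
    min_area: int = DEFAULT_MIN_AREA,
    merge_guard: float = DEFAULT_MERGE_GUARD,
    provenance: dict | None = None,
) -> PipelineResult:
    """Run the full protocol on a segmented volume with landmarks."""
    timings: dict[str, float] = {}

    def stage(name):
        timings[name] = time.perf_counter()
        log.info("stage %s", name)

    def done(name):
        timings[name] = time.perf_counter() - timings[name]

    stage("cej_fit")
    pulp_centroid = vol.pulp_centroid()
    cej_pts = extract_cej_curve(vol)
    cej_plane = fit_plane(cej_pts, apical_reference=pulp_centroid)
    done("cej_fit")

    anchors = landmarks.anchors()
    if len(anchors) < 3:
        raise ValidationError("landmark set has no usable slice anchors (need 3 or 4)")
    a_plane = anchor_slice(landmarks, apical_reference=pulp_centroid)

    stage("reorient")
    vol2, t = reorient(vol, a_plane)
    done("reorient")
    lms2 = landmarks.transformed(t.apply)
    cej2 = t.apply_plane(cej_plane)
    a2 = t.apply_plane(a_plane)

    stage("sweep")
    sections = sweep(vol2, a2, step=step, min_area=min_area)
    done("sweep")

    stage("events")
    tree = detect_events(sections, merge_guard=merge_guard)
    for event in tree.events():
        locate_saddle(event, sections, vol2)
    done("events")

    stage("orifices")
    orifices = assign_orifices(tree, sections)
    hint = _buccal_hint(lms2)
    frame = build_frame(np.asarray(a2.normal), hint, arch, side)
    label_canals(orifices, frame, arch, side)
    done("orifices")

    stage("partition")
    partition = partition_pulp(vol2, tree, orifices, sections)
    done("partition")

    cej_offset = float(-cej2.signed_distance(np.asarray(a2.point))[0])
    prov = dict(provenance or {})
    prov.update({
        "step_mm": step if step is not None else vol.spacing[2],
        "min_area_voxels": min_area,
        "merge_guard_mm": merge_guard,
        "cej_plane": {"point": list(cej2.point), "normal": list(cej2.normal),
                      "fit_residual_mm": cej2.fit_residual},
        "anchor_plane": {"point": list(a2.point), "normal": list(a2.normal),
                         "fit_residual_mm": a2.fit_residual},
        "anchor_depth_below_cej_mm": cej_offset,
        "n_sections": len(sections),
    })
    report = summarize(orifices, partition, tree, arch, side,
                       cej_offset=cej_offset, provenance=prov)
    log.info("pipeline done: %d canals, %d events, configuration %r",
             len(report.canals), len(report.events), report.configuration)
    return PipelineResult(
        report=report, tree=tree, orifices=orifices, partition=partition,
        sections=sections, volume=vol2, transform=t, cej_plane=cej2,
        anchor_plane=a2, frame=frame, timings=timings,
    )
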