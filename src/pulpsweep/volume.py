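"""Core containers: labeled tooth volumes and anatomical landmark sets.

A :class:`LabeledVolume` holds a segmented micro-CT scan (or synthetic
phantom) as a 3D integer array with labels 0=background, 1=enamel,
2=dentine, 3=pulp, plus the voxel spacing and world origin in millimetres.
Voxel indexing is 0-based and axis-aligned: ``world = origin + index *
spacing``.  After re-orientation the voxel index along axis 2 increases
apically (toward the root tips).

A :class:`LandmarkSet` holds named world-coordinate points: a ring of
points along the cemento-enamel junction (CEJ) used for global alignment,
and the 3-4 ``slice_anchor`` points (A-D) that anchor the cross-sectional
sweep plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError

BACKGROUND, ENAMEL, DENTINE, PULP = 0, 1, 2, 3
VALID_LABELS = frozenset((BACKGROUND, ENAMEL, DENTINE, PULP))
LABEL_NAMES = {0: "background", 1: "enamel", 2: "dentine", 3: "pulp"}

ANCHOR_TAG = "slice_anchor"
CEJ_TAG = "cej_ring"


@dataclass
class LabeledVolume:
    """Segmented tooth volume on an axis-aligned voxel grid.

    Parameters
    ----------
    voxels : (nx, ny, nz) integer array with values in {0, 1, 2, 3}.
    spacing : per-axis voxel size (sx, sy, sz) in mm, strictly positive.
    origin : world coordinate (mm) of voxel (0, 0, 0).
    meta : free-form provenance (e.g. CEJ slice index after re-orientation).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValidationError(f"voxels must be 3D, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive values, got {self.spacing}")
        bad = set(np.unique(self.voxels)) - VALID_LABELS
        if bad:
            raise ValidationError(
                f"unknown label value(s) {sorted(bad)}; expected subset of {sorted(VALID_LABELS)}"
            )
        if self.voxels.dtype != np.uint8:
            self.voxels = self.voxels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def world(self, index: np.ndarray) -> np.ndarray:
        """World mm coordinates of (possibly fractional) voxel indices."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def index(self, world: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of world mm coordinates."""
        return (np.asarray(world, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def label_counts(self) -> dict[int, int]:
        counts = np.bincount(self.voxels.ravel(), minlength=4)
        return {lab: int(counts[lab]) for lab in range(4)}

    def pulp_mask(self) -> np.ndarray:
        return self.voxels == PULP

    def pulp_centroid(self) -> np.ndarray:
        """World centroid of the pulp label (the apical mass reference)."""
        idx = np.argwhere(self.voxels == PULP)
        if idx.size == 0:
            raise ValidationError("volume contains no pulp voxels")
        return self.world(idx.mean(axis=0))


@dataclass(frozen=True)
class Landmark:
    name: str
    xyz: tuple[float, float, float]
    tag: str  # cej_ring | slice_anchor
    anatomical_label: str | None = None  # A, B, C, D
    surface: str | None = None  # buccal, lingual, palatal, mesial, distal

    def __post_init__(self) -> None:
        if self.tag not in (ANCHOR_TAG, CEJ_TAG):
            raise ValidationError(f"unknown landmark tag {self.tag!r}")
        object.__setattr__(self, "xyz", tuple(float(v) for v in self.xyz))


@dataclass
class LandmarkSet:
    """Named CEJ-ring and slice-anchor points in world mm."""

    points: list[Landmark]

    def __post_init__(self) -> None:
        names = [p.name for p in self.points]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate landmark names: {dupes}")
        n_anchor = len(self.anchors())
        if n_anchor and n_anchor not in (3, 4):
            raise ValidationError(
                f"slice_anchor subset must have 3 or 4 points, got {n_anchor}"
            )

    def anchors(self) -> list[Landmark]:
        return [p for p in self.points if p.tag == ANCHOR_TAG]

    def cej_ring(self) -> list[Landmark]:
        return [p for p in self.points if p.tag == CEJ_TAG]

    def anchor_array(self) -> np.ndarray:
        return np.array([p.xyz for p in self.anchors()], dtype=float)

    def cej_array(self) -> np.ndarray:
        return np.array([p.xyz for p in self.cej_ring()], dtype=float)

    def transformed(self, fn) -> "LandmarkSet":
        """Apply a world-coordinate mapping ``fn`` (points -> points)."""
        pts = np.array([p.xyz for p in self.points], dtype=float)
        new = fn(pts)
        return LandmarkSet(
            [replace(p, xyz=tuple(q)) for p, q in zip(self.points, np.atleast_2d(new))]
        )


def landmark_set(points: Iterable[Sequence]) -> LandmarkSet:
    """Build a LandmarkSet from (name, xyz, tag[, anatomical_label, surface]) tuples."""
    out = []
    for tup in points:
        name, xyz, tag, *rest = tup
        lab = rest[0] if len(rest) > 0 else None
        surf = rest[1] if len(rest) > 1 else None
        out.append(Landmark(name, tuple(xyz), tag, lab, surf))
    return LandmarkSet(out)
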