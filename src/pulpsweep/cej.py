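"""CEJ curve extraction, reference-plane fitting, and volume re-orientation.

The cemento-enamel junction (CEJ) is recovered from the segmentation as
the ring of external-surface voxels where enamel meets dentine: enamel
caps only the crown, so the apical rim of the enamel label *is* the CEJ.
A best-fit (total-least-squares) plane through the ring, or through
manually supplied CEJ landmarks, defines the occlusal axis; the volume is
then resampled (nearest-neighbour — labels are categorical) onto a grid
whose axis-2 index increases apically along that axis.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .errors import GeometryError, ValidationError
from .geometry import Plane, RigidTransform, fit_plane, rotation_to_axis
from .volume import BACKGROUND, DENTINE, ENAMEL, PULP, LabeledVolume

__all__ = ["extract_cej_curve", "fit_plane", "reorient"]

log = logging.getLogger(__name__)

_N26 = np.ones((3, 3, 3), dtype=bool)


def extract_cej_curve(vol: LabeledVolume) -> np.ndarray:
    """External enamel-dentine boundary voxels (the CEJ ring), world mm.

    A voxel belongs to the curve when it is enamel touching background
    (26-neighbourhood) and has a background-touching dentine voxel among
    its 26 neighbours.  Points are returned ordered by angular position
    about the occlusal axis (enamel centroid minus pulp centroid).
    """
    labels = vol.voxels
    if not (labels == ENAMEL).any():
        raise ValidationError("volume has no enamel label; cannot locate the CEJ")
    if not (labels == DENTINE).any():
        raise ValidationError("volume has no dentine label; cannot locate the CEJ")
    bg_touch = ndimage.binary_dilation(labels == BACKGROUND, structure=_N26)
    enamel_surf = (labels == ENAMEL) & bg_touch
    dentine_surf = (labels == DENTINE) & bg_touch
    cej = enamel_surf & ndimage.binary_dilation(dentine_surf, structure=_N26)
    idx = np.argwhere(cej)
    if idx.size == 0:
        raise GeometryError(
            "no external enamel-dentine contact found; the enamel label does not "
            "reach the tooth surface (solid block or broken segmentation)"
        )
    pts = vol.world(idx)

    # Order by angle about the occlusal axis for a coherent ring traversal.
    if (labels == PULP).any():
        axis = vol.world(np.argwhere(labels == ENAMEL).mean(axis=0)) - vol.pulp_centroid()
    else:
        axis = np.array([0.0, 0.0, -1.0])
    axis = axis / (np.linalg.norm(axis) or 1.0)
    # Rim voxel *centres* sit half a voxel occlusal to the enamel-dentine
    # boundary surface; shift apically by half the voxel extent along the
    # occlusal axis to centre the curve on the surface.
    half_step = 0.5 * float(np.sqrt(np.sum((axis * np.asarray(vol.spacing)) ** 2)))
    pts = pts - axis * half_step
    center = pts.mean(axis=0)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(seed @ axis) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = seed - (seed @ axis) * axis
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    rel = pts - center
    order = np.argsort(np.arctan2(rel @ v, rel @ u))
    return pts[order]


def resample_rigid(
    vol: LabeledVolume,
    t: RigidTransform,
    pad_mm: float = 0.3,
    max_pulp_loss: float = 0.05,
) -> LabeledVolume:
    """Nearest-neighbour resample of ``vol`` under a rigid world transform.

    The output grid keeps the input spacing and is padded so the whole
    transformed volume fits; losing more than ``max_pulp_loss`` of the
    pulp voxels raises a :class:`GeometryError`.
    """
    R = t.rotation
    spacing = np.asarray(vol.spacing)
    shape = np.asarray(vol.shape)

    corners = np.array([[i, j, k] for i in (0, shape[0] - 1)
                        for j in (0, shape[1] - 1) for k in (0, shape[2] - 1)], dtype=float)
    wc = t.apply(vol.world(corners))
    lo = wc.min(axis=0) - pad_mm
    hi = wc.max(axis=0) + pad_mm
    new_shape = np.ceil((hi - lo) / spacing).astype(int) + 1

    grids = np.meshgrid(*(np.arange(n) for n in new_shape), indexing="ij", sparse=True)
    world_new = [lo[a] + grids[a] * spacing[a] for a in range(3)]
    # old world = R^T p' + c  -> old fractional index
    coords = []
    for a in range(3):
        old_world_a = (R[0, a] * world_new[0] + R[1, a] * world_new[1]
                       + R[2, a] * world_new[2] + t.center[a])
        coords.append((old_world_a - vol.origin[a]) / spacing[a])
    coords = np.broadcast_arrays(*coords)
    out = ndimage.map_coordinates(vol.voxels, np.stack(coords), order=0,
                                  mode="constant", cval=BACKGROUND, prefilter=False)

    pulp_before = int((vol.voxels == PULP).sum())
    pulp_after = int((out == PULP).sum())
    if pulp_before and pulp_after < (1.0 - max_pulp_loss) * pulp_before:
        raise GeometryError(
            f"re-orientation lost {1 - pulp_after / pulp_before:.1%} of pulp voxels "
            f"(> {max_pulp_loss:.0%}); increase pad_mm or crop the input less tightly"
        )

    meta = dict(vol.meta)
    meta["resample_rotation"] = R.tolist()
    meta["resample_center"] = list(t.center)
    new_vol = LabeledVolume(out, tuple(spacing), tuple(lo), meta)
    log.info("resampled: shape %s -> %s, pulp %d -> %d voxels",
             tuple(shape), tuple(new_shape), pulp_before, pulp_after)
    return new_vol


def reorient(
    vol: LabeledVolume,
    plane: Plane,
    pad_mm: float = 0.3,
    max_pulp_loss: float = 0.05,
) -> tuple[LabeledVolume, RigidTransform]:
    """Resample ``vol`` so ``plane``'s normal is anti-parallel to axis 2.

    After re-orientation the slice index along axis 2 increases apically
    and the reference plane sits at the constant (fractional) slice
    recorded in ``meta['reference_slice']``.  Returns the volume and the
    rigid world transform, so landmark sets can be mapped alongside.
    """
    R = rotation_to_axis(np.asarray(plane.normal))
    t = RigidTransform(R, np.asarray(plane.point, dtype=float))
    new_vol = resample_rigid(vol, t, pad_mm=pad_mm, max_pulp_loss=max_pulp_loss)
    new_vol.meta["reference_slice"] = float((0.0 - new_vol.origin[2]) / vol.spacing[2])
    return new_vol, t
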