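"""Planes, rigid transforms, and the anatomical reference frame.

The reference plane through the CEJ landmarks is a total-least-squares
(orthogonal-distance) fit: the landmarks ring the tooth, so no coordinate
axis is privileged and regressing z on (x, y) would bias the normal.  The
solution is the classic one — the normal is the singular direction of the
centred points with the smallest singular value.

Plane normals are oriented *occlusally*, i.e. away from the root apices;
the centroid of the pulp label serves as the apical reference mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, ValidationError


@dataclass(frozen=True)
class Plane:
    """A plane ``{x : normal . (x - point) = 0}`` with |normal| = 1.

    ``fit_residual`` is the RMS orthogonal point-to-plane distance of the
    fitted points (0 for an exact 3-point construction).
    """

    point: tuple[float, float, float]
    normal: tuple[float, float, float]
    fit_residual: float = 0.0

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        nn = np.linalg.norm(n)
        if not np.isfinite(nn) or abs(nn - 1.0) > 1e-9:
            raise GeometryError(f"plane normal must be unit length, |n| = {nn}")
        if self.fit_residual < 0:
            raise GeometryError("fit residual must be non-negative")
        object.__setattr__(self, "point", tuple(float(v) for v in self.point))
        object.__setattr__(self, "normal", tuple(float(v) for v in n))

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        """Signed distance along the (occlusal) normal; negative is apical."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        d = (pts - np.asarray(self.point)) @ np.asarray(self.normal)
        return d if d.size > 1 else d

    def flipped(self) -> "Plane":
        return Plane(self.point, tuple(-np.asarray(self.normal)), self.fit_residual)


def fit_plane(points: np.ndarray, apical_reference: np.ndarray | None = None) -> Plane:
    """Total-least-squares plane through ``points`` (>= 3, non-collinear).

    Minimises the RMS orthogonal distance.  If ``apical_reference`` (world
    mm, typically the pulp centroid) is given, the normal is flipped so it
    points *away* from it, i.e. occlusally.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 3 or pts.shape[1] != 3:
        raise ValidationError(f"plane fit needs >= 3 points in 3D, got shape {pts.shape}")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    # Smallest right-singular direction of the centred cloud.
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1e-300) or s[0] == 0.0:
        raise GeometryError("points are collinear; plane is underdetermined")
    normal = vt[2]
    residual = float(np.sqrt(np.mean((centred @ normal) ** 2)))
    plane = Plane(tuple(centroid), tuple(normal / np.linalg.norm(normal)), residual)
    if apical_reference is not None:
        if plane.signed_distance(np.asarray(apical_reference))[0] > 0:
            plane = plane.flipped()
    return plane


@dataclass(frozen=True)
class RigidTransform:
    """World mapping ``p' = R (p - center)`` used by volume re-orientation."""

    rotation: np.ndarray  # (3, 3) orthonormal
    center: np.ndarray  # (3,)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (np.atleast_2d(pts) - self.center) @ self.rotation.T

    def invert(self, pts: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(pts, dtype=float)) @ self.rotation + self.center

    def apply_plane(self, plane: Plane) -> Plane:
        return Plane(
            tuple(self.apply(np.asarray(plane.point))[0]),
            tuple(self.rotation @ np.asarray(plane.normal)),
            plane.fit_residual,
        )


def rotation_to_axis(normal: np.ndarray) -> np.ndarray:
    """Rotation whose new +z axis is *anti-parallel* to ``normal``.

    Used to re-orient a volume so an occlusally-pointing plane normal maps
    to grid -z, i.e. the slice index along axis 2 increases apically.  The
    in-plane axes follow the old x (or y) axis as closely as possible so a
    volume that is already aligned maps to (nearly) itself.
    """
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    zp = -n  # apical direction
    seed = np.array([1.0, 0.0, 0.0])
    if abs(seed @ zp) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    xp = seed - (seed @ zp) * zp
    xp /= np.linalg.norm(xp)
    yp = np.cross(zp, xp)
    return np.vstack([xp, yp, zp])


def rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit ``axis``."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


@dataclass(frozen=True)
class AnatomicalFrame:
    """Orthonormal occlusal / buccal / mesial axes for canal naming.

    The occlusal axis comes from the CEJ plane normal; the buccal axis is
    the direction from the lingual/palatal anchor centroid toward the
    buccal anchor centroid (projected into the plane); the mesial axis is
    the right-handed completion, with its sign set by arch and side so
    that mirrored teeth get mirrored names.
    """

    occlusal: np.ndarray
    buccal: np.ndarray
    mesial: np.ndarray

    def __post_init__(self) -> None:
        M = np.vstack([self.occlusal, self.buccal, self.mesial])
        if np.max(np.abs(M @ M.T - np.eye(3))) > 1e-6:
            raise GeometryError("anatomical frame axes are not orthonormal")


def mesial_sign(arch: str, side: str) -> float:
    """Handedness of mesial = sign * (occlusal x buccal).

    Package convention: +1 for (mandibular, right) and (maxillary, left),
    -1 for their mirror images.  The phantom generator uses the same
    convention, so labelling is equivariant under left/right mirroring.
    """
    if arch not in ("maxillary", "mandibular"):
        raise ValidationError(f"unknown arch {arch!r}")
    if side not in ("left", "right"):
        raise ValidationError(f"unknown side {side!r}")
    if arch == "mandibular":
        return 1.0 if side == "right" else -1.0
    return 1.0 if side == "left" else -1.0


def build_frame(occlusal: np.ndarray, buccal_hint: np.ndarray, arch: str, side: str) -> AnatomicalFrame:
    occ = np.asarray(occlusal, dtype=float)
    occ = occ / np.linalg.norm(occ)
    b = np.asarray(buccal_hint, dtype=float)
    b = b - (b @ occ) * occ
    nb = np.linalg.norm(b)
    if nb < 1e-9:
        raise GeometryError("buccal hint is parallel to the occlusal axis")
    b /= nb
    mes = mesial_sign(arch, side) * np.cross(occ, b)
    return AnatomicalFrame(occ, b, mes)
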