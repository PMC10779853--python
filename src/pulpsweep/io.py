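"""Reading and writing volumes, landmarks, reports, and meshes.

Supported volume containers: NRRD and NIfTI-1 (via SimpleITK and nibabel)
and multi-page TIFF stacks with a JSON sidecar carrying spacing/origin
(TIFF itself has no 3D spacing metadata).  Labels are stored losslessly as
uint8.  Volumes with oblique (non-axis-aligned) direction matrices are
rejected: the package works on axis-aligned grids only.

The landmark JSON schema is original to this package (coordinates are
world mm, not voxel indices, so landmarks survive resampling)::

    {"points": [{"name": "A", "xyz": [x, y, z], "tag": "slice_anchor",
                 "anatomical_label": "A", "surface": "buccal"}, ...]}

Reports are emitted both as JSON (machine-readable, full nesting) and CSV
(one row per canal), with depths in mm below the CEJ best-fit plane,
signed positive apically.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk
import tifffile

from .errors import ValidationError
from .volume import LABEL_NAMES, PULP, LabeledVolume, Landmark, LandmarkSet

log = logging.getLogger(__name__)

FORMATS = ("nrrd", "nifti", "tiff_stack")

_EXT_FORMAT = {
    ".nrrd": "nrrd",
    ".nii": "nifti",
    ".gz": "nifti",  # .nii.gz
    ".tif": "tiff_stack",
    ".tiff": "tiff_stack",
}


def _infer_format(path: Path) -> str:
    fmt = _EXT_FORMAT.get(path.suffix.lower())
    if fmt is None:
        raise ValidationError(f"cannot infer volume format from {path.name!r}; pass format=")
    return fmt


def _check_direction(direction, path) -> None:
    D = np.asarray(direction, dtype=float).reshape(3, 3)
    if np.max(np.abs(D - np.eye(3))) > 1e-6:
        raise ValidationError(
            f"{path}: oblique direction matrix is not supported; "
            "resample the volume to an axis-aligned grid first"
        )


def read_volume(path, format: str | None = None) -> LabeledVolume:
    """Read a labeled volume; labels must be a subset of {0, 1, 2, 3}."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in FORMATS:
        raise ValidationError(f"unknown format {fmt!r}; expected one of {FORMATS}")
    if not path.exists():
        raise ValidationError(f"volume file not found: {path}")

    if fmt == "nrrd":
        img = sitk.ReadImage(str(path))
        _check_direction(img.GetDirection(), path)
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # sitk is (z, y, x)
        spacing = tuple(img.GetSpacing())
        origin = tuple(img.GetOrigin())
    elif fmt == "nifti":
        img = nib.load(str(path))
        aff = img.affine
        if np.max(np.abs(aff[:3, :3] - np.diag(np.diag(aff[:3, :3])))) > 1e-6:
            raise ValidationError(f"{path}: oblique NIfTI affine is not supported")
        diag = np.diag(aff[:3, :3])
        if np.any(diag <= 0):
            raise ValidationError(f"{path}: NIfTI affine must have positive diagonal spacing")
        arr = np.asanyarray(img.dataobj)
        spacing = tuple(float(d) for d in diag)
        origin = tuple(float(v) for v in aff[:3, 3])
    else:  # tiff_stack: pages are z slices of shape (ny, nx)
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ValidationError(
                f"{path}: TIFF stacks require a spacing sidecar ({sidecar.name}); "
                "spacing metadata is mandatory for mm-scale outputs"
            )
        meta = json.loads(sidecar.read_text())
        if "spacing" not in meta:
            raise ValidationError(f"{sidecar}: missing required 'spacing' field")
        arr = tifffile.imread(str(path))
        if arr.ndim == 2:
            arr = arr[None]
        arr = arr.transpose(2, 1, 0)
        spacing = tuple(float(s) for s in meta["spacing"])
        origin = tuple(float(v) for v in meta.get("origin", (0.0, 0.0, 0.0)))

    arr = np.asarray(arr)
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if np.max(np.abs(arr - rounded)) > 1e-6:
            raise ValidationError(f"{path}: non-integer label values present")
        arr = rounded.astype(np.int64)
    vol = LabeledVolume(arr, spacing, origin)
    log.info("read %s (%s): shape=%s spacing=%s labels=%s", path.name, fmt, vol.shape,
             vol.spacing, {LABEL_NAMES[k]: v for k, v in vol.label_counts().items()})
    return vol


def write_volume(vol: LabeledVolume, path, format: str | None = None) -> None:
    """Write a labeled volume losslessly (integer encoding)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in FORMATS:
        raise ValidationError(f"unknown format {fmt!r}; expected one of {FORMATS}")
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = vol.voxels.astype(np.uint8)
    if fmt == "nrrd":
        img = sitk.GetImageFromArray(arr.transpose(2, 1, 0))
        img.SetSpacing(tuple(vol.spacing))
        img.SetOrigin(tuple(vol.origin))
        sitk.WriteImage(img, str(path), useCompression=True)
    elif fmt == "nifti":
        aff = np.eye(4)
        aff[:3, :3] = np.diag(vol.spacing)
        aff[:3, 3] = vol.origin
        nib.save(nib.Nifti1Image(arr, aff), str(path))
    else:
        tifffile.imwrite(str(path), arr.transpose(2, 1, 0), compression="zlib")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"spacing": list(vol.spacing), "origin": list(vol.origin)}))


def read_landmarks(path) -> LandmarkSet:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"landmark file not found: {path}")
    data = json.loads(path.read_text())
    if "points" not in data:
        raise ValidationError(f"{path}: landmark JSON must have a 'points' list")
    pts = [
        Landmark(
            p["name"], tuple(p["xyz"]), p["tag"],
            p.get("anatomical_label"), p.get("surface"),
        )
        for p in data["points"]
    ]
    lms = LandmarkSet(pts)
    if lms.anchors() and len(lms.anchors()) < 3:
        raise ValidationError(f"{path}: fewer than 3 slice_anchor points")
    return lms


def write_landmarks(lms: LandmarkSet, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "points": [
            {
                "name": p.name, "xyz": list(p.xyz), "tag": p.tag,
                "anatomical_label": p.anatomical_label, "surface": p.surface,
            }
            for p in lms.points
        ]
    }
    path.write_text(json.dumps(payload, indent=2))


@dataclass
class CanalEntry:
    """One orifice record in a report; ``labels`` has >1 entry when the
    orifice is shared between canals (e.g. a C-shaped ribbon)."""

    labels: list[str]
    orifice_depth_mm: float  # below the CEJ best-fit plane, positive apically
    centroid: tuple[float, float, float]
    area_mm2: float
    shared_with: list[str] = field(default_factory=list)
    volume_mm3: float = 0.0


@dataclass
class EventEntry:
    kind: str  # bifurcation | trifurcation
    depth_mm: float  # below the CEJ plane
    saddle: tuple[float, float, float]


@dataclass
class MorphologyReport:
    """Per-tooth summary: canals, furcation events, volumes, configuration.

    The configuration string joins canals that share an orifice with a
    double slash (e.g. ``MB//DB``), the notation used when a configuration
    is shared.
    """

    arch: str
    side: str
    canals: list[CanalEntry]
    events: list[EventEntry]
    chamber_volume_mm3: float
    shared_region_volumes_mm3: dict[str, float]
    configuration: str
    notes: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        for c in self.canals:
            if c.area_mm2 < 0 or c.volume_mm3 < 0:
                raise ValidationError("negative area/volume in report")
        if self.chamber_volume_mm3 < 0:
            raise ValidationError("negative chamber volume")

    def total_pulp_volume_mm3(self) -> float:
        return (
            self.chamber_volume_mm3
            + sum(self.shared_region_volumes_mm3.values())
            + sum(c.volume_mm3 for c in self.canals)
        )


def write_report(report: MorphologyReport, path) -> None:
    """Serialize a report as JSON plus a CSV table next to it."""
    report.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(asdict(report), indent=2))
    csv_path = path.with_suffix(".csv")
    with open(csv_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["canal", "orifice_depth_mm", "area_mm2", "centroid_x", "centroid_y",
                    "centroid_z", "shared_with", "volume_mm3"])
        for c in report.canals:
            w.writerow(["//".join(c.labels), f"{c.orifice_depth_mm:.4f}", f"{c.area_mm2:.4f}",
                        *(f"{v:.4f}" for v in c.centroid), "//".join(c.shared_with),
                        f"{c.volume_mm3:.4f}"])


def read_report(path) -> MorphologyReport:
    data = json.loads(Path(path).read_text())
    data["canals"] = [CanalEntry(**c) for c in data["canals"]]
    for c in data["canals"]:
        c.centroid = tuple(c.centroid)
    data["events"] = [EventEntry(e["kind"], e["depth_mm"], tuple(e["saddle"]))
                      for e in data["events"]]
    return MorphologyReport(**data)


def export_pulp_mesh(vol: LabeledVolume, path) -> "trimesh.Trimesh":
    """Export a closed marching-cubes isosurface of the pulp label as PLY."""
    import trimesh
    from skimage import measure

    mask = np.pad(vol.pulp_mask().astype(np.uint8), 1)
    if not mask.any():
        raise ValidationError("volume contains no pulp voxels; nothing to mesh")
    verts, faces, _, _ = measure.marching_cubes(mask, level=0.5, spacing=vol.spacing)
    verts = verts + np.asarray(vol.origin) - np.asarray(vol.spacing)  # undo pad
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if mesh.volume < 0:
        mesh.invert()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(str(path))
    return mesh
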