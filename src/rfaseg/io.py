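"""File I/O: volumes (NIfTI, MetaImage), masks, meshes, contours, configs.

Volumes are read and written through SimpleITK.  Arrays are re-ordered to
the package's (x, y, z) index convention (SimpleITK yields z-major arrays);
spacing and origin come from the header.  Only axis-aligned volumes are
supported — a non-identity direction matrix is rejected rather than
silently ignored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import trimesh
import yaml

from .errors import FormatError
from .surface import SliceContour
from .volume import ImageVolume, SegmentationMask

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "write_mesh",
    "load_contours",
    "RunConfig",
]

_VOLUME_SUFFIXES = (".nii", ".nii.gz", ".mha", ".mhd")
_MESH_SUFFIXES = (".stl", ".obj", ".ply")


def _known_suffix(path: Path) -> str | None:
    name = path.name.lower()
    for suffix in _VOLUME_SUFFIXES:
        if name.endswith(suffix):
            return suffix
    return None


def _check_direction(img: sitk.Image, path) -> None:
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise FormatError(
            f"{path}: direction matrix {direction.tolist()} is not identity; "
            "only axis-aligned volumes are supported"
        )


def read_volume(path) -> ImageVolume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) volume.

    A directory is treated as a DICOM series (best effort).  Rescale slope
    and intercept, when present in the header, are applied by the reader.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"volume not found: {p}")
    if p.is_dir():
        reader = sitk.ImageSeriesReader()
        files = reader.GetGDCMSeriesFileNames(str(p))
        if not files:
            raise FormatError(f"{p}: no DICOM series found in directory")
        reader.SetFileNames(files)
        img = reader.Execute()
    else:
        if _known_suffix(p) is None:
            raise FormatError(
                f"{p}: unknown format (supported: {', '.join(_VOLUME_SUFFIXES)})"
            )
        try:
            img = sitk.ReadImage(str(p))
        except RuntimeError as exc:
            raise FormatError(f"{p}: could not read header ({exc})") from exc
    _check_direction(img, p)
    if img.GetDimension() != 3:
        raise FormatError(f"{p}: expected a 3D volume, got {img.GetDimension()}D")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    values = np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(np.float64)
    return ImageVolume(
        values=values, spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin())
    )


def _to_sitk(values: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def write_volume(volume: ImageVolume, path) -> None:
    """Write a volume as NIfTI or MetaImage (chosen by extension)."""
    p = Path(path)
    if _known_suffix(p) is None:
        raise FormatError(f"{p}: unknown output format")
    sitk.WriteImage(_to_sitk(volume.values, volume.spacing, volume.origin), str(p))


def write_mask(mask: SegmentationMask, path) -> None:
    """Write a binary mask as uint8 NIfTI or MetaImage."""
    p = Path(path)
    if _known_suffix(p) is None:
        raise FormatError(f"{p}: unknown output format")
    img = _to_sitk(mask.grid.astype(np.uint8), mask.spacing, mask.origin)
    sitk.WriteImage(img, str(p))


def read_mask(path) -> SegmentationMask:
    """Read a binary mask (non-zero voxels are foreground)."""
    vol = read_volume(path)
    return SegmentationMask(vol.values != 0, vol.spacing, vol.origin)


def write_mesh(mesh: trimesh.Trimesh, path) -> None:
    """Export a surface mesh as STL, OBJ or PLY (chosen by extension)."""
    p = Path(path)
    if p.suffix.lower() not in _MESH_SUFFIXES:
        raise FormatError(
            f"{p}: unknown mesh format (supported: {', '.join(_MESH_SUFFIXES)})"
        )
    mesh.export(str(p))


def load_contours(path) -> list[SliceContour]:
    """Load manual slice contours from the JSON dialect.

    Schema::

        {"contours": [
            {"slice": 12, "frame": "pixel",
             "points": [[x0, y0], [x1, y1], ..., [x0, y0]]},
            ...
        ]}

    ``frame`` is "pixel" (0-based slice pixel coordinates, default) or
    "world" (mm); each point list must be explicitly closed.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"contour file not found: {p}")
    try:
        payload = json.loads(p.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{p}: invalid JSON ({exc})") from exc
    if not isinstance(payload, dict) or "contours" not in payload:
        raise FormatError(f"{p}: missing top-level 'contours' list")
    contours = []
    for entry in payload["contours"]:
        contours.append(
            SliceContour(
                slice_index=int(entry["slice"]),
                points=np.asarray(entry["points"], dtype=float),
                frame=entry.get("frame", "pixel"),
            )
        )
    return contours


@dataclass
class RunConfig:
    """Everything one segmentation run needs, serializable to YAML."""

    input_path: str
    seed: tuple[float, float, float]
    frame: str = "world"
    delta_r: int = 2
    rays: int = 812
    nodes_per_ray: int = 40
    max_radius_mm: float = 40.0
    reference_mode: str = "median"
    constraints: list = field(default_factory=list)
    out_mask: str | None = None
    out_mesh: str | None = None
    report: str | None = None
    verbosity: int = 0

    def to_yaml(self, path) -> None:
        data = {
            "input": self.input_path,
            "seed": list(self.seed),
            "frame": self.frame,
            "delta_r": self.delta_r,
            "rays": self.rays,
            "nodes_per_ray": self.nodes_per_ray,
            "max_radius_mm": self.max_radius_mm,
            "reference_mode": self.reference_mode,
            "constraints": [list(c) for c in self.constraints],
            "out_mask": self.out_mask,
            "out_mesh": self.out_mesh,
            "report": self.report,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            input_path=data["input"],
            seed=tuple(data["seed"]),
            frame=data.get("frame", "world"),
            delta_r=data.get("delta_r", 2),
            rays=data.get("rays", 812),
            nodes_per_ray=data.get("nodes_per_ray", 40),
            max_radius_mm=data.get("max_radius_mm", 40.0),
            reference_mode=data.get("reference_mode", "median"),
            constraints=[tuple(c) for c in data.get("constraints", [])],
            out_mask=data.get("out_mask"),
            out_mesh=data.get("out_mesh"),
            report=data.get("report"),
        )
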