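"""File I/O: meshes (STL/PLY), volumes (NIfTI/MetaImage), landmarks (JSON),
transforms (JSON) and report CSVs."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .errors import FormatError
from .segmentation import CTVolume, LabelMask
from .surfaces import RigidTransform

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_volume",
    "write_volume",
    "write_mask",
    "read_landmarks",
    "write_landmarks",
    "read_transform",
    "write_transform",
    "write_csv",
    "write_json",
]

_MESH_SUFFIXES = {".stl", ".ply"}
_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_META_SUFFIXES = (".mha", ".mhd")


def read_mesh(path) -> trimesh.Trimesh:
    """Read an STL (ASCII or binary) or PLY surface mesh."""
    path = Path(path)
    if path.suffix.lower() not in _MESH_SUFFIXES:
        raise FormatError(f"unsupported mesh format: {path.suffix!r}")
    try:
        mesh = trimesh.load_mesh(str(path))
    except Exception as exc:  # noqa: BLE001 - normalise loader failures
        raise FormatError(f"could not parse mesh file {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise FormatError(f"mesh file {path} contains no triangles")
    return mesh


def write_mesh(mesh: trimesh.Trimesh, path, ascii_stl: bool = False):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".stl" and ascii_stl:
        path.write_bytes(trimesh.exchange.stl.export_stl_ascii(mesh).encode())
    else:
        mesh.export(str(path))


def _volume_from_sitk(path: Path) -> CTVolume:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    # SimpleITK arrays come back (z, y, x); store (x, y, z)
    values = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return CTVolume(values, np.array(img.GetSpacing()), np.array(img.GetOrigin()))


def read_volume(path) -> CTVolume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) HU volume."""
    path = Path(path)
    name = path.name.lower()
    try:
        if name.endswith(_NIFTI_SUFFIXES):
            img = nib.load(str(path))
            values = np.asarray(img.dataobj, dtype=np.float32)
            affine = img.affine
            spacing = np.linalg.norm(affine[:3, :3], axis=0)
            origin = affine[:3, 3]
            return CTVolume(values, spacing, origin)
        if name.endswith(_META_SUFFIXES):
            return _volume_from_sitk(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"could not parse volume file {path}: {exc}") from exc
    raise FormatError(f"unsupported volume format: {path.name!r}")


def write_volume(volume: CTVolume, path):
    """Write a volume as NIfTI with spacing/origin in the affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*volume.spacing, 1.0])
    affine[:3, 3] = volume.origin
    nib.save(nib.Nifti1Image(volume.values.astype(np.float32), affine), str(path))


def write_mask(mask: LabelMask, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*mask.spacing, 1.0])
    affine[:3, 3] = mask.origin
    nib.save(nib.Nifti1Image(mask.values.astype(np.uint8), affine), str(path))


def read_landmarks(path) -> dict[str, np.ndarray]:
    """Landmark JSON: ``{name: [x, y, z]}`` in mm."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
        out = {}
        for key, value in raw.items():
            arr = np.asarray(value, dtype=float)
            if arr.shape != (3,):
                raise ValueError(f"landmark {key!r} is not a 3-vector")
            out[key] = arr
        return out
    except (json.JSONDecodeError, ValueError, TypeError) as exc:
        raise FormatError(f"could not parse landmark file {path}: {exc}") from exc


def write_landmarks(landmarks: dict, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {k: [float(x) for x in np.asarray(v, dtype=float)] for k, v in landmarks.items()}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_transform(path) -> RigidTransform:
    """Rigid transform from a row-major 4x4 JSON matrix."""
    path = Path(path)
    try:
        M = np.asarray(json.loads(path.read_text()), dtype=float).reshape(4, 4)
    except (json.JSONDecodeError, ValueError) as exc:
        raise FormatError(f"could not parse transform file {path}: {exc}") from exc
    return RigidTransform(M[:3, :3], M[:3, 3])


def write_transform(transform: RigidTransform, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(transform.matrix.tolist(), indent=2))


def write_csv(df: pd.DataFrame, path):
    """UTF-8 CSV with header row and stable float formatting."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6f", encoding="utf-8")


def write_json(payload, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
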