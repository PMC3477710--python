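"""NIfTI-1 round-trip I/O for label volumes and scalar/vector fields.

Label volumes are written as integer NIfTI with the voxel size in the
header and the label-code dictionary (plus head-center metadata) in a
sidecar JSON, since NIfTI itself has no label-map convention.  Fields are
float NIfTI with their units recorded in the header description.  All
phantom volumes use an identity-orientation affine scaled by the voxel
size, with 0-based voxel indices.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

from .phantoms import LabelVolume

_SIDECAR_SUFFIX = ".labels.json"


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + _SIDECAR_SUFFIX)
    return path.with_name(name + _SIDECAR_SUFFIX)


def write_label_volume(vol: LabelVolume, path: str | Path) -> Path:
    """Write labels as int16 NIfTI plus a sidecar JSON with the label codes."""
    path = Path(path)
    affine = np.diag([vol.voxel_mm, vol.voxel_mm, vol.voxel_mm, 1.0])
    img = nib.Nifti1Image(vol.labels.astype(np.int16), affine)
    img.header.set_zooms((vol.voxel_mm,) * 3)
    nib.save(img, path)
    sidecar = {
        "label_codes": vol.label_codes,
        "voxel_mm": vol.voxel_mm,
        "center_vox": list(vol.center_vox) if vol.center_vox is not None else None,
        "meta": _jsonable(vol.meta),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_label_volume(path: str | Path, sidecar: Optional[str | Path] = None) -> LabelVolume:
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"label sidecar {sidecar} not found (expected next to {path})"
        )
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed sidecar {sidecar}: {exc}") from exc
    for key in ("label_codes", "voxel_mm"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} is missing required key {key!r}")
    img = nib.load(path)
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0]):
        raise ValueError(f"{path}: anisotropic voxels are not supported ({zooms})")
    if abs(zooms[0] - meta["voxel_mm"]) > 1e-6:
        raise ValueError(
            f"{path}: header voxel size {zooms[0]} disagrees with sidecar "
            f"voxel_mm {meta['voxel_mm']}"
        )
    labels = np.asarray(img.dataobj).astype(np.int16)
    center = meta.get("center_vox")
    return LabelVolume(
        labels=labels,
        voxel_mm=float(meta["voxel_mm"]),
        label_codes={str(k): int(v) for k, v in meta["label_codes"].items()},
        center_vox=tuple(center) if center is not None else None,
        meta=meta.get("meta", {}),
    )


def write_field(
    data: np.ndarray, voxel_mm: float, path: str | Path, units: str = "V/m"
) -> Path:
    """Write a scalar (3-D) or vector (4-D, last axis components) field."""
    path = Path(path)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header.set_zooms((voxel_mm,) * min(3, data.ndim) + (1.0,) * max(0, data.ndim - 3))
    img.header["descrip"] = units.encode()[:79]
    nib.save(img, path)
    return path


def read_field(path: str | Path) -> tuple[np.ndarray, float, str]:
    """Read a field NIfTI; returns (data, voxel_mm, units)."""
    img = nib.load(Path(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    voxel_mm = float(img.header.get_zooms()[0])
    units = img.header["descrip"].tobytes().split(b"\x00")[0].decode()
    return data, voxel_mm, units


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
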