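"""Volume and table readers/writers.

NRRD and NIfTI files are handled through SimpleITK. Internally every grid is
a C-ordered numpy array indexed ``(i, j, k)`` corresponding to the image's
(x, y, z) axes; SimpleITK's (z, y, x) array convention is transposed away at
the boundary, and spacing/origin come from the file header (the header is
authoritative — an explicit override is required to replace it). Label-map
name tables travel as sidecar CSVs (``label,segment_name``); risk tables as
``segment_name,risk_score`` CSVs.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .errors import VolumeIOError
from .geometry import PathwayMask
from .risk import RiskTable
from .volume import LabeledVolume, RiskVolume, VolumeGeometry

_VOLUME_EXTS = (".nrrd", ".nhdr", ".nii", ".nii.gz")


def _check_ext(path: str) -> None:
    p = str(path).lower()
    if not p.endswith(_VOLUME_EXTS):
        raise VolumeIOError(
            f"unsupported volume format {path!r} (use {', '.join(_VOLUME_EXTS)})")


def _to_image(array: np.ndarray, spacing_mm, origin_mm) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(array.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing_mm))
    img.SetOrigin(tuple(float(o) for o in origin_mm))
    return img


def _from_image(img: sitk.Image):
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return arr, tuple(img.GetSpacing()), tuple(img.GetOrigin())


def names_sidecar_path(volume_path: str) -> str:
    base = str(volume_path)
    for ext in _VOLUME_EXTS:
        if base.lower().endswith(ext):
            base = base[: -len(ext)]
            break
    return base + ".names.csv"


def write_labeled_volume(volume: LabeledVolume, path: str,
                         write_names: bool = True) -> None:
    """Write an integer label map; the label->name table goes to a
    ``<stem>.names.csv`` sidecar."""
    _check_ext(path)
    sitk.WriteImage(
        _to_image(volume.labels.astype(np.int32), volume.spacing_mm,
                  volume.origin_mm),
        str(path),
    )
    if write_names and volume.names:
        pd.DataFrame(
            {"label": list(volume.names), "segment_name": list(volume.names.values())}
        ).to_csv(names_sidecar_path(path), index=False)


def read_labeled_volume(path: str, names_path: str | None = None,
                        spacing_override=None) -> LabeledVolume:
    """Load an integer label map (NRRD/NIfTI).

    Float-valued files are rejected. The name map is read from
    ``names_path`` or, when present, the default ``<stem>.names.csv``
    sidecar. ``spacing_override`` replaces the header spacing explicitly.
    """
    _check_ext(path)
    if not os.path.exists(path):
        raise VolumeIOError(f"no such file: {path}")
    arr, spacing, origin = _from_image(sitk.ReadImage(str(path)))
    if not np.issubdtype(arr.dtype, np.integer):
        raise VolumeIOError(
            f"label map must hold integers, got {arr.dtype} in {path!r}")
    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)
    names: dict[int, str] = {}
    sidecar = names_path or names_sidecar_path(path)
    if os.path.exists(sidecar):
        df = pd.read_csv(sidecar)
        names = {int(l): str(n) for l, n in zip(df["label"], df["segment_name"])}
    return LabeledVolume(arr, spacing, names, origin)


def write_risk_volume(risk: RiskVolume, path: str) -> None:
    """Write a float64 per-voxel risk field (round-trips bit-exactly)."""
    _check_ext(path)
    sitk.WriteImage(
        _to_image(risk.risk.astype(np.float64), risk.spacing_mm, risk.origin_mm),
        str(path),
    )


def read_risk_volume(path: str, spacing_override=None) -> RiskVolume:
    _check_ext(path)
    if not os.path.exists(path):
        raise VolumeIOError(f"no such file: {path}")
    arr, spacing, origin = _from_image(sitk.ReadImage(str(path)))
    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)
    return RiskVolume(np.asarray(arr, dtype=np.float64), spacing, origin)


def write_mask(mask: PathwayMask, geometry: VolumeGeometry, path: str) -> None:
    """Write a corridor mask as a binary (1 = member) volume."""
    _check_ext(path)
    sitk.WriteImage(
        _to_image(mask.to_array(geometry), geometry.spacing_mm,
                  geometry.origin_mm),
        str(path),
    )


def write_path_mask(nodes, geometry: VolumeGeometry, path: str) -> None:
    """Write an ordered voxel path as a binary volume."""
    _check_ext(path)
    arr = np.zeros(geometry.dims, dtype=np.uint8)
    for n in nodes:
        arr[tuple(int(c) for c in n)] = 1
    sitk.WriteImage(
        _to_image(arr, geometry.spacing_mm, geometry.origin_mm), str(path))


def read_mask_voxels(path: str) -> set:
    """Read a binary mask volume into a set of (i, j, k) member voxels."""
    _check_ext(path)
    if not os.path.exists(path):
        raise VolumeIOError(f"no such file: {path}")
    arr, _, _ = _from_image(sitk.ReadImage(str(path)))
    return set(map(tuple, np.argwhere(arr != 0).tolist()))


def write_risk_table(table: RiskTable, path: str) -> None:
    table.to_frame().to_csv(path, index=False)
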