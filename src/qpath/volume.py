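"""Voxel-grid containers.

All grids are indexed ``(i, j, k)`` with 0-based integer coordinates; the
physical position of a voxel centre is ``index * spacing_mm + origin_mm``.
Spacing is carried explicitly so anisotropic grids work everywhere distances
in millimetres matter (cylinder rasterisation, tube phantoms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidSpecError

Index = tuple[int, int, int]


def _as_triple(x, dtype=float) -> tuple:
    t = tuple(dtype(v) for v in np.atleast_1d(x).ravel())
    if len(t) == 1:
        t = t * 3
    if len(t) != 3:
        raise InvalidSpecError(f"expected 3 components, got {x!r}")
    return t


@dataclass(frozen=True)
class VolumeGeometry:
    """Shape, spacing and origin of a voxel grid.

    Parameters
    ----------
    dims : tuple of int
        Voxels per axis, each >= 1.
    spacing_mm : tuple of float
        Centre-to-centre voxel distance per axis, in mm, each > 0.
    origin_mm : tuple of float
        Physical position of voxel (0, 0, 0), in mm.
    """

    dims: tuple[int, int, int]
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "dims", _as_triple(self.dims, int))
        object.__setattr__(self, "spacing_mm", _as_triple(self.spacing_mm))
        object.__setattr__(self, "origin_mm", _as_triple(self.origin_mm))
        if any(d < 1 for d in self.dims):
            raise InvalidSpecError(f"dims must be >= 1, got {self.dims}")
        if any(s <= 0 for s in self.spacing_mm):
            raise InvalidSpecError(f"spacing must be > 0, got {self.spacing_mm}")

    def contains(self, idx) -> bool:
        return all(0 <= int(v) < d for v, d in zip(idx, self.dims))

    def voxel_centers_mm(self) -> np.ndarray:
        """(ni, nj, nk, 3) array of voxel-centre positions in mm."""
        grids = np.meshgrid(
            *(np.arange(d) * s + o for d, s, o in
              zip(self.dims, self.spacing_mm, self.origin_mm)),
            indexing="ij",
        )
        return np.stack(grids, axis=-1)


def voxel_count(geometry: VolumeGeometry) -> int:
    """Total number of voxels in a grid (the product of its dimensions)."""
    return int(np.prod([int(d) for d in geometry.dims]))


@dataclass
class LabeledVolume:
    """An integer label map plus the name of each label.

    Stands in for a parcellated (atlas-segmented) brain volume: every voxel
    carries exactly one integer label and ``names`` maps labels to segment
    names (label 0 may be reserved for background).
    """

    labels: np.ndarray
    spacing_mm: tuple[float, float, float]
    names: dict[int, str] = field(default_factory=dict)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise InvalidSpecError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise InvalidSpecError(f"labels must be integer, got {self.labels.dtype}")
        self.spacing_mm = _as_triple(self.spacing_mm)
        self.origin_mm = _as_triple(self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise InvalidSpecError(f"spacing must be > 0, got {self.spacing_mm}")
        self.names = {int(k): str(v) for k, v in self.names.items()}

    @property
    def geometry(self) -> VolumeGeometry:
        return VolumeGeometry(self.labels.shape, self.spacing_mm, self.origin_mm)

    def present_labels(self) -> np.ndarray:
        return np.unique(self.labels)

    def orphan_labels(self) -> list[int]:
        """Labels present in the grid but absent from the name map."""
        return [int(v) for v in self.present_labels() if int(v) not in self.names]


@dataclass
class RiskVolume:
    """Per-voxel penalty field in [0, 1].

    0 marks risk-free tissue, 1 marks structures the planner is penalised for
    crossing. This is the planner's cost field.
    """

    risk: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.risk = np.asarray(self.risk, dtype=np.float64)
        if self.risk.ndim != 3:
            raise InvalidSpecError("risk must be a 3D array")
        if self.risk.size and (self.risk.min() < 0.0 or self.risk.max() > 1.0):
            raise InvalidSpecError(
                f"risk values must lie in [0, 1], got range "
                f"[{self.risk.min():g}, {self.risk.max():g}]"
            )
        self.spacing_mm = _as_triple(self.spacing_mm)
        self.origin_mm = _as_triple(self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise InvalidSpecError(f"spacing must be > 0, got {self.spacing_mm}")

    @property
    def geometry(self) -> VolumeGeometry:
        return VolumeGeometry(self.risk.shape, self.spacing_mm, self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.risk.shape
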