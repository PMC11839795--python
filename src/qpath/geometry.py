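"""Cylindrical pathway rasterisation and path risk totals.

A hand-specified surgical corridor is modelled as a straight cylinder of
fixed diameter (default 4 mm) between an entry and a target point; the
voxelised corridor is the set of voxels whose centres lie within one radius
of the closed entry-target segment, measured in physical mm so anisotropic
spacings are handled. The corridor's total risk is the arithmetic sum of the
per-voxel risk over its (deduplicated) member voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BoundsError, GeometryError
from .volume import RiskVolume, VolumeGeometry

DEFAULT_DIAMETER_MM = 4.0  # 0.4 cm corridor


@dataclass
class PathwayMask:
    """A voxelised corridor: a set of (i, j, k) voxel indices."""

    voxels: frozenset
    diameter_mm: float
    entry_mm: tuple[float, float, float]
    target_mm: tuple[float, float, float]

    def __post_init__(self):
        self.voxels = frozenset(tuple(int(c) for c in v) for v in self.voxels)
        if not self.voxels:
            raise GeometryError("pathway mask is empty")
        if self.diameter_mm <= 0:
            raise GeometryError(f"diameter must be > 0, got {self.diameter_mm}")

    def __len__(self) -> int:
        return len(self.voxels)

    def to_array(self, geometry: VolumeGeometry) -> np.ndarray:
        """Binary uint8 grid (1 = member) for export."""
        arr = np.zeros(geometry.dims, dtype=np.uint8)
        idx = np.array(sorted(self.voxels))
        arr[idx[:, 0], idx[:, 1], idx[:, 2]] = 1
        return arr


def _point_segment_distance(points: np.ndarray, a: np.ndarray,
                            b: np.ndarray) -> np.ndarray:
    """Distance from each point (…, 3) to the closed segment a-b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=-1)
    t = np.clip(((points - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t[..., None] * ab
    return np.linalg.norm(points - proj, axis=-1)


def voxelize_cylinder(entry_mm, target_mm, diameter_mm: float,
                      geometry: VolumeGeometry) -> PathwayMask:
    """Rasterise a straight corridor of the given diameter.

    Membership is by voxel-centre distance to the closed entry-target
    segment (inclusive boundary, so flat end caps), computed in mm. The mask
    is clipped to the volume; a corridor entirely outside it is an error, as
    is a degenerate (entry == target) axis.
    """
    a = np.asarray(entry_mm, dtype=np.float64)
    b = np.asarray(target_mm, dtype=np.float64)
    if a.shape != (3,) or b.shape != (3,):
        raise GeometryError("entry and target must be 3-vectors (mm)")
    if np.array_equal(a, b):
        raise GeometryError("entry equals target: cylinder axis is degenerate")
    if diameter_mm <= 0:
        raise GeometryError(f"diameter must be > 0, got {diameter_mm}")
    radius = diameter_mm / 2.0
    spacing = np.asarray(geometry.spacing_mm)
    origin = np.asarray(geometry.origin_mm)
    dims = np.asarray(geometry.dims)

    # bounding box of the capsule, in voxel indices, clipped to the grid
    lo_mm = np.minimum(a, b) - radius
    hi_mm = np.maximum(a, b) + radius
    lo = np.maximum(np.floor((lo_mm - origin) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((hi_mm - origin) / spacing).astype(int) + 1, dims)
    if np.any(lo >= hi):
        raise GeometryError("cylinder lies entirely outside the volume")

    axes = [np.arange(l, h) for l, h in zip(lo, hi)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    centers = grid * spacing + origin
    dist = _point_segment_distance(centers, a, b)
    member = dist <= radius + 1e-12
    if not member.any():
        raise GeometryError("cylinder contains no voxel centers inside the volume")
    idx = grid[member]
    return PathwayMask(
        voxels=frozenset(map(tuple, idx.tolist())),
        diameter_mm=float(diameter_mm),
        entry_mm=tuple(a),
        target_mm=tuple(b),
    )


def path_total_risk(mask_or_path, risk: RiskVolume) -> float:
    """Sum of per-voxel risk over a corridor mask or an ordered voxel path.

    Voxels are counted once each (a self-overlapping corridor is still a set
    of coordinates). Accepts a :class:`PathwayMask`, a
    :class:`~qpath.planner.VoxelPath`, or any iterable of (i, j, k).
    """
    if isinstance(mask_or_path, PathwayMask):
        voxels = mask_or_path.voxels
    elif hasattr(mask_or_path, "nodes"):
        voxels = set(map(tuple, mask_or_path.nodes))
    else:
        voxels = set(tuple(int(c) for c in v) for v in mask_or_path)
    geom = risk.geometry
    total = 0.0
    for v in sorted(voxels):
        if not geom.contains(v):
            raise BoundsError(f"voxel {v} outside grid of shape {risk.shape}")
        total += float(risk.risk[v])
    return total
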